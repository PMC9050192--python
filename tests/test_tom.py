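"""Perspective taking, policy inference, action prediction, safety."""

import numpy as np
import pytest

from tomsnn.agents import TrainingConfig, scripted_policy
from tomsnn.gridworld import (
    ACTIONS,
    AgentState,
    GridWorld,
    generate_environment,
    observe,
    step_world,
)
from tomsnn.tom import (
    PerspectiveNetwork,
    ToMNetworks,
    bystander_step,
    collision_predicate,
    evaluate_safety,
    infer_behavior_style,
    infer_other_observation,
    predict_next_state,
    predict_other_action,
    style_reward,
    train_tom,
)


@pytest.fixture(scope="module")
def trained_tom():
    """ToM modules trained on scripted pedestrians (deterministic)."""
    return train_tom(TrainingConfig(episodes=200, rng_seed=5), policy_nets=None, window_length=20)


class TestPerspectiveTaking:
    def test_no_walls_matches_direct_observation(self):
        world = generate_environment(4, include_walls=False)
        net = PerspectiveNetwork()
        self_obs = observe(world, 0)
        inferred = infer_other_observation(net, self_obs, 1, world.agents[1].goal)
        direct = observe(world, 1)
        assert inferred.self_position == direct.self_position
        assert inferred.goal == direct.goal
        assert inferred.visible_agents == direct.visible_agents

    def test_agent_occluded_from_other_is_inhibited(self):
        # observer at (0,5) sees both; agent 2 is hidden from agent 1 by the wall
        world = GridWorld(
            frozenset({(3, 4)}),
            [
                AgentState((0, 5), (6, 6)),
                AgentState((3, 3), (0, 3)),
                AgentState((3, 5), (6, 5)),
            ],
        )
        self_obs = observe(world, 0)
        assert {1, 2} <= set(self_obs.visible_agents)
        inferred = infer_other_observation(PerspectiveNetwork(), self_obs, 1, world.agents[1].goal)
        assert 2 not in inferred.visible_agents

    def test_matches_direct_observation_oracle_when_knowledge_covers(self):
        """Whenever the observer sees everything the other can see, the
        inferred observation equals observe() from the other's seat."""
        checked = 0
        for seed in range(120):
            world = generate_environment(seed)
            self_obs = observe(world, 0)
            if 1 not in self_obs.visible_agents:
                continue
            direct = observe(world, 1)
            known = set(self_obs.visible_agents) | {0}
            if not set(direct.visible_agents) <= known:
                continue
            inferred = infer_other_observation(
                PerspectiveNetwork(), self_obs, 1, world.agents[1].goal
            )
            assert inferred.visible_agents == direct.visible_agents
            assert np.array_equal(inferred.visible_mask, direct.visible_mask)
            checked += 1
        assert checked >= 30

    def test_invisible_other_returns_cached_estimate(self):
        world = GridWorld(
            frozenset({(3, 3)}),
            [AgentState((3, 0), (0, 0)), AgentState((3, 6), (6, 6))],
        )
        net = PerspectiveNetwork()
        with pytest.raises(ValueError):
            infer_other_observation(net, observe(world, 0), 1, world.agents[1].goal)
        open_world = GridWorld(
            frozenset(),
            [AgentState((3, 0), (0, 0)), AgentState((3, 6), (6, 6))],
        )
        first = infer_other_observation(net, observe(open_world, 0), 1, (6, 6))
        # now occlude and ask again: the cached estimate comes back
        cached = infer_other_observation(net, observe(world, 0), 1, (6, 6))
        assert cached is first


class TestStyleReward:
    def test_correct_and_incorrect_values(self):
        assert style_reward("cautious", "cautious") == 1.0
        assert style_reward("cautious", "reckless") == -1.0

    def test_always_within_unit_interval(self):
        for a in ("reckless", "experienced", "cautious"):
            for b in ("reckless", "experienced", "cautious"):
                assert -1.0 <= style_reward(a, b) <= 1.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            style_reward("bold", "cautious")


class TestPredictNextState:
    def test_stay_and_wall_block(self):
        world = generate_environment(2)
        pos = world.agents[1].position
        assert predict_next_state(world, pos, "stay") == pos

    def test_equals_single_agent_step_world_everywhere(self):
        """Oracle equality over all cells x actions: predict_next_state
        matches step_world with every other agent holding still."""
        world = generate_environment(6)
        for r in range(7):
            for c in range(7):
                if (r, c) in world.walls:
                    continue
                for action in ACTIONS:
                    probe = GridWorld(
                        world.walls, [AgentState((r, c), (0, 0) if (0, 0) not in world.walls else (6, 6))]
                    )
                    stepped, _ = step_world(probe, {0: action})
                    assert (
                        predict_next_state(world, (r, c), action)
                        == stepped.agents[0].position
                    )


class TestStateEvaluation:
    def test_untrained_silent_network_defaults_to_safe(self):
        nets = ToMNetworks.fresh(np.random.default_rng(0), window_length=20)
        nets.state_evaluation.synapses.weights[:] = 0.0
        world = generate_environment(1)
        obs = observe(world, 1)
        assert evaluate_safety(nets.state_evaluation, obs) == "safe"

    def test_trained_classifier_matches_collision_predicate(self, trained_tom):
        """Post-training agreement with the collision predicate over an
        enumerated set of two-agent configurations is at least 90%."""
        from tomsnn.gridworld import GridObservation

        agree = total = 0
        for center in [(r, c) for r in range(1, 6) for c in range(1, 6)]:
            for dr, dc in [(0, 0), (0, 1), (1, 0), (1, 1), (0, 2), (2, 0), (2, 2)]:
                other = (center[0] + dr, center[1] + dc)
                if not (0 <= other[0] < 7 and 0 <= other[1] < 7):
                    continue
                state = GridObservation(
                    walls=frozenset(),
                    goal=(0, 0),
                    self_position=center,
                    visible_agents={2: other},
                    self_id=1,
                )
                want = "unsafe" if collision_predicate(state) else "safe"
                got = evaluate_safety(trained_tom.state_evaluation, state)
                agree += want == got
                total += 1
        assert agree / total >= 0.9

    def test_isolated_agent_judged_safe(self, trained_tom):
        from tomsnn.gridworld import GridObservation

        state = GridObservation(
            walls=frozenset(), goal=(0, 0), self_position=(3, 3), visible_agents={2: (0, 6)}, self_id=1
        )
        assert evaluate_safety(trained_tom.state_evaluation, state) == "safe"


class TestPolicyInference:
    def test_untrained_zero_network_keeps_previous_estimate(self):
        nets = ToMNetworks.fresh(np.random.default_rng(0), window_length=20)
        nets.policy_inference.synapses.weights[:] = 0.0
        bits = np.zeros(8, dtype=np.uint8)
        assert infer_behavior_style(nets.policy_inference, "cautious", bits) == "cautious"
        assert infer_behavior_style(nets.policy_inference, None, bits) is None

    def test_trained_classification_beats_chance(self, trained_tom):
        """Majority-vote style classification of scripted pedestrians on
        held-out episodes beats the 1/3 chance level."""
        from tomsnn.tom import _tom_chain

        rng = np.random.default_rng(999)
        correct = total = 0
        for _ in range(45):
            style = str(rng.choice(("reckless", "experienced", "cautious")))
            world = generate_environment(
                rng, n_agents=3, styles=["reckless", style, "reckless"]
            )
            trained_tom.reset_memory()
            votes = []
            for _ in range(10):
                if world.agents[1].done:
                    break
                self_obs = observe(world, 0)
                if 1 in self_obs.visible_agents:
                    estimate, _, _ = _tom_chain(trained_tom, world, self_obs, 1)
                    if estimate.style is not None:
                        votes.append(estimate.style)
                actions = {0: "stay"}
                for i in (1, 2):
                    if not world.agents[i].done:
                        actions[i] = scripted_policy(
                            world.agents[i].policy, observe(world, i)
                        )
                world, _ = step_world(world, actions)
            if votes:
                votes = votes[-5:]  # judgement settles as evidence accumulates
                majority = max(set(votes), key=votes.count)
                correct += majority == style
                total += 1
        assert total >= 30
        assert correct / total > 1 / 3


class TestActionPrediction:
    def test_sentinel_maps_to_stay(self):
        nets = ToMNetworks.fresh(np.random.default_rng(0), window_length=20)
        nets.action_prediction.synapses.weights[:] = 0.0
        world = generate_environment(3, include_walls=False)
        obs_hat = infer_other_observation(
            nets.perspective, observe(world, 0), 1, world.agents[1].goal
        )
        assert predict_other_action(nets.action_prediction, obs_hat, "reckless") == "stay"

    def test_trained_prediction_beats_chance_on_scripted_reckless(self, trained_tom):
        """Next-action accuracy on held-out scripted-reckless states
        clearly exceeds the 1/5 chance level."""
        rng = np.random.default_rng(321)
        correct = total = 0
        for _ in range(40):
            world = generate_environment(rng, n_agents=2, styles=["reckless", "reckless"])
            self_obs = observe(world, 0)
            if 1 not in self_obs.visible_agents:
                continue
            obs_hat = infer_other_observation(
                trained_tom.perspective, self_obs, 1, world.agents[1].goal
            )
            predicted = predict_other_action(trained_tom.action_prediction, obs_hat, "reckless")
            actual = scripted_policy("reckless", observe(world, 1))
            correct += predicted == actual
            total += 1
        assert total >= 25
        assert correct / total > 1 / 5


class TestBystander:
    def test_help_triggered_iff_some_estimate_unsafe(self, trained_tom, rng):
        # two pedestrians about to collide right next to the bystander
        world = GridWorld(
            frozenset(),
            [
                AgentState((1, 2), (0, 0), policy="reckless"),
                AgentState((3, 2), (3, 4), policy="reckless"),
                AgentState((3, 4), (3, 2), policy="reckless"),
            ],
        )
        from tomsnn.agents import DecisionNetwork

        decision = DecisionNetwork.fresh(np.random.default_rng(1), window_length=20)
        action, helped, estimates = bystander_step(trained_tom, decision, world, 0, rng)
        if helped is not None:
            assert action == "stay"
            helped_estimate = next(e for e in estimates if e.agent_id == helped)
            assert helped_estimate.safety == "unsafe"

    def test_all_safe_means_no_help(self, trained_tom, rng):
        world = GridWorld(
            frozenset(),
            [
                AgentState((0, 0), (0, 6), policy="reckless"),
                AgentState((6, 0), (6, 3), policy="reckless"),
                AgentState((3, 6), (0, 6), policy="reckless"),
            ],
        )
        from tomsnn.agents import DecisionNetwork

        decision = DecisionNetwork.fresh(np.random.default_rng(1), window_length=20)
        action, helped, estimates = bystander_step(trained_tom, decision, world, 0, rng)
        if all(e.safety == "safe" for e in estimates):
            assert helped is None

    def test_estimate_consistency_predicted_state_from_action(self, trained_tom, rng):
        for seed in range(5):
            world = generate_environment(seed)
            _, _, estimates = bystander_step(
                trained_tom,
                __import__("tomsnn.agents", fromlist=["DecisionNetwork"]).DecisionNetwork.fresh(
                    np.random.default_rng(1), window_length=20
                ),
                world,
                0,
                rng,
            )
            self_obs = observe(world, 0)
            for e in estimates:
                assert e.predicted_state == predict_next_state(
                    world, self_obs.visible_agents[e.agent_id], e.predicted_action
                )


class TestTrainToM:
    def test_fixed_seed_bit_identical_networks(self):
        a = train_tom(TrainingConfig(episodes=4, rng_seed=5), window_length=10)
        b = train_tom(TrainingConfig(episodes=4, rng_seed=5), window_length=10)
        for x, y in (
            (a.policy_inference, b.policy_inference),
            (a.action_prediction, b.action_prediction),
            (a.state_evaluation, b.state_evaluation),
        ):
            assert np.array_equal(x.synapses.weights, y.synapses.weights)

    def test_all_trainable_weights_stay_bounded(self, trained_tom):
        for net in (
            trained_tom.policy_inference,
            trained_tom.action_prediction,
            trained_tom.state_evaluation,
        ):
            assert np.abs(net.synapses.weights).max() <= 1.0

    def test_action_prediction_improves_over_untrained(self, trained_tom):
        """Average action-match reward on held-out scripted episodes is
        higher after training than before."""
        rng_states = [np.random.default_rng(77), np.random.default_rng(77)]
        fresh = ToMNetworks.fresh(np.random.default_rng(0), window_length=20)

        def mean_e_action(nets, rng):
            total = []
            for _ in range(25):
                world = generate_environment(rng, n_agents=2, styles=["reckless", "reckless"])
                self_obs = observe(world, 0)
                if 1 not in self_obs.visible_agents:
                    continue
                obs_hat = infer_other_observation(
                    nets.perspective, self_obs, 1, world.agents[1].goal
                )
                predicted = predict_other_action(nets.action_prediction, obs_hat, "reckless")
                actual = scripted_policy("reckless", observe(world, 1))
                total.append(1.0 if predicted == actual else -1.0)
            return np.mean(total)

        assert mean_e_action(trained_tom, rng_states[0]) > mean_e_action(fresh, rng_states[1])
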