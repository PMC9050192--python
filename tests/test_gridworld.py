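"""Environment generation, occlusion, dynamics, and the reward functions."""

import numpy as np
import pytest

from tomsnn.gridworld import (
    ACTIONS,
    AgentState,
    GridWorld,
    Transition,
    bfs_distances,
    compute_reward,
    generate_environment,
    observe,
    step_world,
    visible_cells,
    wall_distance,
)


def liang_barsky_blocked(a, b, wall):
    """Independent line-of-sight oracle: segment/AABB overlap via
    parametric clipping in doubled-integer coordinates."""
    x0, y0 = 2 * a[1] + 1, 2 * a[0] + 1
    x1, y1 = 2 * b[1] + 1, 2 * b[0] + 1
    xmin, xmax = 2 * wall[1], 2 * wall[1] + 2
    ymin, ymax = 2 * wall[0], 2 * wall[0] + 2
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - xmin),
        (dx, xmax - x0),
        (-dy, y0 - ymin),
        (dy, ymax - y0),
    ):
        if p == 0:
            if q < 0:
                return False
        else:
            t = q / p
            if p < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
            if t0 > t1:
                return False
    return True


class TestGeneration:
    def test_same_seed_identical_environment(self):
        a = generate_environment(42)
        b = generate_environment(42)
        assert a.walls == b.walls
        assert [x.position for x in a.agents] == [x.position for x in b.agents]
        assert [x.goal for x in a.agents] == [x.goal for x in b.agents]

    def test_many_seeds_valid_and_reachable(self):
        for seed in range(300):
            world = generate_environment(seed)
            starts = {a.position for a in world.agents}
            goals = {a.goal for a in world.agents}
            assert len(starts) == 3 and len(goals) == 3
            assert not (starts | goals) & world.walls
            assert not starts & goals
            assert 2 <= len(world.walls) <= 4
            for a in world.agents:
                assert a.goal in bfs_distances(world.walls, a.position)

    def test_three_agents_with_distinct_goals(self):
        world = generate_environment(7)
        assert world.n_agents == 3
        assert len({a.goal for a in world.agents}) == 3


class TestVisibility:
    def test_no_walls_everything_visible(self):
        world = GridWorld(frozenset(), [AgentState((0, 0), (6, 6))])
        assert visible_cells(world, (0, 0)).all()

    def test_viewpoint_always_visible(self):
        for seed in range(20):
            world = generate_environment(seed)
            for r in range(7):
                for c in range(7):
                    if (r, c) not in world.walls:
                        assert visible_cells(world, (r, c))[r, c]

    def test_wall_directly_between_blocks(self):
        world = GridWorld(frozenset({(3, 3)}), [AgentState((3, 0), (0, 0))])
        mask = visible_cells(world, (3, 0))
        assert not mask[3, 6]
        assert mask[3, 2]  # in front of the wall

    def test_matches_independent_ray_oracle(self):
        for seed in range(15):
            world = generate_environment(seed)
            viewpoint = world.agents[0].position
            mask = visible_cells(world, viewpoint)
            for r in range(7):
                for c in range(7):
                    target = (r, c)
                    expected = not any(
                        w not in (viewpoint, target)
                        and liang_barsky_blocked(viewpoint, target, w)
                        for w in world.walls
                    )
                    assert mask[r, c] == expected, (seed, viewpoint, target)

    def test_visibility_symmetric(self):
        for seed in range(15):
            world = generate_environment(seed)
            cells = [(r, c) for r in range(7) for c in range(7) if (r, c) not in world.walls]
            masks = {cell: visible_cells(world, cell) for cell in cells}
            for a in cells:
                for b in cells:
                    assert masks[a][b] == masks[b][a]

    def test_off_grid_viewpoint_rejected(self):
        world = generate_environment(0)
        with pytest.raises(ValueError):
            visible_cells(world, (7, 3))


class TestObserve:
    def test_occluded_agent_absent(self):
        walls = frozenset({(3, 3)})
        world = GridWorld(
            walls,
            [AgentState((3, 0), (0, 0)), AgentState((3, 6), (6, 6))],
        )
        obs = observe(world, 0)
        assert 1 not in obs.visible_agents

    def test_no_walls_all_other_agents_listed(self):
        world = generate_environment(3, include_walls=False)
        obs = observe(world, 0)
        assert set(obs.visible_agents) == {1, 2}

    def test_unknown_agent_rejected(self):
        with pytest.raises(ValueError):
            observe(generate_environment(0), 5)


class TestStepWorld:
    def test_all_stay_no_change_no_collision(self, open_world):
        new, trs = step_world(open_world, {0: "stay", 1: "stay"})
        assert [a.position for a in new.agents] == [a.position for a in open_world.agents]
        assert not any(t.collided for t in trs.values())

    def test_two_agents_into_same_cell_both_collide(self):
        world = GridWorld(
            frozenset(),
            [AgentState((3, 2), (0, 0)), AgentState((3, 4), (6, 6))],
        )
        _, trs = step_world(world, {0: "right", 1: "left"})
        assert trs[0].collided_agent and trs[1].collided_agent

    def test_swap_counts_as_collision(self):
        world = GridWorld(
            frozenset(),
            [AgentState((3, 2), (0, 0)), AgentState((3, 3), (6, 6))],
        )
        _, trs = step_world(world, {0: "right", 1: "left"})
        assert trs[0].collided_agent and trs[1].collided_agent

    def test_wall_bump_blocks_and_flags(self):
        world = GridWorld(frozenset({(3, 3)}), [AgentState((3, 2), (0, 0))])
        new, trs = step_world(world, {0: "right"})
        assert new.agents[0].position == (3, 2)
        assert trs[0].collided and not trs[0].collided_agent

    def test_goal_reach_marks_done_and_leaves_grid(self):
        world = GridWorld(frozenset(), [AgentState((3, 5), (3, 6)), AgentState((0, 0), (6, 6))])
        new, _ = step_world(world, {0: "right", 1: "stay"})
        assert new.agents[0].done
        assert 0 not in new.active_positions()
        # done agents never move afterwards
        newer, _ = step_world(new, {1: "down"})
        assert newer.agents[0].position == (3, 6)

    def test_agent_count_conserved(self):
        world = generate_environment(11)
        new, _ = step_world(world, {i: "stay" for i in range(3)})
        assert new.n_agents == 3


class TestRewards:
    def test_reckless_fractional_progress(self):
        tr = Transition(dp_prev=2.0, dp_now=1.0, dw_prev=5.0, dw_now=5.0)
        assert compute_reward("reckless", tr) == pytest.approx(0.5)

    def test_reckless_stay_zero(self):
        tr = Transition(dp_prev=3.0, dp_now=3.0, dw_prev=5.0, dw_now=5.0)
        assert compute_reward("reckless", tr) == 0.0

    def test_experienced_collision_penalty(self):
        tr = Transition(dp_prev=2.0, dp_now=1.0, dw_prev=5.0, dw_now=5.0, collided=True)
        assert compute_reward("experienced", tr) == -5.0

    def test_cautious_wall_proximity_and_collision_penalties(self):
        near_wall = Transition(dp_prev=2.0, dp_now=1.0, dw_prev=1.0, dw_now=2.0)
        assert compute_reward("cautious", near_wall) == -5.0
        collided = Transition(dp_prev=2.0, dp_now=1.0, dw_prev=3.0, dw_now=3.0, collided=True)
        assert compute_reward("cautious", collided) == -5.0

    def test_cautious_combines_progress_and_wall_terms(self):
        tr = Transition(dp_prev=4.0, dp_now=3.0, dw_prev=2.0, dw_now=3.0)
        assert compute_reward("cautious", tr) == pytest.approx(0.25 + 0.5)

    def test_reckless_bounded_above_by_one_and_sign(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            dp_prev = rng.uniform(0.5, 8)
            dp_now = rng.uniform(0, 8)
            r = compute_reward(
                "reckless", Transition(dp_prev, dp_now, 5.0, 5.0)
            )
            assert r <= 1.0
            assert (r > 0) == (dp_now < dp_prev)

    def test_zero_dp_prev_off_goal_rejected(self):
        with pytest.raises(ValueError):
            compute_reward("reckless", Transition(0.0, 1.0, 5.0, 5.0))

    def test_wall_distance_no_walls_is_infinite(self):
        assert wall_distance(frozenset(), (3, 3)) == np.inf
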