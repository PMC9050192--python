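"""Decision module (R-STDP trained policy network) and scripted policies.

The decision network is a two-layer spiking network mapping the encoded
observation (588 channels) onto 5 action populations of 6 neurons.  One
decision takes one simulation window: the encoder drives the input layer,
the LIF output layer accumulates spikes, and the population with the most
spikes (after lateral inhibition) is the chosen action.

Training is reward-modulated STDP.  During a window the synapses build a
nearest-neighbour STDP eligibility trace between the input raster and the
output raster; the environment's scalar reward for the executed action
then converts the trace into a weight change (dw = eta * e * r, clipped
to [-1, 1]).  Exploration is epsilon-greedy with linear decay; when an
explored action differs from the network's own choice, the executed
action's population is clamped to fire in the credited raster (an
efference copy), so the reward always modifies the synapses of the
action that was actually taken.

Scripted policies (pure BFS greedy rules, one per behaviour style) are
provided as deterministic stand-ins for trained networks, mainly to give
the theory-of-mind modules exactly reproducible agents in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coding
from .coding import LateralInhibitionConfig, encode_observation
from .gridworld import (
    ACTIONS,
    STYLES,
    GridObservation,
    GridWorld,
    apply_move,
    bfs_distances,
    compute_reward,
    generate_environment,
    observe,
    step_world,
    wall_distance,
)
from .plasticity import SynapseMatrix, apply_reward, window_trace
from .snn_core import (
    NeuronParams,
    PopulationPartition,
    SpikeRaster,
    WindowConfig,
    forward_window,
)

__all__ = [
    "ACTION_PARTITION",
    "DecisionNetwork",
    "ShortTermState",
    "TrainingConfig",
    "GridObservation",
    "act",
    "excitability_ladder",
    "train_decision_module",
    "scripted_policy",
]

ACTION_PARTITION = PopulationPartition(5, 6, ACTIONS)

#: default membrane drive per unit synaptic weight; high enough that one
#: fully potentiated synapse (w = 1) lifts its target above threshold
#: within a short window, even after divisive normalisation over a
#: typical handful of active channels
DEFAULT_GAIN = 60.0

#: default R-STDP learning rate for decision networks
DECISION_ETA = 0.1

#: short-term depression constants used while training (milder than the
#: behaving defaults so the trace reflects most of the stimulus)
TRAIN_STP_U = 0.15
TRAIN_STP_RECOVERY = 0.3


def excitability_ladder(partition: PopulationPartition, spread: float = 0.4) -> np.ndarray:
    """Fixed heterogeneous per-neuron gain, graded within each population.

    Neuron k of every J-neuron population gets gain 1 - spread/2 +
    spread*k/(J-1), so the population's spike count rises smoothly (and
    still monotonically) with its input current instead of jumping in
    steps of J.
    """
    j = partition.neurons_per_population
    if j == 1:
        ladder = np.ones(1)
    else:
        ladder = 1.0 - spread / 2 + spread * np.arange(j) / (j - 1)
    return np.tile(ladder, partition.population_count)


@dataclass
class DecisionNetwork:
    """Policy network: 588 encoded channels -> 5 action populations."""

    synapses: SynapseMatrix
    partition: PopulationPartition = ACTION_PARTITION
    window: WindowConfig = field(default_factory=WindowConfig)
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    gain: float = DEFAULT_GAIN
    inhibition: LateralInhibitionConfig = field(default_factory=LateralInhibitionConfig)
    style: str | None = None

    def __post_init__(self) -> None:
        expected = (self.partition.n_neurons, coding.N_OBS_CHANNELS)
        if self.synapses.weights.shape != expected:
            raise ValueError(f"decision network weights must be {expected}")

    @property
    def neuron_gain(self) -> np.ndarray:
        return excitability_ladder(self.partition)

    @classmethod
    def fresh(
        cls,
        rng: np.random.Generator,
        window_length: int = 50,
        style: str | None = None,
        eta: float = DECISION_ETA,
        **kwargs,
    ) -> "DecisionNetwork":
        syn = SynapseMatrix.random_init(
            ACTION_PARTITION.n_neurons, coding.N_OBS_CHANNELS, rng, learning_rate=eta
        )
        return cls(syn, window=WindowConfig(window_length), style=style, **kwargs)


@dataclass(frozen=True)
class TrainingConfig:
    """Episode budget and exploration schedule for R-STDP training."""

    episodes: int = 300
    exploration_epsilon: float = 1.0
    epsilon_min: float = 0.05
    epsilon_decay: float = 1.0  # fraction of episodes over which epsilon anneals
    rng_seed: int = 0
    step_cap: int = 30

    def __post_init__(self) -> None:
        if self.episodes < 0:
            raise ValueError("episodes must be >= 0")
        if not 0 <= self.exploration_epsilon <= 1:
            raise ValueError("exploration_epsilon must be in [0, 1]")
        if not 0 < self.epsilon_decay <= 1:
            raise ValueError("epsilon_decay must be in (0, 1]")

    def epsilon_at(self, episode: int) -> float:
        horizon = max(1, int(self.episodes * self.epsilon_decay))
        frac = min(1.0, episode / horizon)
        return max(
            self.epsilon_min,
            self.exploration_epsilon
            + frac * (self.epsilon_min - self.exploration_epsilon),
        )


#: membrane current noise at decision time (mV-equivalent); zero-mean
#: Gaussian noise randomises near-tie decisions while leaving strong
#: preferences intact, and breaks the limit cycles a fully deterministic
#: policy can fall into
DECISION_NOISE_STD = 2.0


@dataclass
class ShortTermState:
    """Short-term synaptic depression state of one agent's input drive.

    Input channels that stay active over consecutive decision windows
    depress (release fraction ``u`` per window) and recover between
    uses.  While the agent makes progress its active channel set turns
    over every step, so depression never builds; when the agent is
    stuck in a repeating configuration the same channels depress until
    the decision collapses to a near-tie or silence, at which point
    noise or the random fallback breaks the loop.  State is per agent
    and per episode.
    """

    efficacy: np.ndarray | None = None
    u: float = 0.3
    recovery: float = 0.15

    def release_probability(self, n_channels: int) -> np.ndarray:
        if self.efficacy is None:
            self.efficacy = np.ones(n_channels)
        return self.efficacy

    def update(self, active_channels: np.ndarray) -> None:
        """Recover all synapses, then depress the ones used this window."""
        if self.efficacy is None:
            self.efficacy = np.ones(active_channels.shape[0])
        self.efficacy += self.recovery * (1.0 - self.efficacy)
        self.efficacy[active_channels.astype(bool)] *= 1.0 - self.u


def _decide(
    net: DecisionNetwork,
    stimulus,
    rng: np.random.Generator | None = None,
    stp: ShortTermState | None = None,
) -> tuple[str | None, SpikeRaster, SpikeRaster]:
    """Forward pass for one decision window.

    Returns (winning action or None, input raster, output raster).  With
    ``rng`` the output layer receives seeded membrane noise; with
    ``stp`` the input drive passes through short-term depression (state
    updated here).
    """
    T = net.window.window_length
    if stp is not None and rng is not None:
        p = stp.release_probability(stimulus.active_channels.shape[0])
        in_raster = stimulus.to_raster(T, efficacy=p, rng=rng)
        stp.update(stimulus.active_channels)
    else:
        in_raster = stimulus.to_raster(T)
    out_raster = forward_window(
        net.synapses.weights,
        in_raster,
        net.window,
        params=net.neuron_params,
        gain=net.gain,
        normalize_input=True,
        neuron_gain=net.neuron_gain,
        noise_std=DECISION_NOISE_STD if rng is not None else 0.0,
        rng=rng,
    )
    action = coding.decode_output(out_raster, net.partition, net.inhibition)
    return action, in_raster, out_raster


def act(
    net: DecisionNetwork,
    obs: GridObservation,
    explore: bool = False,
    rng: np.random.Generator | None = None,
    epsilon: float = 0.05,
    stp: ShortTermState | None = None,
) -> str:
    """Choose an action for one observation.

    With ``explore`` the network's choice is replaced by a uniform random
    action with probability ``epsilon``.  A silent network (no-output
    sentinel) falls back to a uniform random action, or ``stay`` when no
    generator is supplied.  ``stp`` carries the acting agent's
    short-term depression state across the episode.
    """
    stimulus = encode_observation(obs)
    action, _, _ = _decide(net, stimulus, rng=rng, stp=stp)
    if action is None:
        action = str(rng.choice(ACTIONS)) if rng is not None else "stay"
    if explore and rng is not None and rng.random() < epsilon:
        action = str(rng.choice(ACTIONS))
    return action


def _credit_raster(
    out_raster: SpikeRaster, partition: PopulationPartition, action: str
) -> SpikeRaster:
    """Efference copy: clamp the executed action's population to fire."""
    spikes = out_raster.spikes.copy()
    spikes[partition.neuron_slice(partition.labels.index(action)), :] = 1
    return SpikeRaster(spikes, dt=out_raster.dt)


def _training_world(style: str, rng: np.random.Generator) -> GridWorld:
    """Random training environment for one policy style.

    The trainee is agent 0.  The collision-sensitive styles (experienced,
    cautious) train alongside one scripted reckless opponent so that
    agent collisions actually occur; the reckless style trains alone.
    """
    if style == "reckless":
        return generate_environment(rng, n_agents=1, styles=[style])
    return generate_environment(rng, n_agents=2, styles=[style, "reckless"])


def train_decision_module(
    policy: str,
    cfg: TrainingConfig,
    window_length: int = 50,
    eta: float = DECISION_ETA,
    gain: float = DEFAULT_GAIN,
    env_factory=None,
) -> tuple[DecisionNetwork, pd.DataFrame]:
    """Train one behaviour style's decision network with R-STDP.

    Each episode draws a fresh random environment (or one from
    ``env_factory(rng)``); each step runs one decision window, executes
    the (possibly explored) action, computes the style's reward, and
    applies the reward-modulated trace update.  Returns the trained
    network and a per-episode training log.
    """
    if policy not in STYLES:
        raise ValueError(f"unknown policy style {policy!r}")
    rng = np.random.default_rng(cfg.rng_seed)
    net = DecisionNetwork.fresh(rng, window_length=window_length, style=policy, eta=eta, gain=gain)
    log: list[dict] = []
    for episode in range(cfg.episodes):
        world = _training_world(policy, rng) if env_factory is None else env_factory(rng)
        epsilon = cfg.epsilon_at(episode)
        total_reward = 0.0
        steps = 0
        # milder depression during plasticity: enough drive variability to
        # decorrelate repeated stimuli, while the eligibility trace still
        # sees most of the stimulus
        stp = ShortTermState(u=TRAIN_STP_U, recovery=TRAIN_STP_RECOVERY)
        for _ in range(cfg.step_cap):
            if world.agents[0].done:
                break
            obs = observe(world, 0)
            stimulus = encode_observation(obs)
            action, in_raster, out_raster = _decide(net, stimulus, rng=rng, stp=stp)
            if action is None or rng.random() < epsilon:
                action = str(rng.choice(ACTIONS))
            actions = {0: action}
            for i, agent in enumerate(world.agents[1:], start=1):
                if not agent.done:
                    actions[i] = scripted_policy(agent.policy, observe(world, i))
            world, transitions = step_world(world, actions)
            reward = compute_reward(policy, transitions[0])
            window_trace(net.synapses, in_raster, _credit_raster(out_raster, net.partition, action))
            apply_reward(net.synapses, reward)
            total_reward += reward
            steps += 1
        log.append(
            {
                "episode": episode,
                "steps": steps,
                "total_reward": total_reward,
                "reached_goal": world.agents[0].done,
                "epsilon": epsilon,
            }
        )
    return net, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# scripted oracle policies

def _candidate_moves(obs: GridObservation) -> dict:
    return {a: apply_move(obs.walls, obs.self_position, a, obs.size) for a in ACTIONS}


def scripted_policy(style: str, obs: GridObservation, rng=None) -> str:
    """Deterministic greedy policy matching one behaviour style.

    reckless: BFS-greedy toward the goal, ignoring agents.
    experienced: BFS-greedy, but never steps onto a visible agent's cell.
    cautious: maximises goal progress plus change in wall clearance.
    Ties break in fixed action order (up, down, left, right, stay).
    """
    if style not in STYLES:
        raise ValueError(f"unknown behaviour style {style!r}")
    dist = bfs_distances(obs.walls, obs.goal, obs.size)
    moves = _candidate_moves(obs)
    occupied = set(obs.visible_agents.values())

    def goal_dist(cell):
        return dist.get(cell, np.inf)

    if style == "reckless":
        return min(ACTIONS, key=lambda a: (goal_dist(moves[a]), ACTIONS.index(a)))
    if style == "experienced":
        allowed = [a for a in ACTIONS if moves[a] not in occupied]
        if not allowed:
            return "stay"
        return min(allowed, key=lambda a: (goal_dist(moves[a]), ACTIONS.index(a)))
    # cautious: goal progress plus wall-clearance change, shunning agents
    d_prev = goal_dist(obs.self_position)
    dw_prev = wall_distance(obs.walls, obs.self_position)

    def score(a):
        cell = moves[a]
        if cell in occupied:
            return -np.inf
        progress = 0.0
        if np.isfinite(d_prev) and d_prev > 0:
            progress = (d_prev - goal_dist(cell)) / d_prev
        wall_term = 0.0
        dw_new = wall_distance(obs.walls, cell)
        if np.isfinite(dw_prev) and dw_prev > 0:
            wall_term = (min(dw_new, obs.size) - dw_prev) / dw_prev
        return progress + wall_term

    return max(ACTIONS, key=lambda a: (score(a), -ACTIONS.index(a)))
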