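"""Evaluation protocol: performance scores and the with/without-ToM study.

Every agent starts an episode with a score budget of ``R_base = 50``
points.  Reaching the goal in ``t`` steps costs ``C_time * t = 3t``
points, a collision costs ``L_collision = 40``, and having spent a step
helping someone costs the bystander ``L_help = 10``; the final score is
floored at zero:

    P = max(R_base - C_time * t - L_collision - L_help, 0)

The benchmark runs 100 randomized 7x7 environments per condition.  Three
agents take part: the bystander (agent 0) and pedestrian 1 (agent 1)
always use the reckless policy; pedestrian 2 (agent 2) uses the
condition's policy (reckless, experienced, or cautious).  With the ToM
model enabled the bystander runs the full inference chain each step and
stops a pedestrian it judges unsafe; without it, the bystander simply
pursues its own goal.  Paired-seed comparisons of the two conditions
measure how much the ToM model reduces collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import (
    DecisionNetwork,
    ShortTermState,
    TrainingConfig,
    act,
    train_decision_module,
)
from .gridworld import STYLES, generate_environment, observe, step_world
from .tom import ToMNetworks, bystander_step, train_tom

__all__ = [
    "ScoreParams",
    "AgentOutcome",
    "EpisodeResult",
    "ConditionSummary",
    "TrainedSystem",
    "performance_score",
    "train_full_system",
    "run_condition",
    "summarize",
    "compare_conditions",
]

STEP_CAP = 30
HISTOGRAM_EDGES = tuple(range(0, 55, 5))


@dataclass(frozen=True)
class ScoreParams:
    """Constants of the performance score."""

    r_base: float = 50.0
    c_time: float = 3.0
    l_collision: float = 40.0
    l_help: float = 10.0

    def __post_init__(self) -> None:
        if min(self.r_base, self.c_time, self.l_collision, self.l_help) < 0:
            raise ValueError("score constants must be non-negative")


def performance_score(
    t: int, collided: bool, helped: bool, p: ScoreParams | None = None
) -> float:
    """Episode score: base minus time, collision, and help costs, floored at 0."""
    if t < 0:
        raise ValueError("steps must be non-negative")
    p = p or ScoreParams()
    raw = p.r_base - p.c_time * t - p.l_collision * bool(collided) - p.l_help * bool(helped)
    return max(raw, 0.0)


@dataclass
class AgentOutcome:
    """One agent's episode bookkeeping."""

    steps: int
    collided: bool
    helped: bool
    score: float


@dataclass
class EpisodeResult:
    """Per-agent outcomes for one randomized episode."""

    seed: int
    outcomes: dict  # agent id -> AgentOutcome
    help_events: int = 0
    helped_agents: frozenset = frozenset()

    def score_of(self, agent_id: int) -> float:
        return self.outcomes[agent_id].score


@dataclass
class ConditionSummary:
    """Score statistics for one agent over one condition's episodes."""

    n: int
    mean: float
    std: float
    min: float
    collisions: int
    histogram: np.ndarray
    bin_edges: tuple = HISTOGRAM_EDGES


@dataclass
class TrainedSystem:
    """Everything the benchmark needs: three policies plus ToM modules."""

    policies: dict  # style -> DecisionNetwork
    tom: ToMNetworks
    score_params: ScoreParams = field(default_factory=ScoreParams)


def train_full_system(
    seed: int,
    policy_episodes: int = 1500,
    tom_episodes: int = 300,
    window_length: int = 20,
) -> TrainedSystem:
    """Train the three policy networks and the ToM modules from scratch.

    The master seed fans out to one child seed per component so each can
    be reproduced independently.
    """
    children = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    policies = {}
    for style, child in zip(STYLES, children[:3]):
        cfg = TrainingConfig(episodes=policy_episodes, rng_seed=int(child), epsilon_min=0.1)
        net, _ = train_decision_module(style, cfg, window_length=window_length)
        policies[style] = net
    tom_cfg = TrainingConfig(episodes=tom_episodes, rng_seed=int(children[3]))
    tom_nets = train_tom(tom_cfg, policy_nets=policies, window_length=window_length)
    return TrainedSystem(policies=policies, tom=tom_nets)


def _episode(
    system: TrainedSystem,
    pedestrian2_style: str,
    with_tom: bool,
    env_seed: int,
) -> EpisodeResult:
    """One evaluation episode on the environment drawn from ``env_seed``."""
    styles = ["reckless", "reckless", pedestrian2_style]
    world = generate_environment(int(env_seed), n_agents=3, styles=styles)
    rng = np.random.default_rng(int(env_seed) + 1)
    system.tom.reset_memory()
    steps_done = {i: STEP_CAP for i in range(3)}
    collided = {i: False for i in range(3)}
    stp = {i: ShortTermState() for i in range(3)}
    bystander_helped = False
    help_events = 0
    helped_agents: set = set()
    for step in range(STEP_CAP):
        if all(a.done for a in world.agents):
            break
        actions = {}
        helped_ped = None
        if with_tom and not world.agents[0].done:
            b_action, helped_ped, _ = bystander_step(
                system.tom,
                system.policies["reckless"],
                world,
                bystander_id=0,
                rng=rng,
                stp=stp[0],
            )
            actions[0] = b_action
            if helped_ped is not None:
                bystander_helped = True
                help_events += 1
                helped_agents.add(helped_ped)
        elif not world.agents[0].done:
            actions[0] = act(system.policies["reckless"], observe(world, 0), rng=rng, stp=stp[0])
        for i in (1, 2):
            if not world.agents[i].done:
                style = world.agents[i].policy
                actions[i] = act(system.policies[style], observe(world, i), rng=rng, stp=stp[i])
        if helped_ped is not None and helped_ped in actions:
            actions[helped_ped] = "stay"
        world, transitions = step_world(world, actions)
        for i, tr in transitions.items():
            if tr.collided_agent:
                collided[i] = True  # only agent-agent contact is scored
            if world.agents[i].done and steps_done[i] == STEP_CAP:
                steps_done[i] = step + 1
    outcomes = {
        i: AgentOutcome(
            steps=steps_done[i],
            collided=collided[i],
            helped=bystander_helped and i == 0,
            score=performance_score(
                steps_done[i],
                collided[i],
                bystander_helped and i == 0,
                system.score_params,
            ),
        )
        for i in range(3)
    }
    return EpisodeResult(
        seed=int(env_seed),
        outcomes=outcomes,
        help_events=help_events,
        helped_agents=frozenset(helped_agents),
    )


def run_condition(
    pedestrian2_style: str,
    with_tom: bool,
    n: int = 100,
    seed: int = 0,
    system: TrainedSystem | None = None,
) -> list[EpisodeResult]:
    """Run ``n`` randomized episodes of one benchmark condition.

    Environment seeds are drawn deterministically from ``seed`` so that
    with/without-ToM runs pair episode by episode.
    """
    if pedestrian2_style not in STYLES:
        raise ValueError(f"unknown style {pedestrian2_style!r}")
    if system is None:
        raise ValueError("a trained system is required (train_full_system)")
    env_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    return [_episode(system, pedestrian2_style, with_tom, s) for s in env_seeds]


def summarize(results: list, agent_id: int = 0) -> ConditionSummary:
    """Score statistics (population std) for one agent over episodes."""
    if not results:
        raise ValueError("no episodes to summarize")
    scores = np.array([r.score_of(agent_id) for r in results], dtype=float)
    collisions = sum(r.outcomes[agent_id].collided for r in results)
    hist, _ = np.histogram(scores, bins=HISTOGRAM_EDGES)
    return ConditionSummary(
        n=len(results),
        mean=float(scores.mean()),
        std=float(scores.std()),  # population convention
        min=float(scores.min()),
        collisions=int(collisions),
        histogram=hist,
    )


@dataclass
class ConditionComparison:
    """Paired with/without-ToM comparison for one pedestrian-2 style."""

    style: str
    with_tom: ConditionSummary
    without_tom: ConditionSummary
    ped2_collisions_with: int
    ped2_collisions_without: int
    help_episodes: int
    ped2_help_episodes: int
    n: int


def compare_conditions(
    style: str,
    n: int = 100,
    seed: int = 0,
    system: TrainedSystem | None = None,
) -> ConditionComparison:
    """Run both arms on identical environment seeds and compare."""
    with_results = run_condition(style, True, n=n, seed=seed, system=system)
    without_results = run_condition(style, False, n=n, seed=seed, system=system)
    if [r.seed for r in with_results] != [r.seed for r in without_results]:
        raise ValueError("paired comparison requires identical seed lists")
    return ConditionComparison(
        style=style,
        with_tom=summarize(with_results, agent_id=0),
        without_tom=summarize(without_results, agent_id=0),
        ped2_collisions_with=sum(r.outcomes[2].collided for r in with_results),
        ped2_collisions_without=sum(r.outcomes[2].collided for r in without_results),
        help_episodes=sum(r.outcomes[0].helped for r in with_results),
        ped2_help_episodes=sum(2 in r.helped_agents for r in with_results),
        n=n,
    )


def plot_score_histogram(summary: ConditionSummary, path, title: str = "") -> None:
    """Save the condition's score histogram as a PNG (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.asarray(summary.bin_edges)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(edges[:-1], summary.histogram, width=np.diff(edges), align="edge", edgecolor="k")
    ax.set_xlabel("performance score")
    ax.set_ylabel("episodes")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def record_episode(
    system: TrainedSystem,
    pedestrian2_style: str,
    env_seed: int,
    with_tom: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replay one episode and log every step and every ToM estimate.

    Returns (trajectory, estimates): the trajectory has one row per
    agent per step (position, action, reward, collision flags), the
    estimates one row per pedestrian per step of the bystander's chain
    (inferred style, predicted action and cell, safety verdict).
    """
    from .tom import bystander_step

    styles = ["reckless", "reckless", pedestrian2_style]
    world = generate_environment(int(env_seed), n_agents=3, styles=styles)
    rng = np.random.default_rng(int(env_seed) + 1)
    system.tom.reset_memory()
    stp = {i: ShortTermState() for i in range(3)}
    traj_rows, est_rows = [], []
    for step in range(STEP_CAP):
        if all(a.done for a in world.agents):
            break
        actions = {}
        helped_ped = None
        if with_tom and not world.agents[0].done:
            b_action, helped_ped, estimates = bystander_step(
                system.tom, system.policies["reckless"], world, 0, rng=rng, stp=stp[0]
            )
            actions[0] = b_action
            for e in estimates:
                est_rows.append(
                    {
                        "step": step,
                        "pedestrian": e.agent_id,
                        "inferred_style": e.style,
                        "predicted_action": e.predicted_action,
                        "predicted_cell": str(e.predicted_state),
                        "safety": e.safety,
                        "helped": e.agent_id == helped_ped,
                    }
                )
        elif not world.agents[0].done:
            actions[0] = act(system.policies["reckless"], observe(world, 0), rng=rng, stp=stp[0])
        for i in (1, 2):
            if not world.agents[i].done:
                actions[i] = act(
                    system.policies[world.agents[i].policy], observe(world, i), rng=rng, stp=stp[i]
                )
        if helped_ped is not None and helped_ped in actions:
            actions[helped_ped] = "stay"
        positions = dict(world.active_positions())
        world, transitions = step_world(world, actions)
        for i, tr in transitions.items():
            from .gridworld import compute_reward

            traj_rows.append(
                {
                    "step": step,
                    "agent": i,
                    "position": str(positions[i]),
                    "action": actions[i],
                    "reward": compute_reward(world.agents[i].policy, tr)
                    if tr.dp_prev > 0 or tr.dp_now == 0
                    else float("nan"),
                    "collided": tr.collided,
                    "collided_agent": tr.collided_agent,
                }
            )
    return pd.DataFrame(traj_rows), pd.DataFrame(est_rows)


def results_frame(results: list) -> pd.DataFrame:
    """Tidy per-agent episode table (episode seed, agent, t, flags, score)."""
    rows = []
    for r in results:
        for agent_id, o in r.outcomes.items():
            rows.append(
                {
                    "seed": r.seed,
                    "agent": agent_id,
                    "steps": o.steps,
                    "collided": o.collided,
                    "helped": o.helped,
                    "score": o.score,
                }
            )
    return pd.DataFrame(rows)
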