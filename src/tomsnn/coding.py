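"""Population encoding of observations and winner-take-all decoding.

A gridworld observation is encoded over ``7*7*(4+8) = 588`` binary
channels: each of the 49 cells owns a block of 12 channels,

    offset 0   wall present (self-centred frame)
    offset 1   the observer's own goal (self-centred frame)
    offset 2   reserved (always 0)
    offset 3   reserved (always 0)
    offset 4+k agent with id ``k`` (k < 8) occupies the cell
               (other agents: self-centred frame; the observer itself:
               absolute position)

The observation contains exactly the goal, the walls, and the visible
agents, and the code mixes absolute and relative position information.
Walls, the goal, and visible other agents are placed relative to the
observer: a feature at offset (dr, dc) from the observer activates the
channel of grid cell (3+dr, 3+dc).  Each feature class has its own
receptive-field radius, matched to the range at which it influences
behaviour: the goal is always present (its offset is clipped to the
window, so its direction is preserved at any range), other agents
appear within two cells (the range at which simultaneous moves can
collide), and walls appear within one cell (the range at which they
block movement).  The observer's own channel stays in absolute
coordinates.  The self-centred frame makes the sensorimotor mapping a
direct association (feature-at-relative-cell -> action), which is what
lets the shallow networks learn it, and the graded receptive fields
keep the stimulus sparse with every active channel decision-relevant --
which matters because reward-gated updates hit all active synapses
alike, so channels that cannot inform the decision only accumulate
noise and dilute the vote of the ones that can.  The absolute self
channel keeps distinct world states distinguishable.  Invisible cells
contribute no agent channels.

Behaviour styles are encoded by three 6-neuron populations (18 channels,
order reckless / experienced / cautious).  Decoding picks the output
population with the most spikes after subtractive lateral inhibition
between populations; an all-silent raster yields the ``None`` sentinel.

:func:`encode_egocentric` applies the same windowing to an arbitrary
configuration centred on a designated cell (used by the
state-evaluation module, whose job -- detecting a collision at the
observed agent's predicted position -- is translation invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridworld import GRID_SIZE, STYLES, GridObservation
from .snn_core import PopulationPartition, SpikeRaster, population_counts, winner_population

__all__ = [
    "CELL_FEATURES",
    "N_OBS_CHANNELS",
    "N_STYLE_CHANNELS",
    "FEATURE_WALL",
    "FEATURE_GOAL",
    "FEATURE_RESERVED",
    "FEATURE_RESERVED2",
    "FEATURE_AGENT0",
    "EncodedStimulus",
    "LateralInhibitionConfig",
    "channel_index",
    "channel_layout",
    "encode_observation",
    "encode_egocentric",
    "encode_style",
    "apply_lateral_inhibition",
    "decode_output",
]

CELL_FEATURES = 12
N_OBS_CHANNELS = GRID_SIZE * GRID_SIZE * CELL_FEATURES  # 588
MAX_AGENTS = 8
N_STYLE_CHANNELS = 3 * 6

FEATURE_WALL = 0
FEATURE_GOAL = 1
FEATURE_RESERVED = 2
FEATURE_RESERVED2 = 3
FEATURE_AGENT0 = 4


@dataclass
class EncodedStimulus:
    """Binary channel activations for one observation."""

    active_channels: np.ndarray

    def __post_init__(self) -> None:
        self.active_channels = np.asarray(self.active_channels, dtype=np.uint8)
        if self.active_channels.shape != (N_OBS_CHANNELS,):
            raise ValueError(f"expected {N_OBS_CHANNELS} channels")
        if not np.isin(self.active_channels, (0, 1)).all():
            raise ValueError("stimulus must be binary")

    def to_raster(
        self,
        n_steps: int,
        efficacy: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> SpikeRaster:
        """Drive raster: every active channel fires on every step.

        With ``efficacy`` (per-channel release probability in (0, 1])
        and ``rng``, each active channel instead fires Bernoulli(p) per
        step -- the spiking realisation of short-term synaptic
        depression.
        """
        if efficacy is None or rng is None:
            return SpikeRaster(np.tile(self.active_channels[:, None], (1, n_steps)))
        p = np.clip(self.active_channels * efficacy, 0.0, 1.0)
        spikes = (rng.random((self.active_channels.shape[0], n_steps)) < p[:, None]).astype(
            np.uint8
        )
        return SpikeRaster(spikes)


@dataclass(frozen=True)
class LateralInhibitionConfig:
    """Subtractive inhibition strength between output populations."""

    strength: float = 0.1

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("inhibition strength must be >= 0")


def channel_index(row: int, col: int, feature: int, size: int = GRID_SIZE) -> int:
    if not (0 <= row < size and 0 <= col < size):
        raise ValueError(f"cell ({row}, {col}) is off-grid")
    if not 0 <= feature < CELL_FEATURES:
        raise ValueError(f"feature index {feature} out of range")
    return (row * size + col) * CELL_FEATURES + feature


def channel_layout() -> dict:
    """Machine-readable description of the channel layout."""
    return {
        "grid_size": GRID_SIZE,
        "cell_features": CELL_FEATURES,
        "n_observation_channels": N_OBS_CHANNELS,
        "channel_order": "cell-major: index = (row*7 + col)*12 + feature",
        "frames": {
            "relative": "cell = (3+dr, 3+dc), offset from the observer; goal clipped, walls/agents dropped beyond +-3",
            "absolute": "cell = grid position",
        },
        "features": {
            "0": "wall present (relative frame)",
            "1": "observer's own goal (relative frame, clipped)",
            "2": "reserved",
            "3": "reserved",
            **{
                str(FEATURE_AGENT0 + k): f"agent {k} occupies cell (relative frame; absolute for the observer itself)"
                for k in range(MAX_AGENTS)
            },
        },
        "style_channels": {
            "count": N_STYLE_CHANNELS,
            "populations": {style: i for i, style in enumerate(STYLES)},
            "neurons_per_population": 6,
        },
        "action_order": ["up", "down", "left", "right", "stay"],
    }


#: receptive-field radius per feature class (relative frame)
WALL_RADIUS = 1
AGENT_RADIUS = 2


def _relative_cell(cell, center, size: int, clip: bool, radius: int | None = None):
    """Map a cell into the window centred on ``center``.

    With ``clip`` the offset is clamped to the window edge (direction
    preserved); without it, cells beyond ``radius`` (default: the full
    half-window) return ``None``.
    """
    half = size // 2
    dr, dc = cell[0] - center[0], cell[1] - center[1]
    if clip:
        dr = max(-half, min(half, dr))
        dc = max(-half, min(half, dc))
    else:
        reach = half if radius is None else radius
        if abs(dr) > reach or abs(dc) > reach:
            return None
    return half + dr, half + dc


def encode_observation(obs: GridObservation) -> EncodedStimulus:
    """Population code of one observation (layout in the module docstring).

    Walls, the goal, and visible agents are placed relative to the
    observer; the observer's own channel is absolute.  Occluded agents
    are absent -- the false-belief channel.
    """
    active = np.zeros(N_OBS_CHANNELS, dtype=np.uint8)
    center = obs.self_position
    for w in obs.walls:
        pos = _relative_cell(w, center, obs.size, clip=False, radius=WALL_RADIUS)
        if pos is not None:
            active[channel_index(*pos, FEATURE_WALL, obs.size)] = 1
    goal_pos = _relative_cell(obs.goal, center, obs.size, clip=True)
    active[channel_index(*goal_pos, FEATURE_GOAL, obs.size)] = 1
    for agent_id, cell in obs.visible_agents.items():
        pos = _relative_cell(cell, center, obs.size, clip=False, radius=AGENT_RADIUS)
        if pos is not None and agent_id < MAX_AGENTS:
            active[channel_index(*pos, FEATURE_AGENT0 + agent_id, obs.size)] = 1
    if obs.self_id < MAX_AGENTS:
        active[channel_index(*obs.self_position, FEATURE_AGENT0 + obs.self_id, obs.size)] = 1
    return EncodedStimulus(active)


def encode_egocentric(
    walls: frozenset,
    agent_positions: dict,
    center: tuple,
    size: int = GRID_SIZE,
) -> EncodedStimulus:
    """Same layout, but in a frame centred on ``center``.

    A cell at offset (dr, dc) from the centre maps to grid position
    (3+dr, 3+dc); offsets beyond +-3 fall outside the window and are
    dropped.  Only wall and agent features are populated.
    """
    if not (0 <= center[0] < size and 0 <= center[1] < size):
        raise ValueError(f"center {center} is off-grid")
    half = GRID_SIZE // 2
    active = np.zeros(N_OBS_CHANNELS, dtype=np.uint8)

    def _ego(cell):
        dr, dc = cell[0] - center[0], cell[1] - center[1]
        if abs(dr) > half or abs(dc) > half:
            return None
        return half + dr, half + dc

    for w in walls:
        pos = _ego(w)
        if pos is not None:
            active[channel_index(*pos, FEATURE_WALL)] = 1
    for agent_id, cell in agent_positions.items():
        pos = _ego(cell)
        if pos is not None and agent_id < MAX_AGENTS:
            active[channel_index(*pos, FEATURE_AGENT0 + agent_id)] = 1
    return EncodedStimulus(active)


def encode_style(style: str) -> np.ndarray:
    """Binary vector over 3 populations x 6 neurons; one population set."""
    if style not in STYLES:
        raise ValueError(f"unknown behaviour style {style!r}")
    vec = np.zeros(N_STYLE_CHANNELS, dtype=np.uint8)
    i = STYLES.index(style)
    vec[6 * i : 6 * (i + 1)] = 1
    return vec


def apply_lateral_inhibition(values: np.ndarray, cfg: LateralInhibitionConfig) -> np.ndarray:
    """Each population loses k times the other populations' activity.

    The transform is (1+k)*v - k*sum(v) floored at zero, which is
    strictly increasing in v, so the argmax population is preserved.
    """
    values = np.asarray(values, dtype=float)
    inhibited = values - cfg.strength * (values.sum() - values)
    return np.maximum(inhibited, 0.0)


def decode_output(
    raster: SpikeRaster,
    partition: PopulationPartition,
    inhibition: LateralInhibitionConfig | None = None,
):
    """Winner-take-all label after lateral inhibition.

    Returns ``None`` (the no-output sentinel) for an all-silent raster.
    """
    counts = population_counts(raster, partition)
    if counts.sum() == 0:
        return None
    if inhibition is not None:
        counts = apply_lateral_inhibition(counts, inhibition)
    return winner_population(counts, partition)
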