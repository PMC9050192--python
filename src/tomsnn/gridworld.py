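"""A 7x7 partially observable multi-agent gridworld.

Three agents (a bystander and two pedestrians) move on a 7x7 grid with a
randomly placed blocking wall.  Walls occlude sight lines: an agent sees
another agent only if the straight segment between their cell centres
crosses no wall cell.  Walls and goals are assumed globally known, so
occlusion of other agents is the only partial-observability channel --
this is what induces false beliefs.

Movement is simultaneous with action space up/down/left/right/stay.
Moving into a wall or off the grid leaves the agent in place and counts
as a collision; two agents ending on the same cell, or swapping cells,
both count as collisions.  An agent reaching its goal is done and leaves
the game (it no longer occupies a cell).

Each behaviour style has its own reward used to train its policy:

* reckless     r = (Dp_prev - Dp_now) / Dp_prev
* experienced  same, but -5 on any collision
* cautious     progress term plus a wall-avoidance term
               (Dw_now - Dw_prev) / Dw_prev, with -5 on collision and -5
               whenever the previous wall distance was <= 1

where Dp is the Euclidean distance to the goal and Dw the Euclidean
distance to the nearest wall cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import deque

import numpy as np

__all__ = [
    "GRID_SIZE",
    "ACTIONS",
    "ACTION_DELTAS",
    "STYLES",
    "GridWorld",
    "AgentState",
    "Transition",
    "GridObservation",
    "generate_environment",
    "visible_cells",
    "observe",
    "step_world",
    "compute_reward",
    "apply_move",
    "bfs_distances",
]

GRID_SIZE = 7
ACTIONS: tuple[str, ...] = ("up", "down", "left", "right", "stay")
ACTION_DELTAS: dict[str, tuple[int, int]] = {
    "up": (-1, 0),
    "down": (1, 0),
    "left": (0, -1),
    "right": (0, 1),
    "stay": (0, 0),
}
STYLES: tuple[str, ...] = ("reckless", "experienced", "cautious")

Cell = tuple[int, int]

COLLISION_PENALTY = -5.0


def _on_grid(cell: Cell, size: int = GRID_SIZE) -> bool:
    r, c = cell
    return 0 <= r < size and 0 <= c < size


@dataclass
class AgentState:
    """One agent: position, policy style, goal, and completion flag."""

    position: Cell
    goal: Cell
    policy: str = "reckless"
    done: bool = False

    def __post_init__(self) -> None:
        if self.policy not in STYLES:
            raise ValueError(f"unknown policy style {self.policy!r}")


@dataclass
class GridWorld:
    """World state: walls, agents (with embedded goals), grid size."""

    walls: frozenset
    agents: list
    size: int = GRID_SIZE
    seed: int | None = None

    def __post_init__(self) -> None:
        self.walls = frozenset(self.walls)
        for w in self.walls:
            if not _on_grid(w, self.size):
                raise ValueError(f"wall cell {w} is off-grid")
        for a in self.agents:
            if not _on_grid(a.position, self.size) or a.position in self.walls:
                raise ValueError(f"agent position {a.position} invalid")

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def active_positions(self) -> dict:
        """Positions of agents still in the game, keyed by agent id."""
        return {i: a.position for i, a in enumerate(self.agents) if not a.done}

    def copy(self) -> "GridWorld":
        return GridWorld(
            self.walls, [replace(a) for a in self.agents], self.size, self.seed
        )


@dataclass(frozen=True)
class Transition:
    """Distance bookkeeping for one agent over one step.

    ``collided`` covers every collision type (wall bump, edge bump,
    agent contact) and feeds the reward functions; ``collided_agent``
    marks contact with another agent specifically, which is what the
    performance score penalises.
    """

    dp_prev: float
    dp_now: float
    dw_prev: float
    dw_now: float
    collided: bool = False
    collided_agent: bool = False

    def __post_init__(self) -> None:
        if min(self.dp_prev, self.dp_now) < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class GridObservation:
    """What one agent sees: global walls and goal, plus visible agents.

    ``visible_agents`` maps agent id -> cell for every *other* agent
    inside the observer's line of sight.  ``visible_mask`` is the 7x7
    boolean visibility grid from ``self_position`` (computed lazily from
    the walls when omitted).
    """

    walls: frozenset
    goal: Cell
    self_position: Cell
    visible_agents: dict = field(default_factory=dict)
    self_id: int = 0
    visible_mask: np.ndarray | None = None
    size: int = GRID_SIZE

    def __post_init__(self) -> None:
        for cell in [self.goal, self.self_position, *self.visible_agents.values()]:
            if not _on_grid(cell, self.size):
                raise ValueError(f"cell {cell} is off-grid")
        if self.visible_mask is None:
            self.visible_mask = visibility_mask(self.walls, self.self_position, self.size)


# ---------------------------------------------------------------------------
# line of sight

def _segment_intersects_cell(a: Cell, b: Cell, cell: Cell) -> bool:
    """Exact test: does segment between centres of a and b touch ``cell``?

    All coordinates are doubled so cell centres and square corners become
    integers, keeping the test exact and symmetric in (a, b).  Squares
    are closed, so a segment grazing a corner or edge counts as touching.
    """
    ay, ax = 2 * a[0] + 1, 2 * a[1] + 1
    by, bx = 2 * b[0] + 1, 2 * b[1] + 1
    y0, y1 = 2 * cell[0], 2 * cell[0] + 2
    x0, x1 = 2 * cell[1], 2 * cell[1] + 2
    # bounding-box rejection
    if max(ax, bx) < x0 or min(ax, bx) > x1:
        return False
    if max(ay, by) < y0 or min(ay, by) > y1:
        return False
    # the segment misses the box iff all four corners lie strictly on one
    # side of the segment's supporting line
    dy, dx = by - ay, bx - ax
    signs = [
        dy * (cx - ax) - dx * (cy - ay)
        for cy, cx in ((y0, x0), (y0, x1), (y1, x0), (y1, x1))
    ]
    if all(s > 0 for s in signs) or all(s < 0 for s in signs):
        return False
    return True


def visibility_mask(walls: frozenset, viewpoint: Cell, size: int = GRID_SIZE) -> np.ndarray:
    """Boolean grid of cells visible from ``viewpoint``.

    A cell is visible iff the straight segment between the cell centres
    touches no wall cell other than the target itself.  The viewpoint is
    always visible; wall cells themselves can be seen (unless another
    wall is in the way).
    """
    if not _on_grid(viewpoint, size):
        raise ValueError(f"viewpoint {viewpoint} is off-grid")
    mask = np.zeros((size, size), dtype=bool)
    for r in range(size):
        for c in range(size):
            target = (r, c)
            if target == viewpoint:
                mask[r, c] = True
                continue
            blocked = any(
                w != target and w != viewpoint and _segment_intersects_cell(viewpoint, target, w)
                for w in walls
            )
            mask[r, c] = not blocked
    return mask


def visible_cells(world: GridWorld, viewpoint: Cell) -> np.ndarray:
    """Visibility mask from ``viewpoint`` in ``world`` (see above)."""
    return visibility_mask(world.walls, viewpoint, world.size)


# ---------------------------------------------------------------------------
# generation

def bfs_distances(walls: frozenset, source: Cell, size: int = GRID_SIZE) -> dict:
    """Shortest path lengths from ``source`` avoiding walls."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        cell = queue.popleft()
        for d in ("up", "down", "left", "right"):
            dr, dc = ACTION_DELTAS[d]
            nxt = (cell[0] + dr, cell[1] + dc)
            if _on_grid(nxt, size) and nxt not in walls and nxt not in dist:
                dist[nxt] = dist[cell] + 1
                queue.append(nxt)
    return dist


def _random_wall(rng: np.random.Generator, size: int = GRID_SIZE) -> frozenset:
    """A contiguous straight wall segment of 2-4 cells."""
    length = int(rng.integers(2, 5))
    horizontal = bool(rng.integers(0, 2))
    if horizontal:
        r = int(rng.integers(0, size))
        c = int(rng.integers(0, size - length + 1))
        cells = {(r, c + k) for k in range(length)}
    else:
        r = int(rng.integers(0, size - length + 1))
        c = int(rng.integers(0, size))
        cells = {(r + k, c) for k in range(length)}
    return frozenset(cells)


def generate_environment(
    rng_seed,
    n_agents: int = 3,
    styles=None,
    include_walls: bool = True,
    size: int = GRID_SIZE,
    max_attempts: int = 1000,
) -> GridWorld:
    """Random world: one 2-4 cell wall, distinct starts and goals.

    Walls, starts, and goals are pairwise disjoint and every agent's goal
    is reachable from its start; layouts violating this are rejected and
    resampled.  ``rng_seed`` may be an int or a ``numpy`` Generator.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    seed = int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else None
    styles = list(styles) if styles is not None else ["reckless"] * n_agents
    if len(styles) != n_agents:
        raise ValueError("need one style per agent")
    for _ in range(max_attempts):
        walls = _random_wall(rng, size) if include_walls else frozenset()
        free = [(r, c) for r in range(size) for c in range(size) if (r, c) not in walls]
        if len(free) < 2 * n_agents:
            continue
        picks = rng.choice(len(free), size=2 * n_agents, replace=False)
        starts = [free[i] for i in picks[:n_agents]]
        goals = [free[i] for i in picks[n_agents:]]
        ok = True
        for s, g in zip(starts, goals):
            if g not in bfs_distances(walls, s, size):
                ok = False
                break
        if not ok:
            continue
        agents = [
            AgentState(position=s, goal=g, policy=st)
            for s, g, st in zip(starts, goals, styles)
        ]
        return GridWorld(walls, agents, size, seed)
    raise RuntimeError(f"no valid environment found in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# observation and dynamics

def observe(world: GridWorld, agent_id: int) -> GridObservation:
    """The observation of one agent: walls, own goal, visible agents."""
    if not 0 <= agent_id < world.n_agents:
        raise ValueError(f"unknown agent id {agent_id}")
    me = world.agents[agent_id]
    mask = visible_cells(world, me.position)
    visible = {
        i: pos
        for i, pos in world.active_positions().items()
        if i != agent_id and mask[pos]
    }
    return GridObservation(
        walls=world.walls,
        goal=me.goal,
        self_position=me.position,
        visible_agents=visible,
        self_id=agent_id,
        visible_mask=mask,
        size=world.size,
    )


def apply_move(walls: frozenset, position: Cell, action: str, size: int = GRID_SIZE) -> Cell:
    """Deterministic single-agent movement rule; blocked moves stay put."""
    if action not in ACTION_DELTAS:
        raise ValueError(f"unknown action {action!r}")
    dr, dc = ACTION_DELTAS[action]
    nxt = (position[0] + dr, position[1] + dc)
    if not _on_grid(nxt, size) or nxt in walls:
        return position
    return nxt


def _euclid(a: Cell, b: Cell) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def wall_distance(walls: frozenset, cell: Cell) -> float:
    """Euclidean distance to the nearest wall cell; inf with no walls."""
    if not walls:
        return float("inf")
    return min(_euclid(cell, w) for w in walls)


def step_world(world: GridWorld, actions: dict) -> tuple[GridWorld, dict]:
    """Advance all agents simultaneously.

    Returns the new world and a per-agent :class:`Transition`.  Collisions:
    blocked move (wall or edge), two agents ending on one cell, or a
    position swap.  Agents reaching their goal become done and leave the
    grid.  Actions supplied for done agents are ignored.
    """
    new_world = world.copy()
    active = world.active_positions()
    for i in active:
        if i not in actions:
            raise ValueError(f"no action supplied for active agent {i}")
    intended: dict = {}
    collided = {i: False for i in active}
    collided_agent = {i: False for i in active}
    for i, pos in active.items():
        nxt = apply_move(world.walls, pos, actions[i], world.size)
        if nxt == pos and actions[i] != "stay":
            collided[i] = True  # bumped a wall or the edge
        intended[i] = nxt
    # same-cell conflicts
    for i in active:
        for j in active:
            if j <= i:
                continue
            if intended[i] == intended[j]:
                collided_agent[i] = collided_agent[j] = True
            elif intended[i] == active[j] and intended[j] == active[i]:
                collided_agent[i] = collided_agent[j] = True  # swap
    transitions: dict = {}
    for i, pos in active.items():
        agent = new_world.agents[i]
        nxt = intended[i]
        tr = Transition(
            dp_prev=_euclid(pos, agent.goal),
            dp_now=_euclid(nxt, agent.goal),
            dw_prev=wall_distance(world.walls, pos),
            dw_now=wall_distance(world.walls, nxt),
            collided=collided[i] or collided_agent[i],
            collided_agent=collided_agent[i],
        )
        agent.position = nxt
        if nxt == agent.goal:
            agent.done = True
        transitions[i] = tr
    return new_world, transitions


def compute_reward(policy: str, tr: Transition) -> float:
    """Per-step reward under one of the three behaviour styles."""
    if policy not in STYLES:
        raise ValueError(f"unknown policy style {policy!r}")
    if tr.dp_prev == 0:
        if tr.dp_now == 0:
            return 0.0  # parked on the goal
        raise ValueError("dp_prev is zero for an agent off its goal")
    progress = (tr.dp_prev - tr.dp_now) / tr.dp_prev
    if policy == "reckless":
        return progress
    if policy == "experienced":
        return COLLISION_PENALTY if tr.collided else progress
    # cautious
    if tr.collided or tr.dw_prev <= 1.0:
        return COLLISION_PENALTY
    if np.isfinite(tr.dw_prev) and tr.dw_prev > 0:
        wall_term = (tr.dw_now - tr.dw_prev) / tr.dw_prev
    else:
        wall_term = 0.0
    return progress + wall_term
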