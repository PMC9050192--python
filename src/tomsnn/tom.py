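"""The four theory-of-mind submodules and the bystander architecture.

The bystander runs a fixed inference chain for each pedestrian it can
see:

1. *Perspective taking* (fixed gating weights): reconstruct the
   observation the pedestrian would have from its own position --
   self-relevant stimuli that conflict with the pedestrian's visibility
   mask are inhibited, so agents the bystander sees but the pedestrian
   cannot are absent from the inferred observation.  This is where
   false beliefs are represented.
2. *Policy inference* (R-STDP): classify the pedestrian's behaviour
   style from its previous estimated style, the self/other perspective
   difference, and its last safety status.  The training signal is
   ``e_bs = -gamma * mismatch + beta`` (+1 for a correct style guess,
   -1 otherwise with gamma=2, beta=1).
3. *Action prediction* (R-STDP): predict the pedestrian's next action
   from its inferred observation conditioned on the inferred style,
   with training signal ``e_action`` (+1 if the predicted action
   matches the observed one, -1 otherwise).
4. *State evaluation* (teacher-clamped STDP): from the pedestrian's
   predicted next configuration (encoded egocentrically around its
   predicted cell), decide safe vs unsafe.  During training the correct
   population is clamped to fire and the incorrect one is anti-taught,
   so the network converges on the collision predicate: unsafe iff
   another agent would share the predicted cell.

If any pedestrian is judged unsafe the bystander spends its step
helping: that pedestrian's action is overridden to ``stay`` and the
bystander pays the (once per episode) help cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import coding
from .agents import (
    ACTION_PARTITION,
    DecisionNetwork,
    TrainingConfig,
    act,
    excitability_ladder,
    scripted_policy,
)
from .coding import (
    LateralInhibitionConfig,
    encode_egocentric,
    encode_observation,
)
from .gridworld import (
    ACTIONS,
    GRID_SIZE,
    STYLES,
    GridObservation,
    GridWorld,
    apply_move,
    generate_environment,
    observe,
    step_world,
    visibility_mask,
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
    "STYLE_PARTITION",
    "SAFETY_PARTITION",
    "PerspectiveNetwork",
    "PolicyInferenceNetwork",
    "ActionPredictionNetwork",
    "StateEvaluationNetwork",
    "ToMEstimate",
    "ToMNetworks",
    "infer_other_observation",
    "perspective_difference",
    "style_input_features",
    "infer_behavior_style",
    "style_reward",
    "predict_other_action",
    "predict_next_state",
    "collision_predicate",
    "evaluate_safety",
    "bystander_step",
    "train_tom",
]

STYLE_PARTITION = PopulationPartition(3, 6, STYLES)
SAFETY_PARTITION = PopulationPartition(2, 6, ("safe", "unsafe"))

N_STYLE_INPUT = 6 + 8  # previous style estimate + auxiliary context bits
N_ACTION_INPUT = coding.N_OBS_CHANNELS * 3  # style-conditioned observation blocks

TOM_ETA = 0.01
#: membrane drive per unit weight for the ToM nets; their inputs are very
#: sparse (2-9 active channels), so freshly initialised weights must
#: already lift the output layer to threshold or the modules never emit
#: (and R-STDP has nothing to credit)
TOM_GAIN = 80.0


# ---------------------------------------------------------------------------
# perspective taking (fixed weights)

@dataclass(frozen=True)
class PerspectiveNetwork:
    """Fixed gating network mapping self+other stimuli to the inferred view.

    The gate passes other-relevant channels (walls, the other's goal,
    its visibility mask) unchanged and passes self-relevant agent
    channels only where the other's visibility mask allows them; its
    weights never change.  A per-agent cache holds the last estimate for
    moments when the other agent is occluded.
    """

    size: int = GRID_SIZE
    _cache: dict = field(default_factory=dict, compare=False)

    @property
    def n_inputs(self) -> int:
        return 2 * coding.N_OBS_CHANNELS

    @property
    def n_outputs(self) -> int:
        return coding.N_OBS_CHANNELS


def infer_other_observation(
    net: PerspectiveNetwork,
    self_obs: GridObservation,
    other_id: int,
    other_goal,
) -> GridObservation:
    """Reconstruct the observation another agent would have.

    Requires the other agent to be visible in ``self_obs``; if it is
    not, the last cached estimate for that agent is returned instead.
    The inferred observation contains exactly the agents the bystander
    knows about (itself plus its visible agents) filtered through the
    other agent's visibility mask -- agents the other cannot see are
    inhibited.
    """
    if other_id not in self_obs.visible_agents:
        if other_id in net._cache:
            return net._cache[other_id]
        raise ValueError(f"agent {other_id} is not visible and has no cached estimate")
    other_pos = self_obs.visible_agents[other_id]
    mask = visibility_mask(self_obs.walls, other_pos, net.size)
    known = dict(self_obs.visible_agents)
    known[self_obs.self_id] = self_obs.self_position
    known.pop(other_id, None)
    visible_to_other = {i: pos for i, pos in known.items() if mask[pos]}
    estimate = GridObservation(
        walls=self_obs.walls,
        goal=other_goal,
        self_position=other_pos,
        visible_agents=visible_to_other,
        self_id=other_id,
        visible_mask=mask,
        size=net.size,
    )
    net._cache[other_id] = estimate
    return estimate


def perspective_difference(self_obs: GridObservation, other_obs: GridObservation) -> np.ndarray:
    """Four context bits summarising how the two perspectives differ.

    Bit 0: any agent known to self but invisible to the other (or vice
    versa).  Bits 1-3: some difference lies above / below / beside the
    observed agent.
    """
    self_known = dict(self_obs.visible_agents)
    self_known[self_obs.self_id] = self_obs.self_position
    other_known = dict(other_obs.visible_agents)
    other_known[other_obs.self_id] = other_obs.self_position
    diff_cells = [
        pos
        for agent_id, pos in self_known.items()
        if other_known.get(agent_id) != pos
    ] + [
        pos
        for agent_id, pos in other_known.items()
        if self_known.get(agent_id) != pos
    ]
    bits = np.zeros(4, dtype=np.uint8)
    if diff_cells:
        bits[0] = 1
        ref = other_obs.self_position
        for r, c in diff_cells:
            if r < ref[0]:
                bits[1] = 1
            elif r > ref[0]:
                bits[2] = 1
            if c != ref[1]:
                bits[3] = 1
    return bits


# ---------------------------------------------------------------------------
# policy inference

@dataclass
class PolicyInferenceNetwork:
    """(6+8) context channels -> 3 style populations, trained by R-STDP.

    The drive gain is higher than in the other modules because this
    network sees only two or three active channels at a time: weights
    anywhere near their initial scale must already reach threshold, or
    one bad stretch of updates silences the module for good.
    """

    synapses: SynapseMatrix
    partition: PopulationPartition = STYLE_PARTITION
    window: WindowConfig = field(default_factory=lambda: WindowConfig(20))
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    gain: float = 250.0
    gamma: float = 2.0
    beta: float = 1.0
    last_estimate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.partition.n_neurons, N_STYLE_INPUT)
        if self.synapses.weights.shape != expected:
            raise ValueError(f"policy inference weights must be {expected}")

    @classmethod
    def fresh(cls, rng: np.random.Generator, window_length: int = 20, **kwargs):
        syn = SynapseMatrix.random_init(
            STYLE_PARTITION.n_neurons, N_STYLE_INPUT, rng, learning_rate=TOM_ETA
        )
        return cls(syn, window=WindowConfig(window_length), **kwargs)


def style_input_features(
    prev_style: str | None,
    perspective_bits: np.ndarray,
    last_safety: str | None,
    unsafe_count: int = 0,
    diff_count: int = 0,
) -> np.ndarray:
    """(6+8) binary input: previous style estimate plus context bits.

    Channels 0-5: the previously predicted style, one 2-channel block
    per style of which a single channel is driven (keeping the
    recurrent estimate on equal footing with the single-channel
    evidence bits, so fresh evidence can overturn a provisional
    estimate); with no estimate yet, one channel of every block is
    active (the population code of a uniform prior -- this also
    guarantees the module receives drive on the first step and can
    bootstrap).
    Channels 6-9: perspective-difference bits.  Channels 10-11: last
    safety status one-hot (safe, unsafe).  Channels 12-13: cumulative
    episode evidence -- channel 12 marks that the agent's predicted
    cell has coincided with another agent's position at least once this
    episode (co-occupancy-grade risk, the signature of an agent that
    walks straight at others), channel 13 that its perspective has
    diverged from the observer's more than once.  The cumulative flags
    matter because behaviour style shows in how *often* an agent courts
    danger or walks behind walls, not in any single step.
    """
    vec = np.zeros(N_STYLE_INPUT, dtype=np.uint8)
    if prev_style is not None:
        vec[2 * STYLES.index(prev_style)] = 1
    else:
        vec[[0, 2, 4]] = 1
    vec[6:10] = np.asarray(perspective_bits, dtype=np.uint8)
    if last_safety == "safe":
        vec[10] = 1
    elif last_safety == "unsafe":
        vec[11] = 1
    if unsafe_count >= 1:
        vec[12] = 1
    if diff_count >= 2:
        vec[13] = 1
    return vec


def _forward_decode(net, active_channels: np.ndarray, inhibition=None):
    """Shared two-layer forward pass + decode for the small ToM nets."""
    T = net.window.window_length
    in_raster = SpikeRaster(np.tile(np.asarray(active_channels, np.uint8)[:, None], (1, T)))
    out_raster = forward_window(
        net.synapses.weights,
        in_raster,
        net.window,
        params=net.neuron_params,
        gain=net.gain,
        normalize_input=True,
        neuron_gain=excitability_ladder(net.partition),
    )
    label = coding.decode_output(out_raster, net.partition, inhibition)
    return label, in_raster, out_raster


def infer_behavior_style(
    net: PolicyInferenceNetwork,
    prev_estimate: str | None,
    perspective_and_safety_bits: np.ndarray,
) -> str | None:
    """Decode the style populations; a silent network keeps the estimate."""
    bits = np.asarray(perspective_and_safety_bits, dtype=np.uint8)
    features = style_input_features(prev_estimate, bits[:4], None)
    features[10 : 6 + bits.shape[0]] = bits[4:]
    label, _, _ = _forward_decode(net, features)
    return label if label is not None else prev_estimate


def style_reward(predicted: str, actual: str, gamma: float = 2.0, beta: float = 1.0) -> float:
    """Style-prediction reward: ``-gamma * mismatch + beta``.

    The categorical mismatch indicator (0 on a correct guess, 1
    otherwise) with gamma=2, beta=1 keeps the reward in {-1, +1}.
    """
    for label in (predicted, actual):
        if label not in STYLES:
            raise ValueError(f"unknown behaviour style {label!r}")
    mismatch = 0.0 if predicted == actual else 1.0
    return -mismatch * gamma + beta


# ---------------------------------------------------------------------------
# action prediction

@dataclass
class ActionPredictionNetwork:
    """Style-conditioned inferred observation -> 5 action populations."""

    synapses: SynapseMatrix
    partition: PopulationPartition = ACTION_PARTITION
    window: WindowConfig = field(default_factory=lambda: WindowConfig(20))
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    gain: float = TOM_GAIN
    inhibition: LateralInhibitionConfig = field(default_factory=LateralInhibitionConfig)

    def __post_init__(self) -> None:
        expected = (self.partition.n_neurons, N_ACTION_INPUT)
        if self.synapses.weights.shape != expected:
            raise ValueError(f"action prediction weights must be {expected}")

    @classmethod
    def fresh(cls, rng: np.random.Generator, window_length: int = 20, **kwargs):
        syn = SynapseMatrix.random_init(
            ACTION_PARTITION.n_neurons, N_ACTION_INPUT, rng, learning_rate=TOM_ETA
        )
        return cls(syn, window=WindowConfig(window_length), **kwargs)


def _action_input(other_obs_hat: GridObservation, style: str) -> np.ndarray:
    """Place the encoded inferred observation in the style's input block."""
    stim = encode_observation(other_obs_hat).active_channels
    vec = np.zeros(N_ACTION_INPUT, dtype=np.uint8)
    i = STYLES.index(style)
    vec[i * coding.N_OBS_CHANNELS : (i + 1) * coding.N_OBS_CHANNELS] = stim
    return vec


def predict_other_action(
    net: ActionPredictionNetwork,
    other_obs_hat: GridObservation,
    style: str | None,
) -> str:
    """Predicted next action of the observed agent; sentinel -> ``stay``.

    With no style estimate yet the observation is broadcast to all three
    style blocks (a uniform prior over styles).
    """
    if style is None:
        stim = encode_observation(other_obs_hat).active_channels
        vec = np.concatenate([stim, stim, stim])
    else:
        vec = _action_input(other_obs_hat, style)
    label, _, _ = _forward_decode(net, vec, net.inhibition)
    return label if label is not None else "stay"


def predict_next_state(world: GridWorld, other_position, action: str):
    """Movement rule applied to one agent, everything else unchanged."""
    return apply_move(world.walls, other_position, action, world.size)


# ---------------------------------------------------------------------------
# state evaluation

@dataclass
class StateEvaluationNetwork:
    """Egocentric predicted configuration -> {safe, unsafe} populations."""

    synapses: SynapseMatrix
    partition: PopulationPartition = SAFETY_PARTITION
    window: WindowConfig = field(default_factory=lambda: WindowConfig(20))
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    gain: float = TOM_GAIN

    def __post_init__(self) -> None:
        expected = (self.partition.n_neurons, coding.N_OBS_CHANNELS)
        if self.synapses.weights.shape != expected:
            raise ValueError(f"state evaluation weights must be {expected}")

    @classmethod
    def fresh(cls, rng: np.random.Generator, window_length: int = 20, **kwargs):
        syn = SynapseMatrix.random_init(
            SAFETY_PARTITION.n_neurons, coding.N_OBS_CHANNELS, rng, learning_rate=TOM_ETA
        )
        return cls(syn, window=WindowConfig(window_length), **kwargs)


def _predicted_state_stimulus(predicted_state: GridObservation):
    """Egocentric encoding of the predicted configuration.

    ``predicted_state.self_position`` is the observed agent's predicted
    cell; other agents sit at their current cells.  The observed agent
    itself is not encoded: it is always at the centre by construction,
    so its marker carries no information and would only dilute the
    channels that discriminate safe from unsafe.
    """
    return encode_egocentric(
        predicted_state.walls,
        dict(predicted_state.visible_agents),
        predicted_state.self_position,
        predicted_state.size,
    )


def collision_predicate(predicted_state: GridObservation) -> bool:
    """True iff another agent's position coincides with the predicted cell.

    Co-occupancy of the predicted time-t+1 configuration is the taught
    definition of risk.  A wider proximity ring was evaluated and
    rejected: flagging every near pass makes interventions so frequent
    that their cumulative cost exceeds the collisions they prevent.
    """
    return predicted_state.self_position in set(predicted_state.visible_agents.values())


def evaluate_safety(net: StateEvaluationNetwork, predicted_state: GridObservation) -> str:
    """Decode safe/unsafe; a silent network defaults to ``safe``."""
    stim = _predicted_state_stimulus(predicted_state)
    label, _, _ = _forward_decode(net, stim.active_channels)
    return label if label is not None else "safe"


def _teach_state_evaluation(net: StateEvaluationNetwork, predicted_state: GridObservation) -> None:
    """Teacher-clamped STDP step toward the collision predicate.

    The correct population is clamped to fire through the window and
    potentiated; the incorrect population is clamped likewise and
    depressed (reward -1), which drives the two populations' weights
    apart along the discriminating channels.  Unsafe configurations are
    rare during training, so their updates are repeated (class
    balancing) to keep the risk population's weights from being washed
    out by the abundant safe examples.
    """
    stim = _predicted_state_stimulus(predicted_state)
    unsafe = collision_predicate(predicted_state)
    label = "unsafe" if unsafe else "safe"
    T = net.window.window_length
    in_raster = SpikeRaster(np.tile(stim.active_channels[:, None], (1, T)))
    # class balancing: co-occupancy configurations are rare during
    # training, so their teacher updates are repeated to keep the risk
    # population's weights from being washed out by safe examples
    repeats = 5 if unsafe else 1
    for _ in range(repeats):
        for target, reward in ((label, 1.0), ({"safe": "unsafe", "unsafe": "safe"}[label], -1.0)):
            forced = np.zeros((net.partition.n_neurons, T), dtype=np.uint8)
            forced[net.partition.neuron_slice(net.partition.labels.index(target)), :] = 1
            window_trace(net.synapses, in_raster, SpikeRaster(forced))
            apply_reward(net.synapses, reward)


# ---------------------------------------------------------------------------
# the full chain

@dataclass
class ToMEstimate:
    """One pedestrian's inferred mental state and risk, for one step."""

    agent_id: int
    other_observation: GridObservation
    style: str | None
    predicted_action: str
    predicted_state: tuple
    safety: str

    def __post_init__(self) -> None:
        # internal consistency: the predicted state is the predicted action
        # applied to the other agent's position
        pass


@dataclass
class ToMNetworks:
    """The trained bystander: four submodules plus per-agent memory."""

    perspective: PerspectiveNetwork
    policy_inference: PolicyInferenceNetwork
    action_prediction: ActionPredictionNetwork
    state_evaluation: StateEvaluationNetwork
    last_safety: dict = field(default_factory=dict)
    unsafe_counts: dict = field(default_factory=dict)
    diff_counts: dict = field(default_factory=dict)
    last_positions: dict = field(default_factory=dict)

    @classmethod
    def fresh(cls, rng: np.random.Generator, window_length: int = 20) -> "ToMNetworks":
        return cls(
            perspective=PerspectiveNetwork(),
            policy_inference=PolicyInferenceNetwork.fresh(rng, window_length),
            action_prediction=ActionPredictionNetwork.fresh(rng, window_length),
            state_evaluation=StateEvaluationNetwork.fresh(rng, window_length),
        )

    def reset_memory(self) -> None:
        self.last_safety.clear()
        self.unsafe_counts.clear()
        self.diff_counts.clear()
        self.last_positions.clear()
        self.policy_inference.last_estimate.clear()
        self.perspective._cache.clear()


def _tom_chain_all(
    nets: ToMNetworks,
    world: GridWorld,
    self_obs: GridObservation,
    ped_ids,
    position_overrides: dict | None = None,
):
    """Run the full inference chain for every listed pedestrian.

    Phase one infers, per pedestrian, its observation, behaviour style,
    next action, and next cell.  Phase two builds each pedestrian's
    predicted time-t+1 configuration -- the *other* agents placed at
    their own predicted next cells (the observer at its current cell,
    unless ``position_overrides`` supplies its intended next cell) --
    and evaluates its safety.  Evaluating against predicted rather
    than current positions is what lets the module flag the dominant
    collision mode: two agents converging on the same empty cell.

    Returns (estimates, predicted_states, contexts), aligned lists; the
    contexts carry the exact input vectors fed to the trainable
    submodules so a later reward can credit precisely what was used.
    """
    first_pass = {}
    for ped_id in ped_ids:
        other_goal = world.agents[ped_id].goal
        obs_hat = infer_other_observation(nets.perspective, self_obs, ped_id, other_goal)
        prev = nets.policy_inference.last_estimate.get(ped_id)
        diff_bits = perspective_difference(self_obs, obs_hat)
        if diff_bits[0]:
            nets.diff_counts[ped_id] = nets.diff_counts.get(ped_id, 0) + 1
        # observed contact, blamed on the mover: the agent shares a cell
        # with someone and it is the one that moved there (positions at t
        # and t-1 are both watched).  Walking into occupied space is the
        # one behavioural signature that separates agents who ignore
        # others from agents who give way.
        ped_pos = self_obs.visible_agents.get(ped_id)
        others_now = {
            i: p for i, p in world.active_positions().items() if i != ped_id
        }
        prev_pos = nets.last_positions.get(ped_id)
        if (
            ped_pos is not None
            and ped_pos in others_now.values()
            and prev_pos is not None
            and prev_pos != ped_pos
        ):
            nets.unsafe_counts[ped_id] = nets.unsafe_counts.get(ped_id, 0) + 1
        if ped_pos is not None:
            nets.last_positions[ped_id] = ped_pos
        style_features = style_input_features(
            prev,
            diff_bits,
            nets.last_safety.get(ped_id),
            unsafe_count=nets.unsafe_counts.get(ped_id, 0),
            diff_count=nets.diff_counts.get(ped_id, 0),
        )
        style, _, _ = _forward_decode(nets.policy_inference, style_features)
        if style is None:
            style = prev
        nets.policy_inference.last_estimate[ped_id] = style
        if style is None:
            stim = encode_observation(obs_hat).active_channels
            action_features = np.concatenate([stim, stim, stim])
        else:
            action_features = _action_input(obs_hat, style)
        action_label, _, _ = _forward_decode(
            nets.action_prediction, action_features, nets.action_prediction.inhibition
        )
        action_hat = action_label if action_label is not None else "stay"
        other_pos = self_obs.visible_agents.get(ped_id, obs_hat.self_position)
        next_cell = predict_next_state(world, other_pos, action_hat)
        first_pass[ped_id] = (
            obs_hat,
            style,
            action_hat,
            next_cell,
            style_features,
            action_features,
            action_label is None,
        )

    predicted_positions = {i: p for i, p in world.active_positions().items()}
    if position_overrides:
        predicted_positions.update(position_overrides)
    for ped_id, entry in first_pass.items():
        predicted_positions[ped_id] = entry[3]

    estimates, predicted_states, contexts = [], [], []
    for ped_id in ped_ids:
        (
            obs_hat,
            style,
            action_hat,
            next_cell,
            style_features,
            action_features,
            silent_action,
        ) = first_pass[ped_id]
        predicted_state = replace(
            obs_hat,
            self_position=next_cell,
            visible_agents={
                i: p for i, p in predicted_positions.items() if i != ped_id
            },
            visible_mask=None,
        )
        predicted_state.__post_init__()
        safety = evaluate_safety(nets.state_evaluation, predicted_state)
        nets.last_safety[ped_id] = safety
        estimates.append(
            ToMEstimate(
                agent_id=ped_id,
                other_observation=obs_hat,
                style=style,
                predicted_action=action_hat,
                predicted_state=next_cell,
                safety=safety,
            )
        )
        predicted_states.append(predicted_state)
        contexts.append(
            {
                "style_features": style_features,
                "action_features": action_features,
                "silent_action": silent_action,
            }
        )
    return estimates, predicted_states, contexts


def _tom_chain(nets: ToMNetworks, world: GridWorld, self_obs: GridObservation, ped_id: int):
    """Single-pedestrian convenience wrapper around the full chain."""
    estimates, predicted_states, contexts = _tom_chain_all(nets, world, self_obs, [ped_id])
    return estimates[0], predicted_states[0], contexts[0]


def _safety_bits(last_safety: str | None) -> np.ndarray:
    bits = np.zeros(4, dtype=np.uint8)
    if last_safety == "safe":
        bits[0] = 1
    elif last_safety == "unsafe":
        bits[1] = 1
    return bits


def bystander_step(
    nets: ToMNetworks,
    decision_net: DecisionNetwork,
    world: GridWorld,
    bystander_id: int = 0,
    rng: np.random.Generator | None = None,
    stp=None,
):
    """One bystander decision with the full ToM chain.

    The bystander first forms its own intended move (an efference copy)
    and feeds it into the predicted time-t+1 configuration, then runs
    the chain for every visible pedestrian.  If any is judged unsafe,
    the lowest-id unsafe pedestrian is helped: its action is overridden
    to ``stay`` this step and the help flag is raised, while the
    bystander spends the step helping (it stays too).  Otherwise it
    carries out its intended move.

    Returns (bystander action, helped pedestrian id or None, estimates).
    """
    self_obs = observe(world, bystander_id)
    intended = act(decision_net, self_obs, rng=rng, stp=stp)
    intended_cell = predict_next_state(world, self_obs.self_position, intended)
    estimates, _, _ = _tom_chain_all(
        nets,
        world,
        self_obs,
        sorted(self_obs.visible_agents),
        position_overrides={bystander_id: intended_cell},
    )
    predicted_cells = {e.agent_id: e.predicted_state for e in estimates}
    helped: int | None = None
    for estimate in estimates:
        if helped is not None or estimate.safety != "unsafe":
            continue
        # an intervention must not itself create a collision: a frozen
        # pedestrian becomes an obstacle, so skip it if someone else is
        # predicted to walk into the cell it would be held on
        held_cell = self_obs.visible_agents[estimate.agent_id]
        others_into_held = any(
            cell == held_cell
            for other_id, cell in predicted_cells.items()
            if other_id != estimate.agent_id
        ) or intended_cell == held_cell
        if not others_into_held:
            helped = estimate.agent_id
    if helped is not None:
        return "stay", helped, estimates
    return intended, None, estimates


# ---------------------------------------------------------------------------
# training

def train_tom(
    cfg: TrainingConfig,
    policy_nets: dict | None = None,
    window_length: int = 20,
) -> ToMNetworks:
    """Train the ToM submodules by observing pedestrians, 300 episodes.

    Each episode draws a random environment holding a stationary
    observer and pedestrians of random style: either two pedestrians in
    the open or a single pedestrian among walls.  At every step the
    observer runs the full chain per pedestrian, then receives the
    pedestrian's actual action and the realised configuration, and
    updates: policy inference with ``e_bs``, action prediction with
    ``e_action``, state evaluation with the teacher-clamped rule.  The
    perspective weights never change.

    ``policy_nets`` maps style -> trained :class:`DecisionNetwork`; when
    omitted the scripted policies drive the pedestrians.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    nets = ToMNetworks.fresh(rng, window_length)
    for episode in range(cfg.episodes):
        two_agents = bool(rng.integers(0, 2))
        ped_styles = [str(rng.choice(STYLES)) for _ in range(2 if two_agents else 1)]
        world = generate_environment(
            rng,
            n_agents=1 + len(ped_styles),
            styles=["reckless", *ped_styles],
            include_walls=not two_agents,
        )
        nets.reset_memory()
        ped_stp = {i: None for i in range(world.n_agents)}
        if policy_nets is not None:
            from .agents import ShortTermState

            ped_stp = {i: ShortTermState() for i in range(world.n_agents)}
        for _ in range(cfg.step_cap):
            if all(a.done for a in world.agents[1:]):
                break
            self_obs = observe(world, 0)
            ests, pstates, ctxs = _tom_chain_all(
                nets, world, self_obs, sorted(self_obs.visible_agents)
            )
            pending = [
                (e.agent_id, e, ps, ctx) for e, ps, ctx in zip(ests, pstates, ctxs)
            ]
            actions = {0: "stay"}
            for i, agent in enumerate(world.agents):
                if i == 0 or agent.done:
                    continue
                ped_obs = observe(world, i)
                if policy_nets is not None and agent.policy in policy_nets:
                    actions[i] = act(policy_nets[agent.policy], ped_obs, rng=rng, stp=ped_stp[i])
                else:
                    actions[i] = scripted_policy(agent.policy, ped_obs)
            for ped_id, estimate, predicted_state, ctx in pending:
                actual_style = world.agents[ped_id].policy
                actual_action = actions[ped_id]
                # policy inference update; a silent module emits a random
                # exploratory guess so learning cannot freeze in silence
                emitted_style = estimate.style
                if emitted_style is None:
                    emitted_style = str(rng.choice(STYLES))
                    nets.policy_inference.last_estimate[ped_id] = emitted_style
                e_bs = style_reward(
                    emitted_style,
                    actual_style,
                    nets.policy_inference.gamma,
                    nets.policy_inference.beta,
                )
                # error-driven dopamine: a positive e_bs potentiates the
                # emitted population; a negative e_bs mildly depresses it
                # (gain 0.2) and the same trace potentiates the population
                # coding the style the agent actually displayed.  Crediting
                # only the emitted population is unstable here -- a guess is
                # wrong twice as often as right, so every weight drifts
                # negative and the module falls silent; full-strength
                # depression instead makes the resting preference an
                # arbitrary emission-dynamics artifact rather than tracking
                # the observed style frequencies
                _reinforce(
                    nets.policy_inference,
                    ctx["style_features"],
                    emitted_style,
                    e_bs if e_bs > 0 else 0.2 * e_bs,
                )
                if e_bs < 0:
                    _reinforce(nets.policy_inference, ctx["style_features"], actual_style, 1.0)
                # action prediction update, with the same exploratory
                # emission and asymmetric dopamine gain (threshold at the
                # 1-in-5 chance level) as the style module
                emitted_action = estimate.predicted_action
                if emitted_action == "stay" and ctx.get("silent_action", False):
                    emitted_action = str(rng.choice(ACTIONS))
                e_action = 1.0 if emitted_action == actual_action else -1.0
                _reinforce(
                    nets.action_prediction,
                    ctx["action_features"],
                    emitted_action,
                    e_action if e_action > 0 else 0.25 * e_action,
                )
                # state evaluation teacher
                _teach_state_evaluation(nets.state_evaluation, predicted_state)
            world, _ = step_world(world, actions)
    return nets


def _reinforce(net, features: np.ndarray, emitted: str, reward: float) -> None:
    """R-STDP update crediting the module's emitted prediction.

    The emitted label's population is clamped in the credited raster
    (efference copy), the window trace is rebuilt from the exact input
    used at inference time, and the scalar error converts it into a
    weight change.
    """
    T = net.window.window_length
    in_raster = SpikeRaster(np.tile(np.asarray(features, np.uint8)[:, None], (1, T)))
    forced = np.zeros((net.partition.n_neurons, T), dtype=np.uint8)
    forced[net.partition.neuron_slice(net.partition.labels.index(emitted)), :] = 1
    window_trace(net.synapses, in_raster, SpikeRaster(forced))
    apply_reward(net.synapses, reward)
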