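# Model and methods

`tomsnn` implements a multi-module spiking neural network in which a
bystander agent infers the mental states of other agents in a partially
observable gridworld and intervenes to keep them out of collisions.
This note documents the model, its assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## Neuron and network model

All networks are two-layer, fully connected, feed-forward spiking
networks.  Output-layer neurons are leaky integrate-and-fire (LIF)
units integrated by explicit Euler with `dt = 1 ms`:

    V(t) = V(t-1) + dt/tau_m * ( -(V(t-1) - V_rest) + R*I(t) )

with `V_th = -55 mV`, `V_rest = -75 mV`, `tau_m = 20 ms`, and a
dimensionless membrane resistance `R = 1`.  A neuron whose updated
potential reaches threshold emits a spike and hard-resets to rest;
there is no refractory period.  Input-layer neurons are forced spike
sources: a neuron fires on every step while its feature channel is
active.  One decision takes one simulation window (`T = 50` steps by
default; the benchmark pipeline uses `T = 20`, which we found loses no
decision accuracy at a 2.5x speedup because decisions are read out from
population spike counts, not precise timing).

Four mechanisms, all standard in LIF modelling, shape the decision
readout:

* **Divisive input normalisation.**  The per-step current is divided by
  the square root of the number of presynaptic spikes, so the output
  layer sits in its sensitive range whether one channel or a dozen are
  active.  Without it, the operating point saturates and population
  counts stop discriminating.
* **Heterogeneous excitability.**  Neuron k of each J-neuron output
  population has a fixed gain factor `1 - s/2 + s*k/(J-1)` (spread
  `s = 0.4`).  The population count then rises smoothly with input
  current instead of jumping in steps of J, which sharply reduces
  winner-take-all ties.
* **Membrane noise.**  When a random generator is supplied (training
  and benchmark evaluation), each output neuron receives zero-mean
  Gaussian current noise (sigma = 2) per step.  Noise randomises
  near-tie decisions and leaves strong preferences intact.
* **Short-term synaptic depression.**  The input drive passes through
  Tsodyks-Markram-style release probabilities: channels active over
  consecutive windows depress (release fraction `u`) and recover
  between uses (`rec` per window).  While an agent makes progress its
  active channel set turns over every step and depression never
  builds; an agent stuck in a repeating configuration depresses its
  own drive until the decision degrades to a near-tie or silence and
  randomness breaks the loop.  Behaving agents use `u = 0.3,
  rec = 0.15`; during plasticity the milder `u = 0.15, rec = 0.3`
  keeps the eligibility trace representative of the full stimulus.
  Without the last two mechanisms the deterministic greedy policy
  locks into wall-pushing loops and two-cycles in 20-30% of episodes;
  with them, under 5%.

## Plasticity

Pair-based STDP with nearest-neighbour accounting: each spike pairs
with the most recent spike on the opposite side of the synapse;
same-step spikes pair with nothing.  The pair value is
`A+ * exp(dt/tau+)` for pre-before-post and `-A- * exp(-dt/tau-)`
otherwise, with `A+ = 0.925`, `A- = 0.1`, `tau+ = tau- = 20 ms`.
Pair values accumulate in a per-synapse eligibility trace leaking with
`tau_e = 5 ms`.  A scalar reward delivered at the end of a decision
window converts the trace into a weight change `dw = eta * e * r`
(`eta = 0.1`), and weights are clipped to [-1, 1] after every update.

Credit assignment under exploration: the executed action's population
is clamped to fire in the credited raster (an efference copy), so the
reward always modifies the synapses of the action actually taken even
when it was an explored rather than chosen action.

A reward-prediction-error baseline (subtracting a running mean reward)
was evaluated and rejected: the navigation reward is fractional
progress, which scales as 1/distance, so a global baseline punishes
correct actions in far-from-goal states and measurably degrades the
learned policy.

## Observation code

An observation is encoded over `7*7*(4+8) = 588` binary channels, 12
per cell: wall, own goal, two reserved channels, and eight
agent-identity slots.  The code mixes absolute and relative position
information: walls, the goal, and visible other agents are placed
relative to the observer (a feature at offset (dr, dc) activates the
channel of cell (3+dr, 3+dc)), while the observer's own channel stays
absolute.  Each feature class has a receptive-field radius matched to
its behavioural range: the goal is always present (offset clipped to
the window, direction preserved), agents appear within two cells,
walls within one.  Two properties of this code carry the learning
results: the sensorimotor mapping becomes a direct association
(feature-at-relative-cell -> action), which a one-layer reward-gated
readout can actually acquire; and the stimulus is sparse with every
active channel decision-relevant, which matters because reward-gated
updates hit all active synapses alike -- channels that cannot inform
the decision only accumulate correlated noise and dilute the channels
that can.  (An always-active visibility-mask block was evaluated and
removed for exactly that reason.)

Behaviour styles are coded by three 6-neuron populations (reckless,
experienced, cautious); actions by five 6-neuron populations (up,
down, left, right, stay).  Decoding applies subtractive lateral
inhibition between populations (strength 0.1; provably
order-preserving) and takes the population with the most spikes; an
all-silent raster yields a sentinel handled per module.

## Environment

A 7x7 grid with one random straight wall segment of 2-4 cells, three
agents with distinct random starts and goals (all off-wall, goals
BFS-reachable; rejection sampling).  Movement is simultaneous over
up/down/left/right/stay.  Bumping a wall or the edge leaves the agent
in place; two agents ending on one cell, or swapping cells, are in
collision.  An agent reaching its goal leaves the grid.  Occlusion:
a cell is visible iff the straight segment between cell centres
touches no wall cell (exact integer-arithmetic segment/square test;
symmetric by construction).  Walls and goals are globally known;
line-of-sight occlusion of *agents* is the only partial observability
-- and the source of false beliefs.

Per-step rewards by style (Dp = Euclidean distance to goal, Dw = to
nearest wall): reckless `(Dp' - Dp)/Dp'`; experienced the same but -5
on any collision (including wall bumps); cautious adds a wall term
`(Dw - Dw')/Dw'` and takes -5 on collision or whenever `Dw' <= 1`.
The performance *score* of an episode, in contrast, charges only
agent-agent collisions: `P = max(50 - 3t - 40*[collision] -
10*[helped], 0)`.

## Policy training

Each style's decision network trains with R-STDP over 1500 episodes of
fresh random environments (the collision-sensitive styles train
alongside one scripted reckless opponent so collisions actually
occur), with epsilon-greedy exploration annealed linearly from 1.0 to
a floor of 0.1.  The trained reckless policy reaches its goal in a
mean of ~5.7-6.2 steps against a BFS optimum of ~4.9, failing to
finish within the 30-step cap in roughly 5% of episodes.  The residual
failures are structural: a policy rewarded by per-step fractional
progress cannot represent detours around walls (temporarily moving
away from the goal is punished in the very step it happens), so goal
positions directly behind walls remain hard.

## Theory-of-mind modules

For each visible pedestrian the bystander runs a fixed chain:

1. **Perspective taking** (fixed gating weights, never trained):
   reconstructs the pedestrian's observation from its position; agents
   outside the pedestrian's line of sight are inhibited even when the
   bystander sees them plainly.  Falls back to a per-agent cached
   estimate when the pedestrian is occluded.
2. **Policy inference** (R-STDP on the style error
   `e_bs = -gamma*mismatch + beta`, gamma=2, beta=1, so e_bs is +1 or
   -1): classifies the pedestrian's style from a 14-channel context --
   its previous estimated style (one channel per style; all three for
   the uniform prior before any estimate exists), four
   perspective-difference bits, last safety status, and two cumulative
   episode-evidence bits (the pedestrian was observed moving into
   contact with another agent; its perspective diverged repeatedly).
   A positive e_bs potentiates the emitted population; a negative e_bs
   mildly depresses it (gain 0.2) and potentiates the population of
   the style actually displayed.  Crediting only the emitted
   population is unstable: a three-way guess is wrong twice as often
   as right, so every weight drifts negative and the module falls
   silent; full-strength depression instead leaves the module's
   resting preference an emission-dynamics artifact rather than a
   reflection of the observed style frequencies.  A silent module
   during training emits an exploratory random style so learning
   cannot freeze.
3. **Action prediction** (R-STDP on the action-match error
   `e_action = +-1`, depressive gain 0.25 -- the chance threshold for
   five classes): predicts the pedestrian's next action from its
   inferred observation, placed in the input block of its inferred
   style (the x3 style-conditioned input layout).  Reaches ~60% next-action
   accuracy against an ~88% ceiling set by the pedestrians' own
   decision noise.
4. **State evaluation** (teacher-clamped STDP): maps the pedestrian's
   predicted time-t+1 configuration -- all agents placed at their
   predicted next cells, encoded egocentrically around the
   pedestrian's predicted cell -- onto safe/unsafe populations.
   During training the correct population is clamped to fire and
   potentiated while the incorrect one is clamped and depressed
   (risky configurations, the rarer class, get doubled updates).  The
   taught predicate is *imminent* collision: another agent within one
   cell of the predicted position.  Exact co-occupancy alone comes too
   late -- single-step predictions of stochastic policies are least
   reliable precisely in the near-tie moments that produce collisions.
   The observed agent itself is not encoded (it is always at the
   centre by construction and would only dilute the discriminating
   channels).  Post-training agreement with the predicate on an
   enumerated state set exceeds 90%.

If any pedestrian is judged unsafe, the bystander spends the step
helping: the lowest-id unsafe pedestrian's action is overridden to
"stay" and the bystander stays too; the help cost is charged once per
episode.  The bystander forms its own intended move first and feeds it
into the predicted configuration (an efference copy), which is what
lets the chain flag pedestrians converging on the bystander's own
path.

ToM training runs 300 episodes of random environments containing a
stationary observer and either two pedestrians in the open or one
pedestrian among walls, pedestrians driven by the trained policy
networks (scripted greedy stand-ins are available for deterministic
tests).

## Known limitations

* Style classification operates near the information ceiling of its
  cue set (~40% for three classes): cautious and experienced agents
  are close to behaviourally indistinguishable in these environments,
  so identification rests mainly on detecting reckless contact
  behaviour.  Some training seeds land at or below chance; the module
  is the weakest link of the chain.
* Safety prediction is limited by single-step action-prediction
  accuracy, and the limitation is sharp at exactly the wrong moments:
  overall next-action accuracy is ~60%, but measured *at the steps
  where collisions actually occur* it falls to chance (~20%), because
  collisions between stochastic policies happen precisely when
  membrane noise decides a near-tie.  With the precise co-occupancy
  risk definition, interventions are therefore rare and the measured
  with/without-ToM difference in collision counts sits at the noise
  level; with a looser proximity definition, interventions fire in
  almost half of all episodes and their cumulative cost exceeds the
  collisions they prevent.  The shipped model uses the precise
  definition.  Deterministic or strongly habitual pedestrians -- the
  regime the false-belief narrative presumes -- would be far more
  predictable and give the bystander real leverage.
* Agent-agent collisions cost the bystander about 7 score points per
  hundred episodes on average (an ~18% episode collision rate at 40
  points each) and are the single largest gap between this
  implementation's bystander scores (roughly 22-31, depending on the evaluation environment set) and the reference pattern
  (36-38), which implies near-zero incident rates.
* The scripted policies are idealised greedy rules, not fits to the
  trained networks; tests that use them check the machinery, not the
  trained agents' exact behaviour.
* Scores depend on the environment distribution (uniform random
  starts/goals give a mean BFS distance of ~4.9, capping the expected
  clean-run score near 35); distributions with shorter routes would
  shift all reported means upward.
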