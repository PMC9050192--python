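# tomsnn

A spiking neural network model of theory-of-mind helping: a bystander
agent watches other agents in a partially observable gridworld, infers
what they can see, what policy they follow and what they will do next,
and steps in to stop them when they are about to collide.

The package is for computational-neuroscience and multi-agent-safety
researchers who want a fully inspectable, biologically grounded
alternative to end-to-end learned observer models: every module has an
interpretable output (an inferred observation, a behaviour-style label,
a predicted action, a safety verdict), and all learning is local and
reward-modulated.

## The model

Agents navigate a 7x7 grid with a random blocking wall.  Walls occlude
line of sight, so an agent may hold a *false belief* about where others
are.  Three behaviour styles are defined by their reward functions
(`Dp` = Euclidean distance to goal, `Dw` = to nearest wall):

    reckless      r = (Dp_{t-1} - Dp_t) / Dp_{t-1}
    experienced   same, but r = -5 on any collision
    cautious      adds (Dw_t - Dw_{t-1}) / Dw_{t-1}, with r = -5 on
                  collision or when Dw_{t-1} <= 1

Each style's policy is a two-layer network of leaky integrate-and-fire
neurons (V_th = -55 mV, V_rest = -75 mV, tau_m = 20 ms) mapping a
588-channel population code of the observation onto five action
populations, trained with reward-modulated STDP: nearest-neighbour
spike pairs (A+ = 0.925, A- = 0.1, tau+/- = 20 ms) accumulate in an
eligibility trace (tau_e = 5 ms) that a scalar reward converts into a
weight change, `dw = eta * e * r`, with weights kept in [-1, 1].

The bystander runs four submodules per visible pedestrian: perspective
taking (fixed gating; occluded agents are inhibited from the inferred
view), policy inference (R-STDP on the style error
`e_bs = -2*mismatch + 1`), action prediction (R-STDP on the match error
`e_action = +-1`), and state evaluation (teacher-clamped STDP mapping
the predicted next configuration onto safe/unsafe populations).  An
unsafe verdict makes the bystander stop that pedestrian for the step.
Episode quality is scored as

    P = max(50 - 3t - 40*[collision] - 10*[helped], 0).

See `docs/methods.md` for the full model description and the design
decisions.

## A worked example

`examples/navigate_gridworld.py` trains a reckless policy for 800
episodes and rolls it out greedily on a fresh world:

    trained 800 episodes; goal reach rate over the last 80: 0.91

    fresh world: start (1, 1), goal (5, 3), walls [(3, 2), (4, 2), (5, 2), (6, 2)]
    shortest path: 6 steps
    greedy rollout (6 steps): [(1, 1), (2, 1), (2, 2), (2, 3), (3, 3), (4, 3), (5, 3)]

The rollout matches the BFS-optimal path: the network's goal-relative
channels have learned the direction map, and the run skirts the wall
without bumping it.  The other scripts in `examples/` demonstrate the
LIF neuron against its closed-form firing time, the STDP/eligibility
arithmetic, false-belief inference through a wall, and a reduced-scale
with/without-ToM benchmark.

A thin CLI wraps the same library calls:

    tomsnn train-policy --style reckless --episodes 1500 --seed 1 --out reckless.h5
    tomsnn train-tom --episodes 300 --seed 1 --policies weights/ --out tom.h5
    tomsnn evaluate --style cautious -n 100 --seed 1 --policies weights/ --tom tom.h5 --out results.csv
    tomsnn demo --seed 3

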