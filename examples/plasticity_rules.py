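"""The STDP window and a reward-modulated weight update, step by step.

Prints the pair-based STDP curve at its standard parameters
(A+ = 0.925, A- = 0.1, tau+ = tau- = 20 ms), then walks one synapse
through a pre-before-post pairing, shows the eligibility trace it
leaves behind (tau_e = 5 ms leak), and applies a dopamine-like reward
to turn the trace into a weight change.
"""

import numpy as np

from tomsnn.plasticity import (
    SpikeHistory,
    STDPParams,
    SynapseMatrix,
    accumulate_trace,
    apply_reward,
    stdp_window,
)

params = STDPParams()
print("STDP window (delta_t = t_pre - t_post):")
for dt in (-40, -20, -5, -1, 1, 5, 20, 40):
    print(f"  STDP({dt:+4d} ms) = {stdp_window(dt, params):+.4f}")
print("  pre-before-post potentiates (LTP), the reverse depresses (LTD).\n")

syn = SynapseMatrix(np.zeros((1, 1)), learning_rate=0.1)
hist = SpikeHistory.empty(1, 1)
one, none = np.ones(1, np.uint8), np.zeros(1, np.uint8)
accumulate_trace(syn, one, none, hist)          # t=1 ms: presynaptic spike
for _ in range(4):
    accumulate_trace(syn, none, none, hist)     # t=2..5 ms: silence
accumulate_trace(syn, none, one, hist)          # t=6 ms: postsynaptic spike
print(f"trace after a pre->post pair 5 ms apart: {syn.traces[0,0]:.4f}")
print(f"  (the pair value 0.925*exp(-5/20) = {0.925*np.exp(-5/20):.4f})")

apply_reward(syn, 1.0)
print(f"weight after reward r=+1 with eta=0.1:    {syn.weights[0,0]:+.4f}")
syn.weights[:] = 0
apply_reward(syn, -1.0)
print(f"same trace but reward r=-1:               {syn.weights[0,0]:+.4f}")
print()
print("Reward reverses the sign of the change: the trace only marks the")
print("synapse; dopamine decides whether the mark becomes potentiation.")
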