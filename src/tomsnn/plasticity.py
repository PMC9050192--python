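"""STDP window, eligibility traces, and reward-modulated weight updates.

Spike-timing-dependent plasticity assigns a signed value to each
pre/post spike pair as a function of the timing difference
``delta_t = t_pre - t_post``:

    STDP(dt) =  A+ * exp(dt / tau+)    for dt < 0   (pre before post, LTP)
             = -A- * exp(-dt / tau-)   for dt > 0   (post before pre, LTD)

Simultaneous spikes (``delta_t == 0``) contribute nothing.  Pairing is
nearest-neighbour: a spike interacts only with the most recent spike on
the opposite side of the synapse.  Pair contributions are accumulated in
a per-synapse eligibility trace that leaks with time constant ``tau_e``;
a scalar reward delivered at the end of a decision window converts the
trace into a weight change (``dw = eta * e * r``), and weights are kept
normalised to the closed interval [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .snn_core import SpikeRaster

__all__ = [
    "STDPParams",
    "SynapseMatrix",
    "RewardSignal",
    "SpikeHistory",
    "stdp_window",
    "accumulate_trace",
    "window_trace",
    "apply_reward",
    "unsupervised_stdp_update",
]


@dataclass(frozen=True)
class STDPParams:
    """Amplitudes and time constants of the pair-based STDP window."""

    a_plus: float = 0.925
    a_minus: float = 0.1
    tau_plus: float = 20.0
    tau_minus: float = 20.0

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")


@dataclass
class SynapseMatrix:
    """Input->output weights with paired eligibility traces.

    ``weights`` and ``traces`` are both outputs x inputs.  Weights stay in
    [-1, 1] after every update; traces are unbounded but leak with
    ``tau_e``.
    """

    weights: np.ndarray
    traces: np.ndarray | None = None
    tau_e: float = 5.0
    learning_rate: float = 0.1
    stdp: STDPParams = field(default_factory=STDPParams)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be outputs x inputs")
        if np.abs(self.weights).max(initial=0.0) > 1.0:
            raise ValueError("weights must lie in [-1, 1]")
        if self.traces is None:
            self.traces = np.zeros_like(self.weights)
        else:
            self.traces = np.asarray(self.traces, dtype=float)
            if self.traces.shape != self.weights.shape:
                raise ValueError("traces must have the same shape as weights")
        if self.tau_e <= 0:
            raise ValueError("tau_e must be positive")

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def random_init(
        cls,
        n_outputs: int,
        n_inputs: int,
        rng: np.random.Generator,
        low: float = 0.0,
        high: float = 0.3,
        **kwargs,
    ) -> "SynapseMatrix":
        return cls(rng.uniform(low, high, size=(n_outputs, n_inputs)), **kwargs)


@dataclass(frozen=True)
class RewardSignal:
    """Scalar neuromodulatory signal (dopamine analogue)."""

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("reward must be finite")


def stdp_window(delta_t, params: STDPParams | None = None):
    """Signed pair contribution for timing difference ``delta_t`` (ms).

    Accepts scalars or arrays; ``delta_t == 0`` maps to 0.
    """
    params = params or STDPParams()
    dt = np.asarray(delta_t, dtype=float)
    out = np.where(
        dt < 0,
        params.a_plus * np.exp(dt / params.tau_plus),
        -params.a_minus * np.exp(-dt / params.tau_minus),
    )
    out = np.where(dt == 0, 0.0, out)
    if np.isscalar(delta_t) or np.ndim(delta_t) == 0:
        return float(out)
    return out


@dataclass
class SpikeHistory:
    """Most recent spike time per neuron on each side of a synapse matrix.

    Times are in steps since the start of the window; ``-inf`` marks a
    neuron that has not fired yet.
    """

    last_pre: np.ndarray
    last_post: np.ndarray
    t: float = 0.0

    @classmethod
    def empty(cls, n_outputs: int, n_inputs: int) -> "SpikeHistory":
        return cls(
            np.full(n_inputs, -np.inf),
            np.full(n_outputs, -np.inf),
        )


def accumulate_trace(
    syn: SynapseMatrix,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    spike_history: SpikeHistory,
    dt: float = 1.0,
) -> SynapseMatrix:
    """Advance the eligibility traces by one step of length ``dt``.

    The trace first leaks by ``exp(-dt/tau_e)``, then receives
    nearest-neighbour STDP impulses for every spike occurring on this
    step.  Spikes on the same step are treated as simultaneous and pair
    with nothing.  ``spike_history`` is updated in place.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    pre = np.asarray(pre_spikes, dtype=bool)
    post = np.asarray(post_spikes, dtype=bool)
    if pre.shape != (syn.n_inputs,) or post.shape != (syn.n_outputs,):
        raise ValueError("spike vector shapes do not match the synapse matrix")
    p = syn.stdp
    t = spike_history.t + dt
    syn.traces *= np.exp(-dt / syn.tau_e)
    # LTP: each post spike pairs with the most recent earlier pre spike.
    if post.any():
        with np.errstate(over="ignore"):
            ltp = p.a_plus * np.exp((spike_history.last_pre - t) / p.tau_plus)
        ltp = np.where(np.isfinite(spike_history.last_pre), ltp, 0.0)
        syn.traces += np.outer(post.astype(float), ltp)
    # LTD: each pre spike pairs with the most recent earlier post spike.
    if pre.any():
        with np.errstate(over="ignore"):
            ltd = -p.a_minus * np.exp(-(t - spike_history.last_post) / p.tau_minus)
        ltd = np.where(np.isfinite(spike_history.last_post), ltd, 0.0)
        syn.traces += np.outer(ltd, pre.astype(float))
    spike_history.last_pre[pre] = t
    spike_history.last_post[post] = t
    spike_history.t = t
    return syn


def window_trace(
    syn: SynapseMatrix, pre_raster: SpikeRaster, post_raster: SpikeRaster
) -> np.ndarray:
    """Eligibility trace accumulated over one full window, from zero.

    Convenience wrapper running :func:`accumulate_trace` over aligned
    pre/post rasters; the result is left in ``syn.traces`` and returned.
    """
    if pre_raster.n_steps != post_raster.n_steps:
        raise ValueError("pre and post rasters must cover the same steps")
    syn.traces = np.zeros_like(syn.weights)
    hist = SpikeHistory.empty(syn.n_outputs, syn.n_inputs)
    for t in range(pre_raster.n_steps):
        accumulate_trace(
            syn, pre_raster.spikes[:, t], post_raster.spikes[:, t], hist, dt=pre_raster.dt
        )
    return syn.traces


def apply_reward(syn: SynapseMatrix, reward: RewardSignal | float) -> SynapseMatrix:
    """Convert the current eligibility trace into a clipped weight change."""
    r = reward.value if isinstance(reward, RewardSignal) else float(reward)
    syn.weights = np.clip(syn.weights + syn.learning_rate * syn.traces * r, -1.0, 1.0)
    return syn


def unsupervised_stdp_update(
    syn: SynapseMatrix, pre_raster: SpikeRaster, post_raster: SpikeRaster
) -> SynapseMatrix:
    """Plain STDP weight update from a pair of rasters, no reward gate.

    Nearest-neighbour pair contributions are summed without eligibility
    leak and applied directly: ``w += eta * sum STDP(dt)``, clipped.
    """
    if pre_raster.n_steps != post_raster.n_steps:
        raise ValueError("pre and post rasters must cover the same steps")
    n_out, n_in = syn.weights.shape
    delta = np.zeros_like(syn.weights)
    last_pre = np.full(n_in, -np.inf)
    last_post = np.full(n_out, -np.inf)
    p = syn.stdp
    for t in range(pre_raster.n_steps):
        pre = pre_raster.spikes[:, t].astype(bool)
        post = post_raster.spikes[:, t].astype(bool)
        if post.any():
            with np.errstate(over="ignore"):
                ltp = p.a_plus * np.exp((last_pre - t) / p.tau_plus)
            ltp = np.where(np.isfinite(last_pre), ltp, 0.0)
            delta += np.outer(post.astype(float), ltp)
        if pre.any():
            with np.errstate(over="ignore"):
                ltd = -p.a_minus * np.exp(-(t - last_post) / p.tau_minus)
            ltd = np.where(np.isfinite(last_post), ltd, 0.0)
            delta += np.outer(ltd, pre.astype(float))
        last_pre[pre] = t
        last_post[post] = t
    syn.weights = np.clip(syn.weights + syn.learning_rate * delta, -1.0, 1.0)
    return syn
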