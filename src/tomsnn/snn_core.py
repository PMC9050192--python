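"""Leaky integrate-and-fire dynamics and the two-layer feed-forward pass.

The networks in this package are all two-layer fully connected spiking
networks.  Input-layer neurons act as forced spike sources driven by the
population encoder (a neuron fires on every step while its feature channel
is active); only the output layer carries LIF dynamics.  The membrane
potential of an output neuron follows the discrete leaky integrator

    V(t) = V(t-1) + dt/tau_m * (-(V(t-1) - V_rest) + R * I(t))

and the neuron emits a spike and hard-resets to ``V_rest`` whenever the
updated potential reaches the threshold ``V_th``.  There is no refractory
period.  Outputs are read out by population: the output layer is divided
into equal-size populations, each standing for one categorical value, and
the population with the most spikes over the simulation window wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "LIFLayerState",
    "SpikeRaster",
    "PopulationPartition",
    "WindowConfig",
    "lif_step",
    "integrate_input",
    "forward_window",
    "population_counts",
    "winner_population",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron constants.

    Defaults are the physiologically motivated values used throughout the
    model: threshold -55 mV, rest -75 mV, membrane time constant 20 ms.
    ``membrane_resistance`` is dimensionless (currents are expressed
    directly in millivolt-equivalent drive) and ``dt`` is the Euler step.
    """

    v_threshold: float = -55.0
    v_rest: float = -75.0
    tau_m: float = 20.0
    membrane_resistance: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.v_threshold > self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class LIFLayerState:
    """Membrane potentials of one layer plus its neuron constants."""

    potentials: np.ndarray
    params: NeuronParams = field(default_factory=NeuronParams)

    @classmethod
    def at_rest(cls, n_neurons: int, params: NeuronParams | None = None) -> "LIFLayerState":
        params = params or NeuronParams()
        return cls(np.full(n_neurons, params.v_rest, dtype=float), params)

    @property
    def n_neurons(self) -> int:
        return self.potentials.shape[0]


@dataclass
class SpikeRaster:
    """Binary spike record, ``spikes[neuron, step]`` in {0, 1}."""

    spikes: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=np.uint8)
        if self.spikes.ndim != 2:
            raise ValueError("spike raster must be neurons x steps")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("spike raster entries must be binary")

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    def total_spikes(self) -> int:
        return int(self.spikes.sum())


@dataclass(frozen=True)
class PopulationPartition:
    """Equal-size split of an output layer into labelled populations."""

    population_count: int
    neurons_per_population: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != self.population_count:
            raise ValueError("need one label per population")
        if len(set(self.labels)) != self.population_count:
            raise ValueError("population labels must be distinct")
        if self.population_count < 1 or self.neurons_per_population < 1:
            raise ValueError("partition dimensions must be positive")

    @property
    def n_neurons(self) -> int:
        return self.population_count * self.neurons_per_population

    def neuron_slice(self, population: int) -> slice:
        j = self.neurons_per_population
        return slice(population * j, (population + 1) * j)


@dataclass(frozen=True)
class WindowConfig:
    """Length of one decision window, in integration steps."""

    window_length: int = 50

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")


def lif_step(state: LIFLayerState, input_current: np.ndarray) -> tuple[LIFLayerState, np.ndarray]:
    """Advance one Euler step; spiking neurons emit 1 and reset to rest.

    Returns a new layer state and the binary spike vector.
    """
    input_current = np.asarray(input_current, dtype=float)
    if input_current.shape != state.potentials.shape:
        raise ValueError(
            f"input current shape {input_current.shape} does not match "
            f"{state.potentials.shape} neurons"
        )
    p = state.params
    v = state.potentials + (p.dt / p.tau_m) * (
        -(state.potentials - p.v_rest) + p.membrane_resistance * input_current
    )
    spikes = (v >= p.v_threshold).astype(np.uint8)
    v = np.where(spikes == 1, p.v_rest, v)
    return LIFLayerState(v, p), spikes


def integrate_input(weights: np.ndarray, presyn_spikes: np.ndarray, gain: float = 1.0) -> np.ndarray:
    """Weighted sum of presynaptic spikes per output neuron.

    ``weights`` is outputs x inputs; ``gain`` is a configurable scalar that
    converts a unit synaptic weight into membrane drive.
    """
    weights = np.asarray(weights, dtype=float)
    presyn_spikes = np.asarray(presyn_spikes, dtype=float)
    if weights.ndim != 2:
        raise ValueError("weights must be a 2-D outputs x inputs matrix")
    if presyn_spikes.shape != (weights.shape[1],):
        raise ValueError(
            f"presynaptic spike vector of length {presyn_spikes.shape} does not "
            f"match {weights.shape[1]} inputs"
        )
    return gain * (weights @ presyn_spikes)


def forward_window(
    weights: np.ndarray,
    input_raster: SpikeRaster,
    cfg: WindowConfig,
    inhibition=None,
    partition: PopulationPartition | None = None,
    params: NeuronParams | None = None,
    gain: float = 1.0,
    normalize_input: bool = False,
    neuron_gain: np.ndarray | None = None,
    noise_std: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SpikeRaster:
    """Run the output layer for ``cfg.window_length`` steps.

    The layer starts freshly at rest each window.  If ``inhibition`` (a
    :class:`~tomsnn.coding.LateralInhibitionConfig`) and ``partition`` are
    given, each population receives a subtractive current proportional to
    the other populations' spikes on the previous step.  With
    ``normalize_input`` the per-step current is divided by the square
    root of the number of presynaptic spikes that step (a divisive
    normalisation that keeps the operating point of the output layer in
    its sensitive range whether one channel or a hundred are active).
    ``neuron_gain`` optionally scales each output neuron's drive by a
    fixed per-neuron factor, modelling heterogeneous excitability; a
    graded ladder within each population turns the population spike
    count into a finer-grained, still monotone, function of the input
    current.  ``noise_std`` adds zero-mean Gaussian membrane current
    noise each step (requires ``rng``); the pass is deterministic
    whenever ``noise_std`` is 0 or no generator is supplied.
    """
    weights = np.asarray(weights, dtype=float)
    T = cfg.window_length
    if input_raster.n_steps < T:
        raise ValueError(f"input raster has {input_raster.n_steps} steps, window needs {T}")
    n_out = weights.shape[0]
    state = LIFLayerState.at_rest(n_out, params)
    out = np.zeros((n_out, T), dtype=np.uint8)
    prev_spikes = np.zeros(n_out, dtype=float)
    for t in range(T):
        current = integrate_input(weights, input_raster.spikes[:, t], gain=gain)
        if normalize_input:
            n_active = input_raster.spikes[:, t].sum()
            if n_active > 1:
                current = current / np.sqrt(n_active)
        if neuron_gain is not None:
            current = current * neuron_gain
        if noise_std > 0.0 and rng is not None:
            current = current + rng.normal(0.0, noise_std, size=n_out)
        if inhibition is not None and partition is not None and inhibition.strength > 0:
            # subtract k * (spikes of all other populations last step)
            pop_prev = np.add.reduceat(
                prev_spikes, np.arange(0, n_out, partition.neurons_per_population)
            )
            others = pop_prev.sum() - pop_prev
            current = current - inhibition.strength * gain * np.repeat(
                others, partition.neurons_per_population
            )
        state, spikes = lif_step(state, current)
        out[:, t] = spikes
        prev_spikes = spikes.astype(float)
    return SpikeRaster(out, dt=input_raster.dt)


def population_counts(raster: SpikeRaster, partition: PopulationPartition) -> np.ndarray:
    """Total spike count per population over the whole raster."""
    if raster.n_neurons != partition.n_neurons:
        raise ValueError(
            f"raster has {raster.n_neurons} neurons, partition covers {partition.n_neurons}"
        )
    per_neuron = raster.spikes.sum(axis=1)
    return per_neuron.reshape(partition.population_count, partition.neurons_per_population).sum(axis=1)


def winner_population(counts: np.ndarray, partition: PopulationPartition) -> str:
    """Label of the population with the most spikes; ties go to the lowest index."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    if counts.shape != (partition.population_count,):
        raise ValueError("counts length must equal the population count")
    return partition.labels[int(np.argmax(counts))]
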