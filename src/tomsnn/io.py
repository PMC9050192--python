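"""Serialization: HDF5 weights, CSV rasters/trajectories, JSON layouts.

Weight files hold one group per network with ``weights`` and ``traces``
datasets plus scalar attributes; a JSON sidecar carries the metadata
needed to rebuild the surrounding objects.  Spike rasters export to
tidy CSV (neuron, timestep) and environments round-trip through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .agents import DecisionNetwork
from .coding import channel_layout
from .gridworld import AgentState, GridWorld
from .plasticity import SynapseMatrix
from .snn_core import SpikeRaster, WindowConfig
from .tom import (
    ActionPredictionNetwork,
    PerspectiveNetwork,
    PolicyInferenceNetwork,
    StateEvaluationNetwork,
    ToMNetworks,
)

__all__ = [
    "save_decision_network",
    "load_decision_network",
    "save_tom_networks",
    "load_tom_networks",
    "raster_to_csv",
    "raster_from_csv",
    "world_to_json",
    "world_from_json",
    "write_channel_schema",
]


def _write_synapses(group: h5py.Group, syn: SynapseMatrix) -> None:
    group.create_dataset("weights", data=syn.weights)
    group.create_dataset("traces", data=syn.traces)
    group.attrs["tau_e"] = syn.tau_e
    group.attrs["learning_rate"] = syn.learning_rate
    group.attrs["a_plus"] = syn.stdp.a_plus
    group.attrs["a_minus"] = syn.stdp.a_minus
    group.attrs["tau_plus"] = syn.stdp.tau_plus
    group.attrs["tau_minus"] = syn.stdp.tau_minus


def _read_synapses(group: h5py.Group) -> SynapseMatrix:
    from .plasticity import STDPParams

    return SynapseMatrix(
        weights=group["weights"][...],
        traces=group["traces"][...],
        tau_e=float(group.attrs["tau_e"]),
        learning_rate=float(group.attrs["learning_rate"]),
        stdp=STDPParams(
            a_plus=float(group.attrs["a_plus"]),
            a_minus=float(group.attrs["a_minus"]),
            tau_plus=float(group.attrs["tau_plus"]),
            tau_minus=float(group.attrs["tau_minus"]),
        ),
    )


def save_decision_network(net: DecisionNetwork, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("decision")
        _write_synapses(grp, net.synapses)
        grp.attrs["window_length"] = net.window.window_length
        grp.attrs["gain"] = net.gain
        grp.attrs["style"] = net.style or ""
    sidecar = {"kind": "decision", "labels": list(net.partition.labels)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_decision_network(path) -> DecisionNetwork:
    with h5py.File(path, "r") as fh:
        grp = fh["decision"]
        syn = _read_synapses(grp)
        net = DecisionNetwork(
            syn,
            window=WindowConfig(int(grp.attrs["window_length"])),
            gain=float(grp.attrs["gain"]),
            style=str(grp.attrs["style"]) or None,
        )
    return net


def save_tom_networks(nets: ToMNetworks, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for name, net in (
            ("policy_inference", nets.policy_inference),
            ("action_prediction", nets.action_prediction),
            ("state_evaluation", nets.state_evaluation),
        ):
            grp = fh.create_group(name)
            _write_synapses(grp, net.synapses)
            grp.attrs["window_length"] = net.window.window_length
            grp.attrs["gain"] = net.gain
    sidecar = {"kind": "tom", "modules": ["policy_inference", "action_prediction", "state_evaluation"]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_tom_networks(path) -> ToMNetworks:
    with h5py.File(path, "r") as fh:
        def _mk(name, cls):
            grp = fh[name]
            return cls(
                _read_synapses(grp),
                window=WindowConfig(int(grp.attrs["window_length"])),
                gain=float(grp.attrs["gain"]),
            )

        return ToMNetworks(
            perspective=PerspectiveNetwork(),
            policy_inference=_mk("policy_inference", PolicyInferenceNetwork),
            action_prediction=_mk("action_prediction", ActionPredictionNetwork),
            state_evaluation=_mk("state_evaluation", StateEvaluationNetwork),
        )


def raster_to_csv(raster: SpikeRaster, path) -> None:
    """Tidy spike list: one row per (neuron, timestep) spike event."""
    neurons, steps = np.nonzero(raster.spikes)
    pd.DataFrame({"neuron": neurons, "timestep": steps}).to_csv(path, index=False)


def raster_from_csv(path, n_neurons: int, n_steps: int, dt: float = 1.0) -> SpikeRaster:
    df = pd.read_csv(path)
    spikes = np.zeros((n_neurons, n_steps), dtype=np.uint8)
    spikes[df["neuron"].to_numpy(), df["timestep"].to_numpy()] = 1
    return SpikeRaster(spikes, dt=dt)


def world_to_json(world: GridWorld, path=None) -> str:
    payload = {
        "size": world.size,
        "seed": world.seed,
        "walls": sorted(map(list, world.walls)),
        "agents": [
            {
                "position": list(a.position),
                "goal": list(a.goal),
                "policy": a.policy,
                "done": a.done,
            }
            for a in world.agents
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def world_from_json(source) -> GridWorld:
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(source)
    agents = [
        AgentState(
            position=tuple(a["position"]),
            goal=tuple(a["goal"]),
            policy=a["policy"],
            done=a["done"],
        )
        for a in data["agents"]
    ]
    return GridWorld(
        walls=frozenset(map(tuple, data["walls"])),
        agents=agents,
        size=data["size"],
        seed=data.get("seed"),
    )


def write_channel_schema(path) -> None:
    """Dump the machine-readable channel layout next to exported data."""
    Path(path).write_text(json.dumps(channel_layout(), indent=2))
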