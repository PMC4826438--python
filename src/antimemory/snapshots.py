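"""HDF5 network snapshots, spike-record containers, and run manifests.

A snapshot stores every array of a `NetworkState` plus its spec and neuron
parameters, with a SHA-256 checksum over the array payload so corruption
is detected at load time. Loading a snapshot and continuing integration is
bit-identical to an uninterrupted run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .params import NeuronParams, NetworkSpec, SYNAPSE_CLASSES
from .state import NetworkState, SpikeRecord, Synapses


class SnapshotError(RuntimeError):
    """A snapshot file is missing, truncated, or fails its checksum."""


_STATE_ARRAYS = ("v", "g_exc", "g_inh", "refractory_until",
                 "trace_e", "trace_i", "stimulus_scale")
_SYN_ARRAYS = ("indptr", "targets", "weights")


def _payload_digest(h5: h5py.Group) -> str:
    digest = hashlib.sha256()
    for name in _STATE_ARRAYS:
        digest.update(np.ascontiguousarray(h5["state"][name][...]).tobytes())
    for cls in SYNAPSE_CLASSES:
        for name in _SYN_ARRAYS:
            digest.update(
                np.ascontiguousarray(h5[f"synapses/{cls}"][name][...]).tobytes())
    return digest.hexdigest()


def save_state(state: NetworkState, path) -> str:
    """Write a snapshot; returns the payload checksum."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.attrs["spec_json"] = json.dumps(state.spec.as_dict())
        h5.attrs["params_json"] = json.dumps(state.params.as_dict())
        h5.attrs["t_ms"] = state.t_ms
        h5.attrs["global_inhibition_scale"] = state.global_inhibition_scale
        h5.attrs["drive_rng_state"] = str(state.drive_rng_state)
        grp = h5.create_group("state")
        for name in _STATE_ARRAYS:
            grp.create_dataset(name, data=getattr(state, name))
        for cls in SYNAPSE_CLASSES:
            sgrp = h5.create_group(f"synapses/{cls}")
            syn = state.synapses[cls]
            sgrp.attrs["n_pre"] = syn.n_pre
            sgrp.attrs["n_post"] = syn.n_post
            for name in _SYN_ARRAYS:
                sgrp.create_dataset(name, data=getattr(syn, name))
        checksum = _payload_digest(h5)
        h5.attrs["sha256"] = checksum
    return checksum


def load_state(path) -> NetworkState:
    """Load a snapshot, verifying its checksum; raises `SnapshotError` on
    any corruption (including truncated files)."""
    path = Path(path)
    if not path.exists():
        raise SnapshotError(f"snapshot not found: {path}")
    try:
        with h5py.File(path, "r") as h5:
            stored = h5.attrs.get("sha256")
            if stored is None:
                raise SnapshotError(f"snapshot {path} has no checksum")
            if _payload_digest(h5) != stored:
                raise SnapshotError(f"snapshot {path} failed its checksum")
            spec = NetworkSpec(**json.loads(h5.attrs["spec_json"]))
            params = NeuronParams(**json.loads(h5.attrs["params_json"]))
            arrays = {name: h5["state"][name][...] for name in _STATE_ARRAYS}
            synapses = {}
            for cls in SYNAPSE_CLASSES:
                sgrp = h5[f"synapses/{cls}"]
                synapses[cls] = Synapses(
                    int(sgrp.attrs["n_pre"]), int(sgrp.attrs["n_post"]),
                    sgrp["indptr"][...], sgrp["targets"][...],
                    sgrp["weights"][...])
            return NetworkState(
                spec=spec, params=params,
                v=arrays["v"], g_exc=arrays["g_exc"], g_inh=arrays["g_inh"],
                refractory_until=arrays["refractory_until"],
                synapses=synapses,
                trace_e=arrays["trace_e"], trace_i=arrays["trace_i"],
                global_inhibition_scale=float(
                    h5.attrs["global_inhibition_scale"]),
                stimulus_scale=arrays["stimulus_scale"],
                t_ms=float(h5.attrs["t_ms"]),
                drive_rng_state=int(h5.attrs["drive_rng_state"]))
    except (OSError, KeyError) as exc:
        raise SnapshotError(f"snapshot {path} is unreadable or truncated: "
                            f"{exc}") from exc


def save_spikes_h5(rec: SpikeRecord, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time_ms", data=rec.times)
        h5.create_dataset("neuron_id", data=rec.ids)
        h5.attrs["t_start"] = rec.t_start
        h5.attrs["t_stop"] = rec.t_stop


def load_spikes_h5(path) -> SpikeRecord:
    with h5py.File(path, "r") as h5:
        return SpikeRecord(h5["time_ms"][...], h5["neuron_id"][...],
                           float(h5.attrs["t_start"]),
                           float(h5.attrs["t_stop"]))


# ---------------------------------------------------------------------------
# run manifests

def _file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one run: the exact configuration, master
    seed, substream labels used, simulated-time span, and a checksummed
    inventory of output files."""

    config: dict
    seed: int
    substreams: list = field(default_factory=list)
    t_start_ms: float = 0.0
    t_end_ms: float = 0.0
    outputs: dict = field(default_factory=dict)   # path -> sha256
    schema_version: int = 1

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _file_sha256(path)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "schema_version": self.schema_version,
            "seed": self.seed,
            "substreams": self.substreams,
            "t_start_ms": self.t_start_ms,
            "t_end_ms": self.t_end_ms,
            "outputs": self.outputs,
            "config": self.config,
        }, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(config=data["config"], seed=data["seed"],
                   substreams=data["substreams"],
                   t_start_ms=data["t_start_ms"], t_end_ms=data["t_end_ms"],
                   outputs=data["outputs"],
                   schema_version=data["schema_version"])

    def verify_outputs(self) -> bool:
        return all(Path(p).exists() and _file_sha256(p) == digest
                   for p, digest in self.outputs.items())
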