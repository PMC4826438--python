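"""Mutable simulation state: sparse synapse stores, network state, spike records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import NeuronParams, NetworkSpec, SYNAPSE_CLASSES


@dataclass
class Synapses:
    """One synapse class as a CSR structure keyed by presynaptic neuron.

    ``indptr``/``targets`` give, for presynaptic neuron ``j``, the
    postsynaptic population indices ``targets[indptr[j]:indptr[j+1]]``;
    ``weights`` holds the conductance of each synapse in the same order.
    ``csc_indptr``/``csc_flat``/``csc_pre`` are the transpose view: for
    postsynaptic neuron ``k``, the flat indices into ``weights`` of the
    synapses onto ``k`` and their presynaptic sources (needed by plasticity
    rules triggered by postsynaptic spikes).
    """

    n_pre: int
    n_post: int
    indptr: np.ndarray       # int64, n_pre + 1
    targets: np.ndarray      # int32, nnz
    weights: np.ndarray      # float64, nnz
    csc_indptr: np.ndarray = field(default=None, repr=False)
    csc_flat: np.ndarray = field(default=None, repr=False)
    csc_pre: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.csc_indptr is None:
            self._build_csc()

    def _build_csc(self) -> None:
        nnz = len(self.targets)
        order = np.argsort(self.targets, kind="stable")
        self.csc_flat = order.astype(np.int64)
        counts = np.bincount(self.targets, minlength=self.n_post)
        self.csc_indptr = np.zeros(self.n_post + 1, dtype=np.int64)
        np.cumsum(counts, out=self.csc_indptr[1:])
        pre = np.repeat(
            np.arange(self.n_pre, dtype=np.int32),
            np.diff(self.indptr).astype(np.int64)) if nnz else np.empty(0, np.int32)
        self.csc_pre = pre[order] if nnz else np.empty(0, np.int32)

    @property
    def nnz(self) -> int:
        return len(self.targets)

    def copy(self) -> "Synapses":
        return Synapses(self.n_pre, self.n_post,
                        self.indptr.copy(), self.targets.copy(),
                        self.weights.copy(), self.csc_indptr.copy(),
                        self.csc_flat.copy(), self.csc_pre.copy())

    def dense(self) -> np.ndarray:
        """Dense (n_pre, n_post) weight matrix; zeros where no synapse."""
        m = np.zeros((self.n_pre, self.n_post))
        for j in range(self.n_pre):
            sl = slice(self.indptr[j], self.indptr[j + 1])
            m[j, self.targets[sl]] = self.weights[sl]
        return m


@dataclass
class SpikeRecord:
    """Ordered spike events over a window: (time in ms, global neuron id)."""

    times: np.ndarray        # float64 ms, nondecreasing
    ids: np.ndarray          # int32
    t_start: float
    t_stop: float

    @property
    def n_events(self) -> int:
        return len(self.times)

    def counts(self, n_neurons: int) -> np.ndarray:
        """Per-neuron spike counts over the record window."""
        return np.bincount(self.ids, minlength=n_neurons)

    def select(self, ids) -> "SpikeRecord":
        mask = np.isin(self.ids, np.asarray(ids))
        return SpikeRecord(self.times[mask], self.ids[mask],
                           self.t_start, self.t_stop)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "neuron_id": self.ids})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, t_start=None, t_stop=None) -> "SpikeRecord":
        df = pd.read_csv(path, sep="\t")
        t = df["time_ms"].to_numpy(dtype=np.float64)
        if t_start is None:
            t_start = float(t[0]) if len(t) else 0.0
        if t_stop is None:
            t_stop = float(t[-1]) if len(t) else 0.0
        return cls(t, df["neuron_id"].to_numpy(dtype=np.int32),
                   float(t_start), float(t_stop))

    @staticmethod
    def concatenate(records: list["SpikeRecord"]) -> "SpikeRecord":
        if not records:
            return SpikeRecord(np.empty(0), np.empty(0, np.int32), 0.0, 0.0)
        return SpikeRecord(
            np.concatenate([r.times for r in records]),
            np.concatenate([r.ids for r in records]),
            records[0].t_start, records[-1].t_stop)


@dataclass
class NetworkState:
    """Full mutable state of the recurrent network.

    Neuron indexing is global: excitatory neurons ``0..n_e-1`` first, then
    inhibitory ``n_e..n_e+n_i-1``. ``global_inhibition_scale`` multiplies
    every effective I→E and I→I conductance at spike-propagation time
    (stored weights are untouched, so the manipulation is reversible);
    ``stimulus_scale`` does the same per excitatory target for the
    disinhibition stimulus. ``trace_e``/``trace_i`` are the low-pass spike
    traces of the inhibitory plasticity rule; ``drive_rng_state`` is the
    64-bit counter state of the background-drive noise stream.
    """

    spec: NetworkSpec
    params: NeuronParams
    v: np.ndarray                     # mV, n_total
    g_exc: np.ndarray                 # leak units, n_total
    g_inh: np.ndarray                 # leak units, n_total
    refractory_until: np.ndarray      # ms, n_total
    synapses: dict                    # class -> Synapses
    trace_e: np.ndarray               # n_excitatory
    trace_i: np.ndarray               # n_inhibitory
    global_inhibition_scale: float = 1.0
    stimulus_scale: np.ndarray = None  # n_excitatory, 1.0 = no stimulus
    t_ms: float = 0.0
    drive_rng_state: int = 0

    def __post_init__(self):
        if self.stimulus_scale is None:
            self.stimulus_scale = np.ones(self.spec.n_excitatory)

    @property
    def n_excitatory(self) -> int:
        return self.spec.n_excitatory

    @property
    def n_inhibitory(self) -> int:
        return self.spec.n_inhibitory

    @property
    def n_total(self) -> int:
        return self.spec.n_total

    def copy(self) -> "NetworkState":
        return NetworkState(
            spec=self.spec, params=self.params,
            v=self.v.copy(), g_exc=self.g_exc.copy(), g_inh=self.g_inh.copy(),
            refractory_until=self.refractory_until.copy(),
            synapses={c: s.copy() for c, s in self.synapses.items()},
            trace_e=self.trace_e.copy(), trace_i=self.trace_i.copy(),
            global_inhibition_scale=self.global_inhibition_scale,
            stimulus_scale=self.stimulus_scale.copy(),
            t_ms=self.t_ms, drive_rng_state=self.drive_rng_state)

    def allclose(self, other: "NetworkState", exact: bool = True) -> bool:
        """Array-by-array equality with another state (bit-exact by default)."""
        cmp = np.array_equal if exact else np.allclose
        if not all(cmp(getattr(self, a), getattr(other, a))
                   for a in ("v", "g_exc", "g_inh", "refractory_until",
                             "trace_e", "trace_i", "stimulus_scale")):
            return False
        for c in SYNAPSE_CLASSES:
            if not cmp(self.synapses[c].weights, other.synapses[c].weights):
                return False
            if not np.array_equal(self.synapses[c].targets,
                                  other.synapses[c].targets):
                return False
        return (self.global_inhibition_scale == other.global_inhibition_scale
                and self.t_ms == other.t_ms
                and self.drive_rng_state == other.drive_rng_state)
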