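"""Network construction: Erdős–Rényi sparse connectivity per synapse class."""

from __future__ import annotations

import numpy as np

from .params import NeuronParams, NetworkSpec
from .rng import substream_rng, substream_seed
from .state import NetworkState, Synapses

_CLASS_POPS = {
    # class -> (pre is excitatory?, post is excitatory?)
    "ee": (True, True),
    "ei": (True, False),
    "ie": (False, True),
    "ii": (False, False),
}


def _draw_class(rng: np.random.Generator, n_pre: int, n_post: int,
                p: float, weight: float, exclude_diagonal: bool) -> Synapses:
    if p <= 0.0:
        return Synapses(n_pre, n_post,
                        np.zeros(n_pre + 1, dtype=np.int64),
                        np.empty(0, dtype=np.int32),
                        np.empty(0, dtype=np.float64))
    mask = rng.random((n_pre, n_post)) < p
    if exclude_diagonal:
        np.fill_diagonal(mask, False)
    pre_idx, post_idx = np.nonzero(mask)  # row-major: sorted by pre
    counts = np.bincount(pre_idx, minlength=n_pre)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return Synapses(n_pre, n_post, indptr,
                    post_idx.astype(np.int32),
                    np.full(len(post_idx), weight, dtype=np.float64))


def build_network(spec: NetworkSpec, params: NeuronParams) -> NetworkState:
    """Construct a network at rest with all weights at their baseline values.

    Connectivity for each of the four classes is an independent Erdős–Rényi
    draw at ``spec.connection_probability`` (no self-connections, at most
    one synapse per ordered pair), fully determined by ``spec.seed`` via the
    "connectivity" substream. Membrane potentials start at rest, traces and
    conductances at zero, simulated time at zero.
    """
    spec.validate()
    params.validate()
    rng = substream_rng(spec.seed, "connectivity")
    n_e, n_i = spec.n_excitatory, spec.n_inhibitory
    sizes = {True: n_e, False: n_i}
    synapses = {}
    for cls, (pre_e, post_e) in _CLASS_POPS.items():
        synapses[cls] = _draw_class(
            rng, sizes[pre_e], sizes[post_e],
            spec.connection_probability, spec.baseline_weights[cls],
            exclude_diagonal=(pre_e == post_e))
    n = spec.n_total
    return NetworkState(
        spec=spec, params=params,
        v=np.full(n, params.v_rest),
        g_exc=np.zeros(n), g_inh=np.zeros(n),
        refractory_until=np.full(n, -np.inf),
        synapses=synapses,
        trace_e=np.zeros(n_e), trace_i=np.zeros(n_i),
        drive_rng_state=substream_seed(spec.seed, "drive"),
    )
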