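"""Named deterministic test fixtures: tiny networks with enumerable structure.

Each fixture builder returns ``(state, expected)`` where ``expected`` holds
independently enumerated facts about the fixture (synapse counts, masks,
memberships) that tests compare against the implementation's own output.
Fixtures are deterministic given their seed argument and contain no other
randomness.
"""

from __future__ import annotations

import numpy as np

from .build import build_network
from .params import NeuronParams, NetworkSpec
from .protocol import AssemblySpec


class UnknownFixtureError(KeyError):
    pass


def _pair_clamp(seed: int):
    """One excitatory and one inhibitory neuron joined by a single plastic
    I→E synapse (connection probability 1): the minimal substrate for
    clamped-spike-train plasticity tests."""
    spec = NetworkSpec(n_excitatory=1, n_inhibitory=1,
                       connection_probability=1.0,
                       baseline_weights={"ee": 0.0, "ei": 0.0,
                                         "ie": 0.5, "ii": 0.0},
                       seed=seed)
    params = NeuronParams(drive_rate_hz=0.0)
    state = build_network(spec, params)
    expected = {
        "n_ie_synapses": 1,
        "ie_pre": 0, "ie_post": 0,
        "ie_weight": 0.5,
    }
    return state, expected


def _two_assembly_toy(seed: int):
    """16 excitatory + 4 inhibitory neurons, dense enough to enumerate, with
    two 4-neuron assemblies (ids 0–3 "red", 4–7 "green") and constant
    suprathreshold current drive so the dynamics are fully deterministic
    (no Poisson noise). Used for oracle cross-checks and mask tests."""
    spec = NetworkSpec(n_excitatory=16, n_inhibitory=4,
                       connection_probability=0.35,
                       baseline_weights={"ee": 0.05, "ei": 0.05,
                                         "ie": 0.3, "ii": 0.3},
                       seed=seed)
    params = NeuronParams(drive_rate_hz=0.0, drive_current_mv=12.0)
    state = build_network(spec, params)
    assemblies = AssemblySpec(
        {"red": np.arange(0, 4), "green": np.arange(4, 8)},
        within_assembly_gain=2.0)

    # independently enumerated within-assembly mask over the drawn E->E graph
    ee = state.synapses["ee"]
    within_pairs = set()
    for j in range(16):
        for p in range(ee.indptr[j], ee.indptr[j + 1]):
            k = int(ee.targets[p])
            if (j < 4 and k < 4) or (4 <= j < 8 and 4 <= k < 8):
                within_pairs.add((j, k))
    expected = {
        "assemblies": assemblies,
        "within_pairs": within_pairs,
        "membership": np.array([0] * 4 + [1] * 4 + [-1] * 8),
        "synapse_counts": {c: state.synapses[c].nnz
                           for c in ("ee", "ei", "ie", "ii")},
    }
    return state, expected


_REGISTRY = {
    "pair-clamp": _pair_clamp,
    "two-assembly-toy": _two_assembly_toy,
}


def list_fixtures() -> list:
    return sorted(_REGISTRY)


def make_fixture(name: str, seed: int = 1):
    """Build the named fixture; raises `UnknownFixtureError` listing the
    registered names if ``name`` is not one of them."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {list_fixtures()}")
    return builder(seed)
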