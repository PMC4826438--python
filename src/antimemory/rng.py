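"""Seeding policy and the counter-based noise stream used by the integration kernel.

All randomness in the package derives from one master seed. Named substreams
("connectivity", "drive", "probe-3-trial-0", ...) are derived by hashing the
substream label into the seed material, so adding a new substream never
perturbs draws from existing ones.

Connectivity and other build-time draws use NumPy generators. The background
Poisson drive inside the compiled integration kernel uses a splitmix64
counter stream instead: its state is a single 64-bit integer, which makes
mid-run checkpoints trivially serializable and lets the pure-Python
reference integrator reproduce the identical event sequence.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = (1 << 64) - 1
_GAMMA = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB


def substream_seed(master_seed: int, name: str) -> int:
    """64-bit seed for the named substream of ``master_seed``."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1, np.uint64)[0])


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    """NumPy generator for the named substream (build-time draws)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    return np.random.default_rng(ss)


def splitmix64_next(state: int) -> tuple[int, int]:
    """Advance a splitmix64 stream once; returns (new_state, output)."""
    state = (state + _GAMMA) & _MASK
    z = state
    z = ((z ^ (z >> 30)) * _MIX1) & _MASK
    z = ((z ^ (z >> 27)) * _MIX2) & _MASK
    return state, z ^ (z >> 31)


def splitmix64_uniform(state: int) -> tuple[int, float]:
    """Advance once; returns (new_state, uniform in [0, 1))."""
    state, z = splitmix64_next(state)
    return state, (z >> 11) * 2.0 ** -53


class DriveStream:
    """Pure-Python mirror of the kernel's drive stream (reference/oracle use).

    Reproduces, draw for draw, the pooled-Poisson background-event sequence
    the compiled kernel generates: per step a Poisson event count (Knuth's
    method below ``_KNUTH_MAX``, a rounded normal approximation above it via
    Box-Muller), then one uniform per event for the target neuron index.
    """

    _KNUTH_MAX = 30.0

    def __init__(self, seed: int):
        self.state = int(seed) & _MASK

    def uniform(self) -> float:
        self.state, u = splitmix64_uniform(self.state)
        return u

    def poisson(self, lam: float) -> int:
        if lam <= 0.0:
            return 0
        if lam < self._KNUTH_MAX:
            import math

            limit = math.exp(-lam)
            k = 0
            p = 1.0
            while True:
                p *= self.uniform()
                if p <= limit:
                    return k
                k += 1
        else:
            import math

            u1 = self.uniform()
            u2 = self.uniform()
            if u1 <= 0.0:
                u1 = 2.0 ** -53
            z = math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)
            k = int(round(lam + math.sqrt(lam) * z))
            return max(k, 0)

    def event_targets(self, lam: float, n: int) -> list[int]:
        """Targets hit by background events in one step (may repeat)."""
        k = self.poisson(lam)
        return [int(self.state_next_index(n)) for _ in range(k)]

    def state_next_index(self, n: int) -> int:
        self.state, z = splitmix64_next(self.state)
        return z % n
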