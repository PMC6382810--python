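"""Deterministic counter-free PCG32 streams usable from both Python and njit kernels.

The simulation keeps independent named streams so that, e.g., toggling the
mortality regime does not perturb the mutation sequence. Streams are arrays of
(state, increment) pairs; every consumer (Python API or compiled kernel)
advances the same arrays, which is what makes runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stream indices
TRAITS = 0      # mutation options and magnitudes
MOTILITY = 1    # directions and persistence times
MORTALITY = 2   # random deaths, catastrophe centers and apoptosis delays
PLACEMENT = 3   # daughter placement angles
SCHEDULE = 4    # per-frame update-order shuffle, packed-initializer phases
N_STREAMS = 5

_MULT = np.uint64(6364136223846793005)
_U32_NORM = 2.3283064365386963e-10  # 2**-32


@njit(cache=True)
def _pcg32(states, incs, k):
    old = states[k]
    states[k] = old * _MULT + incs[k]
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32((xorshifted >> rot) | (xorshifted << ((np.uint32(0) - rot) & np.uint32(31))))


@njit(cache=True)
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _seed_streams(states, incs, seed):
    z = seed
    for k in range(states.size):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        s1 = _mix64(z)
        z = z + np.uint64(0x9E3779B97F4A7C15)
        s2 = _mix64(z)
        incs[k] = (s2 << np.uint64(1)) | np.uint64(1)
        states[k] = np.uint64(0)
        _pcg32(states, incs, k)
        states[k] = states[k] + s1
        _pcg32(states, incs, k)


@njit(cache=True)
def uniform(states, incs, k):
    """Uniform float64 on [0, 1)."""
    return np.float64(_pcg32(states, incs, k)) * _U32_NORM


@njit(cache=True)
def uniform_open(states, incs, k):
    """Uniform float64 on (0, 1] (for strictly-positive step magnitudes)."""
    return (np.float64(_pcg32(states, incs, k)) + 1.0) * _U32_NORM


@njit(cache=True)
def normal(states, incs, k):
    """Standard normal draw (Box-Muller, one value per call)."""
    u1 = uniform_open(states, incs, k)
    u2 = uniform(states, incs, k)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True)
def shuffle(order, n, states, incs, k):
    """In-place Fisher-Yates shuffle of order[:n]."""
    for i in range(n - 1, 0, -1):
        j = int(uniform(states, incs, k) * (i + 1))
        if j > i:
            j = i
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp


class RngStreams:
    """Named PCG32 streams derived from one master seed."""

    __slots__ = ("seed", "states", "incs")

    def __init__(self, seed: int):
        if not (0 <= int(seed) < 2**63):
            raise ValueError("seed must be a non-negative integer below 2**63")
        self.seed = int(seed)
        self.states = np.zeros(N_STREAMS, dtype=np.uint64)
        self.incs = np.zeros(N_STREAMS, dtype=np.uint64)
        _seed_streams(self.states, self.incs, np.uint64(self.seed))

    def uniform(self, stream: int = TRAITS) -> float:
        return float(uniform(self.states, self.incs, stream))

    def uniform_open(self, stream: int = TRAITS) -> float:
        return float(uniform_open(self.states, self.incs, stream))

    def normal(self, stream: int = MOTILITY) -> float:
        return float(normal(self.states, self.incs, stream))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngStreams(seed={self.seed})"
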