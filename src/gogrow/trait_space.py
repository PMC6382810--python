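"""The two-trait phenotype space, its tradeoff boundaries, and mutation on division.

A phenotype is the heritable pair (intermitotic time tau in hours, migration
speed nu in um/h). tau ranges over [10, 40] h and nu over [0, 20] um/h; short
tau means fast proliferation. Feasibility can be restricted by a tradeoff
boundary: ``open`` (no tradeoff), ``convex`` (feasible set bows outward) or
``concave`` (bows inward). Both curved boundaries are the unit-radius circular
arcs through the two specialist extremes, expressed in coordinates normalized
so that (1, 0) is the pure fast proliferator and (0, 1) the pure fast migrator:

    x = (40 - tau) / 30,  y = nu / 20
    convex feasible:   x**2 + y**2 <= 1
    concave feasible:  (x - 1)**2 + (y - 1)**2 >= 1

On division each trait of the inheriting cell independently improves, stays,
or diminishes with equal weight among the options that can remain feasible;
step magnitudes are uniform on (0, 4.5] h for tau and (0, 3] um/h for nu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import _rng
from ._rng import TRAITS, RngStreams

TAU_MIN, TAU_MAX = 10.0, 40.0
NU_MIN, NU_MAX = 0.0, 20.0
DTAU_MAX_DEFAULT = 4.5
DNU_MAX_DEFAULT = 3.0

OPEN, CONVEX, CONCAVE = 0, 1, 2
_KIND_CODES = {"open": OPEN, "convex": CONVEX, "concave": CONCAVE}

#: numeric slack on the arc inequalities so the arc endpoints are feasible exactly
ARC_TOL = 1e-12


@dataclass(frozen=True)
class Phenotype:
    """Heritable trait pair; validates the trait ranges at construction."""

    tau: float  # intermitotic time, hours
    nu: float   # migration speed, um/h

    def __post_init__(self):
        if not (TAU_MIN <= self.tau <= TAU_MAX):
            raise ValueError(f"tau={self.tau} outside [{TAU_MIN}, {TAU_MAX}] h")
        if not (NU_MIN <= self.nu <= NU_MAX):
            raise ValueError(f"nu={self.nu} outside [{NU_MIN}, {NU_MAX}] um/h")


@dataclass(frozen=True)
class TradeoffBoundary:
    """Feasibility predicate over trait space: 'open', 'convex' or 'concave'."""

    kind: str = "open"

    def __post_init__(self):
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown tradeoff kind {self.kind!r}")

    @property
    def code(self) -> int:
        return _KIND_CODES[self.kind]


@dataclass(frozen=True)
class MutationKernel:
    """Per-division step bounds; defaults are the model's standard values."""

    dtau_max: float = DTAU_MAX_DEFAULT  # hours
    dnu_max: float = DNU_MAX_DEFAULT    # um/h

    def __post_init__(self):
        if self.dtau_max <= 0 or self.dnu_max <= 0:
            raise ValueError("mutation step bounds must be positive")


@njit(cache=True)
def _normalize(tau, nu):
    return (TAU_MAX - tau) / (TAU_MAX - TAU_MIN), nu / NU_MAX


@njit(cache=True)
def _feasible(tau, nu, code):
    if tau < TAU_MIN or tau > TAU_MAX or nu < NU_MIN or nu > NU_MAX:
        return False
    if code == 0:
        return True
    x, y = _normalize(tau, nu)
    if code == 1:
        return x * x + y * y <= 1.0 + ARC_TOL
    return (x - 1.0) * (x - 1.0) + (y - 1.0) * (y - 1.0) >= 1.0 - ARC_TOL


@njit(cache=True)
def _mutate(tau, nu, code, dtau_max, dnu_max, states, incs):
    # per-trait direction options that can remain feasible for a small step,
    # probing each trait with the other held at the parent value
    eps_t = 1e-9 * (TAU_MAX - TAU_MIN)
    eps_n = 1e-9 * (NU_MAX - NU_MIN)
    topts = np.empty(3, dtype=np.int64)
    nopts = np.empty(3, dtype=np.int64)
    nt = 0
    nn = 0
    for d in (-1, 0, 1):
        if _feasible(tau + d * eps_t, nu, code):
            topts[nt] = d
            nt += 1
        if _feasible(tau, nu + d * eps_n, code):
            nopts[nn] = d
            nn += 1
    dt_dir = topts[int(_rng.uniform(states, incs, TRAITS) * nt)]
    dn_dir = nopts[int(_rng.uniform(states, incs, TRAITS) * nn)]
    step_t = 0.0
    step_n = 0.0
    for _ in range(100):
        step_t = dt_dir * _rng.uniform_open(states, incs, TRAITS) * dtau_max
        step_n = dn_dir * _rng.uniform_open(states, incs, TRAITS) * dnu_max
        if _feasible(tau + step_t, nu + step_n, code):
            return tau + step_t, nu + step_n
    # clamp along the chosen step vector toward the (feasible) parent
    for j in range(1, 101):
        s = 1.0 - j / 100.0
        if _feasible(tau + s * step_t, nu + s * step_n, code):
            return tau + s * step_t, nu + s * step_n
    return tau, nu


def normalize(ph: Phenotype) -> tuple[float, float]:
    """Map a phenotype to unit-square coordinates (x, y).

    x = 1 is the fastest proliferator (tau = 10 h), y = 1 the fastest migrator
    (nu = 20 um/h). Out-of-range phenotypes are rejected by ``Phenotype``.
    """
    x, y = _normalize(ph.tau, ph.nu)
    return float(x), float(y)


def is_feasible(ph: Phenotype, boundary: TradeoffBoundary) -> bool:
    """True iff the phenotype lies inside the boundary's fitness set."""
    return bool(_feasible(ph.tau, ph.nu, boundary.code))


def mutate(
    parent: Phenotype,
    boundary: TradeoffBoundary,
    kernel: MutationKernel = MutationKernel(),
    rng: RngStreams | None = None,
) -> Phenotype:
    """Draw a daughter phenotype from a feasible parent.

    Each trait independently chooses improve / stay / diminish with equal
    weight among the options that can remain feasible; magnitudes are uniform
    on (0, max]. Infeasible combinations are resampled (magnitudes first, then
    clamped toward the parent), so the result is always feasible.
    """
    if rng is None:
        raise ValueError("mutate requires an RngStreams instance")
    if not is_feasible(parent, boundary):
        raise ValueError(f"parent {parent} infeasible under {boundary.kind} boundary")
    tau, nu = _mutate(
        parent.tau, parent.nu, boundary.code,
        kernel.dtau_max, kernel.dnu_max, rng.states, rng.incs,
    )
    return Phenotype(float(tau), float(nu))
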