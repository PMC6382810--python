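"""Reusable experiment drivers: space-filling capacity, death-rate
calibration at capacity, catastrophe-scheduler compensation, and the
scaled-down two-phase selection runs.

These are the computations behind the package's headline numbers; the test
suite and scripts/acceptance.py both call them. Seeds are explicit
everywhere; every experiment is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (REFERENCE_RADIUS, SimConfig, World, estimated_capacity,
                     initialize, initialize_packed, run)
from .mortality import HIGH_DEATH_RATE, MortalityRegime
from .spatial_index import CELL_RADIUS
from .trait_space import Phenotype

#: phenotype used for capacity-at-steady-state experiments: the fully evolved
#: aggressive generalist (fastest proliferation and migration), the open-boundary
#: evolutionary endpoint of a tumor that has filled its space. Migration is what
#: lets the population keep refilling the gaps that mortality opens.
FILLED_TUMOR_PHENOTYPE = (10.0, 20.0)


def fill_domain(radius: float, seed: int, start: tuple = FILLED_TUMOR_PHENOTYPE,
                boundary: str = "open", max_days: float = 60.0):
    """Grow from one founder until division halts everywhere.

    Returns (final cell count, packing fraction, snapshots). The run stops
    when no cell is cycling (all surrounded or boundary-arrested).
    """
    cfg = SimConfig(duration_days=max_days, domain_radius=radius,
                    boundary=boundary, initial_phenotype=start, seed=seed,
                    snapshot_days=5.0)
    world = initialize(cfg)
    snaps = run(cfg, world=world,
                stop_when=lambda w: w.n_cycling == 0, check_every_days=0.25)
    n = world.n_live
    packing = n * CELL_RADIUS**2 / radius**2
    return n, packing, snaps


def capacity_extrapolation(seeds, radii=(300.0, 500.0, 700.0)):
    """Packing fractions of filled test domains and the implied capacity of
    the reference 1350 um-radius domain."""
    per_radius = {}
    for r in radii:
        fractions = []
        for s in seeds:
            _, phi, _ = fill_domain(r, seed=s)
            fractions.append(phi)
        per_radius[r] = float(np.mean(fractions))
    mean_phi = float(np.mean(list(per_radius.values())))
    extrapolated = mean_phi * REFERENCE_RADIUS**2 / CELL_RADIUS**2
    return per_radius, mean_phi, extrapolated


def deaths_per_day_at_capacity(seed: int, p_death: float, f: float = 0.0,
                               days: float = 1.0,
                               radius: float = REFERENCE_RADIUS):
    """Removals per simulated day with the domain held at capacity.

    The packed initializer fills the domain with the filled-tumor phenotype;
    births refill the space that deaths open. Returns (deaths/day, initial N).
    """
    cfg = SimConfig(duration_days=days, domain_radius=radius,
                    regime=MortalityRegime(p_death, f), seed=seed,
                    initial_phenotype=FILLED_TUMOR_PHENOTYPE,
                    snapshot_days=max(days, 1.0))
    world = initialize_packed(cfg)
    n0 = world.n_live
    run(cfg, world=world)
    return float(world.counts[3]) / days, n0


def mean_deaths_per_day(seeds, p_death: float, f: float = 0.0,
                        days: float = 1.0) -> tuple[float, int]:
    """Average removals/day over seeds; returns (mean rate, initial N)."""
    rates = []
    n0 = 0
    for s in seeds:
        r, n0 = deaths_per_day_at_capacity(s, p_death, f=f, days=days)
        rates.append(r)
    return float(np.mean(rates)), n0


def scheduler_compensation(seed: int, days: float = 10.0):
    """Realized deaths/day at capacity under 100% catastrophic vs 100%
    demographic mortality at the high rate. Returns (rate_f1, rate_f0)."""
    rate_f1, _ = deaths_per_day_at_capacity(seed, HIGH_DEATH_RATE, f=1.0, days=days)
    rate_f0, _ = deaths_per_day_at_capacity(seed, HIGH_DEATH_RATE, f=0.0, days=days)
    return rate_f1, rate_f0


#: area fraction at which unconstrained growth jams in this model (measured
#: from fill_domain runs; stable across domain radii). Contact placement at
#: one diameter with no pushing jams near random-sequential-adsorption
#: density, well below hexagonal close packing.
NATURAL_PACKING_FRACTION = 0.52


def natural_capacity(radius: float) -> int:
    """Cell count at which this model's growth jams in a domain."""
    return int(round(NATURAL_PACKING_FRACTION * radius**2 / CELL_RADIUS**2))


@dataclass
class SelectionRun:
    """Summary of one scaled-down evolution run."""

    boundary: str
    f: float
    seed: int
    fill_time_days: float | None  # first time the population had filled space
    nu_at_fill: float             # mean nu when space first filled
    tau_at_fill: float
    nu_end: float
    tau_end: float
    n_end: int
    snapshots: list


def scaled_selection_run(seed: int, boundary: str, f: float = 0.0,
                         duration_days: float = 90.0,
                         radius: float = 500.0) -> SelectionRun:
    """One two-phase run in a 500 um-radius domain under the high death rate,
    from the least aggressive founder."""
    cfg = SimConfig(duration_days=duration_days, domain_radius=radius,
                    boundary=boundary, regime=MortalityRegime(HIGH_DEATH_RATE, f),
                    seed=seed, snapshot_days=2.5)
    snaps = run(cfg)
    fill_n = 0.85 * natural_capacity(radius)
    fill_time = None
    nu_fill = tau_fill = float("nan")
    for s in snaps:
        if s.n >= fill_n:
            fill_time = s.time_days
            nu_fill = s.mean_nu
            tau_fill = s.mean_tau
            break
    last = snaps[-1]
    return SelectionRun(boundary=boundary, f=f, seed=seed,
                        fill_time_days=fill_time, nu_at_fill=nu_fill,
                        tau_at_fill=tau_fill, nu_end=last.mean_nu,
                        tau_end=last.mean_tau, n_end=last.n, snapshots=snaps)


def surviving_selection_runs(n_runs: int, boundary: str, f: float = 0.0,
                             base_seed: int = 1, duration_days: float = 90.0,
                             radius: float = 500.0, max_attempts: int = 25,
                             survival_n: float | None = None):
    """Collect ``n_runs`` non-extinct runs, scanning seeds from ``base_seed``.

    Starting from a single cell under a per-cell death rate, lineage
    extinction is a genuine branching-process outcome (the founder can die
    before dividing); like comparable eco-evolutionary studies, endpoint
    statistics condition on persistence. By default a run counts as surviving
    when its final population exceeds a quarter of the natural capacity;
    short expansion-phase runs should pass a smaller ``survival_n`` (any
    clearly established lineage).
    """
    out = []
    seed = base_seed
    floor = 0.25 * natural_capacity(radius) if survival_n is None else survival_n
    for _ in range(max_attempts):
        if len(out) >= n_runs:
            break
        r = scaled_selection_run(seed, boundary, f=f,
                                 duration_days=duration_days, radius=radius)
        if r.n_end >= floor:
            out.append(r)
        seed += 1
    return out
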