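"""Demographic and environmental (catastrophic) mortality.

Two mortality channels share a single per-cell death rate ``p_death`` (per
day; the *high* rate is one death per cell per week, the *low* rate one per
two weeks). A fraction ``f`` of all mortality is delivered as spatial
catastrophes: every cell inside a randomly placed circle of radius 250 um
(500 um diameter) dies at once, after an individual apoptosis delay drawn
uniformly from 6-15 h. The remaining fraction ``1 - f`` is demographic:
independent per-cell Bernoulli deaths each one-minute frame, removed at the
end of that frame.

The interval between catastrophes is adaptive:

    T_cat = (N_deaths / N) / (f * p_death)

with ``N_deaths`` the kill count of the *previous* event, so that events that
overlap old gaps or the domain edge (and so kill fewer cells) are compensated
by a shorter wait, keeping the long-run catastrophic death rate at its target
share ``f * p_death`` of total mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import _rng
from ._rng import MORTALITY
from .lifestate import DYING

HIGH_DEATH_RATE = 1.0 / 7.0   # per day: one death per cell per week
LOW_DEATH_RATE = 1.0 / 14.0   # per day: one death per cell per two weeks
CAT_RADIUS_DEFAULT = 250.0    # um (500 um diameter region)
DELAY_RANGE_DEFAULT = (6.0, 15.0)  # hours, apoptosis delay for catastrophic deaths
MINUTES_PER_DAY = 1440.0

#: smallest admissible inter-catastrophe interval (one frame), in days
T_CAT_FLOOR_DAYS = 1.0 / MINUTES_PER_DAY


@dataclass(frozen=True)
class MortalityRegime:
    """Per-cell death rate, catastrophic share and catastrophe geometry."""

    p_death: float = 0.0          # per day
    f: float = 0.0                # fraction of deaths that are catastrophic
    cat_radius: float = CAT_RADIUS_DEFAULT          # um
    delay_hours: tuple = DELAY_RANGE_DEFAULT        # apoptosis delay bounds
    delay_random_deaths: bool = False  # also delay demographic deaths

    def __post_init__(self):
        if self.p_death < 0:
            raise ValueError("p_death must be non-negative")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must lie in [0, 1]")
        if self.cat_radius <= 0:
            raise ValueError("cat_radius must be positive")
        lo, hi = self.delay_hours
        if not (0 < lo <= hi):
            raise ValueError("delay range must be positive and ordered")

    @classmethod
    def none(cls) -> "MortalityRegime":
        return cls(0.0, 0.0)

    @classmethod
    def low(cls, f: float = 0.0) -> "MortalityRegime":
        return cls(LOW_DEATH_RATE, f)

    @classmethod
    def high(cls, f: float = 0.0) -> "MortalityRegime":
        return cls(HIGH_DEATH_RATE, f)


def per_frame_death_prob(p_death: float, dt: float = 1.0, f: float = 0.0) -> float:
    """Linearized per-frame Bernoulli probability of demographic death.

    ``p_death`` is per day, ``dt`` in minutes. Scaled by (1 - f) so that
    demographic deaths account for exactly their share of total mortality.
    """
    if p_death < 0 or dt < 0:
        raise ValueError("p_death and dt must be non-negative")
    if not (0.0 <= f <= 1.0):
        raise ValueError("f must lie in [0, 1]")
    return min(1.0, p_death * (1.0 - f) * dt / MINUTES_PER_DAY)


def next_interval(prev_kill_count: float, n: int, f: float, p_death: float) -> float | None:
    """Adaptive time to the next catastrophe, in days.

    Returns None when ``f * p_death == 0`` (scheduler disabled). The kill
    count is floored at one cell so that an event landing on empty space
    reschedules at T = (1/N)/(f*p_death) instead of collapsing to zero; the
    interval is additionally floored at one frame.
    """
    if f * p_death == 0.0:
        return None
    if n <= 0:
        raise ValueError("population must be positive")
    kills = max(float(prev_kill_count), 1.0)
    return max((kills / n) / (f * p_death), T_CAT_FLOOR_DAYS)


@dataclass
class CatastropheScheduler:
    """Adaptive catastrophe clock (times in simulation minutes)."""

    next_event_min: float = np.inf
    prev_kill_count: float = 0.0
    t_cat_days: float = np.inf
    started: bool = False
    onset_population: int = 0  # population at which scheduling begins
    events: int = 0

    def schedule_first(self, clock_min: float, n: int, f: float, p_death: float,
                       area_fraction: float) -> None:
        """Seed the first interval with the expected kill count of a fully
        interior event, ``area_fraction * N``."""
        self.prev_kill_count = area_fraction * n
        t = next_interval(self.prev_kill_count, n, f, p_death)
        self.t_cat_days = t
        self.next_event_min = clock_min + t * MINUTES_PER_DAY
        self.started = True

    def record_event(self, clock_min: float, kills: int, n: int, f: float,
                     p_death: float) -> None:
        self.prev_kill_count = float(kills)
        self.events += 1
        if n <= 0:
            self.next_event_min = np.inf
            return
        t = next_interval(kills, n, f, p_death)
        self.t_cat_days = t
        self.next_event_min = clock_min + t * MINUTES_PER_DAY


@njit(cache=True)
def _sample_deaths(n_slots, alive, state, death_clock, p_frame, delay,
                   delay_lo_min, delay_hi_min, states, incs, out):
    """Independent Bernoulli(p_frame) per live, non-dying cell, in slot order.

    Selected cells enter the dying state; with ``delay`` false their clock is
    zero (removal at the end of the current frame), otherwise uniform on the
    apoptosis-delay window. Returns the number selected.
    """
    n = 0
    for c in range(n_slots):
        if alive[c] and state[c] != DYING:
            if _rng.uniform(states, incs, MORTALITY) < p_frame:
                state[c] = DYING
                if delay:
                    u = _rng.uniform(states, incs, MORTALITY)
                    death_clock[c] = delay_lo_min + u * (delay_hi_min - delay_lo_min)
                else:
                    death_clock[c] = 0.0
                out[n] = c
                n += 1
    return n


@njit(cache=True)
def _process_dying(n_slots, alive, state, death_clock, dt, pos, cache,
                   head, nxt, imin, jmin, nx, ny, free_slots, counts,
                   invalidate_range):
    """Decrement death clocks; remove expired cells and free their space.

    Removal marks the slot dead, unlinks it from its grid bin (so the slot
    can be reused by a later birth without corrupting the bin chain), pushes
    it on the free list, and dirties the cached surround status of every live
    cell within the invalidation range. Returns the number of removals.
    """
    removed = 0
    r2 = invalidate_range * invalidate_range
    for c in range(n_slots):
        if alive[c] and state[c] == DYING:
            death_clock[c] -= dt
            if death_clock[c] <= 0.0:
                alive[c] = False
                free_slots[counts[0]] = c
                counts[0] += 1
                removed += 1
                x = pos[c, 0]
                y = pos[c, 1]
                i0 = int(np.floor(x / 67.0)) - imin
                j0 = int(np.floor(y / 67.0)) - jmin
                # unlink c from its bin chain (dying cells never move, so the
                # chain it was built into at frame top is the one at pos[c])
                b = i0 * ny + j0
                if 0 <= i0 < nx and 0 <= j0 < ny:
                    q = head[b]
                    if q == c:
                        head[b] = nxt[c]
                    else:
                        while q >= 0:
                            if nxt[q] == c:
                                nxt[q] = nxt[c]
                                break
                            q = nxt[q]
                for di in (-1, 0, 1):
                    i = i0 + di
                    if i < 0 or i >= nx:
                        continue
                    for dj in (-1, 0, 1):
                        j = j0 + dj
                        if j < 0 or j >= ny:
                            continue
                        q = head[i * ny + j]
                        while q >= 0:
                            if alive[q]:
                                dx = pos[q, 0] - x
                                dy = pos[q, 1] - y
                                if dx * dx + dy * dy < r2:
                                    cache[q] = -1
                            q = nxt[q]
    return removed


def sample_random_deaths(world, p_frame: float) -> np.ndarray:
    """Mark live cells for demographic death with probability ``p_frame`` each.

    Returns the slot indices of the cells that entered the dying state.
    """
    regime = world.regime
    out = np.empty(world.n_slots, dtype=np.int64)
    lo, hi = regime.delay_hours
    n = _sample_deaths(world.n_slots, world.alive, world.state, world.death_clock,
                       p_frame, regime.delay_random_deaths, lo * 60.0, hi * 60.0,
                       world.rng.states, world.rng.incs, out)
    return out[:n]


def apply_catastrophe(world) -> np.ndarray:
    """Fire one catastrophe: kill every live cell within ``cat_radius`` of a
    uniformly placed center; each victim gets an individual 6-15 h delay.

    Returns the slot indices of the victims (already-dying cells excluded).
    """
    regime = world.regime
    R = world.domain.radius
    u1 = world.rng.uniform(MORTALITY)
    u2 = world.rng.uniform(MORTALITY)
    r = R * np.sqrt(u1)
    theta = 2.0 * np.pi * u2
    cx, cy = r * np.cos(theta), r * np.sin(theta)
    ns = world.n_slots
    d2 = (world.pos[:ns, 0] - cx) ** 2 + (world.pos[:ns, 1] - cy) ** 2
    sel = np.flatnonzero(world.alive[:ns] & (world.state[:ns] != DYING)
                         & (d2 <= regime.cat_radius ** 2))
    lo, hi = regime.delay_hours
    for c in sel:
        u = world.rng.uniform(MORTALITY)
        world.state[c] = DYING
        world.death_clock[c] = (lo + u * (hi - lo)) * 60.0
    return sel


def process_dying(world, dt: float = 1.0) -> int:
    """Advance apoptosis clocks and remove expired cells. Returns removals."""
    world.sync_grid()
    g = world.grid
    from .motility import INVALIDATION_RANGE
    removed = _process_dying(world.n_slots, world.alive, world.state,
                             world.death_clock, dt, world.pos, world.cache,
                             g.head, g.nxt, g.imin, g.jmin, g.nx, g.ny,
                             world.free_slots, world.counts, INVALIDATION_RANGE)
    world.counts[3] += removed
    return removed
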