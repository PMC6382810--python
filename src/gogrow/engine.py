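"""World state and the per-minute update loop.

Each one-minute frame proceeds in a fixed order: (1) the 67 um hash grid is
rebuilt from current positions; (2) a pending catastrophe fires and
demographic deaths are sampled; (3) apoptosis clocks advance and expired
cells are removed; (4) every live, non-dying cell acts once, in a freshly
shuffled order: its surrounded/free status is (re-)evaluated, a cycling cell
decrements its intermitotic countdown and divides when it reaches zero
(placing the daughter one diameter away at a free angle, or arresting when
fully blocked), and otherwise takes one persistent-random-walk sub-move.

Division mutates the newly placed daughter only (the cell keeping the
original position retains the parental phenotype; set ``mutate_both`` to
mutate both). A division consumes the cell's frame; arrest pauses the cycle
clock where it stands and is reversible when a neighbor's death reopens
space. The whole update is compiled (numba) and driven by named PCG32
streams, so identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _rng, mortality, observables
from ._rng import MOTILITY, PLACEMENT, SCHEDULE, RngStreams
from .lifestate import ARRESTED, BOUNDARY_ARRESTED, CYCLING, DYING
from .mortality import (CatastropheScheduler, MortalityRegime,
                        per_frame_death_prob, _process_dying, _sample_deaths)
from .motility import INVALIDATION_RANGE, _draw_persistence, _invalidate_near, _move_cell
from .spatial_index import (CELL_DIAMETER, CELL_RADIUS, INTERACTION_RANGE,
                            MAX_NEIGHBORS, SURROUND_TOL, TWO_PI, Domain,
                            HashGrid, _arcs_from_neighbors, _free_intervals,
                            _gather_within, _grid_build, _grid_insert,
                            _sample_free)
from .trait_space import (MutationKernel, Phenotype, TradeoffBoundary,
                          _mutate, is_feasible)

#: space-filled capacity of the reference 1350 um-radius domain, used to set
#: the packed-initializer density and the catastrophe-scheduler onset
REFERENCE_CAPACITY = 13000
REFERENCE_RADIUS = 1350.0
#: corresponding area fraction covered by cells (capacity * cell area / domain area)
PACKING_FRACTION = REFERENCE_CAPACITY * CELL_RADIUS**2 / REFERENCE_RADIUS**2


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulation run."""

    duration_days: float = 90.0
    domain_radius: float = REFERENCE_RADIUS       # um
    boundary: str = "open"                        # tradeoff kind
    regime: MortalityRegime = field(default_factory=MortalityRegime.none)
    mutation: MutationKernel = field(default_factory=MutationKernel)
    initial_phenotype: tuple = (40.0, 0.0)        # (tau h, nu um/h); least aggressive
    initial_position: tuple = (0.0, 0.0)          # um
    seed: int = 0
    snapshot_days: float = 5.0
    dt: float = 1.0                               # minutes; the model's frame
    mutate_both: bool = False

    def __post_init__(self):
        if self.duration_days < 0:
            raise ValueError("duration must be non-negative")
        if self.dt != 1.0:
            raise ValueError("the update frame is fixed at 1 minute")
        if self.snapshot_days <= 0:
            raise ValueError("snapshot interval must be positive")

    def tradeoff(self) -> TradeoffBoundary:
        return TradeoffBoundary(self.boundary)


def estimated_capacity(radius: float) -> int:
    """Expected space-filled cell count of a domain, by packing-fraction scaling."""
    return int(round(PACKING_FRACTION * radius**2 / CELL_RADIUS**2))


class World:
    """Structure-of-arrays cell population plus domain, grid, clock and RNG."""

    def __init__(self, config: SimConfig, capacity: int = 256):
        ph = Phenotype(*config.initial_phenotype)
        if not is_feasible(ph, config.tradeoff()):
            raise ValueError(
                f"initial phenotype {config.initial_phenotype} infeasible under "
                f"the {config.boundary} boundary")
        self.config = config
        self.domain = Domain(config.domain_radius)
        self.boundary = config.tradeoff()
        self.regime = config.regime
        self.kernel = config.mutation
        self.dt = config.dt
        self.rng = RngStreams(config.seed)
        self.clock_min = 0.0
        self.frame = 0

        self._alloc(capacity)
        self.grid = HashGrid(self.domain, capacity)
        self._grid_synced = False

        self.p_frame = per_frame_death_prob(self.regime.p_death, self.dt, self.regime.f)
        self.cat_active = self.regime.f * self.regime.p_death > 0
        self.cat_area_fraction = min(
            1.0, (self.regime.cat_radius / self.domain.radius) ** 2)
        region_cap = max(1, int(round(
            PACKING_FRACTION * self.regime.cat_radius**2 / CELL_RADIUS**2)))
        onset = min(region_cap,
                    max(1, int(math.ceil(0.5 * estimated_capacity(self.domain.radius)))))
        self.scheduler = CatastropheScheduler(onset_population=onset)

    # -- storage ---------------------------------------------------------

    def _alloc(self, capacity: int) -> None:
        self.pos = np.zeros((capacity, 2))
        self.tau = np.zeros(capacity)
        self.nu = np.zeros(capacity)
        self.cyc = np.zeros(capacity)
        self.direction = np.zeros(capacity)
        self.persistence = np.zeros(capacity)
        self.death_clock = np.zeros(capacity)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.cache = np.full(capacity, -1, dtype=np.int8)
        self.alive = np.zeros(capacity, dtype=np.bool_)
        self.cell_id = np.zeros(capacity, dtype=np.int64)
        self.free_slots = np.zeros(capacity, dtype=np.int64)
        # counts: [0] n_free [1] next_id [2] births [3] removals [4] n_slots
        self.counts = np.zeros(8, dtype=np.int64)
        self._order = np.zeros(capacity, dtype=np.int64)
        self._nb_idx = np.zeros(4 * MAX_NEIGHBORS, dtype=np.int64)
        self._nb_xy = np.zeros((4 * MAX_NEIGHBORS, 2))
        self._arcs = np.zeros((4 * MAX_NEIGHBORS + 2, 2))
        self._work = np.zeros((8 * MAX_NEIGHBORS + 6, 2))
        self._ivl = np.zeros((8 * MAX_NEIGHBORS + 6, 2))

    def _grow(self, capacity: int) -> None:
        old = self.n_slots
        for name in ("pos", "tau", "nu", "cyc", "direction", "persistence",
                     "death_clock", "state", "cache", "alive", "cell_id",
                     "free_slots", "_order"):
            arr = getattr(self, name)
            shape = (capacity,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            new[:old] = arr[:old]
            setattr(self, name, new)
        self.grid.grow(capacity)
        self._grid_synced = False

    @property
    def capacity(self) -> int:
        return self.tau.size

    @property
    def n_slots(self) -> int:
        return int(self.counts[4])

    @property
    def n_live(self) -> int:
        """Live, non-dying cells (the population that evolves)."""
        ns = self.n_slots
        return int(np.count_nonzero(self.alive[:ns] & (self.state[:ns] != DYING)))

    @property
    def n_total(self) -> int:
        """All cells occupying space, dying included."""
        return int(np.count_nonzero(self.alive[: self.n_slots]))

    @property
    def n_cycling(self) -> int:
        ns = self.n_slots
        return int(np.count_nonzero(self.alive[:ns] & (self.state[:ns] == CYCLING)))

    def live_indices(self, include_dying: bool = False) -> np.ndarray:
        ns = self.n_slots
        mask = self.alive[:ns].copy()
        if not include_dying:
            mask &= self.state[:ns] != DYING
        return np.flatnonzero(mask)

    def add_cell(self, x: float, y: float, phenotype: Phenotype,
                 cycle_remaining: float | None = None, state: int = CYCLING) -> int:
        """Insert a cell (used by initializers and tests). Returns its slot."""
        if not self.domain.contains_cell(x, y):
            raise ValueError(f"position ({x}, {y}) outside the domain")
        if not is_feasible(phenotype, self.boundary):
            raise ValueError(f"{phenotype} infeasible under {self.boundary.kind}")
        if self.counts[0] > 0:
            self.counts[0] -= 1
            s = int(self.free_slots[self.counts[0]])
        else:
            if self.n_slots >= self.capacity:
                self._grow(max(16, 2 * self.capacity))
            s = self.n_slots
            self.counts[4] += 1
        self.pos[s] = (x, y)
        self.tau[s] = phenotype.tau
        self.nu[s] = phenotype.nu
        self.cyc[s] = phenotype.tau * 60.0 if cycle_remaining is None else cycle_remaining
        self.direction[s] = TWO_PI * self.rng.uniform(MOTILITY)
        self.persistence[s] = _draw_persistence(self.rng.states, self.rng.incs)
        self.death_clock[s] = 0.0
        self.state[s] = state
        self.cache[s] = -1
        self.alive[s] = True
        self.cell_id[s] = int(self.counts[1])
        self.counts[1] += 1
        self._grid_synced = False
        return s

    def sync_grid(self) -> None:
        """Rebuild the hash grid from current positions (frame-top contract)."""
        self.grid.rebuild(self.pos, self.alive, self.n_slots)
        self._grid_synced = True


@njit(cache=True)
def _eval_surround(i, pos, alive, head, nxt, imin, jmin, nx, ny, R,
                   nb_idx, nb_xy, arcs, work, ivl):
    """Recompute blocked arcs for cell i; returns (n_free, free_measure)."""
    n_nb = _gather_within(pos[i, 0], pos[i, 1], i, INTERACTION_RANGE, pos, alive,
                          head, nxt, imin, jmin, nx, ny, nb_idx)
    for q in range(n_nb):
        nb_xy[q, 0] = pos[nb_idx[q], 0]
        nb_xy[q, 1] = pos[nb_idx[q], 1]
    n_arcs = _arcs_from_neighbors(pos[i, 0], pos[i, 1], R, nb_xy, n_nb, arcs)
    return _free_intervals(arcs, n_arcs, work, ivl)


@njit(cache=True)
def _try_divide(i, pos, tau, nu, cyc, direction, persistence, death_clock,
                state, cache, alive, cell_id, head, nxt, imin, jmin, nx, ny,
                free_slots, counts, nb_idx, nb_xy, arcs, work, ivl,
                R, kind, dtau_max, dnu_max, mutate_both, states, incs):
    """Divide cell i if a free placement angle exists; returns the daughter
    slot, or -1 when the cell is completely surrounded (it arrests)."""
    nf, measure = _eval_surround(i, pos, alive, head, nxt, imin, jmin, nx, ny,
                                 R, nb_idx, nb_xy, arcs, work, ivl)
    if measure < SURROUND_TOL:
        cache[i] = 1
        state[i] = ARRESTED
        return -1
    u = _rng.uniform(states, incs, PLACEMENT)
    angle = _sample_free(ivl, nf, measure, u)
    dx = pos[i, 0] + CELL_DIAMETER * np.cos(angle)
    dy = pos[i, 1] + CELL_DIAMETER * np.sin(angle)
    if counts[0] > 0:
        counts[0] -= 1
        s = free_slots[counts[0]]
    else:
        s = counts[4]
        counts[4] += 1
    d_tau, d_nu = _mutate(tau[i], nu[i], kind, dtau_max, dnu_max, states, incs)
    if mutate_both:
        m_tau, m_nu = _mutate(tau[i], nu[i], kind, dtau_max, dnu_max, states, incs)
        tau[i] = m_tau
        nu[i] = m_nu
    pos[s, 0] = dx
    pos[s, 1] = dy
    tau[s] = d_tau
    nu[s] = d_nu
    cyc[i] = tau[i] * 60.0
    cyc[s] = d_tau * 60.0
    direction[i] = TWO_PI * _rng.uniform(states, incs, MOTILITY)
    persistence[i] = _draw_persistence(states, incs)
    direction[s] = TWO_PI * _rng.uniform(states, incs, MOTILITY)
    persistence[s] = _draw_persistence(states, incs)
    death_clock[s] = 0.0
    state[s] = CYCLING
    state[i] = CYCLING
    alive[s] = True
    cell_id[s] = counts[1]
    counts[1] += 1
    _grid_insert(head, nxt, s, dx, dy, imin, jmin, nx, ny)
    _invalidate_near(dx, dy, pos, alive, cache, head, nxt, imin, jmin, nx, ny)
    cache[i] = -1
    cache[s] = -1
    counts[2] += 1
    return s


@njit(cache=True)
def _frame(pos, tau, nu, cyc, direction, persistence, death_clock, state,
           cache, alive, cell_id, head, nxt, imin, jmin, nx, ny,
           free_slots, counts, order, nb_idx, nb_xy, arcs, work, ivl,
           R, kind, dt, dtau_max, dnu_max, p_frame,
           delay_random, delay_lo_min, delay_hi_min, mutate_both,
           states, incs):
    """Sub-steps (1)-(4) of one frame (the catastrophe check precedes this
    call). Returns the number of divisions."""
    n_slots = counts[4]
    _grid_build(head, nxt, pos, alive, n_slots, imin, jmin, nx, ny)
    if p_frame > 0.0:
        _sample_deaths(n_slots, alive, state, death_clock, p_frame,
                       delay_random, delay_lo_min, delay_hi_min,
                       states, incs, order)
    removed = _process_dying(n_slots, alive, state, death_clock, dt, pos,
                             cache, head, nxt, imin, jmin, nx, ny,
                             free_slots, counts, INVALIDATION_RANGE)
    counts[3] += removed
    n_order = 0
    for c in range(n_slots):
        if alive[c] and (state[c] == CYCLING or state[c] == ARRESTED):
            order[n_order] = c
            n_order += 1
    _rng.shuffle(order, n_order, states, incs, SCHEDULE)
    births = 0
    for oi in range(n_order):
        i = order[oi]
        if not alive[i] or state[i] == DYING or state[i] == BOUNDARY_ARRESTED:
            continue
        if cache[i] == -1:
            _, measure = _eval_surround(i, pos, alive, head, nxt, imin, jmin,
                                        nx, ny, R, nb_idx, nb_xy, arcs, work, ivl)
            cache[i] = 1 if measure < SURROUND_TOL else 0
        if cache[i] == 1:
            state[i] = ARRESTED
            continue
        if state[i] == ARRESTED:
            # space reopened: resume cycling, clock restarts next frame
            state[i] = CYCLING
            continue
        cyc[i] -= dt
        if cyc[i] <= 0.0:
            cyc[i] = 0.0
            s = _try_divide(i, pos, tau, nu, cyc, direction, persistence,
                            death_clock, state, cache, alive, cell_id,
                            head, nxt, imin, jmin, nx, ny, free_slots, counts,
                            nb_idx, nb_xy, arcs, work, ivl,
                            R, kind, dtau_max, dnu_max, mutate_both, states, incs)
            if s >= 0:
                births += 1
            continue  # a division attempt consumes the frame
        _move_cell(i, pos, direction, persistence, nu, state, cache, alive,
                   head, nxt, imin, jmin, nx, ny, R, dt, states, incs)
    return births


def initialize(config: SimConfig, capacity: int = 256) -> World:
    """One founder cell (default: the least aggressive phenotype at the center)."""
    world = World(config, capacity=capacity)
    x, y = config.initial_position
    world.add_cell(float(x), float(y), Phenotype(*config.initial_phenotype))
    return world


def packed_positions(radius: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice points covering the domain interior."""
    rmax = radius - CELL_RADIUS - 1e-9
    dy = spacing * math.sqrt(3.0) / 2.0
    kmax = int(math.floor(rmax / dy)) + 1
    pts = []
    for k in range(-kmax, kmax + 1):
        y = k * dy
        xoff = 0.5 * spacing if (k % 2) else 0.0
        mmax = int(math.floor((rmax + abs(xoff)) / spacing)) + 1
        for m in range(-mmax, mmax + 1):
            x = m * spacing + xoff
            if x * x + y * y <= rmax * rmax:
                pts.append((x, y))
    return np.array(pts)


def initialize_packed(config: SimConfig, phenotype: Phenotype | None = None) -> World:
    """Dense-packing initializer: the domain already filled to capacity.

    Stands in for a completed growth run: a hexagonal lattice at the spacing
    that reproduces the reference space-filled density (~13,000 cells in the
    default domain), with cycle clocks at uniformly random phases. At this
    spacing every interior cell is completely surrounded, so divisions only
    resume where deaths open space.
    """
    if phenotype is None:
        phenotype = Phenotype(*config.initial_phenotype)
    spacing = math.sqrt(2.0 * math.pi * CELL_RADIUS**2
                        / (math.sqrt(3.0) * PACKING_FRACTION))
    pts = packed_positions(config.domain_radius, spacing)
    world = World(config, capacity=int(1.3 * len(pts)) + 64)
    for x, y in pts:
        u = world.rng.uniform(SCHEDULE)
        world.add_cell(float(x), float(y), phenotype,
                       cycle_remaining=u * phenotype.tau * 60.0)
    return world


def attempt_division(world: World, i: int) -> int | None:
    """Divide cell i now if space allows; returns the daughter slot or None.

    The cell must be live; a fully surrounded cell arrests instead.
    """
    if not world.alive[i]:
        raise ValueError(f"cell slot {i} is not live")
    world.sync_grid()
    g = world.grid
    s = _try_divide(i, world.pos, world.tau, world.nu, world.cyc,
                    world.direction, world.persistence, world.death_clock,
                    world.state, world.cache, world.alive, world.cell_id,
                    g.head, g.nxt, g.imin, g.jmin, g.nx, g.ny,
                    world.free_slots, world.counts,
                    world._nb_idx, world._nb_xy, world._arcs, world._work,
                    world._ivl, world.domain.radius, world.boundary.code,
                    world.kernel.dtau_max, world.kernel.dnu_max,
                    world.config.mutate_both, world.rng.states, world.rng.incs)
    return None if s < 0 else int(s)


def _ensure_headroom(world: World) -> None:
    ns = world.n_slots
    pending = int(np.count_nonzero(world.alive[:ns] & (world.state[:ns] == CYCLING)
                                   & (world.cyc[:ns] <= world.dt)))
    free = int(world.counts[0]) + (world.capacity - ns)
    if pending + 8 > free:
        world._grow(max(world.capacity * 2, ns + pending + 64))


def step(world: World) -> int:
    """Advance the world by one frame (1 minute). Returns divisions."""
    reg = world.regime
    if world.cat_active:
        sch = world.scheduler
        if not sch.started and world.n_live >= sch.onset_population:
            sch.schedule_first(world.clock_min, world.n_live, reg.f, reg.p_death,
                               world.cat_area_fraction)
        if sch.started and world.clock_min >= sch.next_event_min:
            n_before = world.n_live
            victims = mortality.apply_catastrophe(world)
            sch.record_event(world.clock_min, len(victims), n_before,
                             reg.f, reg.p_death)
    _ensure_headroom(world)
    g = world.grid
    lo, hi = reg.delay_hours
    births = _frame(world.pos, world.tau, world.nu, world.cyc, world.direction,
                    world.persistence, world.death_clock, world.state,
                    world.cache, world.alive, world.cell_id,
                    g.head, g.nxt, g.imin, g.jmin, g.nx, g.ny,
                    world.free_slots, world.counts, world._order,
                    world._nb_idx, world._nb_xy, world._arcs, world._work,
                    world._ivl, world.domain.radius, world.boundary.code,
                    world.dt, world.kernel.dtau_max, world.kernel.dnu_max,
                    world.p_frame, reg.delay_random_deaths, lo * 60.0, hi * 60.0,
                    world.config.mutate_both, world.rng.states, world.rng.incs)
    world.clock_min += world.dt
    world.frame += 1
    world._grid_synced = True  # grid was rebuilt at frame top (births inserted)
    return int(births)


def run(config: SimConfig, stop_when=None, check_every_days: float = 1.0,
        progress=None, world: World | None = None):
    """Execute a full run; returns the list of snapshots.

    ``stop_when(world) -> bool`` is evaluated every ``check_every_days`` of
    simulated time and ends the run early (e.g. "no cycling cells" for
    space-filling experiments). ``progress(world)`` is called once per
    simulated day. Pass ``world`` to run from a custom initial state (e.g.
    the packed initializer).
    """
    if world is None:
        world = initialize(config)
    n_frames = int(round(config.duration_days * 1440.0 / config.dt))
    snap_every = max(1, int(round(config.snapshot_days * 1440.0 / config.dt)))
    check_every = max(1, int(round(check_every_days * 1440.0 / config.dt)))
    snapshots = [observables.snapshot_from_world(world)]
    last_removals = int(world.counts[3])
    for k in range(1, n_frames + 1):
        step(world)
        emit = (k % snap_every == 0) or (k == n_frames)
        stop = False
        if k % check_every == 0:
            if progress is not None:
                progress(world)
            if stop_when is not None and stop_when(world):
                stop = True
                emit = True
        if emit:
            snap = observables.snapshot_from_world(
                world, deaths_since_last=int(world.counts[3]) - last_removals)
            last_removals = int(world.counts[3])
            snapshots.append(snap)
        if stop or world.n_total == 0:
            if world.n_total == 0 and not emit:
                snapshots.append(observables.snapshot_from_world(
                    world, deaths_since_last=int(world.counts[3]) - last_removals))
            break
    return snapshots
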