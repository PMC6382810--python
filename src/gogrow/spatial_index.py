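"""Domain geometry, the 67 um spatial hash grid, and daughter-placement arcs.

Cells are hard disks of diameter 20 um inside a circular domain (default
radius 1350 um, i.e. the ~2.7 mm tissue). Neighbor interactions are restricted
to a Moore neighborhood (3x3 block) of a 67 um square grid, which is a
superset of everything within 67 um and therefore of the 40 um range at which
a neighbor can interfere with a division placement.

A daughter is placed one diameter (20 um) from the mother. A neighbor whose
center lies at distance d < 40 um blocks the placement angles theta (measured
from the mother-to-neighbor direction) with cos(theta) > d/40, an arc of
half-width arccos(d/40). The domain boundary blocks the outward arc where the
daughter center would leave radius R - 10. A mother is *surrounded* when the
union of blocked arcs covers the full circle; surrounded cells neither cycle
nor move until space opens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from . import _rng
from ._rng import PLACEMENT, RngStreams

BIN_SIZE = 67.0          # um, hash-grid pitch
CELL_DIAMETER = 20.0     # um
CELL_RADIUS = 10.0       # um
INTERACTION_RANGE = 2.0 * CELL_DIAMETER  # um; max center distance that blocks placement
OVERLAP_TOL = 1e-9       # um; tangency (distance exactly 20) is not overlap
SURROUND_TOL = 1e-9      # rad; free measure below this counts as fully blocked
TWO_PI = 2.0 * math.pi

#: capacity bounds for scratch buffers: disks with centers >= ~20 um apart
#: admit at most ~25 centers within 40 um; 64 leaves a wide margin.
MAX_NEIGHBORS = 64


@dataclass(frozen=True)
class Domain:
    """Circular tissue centered at the origin."""

    radius: float = 1350.0  # um

    def __post_init__(self):
        if self.radius <= 2 * CELL_RADIUS:
            raise ValueError("domain radius must exceed one cell diameter")

    def contains_cell(self, x: float, y: float) -> bool:
        return math.hypot(x, y) <= self.radius - CELL_RADIUS


def bin_of(pos) -> tuple[int, int]:
    """Hash-grid bin of a position: (floor(x/67), floor(y/67))."""
    x, y = float(pos[0]), float(pos[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("position must be finite")
    return int(math.floor(x / BIN_SIZE)), int(math.floor(y / BIN_SIZE))


@njit(cache=True)
def _bin_flat(x, y, imin, jmin, nx, ny):
    i = int(np.floor(x / BIN_SIZE)) - imin
    j = int(np.floor(y / BIN_SIZE)) - jmin
    if i < 0:
        i = 0
    elif i >= nx:
        i = nx - 1
    if j < 0:
        j = 0
    elif j >= ny:
        j = ny - 1
    return i * ny + j


@njit(cache=True)
def _grid_build(head, nxt, pos, alive, n_slots, imin, jmin, nx, ny):
    head[:] = -1
    for c in range(n_slots):
        if alive[c]:
            b = _bin_flat(pos[c, 0], pos[c, 1], imin, jmin, nx, ny)
            nxt[c] = head[b]
            head[b] = c


@njit(cache=True)
def _grid_insert(head, nxt, c, x, y, imin, jmin, nx, ny):
    b = _bin_flat(x, y, imin, jmin, nx, ny)
    nxt[c] = head[b]
    head[b] = c


@njit(cache=True)
def _gather_block(x, y, self_idx, pos, alive, head, nxt, imin, jmin, nx, ny, out):
    """All live cells in the 3x3 Moore block around (x, y), excluding self."""
    i0 = int(np.floor(x / BIN_SIZE)) - imin
    j0 = int(np.floor(y / BIN_SIZE)) - jmin
    n = 0
    for di in (-1, 0, 1):
        i = i0 + di
        if i < 0 or i >= nx:
            continue
        for dj in (-1, 0, 1):
            j = j0 + dj
            if j < 0 or j >= ny:
                continue
            c = head[i * ny + j]
            while c >= 0:
                if c != self_idx and alive[c]:
                    out[n] = c
                    n += 1
                c = nxt[c]
    return n


@njit(cache=True)
def _gather_within(x, y, self_idx, maxdist, pos, alive, head, nxt,
                   imin, jmin, nx, ny, out):
    """Live cells with center within maxdist of (x, y), excluding self."""
    i0 = int(np.floor(x / BIN_SIZE)) - imin
    j0 = int(np.floor(y / BIN_SIZE)) - jmin
    m2 = maxdist * maxdist
    n = 0
    for di in (-1, 0, 1):
        i = i0 + di
        if i < 0 or i >= nx:
            continue
        for dj in (-1, 0, 1):
            j = j0 + dj
            if j < 0 or j >= ny:
                continue
            c = head[i * ny + j]
            while c >= 0:
                if c != self_idx and alive[c]:
                    dx = pos[c, 0] - x
                    dy = pos[c, 1] - y
                    if dx * dx + dy * dy < m2:
                        out[n] = c
                        n += 1
                c = nxt[c]
    return n


@njit(cache=True)
def _overlaps(ax, ay, bx, by):
    dx = bx - ax
    dy = by - ay
    lim = CELL_DIAMETER - OVERLAP_TOL
    return dx * dx + dy * dy < lim * lim


@njit(cache=True)
def _arcs_from_neighbors(mx, my, R, nb_xy, n_nb, arcs):
    """Fill arcs[:n] with blocked placement intervals; return n, or -1 if the
    geometry blocks the full circle outright."""
    n = 0
    for q in range(n_nb):
        dx = nb_xy[q, 0] - mx
        dy = nb_xy[q, 1] - my
        d2 = dx * dx + dy * dy
        if d2 >= INTERACTION_RANGE * INTERACTION_RANGE:
            continue
        d = np.sqrt(d2)
        if d <= 1e-12:
            return -1  # coincident center: nothing can be placed
        half = np.arccos(min(d / INTERACTION_RANGE, 1.0))
        ang = np.arctan2(dy, dx)
        arcs[n, 0] = ang - half
        arcs[n, 1] = ang + half
        n += 1
    # domain boundary: daughter center must satisfy |m + 20*u| <= R - 10
    rmax = R - CELL_RADIUS
    rm2 = mx * mx + my * my
    rm = np.sqrt(rm2)
    if rm + CELL_DIAMETER > rmax:
        if rm < 1e-12:
            return -1 if CELL_DIAMETER > rmax else n
        c = (rmax * rmax - rm2 - CELL_DIAMETER * CELL_DIAMETER) / (2.0 * CELL_DIAMETER * rm)
        if c <= -1.0:
            return -1
        if c < 1.0:
            # blocked where cos(angle from the outward direction) > c, an arc
            # of half-width arccos(c) centered on the outward direction
            half = np.arccos(c)
            ang = np.arctan2(my, mx)
            arcs[n, 0] = ang - half
            arcs[n, 1] = ang + half
            n += 1
    return n


@njit(cache=True)
def _free_intervals(arcs, n_arcs, work, ivl):
    """Complement of the arc union on the circle.

    Returns (n_free, free_measure); free intervals are written to ivl[:n_free]
    as [lo, hi] with 0 <= lo < hi <= 2*pi.
    """
    if n_arcs < 0:
        return 0, 0.0
    if n_arcs == 0:
        ivl[0, 0] = 0.0
        ivl[0, 1] = TWO_PI
        return 1, TWO_PI
    # normalize into [0, 2pi), split wrap-around arcs
    m = 0
    for q in range(n_arcs):
        lo = arcs[q, 0]
        w = arcs[q, 1] - arcs[q, 0]
        if w >= TWO_PI:
            return 0, 0.0
        lo = lo % TWO_PI
        if lo < 0.0:
            lo += TWO_PI
        hi = lo + w
        if hi > TWO_PI:
            work[m, 0] = lo
            work[m, 1] = TWO_PI
            m += 1
            work[m, 0] = 0.0
            work[m, 1] = hi - TWO_PI
            m += 1
        else:
            work[m, 0] = lo
            work[m, 1] = hi
            m += 1
    # insertion sort by interval start (m is small)
    for a in range(1, m):
        lo = work[a, 0]
        hi = work[a, 1]
        b = a - 1
        while b >= 0 and work[b, 0] > lo:
            work[b + 1, 0] = work[b, 0]
            work[b + 1, 1] = work[b, 1]
            b -= 1
        work[b + 1, 0] = lo
        work[b + 1, 1] = hi
    # sweep the merged union, emitting gaps
    n_free = 0
    free = 0.0
    cursor = 0.0
    for a in range(m):
        lo = work[a, 0]
        hi = work[a, 1]
        if lo > cursor:
            ivl[n_free, 0] = cursor
            ivl[n_free, 1] = lo
            free += lo - cursor
            n_free += 1
        if hi > cursor:
            cursor = hi
    if cursor < TWO_PI:
        ivl[n_free, 0] = cursor
        ivl[n_free, 1] = TWO_PI
        free += TWO_PI - cursor
        n_free += 1
    return n_free, free


@njit(cache=True)
def _sample_free(ivl, n_free, free_measure, u):
    """Map u in [0,1) to an angle uniform on the free union."""
    target = u * free_measure
    for a in range(n_free):
        w = ivl[a, 1] - ivl[a, 0]
        if target <= w or a == n_free - 1:
            return ivl[a, 0] + min(target, w)
        target -= w
    return 0.0  # unreachable


class HashGrid:
    """67 um spatial hash over a circular domain, rebuilt each frame.

    Stores per-bin singly-linked lists (``head``/``nxt``) so that mid-frame
    births can be inserted in O(1); removed cells are skipped lazily via the
    ``alive`` mask.
    """

    def __init__(self, domain: Domain, capacity: int):
        self.domain = domain
        r = domain.radius
        self.imin = int(math.floor(-r / BIN_SIZE)) - 1
        imax = int(math.floor(r / BIN_SIZE)) + 1
        self.jmin = self.imin
        self.nx = imax - self.imin + 1
        self.ny = self.nx
        self.head = np.full(self.nx * self.ny, -1, dtype=np.int64)
        self.nxt = np.full(capacity, -1, dtype=np.int64)
        self.pos = None
        self.alive = None

    def grow(self, capacity: int) -> None:
        if capacity > self.nxt.size:
            new = np.full(capacity, -1, dtype=np.int64)
            new[: self.nxt.size] = self.nxt
            self.nxt = new

    def rebuild(self, pos: np.ndarray, alive: np.ndarray, n_slots: int) -> None:
        self.pos = pos
        self.alive = alive
        _grid_build(self.head, self.nxt, pos, alive, n_slots,
                    self.imin, self.jmin, self.nx, self.ny)


def moore_query(pos, grid: HashGrid, exclude: int = -1) -> np.ndarray:
    """Indices of all live cells in the 3x3 bin block around ``pos``.

    Guaranteed to contain every live cell whose center is within 67 um of
    ``pos`` (hence every possible interaction partner at <= 40 um).
    """
    out = np.empty(grid.nxt.size, dtype=np.int64)
    n = _gather_block(float(pos[0]), float(pos[1]), exclude, grid.pos, grid.alive,
                      grid.head, grid.nxt, grid.imin, grid.jmin, grid.nx, grid.ny, out)
    return out[:n]


def overlaps(a, b) -> bool:
    """True iff two cell centers are closer than one diameter (tangency allowed)."""
    return bool(_overlaps(float(a[0]), float(a[1]), float(b[0]), float(b[1])))


def _neighbors_array(neighbors) -> np.ndarray:
    nb = np.asarray(neighbors, dtype=np.float64)
    if nb.size == 0:
        return np.empty((0, 2))
    return nb.reshape(-1, 2)


def blocked_arcs(mother, neighbors, domain: Domain = Domain()) -> np.ndarray:
    """Blocked placement-angle intervals (radians) on the 20 um circle.

    Returns an (m, 2) array of [start, end] intervals with starts in
    [0, 2*pi) (arcs crossing zero are split); a fully blocked geometry
    returns the single interval [0, 2*pi].
    """
    nb = _neighbors_array(neighbors)
    arcs = np.empty((nb.shape[0] + 1, 2))
    n = _arcs_from_neighbors(float(mother[0]), float(mother[1]), domain.radius,
                             nb, nb.shape[0], arcs)
    if n < 0:
        return np.array([[0.0, TWO_PI]])
    out = []
    for lo, hi in arcs[:n]:
        w = hi - lo
        lo = lo % TWO_PI
        if lo + w > TWO_PI:
            out.append((lo, TWO_PI))
            out.append((0.0, lo + w - TWO_PI))
        else:
            out.append((lo, lo + w))
    return np.array(out).reshape(-1, 2)


def _free_of(mother, neighbors, domain):
    nb = _neighbors_array(neighbors)
    arcs = np.empty((nb.shape[0] + 1, 2))
    n = _arcs_from_neighbors(float(mother[0]), float(mother[1]), domain.radius,
                             nb, nb.shape[0], arcs)
    work = np.empty((2 * (nb.shape[0] + 1) + 2, 2))
    ivl = np.empty((2 * (nb.shape[0] + 1) + 2, 2))
    n_free, measure = _free_intervals(arcs, n, work, ivl)
    return ivl, n_free, measure


def is_surrounded(mother, neighbors, domain: Domain = Domain()) -> bool:
    """True iff no daughter placement at 20 um avoids overlap and stays in-domain."""
    _, _, measure = _free_of(mother, neighbors, domain)
    return measure < SURROUND_TOL


def free_angle(mother, neighbors, domain: Domain = Domain(),
               rng: RngStreams | None = None) -> float | None:
    """An angle uniform on the unblocked union, or None when surrounded."""
    if rng is None:
        raise ValueError("free_angle requires an RngStreams instance")
    ivl, n_free, measure = _free_of(mother, neighbors, domain)
    if measure < SURROUND_TOL:
        return None
    u = _rng.uniform(rng.states, rng.incs, PLACEMENT)
    return float(_sample_free(ivl, n_free, measure, u))
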