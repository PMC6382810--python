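"""Persistent random walk with collision rejection and boundary arrest.

A cycling cell moves at its phenotype speed nu (um/h) along a fixed heading
for a persistence time drawn from N(80 min, 40 min) truncated to positive
values, then turns to a fresh uniform heading. A 1-minute sub-move that would
overlap a Moore neighbor is rejected outright (position reverted) and the
heading and persistence are redrawn; a sub-move that would cross the domain
boundary arrests the cell (it stops cycling and migrating).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import _rng, spatial_index
from ._rng import MOTILITY, RngStreams
from .lifestate import BOUNDARY_ARRESTED
from .spatial_index import (CELL_DIAMETER, CELL_RADIUS, OVERLAP_TOL, TWO_PI,
                            _bin_flat, _gather_within)

PERSISTENCE_MEAN = 80.0  # minutes
PERSISTENCE_SD = 40.0    # minutes

#: occupancy changes within this distance of a cell invalidate its cached
#: surround status (40 um interaction range + one sub-move of slack)
INVALIDATION_RANGE = 40.5


@njit(cache=True)
def _draw_persistence(states, incs):
    while True:
        v = PERSISTENCE_MEAN + PERSISTENCE_SD * _rng.normal(states, incs, MOTILITY)
        if v > 0.0:
            return v


@njit(cache=True)
def _invalidate_near(x, y, pos, alive, cache, head, nxt, imin, jmin, nx, ny):
    """Mark the cached surround status dirty for all live cells within
    INVALIDATION_RANGE of (x, y)."""
    i0 = int(np.floor(x / spatial_index.BIN_SIZE)) - imin
    j0 = int(np.floor(y / spatial_index.BIN_SIZE)) - jmin
    r2 = INVALIDATION_RANGE * INVALIDATION_RANGE
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
                if alive[c]:
                    dx = pos[c, 0] - x
                    dy = pos[c, 1] - y
                    if dx * dx + dy * dy < r2:
                        cache[c] = -1
                c = nxt[c]


@njit(cache=True)
def _move_cell(i, pos, direction, persistence, nu, state, cache,
               alive, head, nxt, imin, jmin, nx, ny, R, dt, states, incs):
    """One 1-minute sub-move for cycling cell i. Returns 1 if the position
    changed, 0 otherwise."""
    v = nu[i] * dt / 60.0
    if v <= 0.0:
        # stationary phenotype: persistence still elapses
        persistence[i] -= dt
        if persistence[i] <= 0.0:
            direction[i] = TWO_PI * _rng.uniform(states, incs, MOTILITY)
            persistence[i] = _draw_persistence(states, incs)
        return 0
    tx = pos[i, 0] + v * np.cos(direction[i])
    ty = pos[i, 1] + v * np.sin(direction[i])
    if tx * tx + ty * ty > (R - CELL_RADIUS) * (R - CELL_RADIUS):
        state[i] = BOUNDARY_ARRESTED
        return 0
    # collision test against every live Moore neighbor
    lim = CELL_DIAMETER - OVERLAP_TOL
    lim2 = lim * lim
    i0 = int(np.floor(pos[i, 0] / spatial_index.BIN_SIZE)) - imin
    j0 = int(np.floor(pos[i, 1] / spatial_index.BIN_SIZE)) - jmin
    for di in (-1, 0, 1):
        bi = i0 + di
        if bi < 0 or bi >= nx:
            continue
        for dj in (-1, 0, 1):
            bj = j0 + dj
            if bj < 0 or bj >= ny:
                continue
            c = head[bi * ny + bj]
            while c >= 0:
                if c != i and alive[c]:
                    dx = pos[c, 0] - tx
                    dy = pos[c, 1] - ty
                    if dx * dx + dy * dy < lim2:
                        direction[i] = TWO_PI * _rng.uniform(states, incs, MOTILITY)
                        persistence[i] = _draw_persistence(states, incs)
                        return 0
                c = nxt[c]
    ox = pos[i, 0]
    oy = pos[i, 1]
    pos[i, 0] = tx
    pos[i, 1] = ty
    persistence[i] -= dt
    if persistence[i] <= 0.0:
        direction[i] = TWO_PI * _rng.uniform(states, incs, MOTILITY)
        persistence[i] = _draw_persistence(states, incs)
    _invalidate_near(ox, oy, pos, alive, cache, head, nxt, imin, jmin, nx, ny)
    return 1


def draw_persistence(rng: RngStreams) -> float:
    """Persistence time in minutes: N(80, 40) truncated to positive values."""
    return float(_draw_persistence(rng.states, rng.incs))


def move_step(world, i: int, dt: float = 1.0) -> bool:
    """Advance cell i by one sub-move inside ``world`` (see engine.World).

    Returns True if the position changed. The caller is responsible for the
    cell being in the cycling state; the world grid must be current.
    """
    g = world.grid
    moved = _move_cell(i, world.pos, world.direction, world.persistence,
                       world.nu, world.state, world.cache, world.alive,
                       g.head, g.nxt, g.imin, g.jmin, g.nx, g.ny,
                       world.domain.radius, dt, world.rng.states, world.rng.incs)
    return bool(moved)
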