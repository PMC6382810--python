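import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gogrow._rng import RngStreams
from gogrow.spatial_index import (Domain, HashGrid, TWO_PI, bin_of,
                                  blocked_arcs, free_angle, is_surrounded,
                                  moore_query, overlaps, _free_intervals)

BIG = Domain(5000.0)


@pytest.mark.parametrize("pos,expected", [
    ((0.0, 0.0), (0, 0)),
    ((70.0, 0.0), (1, 0)),
    ((-1.0, 5.0), (-1, 0)),   # floor convention for negatives
    ((66.9, 67.0), (0, 1)),
])
def test_bin_of(pos, expected):
    assert bin_of(pos) == expected


def test_bin_of_rejects_nonfinite():
    with pytest.raises(ValueError):
        bin_of((np.nan, 0.0))


@pytest.mark.parametrize("d,expected", [(19.9, True), (20.0, False), (0.0, True),
                                        (20.0000001, False)])
def test_overlap_threshold_allows_tangency(d, expected):
    assert overlaps((0.0, 0.0), (d, 0.0)) is expected


def _grid_for(points, domain=BIG):
    pos = np.asarray(points, dtype=float).reshape(-1, 2)
    alive = np.ones(len(pos), dtype=np.bool_)
    g = HashGrid(domain, len(pos))
    g.rebuild(pos, alive, len(pos))
    return g


def test_moore_query_on_empty_world():
    g = _grid_for(np.empty((0, 2)))
    assert moore_query((0.0, 0.0), g).size == 0


def test_moore_query_finds_and_excludes_by_range():
    g = _grid_for([(0.0, 0.0), (40.0, 0.0), (250.0, 0.0)])
    near = set(moore_query((0.0, 0.0), g, exclude=0))
    assert 1 in near           # within 67 um: guaranteed present
    assert 2 not in near       # 250 um away: outside the Moore block


def test_moore_query_brute_force_oracle():
    # query must contain everything within 40 um (the interaction range) and
    # agree with brute force for all pairs within 67 um
    np_rng = np.random.default_rng(5)
    domain = Domain(500.0)
    for _ in range(100):
        n = int(np_rng.integers(1, 51))
        r = 490.0 * np.sqrt(np_rng.uniform(size=n))
        th = np_rng.uniform(0, TWO_PI, size=n)
        pos = np.c_[r * np.cos(th), r * np.sin(th)]
        g = _grid_for(pos, domain)
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        for i in range(n):
            got = set(moore_query(pos[i], g, exclude=i))
            within40 = {j for j in range(n) if j != i and d[i, j] < 40.0}
            within67 = {j for j in range(n) if j != i and d[i, j] <= 67.0}
            assert within40 <= got
            assert within67 <= got


def test_blocked_arc_width_touching_neighbor():
    # one touching neighbor (d=20) blocks 2*arccos(20/40) = 120 degrees
    arcs = blocked_arcs((0.0, 0.0), [(20.0, 0.0)], BIG)
    width = float(np.sum(arcs[:, 1] - arcs[:, 0]))
    assert width == pytest.approx(TWO_PI / 3.0, abs=1e-9)
    # intervals normalized onto [0, 2*pi)
    assert np.all(arcs[:, 0] >= 0.0) and np.all(arcs[:, 1] <= TWO_PI + 1e-12)
    assert np.all(arcs[:, 0] < arcs[:, 1])


def test_blocked_arcs_far_neighbor_and_empty():
    assert blocked_arcs((0.0, 0.0), [(40.0, 0.0)], BIG).shape[0] == 0
    assert blocked_arcs((0.0, 0.0), [], BIG).shape[0] == 0


def _ring(k, d=20.0):
    return [(d * math.cos(2 * math.pi * j / k), d * math.sin(2 * math.pi * j / k))
            for j in range(k)]


def test_three_touching_neighbors_tile_the_circle():
    assert is_surrounded((0.0, 0.0), _ring(3), BIG) is True
    assert is_surrounded((0.0, 0.0), _ring(1), BIG) is False
    assert is_surrounded((0.0, 0.0), [], BIG) is False


def test_boundary_blocks_outward_placement():
    d = Domain(200.0)
    # mother touching the boundary: outward cone blocked but not surrounded
    assert not is_surrounded((190.0, 0.0), [], d)
    arcs = blocked_arcs((190.0, 0.0), [], d)
    # outward cone of half-width arccos(c), split at angle zero
    expected = 2 * math.acos((190.0 ** 2 - 190.0 ** 2 - 400.0) / (40.0 * 190.0))
    assert float(np.sum(arcs[:, 1] - arcs[:, 0])) == pytest.approx(expected, abs=1e-9)
    # two flanking touching neighbors + boundary can fully surround
    nb = [(190.0 + 20 * math.cos(a), 20 * math.sin(a))
          for a in (2 * math.pi / 3, -2 * math.pi / 3)]
    assert is_surrounded((190.0, 0.0), nb, d)


def test_free_angle_respects_blocked_arc(rng):
    # one touching neighbor at angle 0 leaves only (60, 300) degrees free
    for _ in range(200):
        a = free_angle((0.0, 0.0), [(20.0, 0.0)], BIG, rng)
        a = a % TWO_PI
        assert TWO_PI / 6 < a < 5 * TWO_PI / 6 or math.isclose(a, TWO_PI / 6)


def test_free_angle_surrounded_returns_none(rng):
    assert free_angle((0.0, 0.0), _ring(3), BIG, rng) is None


def test_free_angle_placement_never_overlaps(rng):
    np_rng = np.random.default_rng(23)
    for _ in range(300):
        n = int(np_rng.integers(0, 7))
        nb = []
        while len(nb) < n:
            d = np_rng.uniform(20.0, 45.0)
            th = np_rng.uniform(0, TWO_PI)
            cand = (d * math.cos(th), d * math.sin(th))
            if all(math.dist(cand, o) >= 20.0 for o in nb):
                nb.append(cand)
        a = free_angle((0.0, 0.0), nb, BIG, rng)
        if a is None:
            continue
        daughter = (20 * math.cos(a), 20 * math.sin(a))
        assert all(not overlaps(daughter, o) for o in nb)
        assert math.hypot(*daughter) <= BIG.radius - 10.0


def test_surrounded_monte_carlo_oracle():
    # free-angle search agrees with direct random trial placement
    np_rng = np.random.default_rng(31)
    domain = Domain(300.0)
    angles = np_rng.uniform(0, TWO_PI, size=10_000)
    ca, sa = np.cos(angles), np.sin(angles)
    for _ in range(200):
        m = np.array([np_rng.uniform(-280, 280), np_rng.uniform(-280, 280)])
        if np.hypot(*m) > 290.0:
            continue
        n = int(np_rng.integers(0, 8))
        nb = m + np_rng.uniform(15.0, 45.0, size=(n, 1)) * _unit(np_rng, n)
        px = m[0] + 20.0 * ca
        py = m[1] + 20.0 * sa
        ok = np.hypot(px, py) <= domain.radius - 10.0
        for q in range(n):
            ok &= np.hypot(px - nb[q, 0], py - nb[q, 1]) >= 20.0 - 1e-9
        mc_any = bool(ok.any())
        if is_surrounded(m, nb, domain):
            assert not mc_any
        else:
            # ignore knife-edge geometries below Monte-Carlo resolution
            from gogrow.spatial_index import _free_of
            _, _, measure = _free_of(m, nb, domain)
            if measure > 1e-2:
                assert mc_any


def _unit(np_rng, n):
    th = np_rng.uniform(0, TWO_PI, size=(n, 1))
    return np.c_[np.cos(th), np.sin(th)].reshape(n, 2)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-10.0, 10.0), st.floats(0.01, 6.0)),
                min_size=0, max_size=12))
def test_arc_union_partitions_the_circle(arc_spec):
    # free measure + blocked-union measure = 2*pi, intervals disjoint & sorted
    arcs = np.array([[s, s + w] for s, w in arc_spec]).reshape(-1, 2)
    work = np.empty((2 * len(arc_spec) + 4, 2))
    ivl = np.empty((2 * len(arc_spec) + 4, 2))
    n_free, measure = _free_intervals(arcs, arcs.shape[0], work, ivl)
    assert 0.0 <= measure <= TWO_PI + 1e-9
    prev_hi = -1.0
    total = 0.0
    for k in range(n_free):
        lo, hi = ivl[k]
        assert 0.0 <= lo < hi <= TWO_PI + 1e-12
        assert lo >= prev_hi
        prev_hi = hi
        total += hi - lo
    assert total == pytest.approx(measure, abs=1e-9)
    # discretized independent oracle (resolution-limited tolerance)
    blocked = _union_measure(arc_spec)
    assert measure == pytest.approx(TWO_PI - blocked, abs=1e-2)


def _union_measure(arc_spec):
    # independent interval-union oracle on a fine circle discretization
    if not arc_spec:
        return 0.0
    grid = np.linspace(0, TWO_PI, 50_001)[:-1]
    covered = np.zeros(grid.size, dtype=bool)
    for s, w in arc_spec:
        if w >= TWO_PI:
            return TWO_PI
        lo = s % TWO_PI
        hi = lo + w
        covered |= (grid >= lo) & (grid < hi)
        if hi > TWO_PI:
            covered |= grid < hi - TWO_PI
    return covered.mean() * TWO_PI
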