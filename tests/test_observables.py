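import json

import numpy as np
import pytest
from click.testing import CliRunner

from gogrow.cli import main as cli_main
from gogrow.engine import SimConfig, run
from gogrow.observables import (Snapshot, SnapshotFormatError, mean_traits,
                                read_snapshots, render_density_map,
                                snapshot_from_world, summary_frame,
                                trait_histogram, write_snapshots)
from gogrow.scenarios import PRESETS, get_preset, list_presets


class TestTraitHistogram:
    def test_least_aggressive_corner_bin(self):
        h = trait_histogram([40.0], [0.0])
        assert h.shape == (11, 11) and h.sum() == 1
        assert h[10, 0] == 1  # last tau bin, first nu bin

    def test_most_aggressive_corner_right_edge_inclusive(self):
        h = trait_histogram([10.0], [20.0])
        assert h[0, 10] == 1

    def test_counts_are_conserved(self):
        np_rng = np.random.default_rng(1)
        tau = np_rng.uniform(10, 40, size=500)
        nu = np_rng.uniform(0, 20, size=500)
        assert trait_histogram(tau, nu).sum() == 500


class TestMeanTraits:
    def test_single_cell(self):
        assert mean_traits([25.0], [10.0]) == (25.0, 10.0)

    def test_two_cells_average(self):
        assert mean_traits([10.0, 40.0], [0.0, 20.0]) == (25.0, 10.0)

    def test_empty_population_signal(self):
        assert mean_traits([], []) is None


def _random_snapshots(k=3, seed=0):
    np_rng = np.random.default_rng(seed)
    out = []
    for j in range(k):
        out.append(Snapshot(
            time_days=float(j) * 5 + np_rng.uniform(),
            n=int(np_rng.integers(0, 500)),
            mean_tau=float(np_rng.uniform(10, 40)),
            mean_nu=float(np_rng.uniform(0, 20)),
            hist11=np_rng.integers(0, 9, size=(11, 11)).astype(np.int64),
            deaths_since_last=int(np_rng.integers(0, 50))))
    return out


def test_snapshot_round_trip_is_exact(tmp_path):
    snaps = _random_snapshots()
    write_snapshots(snaps, tmp_path / "d", config=SimConfig(duration_days=1.0), seed=7)
    back, meta = read_snapshots(tmp_path / "d")
    assert meta["seed"] == 7
    assert meta["config"]["duration_days"] == 1.0
    for a, b in zip(snaps, back):
        assert a.time_days == b.time_days
        assert a.n == b.n
        assert a.mean_tau == b.mean_tau
        assert a.mean_nu == b.mean_nu
        assert a.deaths_since_last == b.deaths_since_last
        assert np.array_equal(a.hist11, b.hist11)


def test_empty_trajectory_round_trip(tmp_path):
    write_snapshots([], tmp_path / "d")
    back, _ = read_snapshots(tmp_path / "d")
    assert back == []


def test_malformed_bundles_raise_with_context(tmp_path):
    with pytest.raises(SnapshotFormatError, match="summary.csv"):
        read_snapshots(tmp_path)
    d = tmp_path / "d"
    write_snapshots(_random_snapshots(), d)
    (d / "bundle.json").write_text("{not json")
    with pytest.raises(SnapshotFormatError, match="line"):
        read_snapshots(d)
    (d / "bundle.json").write_text(json.dumps({"hist11": []}))
    (d / "summary.csv").write_text("time_days,n\n0,1\n")
    with pytest.raises(SnapshotFormatError, match="missing column"):
        read_snapshots(d)


def test_render_density_map_writes_png(tmp_path):
    snaps = _random_snapshots()
    p = render_density_map(snaps[-1].hist11, snaps, tmp_path / "m.png")
    assert p.exists() and p.stat().st_size > 0
    # an all-empty histogram still renders (fully white panel)
    p2 = render_density_map(np.zeros((11, 11)), [], tmp_path / "w.png")
    assert p2.exists()


def test_snapshot_from_world_excludes_dying_cells(world_factory):
    from gogrow.lifestate import DYING
    from gogrow.trait_space import Phenotype
    w = world_factory(radius=300.0)
    w.add_cell(0.0, 0.0, Phenotype(20.0, 5.0))
    j = w.add_cell(50.0, 0.0, Phenotype(30.0, 15.0))
    w.state[j] = DYING
    w.death_clock[j] = 100.0
    s = snapshot_from_world(w)
    assert s.n == 1
    assert s.hist11.sum() == 1
    assert s.mean_tau == 20.0


class TestScenarios:
    def test_catalogue_covers_the_study_grid(self):
        names = list_presets()
        assert len(names) >= 12
        for b in ("open", "convex", "concave"):
            assert f"growth_{b}" in names
            for lvl in ("low", "high"):
                assert f"turnover_{lvl}_{b}" in names
            for tag in ("half", "full"):
                assert f"catastrophe_{tag}_{b}" in names

    @pytest.mark.parametrize("name,boundary,p_death,f", [
        ("growth_open", "open", 0.0, 0.0),
        ("turnover_low_convex", "convex", 1 / 14, 0.0),
        ("turnover_high_concave", "concave", 1 / 7, 0.0),
        ("catastrophe_half_open", "open", 1 / 7, 0.5),
        ("catastrophe_full_concave", "concave", 1 / 7, 1.0),
    ])
    def test_preset_parameters_match_their_design(self, name, boundary, p_death, f):
        p = PRESETS[name]
        assert p.boundary == boundary
        assert p.p_death == pytest.approx(p_death)
        assert p.cat_fraction == f
        assert p.initial_phenotype == (40.0, 0.0)
        small = PRESETS[name + "_small"]
        assert small.domain_radius == 500.0

    def test_preset_to_config_round_trip(self):
        cfg = get_preset("turnover_high_open_small").to_config(seed=9)
        assert cfg.seed == 9
        assert cfg.domain_radius == 500.0
        assert cfg.regime.p_death == pytest.approx(1 / 7)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            get_preset("nope")


class TestCli:
    def test_scenarios_listing(self):
        res = CliRunner().invoke(cli_main, ["scenarios"])
        assert res.exit_code == 0
        assert len(res.output.strip().splitlines()) >= 12

    def test_run_writes_bundle_and_render_consumes_it(self, tmp_path):
        out = tmp_path / "out"
        res = CliRunner().invoke(cli_main, [
            "run", "--scenario", "growth_open_small", "--seed", "1",
            "--out", str(out), "--duration", "0.02", "--snapshot-days", "0.01"])
        assert res.exit_code == 0, res.output
        assert (out / "summary.csv").exists() and (out / "bundle.json").exists()
        res = CliRunner().invoke(cli_main, ["render", str(out)])
        assert res.exit_code == 0
        assert (out / "density_map.png").exists()

    def test_missing_config_file_fails(self, tmp_path):
        res = CliRunner().invoke(cli_main, [
            "run", "--config", str(tmp_path / "missing.yaml"), "--out", "x"])
        assert res.exit_code != 0

    def test_invalid_config_fields_fail(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("duration_days: 1.0\nwarp_speed: 9\n")
        res = CliRunner().invoke(cli_main, [
            "run", "--config", str(bad), "--out", str(tmp_path / "o")])
        assert res.exit_code != 0
        assert "warp_speed" in res.output

    def test_yaml_config_run(self, tmp_path):
        cfgf = tmp_path / "c.yaml"
        cfgf.write_text(
            "duration_days: 0.02\ndomain_radius: 300.0\nboundary: concave\n"
            "snapshot_days: 0.01\nregime:\n  p_death: 0.142857\n  f: 0.5\n")
        res = CliRunner().invoke(cli_main, [
            "run", "--config", str(cfgf), "--seed", "3", "--out", str(tmp_path / "o")])
        assert res.exit_code == 0, res.output
        back, meta = read_snapshots(tmp_path / "o")
        assert meta["seed"] == 3
        assert meta["config"]["boundary"] == "concave"


def test_stored_config_reproduces_the_stored_summary(tmp_path):
    cfg = SimConfig(duration_days=1.0, domain_radius=200.0, seed=11,
                    initial_phenotype=(12.0, 6.0), snapshot_days=0.5)
    snaps = run(cfg)
    write_snapshots(snaps, tmp_path / "d", config=cfg, seed=cfg.seed)
    back, meta = read_snapshots(tmp_path / "d")
    replay = run(SimConfig(duration_days=meta["config"]["duration_days"],
                           domain_radius=meta["config"]["domain_radius"],
                           seed=meta["seed"],
                           initial_phenotype=tuple(meta["config"]["initial_phenotype"]),
                           snapshot_days=meta["config"]["snapshot_days"]))
    assert summary_frame(replay).equals(summary_frame(back))
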