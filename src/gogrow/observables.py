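"""Snapshots, trait-density histograms, trajectory I/O and density maps.

A snapshot summarizes the live (non-dying) population at one time point:
count, mean traits, and an 11 x 11 histogram of (tau, nu) over the full trait
ranges (tau axis [10, 40] h, nu axis [0, 20] um/h, equal-width bins, right
edge inclusive in the last bin). Trajectories are written as a summary CSV
plus a JSON bundle (config, seed, histogram stack); per-cell tables are
optional CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lifestate import DYING, STATE_NAMES
from .trait_space import NU_MAX, NU_MIN, TAU_MAX, TAU_MIN

N_BINS = 11
TAU_EDGES = np.linspace(TAU_MIN, TAU_MAX, N_BINS + 1)
NU_EDGES = np.linspace(NU_MIN, NU_MAX, N_BINS + 1)

_SUMMARY_COLS = ["time_days", "n", "mean_tau", "mean_nu", "deaths_since_last"]


class SnapshotFormatError(ValueError):
    """A snapshot file is malformed; the message carries file/field context."""


@dataclass
class Snapshot:
    time_days: float
    n: int
    mean_tau: float  # nan when empty
    mean_nu: float
    hist11: np.ndarray  # (11, 11) counts, [tau_bin, nu_bin]
    deaths_since_last: int = 0
    cells: pd.DataFrame | None = None


def trait_histogram(tau, nu) -> np.ndarray:
    """11 x 11 counts of (tau, nu) pairs over the full trait ranges."""
    tau = np.asarray(tau, dtype=float).ravel()
    nu = np.asarray(nu, dtype=float).ravel()
    h, _, _ = np.histogram2d(tau, nu, bins=[TAU_EDGES, NU_EDGES])
    return h.astype(np.int64)


def mean_traits(tau, nu):
    """Arithmetic mean (tau, nu) over cells, or None for an empty population."""
    tau = np.asarray(tau, dtype=float).ravel()
    nu = np.asarray(nu, dtype=float).ravel()
    if tau.size == 0:
        return None
    return float(tau.mean()), float(nu.mean())


def snapshot_from_world(world, deaths_since_last: int = 0,
                        per_cell: bool = False) -> Snapshot:
    """Summarize a world's live, non-dying population."""
    idx = world.live_indices()
    tau = world.tau[idx]
    nu = world.nu[idx]
    mt = mean_traits(tau, nu)
    cells = None
    if per_cell:
        cells = pd.DataFrame({
            "id": world.cell_id[idx],
            "x": world.pos[idx, 0],
            "y": world.pos[idx, 1],
            "tau": tau,
            "nu": nu,
            "life_state": [STATE_NAMES[int(s)] for s in world.state[idx]],
        })
    return Snapshot(
        time_days=world.clock_min / 1440.0,
        n=int(idx.size),
        mean_tau=mt[0] if mt else float("nan"),
        mean_nu=mt[1] if mt else float("nan"),
        hist11=trait_histogram(tau, nu),
        deaths_since_last=int(deaths_since_last),
        cells=cells,
    )


def summary_frame(snapshots) -> pd.DataFrame:
    return pd.DataFrame({
        "time_days": [s.time_days for s in snapshots],
        "n": [s.n for s in snapshots],
        "mean_tau": [s.mean_tau for s in snapshots],
        "mean_nu": [s.mean_nu for s in snapshots],
        "deaths_since_last": [s.deaths_since_last for s in snapshots],
    })


def write_snapshots(snapshots, outdir, config=None, seed=None) -> Path:
    """Write a trajectory: summary.csv, bundle.json, optional per-cell CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly
    summary_frame(snapshots).to_csv(outdir / "summary.csv", index=False,
                                    float_format="%.17g")
    bundle = {
        "seed": seed,
        "config": _config_dict(config) if config is not None else None,
        "times_days": [s.time_days for s in snapshots],
        "hist11": [s.hist11.tolist() for s in snapshots],
    }
    (outdir / "bundle.json").write_text(json.dumps(bundle))
    for k, s in enumerate(snapshots):
        if s.cells is not None:
            s.cells.to_csv(outdir / f"cells_{k:04d}.csv", index=False)
    return outdir


def read_snapshots(indir):
    """Inverse of write_snapshots on the summary fields.

    Returns (snapshots, meta) where meta holds the stored seed/config dict.
    """
    indir = Path(indir)
    try:
        df = pd.read_csv(indir / "summary.csv", float_precision="round_trip")
    except FileNotFoundError:
        raise SnapshotFormatError(f"{indir}: missing summary.csv")
    except Exception as exc:  # malformed CSV
        raise SnapshotFormatError(f"{indir}/summary.csv: {exc}") from exc
    for col in _SUMMARY_COLS:
        if col not in df.columns:
            raise SnapshotFormatError(f"{indir}/summary.csv: missing column {col!r}")
    try:
        bundle = json.loads((indir / "bundle.json").read_text())
        hists = [np.asarray(h, dtype=np.int64) for h in bundle.get("hist11", [])]
    except FileNotFoundError:
        raise SnapshotFormatError(f"{indir}: missing bundle.json")
    except json.JSONDecodeError as exc:
        raise SnapshotFormatError(
            f"{indir}/bundle.json: invalid JSON at line {exc.lineno}") from exc
    snapshots = []
    for k, row in df.iterrows():
        h = hists[k] if k < len(hists) else np.zeros((N_BINS, N_BINS), np.int64)
        if h.shape != (N_BINS, N_BINS):
            raise SnapshotFormatError(f"{indir}/bundle.json: hist {k} has shape {h.shape}")
        snapshots.append(Snapshot(
            time_days=float(row["time_days"]), n=int(row["n"]),
            mean_tau=float(row["mean_tau"]), mean_nu=float(row["mean_nu"]),
            hist11=h, deaths_since_last=int(row["deaths_since_last"])))
    meta = {"seed": bundle.get("seed"), "config": bundle.get("config")}
    return snapshots, meta


def _config_dict(config):
    d = dataclasses.asdict(config)
    return d


def render_density_map(hist11, snapshots, path, title=None) -> Path:
    """Trait-density map with the mean-trait trajectory overlaid.

    The horizontal axis is proliferation (fast proliferation = short tau on
    the right), the vertical axis migration speed. Density is shown as a
    transparency-weighted color map: empty bins are white. Trajectory points
    mark the population mean at each snapshot; the endpoint gets a star.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist11 = np.asarray(hist11, dtype=float)
    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    masked = np.ma.masked_where(hist11 == 0, hist11)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("white")
    # hist indexed [tau_bin, nu_bin]; transpose so nu is vertical, and invert
    # the horizontal extent so short tau (fast proliferation) sits right
    ax.imshow(masked.T, origin="lower", cmap=cmap, aspect="auto",
              extent=[TAU_MAX, TAU_MIN, NU_MIN, NU_MAX],
              interpolation="nearest")
    xs = [s.mean_tau for s in snapshots if s.n > 0]
    ys = [s.mean_nu for s in snapshots if s.n > 0]
    if xs:
        ax.plot(xs, ys, "-o", color="red", ms=3, lw=1)
        ax.plot(xs[-1], ys[-1], "*", color="black", ms=12)
    ax.set_xlim(TAU_MAX, TAU_MIN)
    ax.set_ylim(NU_MIN, NU_MAX)
    ax.set_xlabel("intermitotic time tau (h)  [fast proliferation ->]")
    ax.set_ylabel("migration speed nu (um/h)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
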