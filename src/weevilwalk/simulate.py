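"""Individual-based forward simulation of the lattice Markov walk.

Each individual performs independent daily transitions sampled from the
transition row of its current cell.  Reproducibility is per-stream: every
(run, individual) pair owns an RNG stream spawned from the master seed, so
dropping or reordering individuals never perturbs other individuals' paths.
Detection thinning emulates imperfect daily recapture of tagged insects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import TrackDataset
from .kernel import ParameterSet, TransitionModel
from .lattice import PlotRaster


@dataclass
class SimulationConfig:
    """Settings for one simulation experiment.

    ``releases`` gives one row per individual with columns
    ``individual_id, plot_id, row, col``; every individual is released on
    day 0 at its release cell, then walks for ``horizon`` days.
    """

    releases: pd.DataFrame
    n_runs: int = 100
    horizon: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be ≥ 1")
        if self.horizon < 0:
            raise ValueError("horizon must be ≥ 0")
        required = {"individual_id", "plot_id", "row", "col"}
        if not required.issubset(self.releases.columns):
            raise ValueError(f"releases must have columns {sorted(required)}")


def _walker_rng(seed: int, run: int, individual_id) -> np.random.Generator:
    # stream keyed by a stable hash of the id, not position, so dropping or
    # reordering individuals never changes other individuals' paths
    key = zlib.crc32(str(individual_id).encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(run, key)))


def simulate_walks(plots: dict[str, PlotRaster], params: ParameterSet,
                   config: SimulationConfig) -> TrackDataset:
    """Simulate daily Markov walks for every (run, individual).

    Returns the full daily positions (no missingness) as a track table with
    a ``run`` column.  Transition rows are materialized lazily for visited
    departure cells only, and sampling is inverse-CDF on the cached
    cumulative row.  Bit-identical output for identical seeds.
    """
    config.releases.reset_index(drop=True)
    models = {pid: TransitionModel(plots[pid], params)
              for pid in config.releases["plot_id"].unique()}
    for pid, grp in config.releases.groupby("plot_id", sort=False):
        plot = plots[pid]
        if ((grp["row"] < 0).any() or (grp["row"] >= plot.n_rows).any()
                or (grp["col"] < 0).any() or (grp["col"] >= plot.n_cols).any()):
            raise ValueError(f"release cell out of bounds in plot {pid!r}")

    rel = config.releases.reset_index(drop=True)
    n_ind = len(rel)
    T = config.horizon
    runs_col = np.repeat(np.arange(config.n_runs), n_ind * (T + 1))
    ind_col = np.tile(np.repeat(rel["individual_id"].to_numpy(), T + 1),
                      config.n_runs)
    plot_col = np.tile(np.repeat(rel["plot_id"].to_numpy(), T + 1),
                       config.n_runs)
    day_col = np.tile(np.arange(T + 1), config.n_runs * n_ind)
    rows = np.empty(len(runs_col), dtype=np.int64)
    cols = np.empty(len(runs_col), dtype=np.int64)

    pos = 0
    for run in range(config.n_runs):
        for k in range(n_ind):
            pid = rel.at[k, "plot_id"]
            plot, tm = plots[pid], models[pid]
            cur = int(rel.at[k, "row"]) * plot.n_cols + int(rel.at[k, "col"])
            rng = _walker_rng(config.seed, run, rel.at[k, "individual_id"])
            draws = rng.random(T) if T else ()
            path = np.empty(T + 1, dtype=np.int64)
            path[0] = cur
            for t in range(T):
                cum = tm.cumulative_row(cur)
                cur = int(np.searchsorted(cum, draws[t], side="right"))
                path[t + 1] = cur
            rows[pos:pos + T + 1] = path // plot.n_cols
            cols[pos:pos + T + 1] = path % plot.n_cols
            pos += T + 1

    return TrackDataset(records=pd.DataFrame({
        "run": runs_col, "individual_id": ind_col, "plot_id": plot_col,
        "day": day_col, "row": rows, "col": cols}))


def apply_detection(tracks: TrackDataset,
                    recapture_prob: float | tuple[float, float] | dict,
                    seed: int = 0) -> TrackDataset:
    """Thin daily records with imperfect detection.

    Each record is retained independently with the recapture probability;
    a ``(low, high)`` range draws one probability per plot uniformly, and a
    ``{plot_id: p}`` mapping fixes it per plot (e.g. probabilities
    estimated from an observed dataset).  Release-day records (each
    individual's first day) are always retained — releases are known
    exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(0xDE7EC7,)))
    df = tracks.records
    if isinstance(recapture_prob, dict):
        if any(not 0 <= v <= 1 for v in recapture_prob.values()):
            raise ValueError("recapture probabilities must be in [0, 1]")
        p = df["plot_id"].map(recapture_prob).to_numpy(dtype=float)
        if np.any(np.isnan(p)):
            raise ValueError("recapture mapping misses some plots")
    elif isinstance(recapture_prob, tuple):
        lo, hi = recapture_prob
        if not (0 <= lo <= hi <= 1):
            raise ValueError("recapture range must satisfy 0 ≤ lo ≤ hi ≤ 1")
        plot_ids = sorted(df["plot_id"].unique())
        per_plot = {pid: float(rng.uniform(lo, hi)) for pid in plot_ids}
        p = df["plot_id"].map(per_plot).to_numpy()
    else:
        if not 0 <= recapture_prob <= 1:
            raise ValueError("recapture probability must be in [0, 1]")
        p = float(recapture_prob)
    key = ["run", "individual_id"] if tracks.has_runs else ["individual_id"]
    release = df.groupby(key, sort=False)["day"].transform("min")
    keep = (rng.random(len(df)) < p) | (df["day"] == release)
    return TrackDataset(records=df.loc[keep].reset_index(drop=True))


def estimate_recapture(tracks: TrackDataset, horizon: int) -> dict[str, float]:
    """Per-plot daily recapture probability estimated from observed tracks.

    Releases are detected by design, so the estimate is the fraction of the
    ``n_individuals × horizon`` post-release record-days actually observed.
    Used to thin model simulations with the same observation process as the
    data before pattern comparison.
    """
    df = tracks.records
    key = ["run", "individual_id"] if tracks.has_runs else ["individual_id"]
    release = df.groupby(key, sort=False)["day"].transform("min")
    post = df[df["day"] > release]
    out = {}
    for pid in df["plot_id"].unique():
        n_ind = df.loc[df["plot_id"] == pid].drop_duplicates(subset=key).shape[0]
        n_obs = int((post["plot_id"] == pid).sum())
        out[pid] = min(1.0, n_obs / (n_ind * horizon)) if n_ind else float("nan")
    return out


def stationary_distribution(tm: TransitionModel) -> np.ndarray:
    """Stationary distribution of the explicit transition matrix.

    Solves the left-eigenvector problem on the materialized matrix;
    intended for small plots (the matrix is dense n×n).
    """
    P = tm.full_matrix()
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()
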