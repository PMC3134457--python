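"""Pattern-oriented modelling (POM) validation.

A fitted movement model is validated by simulating the released cohort
forward and comparing two population-level patterns against observation,
per plot:

* the proportion of individuals that remain in their release cell
  throughout the study period (χ² test on stay/leave counts, df = 1,
  against the across-run simulated mean proportion);
* the distribution of one-day dispersal distances (two-sample
  Kolmogorov–Smirnov test of observed step lengths against step lengths
  pooled across simulation runs).

These two patterns discriminate between habitat-independent and
habitat-dependent kernels; direction-of-movement and mean-squared
displacement are deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inference import TrackDataset, extract_steps
from .kernel import ParameterSet
from .lattice import PlotRaster


@dataclass
class PlotPattern:
    """Observed-vs-simulated patterns and test results for one plot."""

    plot_id: str
    n_individuals: int
    observed_stay: float
    simulated_stay_mean: float
    simulated_stay_interval: tuple[float, float]  # 2.5%–97.5% across runs
    stay_chi2: float | None
    stay_df: int
    stay_p: float | None
    observed_distances: np.ndarray
    simulated_distances: np.ndarray
    ks_statistic: float | None
    ks_p: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class PomReport:
    """Per-plot POM comparison of observed and simulated patterns."""

    plots: dict[str, PlotPattern]
    n_runs: int
    horizon: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for p in self.plots.values():
            rows.append({
                "plot_id": p.plot_id, "n_individuals": p.n_individuals,
                "observed_stay": p.observed_stay,
                "simulated_stay_mean": p.simulated_stay_mean,
                "stay_lo": p.simulated_stay_interval[0],
                "stay_hi": p.simulated_stay_interval[1],
                "stay_chi2": p.stay_chi2, "stay_df": p.stay_df,
                "stay_p": p.stay_p,
                "n_obs_dist": len(p.observed_distances),
                "n_sim_dist": len(p.simulated_distances),
                "ks_statistic": p.ks_statistic, "ks_p": p.ks_p,
                "flags": ";".join(p.flags)})
        return pd.DataFrame(rows)


def stay_proportion(tracks: TrackDataset, horizon: int) -> dict[str, float]:
    """Per-plot fraction of individuals never observed off their release
    cell within ``horizon`` days of release.

    A plot with zero individuals maps to ``nan`` (flagged, not an error).
    Non-increasing in ``horizon``: a longer window can only reveal more
    movement.
    """
    per_ind, plot_of = _stayed_per_individual(tracks, horizon)
    means = per_ind.groupby(plot_of, observed=True).mean()
    return {pid: float(means.get(pid, float("nan")))
            for pid in tracks.records["plot_id"].unique()}


def _stayed_per_individual(tracks: TrackDataset, horizon: int):
    """Per-individual stayed flag (all in-window positions = release cell)
    and the plot of each individual, indexed identically."""
    key = ["run", "individual_id"] if tracks.has_runs else ["individual_id"]
    df = tracks.records.sort_values(key + ["day"], kind="stable")
    release_day = df.groupby(key, sort=False)["day"].transform("first")
    sub = df[df["day"] - release_day <= horizon]
    gs = sub.groupby(key, sort=False)
    same = ((sub["row"] == gs["row"].transform("first"))
            & (sub["col"] == gs["col"].transform("first")))
    per_ind = same.groupby([sub[k] for k in key], sort=False).all()
    plot_of = gs["plot_id"].first()
    return per_ind, plot_of


def stay_counts(tracks: TrackDataset, horizon: int) -> dict[str, tuple[int, int]]:
    """Per-plot (n_stayed, n_total) individual counts within the horizon."""
    per_ind, plot_of = _stayed_per_individual(tracks, horizon)
    out = {}
    for pid in tracks.records["plot_id"].unique():
        sel = plot_of == pid
        out[pid] = (int(per_ind[sel].sum()), int(sel.sum()))
    return out


def displacement_distances(tracks: TrackDataset,
                           plots: dict[str, PlotRaster],
                           max_week: int | None = None,
                           include_zero: bool = True,
                           mode: str = "step") -> dict[str, np.ndarray]:
    """Per-plot samples of dispersal distances (metres).

    ``mode="step"`` (default): Euclidean length of every one-day step,
    pooled over individuals and days, using the same step-extraction rule
    as the likelihood.  ``mode="net"``: net displacement from the release
    cell to the last observation in the window (an alternative reading of
    "dispersal distance").  Zero-length records are included by default.
    """
    if mode not in ("step", "net"):
        raise ValueError(f"unknown distance mode {mode!r}")
    out: dict[str, np.ndarray] = {pid: np.array([]) for pid in plots}
    if mode == "step":
        window = 10**9 if max_week is None else max_week
        steps = extract_steps(tracks, max_week=window)
        for pid, grp in steps.groupby("plot_id", sort=False):
            d = np.hypot(grp["to_row"] - grp["from_row"],
                         grp["to_col"] - grp["from_col"]).to_numpy(float)
            d *= plots[pid].cell_size
            out[pid] = d if include_zero else d[d > 0]
        return out
    df = tracks.records
    key = ["run", "individual_id"] if tracks.has_runs else ["individual_id"]
    g = df.groupby(key, sort=False)
    release_day = g["day"].transform("min")
    window = df["day"] - release_day <= (10**9 if max_week is None else max_week)
    sub = df[window]
    gsub = sub.groupby(key, sort=False)
    first = sub.loc[gsub["day"].idxmin()]
    last = sub.loc[gsub["day"].idxmax()]
    d = np.hypot(last["row"].to_numpy() - first["row"].to_numpy(),
                 last["col"].to_numpy() - first["col"].to_numpy()).astype(float)
    dd = pd.DataFrame({"plot_id": first["plot_id"].to_numpy(), "d": d})
    for pid, grp in dd.groupby("plot_id", sort=False):
        v = grp["d"].to_numpy() * plots[pid].cell_size
        out[pid] = v if include_zero else v[v > 0]
    return out


def proportion_test(n_stayed: int, n_total: int,
                    simulated_mean: float) -> tuple[float | None, int,
                                                    float | None]:
    """One-sample χ² comparing observed stay/leave counts to expectation
    under the simulated mean proportion (df = 1, no continuity correction).

    Returns ``(chi2, 1, p)``; ``(None, 1, None)`` flags a degenerate
    expectation (simulated mean 0 or 1, giving an expected count of zero).
    """
    if n_total <= 0:
        raise ValueError("observed total must be positive")
    expected = np.array([n_total * simulated_mean,
                         n_total * (1.0 - simulated_mean)])
    if np.any(expected <= 0):
        return None, 1, None
    observed = np.array([n_stayed, n_total - n_stayed], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


def distance_distribution_test(observed: np.ndarray,
                               simulated: np.ndarray):
    """Two-sample Kolmogorov–Smirnov test of observed vs pooled simulated
    dispersal distances.

    Returns ``(statistic, p, (obs_ecdf, sim_ecdf))`` where each ECDF is a
    ``(sorted values, cumulative fraction)`` pair for plotting.
    ``(None, None, ...)`` flags an empty sample.
    """
    observed = np.asarray(observed, float)
    simulated = np.asarray(simulated, float)

    def ecdf(x):
        if len(x) == 0:
            return np.array([]), np.array([])
        xs = np.sort(x)
        return xs, np.arange(1, len(xs) + 1) / len(xs)

    curves = (ecdf(observed), ecdf(simulated))
    if len(observed) == 0 or len(simulated) == 0:
        return None, None, curves
    res = stats.ks_2samp(observed, simulated, method="asymp")
    return float(res.statistic), float(res.pvalue), curves


def pom_report(observed: TrackDataset, simulated: TrackDataset,
               plots: dict[str, PlotRaster], horizon: int = 10,
               max_week: int | None = None,
               include_zero: bool = True) -> PomReport:
    """Full POM comparison: per-plot stay proportions (with across-run mean
    and 95% quantile interval) and distance distributions, with tests.

    ``simulated`` must carry a ``run`` column; the simulated stay summary
    is across runs, and the simulated distance sample pools all runs.
    """
    if not simulated.has_runs:
        raise ValueError("simulated tracks must have a 'run' column")
    runs = sorted(simulated.records["run"].unique())
    obs_counts = stay_counts(observed, horizon)
    obs_dist = displacement_distances(observed, plots, max_week=max_week,
                                      include_zero=include_zero)
    sim_dist = displacement_distances(simulated, plots, max_week=max_week,
                                      include_zero=include_zero)
    per_run_stay: dict[str, list[float]] = {pid: [] for pid in plots}
    for run in runs:
        sub = TrackDataset(records=simulated.records[
            simulated.records["run"] == run].drop(columns=["run"]))
        for pid, prop in stay_proportion(sub, horizon).items():
            per_run_stay.setdefault(pid, []).append(prop)
    patterns = {}
    for pid in plots:
        flags = []
        n_stay, n_tot = obs_counts.get(pid, (0, 0))
        stays = np.array(per_run_stay.get(pid, []), dtype=float)
        if n_tot == 0 or stays.size == 0 or np.all(np.isnan(stays)):
            flags.append("no-individuals")
            patterns[pid] = PlotPattern(
                plot_id=pid, n_individuals=n_tot,
                observed_stay=float("nan"), simulated_stay_mean=float("nan"),
                simulated_stay_interval=(float("nan"), float("nan")),
                stay_chi2=None, stay_df=1, stay_p=None,
                observed_distances=obs_dist.get(pid, np.array([])),
                simulated_distances=sim_dist.get(pid, np.array([])),
                ks_statistic=None, ks_p=None, flags=flags)
            continue
        sim_mean = float(np.nanmean(stays))
        lo, hi = np.nanquantile(stays, [0.025, 0.975])
        chi2, df_, p = proportion_test(n_stay, n_tot, sim_mean) \
            if 0 < sim_mean < 1 else (None, 1, None)
        if chi2 is None:
            flags.append("degenerate-stay-expectation")
        ks, ksp, _ = distance_distribution_test(
            obs_dist.get(pid, np.array([])), sim_dist.get(pid, np.array([])))
        if ks is None:
            flags.append("empty-distance-sample")
        patterns[pid] = PlotPattern(
            plot_id=pid, n_individuals=n_tot,
            observed_stay=n_stay / n_tot, simulated_stay_mean=sim_mean,
            simulated_stay_interval=(float(lo), float(hi)),
            stay_chi2=chi2, stay_df=1, stay_p=p,
            observed_distances=obs_dist.get(pid, np.array([])),
            simulated_distances=sim_dist.get(pid, np.array([])),
            ks_statistic=ks, ks_p=ksp, flags=flags)
    return PomReport(plots=patterns, n_runs=len(runs), horizon=horizon)


# ---------------------------------------------------------------------------
# figures


def plot_kernel_curves(params: ParameterSet, betas_null: float | None = None,
                       d_max: float = 4.0, ax=None):
    """Kernel survival curves exp(−β_h d) per habitat (plus an optional
    habitat-independent curve in grey)."""
    import matplotlib.pyplot as plt

    from .kernel import decumulative_kernel
    from .lattice import HABITAT_NAMES

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    d = np.linspace(0, d_max, 200)
    for h, b in params.beta.items():
        ax.plot(d, decumulative_kernel(b, d), color="black", lw=1,
                label=f"{HABITAT_NAMES[h]} (β={b:.2f})")
    if betas_null is not None:
        ax.plot(d, decumulative_kernel(betas_null, d), color="grey", lw=2,
                label=f"habitat-independent (β={betas_null:.2f})")
    ax.set_xlabel("displacement d (m)")
    ax.set_ylabel("exp(−β·d)")
    ax.legend(fontsize=7)
    return ax


def plot_stay_scatter(report: PomReport, ax=None, **kwargs):
    """Observed vs simulated stay proportion per plot with 95% quantile
    bars and the 1:1 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for p in report.plots.values():
        lo, hi = p.simulated_stay_interval
        ax.errorbar(p.observed_stay, p.simulated_stay_mean,
                    yerr=[[p.simulated_stay_mean - lo],
                          [hi - p.simulated_stay_mean]],
                    fmt=kwargs.get("fmt", "ko"), capsize=3)
        mark = "*" if (p.stay_p is not None and p.stay_p < 0.01) else ""
        ax.annotate(f"{p.plot_id}{mark}",
                    (p.observed_stay, p.simulated_stay_mean),
                    textcoords="offset points", xytext=(4, 4), fontsize=7)
    ax.plot([0, 1], [0, 1], "k:")
    ax.set_xlabel("observed stay proportion")
    ax.set_ylabel("simulated stay proportion")
    return ax


def plot_distance_ecdfs(report: PomReport, axes=None):
    """Cumulative-distribution overlays of observed (bold) vs simulated
    (dashed) dispersal distances, one panel per plot."""
    import matplotlib.pyplot as plt

    ids = list(report.plots)
    if axes is None:
        _, axes = plt.subplots(1, len(ids), figsize=(3 * len(ids), 3),
                               squeeze=False)
        axes = axes[0]
    for ax, pid in zip(axes, ids):
        p = report.plots[pid]
        _, _, ((ox, oy), (sx, sy)) = distance_distribution_test(
            p.observed_distances, p.simulated_distances)
        if len(ox):
            ax.step(ox, oy, where="post", color="black", lw=2,
                    label="observed")
        if len(sx):
            ax.step(sx, sy, where="post", color="black", lw=1, ls="--",
                    label="simulated")
        label = "n/a" if p.ks_p is None else f"{p.ks_p:.2g}"
        ax.set_title(f"{pid} (KS p={label})", fontsize=8)
        ax.set_xlabel("distance (m)")
    axes[0].set_ylabel("cumulative fraction")
    axes[0].legend(fontsize=7)
    return axes
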