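"""Likelihood inference for the habitat-dependent kernel model.

The data are daily radio-tracking relocations.  Only relocation pairs
separated by exactly one day, and falling within the first week after
release, enter the likelihood; each such pair contributes one factor
``p_{from,to}`` from the daily transition kernel.  Parameters are shared
across plots, so the full log-likelihood is the sum over plots of the sums
of log transition probabilities of their one-day steps.

Maximisation uses Nelder–Mead on unconstrained coordinates: each β block is
fitted on the log scale, and the α simplex blocks through an additive
log-ratio transform (last block as reference), which enforces positivity
and the Σα = 1 constraint exactly.  Nested model families (habitat
groupings of α and β) are compared with likelihood-ratio tests against a
χ² reference with df equal to the difference in free-parameter counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kernel import ModelSpec, ParameterSet
from .lattice import HABITATS, N_HABITATS, PlotRaster

TRACK_COLUMNS = ["individual_id", "plot_id", "day", "row", "col"]


class DataError(ValueError):
    """Malformed relocation data (duplicates, out-of-bounds cells)."""


@dataclass
class TrackDataset:
    """Daily relocation records: one row per individual per observed day.

    ``records`` has columns ``individual_id, plot_id, day, row, col`` and
    optionally ``run`` (for simulated replicates).  The release day of an
    individual defaults to its first observed day.
    """

    records: pd.DataFrame
    release_day: dict | None = None

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.records.columns)
        if missing:
            raise DataError(f"track table missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        key = [c for c in ("run", "individual_id", "day")
               if c in self.records.columns]
        dup = self.records.duplicated(subset=key)
        if dup.any():
            bad = self.records.loc[dup, key].head(5).to_dict("records")
            raise DataError(
                f"duplicate relocations for the same individual and day "
                f"(one fix per day expected); first offenders: {bad}")

    @property
    def has_runs(self) -> bool:
        return "run" in self.records.columns

    def releases(self) -> pd.DataFrame:
        """First observed record per individual (per run if present)."""
        key = ["run", "individual_id"] if self.has_runs else ["individual_id"]
        idx = self.records.groupby(key, sort=False)["day"].idxmin()
        return self.records.loc[idx].reset_index(drop=True)

    def validate_against(self, plots: dict[str, PlotRaster]) -> None:
        for plot_id, grp in self.records.groupby("plot_id", sort=False):
            if plot_id not in plots:
                raise DataError(f"unknown plot id {plot_id!r} in tracks")
            plot = plots[plot_id]
            if ((grp["row"] < 0).any() or (grp["row"] >= plot.n_rows).any()
                    or (grp["col"] < 0).any()
                    or (grp["col"] >= plot.n_cols).any()):
                raise DataError(
                    f"out-of-bounds cells in tracks for plot {plot_id!r}")


def extract_steps(tracks: TrackDataset, max_week: int = 7) -> pd.DataFrame:
    """One-day movement steps from a relocation table.

    Keeps exactly the pairs of relocations of one individual on consecutive
    days (t, t+1) with the arrival day at most ``max_week`` days after
    release; gaps longer than one day contribute no step.  Returns a frame
    with columns ``individual_id, plot_id, day, from_row, from_col, to_row,
    to_col`` (plus ``run`` when present), where ``day`` is the departure day.
    """
    df = tracks.records
    key = ["run", "individual_id"] if tracks.has_runs else ["individual_id"]
    df = df.sort_values(key + ["day"], kind="stable")
    grp = df.groupby(key, sort=False)
    release = grp["day"].transform("min")
    nxt_day = grp["day"].shift(-1)
    nxt_row = grp["row"].shift(-1)
    nxt_col = grp["col"].shift(-1)
    keep = (nxt_day == df["day"] + 1) & (nxt_day - release <= max_week)
    out = pd.DataFrame({
        "individual_id": df.loc[keep, "individual_id"],
        "plot_id": df.loc[keep, "plot_id"],
        "day": df.loc[keep, "day"],
        "from_row": df.loc[keep, "row"],
        "from_col": df.loc[keep, "col"],
        "to_row": nxt_row[keep].astype(int),
        "to_col": nxt_col[keep].astype(int),
    })
    if tracks.has_runs:
        out.insert(0, "run", df.loc[keep, "run"])
    return out.reset_index(drop=True)


class _PlotSteps:
    """Per-plot sufficient statistics for fast likelihood evaluation.

    For the kernel model the log-likelihood of a plot's steps decomposes as

        Σ log α_{h_to}  −  Σ β_{h_from} d_step  −  Σ_i m_i log Z_i(α, β)

    where the first two terms depend on the data only through arrival-habitat
    counts and the total step distance per departure habitat, and the
    normalizers ``Z_i`` are needed only at the distinct departure cells
    (multiplicity ``m_i``).
    """

    def __init__(self, plot: PlotRaster, from_lin: np.ndarray,
                 to_lin: np.ndarray):
        self.plot = plot
        self.n_steps = len(from_lin)
        hab = plot.habitat_flat
        D = plot.distance_matrix()
        d_step = D[from_lin, to_lin]
        h_from = hab[from_lin]
        self.h_to = hab[to_lin]
        self.to_hab_counts = np.bincount(self.h_to, minlength=N_HABITATS)
        self.dist_by_from_hab = np.bincount(
            h_from, weights=d_step, minlength=N_HABITATS)
        uniq, counts = np.unique(from_lin, return_counts=True)
        self.alpha_cells_hab = hab  # habitat index of every cell
        # group distinct departure cells by habitat: they share β
        self.groups = []
        h_uniq = hab[uniq]
        for h in range(N_HABITATS):
            sel = h_uniq == h
            if sel.any():
                idx = uniq[sel]
                self.groups.append((h, D[idx, :], counts[sel]))

    def log_likelihood(self, alpha4: np.ndarray, beta4: np.ndarray):
        """Returns (logL, offending-habitat list) — offenders make it −inf."""
        offenders = [HABITATS[h] for h in range(N_HABITATS)
                     if self.to_hab_counts[h] > 0 and alpha4[h] <= 0]
        if offenders:
            return -np.inf, offenders
        ll = float(self.to_hab_counts @ np.log(
            np.where(alpha4 > 0, alpha4, 1.0)))
        ll -= float(beta4 @ self.dist_by_from_hab)
        a_cells = alpha4[self.alpha_cells_hab]
        for h, D_h, m_h in self.groups:
            z = np.exp(-beta4[h] * D_h) @ a_cells
            ll -= float(m_h @ np.log(z))
        return ll, []


def pack_steps(steps: pd.DataFrame,
               plots: dict[str, PlotRaster]) -> list[_PlotSteps]:
    """Precompute per-plot sufficient statistics from a step table."""
    packed = []
    for plot_id, grp in steps.groupby("plot_id", sort=False):
        plot = plots[plot_id]
        for col, n in (("from_row", plot.n_rows), ("from_col", plot.n_cols),
                       ("to_row", plot.n_rows), ("to_col", plot.n_cols)):
            if (grp[col] < 0).any() or (grp[col] >= n).any():
                raise DataError(
                    f"step cells out of bounds for plot {plot_id!r}")
        from_lin = grp["from_row"].to_numpy() * plot.n_cols \
            + grp["from_col"].to_numpy()
        to_lin = grp["to_row"].to_numpy() * plot.n_cols \
            + grp["to_col"].to_numpy()
        packed.append(_PlotSteps(plot, from_lin, to_lin))
    return packed


def log_likelihood(steps: pd.DataFrame, plots: dict[str, PlotRaster],
                   model: ModelSpec, params: ParameterSet,
                   _packed: list[_PlotSteps] | None = None) -> float:
    """Total log-likelihood of one-day steps under shared parameters.

    Sums log transition probabilities over all steps of all plots; always
    ≤ 0.  A step whose arrival habitat has α = 0 has probability zero: the
    result is −inf and a diagnostic warning lists the offending habitats.
    """
    params.validate_for(model)
    packed = pack_steps(steps, plots) if _packed is None else _packed
    alpha4, beta4 = params.alpha_array, params.beta_array
    total, all_off = 0.0, []
    for ps in packed:
        ll, off = ps.log_likelihood(alpha4, beta4)
        total += ll
        all_off.extend(off)
    if all_off:
        warnings.warn(
            f"steps arriving in zero-α habitats {sorted(set(all_off))} have "
            f"probability 0; log-likelihood is -inf", stacklevel=2)
    return total


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_mle`.

    ``restarts`` extra Nelder–Mead starts are jittered around the heuristic
    initial point; β is searched on the log scale within ``beta_bounds``
    (per metre) to catch degenerate data, and the α blocks through an
    additive log-ratio transform.
    """

    restarts: int = 10
    fatol: float = 1e-8
    xatol: float = 1e-6
    maxiter: int | None = None
    seed: int = 0
    beta_bounds: tuple[float, float] = (1e-4, 50.0)
    jitter: float = 0.5


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: ModelSpec
    minus_two_log_L: float
    estimates: ParameterSet | None = None
    converged: bool = True
    at_beta_boundary: bool = False
    n_steps: int = 0
    n_evaluations: int = 0
    message: str = ""

    @property
    def df(self) -> int:
        return self.model.free_parameter_count


def _theta_to_params(theta: np.ndarray, model: ModelSpec,
                     beta_bounds) -> ParameterSet | None:
    """Unconstrained coordinates → ParameterSet (None if β out of bounds)."""
    n_beta = len(model.beta_grouping)
    beta_vals = np.exp(theta[:n_beta])
    if np.any(beta_vals < beta_bounds[0]) or np.any(beta_vals > beta_bounds[1]):
        return None
    blocks = model.alpha_grouping
    sizes = np.array([len(b) for b in blocks], dtype=float)
    z = np.concatenate([theta[n_beta:], [0.0]])  # last block is reference
    ez = np.exp(z - z.max())
    base = ez / float(sizes @ ez)  # per-habitat value within each block
    alpha = {}
    for b, v in zip(blocks, base):
        for h in b:
            alpha[h] = float(v)
    beta = {}
    for b, v in zip(model.beta_grouping, beta_vals):
        for h in b:
            beta[h] = float(v)
    return ParameterSet(alpha=alpha, beta=beta)


def _initial_theta(packed: list[_PlotSteps], model: ModelSpec) -> np.ndarray:
    """Heuristic start: β = 1.5 per block; α from arrival-habitat counts."""
    counts = np.zeros(N_HABITATS)
    for ps in packed:
        counts += ps.to_hab_counts
    freq = (counts + 1.0) / (counts.sum() + N_HABITATS)
    blocks = model.alpha_grouping
    base = np.array([np.mean([freq[HABITATS.index(h)] for h in b])
                     for b in blocks])
    base /= float(np.array([len(b) for b in blocks]) @ base)
    z = np.log(base / base[-1])[:-1]
    return np.concatenate([np.full(len(model.beta_grouping), np.log(1.5)), z])


def fit_mle(steps: pd.DataFrame, plots: dict[str, PlotRaster],
            model: ModelSpec,
            options: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of one model spec to one-day steps.

    Nelder–Mead on unconstrained coordinates (log β per block, additive
    log-ratio α), with jittered restarts; the best restart wins.
    Non-convergence after all restarts yields a flagged result, not an
    exception.
    """
    if len(steps) == 0:
        raise DataError("cannot fit with zero steps")
    opt = options or FitOptions()
    packed = pack_steps(steps, plots)
    n_steps = sum(ps.n_steps for ps in packed)
    n_evals = 0

    def negloglik(theta: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        p = _theta_to_params(theta, model, opt.beta_bounds)
        if p is None:
            return 1e12
        a4, b4 = p.alpha_array, p.beta_array
        total = 0.0
        for ps in packed:
            ll, off = ps.log_likelihood(a4, b4)
            if off:
                return 1e12
            total += ll
        return -total

    theta0 = _initial_theta(packed, model)
    rng = np.random.default_rng(opt.seed)
    starts = [theta0] + [theta0 + rng.normal(0, opt.jitter, size=theta0.size)
                         for _ in range(opt.restarts)]
    best = None
    any_success = False
    for start in starts:
        res = optimize.minimize(
            negloglik, start, method="Nelder-Mead",
            options={"fatol": opt.fatol, "xatol": opt.xatol,
                     "maxiter": opt.maxiter, "adaptive": theta0.size > 4})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    lo, hi = opt.beta_bounds
    # degenerate data leave the profile flat towards a β bound and stall the
    # simplex early; if pinning a block at the bound is no worse, the MLE is
    # on the boundary — report it there and flag it
    best_x, best_fun = np.array(best.x), float(best.fun)
    at_boundary = False
    n_beta = len(model.beta_grouping)
    for b in range(n_beta):
        for bound in (lo, hi):
            trial = best_x.copy()
            trial[b] = np.log(bound)
            f = negloglik(trial)
            if f <= best_fun + 1e-9:
                best_x, best_fun, at_boundary = trial, min(f, best_fun), True
    params = _theta_to_params(best_x, model, opt.beta_bounds)
    if params is None:  # should not happen: bounded evaluations return 1e12
        params = _theta_to_params(np.clip(best_x, -9, 3.9), model,
                                  (0.0, np.inf))
    bvals = np.array([params.beta[b[0]] for b in model.beta_grouping])
    at_boundary = at_boundary or bool(
        np.any(bvals <= lo * 1.01) or np.any(bvals >= hi * 0.99))
    return FitResult(
        model=model,
        minus_two_log_L=2.0 * best_fun,
        estimates=params,
        converged=any_success and best_fun < 1e11,
        at_beta_boundary=at_boundary,
        n_steps=n_steps,
        n_evaluations=n_evals,
        message=str(best.message),
    )


class LRTResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_null: FitResult,
                          fit_general: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested null against a general model.

    The statistic is the difference of the −2·logL values; its null
    reference is χ² with df equal to the difference in free parameters.
    A slightly negative statistic (optimizer noise) is clamped to 0 with
    a warning.
    """
    if not fit_null.model.is_nested_in(fit_general.model):
        raise ValueError(
            f"model {fit_null.model.name!r} is not nested in "
            f"{fit_general.model.name!r}")
    df = fit_general.df - fit_null.df
    if df <= 0:
        raise ValueError("general model must have more free parameters")
    statistic = fit_null.minus_two_log_L - fit_general.minus_two_log_L
    if statistic < 0:
        warnings.warn(
            f"negative LRT statistic {statistic:.3g} clamped to 0 "
            f"(optimizer tolerance)", stacklevel=2)
        statistic = 0.0
    p_value = float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic=float(statistic), df=int(df), p_value=p_value)


def format_p(p: float | None, threshold: float = 0.001) -> str:
    """Human-readable p-value: exact above the threshold, '<0.001' below,
    'n/a' for a flagged (absent) test."""
    if p is None:
        return "n/a"
    return f"<{threshold:g}" if p < threshold else f"{p:.2g}"


def model_comparison_table(fits: Iterable[FitResult]) -> pd.DataFrame:
    """Summary table across fitted models.

    One row per model: β per block, pooled α per block (block sums), the
    per-habitat base α alongside, free-parameter count and −2·logL.
    """
    rows = []
    for fit in fits:
        row: dict = {"model": fit.model.name, "df": fit.df,
                     "minus_two_log_L": fit.minus_two_log_L,
                     "n_steps": fit.n_steps, "converged": fit.converged}
        if fit.estimates is not None:
            for label, v in fit.estimates.block_beta(fit.model).items():
                row[f"beta_{label}"] = v
            for label, v in fit.estimates.pooled_alpha(fit.model).items():
                row[f"alpha_{label}"] = v
                nb = label.count("+") + 1
                row[f"alpha_per_habitat_{label}"] = v / nb
        rows.append(row)
    return pd.DataFrame(rows)
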