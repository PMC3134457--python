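"""Step extraction, likelihood, MLE and likelihood-ratio tests."""

import math

import numpy as np
import pandas as pd
import pytest

from weevilwalk.inference import (DataError, FitOptions, FitResult,
                                  TrackDataset, extract_steps, fit_mle,
                                  likelihood_ratio_test, log_likelihood,
                                  model_comparison_table)
from weevilwalk.kernel import CANONICAL_MODELS, ParameterSet
from weevilwalk.lattice import HABITATS, raster_from_codes

from .conftest import (brute_force_log_likelihood, random_params,
                       random_raster, random_steps)


def tracks_from_days(days, cells=None, plot_id="p"):
    cells = cells or [(0, 0)] * len(days)
    return TrackDataset(records=pd.DataFrame({
        "individual_id": "a", "plot_id": plot_id, "day": days,
        "row": [c[0] for c in cells], "col": [c[1] for c in cells]}))


class TestExtractSteps:
    def test_consecutive_days_make_steps(self):
        steps = extract_steps(tracks_from_days([0, 1, 2]))
        assert len(steps) == 2

    def test_gap_drops_step(self):
        steps = extract_steps(tracks_from_days([0, 2, 3]))
        assert len(steps) == 1
        assert steps.iloc[0]["day"] == 2

    def test_first_week_filter(self):
        steps = extract_steps(tracks_from_days(list(range(12))), max_week=7)
        # arrival day at most 7 days after release → pairs (0,1)..(6,7)
        assert len(steps) == 7

    def test_duplicate_relocations_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            tracks_from_days([0, 1, 1])

    def test_brute_force_recount(self):
        """Step count on a thinned cohort equals an independent pair scan."""
        rng = np.random.default_rng(17)
        rows = []
        for ind in range(60):
            release = 0
            for day in range(10):
                if day == release or rng.random() < 0.65:
                    rows.append({"individual_id": f"i{ind}", "plot_id": "p",
                                 "day": day, "row": 0, "col": 0})
        tracks = TrackDataset(records=pd.DataFrame(rows))
        steps = extract_steps(tracks, max_week=7)
        expected = 0
        for _, grp in tracks.records.groupby("individual_id"):
            days = sorted(grp["day"])
            release = days[0]
            for t in days:
                if t + 1 in days and (t + 1) - release <= 7:
                    expected += 1
        assert len(steps) == expected


class TestLogLikelihood:
    def test_zero_steps_zero_loglik(self, uniform_params):
        r = raster_from_codes("p", [["P", "P"]])
        empty = random_steps(np.random.default_rng(0), r, 0)
        assert log_likelihood(empty, {"p": r}, CANONICAL_MODELS["MG1"],
                              uniform_params) == 0.0

    def test_single_uniform_step(self):
        r = raster_from_codes("p", [["P", "P"]])
        params = ParameterSet(alpha={h: 0.25 for h in HABITATS},
                              beta={h: 0.0 for h in HABITATS})
        steps = pd.DataFrame({"individual_id": ["a"], "plot_id": ["p"],
                              "day": [0], "from_row": [0], "from_col": [0],
                              "to_row": [0], "to_col": [1]})
        ll = log_likelihood(steps, {"p": r}, CANONICAL_MODELS["MG1"], params)
        assert ll == pytest.approx(math.log(0.5))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        r = random_raster(rng, 6, 6, plot_id="p")
        params = random_params(rng)
        steps = random_steps(rng, r, 50)
        fast = log_likelihood(steps, {"p": r}, CANONICAL_MODELS["MG4"],
                              params)
        slow = brute_force_log_likelihood(steps, {"p": r}, params)
        assert fast == pytest.approx(slow, abs=1e-9)
        assert fast <= 0

    def test_zero_alpha_target_is_minus_inf(self):
        r = raster_from_codes("p", [["P", "B"]])
        params = ParameterSet(alpha={"P": 1.0, "C": 0.0, "B": 0.0, "D": 0.0},
                              beta={h: 1.0 for h in HABITATS})
        steps = pd.DataFrame({"individual_id": ["a"], "plot_id": ["p"],
                              "day": [0], "from_row": [0], "from_col": [0],
                              "to_row": [0], "to_col": [1]})
        with pytest.warns(UserWarning, match="zero-α"):
            ll = log_likelihood(steps, {"p": r}, CANONICAL_MODELS["MG4"],
                                params)
        assert ll == -math.inf


class TestFitMLE:
    def test_grid_search_oracle_single_beta(self):
        """The fitted single-block β agrees with a fine grid search over the
        1-D profile on a uniform-habitat plot."""
        rng = np.random.default_rng(7)
        plot = raster_from_codes("p", [["P"] * 8] * 8)
        truth = ParameterSet(alpha={h: 0.25 for h in HABITATS},
                             beta={h: 1.3 for h in HABITATS})
        from weevilwalk.simulate import SimulationConfig, simulate_walks
        releases = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(40)], "plot_id": "p",
            "row": rng.integers(0, 8, 40), "col": rng.integers(0, 8, 40)})
        tracks = simulate_walks({"p": plot}, truth, SimulationConfig(
            releases=releases, n_runs=1, horizon=6, seed=3))
        steps = extract_steps(tracks, max_week=7)
        model = CANONICAL_MODELS["MG1"]
        fit = fit_mle(steps, {"p": plot}, model, FitOptions(restarts=2))
        grid = np.arange(0.01, 10.0, 0.001)
        lls = [log_likelihood(
            steps, {"p": plot}, model,
            ParameterSet(alpha={h: 0.25 for h in HABITATS},
                         beta={h: float(b) for h in HABITATS}))
            for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.estimates.beta["P"] == pytest.approx(best, abs=2e-3)
        assert fit.converged

    def test_immobile_data_hits_beta_bound(self):
        """If nobody ever moves, β̂ runs to the upper bound and is flagged."""
        plot = raster_from_codes("p", [["P"] * 3] * 3)
        steps = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(20)], "plot_id": "p",
            "day": 0, "from_row": 1, "from_col": 1, "to_row": 1,
            "to_col": 1})
        fit = fit_mle(steps, {"p": plot}, CANONICAL_MODELS["MG1"],
                      FitOptions(restarts=2))
        assert fit.at_beta_boundary
        assert fit.estimates.beta["P"] >= 45.0

    def test_zero_steps_rejected(self):
        plot = raster_from_codes("p", [["P"]])
        with pytest.raises(DataError):
            fit_mle(pd.DataFrame(columns=["plot_id"]), {"p": plot},
                    CANONICAL_MODELS["MG1"])

    def test_nested_fit_never_beats_general(self):
        """−2logL(M_0) ≥ −2logL(M_G) on the same data, up to tolerance."""
        rng = np.random.default_rng(21)
        plot = random_raster(rng, 8, 8, plot_id="p")
        steps = random_steps(rng, plot, 300)
        opts = FitOptions(restarts=3, seed=1)
        f0 = fit_mle(steps, {"p": plot}, CANONICAL_MODELS["M04"], opts)
        fg = fit_mle(steps, {"p": plot}, CANONICAL_MODELS["MG4"], opts)
        assert f0.minus_two_log_L >= fg.minus_two_log_L - 1e-4


class TestLikelihoodRatioTest:
    def test_printed_headline_pairs(self):
        """The published −2logL table reproduces the published statistics."""
        M = CANONICAL_MODELS
        cases = [
            ("M04", 12991, "MG4", 12394, 597, 3),
            ("M03_PC", 12991, "MG3_PC", 12395, 596, 2),
            ("M03_BD", 12993, "MG3_BD", 12422, 571, 2),
            ("M02", 13014, "MG2", 12445, 569, 1),
        ]
        for n, ln, g, lg, stat, df in cases:
            res = likelihood_ratio_test(FitResult(M[n], ln),
                                        FitResult(M[g], lg))
            assert res.statistic == pytest.approx(stat)
            assert res.df == df
            assert res.p_value < 0.001
        res = likelihood_ratio_test(FitResult(M["MG3_PC"], 12395),
                                    FitResult(M["MG4"], 12394))
        assert (res.statistic, res.df) == (1, 2)
        assert res.p_value == pytest.approx(0.61, abs=5e-3)

    def test_identical_fits(self):
        M = CANONICAL_MODELS
        res = likelihood_ratio_test(FitResult(M["M04"], 1000.0),
                                    FitResult(M["MG4"], 1000.0))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_non_nested_rejected(self):
        M = CANONICAL_MODELS
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(FitResult(M["M03_PC"], 1.0),
                                  FitResult(M["MG3_BD"], 0.5))

    def test_negative_statistic_clamped(self):
        M = CANONICAL_MODELS
        with pytest.warns(UserWarning, match="clamped"):
            res = likelihood_ratio_test(FitResult(M["M04"], 999.99),
                                        FitResult(M["MG4"], 1000.0))
        assert res.statistic == 0.0


class TestComparisonTable:
    def test_single_fit_one_row(self):
        M = CANONICAL_MODELS
        params = ParameterSet(alpha={h: 0.25 for h in HABITATS},
                              beta={h: 1.62 for h in HABITATS})
        table = model_comparison_table(
            [FitResult(M["MG1"], 14769.0, estimates=params)])
        assert len(table) == 1
        assert table.loc[0, "df"] == 1
        assert table.loc[0, "alpha_per_habitat_P+C+B+D"] == pytest.approx(0.25)
        assert table.loc[0, "alpha_P+C+B+D"] == pytest.approx(1.0)

    def test_canonical_df_column(self):
        """df column equals the free-parameter count recomputed from
        partitions, across the full canonical family."""
        fits = [FitResult(m, 0.0) for m in CANONICAL_MODELS.values()]
        table = model_comparison_table(fits)
        recount = [len(m.beta_grouping) + len(m.alpha_grouping) - 1
                   for m in CANONICAL_MODELS.values()]
        assert list(table["df"]) == recount
        assert sorted(table["df"]) == sorted([4, 7, 3, 5, 3, 5, 2, 3, 1])
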