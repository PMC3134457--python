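"""Pattern computation and the POM comparison tests."""

import numpy as np
import pandas as pd
import pytest

from weevilwalk.inference import TrackDataset
from weevilwalk.kernel import ParameterSet
from weevilwalk.lattice import raster_from_codes
from weevilwalk.pom import (displacement_distances,
                            distance_distribution_test, pom_report,
                            proportion_test, stay_counts, stay_proportion)
from weevilwalk.simulate import SimulationConfig, simulate_walks

from .conftest import random_params


def tracks_of(rows):
    return TrackDataset(records=pd.DataFrame(
        rows, columns=["individual_id", "plot_id", "day", "row", "col"]))


class TestStayProportion:
    def test_all_immobile(self):
        t = tracks_of([("a", "p", d, 1, 1) for d in range(5)]
                      + [("b", "p", d, 0, 2) for d in range(5)])
        assert stay_proportion(t, horizon=10) == {"p": 1.0}

    def test_one_of_two_moves(self):
        t = tracks_of([("a", "p", 0, 1, 1), ("a", "p", 1, 1, 1),
                       ("b", "p", 0, 0, 0), ("b", "p", 1, 0, 1)])
        assert stay_proportion(t, horizon=10) == {"p": 0.5}

    def test_horizon_monotonicity(self):
        # individual moves on day 6 only
        t = tracks_of([("a", "p", d, 0, 0) for d in range(6)]
                      + [("a", "p", 6, 0, 1)])
        props = [stay_proportion(t, horizon=h)["p"] for h in range(0, 9)]
        assert all(a >= b for a, b in zip(props, props[1:]))
        assert props[5] == 1.0 and props[6] == 0.0

    def test_recount_oracle_on_simulated_cohort(self):
        plot = raster_from_codes("p", [["P", "C"], ["B", "D"]])
        params = random_params(np.random.default_rng(0))
        rel = pd.DataFrame({"individual_id": [f"i{k}" for k in range(30)],
                            "plot_id": "p", "row": 0, "col": 0})
        sim = simulate_walks({"p": plot}, params, SimulationConfig(
            releases=rel, n_runs=1, horizon=6, seed=5))
        t = TrackDataset(records=sim.records.drop(columns=["run"]))
        n_stay, n_tot = stay_counts(t, horizon=6)["p"]
        # brute-force per-track recount
        expected = sum(
            int((grp[["row", "col"]].nunique() == 1).all())
            for _, grp in t.records.groupby("individual_id"))
        assert (n_stay, n_tot) == (expected, 30)

    def test_empty_plot_flagged_nan(self):
        t = tracks_of([("a", "p", 0, 0, 0)])
        assert np.isnan(stay_proportion(t, horizon=5).get("q", float("nan")))


class TestDisplacementDistances:
    def test_immobile_track_all_zero(self):
        plot = raster_from_codes("p", [["P", "C"]])
        t = tracks_of([("a", "p", d, 0, 0) for d in range(4)])
        d = displacement_distances(t, {"p": plot})
        assert np.all(d["p"] == 0.0)
        assert len(d["p"]) == 3

    def test_three_four_five_triangle(self):
        plot = raster_from_codes("p", [["P"] * 5] * 4)
        t = tracks_of([("a", "p", 0, 0, 0), ("a", "p", 1, 3, 4)])
        d = displacement_distances(t, {"p": plot})
        assert d["p"] == pytest.approx([5.0])

    def test_pooled_count_matches_step_extraction(self):
        from weevilwalk.inference import extract_steps
        plot = raster_from_codes("p", [["P", "C"], ["B", "D"]])
        params = random_params(np.random.default_rng(2))
        rel = pd.DataFrame({"individual_id": [f"i{k}" for k in range(20)],
                            "plot_id": "p", "row": 1, "col": 0})
        sim = simulate_walks({"p": plot}, params, SimulationConfig(
            releases=rel, n_runs=1, horizon=5, seed=6))
        t = TrackDataset(records=sim.records.drop(columns=["run"]))
        d = displacement_distances(t, {"p": plot})
        assert len(d["p"]) == len(extract_steps(t, max_week=10**9))

    def test_exclude_zero_option(self):
        plot = raster_from_codes("p", [["P", "C"]])
        t = tracks_of([("a", "p", 0, 0, 0), ("a", "p", 1, 0, 0),
                       ("a", "p", 2, 0, 1)])
        with_zero = displacement_distances(t, {"p": plot})
        without = displacement_distances(t, {"p": plot}, include_zero=False)
        assert len(with_zero["p"]) == 2 and len(without["p"]) == 1

    def test_net_displacement_mode(self):
        plot = raster_from_codes("p", [["P"] * 5] * 5)
        t = tracks_of([("a", "p", 0, 0, 0), ("a", "p", 1, 2, 2),
                       ("a", "p", 2, 0, 3)])
        d = displacement_distances(t, {"p": plot}, mode="net")
        assert d["p"] == pytest.approx([3.0])


class TestProportionTest:
    def test_exact_match_gives_zero(self):
        chi2, df, p = proportion_test(50, 100, 0.5)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_hand_computed_chi2(self):
        """30/100 staying vs simulated mean 0.5:
        χ² = (30−50)²/50 + (70−50)²/50 = 16."""
        chi2, df, p = proportion_test(30, 100, 0.5)
        assert chi2 == pytest.approx(16.0)
        assert p < 0.001

    def test_degenerate_expectation_flagged(self):
        chi2, df, p = proportion_test(10, 20, 1.0)
        assert chi2 is None and p is None

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(0, 0, 0.5)


class TestDistanceDistributionTest:
    def test_sample_against_itself(self):
        x = np.array([0.0, 1.0, 1.0, 2.5, 4.0])
        stat, p, _ = distance_distribution_test(x, x.copy())
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, p, _ = distance_distribution_test(np.zeros(30), np.ones(30))
        assert stat == 1.0

    def test_empty_sample_flagged(self):
        stat, p, curves = distance_distribution_test(np.array([]),
                                                     np.ones(3))
        assert stat is None and p is None

    def test_invariance_under_monotone_rescaling(self):
        rng = np.random.default_rng(11)
        a, b = rng.exponential(1.0, 80), rng.exponential(1.5, 120)
        s1, _, _ = distance_distribution_test(a, b)
        s2, _, _ = distance_distribution_test(np.sqrt(a), np.sqrt(b))
        assert s1 == pytest.approx(s2)

    def test_null_calibration_over_replicates(self):
        """Two same-sized draws from one simulated distance pool: the KS
        test rejects at 5% in ≲5% of 200 replicates (ties between lattice
        distances make the test conservative, never anti-conservative)."""
        plot = raster_from_codes("p", [["P", "C", "B"], ["B", "P", "D"]])
        params = random_params(np.random.default_rng(1))
        rel = pd.DataFrame({"individual_id": [f"i{k}" for k in range(40)],
                            "plot_id": "p", "row": 0, "col": 0})
        sim = simulate_walks({"p": plot}, params, SimulationConfig(
            releases=rel, n_runs=5, horizon=8, seed=21))
        pool = displacement_distances(sim, {"p": plot})["p"]
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(200):
            a = rng.choice(pool, size=150, replace=True)
            b = rng.choice(pool, size=150, replace=True)
            _, p, _ = distance_distribution_test(a, b)
            rejections += p < 0.05
        assert rejections / 200 <= 0.08


class TestPomReport:
    def make_world(self, seed=0):
        plot = raster_from_codes(
            "p", [["P", "C", "B", "B"], ["B", "P", "D", "B"],
                  ["C", "B", "P", "B"]])
        params = ParameterSet(
            alpha={"P": 0.6, "C": 0.3, "B": 0.07, "D": 0.03},
            beta={"P": 2.0, "C": 2.0, "B": 1.0, "D": 0.7})
        rel = pd.DataFrame({"individual_id": [f"i{k}" for k in range(60)],
                            "plot_id": "p",
                            "row": np.random.default_rng(seed).integers(0, 3, 60),
                            "col": np.random.default_rng(seed + 1).integers(0, 4, 60)})
        return plot, params, rel

    def test_self_comparison_passes(self):
        """Simulated data validated against its own generating model shows
        no significant discrepancy."""
        plot, params, rel = self.make_world()
        obs_sim = simulate_walks({"p": plot}, params, SimulationConfig(
            releases=rel, n_runs=1, horizon=8, seed=3))
        observed = TrackDataset(
            records=obs_sim.records.drop(columns=["run"]))
        sim = simulate_walks({"p": plot}, params, SimulationConfig(
            releases=rel, n_runs=50, horizon=8, seed=4))
        report = pom_report(observed, sim, {"p": plot}, horizon=8)
        pat = report.plots["p"]
        assert pat.stay_p is None or pat.stay_p > 0.01
        assert pat.ks_p is None or pat.ks_p > 0.01
        lo, hi = pat.simulated_stay_interval
        assert 0 <= lo <= pat.simulated_stay_mean <= hi <= 1

    def test_report_requires_runs(self):
        plot, params, rel = self.make_world()
        obs = simulate_walks({"p": plot}, params, SimulationConfig(
            releases=rel, n_runs=1, horizon=3, seed=3))
        observed = TrackDataset(records=obs.records.drop(columns=["run"]))
        with pytest.raises(ValueError, match="run"):
            pom_report(observed, observed, {"p": plot})

    def test_summary_recomputes_from_patterns(self):
        plot, params, rel = self.make_world()
        obs = TrackDataset(records=simulate_walks(
            {"p": plot}, params, SimulationConfig(
                releases=rel, n_runs=1, horizon=5,
                seed=9)).records.drop(columns=["run"]))
        sim = simulate_walks({"p": plot}, params, SimulationConfig(
            releases=rel, n_runs=20, horizon=5, seed=10))
        report = pom_report(obs, sim, {"p": plot}, horizon=5)
        summary = report.summary()
        pat = report.plots["p"]
        assert summary.loc[0, "observed_stay"] == pytest.approx(
            pat.observed_stay)
        assert summary.loc[0, "ks_statistic"] == pytest.approx(
            pat.ks_statistic)
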