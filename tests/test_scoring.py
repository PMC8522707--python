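import numpy as np
import pandas as pd
import pytest

from scsignal import (
    CoverageError,
    PredictionSet,
    basal_correction,
    basal_means,
    bayes_factor,
    bayes_factor_matrix,
    bootstrap_scores,
    compute_condition_stats,
    condition_medians,
    n_statistics,
    normalize_per_statistic,
    prediction_basal_means,
    sc1_diagnostics,
    score_sc1,
    score_sc23,
    score_sc4,
)
from tests.conftest import make_cells


def sc1_prediction_from(truth, targets, transform):
    long = truth.data.melt(
        id_vars=["cell_line", "treatment", "time", "cellID"],
        value_vars=list(targets), var_name="marker", value_name="value")
    long["value"] = transform(long)
    return PredictionSet("SC1", long, truth.panel)


class TestScoreSc1:
    @pytest.fixture
    def truth(self, mini_panel, rng):
        return make_cells(mini_panel,
                          [("CL01", "EGF", 0.0), ("CL01", "iMEK", 7.0),
                           ("CL02", "EGF", 0.0)], n_cells=20, rng=rng)

    def test_perfect_prediction_scores_zero(self, truth, mini_panel):
        pred = sc1_prediction_from(truth, mini_panel.sc1_targets,
                                   lambda d: d["value"])
        rep = score_sc1(pred, truth)
        assert rep.final == 0.0
        assert (rep.per_condition["score"] == 0.0).all()

    def test_constant_offset_scores_delta(self, truth, mini_panel):
        pred = sc1_prediction_from(truth, mini_panel.sc1_targets,
                                   lambda d: d["value"] + 0.7)
        assert score_sc1(pred, truth).final == pytest.approx(0.7, abs=1e-12)

    def test_two_cell_example(self, mini_panel):
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 2,
                           np.random.default_rng(0))
        truth.data.loc[:, "m1"] = [1.0, 3.0]
        pred = sc1_prediction_from(truth, ["m1"], lambda d: [2.0, 2.0])
        rep = score_sc1(pred, truth, targets=["m1"])
        assert rep.final == pytest.approx(1.0)

    def test_missing_prediction_raises_coverage(self, truth, mini_panel):
        pred = sc1_prediction_from(truth, mini_panel.sc1_targets,
                                   lambda d: d["value"])
        pred.data = pred.data.iloc[1:]
        with pytest.raises(CoverageError):
            score_sc1(pred, truth)

    def test_nan_rejected(self, truth, mini_panel):
        pred = sc1_prediction_from(truth, mini_panel.sc1_targets,
                                   lambda d: d["value"])
        pred.data.loc[0, "value"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            score_sc1(pred, truth)

    def test_invariant_to_cell_order(self, truth, mini_panel):
        pred = sc1_prediction_from(truth, mini_panel.sc1_targets,
                                   lambda d: d["value"] * 1.1)
        shuffled = PredictionSet(
            "SC1", pred.data.sample(frac=1, random_state=4), truth.panel)
        assert score_sc1(shuffled, truth).final == \
            pytest.approx(score_sc1(pred, truth).final, abs=1e-12)


class TestSc1Diagnostics:
    @pytest.fixture
    def truth(self, mini_panel, rng):
        return make_cells(mini_panel, [("CL01", "EGF", 0.0)], 50, rng)

    def test_perfect_prediction(self, truth):
        pred = sc1_prediction_from(truth, ["m1"], lambda d: d["value"])
        diag = sc1_diagnostics(pred, truth, targets=["m1"])
        assert diag["correlation"].iloc[0] == pytest.approx(1.0)
        assert diag["r2"].iloc[0] == pytest.approx(1.0)

    def test_condition_mean_gives_zero_r2(self, truth):
        mean = truth.data["m1"].mean()
        pred = sc1_prediction_from(truth, ["m1"], lambda d: mean)
        diag = sc1_diagnostics(pred, truth, targets=["m1"])
        assert diag["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_prediction(self, truth):
        mean = truth.data["m1"].mean()
        pred = sc1_prediction_from(
            truth, ["m1"], lambda d: 2 * mean - d["value"])
        diag = sc1_diagnostics(pred, truth, targets=["m1"])
        assert diag["correlation"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_truth_reported_missing(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 5, rng)
        truth.data["m1"] = 2.0
        pred = sc1_prediction_from(truth, ["m1"], lambda d: d["value"] + 0.1)
        diag = sc1_diagnostics(pred, truth, targets=["m1"])
        assert np.isnan(diag["correlation"].iloc[0])


class TestBasalCorrection:
    def test_exact_shift_removal(self, mini_panel, rng):
        truth = make_cells(mini_panel,
                           [("CL01", "EGF", 0.0), ("CL01", "EGF", 30.0)],
                           30, rng)
        pred = sc1_prediction_from(truth, ["m1"],
                                   lambda d: d["value"] + 1.5)
        tb = basal_means(truth, ["m1"])
        pb = prediction_basal_means(pred)
        corrected = basal_correction(pred, tb, pb)
        # the per-line constant shift is removed exactly
        assert score_sc1(corrected, truth, targets=["m1"]).final == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_offsets_leave_prediction_unchanged(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 20, rng)
        pred = sc1_prediction_from(truth, ["m1"], lambda d: d["value"])
        tb = basal_means(truth, ["m1"])
        corrected = basal_correction(pred, tb, tb.copy())
        pd.testing.assert_series_equal(corrected.data["value"],
                                       pred.data["value"])

    def test_missing_pair_raises(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 20, rng)
        pred = sc1_prediction_from(truth, ["m1"], lambda d: d["value"])
        tb = basal_means(truth, ["m1"])
        with pytest.raises(CoverageError):
            basal_correction(pred, tb.iloc[:0], tb)

    def test_never_hurts_for_constant_offsets(self, mini_panel, rng):
        """Per-(line, marker) constant biases are exactly what the basal
        correction removes; the corrected score cannot be worse."""
        truth = make_cells(mini_panel,
                           [("CL01", "EGF", 0.0), ("CL02", "EGF", 0.0),
                            ("CL01", "EGF", 30.0), ("CL02", "EGF", 30.0)],
                           40, rng)
        offsets = {"CL01": 0.9, "CL02": -0.4}
        pred = sc1_prediction_from(
            truth, ["m1"],
            lambda d: d["value"] + d["cell_line"].map(offsets))
        tb = basal_means(truth, ["m1"])
        pb = prediction_basal_means(pred)
        before = score_sc1(pred, truth, targets=["m1"]).final
        after = score_sc1(basal_correction(pred, tb, pb), truth,
                          targets=["m1"]).final
        assert after <= before + 1e-12
        assert after == pytest.approx(0.0, abs=1e-9)


class TestConditionStats:
    def test_two_cell_variance_uses_n_minus_1(self, mini_panel):
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 2,
                           np.random.default_rng(0))
        truth.data.loc[:, "m1"] = [0.0, 2.0]
        st = compute_condition_stats(truth, ("CL01", "EGF", 0.0))
        assert st.mean["m1"] == pytest.approx(1.0)
        assert st.cov.loc["m1", "m1"] == pytest.approx(2.0)

    def test_identical_cells_zero_covariance(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 5, rng,
                           sd=1.0)
        truth.data[list(mini_panel.names)] = 3.0
        st = compute_condition_stats(truth, ("CL01", "EGF", 0.0))
        assert (st.cov.to_numpy() == 0).all()

    def test_single_cell_rejected(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 1, rng)
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_condition_stats(truth, ("CL01", "EGF", 0.0))

    def test_large_sample_recovers_known_gaussian(self, mini_panel):
        rng = np.random.default_rng(7)
        n = 200_000
        truth = make_cells(mini_panel, [("CL01", "EGF", 0.0)], n, rng,
                           mean=2.0, sd=0.5)
        st = compute_condition_stats(truth, ("CL01", "EGF", 0.0))
        se_mean = 0.5 / np.sqrt(n)
        assert np.all(np.abs(st.mean - 2.0) < 4 * se_mean)
        se_var = 0.25 * np.sqrt(2 / (n - 1))
        assert np.all(np.abs(np.diag(st.cov) - 0.25) < 4 * se_var)


class TestScoreSc23:
    def test_identical_cells_score_zero(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "iMEK", 7.0)], 30, rng)
        pred = PredictionSet("SC2", truth.data.copy(), mini_panel)
        assert score_sc23(pred, truth).final == pytest.approx(0.0, abs=1e-20)

    def test_single_marker_mean_shift_scores_delta_squared(self, mini_panel,
                                                           rng):
        truth = make_cells(mini_panel, [("CL01", "iMEK", 7.0)], 30, rng)
        shifted = truth.data.copy()
        shifted["m1"] = shifted["m1"] + 0.5
        pred = PredictionSet("SC2", shifted, mini_panel)
        rep = score_sc23(pred, truth)
        assert rep.final == pytest.approx(0.25, abs=1e-12)
        assert rep.per_condition["s_sigma"].iloc[0] == pytest.approx(0.0,
                                                                     abs=1e-20)

    def test_missing_condition_raises(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "iMEK", 7.0),
                                        ("CL01", "iPKC", 7.0)], 10, rng)
        pred = PredictionSet(
            "SC2", truth.data[truth.data["treatment"] == "iMEK"].copy(),
            mini_panel)
        with pytest.raises(CoverageError):
            score_sc23(pred, truth)

    def test_invariant_to_predicted_cell_permutation(self, mini_panel, rng):
        truth = make_cells(mini_panel, [("CL01", "iMEK", 7.0)], 40, rng)
        pred_cells = make_cells(mini_panel, [("CL01", "iMEK", 7.0)], 40,
                                np.random.default_rng(5))
        a = score_sc23(PredictionSet("SC2", pred_cells.data, mini_panel),
                       truth).final
        permuted = pred_cells.data.sample(frac=1, random_state=3) \
            .reset_index(drop=True)
        permuted["cellID"] = np.arange(len(permuted))
        b = score_sc23(PredictionSet("SC2", permuted, mini_panel), truth).final
        assert a == pytest.approx(b, abs=1e-12)


class TestNormalizePerStatistic:
    def test_challenge_statistic_count(self):
        # 35 markers: 35 means + 630 covariance pairs + 35 variances
        assert n_statistics(35, 1) == 35 + 35 * 36 // 2
        assert n_statistics(35, 1) == 665

    def test_doubling_conditions_leaves_normalized_unchanged(self):
        per = pd.DataFrame({"cell_line": ["a", "b"], "treatment": ["iMEK"] * 2,
                            "time": [0.0, 0.0], "score": [3.0, 3.0]})
        rep1 = type("R", (), {"per_condition": per.iloc[:1]})
        rep2 = type("R", (), {"per_condition": per})
        n1 = normalize_per_statistic(rep1, n_statistics(5, 1))
        n2 = normalize_per_statistic(rep2, n_statistics(5, 2))
        assert n1 == pytest.approx(n2)

    def test_zero_error_normalizes_to_zero(self):
        rep = type("R", (), {"per_condition": pd.DataFrame({"score": [0.0]})})
        assert normalize_per_statistic(rep, 10) == 0.0

    def test_nonpositive_count_rejected(self):
        rep = type("R", (), {"per_condition": pd.DataFrame({"score": [1.0]})})
        with pytest.raises(ValueError):
            normalize_per_statistic(rep, 0)


class TestScoreSc4:
    def medians_frame(self, curves):
        rows = []
        for (cl, tr, marker), series in curves.items():
            for t, v in series.items():
                rows.append({"cell_line": cl, "treatment": tr, "time": t,
                             "marker": marker, "value": v})
        return pd.DataFrame(rows)

    def test_perfect_prediction_zero(self):
        tm = self.medians_frame(
            {("CL01", "EGF", "m1"): {0.0: 1.0, 30.0: 2.0}})
        pred = PredictionSet("SC4", tm.copy())
        assert score_sc4(pred, tm).final == 0.0

    def test_offset_on_one_of_k_curves(self):
        tm = self.medians_frame(
            {("CL01", "EGF", "m1"): {0.0: 1.0, 30.0: 2.0},
             ("CL01", "iMEK", "m1"): {0.0: 1.0, 30.0: 1.0}})
        pred_df = tm.copy()
        mask = pred_df["treatment"] == "iMEK"
        pred_df.loc[mask, "value"] += 0.8
        assert score_sc4(PredictionSet("SC4", pred_df), tm).final == \
            pytest.approx(0.4, abs=1e-12)

    def test_alternating_residuals(self):
        tm = self.medians_frame(
            {("CL01", "EGF", "m1"): {0.0: 0.0, 10.0: 0.0, 20.0: 0.0,
                                     30.0: 0.0}})
        pred_df = tm.copy()
        pred_df["value"] = [1.0, -1.0, 1.0, -1.0]
        assert score_sc4(PredictionSet("SC4", pred_df), tm).final == \
            pytest.approx(1.0)

    def test_missing_time_point_raises(self):
        tm = self.medians_frame(
            {("CL01", "EGF", "m1"): {0.0: 1.0, 30.0: 2.0}})
        pred = PredictionSet("SC4", tm.iloc[:1].copy())
        with pytest.raises(CoverageError):
            score_sc4(pred, tm)

    def test_condition_medians_matches_numpy(self, mini_panel, rng):
        table = make_cells(mini_panel, [("CL01", "EGF", 0.0)], 11, rng)
        tm = condition_medians(table)
        for m in mini_panel.names:
            got = tm[tm["marker"] == m]["value"].iloc[0]
            assert got == pytest.approx(np.median(table.data[m]))


class TestBootstrap:
    def per_condition(self, scores):
        return pd.DataFrame({
            "cell_line": [f"CL{i:02d}" for i in range(len(scores))],
            "treatment": ["iMEK"] * len(scores),
            "time": [7.0] * len(scores),
            "score": scores})

    def test_single_condition_degenerate(self):
        per = self.per_condition([2.5])
        boot = bootstrap_scores(per, "SC1", n_boot=50, seed=0)
        assert (boot.iloc[:, 0] == 2.5).all()

    def test_seed_reproducible(self):
        per = self.per_condition([1.0, 2.0, 3.0, 4.0])
        a = bootstrap_scores(per, "SC1", n_boot=100, seed=9)
        b = bootstrap_scores(per, "SC1", n_boot=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bootstrap_mean_near_point_score(self):
        rng = np.random.default_rng(21)
        scores = rng.uniform(0.5, 1.5, size=50)
        per = self.per_condition(list(scores))
        boot = bootstrap_scores(per, "SC1", n_boot=2000, seed=1)
        point = scores.mean()
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(boot.iloc[:, 0].mean() - point) < 3 * se

    def test_teams_share_resamples(self):
        per_a = self.per_condition([1.0, 2.0, 3.0])
        per_b = per_a.copy()
        per_b["score"] += 0.5
        boot = bootstrap_scores({"a": per_a, "b": per_b}, "SC1",
                                n_boot=200, seed=2)
        np.testing.assert_allclose(boot["b"] - boot["a"], 0.5)

    def test_misaligned_teams_rejected(self):
        per_a = self.per_condition([1.0, 2.0])
        per_b = self.per_condition([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="different condition"):
            bootstrap_scores({"a": per_a, "b": per_b}, "SC1", n_boot=10)

    def test_two_axis_resampling_covers_cross(self):
        rows = []
        for cl in ["CL01", "CL02", "CL03"]:
            for tr in ["iMEK", "iPKC"]:
                rows.append({"cell_line": cl, "treatment": tr, "time": 7.0,
                             "score": 1.0})
        per = pd.DataFrame(rows)
        boot = bootstrap_scores(per, "SC2", n_boot=20, seed=0)
        np.testing.assert_allclose(boot.iloc[:, 0], 1.0)


class TestBayesFactor:
    def test_strict_domination_is_infinite(self):
        x = np.zeros(1000)
        y = np.ones(1000)
        assert bayes_factor(x, y) == np.inf

    def test_999_to_1(self):
        x = np.zeros(1000)
        y = np.ones(1000)
        y[0] = -1.0
        assert bayes_factor(x, y) == pytest.approx(999.0)

    def test_all_ties_is_one(self):
        x = np.ones(100)
        assert bayes_factor(x, x.copy()) == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        bf = bayes_factor(x, y)
        assert bf * bayes_factor(y, x) == pytest.approx(1.0)

    def test_matrix_diagonal_and_antisymmetry(self):
        rng = np.random.default_rng(4)
        boot = pd.DataFrame({"a": rng.normal(size=300),
                             "b": rng.normal(0.3, 1, size=300)})
        mat = bayes_factor_matrix(boot)
        assert mat.loc["a", "a"] == 1.0
        assert mat.loc["a", "b"] * mat.loc["b", "a"] == pytest.approx(1.0)
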