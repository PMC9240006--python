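"""Mahalanobis primitives, threshold selection (against an exact-arithmetic
brute force), the fitted origin model and three-way calls."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from matfet.features import DifferenceRatioMatrix, compute_difference_ratios
from matfet.origin import (
    DEFAULT_CAP,
    CellOriginModel,
    CellOriginResults,
    EvaluationError,
    SelectionError,
    TrainingError,
    compute_ratio,
    evaluate_calls,
    mahalanobis_sq,
    select_thresholds,
)
from matfet.reference import panels_from_cord_cells
from matfet.simulate import simulate_cell_allele_counts


class TestMahalanobis:
    def test_zero_at_centroid(self):
        assert mahalanobis_sq([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_one_dimensional_closed_form(self):
        # (3-1)^2 / 4 = 1
        assert mahalanobis_sq(3.0, 1.0, 4.0) == pytest.approx(1.0)

    def test_identity_covariance_closed_form(self):
        assert mahalanobis_sq([1.0, 1.0], [0.0, 0.0], np.eye(2)) == pytest.approx(2.0)

    def test_matches_explicit_inverse_on_random_spd(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            d = int(rng.integers(1, 6))
            A = rng.normal(size=(d, d))
            S = A @ A.T + 0.5 * np.eye(d)
            x, mu = rng.normal(size=d), rng.normal(size=d)
            expected = (x - mu) @ np.linalg.inv(S) @ (x - mu)
            assert mahalanobis_sq(x, mu, S) == pytest.approx(expected, rel=1e-10)

    def test_affine_invariance(self):
        # joint invertible transform of x, mu and S leaves the distance fixed
        rng = np.random.default_rng(7)
        for _ in range(50):
            d = int(rng.integers(1, 5))
            A = rng.normal(size=(d, d))
            S = A @ A.T + 0.5 * np.eye(d)
            x, mu = rng.normal(size=d), rng.normal(size=d)
            T = rng.normal(size=(d, d)) + 2 * np.eye(d)
            base = mahalanobis_sq(x, mu, S)
            moved = mahalanobis_sq(T @ x, T @ mu, T @ S @ T.T)
            assert moved == pytest.approx(base, rel=1e-8)

    def test_singular_covariance_reports_diagnostic(self):
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            mahalanobis_sq([1.0, 0.0], [0.0, 0.0], np.zeros((2, 2)), ridge=0.0)

    def test_batch_agrees_with_loop(self):
        rng = np.random.default_rng(2)
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        X = rng.normal(size=(20, 2))
        mu = np.array([0.5, -0.5])
        batch = mahalanobis_sq(X, mu, S)
        singles = [mahalanobis_sq(x, mu, S) for x in X]
        np.testing.assert_allclose(batch, singles)


def manual_results(mu_f, mu_m, orientation="as_printed", cuts=(0.5, 2.0)):
    d = len(mu_f)
    return CellOriginResults(
        model=None,
        mu_fetal=np.asarray(mu_f, float),
        cov_fetal=np.eye(d),
        mu_maternal=np.asarray(mu_m, float),
        cov_maternal=np.eye(d),
        ridge=0.0,
        orientation=orientation,
        fetal_cut=cuts[0],
        maternal_cut=cuts[1],
    )


class TestComputeRatio:
    def test_zero_at_maternal_centroid(self):
        res = manual_results([0.0, 0.0], [1.0, 1.0])
        assert compute_ratio(np.array([1.0, 1.0]), res, oriented=False) == 0.0

    def test_capped_at_fetal_centroid(self):
        res = manual_results([0.0, 0.0], [1.0, 1.0])
        assert compute_ratio(np.array([0.0, 0.0]), res, oriented=False) == DEFAULT_CAP

    def test_unity_when_equidistant(self):
        res = manual_results([0.0, 0.0], [2.0, 0.0])
        assert compute_ratio(np.array([1.0, 0.0]), res, oriented=False) == pytest.approx(1.0)

    def test_oriented_ratio_monotone_from_maternal_to_fetal(self):
        # walking the segment from the maternal centroid to the fetal one,
        # the printed ratio rises strictly; the inverted orientation falls
        res = manual_results([0.0, 0.0], [3.0, 0.0])
        ts = np.linspace(0.05, 0.95, 19)
        pts = np.outer(1 - ts, [3.0, 0.0]) + np.outer(ts, [0.0, 0.0])
        printed = compute_ratio(pts, res, oriented=False)
        assert (np.diff(printed) > 0).all()
        res.orientation = "inverted"
        oriented = compute_ratio(pts, res)
        assert (np.diff(oriented) < 0).all()


def oracle_select(ratios, labels, grid, criterion):
    """Exact-arithmetic brute force over the grid (Fractions throughout)."""
    y = np.asarray([l == "fetal" for l in labels])
    P, N = int(y.sum()), int((~y).sum())
    scored = []
    for c in grid:
        pred = np.asarray(ratios) < c
        tp = int((pred & y).sum())
        tn = int((~pred & ~y).sum())
        acc = Fraction(tp + tn, P + N)
        youden = Fraction(tp, P) + Fraction(tn, N) - 1
        key = (acc, youden) if criterion == "accuracy" else (youden, acc)
        scored.append((key, c))
    best = max(k for k, _ in scored)
    opt = [c for k, c in scored if k == best]
    return min(opt), max(opt)


class TestSelectThresholds:
    def test_perfect_separation_reaches_perfect_metrics(self):
        ratios = np.array([0.1, 0.2, 5.0, 6.0])
        labels = ["fetal", "fetal", "maternal", "maternal"]
        f_cut, m_cut, table = select_thresholds(ratios, labels)
        assert f_cut <= m_cut
        row = table[table["cut"] == f_cut].iloc[0]
        assert row["sensitivity"] == row["specificity"] == row["accuracy"] == 1.0

    def test_identical_ratios_are_a_selection_error(self):
        with pytest.raises(SelectionError):
            select_thresholds(np.ones(10), ["fetal"] * 5 + ["maternal"] * 5)

    def test_single_class_rejected(self):
        with pytest.raises(SelectionError):
            select_thresholds(np.arange(5.0), ["fetal"] * 5)

    @pytest.mark.parametrize("criterion", ["accuracy", "youden"])
    def test_matches_bruteforce_on_random_sets(self, criterion):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(20, 80))
            labels = np.where(rng.random(n) < 0.5, "fetal", "maternal")
            if len(set(labels)) < 2:
                continue
            ratios = np.where(
                labels == "fetal", rng.normal(0.5, 0.4, n), rng.normal(1.5, 0.6, n)
            ).clip(0)
            grid = np.unique(np.round(rng.uniform(0, 3, 15), 3))
            f_cut, m_cut, _ = select_thresholds(ratios, labels, grid=grid, criterion=criterion)
            of, om = oracle_select(ratios, labels, grid, criterion)
            assert (f_cut, m_cut) == (of, om)


def drm_from_values(values, covered=None, min_sites=1):
    values = pd.DataFrame(values)
    covered = (
        pd.DataFrame(covered, index=values.index, columns=values.columns)
        if covered is not None
        else pd.DataFrame(100, index=values.index, columns=values.columns)
    )
    return DifferenceRatioMatrix(values=values, covered=covered, min_sites=min_sites)


class TestModelFit:
    def make_drm_labels(self, seed=0, n=60, sep=0.4):
        rng = np.random.default_rng(seed)
        fet = rng.normal(0.1, 0.05, size=(n, 2)).clip(0, 1)
        mat = rng.normal(0.1 + sep, 0.05, size=(n, 2)).clip(0, 1)
        values = pd.DataFrame(
            np.vstack([fet, mat]),
            index=[f"c{i}" for i in range(2 * n)],
            columns=["p1", "p2"],
        )
        labels = pd.Series(
            ["fetal"] * n + ["maternal"] * n, index=values.index
        )
        return drm_from_values(values), labels

    def test_centroids_equal_class_column_means(self):
        drm, labels = self.make_drm_labels()
        res = CellOriginModel(drm, labels).fit()
        np.testing.assert_allclose(
            res.mu_fetal, drm.values.iloc[:60].mean().to_numpy()
        )
        np.testing.assert_allclose(
            res.mu_maternal, drm.values.iloc[60:].mean().to_numpy()
        )
        # covariances are the sample covariances (ddof=1), as in R's var()
        np.testing.assert_allclose(
            res.cov_fetal, np.cov(drm.values.iloc[:60].to_numpy(), rowvar=False)
        )

    def test_single_class_is_a_training_error(self):
        drm, labels = self.make_drm_labels()
        with pytest.raises(TrainingError):
            CellOriginModel(drm, labels[labels == "fetal"]).fit()

    def test_class_below_two_cells_is_a_training_error(self):
        drm, labels = self.make_drm_labels()
        keep = list(labels.index[:60]) + [labels.index[60]]
        with pytest.raises(TrainingError):
            CellOriginModel(drm, labels.loc[keep]).fit()

    def test_zero_variance_feature_needs_positive_ridge(self):
        values = pd.DataFrame(
            {"p1": [0.0, 0.0, 1.0, 1.0], "p2": [0.0, 0.0, 1.0, 1.0]},
            index=list("abcd"),
        )
        labels = pd.Series(["fetal", "fetal", "maternal", "maternal"], index=list("abcd"))
        with pytest.raises(TrainingError):
            CellOriginModel(drm_from_values(values), labels, ridge=0.0).fit()

    def test_fitted_orientation_puts_fetal_low(self):
        drm, labels = self.make_drm_labels()
        res = CellOriginModel(drm, labels).fit()
        r = res.training_ratios
        assert np.median(r[labels == "fetal"]) < np.median(r[labels == "maternal"])

    def test_squared_and_plain_distances_give_identical_calls(self):
        drm, labels = self.make_drm_labels(seed=5, sep=0.25)
        calls_sq = CellOriginModel(drm, labels, squared=True).fit().predict(drm)
        calls_pl = CellOriginModel(drm, labels, squared=False).fit().predict(drm)
        assert (calls_sq["call"] == calls_pl["call"]).all()

    def test_summary_mentions_fit_ingredients(self):
        drm, labels = self.make_drm_labels()
        text = CellOriginModel(drm, labels).fit().summary()
        for token in ("orientation", "fetal cut", "accuracy"):
            assert token in text

    def test_model_json_roundtrip(self, tmp_path):
        drm, labels = self.make_drm_labels()
        res = CellOriginModel(drm, labels).fit()
        path = tmp_path / "model.json"
        res.save(path)
        back = CellOriginResults.load(path)
        np.testing.assert_allclose(back.mu_fetal, res.mu_fetal)
        assert back.orientation == res.orientation
        assert (back.fetal_cut, back.maternal_cut) == (res.fetal_cut, res.maternal_cut)
        calls = back.predict(drm)
        assert (calls["call"] == res.predict(drm)["call"]).all()


class TestClassify:
    def test_decision_rule_three_ways(self):
        # fetal below the fetal cut, maternal above the maternal cut,
        # unknown in between
        res = manual_results([0.0], [10.0], orientation="as_printed", cuts=(0.5, 2.0))
        # choose points whose oriented ratio is 0.3, 1.0, 3.0 via 1-D algebra:
        # ratio = (x-10)^2 / x^2
        def x_for(r):
            return 10.0 / (1.0 + np.sqrt(r))

        values = pd.DataFrame({"p1": [x_for(0.3), x_for(1.0), x_for(3.0)]},
                              index=["a", "b", "c"])
        drm = drm_from_values(values)
        calls = res.predict(drm)
        assert list(calls["call"]) == ["fetal", "unknown", "maternal"]
        assert calls.loc["a", "ratio"] == pytest.approx(0.3)

    def test_low_coverage_is_unknown_regardless_of_ratio(self):
        res = manual_results([0.0], [10.0], cuts=(0.5, 2.0))
        values = pd.DataFrame({"p1": [9.0]}, index=["a"])  # clearly fetal side? no: ratio=(9-10)^2/81
        drm = drm_from_values(values, covered=[[2]], min_sites=10)
        assert res.predict(drm)["call"].iloc[0] == "unknown"

    def test_unfitted_thresholds_rejected(self):
        res = manual_results([0.0], [1.0])
        res.fetal_cut = np.nan
        with pytest.raises(ValueError):
            res.predict(drm_from_values(pd.DataFrame({"p1": [0.5]}, index=["a"])))


class TestEvaluate:
    def test_all_correct_no_unknown(self):
        calls = pd.DataFrame(
            {"call": ["fetal", "maternal"], "ratio": [0.1, 5.0], "covered_sites": [50, 50]},
            index=["a", "b"],
        )
        m = evaluate_calls(calls, {"a": "fetal", "b": "maternal"})
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 1.0
        assert m["unknown_fraction"] == 0.0

    def test_all_unknown_reports_absent_metrics(self):
        calls = pd.DataFrame(
            {"call": ["unknown", "unknown"], "ratio": [1.0, 1.0], "covered_sites": [5, 5]},
            index=["a", "b"],
        )
        m = evaluate_calls(calls, {"a": "fetal", "b": "maternal"})
        assert m["unknown_fraction"] == 1.0
        assert m["sensitivity"] is None and m["accuracy"] is None

    def test_no_shared_barcodes_is_an_error(self):
        calls = pd.DataFrame(
            {"call": ["fetal"], "ratio": [0.1], "covered_sites": [10]}, index=["a"]
        )
        with pytest.raises(EvaluationError):
            evaluate_calls(calls, {"z": "fetal"})

    def test_metrics_match_direct_recount_on_simulated_cells(self, trio, balanced_obs):
        cord = {
            f"c{k}": simulate_cell_allele_counts(
                trio, 200, fetal_fraction=1.0,
                sites_per_cell={"dist": "negbin", "mean": 150, "dispersion": 30},
                error_rate=0.01, seed=60 + k,
            )
            for k in range(3)
        }
        ref = panels_from_cord_cells(cord, min_support=3)
        drm = compute_difference_ratios(balanced_obs, ref, min_sites=10)
        labels = balanced_obs.truth
        res = CellOriginModel(drm, labels.iloc[:300]).fit()
        calls = res.predict(drm).iloc[300:]
        truth = labels.iloc[300:]
        m = evaluate_calls(calls, truth)
        # independent recount straight off the saved calls
        joined = calls.join(truth.rename("truth"))
        called = joined[joined["call"] != "unknown"]
        tp = ((called["call"] == "fetal") & (called["truth"] == "fetal")).sum()
        tn = ((called["call"] == "maternal") & (called["truth"] == "maternal")).sum()
        assert m["accuracy"] == pytest.approx((tp + tn) / len(called))
        assert m["unknown_fraction"] == pytest.approx(
            (joined["call"] == "unknown").mean()
        )
        assert m["confusion"]["tp"] == tp
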