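"""Grid search, lasso region selection, and the composite index."""

import numpy as np
import pandas as pd
import pytest

from aqipet import evaluate as ev
from aqipet import optimize_select as osel
from aqipet.frames import FrameSchedule, SubjectRecord
from aqipet.pipeline import quantify_cohort
from aqipet.quantify import AQIParams

from conftest import make_tac


def _constant_cohort(n_per_group=5):
    """AD and HC share identical flat TACs: no signal at any grid point."""
    subs = []
    sched = FrameSchedule.from_durations([10.0] * 12 + [60.0] * 3 + [300.0] * 11)
    for g in ("AD", "HC"):
        for i in range(n_per_group):
            tac = make_tac(
                np.full(26, 800.0 + 10 * i), schedule=sched, region="roi", dose=300.0
            )
            subs.append(
                SubjectRecord(
                    subject_id=f"{g}_{i}", group=g, tacs={"roi": tac},
                    cdr_sob=0.0 if g == "HC" else 1.0,
                )
            )
    return subs


def _toy_cohort():
    """Noiseless templates identical before ~900 s; groups differ only in the
    retention sample S(1200).  On the grid below, exactly one parameter set
    (a=1, t1=1200, t2=1650) classifies perfectly."""
    sched = FrameSchedule.from_durations([10.0, 1180.0, 20.0, 880.0, 1510.0])
    # mids: 5, 600, 1200, 1650, 2845
    subs = []
    rng = np.random.default_rng(0)
    for i in range(5):
        s600 = 60.0 + rng.uniform(-2, 2)
        s1650_ad = rng.uniform(5.0, 95.0)
        s1650_hc = rng.uniform(5.0, 95.0)
        ad = make_tac(
            [100.0, s600, 80.0 + i, s1650_ad, 2.0], schedule=sched, dose=1.0
        )
        hc = make_tac(
            [100.0, s600 + 0.5, 40.0 + i, s1650_hc, 2.0], schedule=sched, dose=1.0
        )
        subs.append(SubjectRecord(f"AD_{i}", "AD", {"roi": ad}))
        subs.append(SubjectRecord(f"HC_{i}", "HC", {"roi": hc}))
    return subs


TOY_GRID = osel.GridSpec(
    t1_range=(600.0, 1200.0), t1_step=600.0,
    t2_range=(1650.0, 1650.0), t2_step=50.0,
    a_range=(0.0, 1.0), a_step=0.5,
)


class TestOptimizeParams:
    def test_no_signal_cohort_returns_minimal_scan_time_corner(self):
        grid = osel.GridSpec(
            t1_range=(50.0, 300.0), t1_step=50.0,
            t2_range=(300.0, 600.0), t2_step=300.0,
            a_range=(0.0, 1.0), a_step=0.5,
        )
        res = osel.optimize_params(_constant_cohort(), "roi", grid, cv_folds=5, rng=0)
        # flat surface at 0.5 -> minimal max(t1,t2), then minimal t1, then a
        assert res.best_accuracy == pytest.approx(0.5)
        assert np.allclose(res.surface["accuracy"].dropna(), 0.5)
        assert res.best_params == AQIParams(a=0.0, t1=50.0, t2=300.0)

    def test_toy_cohort_unique_perfect_point_is_returned(self):
        subs = _toy_cohort()
        res = osel.optimize_params(subs, "roi", TOY_GRID, cv_folds=5, rng=1)
        assert res.best_accuracy == 1.0
        assert res.best_params == AQIParams(a=1.0, t1=1200.0, t2=1650.0)
        surf = res.surface
        perfect = surf[surf["accuracy"] == 1.0]
        assert len(perfect) == 1  # no other grid point reaches accuracy 1

    def test_deterministic_for_fixed_fold_seed(self):
        subs = _toy_cohort()
        r1 = osel.optimize_params(subs, "roi", TOY_GRID, cv_folds=5, rng=42)
        r2 = osel.optimize_params(subs, "roi", TOY_GRID, cv_folds=5, rng=42)
        assert r1.best_params == r2.best_params
        pd.testing.assert_frame_equal(r1.surface, r2.surface)

    def test_permutation_invariance_up_to_folds(self):
        subs = _toy_cohort()
        rng = np.random.default_rng(3)
        shuffled = list(subs)
        rng.shuffle(shuffled)
        r1 = osel.optimize_params(subs, "roi", TOY_GRID, cv_folds=5, rng=42)
        r2 = osel.optimize_params(shuffled, "roi", TOY_GRID, cv_folds=5, rng=42)
        assert r1.best_params == r2.best_params

    def test_invalid_grid_points_excluded_not_fatal(self):
        subs = _toy_cohort()
        grid = osel.GridSpec(
            t1_range=(600.0, 600.0), t1_step=50.0,
            t2_range=(1650.0, 3300.0), t2_step=1650.0,  # 3300 beyond last mid 2845
            a_range=(0.5, 0.5), a_step=0.5,
        )
        res = osel.optimize_params(subs, "roi", grid, cv_folds=5, rng=0)
        surf = res.surface
        assert not surf.loc[surf["t2"] == 3300.0, "valid"].any()
        assert surf.loc[surf["t2"] == 1650.0, "valid"].all()


def _lasso_design(n=200, p=10, seed=2024, label_noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    logitp = 3.0 * X[:, 0] + 2.5 * X[:, 1]
    y = (logitp + rng.normal(0, label_noise, n) > 0).astype(float)
    cols = [f"region_{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestLassoSelect:
    def test_constant_response_selects_nothing(self):
        X, _ = _lasso_design(40, 5)
        sel = osel.lasso_select(X, np.ones(40))
        assert sel.regions == () and sel.beta == {}

    def test_constant_feature_dropped_with_warning(self, caplog):
        X, y = _lasso_design(60, 4)
        X["flat"] = 1.0
        with caplog.at_level("WARNING"):
            sel = osel.lasso_select(X, y, rng=0)
        assert "flat" in caplog.text
        assert "flat" not in sel.regions

    def test_two_informative_regions_recovered_exactly(self):
        X, y = _lasso_design()
        sel = osel.lasso_select(X, y, rng=0)
        assert set(sel.regions) == {"region_0", "region_1"}
        # sorted by |beta| descending; the stronger effect first
        assert sel.regions[0] == "region_0"

    def test_lambda_to_zero_limit_matches_ols_oracle(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = (rng.normal(size=20) > 0).astype(float)
        grid = np.geomspace(1.0, 1e-10, 60)
        sel = osel.lasso_select(X, y, lambda_grid=grid, cv_folds=5, rng=1)
        Z = (X - X.mean()) / X.std(ddof=0)
        D = np.column_stack([np.ones(20), Z.to_numpy()])
        ols = np.linalg.solve(D.T @ D, D.T @ y)[1:]
        smallest = sel.coef_path[sel.coef_path.columns[-1]].to_numpy()
        assert np.allclose(smallest, ols, atol=1e-4)

    def test_path_sparsity_monotone_in_lambda(self):
        X, y = _lasso_design(120, 8, seed=9)
        sel = osel.lasso_select(X, y, rng=0)
        nnz = (np.abs(sel.coef_path.to_numpy()) > 1e-10).sum(axis=0)
        assert np.all(np.diff(nnz) >= 0)  # columns ordered by decreasing alpha

    def test_default_cohort_positive_coefficients_are_the_signal_regions(
        self, default_cohort
    ):
        subs, _ = default_cohort
        m = quantify_cohort(subs)
        cols = [c for c in m.columns if c.startswith("aqi__")]
        X = m[cols].astype(float)
        X.columns = [c.removeprefix("aqi__") for c in cols]
        sel = osel.lasso_select(X, m["group"].to_numpy(), rng=1234)
        positives = {r for r, b in sel.beta.items() if b > 0}
        assert positives == {"caudal_anterior_cingulate", "caudate"}
        assert sel.regions[0] == "caudal_anterior_cingulate"


class TestOverallIndex:
    def test_balanced_cohort_intercept_is_half(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"r1": rng.normal(size=20), "r2": rng.normal(size=20)})
        y = np.array([0, 1] * 10)
        model = osel.fit_overall(X, y)
        assert model.intercept == pytest.approx(0.5, abs=1e-12)

    def test_perfect_single_feature_reproduces_labels(self):
        y = np.array([0.0, 0, 1, 1])
        X = pd.DataFrame({"r": y.copy()})
        model = osel.fit_overall(X, y)
        fitted = osel.apply_overall(model, X)
        assert np.allclose((fitted >= 0.5).astype(float), y)
        assert np.allclose(fitted, y)  # single binary feature: exact fit

    def test_four_subject_normal_equations_oracle(self):
        X = pd.DataFrame({"r": [-1.0, -1.0, 1.0, 1.0]})
        y = np.array([0.0, 0.0, 1.0, 1.0])
        model = osel.fit_overall(X, y)
        # z-scored feature (sd with ddof=1) is (-1,-1,1,1)/sd; hand normal
        # equations give slope = cov(z,y)/var(z) = 0.5 * sd
        sd = X["r"].std(ddof=1)
        assert model.coef[0] == pytest.approx(0.5 * sd)
        assert model.intercept == pytest.approx(0.5)

    def test_apply_at_training_means_returns_intercept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12)})
        y = np.array([0, 1] * 6)
        model = osel.fit_overall(X, y)
        at_mean = {"a": np.array([X["a"].mean()]), "b": np.array([X["b"].mean()])}
        assert osel.apply_overall(model, at_mean)[0] == pytest.approx(model.intercept)

    def test_published_style_coefficients_arithmetic(self):
        model = osel.OverallIndexModel(
            regions=("x1", "x2"),
            means=np.array([0.0, 0.0]),
            sds=np.array([1.0, 1.0]),
            coef=np.array([3.6092, 0.2750]),
            intercept=0.5378,
        )
        out = osel.apply_overall(model, {"x1": np.array([1.0]), "x2": np.array([0.0])})
        assert out[0] == pytest.approx(4.1470)

    def test_apply_reproduces_in_sample_fit(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = np.array([0, 1] * 15)
        model = osel.fit_overall(X, y)
        fitted = osel.apply_overall(model, X)
        Z = (X - X.mean()) / X.std(ddof=1)
        D = np.column_stack([np.ones(30), Z.to_numpy()])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.allclose(fitted, D @ beta)

    def test_missing_region_named_in_error(self):
        model = osel.OverallIndexModel(
            regions=("caudate",), means=np.zeros(1), sds=np.ones(1),
            coef=np.ones(1), intercept=0.0,
        )
        with pytest.raises(ValueError, match="caudate"):
            osel.apply_overall(model, {"other": np.array([1.0])})

    def test_zero_variance_feature_errors(self):
        X = pd.DataFrame({"r": [1.0, 1.0, 1.0, 1.0]})
        y = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="z-score"):
            osel.fit_overall(X, y)
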