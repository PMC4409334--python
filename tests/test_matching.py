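import numpy as np
import pandas as pd
import pytest

from firescape.errors import MatchingError
from firescape.grid import BINARY, GridGeometry, GridStack, Raster
from firescape.matching import (
    UnitTable,
    att_estimate,
    balance_report,
    build_unit_table,
    correlation_screen,
    fit_propensity,
    mahalanobis_match,
    standardized_mean_differences,
)
from firescape.synthetic import generate_covariates, generate_fires
from tests.conftest import make_raster, recovery_config


def units_from_arrays(X, T, Y):
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    covs = tuple(f"x{j}" for j in range(d))
    df = pd.DataFrame(X, columns=list(covs))
    df.insert(0, "Y", np.asarray(Y, dtype=int))
    df.insert(0, "T", np.asarray(T, dtype=int))
    df.insert(0, "col", np.zeros(n, dtype=int))
    df.insert(0, "row", np.arange(n))
    df.insert(0, "unit_id", np.arange(n))
    return UnitTable(df, covs)


def brute_force_match(X, T, caliper_sd=1.0, tie_tol=1e-9):
    """Independent O(n_t * n_c) all-pairs matching oracle.

    Recomputes the pooled covariance, scans every treated/control pair,
    keeps the minimum-distance ties, and applies the per-covariate caliper
    to the tied set.
    """
    X = np.asarray(X, dtype=float)
    S = np.atleast_2d(np.cov(X, rowvar=False))
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        S = S + np.eye(S.shape[0]) * (1e-8 * np.trace(S) / S.shape[0])
    VI = np.linalg.inv(S)
    sds = X.std(axis=0, ddof=1)
    sds = np.where(sds == 0, np.inf, sds)
    t_idx = [i for i in range(len(T)) if T[i] == 1]
    c_idx = [i for i in range(len(T)) if T[i] == 0]
    matched, excluded = {}, []
    for ti in t_idx:
        dists = []
        for ci in c_idx:
            diff = X[ti] - X[ci]
            dists.append(np.sqrt(diff @ VI @ diff))
        dmin = min(dists)
        ties = [c_idx[k] for k, dv in enumerate(dists) if dv <= dmin + tie_tol * max(1.0, dmin)]
        ok = [ci for ci in ties if np.all(np.abs(X[ti] - X[ci]) <= caliper_sd * sds)]
        if not ok:
            excluded.append(ti)
        else:
            matched[ti] = sorted(ok)
    return matched, excluded


# ------------------------------------------------------------ build_unit_table
def _toy_stack(rng, shape=(4, 4), n_protected=6):
    geom = GridGeometry(*shape)
    covs = {
        name: Raster(geom, rng.normal(size=shape), name=name)
        for name in ("tree_cover", "elevation")
    }
    prot = np.zeros(shape, dtype=np.uint8)
    prot.ravel()[:n_protected] = 1
    fire = (rng.random(shape) < 0.5).astype(np.uint8)
    return GridStack(
        geometry=geom,
        covariates=covs,
        protection=Raster(geom, prot, kind=BINARY, nodata=255),
        fire=Raster(geom, fire, kind=BINARY, nodata=255),
    )


class TestBuildUnitTable:
    def test_counts(self, rng):
        stack = _toy_stack(rng)
        units = build_unit_table(stack, covariates=("tree_cover", "elevation"))
        assert len(units) == 16
        assert (units.T == 1).sum() == 6

    def test_nodata_excluded(self, rng):
        stack = _toy_stack(rng)
        stack.covariates["elevation"].values[2, 2] = np.nan
        units = build_unit_table(stack, covariates=("tree_cover", "elevation"))
        assert len(units) == 15

    def test_forest_only_mask_oracle(self, rng):
        stack = _toy_stack(rng)
        tc = rng.uniform(0, 100, size=(4, 4))
        stack.covariates["tree_cover"].values[:] = tc
        units = build_unit_table(
            stack, forest_only=True, forest_threshold=25.0,
            covariates=("tree_cover", "elevation"),
        )
        assert len(units) == int((tc >= 25).sum())
        assert (units.frame["tree_cover"] >= 25).all()

    def test_no_treated_error(self, rng):
        stack = _toy_stack(rng, n_protected=0)
        with pytest.raises(MatchingError):
            build_unit_table(stack, covariates=("tree_cover", "elevation"))


# --------------------------------------------------------------- propensity
class TestFitPropensity:
    def test_null_model(self, rng):
        n = 5000
        X = rng.normal(size=(n, 3))
        T = rng.random(n) < 0.3
        units = units_from_arrays(X, T.astype(int), np.zeros(n))
        model = fit_propensity(units)
        assert model.converged
        assert np.abs(model.coefficients[1:]).max() < 0.1
        assert model.scores.mean() == pytest.approx(T.mean(), abs=0.02)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(7)
        n = 20_000
        beta = np.array([-0.5, 0.8, -0.6, 0.3])
        X = rng.normal(size=(n, 3))
        eta = beta[0] + X @ beta[1:]
        T = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        units = units_from_arrays(X, T, np.zeros(n))
        model = fit_propensity(units)
        # observed-information SEs at the fitted coefficients
        A = np.column_stack([np.ones(n), X])
        p = model.scores
        H = (A * (p * (1 - p))[:, None]).T @ A
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        assert np.all(np.abs(model.coefficients - beta) < 3 * se)

    def test_duplication_invariance(self, rng):
        n = 400
        X = rng.normal(size=(n, 2))
        T = (rng.random(n) < 0.4).astype(int)
        u1 = units_from_arrays(X, T, np.zeros(n))
        u2 = units_from_arrays(np.vstack([X, X]), np.r_[T, T], np.zeros(2 * n))
        m1, m2 = fit_propensity(u1), fit_propensity(u2)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-6)

    def test_separation_flagged(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        T = (X.ravel() > 0).astype(int)
        units = units_from_arrays(X, T, np.zeros(40))
        with pytest.warns(UserWarning):
            model = fit_propensity(units)
        assert model.separation_flagged
        assert model.scores.min() >= 1e-6 and model.scores.max() <= 1 - 1e-6


# ----------------------------------------------------------------- matching
class TestMahalanobisMatch:
    def test_identity_covariance_equals_euclidean(self, rng):
        n = 80
        X = rng.normal(size=(n, 3))
        # whiten so the pooled sample covariance is exactly identity
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X, rowvar=False))).T
        T = np.zeros(n, dtype=int)
        T[:20] = 1
        units = units_from_arrays(X, T, np.zeros(n))
        m = mahalanobis_match(units, caliper_sd=np.inf)
        c_idx = np.nonzero(T == 0)[0]
        for ti, cset in zip(m.treated_index, m.control_sets):
            d = np.linalg.norm(X[c_idx] - X[ti], axis=1)
            assert c_idx[np.argmin(d)] in cset

    def test_exact_twins_distance_zero(self, rng):
        Xt = rng.normal(size=(10, 4))
        X = np.vstack([Xt, Xt, rng.normal(size=(30, 4)) + 5])
        T = np.r_[np.ones(10), np.zeros(40)].astype(int)
        units = units_from_arrays(X, T, np.zeros(50))
        m = mahalanobis_match(units)
        assert m.n_treated_matched == 10
        np.testing.assert_allclose(m.distances, 0.0, atol=1e-10)
        for k, cset in enumerate(m.control_sets):
            assert 10 + k in cset

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        d = int(rng.integers(2, 6))
        X = rng.normal(size=(n, d))
        T = (rng.random(n) < 0.4).astype(int)
        if T.sum() == 0 or T.sum() == n:
            T[0], T[-1] = 1, 0
        caliper = float(rng.uniform(0.5, 2.0))
        units = units_from_arrays(X, T, np.zeros(n))
        oracle_matches, oracle_excluded = brute_force_match(X, T, caliper)
        try:
            m = mahalanobis_match(units, caliper_sd=caliper)
            got = {
                int(ti): list(map(int, cset))
                for ti, cset in zip(m.treated_index, m.control_sets)
            }
            got_excl = sorted(map(int, m.excluded_index))
        except MatchingError:
            got, got_excl = {}, sorted(np.nonzero(T == 1)[0])
        assert got == oracle_matches
        assert got_excl == sorted(oracle_excluded)

    def test_affine_invariance(self, rng):
        n = 100
        X = rng.normal(size=(n, 4))
        T = (rng.random(n) < 0.3).astype(int)
        T[0], T[-1] = 1, 0
        units = units_from_arrays(X, T, np.zeros(n))
        m1 = mahalanobis_match(units, caliper_sd=np.inf)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        units2 = units_from_arrays(X @ A.T + b, T, np.zeros(n))
        m2 = mahalanobis_match(units2, caliper_sd=np.inf)
        assert [list(c) for c in m1.control_sets] == [list(c) for c in m2.control_sets]

    def test_permutation_symmetry(self, rng):
        n = 60
        X = rng.normal(size=(n, 3))
        T = (rng.random(n) < 0.4).astype(int)
        T[0], T[-1] = 1, 0
        units = units_from_arrays(X, T, np.zeros(n))
        m1 = mahalanobis_match(units, caliper_sd=np.inf)
        perm = rng.permutation(n)
        units2 = units_from_arrays(X[perm], T[perm], np.zeros(n))
        m2 = mahalanobis_match(units2, caliper_sd=np.inf)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        pairs1 = {int(ti): sorted(map(int, c)) for ti, c in zip(m1.treated_index, m1.control_sets)}
        pairs2 = {
            int(perm[ti]): sorted(int(perm[ci]) for ci in c)
            for ti, c in zip(m2.treated_index, m2.control_sets)
        }
        assert pairs1 == pairs2

    def test_all_excluded_error(self):
        X = np.array([[0.0], [100.0], [101.0]])
        T = np.array([1, 0, 0])
        units = units_from_arrays(X, T, np.zeros(3))
        with pytest.raises(MatchingError):
            mahalanobis_match(units, caliper_sd=0.1)

    def test_tie_weights_equal(self):
        # two controls equidistant from the treated unit
        X = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [3.0, 1.0], [3.0, -1.0]])
        T = np.array([1, 0, 0, 0, 0])
        units = units_from_arrays(X, T, np.zeros(5))
        m = mahalanobis_match(units, caliper_sd=np.inf)
        assert len(m.control_sets[0]) == 2
        np.testing.assert_allclose(m.weights[0], 0.5)


# ---------------------------------------------------------------------- ATT
class TestATTEstimate:
    def test_identical_outcomes_null(self, rng):
        Xt = rng.normal(size=(15, 3))
        X = np.vstack([Xt, Xt])
        T = np.r_[np.ones(15), np.zeros(15)].astype(int)
        Y = np.r_[np.ones(15), np.ones(15)].astype(int)
        units = units_from_arrays(X, T, Y)
        m = mahalanobis_match(units)
        est = att_estimate(units, m)
        assert est.att == 0.0

    def test_constant_effect_exact(self, rng):
        # exact twins; treated outcome exceeds the twin's by a deterministic
        # pattern whose mean is the constructed oracle value
        Xt = rng.normal(size=(20, 3))
        X = np.vstack([Xt, Xt])
        T = np.r_[np.ones(20), np.zeros(20)].astype(int)
        y_c = np.zeros(20, dtype=int)
        delta = np.array([1] * 12 + [0] * 8)
        Y = np.r_[y_c + delta, y_c]
        units = units_from_arrays(X, T, Y)
        m = mahalanobis_match(units)
        est = att_estimate(units, m)
        assert est.att == pytest.approx(delta.mean(), abs=1e-12)
        assert est.n_treated_matched == 20

    def test_se_positive_and_t(self, rng):
        n = 400
        X = rng.normal(size=(n, 2))
        T = (rng.random(n) < 0.4).astype(int)
        T[:2], T[-2:] = 1, 0
        Y = (rng.random(n) < 0.4).astype(int)
        units = units_from_arrays(X, T, Y)
        m = mahalanobis_match(units)
        est = att_estimate(units, m)
        assert est.se > 0
        assert est.t_value == pytest.approx(est.att / est.se)
        assert abs(est.att) <= 1

    def test_too_few_matched(self, rng):
        X = np.array([[0.0], [0.1], [0.2]])
        units = units_from_arrays(X, [1, 0, 0], [1, 0, 0])
        m = mahalanobis_match(units, caliper_sd=np.inf)
        with pytest.raises(MatchingError):
            att_estimate(units, m)


# -------------------------------------------------------------------- balance
class TestBalanceReport:
    def test_exact_twins_perfect_balance(self, rng):
        Xt = rng.normal(size=(25, 4))
        X = np.vstack([Xt, Xt, rng.normal(size=(50, 4)) + 8])
        T = np.r_[np.ones(25), np.zeros(75)].astype(int)
        units = units_from_arrays(X, T, np.zeros(100))
        m = mahalanobis_match(units)
        rep = balance_report(units, m)
        np.testing.assert_allclose(rep["variance_ratio_after"], 1.0, atol=1e-12)
        np.testing.assert_allclose(
            rep["mean_control_after"], rep["mean_treatment"], atol=1e-12
        )

    def test_before_columns_invariant_to_matching(self, rng):
        n = 120
        X = rng.normal(size=(n, 3))
        T = (rng.random(n) < 0.35).astype(int)
        T[0], T[-1] = 1, 0
        Y = (rng.random(n) < 0.3).astype(int)
        units = units_from_arrays(X, T, Y)
        r1 = balance_report(units, mahalanobis_match(units, caliper_sd=0.9))
        r2 = balance_report(units, mahalanobis_match(units, caliper_sd=5.0))
        before = ["mean_treatment", "mean_control_before", "variance_ratio_before"]
        pd.testing.assert_frame_equal(r1[before], r2[before])

    def test_weighted_moments_oracle(self, rng):
        n = 80
        X = rng.normal(size=(n, 2))
        T = (rng.random(n) < 0.4).astype(int)
        T[0], T[-1] = 1, 0
        units = units_from_arrays(X, T, np.zeros(n))
        m = mahalanobis_match(units)
        rep = balance_report(units, m)
        # brute-force weighted control moments
        K = np.zeros(n)
        for cset, w in zip(m.control_sets, m.weights):
            for ci, wi in zip(cset, w):
                K[ci] += wi
        for j, cov in enumerate(units.covariates):
            x = X[:, j]
            mean_w = (K * x).sum() / K.sum()
            var_w = (K * (x - mean_w) ** 2).sum() / K.sum()
            row = rep[rep["covariate"] == cov].iloc[0]
            assert row["mean_control_after"] == pytest.approx(mean_w, abs=1e-12)
            var_t = x[m.treated_index].var()
            assert row["variance_ratio_after"] == pytest.approx(var_t / var_w, abs=1e-10)

    def test_smd_improves_on_confounded_landscape(self):
        cfg = recovery_config(n_rows=60, n_cols=60)
        stack = generate_covariates(cfg, seed=11)
        fire, _ = generate_fires(stack, cfg, seed=12)
        stack.fire = fire
        units = build_unit_table(stack, forest_only=False)
        m = mahalanobis_match(units)
        before = standardized_mean_differences(units).mean()
        after = standardized_mean_differences(units, m).mean()
        assert after < before


# --------------------------------------------------------- correlation screen
class TestCorrelationScreen:
    def test_diagonal_is_one(self, rng):
        units = units_from_arrays(rng.normal(size=(50, 3)), [1] * 25 + [0] * 25, np.zeros(50))
        mat, flagged, constant = correlation_screen(units)
        np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0)
        assert constant == []

    def test_lapse_correlation_not_flagged_at_080(self, rng):
        n = 2000
        elev = rng.uniform(0, 2500, n)
        temp = 28 - 0.0065 * elev + rng.normal(0, 3.0, n)
        X = np.column_stack([elev, temp])
        T = np.r_[np.ones(n // 2), np.zeros(n - n // 2)].astype(int)
        units = units_from_arrays(X, T, np.zeros(n))
        mat, flagged, _ = correlation_screen(units, threshold=0.95)
        r = mat.loc["x0", "x1"]
        assert r < -0.6  # strongly negative but below the collinearity bar
        assert flagged == []

    def test_near_duplicate_flagged(self, rng):
        n = 200
        a = rng.normal(size=n)
        X = np.column_stack([a, a + rng.normal(0, 1e-3, n), rng.normal(size=n)])
        units = units_from_arrays(X, [1] * 100 + [0] * 100, np.zeros(n))
        _, flagged, _ = correlation_screen(units, threshold=0.95)
        assert ("x0", "x1") in {(f[0], f[1]) for f in flagged}

    def test_brute_force_pairwise_oracle(self, rng):
        n = 60
        X = rng.normal(size=(n, 4))
        units = units_from_arrays(X, [1] * 30 + [0] * 30, np.zeros(n))
        mat, _, _ = correlation_screen(units)
        for a in range(4):
            for b in range(4):
                xa, xb = X[:, a], X[:, b]
                r = ((xa - xa.mean()) * (xb - xb.mean())).mean() / (xa.std() * xb.std())
                assert mat.iloc[a, b] == pytest.approx(r, abs=1e-12)

    def test_constant_covariate_warned_and_excluded(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        units = units_from_arrays(X, [1] * 15 + [0] * 15, np.zeros(30))
        with pytest.warns(UserWarning):
            mat, _, constant = correlation_screen(units)
        assert constant == ["x0"]
        assert list(mat.columns) == ["x1"]
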