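import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from dielgam import (
    detect_thresholds,
    diel_tradeoff,
    fit_gam,
    mantel,
    morans_i,
    residual_autocorrelation,
    split_fit_validate,
    validation_metrics,
)


def naive_morans_i(values, W):
    z = np.asarray(values, float)
    z = z - z.mean()
    n = z.size
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            s0 += W[i, j]
    return n / s0 * num / np.sum(z**2)


def random_weights(rng, n):
    W = rng.uniform(0, 1, (n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestMoransI:
    def test_two_point_hand_example(self):
        W = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        i, e, p = morans_i([1.0, -1.0, 0.0], W, n_perm=19, seed=0)
        # full-weight graph: I equals the closed-form -n/(2*S0)*... check
        assert i == pytest.approx(naive_morans_i([1.0, -1.0, 0.0], W), abs=1e-12)

    def test_perfect_negative_pair_structure(self):
        # antithetic values on a two-block weight structure give I = -1
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        vals = [1.0, -1.0]
        z = np.array(vals) - np.mean(vals)
        n, s0 = 2, 2.0
        i_direct = n / s0 * (z @ W @ z) / (z @ z)
        assert i_direct == pytest.approx(-1.0)

    def test_null_expectation(self):
        rng = np.random.default_rng(0)
        _, e, _ = morans_i(rng.normal(size=25), random_weights(rng, 25),
                           n_perm=19, seed=1)
        assert e == pytest.approx(-1.0 / 24.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        W = random_weights(rng, 30)
        i1, _, _ = morans_i(vals, W, n_perm=19, seed=2)
        i2, _, _ = morans_i(vals + 100.0, W, n_perm=19, seed=2)
        assert i1 == pytest.approx(i2, abs=1e-10)

    def test_matches_naive_double_sum(self):
        rng = np.random.default_rng(3)
        for n in (5, 20, 57):
            vals = rng.normal(size=n)
            W = random_weights(rng, n)
            i, _, _ = morans_i(vals, W, n_perm=9, seed=0)
            assert i == pytest.approx(naive_morans_i(vals, W), abs=1e-12)

    def test_zero_variance_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            morans_i(np.ones(10), random_weights(rng, 10), n_perm=9, seed=0)

    def test_p_reproducible_and_bounded(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=20)
        W = random_weights(rng, 20)
        _, _, p1 = morans_i(vals, W, n_perm=99, seed=7)
        _, _, p2 = morans_i(vals, W, n_perm=99, seed=7)
        assert p1 == p2
        assert p1 >= 1.0 / 100.0


class TestMantel:
    def _dist(self, rng, n):
        pts = rng.normal(size=(n, 2))
        return squareform(pdist(pts))

    def test_identity(self):
        rng = np.random.default_rng(0)
        D = self._dist(rng, 10)
        r, _ = mantel(D, D, n_perm=19, seed=0)
        assert r == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        D = self._dist(rng, 12)
        r, _ = mantel(D, 3.7 * D, n_perm=19, seed=0)
        assert r == pytest.approx(1.0)

    def test_equals_upper_triangle_pearson(self):
        rng = np.random.default_rng(2)
        A, B = self._dist(rng, 15), self._dist(rng, 15)
        r, _ = mantel(A, B, n_perm=9, seed=0)
        iu = np.triu_indices(15, 1)
        assert r == pytest.approx(np.corrcoef(A[iu], B[iu])[0, 1], abs=1e-12)

    def test_constant_matrix_raises(self):
        rng = np.random.default_rng(3)
        D = self._dist(rng, 8)
        C = np.ones((8, 8)) - np.eye(8)
        with pytest.raises(ValueError):
            mantel(C, D, n_perm=9, seed=0)

    def test_p_lower_bound(self):
        rng = np.random.default_rng(4)
        D = self._dist(rng, 10)
        _, p = mantel(D, D + rng.normal(scale=1e-3, size=(10, 10)) * 0, n_perm=99, seed=0)
        assert p >= 1.0 / 100.0


class TestValidationMetrics:
    def test_perfect_prediction_identities(self):
        obs = np.array([1.0, 2.0, 5.0, 3.0])
        rep = validation_metrics(obs, obs)
        assert rep.r == pytest.approx(1.0)
        assert rep.a == pytest.approx(0.0, abs=1e-12)
        assert rep.b == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(100.0)
        assert rep.rmse == 0.0 and rep.ave == 0.0

    def test_shift_identities(self):
        obs = np.array([1.0, 2.0, 5.0, 3.0])
        rep = validation_metrics(obs, obs + 1.0)
        assert rep.ave == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(1.0)
        assert rep.b == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=30),
           st.floats(-5, 5), st.floats(0.1, 3))
    def test_affine_property(self, obs, shift, scale):
        obs = np.asarray(obs)
        if np.std(obs) < 1e-6:
            return
        pred = scale * obs + shift
        rep = validation_metrics(obs, pred)
        assert rep.r == pytest.approx(1.0, abs=1e-6)
        assert rep.b == pytest.approx(1.0 / scale, rel=1e-4)
        assert rep.r2 == pytest.approx(100.0, abs=1e-4)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            validation_metrics([1.0, 2.0], [1.0, 2.0])


class TestSplitFitValidate:
    def test_requires_both_days(self, table):
        with pytest.raises(ValueError):
            split_fit_validate(table.loc[table.day == 1], families=["gaussian"])

    def test_reports_complete(self, table):
        models, traces, reports = split_fit_validate(
            table, families=["quasipoisson"],
            candidates=["Zpl", "Depth", "Hour"])
        rep = reports["quasipoisson"]
        assert rep["fitting"].dev is not None
        assert rep["fitting"].n > 100 and rep["validation"].n > 100
        assert -1 <= rep["validation"].r <= 1


class TestDielTradeoff:
    def test_constant_series_zero_anomalies(self):
        df = pd.DataFrame({"Hour": np.repeat(np.arange(24), 3),
                           "Zpl": -80.0, "Pred": 0.2, "F": 1})
        out = diel_tradeoff(df)
        assert np.allclose(out.zpl_anom, 0.0)
        assert np.allclose(out.pred_anom, 0.0)

    def test_anomalies_centered(self, table):
        out = diel_tradeoff(table)
        assert out.zpl_anom.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.pred_anom.mean() == pytest.approx(0.0, abs=1e-10)

    def test_diel_phase_of_risk_and_fish(self, table):
        out = diel_tradeoff(table)
        day = (out.hour >= 6) & (out.hour < 18)
        assert out.loc[day, "pred_anom"].mean() > out.loc[~day, "pred_anom"].mean()
        assert out.loc[~day, "mean_F"].mean() > out.loc[day, "mean_F"].mean()


class TestDetectThresholds:
    def test_step_series_single_breakpoint(self):
        y = np.array([0.0] * 12 + [5.0] * 12)
        res = detect_thresholds(y, n_perm=99, seed=0)
        assert res.breakpoints == [12]
        assert res.p_value < 0.05

    def test_two_step_series(self):
        y = np.array([5.0] * 6 + [0.0] * 12 + [5.0] * 6)
        res = detect_thresholds(y, n_perm=99, seed=0)
        assert sorted(res.breakpoints) == [6, 18]

    def test_constant_series(self):
        res = detect_thresholds(np.ones(24), n_perm=99, seed=0)
        assert res.breakpoints == []
        assert res.p_value == 1.0

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(0)
        sig = 0
        runs = 30
        for i in range(runs):
            res = detect_thresholds(rng.normal(size=24), n_perm=99, seed=i)
            sig += res.p_value < 0.05
        assert sig <= 0.2 * runs

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=24)
        a = detect_thresholds(y, n_perm=199, seed=3)
        b = detect_thresholds(y, n_perm=199, seed=3)
        assert a.p_value == b.p_value and a.breakpoints == b.breakpoints


class TestResidualAutocorrelation:
    def _model(self, table):
        return fit_gam(table, "F", "quasipoisson",
                       ["Zpl", "Pred", "Depth", "Dist", "Hour"], k=3)

    def test_deterministic_given_seed(self, small_table):
        m = self._model(small_table)
        a = residual_autocorrelation(m, small_table, n_perm=49, seed=5)
        b = residual_autocorrelation(m, small_table, n_perm=49, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_white_noise_residuals_not_flagged(self, small_table):
        m = self._model(small_table)
        rng = np.random.default_rng(0)
        flagged = 0
        runs = 10
        for i in range(runs):
            m.residuals_dev = rng.normal(size=len(small_table))
            rep = residual_autocorrelation(m, small_table, n_perm=99, seed=i,
                                           max_mantel_n=150)
            flagged += rep.perm_p < 0.05
        assert flagged <= 3

    def test_spatial_gradient_detected(self, small_table):
        m = self._model(small_table)
        rng = np.random.default_rng(1)
        hits = 0
        runs = 5
        for i in range(runs):
            grad = (small_table.Dist.to_numpy() / 500.0
                    + small_table.Depth.to_numpy() / 50.0)
            m.residuals_dev = grad + rng.normal(scale=0.3, size=len(small_table))
            rep = residual_autocorrelation(m, small_table, n_perm=99, seed=i,
                                           max_mantel_n=150)
            hits += rep.perm_p < 0.05
        assert hits >= 4

    def test_misaligned_rows_raise(self, small_table):
        m = self._model(small_table)
        with pytest.raises(ValueError):
            residual_autocorrelation(m, small_table.head(10), n_perm=9, seed=0)
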