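import math

import numpy as np
import pandas as pd
import pytest

from dielgam import (
    classify_shape,
    deviance_explained,
    fit_gam,
    forward_select,
    hurdle_combine,
    partial_effect,
    predict_gam,
)
from dielgam.gam import CubicRegressionSpline, FitError, GamModel


def poisson_table(n=2000, seed=0, beta=0.5):
    rng = np.random.default_rng(seed)
    v = rng.uniform(-2, 2, n)
    lam = np.exp(1.0 + beta * v)
    return pd.DataFrame({"F": rng.poisson(lam), "V": v})


class TestSpline:
    def test_interpolates_knot_values(self):
        sp = CubicRegressionSpline([0.0, 1.0, 3.0])
        X = sp.basis(np.array([0.0, 1.0, 3.0]))
        assert np.allclose(X, np.eye(3), atol=1e-12)

    def test_penalty_annihilates_linear_functions(self):
        sp = CubicRegressionSpline([0.0, 1.0, 2.5, 4.0])
        S = sp.penalty()
        lin = np.array([1.0, 2.0, 3.5, 5.0])  # values of x+1 at the knots
        assert np.allclose(S @ lin, 0.0, atol=1e-10)

    def test_linear_extrapolation(self):
        sp = CubicRegressionSpline([0.0, 1.0, 2.0])
        beta = np.array([0.3, -0.1, 0.8])
        f = lambda x: sp.basis(np.array(x)) @ beta
        left = (f([-1.0])[0], f([-2.0])[0])
        slope_out = left[0] - left[1]
        slope_at_edge = (f([-0.9])[0] - f([-1.0])[0]) / 0.1
        assert slope_out == pytest.approx(slope_at_edge, rel=1e-8)


class TestFitGam:
    def test_intercept_only_gaussian(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 6.0]})
        m = fit_gam(df, "y", "gaussian", [])
        assert m.intercept == pytest.approx(3.0)
        assert deviance_explained(m) == pytest.approx(0.0, abs=1e-9)

    def test_poisson_slope_recovery(self):
        df = poisson_table()
        m = fit_gam(df, "F", "quasipoisson", ["V"], k=3)
        grid = np.linspace(-2, 2, 41)
        pe = partial_effect(m, "V", grid)
        truth = 0.5 * grid
        truth = truth - truth.mean()
        r = np.corrcoef(pe.effect, truth)[0, 1]
        assert r > 0.99

    def test_dome_recovery(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(-1, 1, 3000)
        lam = np.exp(1.0 - 2.0 * v**2)
        df = pd.DataFrame({"F": rng.poisson(lam), "V": v})
        m = fit_gam(df, "F", "quasipoisson", ["V"], k=3)
        pe = partial_effect(m, "V", np.linspace(-1, 1, 41))
        tag, loc = classify_shape(pe.grid, pe.effect)
        assert tag == "dome"
        assert abs(loc) < 0.3

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 1.5, 2.5], "c": [1.0] * 4})
        with pytest.raises(FitError, match="constant"):
            fit_gam(df, "y", "gaussian", ["c"])

    def test_count_family_requires_counts(self):
        df = pd.DataFrame({"F": [0.5, 1.2, 2.0, 1.0], "V": [0, 1, 2, 3.0]})
        with pytest.raises(ValueError):
            fit_gam(df, "F", "quasipoisson", ["V"])

    def test_binomial_mean_matches_observed_rate(self, table):
        m = fit_gam(table, "presence", "binomial", ["Zpl", "Depth"], k=3)
        assert m.fitted.mean() == pytest.approx(table.presence.mean(), abs=1e-6)

    def test_edf_within_bounds(self, table):
        m = fit_gam(table, "F", "quasipoisson", ["Zpl", "Depth"], k=3)
        for t in m.terms:
            assert 0.0 < t.edf <= 2.0 + 1e-8
        assert m.deviance <= m.null_deviance + 1e-8

    def test_nb_and_qp_fitted_means_agree(self, table):
        preds = ["Zpl", "Pred", "Depth", "Dist", "Hour"]
        qp = fit_gam(table, "F", "quasipoisson", preds, k=3)
        nb = fit_gam(table, "F", "negbinomial", preds, k=3)
        r = np.corrcoef(qp.fitted, nb.fitted)[0, 1]
        assert r > 0.95


class TestDevianceExplained:
    def test_trivial_bounds(self):
        df = poisson_table(400, seed=2)
        m = fit_gam(df, "F", "quasipoisson", ["V"])
        assert 0.0 <= deviance_explained(m) <= 100.0

    def test_separating_predictor_gives_full_deviance(self):
        df = pd.DataFrame({"y": [0.0, 0.0, 3.0, 3.0], "V": [0.0, 0.0, 1.0, 1.0]})
        m = fit_gam(df, "y", "gaussian", ["V"], loglams=[-8.0])
        assert deviance_explained(m) == pytest.approx(100.0, abs=1e-3)


class TestPredict:
    def test_consistency_on_training_rows(self, table):
        m = fit_gam(table, "F", "quasipoisson", ["Zpl", "Depth"], k=3)
        out = predict_gam(m, table)
        assert np.allclose(out.fit.to_numpy(), m.fitted, rtol=1e-10)

    def test_interval_ordering(self, table):
        m = fit_gam(table, "F", "quasipoisson", ["Zpl", "Depth"], k=3)
        out = predict_gam(m, table)
        assert np.all(out.lower <= out.fit + 1e-12)
        assert np.all(out.fit <= out.upper + 1e-12)

    def test_se_grows_with_extrapolation(self):
        df = poisson_table(800, seed=3)
        m = fit_gam(df, "F", "quasipoisson", ["V"], k=3)
        new = pd.DataFrame({"V": [0.0, 3.0, 6.0]})
        out = predict_gam(m, new)
        assert out.se.iloc[0] < out.se.iloc[1] < out.se.iloc[2]
        assert not out.extrapolated.iloc[0] and out.extrapolated.iloc[2]

    def test_missing_predictor_raises(self, table):
        m = fit_gam(table, "F", "quasipoisson", ["Zpl"], k=3)
        with pytest.raises(KeyError, match="Zpl"):
            predict_gam(m, table.drop(columns=["Zpl"]))


class TestPartialEffect:
    def test_sum_to_zero_over_training_values(self, table):
        m = fit_gam(table, "F", "quasipoisson", ["Zpl", "Depth"], k=3)
        eff = partial_effect(m, "Zpl", table.Zpl.to_numpy()).effect
        assert abs(eff.mean()) < 1e-8

    def test_unknown_predictor_raises(self, table):
        m = fit_gam(table, "F", "quasipoisson", ["Zpl"], k=3)
        with pytest.raises(KeyError):
            partial_effect(m, "Hour", [0, 12])


class TestHurdle:
    def _models(self, table):
        bi = fit_gam(table, "presence", "binomial", ["Zpl", "Depth"], k=3)
        pos = table.loc[table.F > 0].copy()
        pos["lnF"] = np.log(pos.F)
        ga = fit_gam(pos, "lnF", "gaussian", ["Zpl", "Depth"], k=3)
        return bi, ga

    def test_lognormal_identity(self, table):
        bi, ga = self._models(table)
        sub = table.head(20)
        out = hurdle_combine(bi, ga, sub)
        p = predict_gam(bi, sub).fit.to_numpy()
        m, _ = ga.linear_predictor(sub)
        assert np.allclose(out, p * np.exp(m) * math.exp(ga.scale / 2.0))
        assert np.allclose(out[p < 1e-12], 0.0)  # no presence, no fish

    def test_degenerate_correction(self, table):
        bi, ga = self._models(table)
        ga.scale = 0.0
        m, _ = ga.linear_predictor(table.head(5))
        p = predict_gam(bi, table.head(5)).fit.to_numpy()
        assert np.allclose(hurdle_combine(bi, ga, table.head(5)), p * np.exp(m))

    def test_smearing_close_to_lognormal(self, table):
        bi, ga = self._models(table)
        a = hurdle_combine(bi, ga, table.head(200), smearing=False)
        b = hurdle_combine(bi, ga, table.head(200), smearing=True)
        assert np.corrcoef(a, b)[0, 1] > 0.999


class TestForwardSelect:
    def test_pure_noise_keeps_intercept_only(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400
            df = pd.DataFrame({
                "F": rng.poisson(2.0, n),
                "A": rng.normal(size=n), "B": rng.normal(size=n),
                "C": rng.normal(size=n),
            })
            m, trace = forward_select(df, "F", "quasipoisson",
                                      candidates=["A", "B", "C"], k=3)
            hits += len(m.predictors) == 0
        assert hits >= 4  # type-I control: ~alpha per step

    def test_single_informative_selected_first(self):
        rng = np.random.default_rng(9)
        n = 1500
        v = rng.uniform(-2, 2, n)
        df = pd.DataFrame({
            "F": rng.poisson(np.exp(0.5 + 0.8 * v)),
            "V": v, "N1": rng.normal(size=n), "N2": rng.normal(size=n),
        })
        m, trace = forward_select(df, "F", "quasipoisson",
                                  candidates=["N1", "V", "N2"], k=3)
        assert trace.steps[0]["candidate"] == "V"
        assert "V" in m.predictors

    def test_scores_non_increasing_along_accepted_steps(self, table):
        m, trace = forward_select(table, "F", "quasipoisson", k=3)
        accepted = [s for s in trace.steps if s["accepted"]]
        for s in accepted:
            assert s["score_after"] <= s["score_before"] + 1e-9

    def test_trace_frame_schema(self, table):
        _, trace = forward_select(table, "presence", "binomial",
                                  candidates=["Zpl", "Temp"], k=3)
        df = trace.to_frame()
        assert {"step", "candidate", "score_before", "score_after",
                "lrt_p", "accepted"} <= set(df.columns)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, table):
        m = fit_gam(table, "F", "quasipoisson", ["Zpl", "Depth", "Hour"], k=3)
        m2 = GamModel.from_json(m.to_json())
        new = table.sample(50, random_state=0)
        a = predict_gam(m, new)
        b = predict_gam(m2, new)
        assert np.allclose(a.fit, b.fit, atol=0, rtol=0)
        assert np.allclose(a.se, b.se)


class TestClassifyShape:
    @pytest.mark.parametrize("vals,expected", [
        (np.linspace(0, 1, 50), "increasing"),
        (np.linspace(1, 0, 50), "decreasing"),
        (-((np.linspace(-1, 1, 50)) ** 2), "dome"),
        ((np.linspace(-1, 1, 50)) ** 2, "ushape"),
        (np.zeros(50), "flat"),
    ])
    def test_canonical_shapes(self, vals, expected):
        tag, _ = classify_shape(np.linspace(0, 1, 50), vals)
        assert tag == expected

    def test_small_wiggle_does_not_flip_monotone(self, rng):
        g = np.linspace(0, 1, 80)
        v = g + 0.01 * np.sin(40 * g)
        tag, _ = classify_shape(g, v)
        assert tag == "increasing"

    def test_extremum_location(self):
        g = np.linspace(0, 100, 101)
        v = -((g - 40.0) ** 2)
        tag, loc = classify_shape(g, v)
        assert tag == "dome" and loc == pytest.approx(40.0, abs=1.0)
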