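"""Penalized-spline GAM ensemble for zero-inflated fish counts.

Implements the four-family ensemble — quasi-Poisson and negative
binomial on counts, binomial on presence/absence, Gaussian on the log
abundance of presence rows — with natural cubic regression spline
smooths of basis dimension ``k`` (default 3), quadratic curvature
penalties, sum-to-zero identifiability constraints, smoothing-parameter
choice by GCV (scale unknown) or UBRE (scale fixed), forward predictor
selection combining score decrease with likelihood-ratio acceptance,
response-scale prediction intervals and centered partial-effect curves.

The smoother is a classical value-parameterized natural cubic spline on
``k`` knots with the integrated-squared-second-derivative penalty
``S = D' B^{-1} D``; outside the knot range the basis extrapolates
linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve, null_space

__all__ = [
    "CubicRegressionSpline",
    "SmoothTerm",
    "GamModel",
    "SelectionTrace",
    "FitError",
    "fit_gam",
    "forward_select",
    "deviance_explained",
    "predict_gam",
    "partial_effect",
    "hurdle_combine",
    "classify_shape",
]

_Z975 = 1.959963984540054


class FitError(RuntimeError):
    """Raised when a family fit cannot converge or is degenerate."""


# ---------------------------------------------------------------------------
# spline basis


class CubicRegressionSpline:
    """Natural cubic regression spline on fixed knots.

    Coefficients are the function values at the knots; second
    derivatives at interior knots follow from the natural-spline
    conditions, giving the curvature penalty ``D' B^{-1} D``.
    """

    def __init__(self, knots: Sequence[float]):
        knots = np.asarray(sorted(knots), dtype=float)
        if knots.size < 3:
            raise ValueError("need at least 3 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        k = knots.size
        h = np.diff(knots)
        D = np.zeros((k - 2, k))
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        F = np.linalg.solve(B, D)
        self._Fm = np.zeros((k, k))
        self._Fm[1:-1, :] = F  # second derivatives: m = Fm @ beta (m_1 = m_k = 0)
        self._S = D.T @ F
        self._h = h

    @property
    def k(self) -> int:
        return self.knots.size

    def penalty(self) -> np.ndarray:
        return self._S.copy()

    def basis(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        kn, h, Fm = self.knots, self._h, self._Fm
        k = kn.size
        X = np.zeros((x.size, k))

        inside = (x >= kn[0]) & (x <= kn[-1])
        xi = x[inside]
        j = np.clip(np.searchsorted(kn, xi, side="right") - 1, 0, k - 2)
        hj = h[j]
        am = (kn[j + 1] - xi) / hj
        ap = (xi - kn[j]) / hj
        cm = ((kn[j + 1] - xi) ** 3 / hj - hj * (kn[j + 1] - xi)) / 6.0
        cp = ((xi - kn[j]) ** 3 / hj - hj * (xi - kn[j])) / 6.0
        rows = np.zeros((xi.size, k))
        rows[np.arange(xi.size), j] += am
        rows[np.arange(xi.size), j + 1] += ap
        rows += cm[:, None] * Fm[j] + cp[:, None] * Fm[j + 1]
        X[inside] = rows

        below = x < kn[0]
        if below.any():
            # linear extrapolation with the boundary slope
            slope = np.zeros(k)
            slope[0] -= 1.0 / h[0]
            slope[1] += 1.0 / h[0]
            slope -= h[0] / 6.0 * Fm[1]
            base = np.zeros(k)
            base[0] = 1.0
            X[below] = base + (x[below] - kn[0])[:, None] * slope
        above = x > kn[-1]
        if above.any():
            slope = np.zeros(k)
            slope[-2] -= 1.0 / h[-1]
            slope[-1] += 1.0 / h[-1]
            slope += h[-1] / 6.0 * Fm[-2]
            base = np.zeros(k)
            base[-1] = 1.0
            X[above] = base + (x[above] - kn[-1])[:, None] * slope
        return X


def _choose_knots(x: np.ndarray, k: int) -> np.ndarray:
    qs = np.quantile(np.unique(x), np.linspace(0, 1, k))
    if np.any(np.diff(qs) <= 0):  # heavy ties: fall back to even spacing
        qs = np.linspace(float(np.min(x)), float(np.max(x)), k)
    if np.any(np.diff(qs) <= 0):
        raise FitError("predictor has (near-)constant values; cannot place knots")
    return qs


# ---------------------------------------------------------------------------
# families


class _Family:
    name: str
    score_kind: str  # "gcv" (scale unknown) or "ubre" (scale fixed)

    def link(self, mu): ...
    def inverse(self, eta): ...
    def dmu_deta(self, eta): ...
    def variance(self, mu): ...
    def deviance(self, y, mu): ...
    def initialize(self, y): ...


class _QuasiPoisson(_Family):
    name, score_kind = "quasipoisson", "gcv"

    def link(self, mu):
        return np.log(mu)

    def inverse(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def dmu_deta(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def variance(self, mu):
        return mu

    def deviance(self, y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))

    def initialize(self, y):
        return np.maximum(y, 0) + 0.5


class _NegBinomial(_Family):
    score_kind = "ubre"

    def __init__(self, theta: float = 1.0):
        self.theta = float(theta)
        self.name = "negbinomial"

    def link(self, mu):
        return np.log(mu)

    def inverse(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def dmu_deta(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def variance(self, mu):
        return mu + mu**2 / self.theta

    def deviance(self, y, mu):
        th = self.theta
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + th) * np.log((y + th) / (mu + th))
        return float(2.0 * np.sum(t1 - t2))

    def loglik(self, y, mu):
        th = self.theta
        return float(np.sum(
            special.gammaln(y + th) - special.gammaln(th) - special.gammaln(y + 1)
            + th * np.log(th / (th + mu)) + y * np.log(mu / (th + mu))
        ))

    def initialize(self, y):
        return np.maximum(y, 0) + 0.5


class _Binomial(_Family):
    name, score_kind = "binomial", "ubre"

    def link(self, mu):
        return np.log(mu / (1 - mu))

    def inverse(self, eta):
        return special.expit(eta)

    def dmu_deta(self, eta):
        p = special.expit(eta)
        return p * (1 - p)

    def variance(self, mu):
        return mu * (1 - mu)

    def deviance(self, y, mu):
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t0 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return float(2.0 * np.sum(t1 + t0))

    def initialize(self, y):
        return (y + 0.5) / 2.0


class _Gaussian(_Family):
    name, score_kind = "gaussian", "gcv"

    def link(self, mu):
        return mu

    def inverse(self, eta):
        return eta

    def dmu_deta(self, eta):
        return np.ones_like(eta)

    def variance(self, mu):
        return np.ones_like(mu)

    def deviance(self, y, mu):
        return float(np.sum((y - mu) ** 2))

    def initialize(self, y):
        return y.astype(float)


def _make_family(name: str, theta: float | None = None) -> _Family:
    if name == "quasipoisson":
        return _QuasiPoisson()
    if name == "negbinomial":
        return _NegBinomial(theta if theta is not None else 1.0)
    if name == "binomial":
        return _Binomial()
    if name == "gaussian":
        return _Gaussian()
    raise ValueError(f"unknown family {name!r}")


# ---------------------------------------------------------------------------
# model containers


@dataclass
class SmoothTerm:
    """One fitted smooth: constrained spline block of a GAM."""

    predictor: str
    spline: CubicRegressionSpline
    Z: np.ndarray              # (k, k-1) sum-to-zero reparameterization
    sl: slice                  # columns of this block in the model matrix
    lam: float = 0.0
    edf: float = 0.0
    data_range: tuple[float, float] = (0.0, 1.0)

    def design(self, x) -> np.ndarray:
        return self.spline.basis(x) @ self.Z

    def penalty(self) -> np.ndarray:
        return self.Z.T @ self.spline.penalty() @ self.Z


@dataclass
class GamModel:
    """Fitted ensemble member."""

    family: str
    response: str
    beta: np.ndarray
    cov: np.ndarray
    terms: list[SmoothTerm]
    scale: float
    theta: float | None
    null_deviance: float
    deviance: float
    edf: float
    score: float
    score_name: str
    n: int
    fitted: np.ndarray
    residuals_dev: np.ndarray
    y: np.ndarray

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def predictors(self) -> list[str]:
        return [t.predictor for t in self.terms]

    def design_matrix(self, table: pd.DataFrame) -> np.ndarray:
        n = len(table)
        X = np.ones((n, 1 + sum(t.Z.shape[1] for t in self.terms)))
        for t in self.terms:
            if t.predictor not in table.columns:
                raise KeyError(f"predictor {t.predictor!r} missing from new data")
            X[:, t.sl] = t.design(table[t.predictor].to_numpy(dtype=float))
        return X

    def linear_predictor(self, table: pd.DataFrame):
        X = self.design_matrix(table)
        eta = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return eta, se

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "response": self.response,
            "intercept": self.intercept,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "scale": self.scale,
            "theta": self.theta,
            "null_deviance": self.null_deviance,
            "deviance": self.deviance,
            "edf": self.edf,
            "score": self.score,
            "score_name": self.score_name,
            "n": self.n,
            "terms": [
                {
                    "predictor": t.predictor,
                    "knots": t.spline.knots.tolist(),
                    "Z": t.Z.tolist(),
                    "columns": [t.sl.start, t.sl.stop],
                    "lambda": t.lam,
                    "edf": t.edf,
                    "data_range": list(t.data_range),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_json(cls, d: dict) -> "GamModel":
        terms = [
            SmoothTerm(
                predictor=t["predictor"],
                spline=CubicRegressionSpline(t["knots"]),
                Z=np.asarray(t["Z"]),
                sl=slice(t["columns"][0], t["columns"][1]),
                lam=t["lambda"],
                edf=t["edf"],
                data_range=tuple(t["data_range"]),
            )
            for t in d["terms"]
        ]
        return cls(
            family=d["family"], response=d["response"],
            beta=np.asarray(d["beta"]), cov=np.asarray(d["cov"]), terms=terms,
            scale=d["scale"], theta=d["theta"], null_deviance=d["null_deviance"],
            deviance=d["deviance"], edf=d["edf"], score=d["score"],
            score_name=d["score_name"], n=d["n"],
            fitted=np.array([]), residuals_dev=np.array([]), y=np.array([]),
        )


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)
    final_predictors: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


# ---------------------------------------------------------------------------
# fitting machinery


def _response_vector(table: pd.DataFrame, response: str, family: str) -> np.ndarray:
    y = table[response].to_numpy(dtype=float)
    if family in ("quasipoisson", "negbinomial"):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("count family requires non-negative integer response")
    elif family == "binomial":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("binomial family requires a 0/1 response")
    return y


def _pirls(X: np.ndarray, S: np.ndarray, y: np.ndarray, fam: _Family,
           max_iter: int = 100, tol: float = 1e-9):
    """Penalized IRLS.  Returns (beta, mu, eta, dev, edf, edf_diag, XtWX_chol)."""
    mu = fam.initialize(y)
    eta = fam.link(np.clip(mu, 1e-8, None) if fam.name != "gaussian" else mu)
    if fam.name == "binomial":
        mu = np.clip(mu, 1e-6, 1 - 1e-6)
        eta = fam.link(mu)
    dev = fam.deviance(y, fam.inverse(eta) if fam.name != "gaussian" else eta)
    beta = None
    for _ in range(max_iter):
        dmu = fam.dmu_deta(eta)
        var = fam.variance(mu)
        w = dmu**2 / np.maximum(var, 1e-12)
        z = eta + (y - mu) / np.maximum(dmu, 1e-12)
        WX = X * w[:, None]
        A = X.T @ WX + S
        b = WX.T @ z
        try:
            c, low = cho_factor(A)
        except np.linalg.LinAlgError:
            c, low = cho_factor(A + 1e-8 * np.eye(A.shape[0]))
        beta_new = cho_solve((c, low), b)
        eta = X @ beta_new
        mu = fam.inverse(eta)
        if fam.name == "binomial":
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
        dev_new = fam.deviance(y, mu)
        done = abs(dev_new - dev) < tol * (abs(dev_new) + 0.1)
        beta, dev = beta_new, dev_new
        if done:
            break
    else:
        raise FitError(f"{fam.name} PIRLS failed to converge (deviance {dev:.4g})")
    XtWX = X.T @ (X * (fam.dmu_deta(eta) ** 2 / np.maximum(fam.variance(mu), 1e-12))[:, None])
    A = XtWX + S
    try:
        c, low = cho_factor(A)
    except np.linalg.LinAlgError:
        c, low = cho_factor(A + 1e-8 * np.eye(A.shape[0]))
    H = cho_solve((c, low), XtWX)  # influence: edf per column on the diagonal
    edf_diag = np.diag(H).copy()
    Ainv = cho_solve((c, low), np.eye(A.shape[0]))
    return beta, mu, eta, dev, float(np.sum(edf_diag)), edf_diag, Ainv


def _score(dev: float, n: int, edf: float, kind: str, phi: float = 1.0) -> float:
    if kind == "gcv":
        return n * dev / (n - edf) ** 2
    return dev / n + 2.0 * phi * edf / n - phi


def _pearson_scale(y, mu, fam: _Family, n: int, edf: float) -> float:
    resid2 = (y - mu) ** 2 / np.maximum(fam.variance(mu), 1e-12)
    return float(np.sum(resid2) / max(n - edf, 1.0))


def _build_terms(table: pd.DataFrame, predictors: Sequence[str], k: int):
    terms, col = [], 1
    for name in predictors:
        x = table[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"predictor {name!r} has non-finite values")
        if np.std(x) < 1e-12:
            raise FitError(f"predictor {name!r} is constant")
        spline = CubicRegressionSpline(_choose_knots(x, k))
        colsum = spline.basis(x).sum(axis=0, keepdims=True)
        Z = null_space(colsum)
        if Z.shape[1] != spline.k - 1:
            raise FitError(f"constraint failure for predictor {name!r}")
        terms.append(SmoothTerm(
            predictor=name, spline=spline, Z=Z,
            sl=slice(col, col + Z.shape[1]),
            data_range=(float(np.min(x)), float(np.max(x))),
        ))
        col += Z.shape[1]
    return terms, col


def _assemble(table: pd.DataFrame, terms: list[SmoothTerm], ncol: int):
    X = np.ones((len(table), ncol))
    for t in terms:
        X[:, t.sl] = t.design(table[t.predictor].to_numpy(dtype=float))
    return X


def _penalty_matrix(terms: list[SmoothTerm], ncol: int, loglams: np.ndarray) -> np.ndarray:
    S = np.zeros((ncol, ncol))
    for t, ll in zip(terms, loglams):
        S[t.sl, t.sl] += 10.0 ** np.clip(ll, -8.0, 10.0) * t.penalty()
    return S


def fit_gam(table: pd.DataFrame, response: str, family: str,
            predictors: Sequence[str], k: int = 3,
            theta: float | None = None,
            loglams: Sequence[float] | None = None,
            optimize_lambda: bool = True) -> GamModel:
    """Fit one penalized GAM.

    Smoothing parameters minimize GCV (quasi-Poisson, Gaussian) or UBRE
    (binomial; negative binomial after profiling theta).  ``response``
    names a column of ``table``; for the Gaussian presence model pass a
    pre-computed ln(F) column restricted to presence rows.
    """
    y = _response_vector(table, response, family)
    n = len(y)
    terms, ncol = _build_terms(table, predictors, k)
    if n <= ncol:
        raise FitError(f"n={n} too small for {ncol} coefficients")
    X = _assemble(table, terms, ncol)

    if family == "negbinomial" and theta is None:
        theta = _profile_theta(X, terms, ncol, y)
    fam = _make_family(family, theta)

    def fit_at(lls: np.ndarray):
        S = _penalty_matrix(terms, ncol, lls)
        return _pirls(X, S, y, fam)

    p = len(terms)
    if p == 0:
        lls = np.array([])
    elif loglams is not None:
        lls = np.asarray(loglams, dtype=float)
    elif not optimize_lambda:
        lls = np.zeros(p)
    else:
        def objective(lls_raw):
            lls_c = np.clip(lls_raw, -8.0, 10.0)
            try:
                _, mu_, _, dev_, edf_, _, _ = fit_at(lls_c)
            except FitError:
                return 1e12
            if fam.score_kind == "gcv":
                return _score(dev_, n, edf_, "gcv")
            return _score(dev_, n, edf_, "ubre")

        x0 = np.zeros(p)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 0.05, "fatol": 1e-8,
                                         "maxiter": 120 * max(p, 1)})
        lls = np.clip(res.x, -8.0, 10.0)

    beta, mu, eta, dev, edf, edf_diag, Ainv = fit_at(lls)
    for t, ll in zip(terms, lls):
        t.lam = float(10.0**ll)
        t.edf = float(np.sum(edf_diag[t.sl]))

    if fam.score_kind == "gcv":
        phi = _pearson_scale(y, mu, fam, n, edf)
        score = _score(dev, n, edf, "gcv")
        score_name = "GCV"
    else:
        phi = 1.0
        score = _score(dev, n, edf, "ubre")
        score_name = "UBRE"
    if family == "gaussian":
        phi = dev / max(n - edf, 1.0)

    null_dev = _null_deviance(y, fam)
    sign = np.sign(y - mu)
    dev_i = _pointwise_deviance(y, mu, fam)
    resid_dev = sign * np.sqrt(np.maximum(dev_i, 0.0))

    return GamModel(
        family=family, response=response, beta=beta, cov=phi * Ainv, terms=terms,
        scale=phi, theta=theta, null_deviance=null_dev, deviance=dev, edf=edf,
        score=score, score_name=score_name, n=n, fitted=mu,
        residuals_dev=resid_dev, y=y,
    )


def _pointwise_deviance(y, mu, fam: _Family) -> np.ndarray:
    if fam.name == "gaussian":
        return (y - mu) ** 2
    if fam.name == "quasipoisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * (term - (y - mu))
    if fam.name == "negbinomial":
        th = fam.theta
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * (t1 - (y + th) * np.log((y + th) / (mu + th)))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t0 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return 2.0 * (t1 + t0)


def _null_deviance(y: np.ndarray, fam: _Family) -> float:
    mu0 = np.full_like(y, float(np.mean(y)), dtype=float)
    if fam.name == "binomial":
        mu0 = np.clip(mu0, 1e-12, 1 - 1e-12)
    return fam.deviance(y, mu0)


def _profile_theta(X, terms, ncol, y) -> float:
    """Outer 1-D profile of the negative-binomial size parameter at unit
    smoothing penalties; theta is then held fixed for the UBRE fit."""
    S = _penalty_matrix(terms, ncol, np.zeros(len(terms)))

    def neg_loglik(log_th):
        fam = _NegBinomial(math.exp(log_th))
        try:
            _, mu, _, _, _, _, _ = _pirls(X, S, y, fam)
        except FitError:
            return 1e12
        return -fam.loglik(np.maximum(y, 0), np.maximum(mu, 1e-10))

    res = optimize.minimize_scalar(neg_loglik, bounds=(math.log(0.05), math.log(5e3)),
                                   method="bounded", options={"xatol": 0.02})
    return float(math.exp(res.x))


def deviance_explained(model: GamModel) -> float:
    """Percentage of null deviance removed by the model."""
    if model.null_deviance <= 0:
        return float("nan")
    return 100.0 * (model.null_deviance - model.deviance) / model.null_deviance


def predict_gam(model: GamModel, new_rows: pd.DataFrame, level: float = 0.95):
    """Response-scale predictions with link-scale Wald intervals.

    Returns a DataFrame with columns fit, se, lower, upper and an
    ``extrapolated`` flag for rows outside the fitted predictor ranges.
    """
    eta, se = model.linear_predictor(new_rows)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    fam = _make_family(model.family, model.theta)
    fit = fam.inverse(eta)
    lower = fam.inverse(eta - zq * se)
    upper = fam.inverse(eta + zq * se)
    extrap = np.zeros(len(new_rows), dtype=bool)
    for t in model.terms:
        x = new_rows[t.predictor].to_numpy(dtype=float)
        lo, hi = t.data_range
        extrap |= (x < lo) | (x > hi)
    return pd.DataFrame({"fit": fit, "se": se, "lower": lower, "upper": upper,
                         "extrapolated": extrap})


def partial_effect(model: GamModel, predictor: str, grid) -> pd.DataFrame:
    """Centered link-scale smooth of one predictor with pointwise SE."""
    for t in model.terms:
        if t.predictor == predictor:
            Xg = t.design(np.asarray(grid, dtype=float))
            block = model.cov[t.sl, t.sl]
            eff = Xg @ model.beta[t.sl]
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, block, Xg), 0.0))
            return pd.DataFrame({"grid": np.asarray(grid, dtype=float),
                                 "effect": eff, "se": se})
    raise KeyError(f"predictor {predictor!r} not in model")


def hurdle_combine(binomial_model: GamModel, gaussian_model: GamModel,
                   new_rows: pd.DataFrame, smearing: bool = False) -> np.ndarray:
    """Delta-model expectation: presence probability times the
    conditional mean back-transformed from the log scale.

    Uses the log-normal correction exp(m + sigma^2/2), or Duan's
    smearing factor when ``smearing`` is set.
    """
    p = predict_gam(binomial_model, new_rows)["fit"].to_numpy()
    m, _ = gaussian_model.linear_predictor(new_rows)
    if smearing:
        if gaussian_model.y.size == 0:
            raise ValueError("smearing requires the fitted training residuals")
        factor = float(np.mean(np.exp(gaussian_model.y - gaussian_model.fitted)))
    else:
        factor = math.exp(gaussian_model.scale / 2.0)
    return p * np.exp(m) * factor


# ---------------------------------------------------------------------------
# forward selection


def _lrt(dev_small: float, dev_big: float, edf_small: float, edf_big: float,
         n: int, family: str, phi_big: float) -> tuple[float, float, float]:
    """Deviance-based test for the added term.

    Quasi-likelihood and Gaussian families use the F form scaled by the
    larger model's dispersion; binomial and negative binomial use the
    chi-square form.  The df is the edf change rounded to nearest 0.5.
    """
    d_dev = max(dev_small - dev_big, 0.0)
    d_df = max(round(2.0 * (edf_big - edf_small)) / 2.0, 0.5)
    if family in ("quasipoisson", "gaussian"):
        fstat = (d_dev / d_df) / max(phi_big, 1e-12)
        p = float(stats.f.sf(fstat, d_df, max(n - edf_big, 1.0)))
        return fstat, d_df, p
    chi2 = d_dev
    p = float(stats.chi2.sf(chi2, d_df))
    return chi2, d_df, p


def forward_select(table: pd.DataFrame, response: str, family: str,
                   candidates: Sequence[str] = ("Zpl", "Pred", "Depth", "Dist", "Hour", "Temp"),
                   k: int = 3, alpha: float = 0.05) -> tuple[GamModel, SelectionTrace]:
    """Stepwise forward selection by score decrease plus LRT acceptance.

    Starting from the intercept-only model, each step adds the candidate
    with the largest GCV/UBRE decrease, accepted only when the score
    decreases and the deviance test of the added term has p < alpha.
    Ties follow candidate order.  During the scan only the new term's
    smoothing parameter is optimized (existing ones are held); the
    accepted model is refitted with a joint optimization.
    """
    current = fit_gam(table, response, family, [], k=k)
    theta = current.theta
    trace = SelectionTrace()
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        best = None
        for cand in remaining:
            held = [t2 for t2 in current.terms]
            lls0 = [math.log10(max(t2.lam, 1e-8)) for t2 in held]
            try:
                cand_model = _fit_add_term(table, response, family, current.predictors,
                                           cand, k, lls0, theta)
            except FitError:
                continue
            if best is None or cand_model.score < best[1].score - 1e-12:
                best = (cand, cand_model)
        if best is None:
            break
        cand, cand_model = best
        stat, d_df, p = _lrt(current.deviance, cand_model.deviance, current.edf,
                             cand_model.edf, cand_model.n, family, cand_model.scale)
        accepted = (cand_model.score < current.score - 1e-12) and (p < alpha)
        trace.steps.append({
            "step": step, "candidate": cand, "score_before": current.score,
            "score_after": cand_model.score, "lrt_stat": stat, "lrt_df": d_df,
            "lrt_p": p, "accepted": bool(accepted),
        })
        if not accepted:
            break
        # joint refit of all smoothing parameters for the accepted model
        current = fit_gam(table, response, family, current.predictors + [cand],
                          k=k, theta=theta)
        if theta is None:
            theta = current.theta
        remaining.remove(cand)
    trace.final_predictors = current.predictors
    return current, trace


def _fit_add_term(table, response, family, base_predictors, cand, k, base_loglams, theta):
    """Fit base + candidate, optimizing only the candidate's lambda."""
    predictors = list(base_predictors) + [cand]

    y = _response_vector(table, response, family)
    n = len(y)
    terms, ncol = _build_terms(table, predictors, k)
    if n <= ncol:
        raise FitError("too few rows")
    X = _assemble(table, terms, ncol)
    if family == "negbinomial" and theta is None:
        theta = _profile_theta(X, terms, ncol, y)
    fam = _make_family(family, theta)

    def score_at(ll_new: float) -> float:
        lls = np.array(list(base_loglams) + [ll_new])
        S = _penalty_matrix(terms, ncol, lls)
        try:
            _, mu, _, dev, edf, _, _ = _pirls(X, S, y, fam)
        except FitError:
            return 1e12
        return _score(dev, n, edf, fam.score_kind)

    res = optimize.minimize_scalar(score_at, bounds=(-8.0, 10.0), method="bounded",
                                   options={"xatol": 0.1})
    lls = list(base_loglams) + [float(res.x)]
    return fit_gam(table, response, family, predictors, k=k, theta=theta, loglams=lls)


# ---------------------------------------------------------------------------
# shape classification


def classify_shape(grid, values, rel_tol: float = 0.08) -> tuple[str, float]:
    """Classify a curve as flat / increasing / decreasing / dome / ushape.

    Returns ``(tag, extremum_location)``.  The tolerance is relative to
    the curve's total range, so small wiggles do not flip the class.
    """
    g = np.asarray(grid, dtype=float)
    v = np.asarray(values, dtype=float)
    rng = float(np.max(v) - np.min(v))
    if rng < 1e-10:
        return "flat", float(g[len(g) // 2])
    tol = rel_tol * rng
    # largest rise/drop over any ordered pair, so grid spacing cannot
    # hide a trend below a per-step tolerance
    max_drop = float(np.max(np.maximum.accumulate(v) - v))
    max_rise = float(np.max(v - np.minimum.accumulate(v)))
    if max_drop <= tol:
        return "increasing", float(g[-1])
    if max_rise <= tol:
        return "decreasing", float(g[0])
    imax, imin = int(np.argmax(v)), int(np.argmin(v))
    max_interior = 0 < imax < len(v) - 1
    min_interior = 0 < imin < len(v) - 1
    dome_depth = min(v[imax] - v[0], v[imax] - v[-1]) if max_interior else -np.inf
    u_depth = min(v[0] - v[imin], v[-1] - v[imin]) if min_interior else -np.inf
    if dome_depth >= u_depth and dome_depth > tol:
        return "dome", float(g[imax])
    if u_depth > tol:
        return "ushape", float(g[imin])
    return ("increasing", float(g[-1])) if v[-1] >= v[0] else ("decreasing", float(g[0]))
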