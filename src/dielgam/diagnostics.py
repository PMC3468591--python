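"""Residual autocorrelation diagnostics, split-sample validation and the
diel trade-off summary.

Moran's I and the Mantel test are implemented directly (centered
double-sum and upper-triangle correlation) with seeded permutation
p-values; validation metrics follow the observed-vs-predicted regression
convention (ideal a = 0, b = 1) and AVE = mean(predicted - observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .gam import GamModel, deviance_explained, fit_gam, forward_select, predict_gam

__all__ = [
    "ValidationReport",
    "AutocorrReport",
    "morans_i",
    "mantel",
    "residual_autocorrelation",
    "validation_metrics",
    "split_fit_validate",
    "diel_tradeoff",
    "detect_thresholds",
    "ThresholdResult",
]


# ---------------------------------------------------------------------------
# spatial statistics


def morans_i(values, weights, n_perm: int = 999, seed: int = 0,
             two_sided: bool = True):
    """Moran's I with a permutation p-value.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z centered and
    S0 the total weight.  The p-value uses ``n_perm`` random
    relabelings with the +1 correction; two-sided by default around the
    null expectation -1/(n-1).
    """
    z = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if W.shape != (n, n) or np.any(W < 0) or np.any(np.diag(W) != 0):
        raise ValueError("weights must be a non-negative matrix with zero diagonal")
    s0 = W.sum()
    if s0 <= 0:
        raise ValueError("weights sum to zero")
    z = z - z.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValueError("zero variance in values")
    i_obs = float(n / s0 * (z @ W @ z) / denom)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        i_p = float(n / s0 * (zp @ W @ zp) / denom)
        if two_sided:
            count += abs(i_p - expected) >= abs(i_obs - expected) - 1e-15
        else:
            count += i_p >= i_obs - 1e-15
    p = (count + 1) / (n_perm + 1)
    return i_obs, expected, float(p)


def mantel(dist_a, dist_b, n_perm: int = 999, seed: int = 0):
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; the p-value
    comes from simultaneous row/column permutations of the second
    matrix (one-sided, upper tail, +1 correction).
    """
    A = np.asarray(dist_a, dtype=float)
    B = np.asarray(dist_b, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or B.shape != (n, n) or n < 4:
        raise ValueError("need two square matrices of size >= 4")
    for M in (A, B):
        if not np.allclose(M, M.T) or np.any(np.diag(M) != 0):
            raise ValueError("matrices must be symmetric with zero diagonal")
    iu = np.triu_indices(n, 1)
    a, b = A[iu], B[iu]
    if np.std(a) < 1e-15 or np.std(b) < 1e-15:
        raise ValueError("constant distance matrix")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][iu]
        count += np.corrcoef(a, bp)[0, 1] >= r_obs - 1e-15
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


@dataclass
class AutocorrReport:
    morans_i: float
    expected: float
    perm_p: float
    mantel_r: float
    mantel_p: float
    skewness: float
    kurtosis: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("morans_i", "expected", "perm_p", "mantel_r", "mantel_p",
                 "skewness", "kurtosis", "n_perm", "seed")}


def _hourly_moran(resid: np.ndarray, coords: np.ndarray, groups: np.ndarray):
    """Average within-hour Moran's I and the per-group machinery needed
    to recompute the averaged statistic under global permutation."""
    infos = []
    for gval in np.unique(groups):
        idx = np.where(groups == gval)[0]
        if idx.size < 3:
            continue
        d = squareform(pdist(coords[idx]))
        with np.errstate(divide="ignore"):
            W = np.where(d > 0, 1.0 / d, 0.0)
        np.fill_diagonal(W, 0.0)
        if W.sum() <= 0:
            continue
        infos.append((idx, W, W.sum()))
    if not infos:
        raise ValueError("no hour group large enough for Moran's I")

    def stat(values: np.ndarray) -> float:
        acc = []
        for idx, W, s0 in infos:
            z = values[idx] - values[idx].mean()
            denom = float(z @ z)
            if denom <= 0:
                continue
            acc.append(idx.size / s0 * (z @ W @ z) / denom)
        return float(np.mean(acc)) if acc else 0.0

    exp_vals = [-1.0 / (idx.size - 1) for idx, _, _ in infos]
    return stat, float(np.mean(exp_vals))


def residual_autocorrelation(model: GamModel, table: pd.DataFrame,
                             n_perm: int = 999, seed: int = 0,
                             max_mantel_n: int = 300) -> AutocorrReport:
    """Spatio-temporal autocorrelation checks on deviance residuals.

    Moran's I uses inverse-Euclidean weights over (Dist, Depth) within
    each (day, hour) group, averaged across groups; the permutation
    null permutes residuals globally.  The Mantel test compares the
    residual-difference matrix with the Euclidean distance over
    standardized (Dist, Depth, Hour), on a seeded subsample capped at
    ``max_mantel_n`` rows.  Skewness and excess kurtosis serve as the
    normality check.
    """
    resid = np.asarray(model.residuals_dev, dtype=float)
    if resid.size != len(table):
        raise ValueError("residuals not aligned with table rows")
    rng = np.random.default_rng(seed)

    coords = table[["Dist", "Depth"]].to_numpy(dtype=float)
    groups = (table["day"].to_numpy() * 100 + table["Hour"].to_numpy()
              if "day" in table.columns else table["Hour"].to_numpy())
    stat, expected = _hourly_moran(resid, coords, groups)
    i_obs = stat(resid)
    count = 0
    for _ in range(n_perm):
        i_p = stat(rng.permutation(resid))
        count += abs(i_p - expected) >= abs(i_obs - expected) - 1e-15
    moran_p = (count + 1) / (n_perm + 1)

    idx = np.arange(len(table))
    if idx.size > max_mantel_n:
        idx = np.sort(rng.choice(idx, size=max_mantel_n, replace=False))
    st = table.iloc[idx][["Dist", "Depth", "Hour"]].to_numpy(dtype=float)
    st = (st - st.mean(axis=0)) / np.where(st.std(axis=0) > 0, st.std(axis=0), 1.0)
    d_space = squareform(pdist(st))
    d_resid = np.abs(resid[idx][:, None] - resid[idx][None, :])
    np.fill_diagonal(d_resid, 0.0)
    m_r, m_p = mantel(d_resid, d_space, n_perm=n_perm,
                      seed=int(rng.integers(2**31 - 1)))

    return AutocorrReport(
        morans_i=i_obs, expected=expected, perm_p=float(moran_p),
        mantel_r=m_r, mantel_p=m_p,
        skewness=float(stats.skew(resid)), kurtosis=float(stats.kurtosis(resid)),
        n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# validation metrics


@dataclass
class ValidationReport:
    phase: str
    r: float
    a: float
    b: float
    r2: float
    rmse: float
    ave: float
    n: int
    dev: float | None = None

    def to_dict(self) -> dict:
        d = {"phase": self.phase, "r": self.r, "a": self.a, "b": self.b,
             "r2": self.r2, "RMSE": self.rmse, "AVE": self.ave, "n": self.n}
        if self.dev is not None:
            d["DEV"] = self.dev
        return d


def validation_metrics(observed, predicted, phase: str = "validation",
                       dev: float | None = None) -> ValidationReport:
    """Observed-vs-predicted metric block.

    r is the Pearson correlation; (a, b) is the least-squares fit of
    observed = a + b * predicted; r2 = 100 r^2;
    RMSE = sqrt(mean((pred - obs)^2)); AVE = mean(pred - obs).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n <= 2:
        raise ValueError("need more than 2 paired values")
    err = pred - obs
    if np.std(pred) < 1e-14 or np.std(obs) < 1e-14:
        r = 0.0 if np.std(pred) >= 1e-14 or np.std(obs) >= 1e-14 else 1.0
        b = 0.0
        a = float(np.mean(obs))
        if np.allclose(pred, obs):
            r, a, b = 1.0, 0.0, 1.0
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
        b, a = np.polyfit(pred, obs, 1)
    return ValidationReport(
        phase=phase, r=r, a=float(a), b=float(b), r2=100.0 * r**2,
        rmse=float(np.sqrt(np.mean(err**2))), ave=float(np.mean(err)),
        n=int(n), dev=dev,
    )


_FAMILY_RESPONSES = {
    "quasipoisson": ("F", None),
    "negbinomial": ("F", None),
    "binomial": ("presence", None),
    "gaussian": ("lnF", "presence"),
}


def prepare_response(table: pd.DataFrame, family: str) -> tuple[pd.DataFrame, str]:
    """Subset/derive the response column for a family.

    Count families use F on all rows, binomial uses presence on all
    rows, and the Gaussian model uses ln(F) on presence rows only.
    """
    if family == "gaussian":
        sub = table.loc[table["F"] > 0].copy()
        sub["lnF"] = np.log(sub["F"].to_numpy(dtype=float))
        return sub, "lnF"
    response = "presence" if family == "binomial" else "F"
    return table, response


def split_fit_validate(table: pd.DataFrame,
                       families: Sequence[str] = ("quasipoisson", "negbinomial",
                                                  "binomial", "gaussian"),
                       candidates: Sequence[str] = ("Zpl", "Pred", "Depth",
                                                    "Dist", "Hour", "Temp"),
                       k: int = 3, alpha: float = 0.05,
                       select: bool = True):
    """Day-1 fit / day-2 predict validation for each family.

    Each family is forward-selected and fitted on day-1 rows, then used
    to predict day-2 rows.  Returns ``(models, traces, reports)`` where
    ``reports[family]`` holds fitting and validation metric blocks.
    """
    days = set(table["day"].unique())
    if not {1, 2} <= days:
        raise ValueError(f"table must contain day 1 and day 2 rows, got {sorted(days)}")
    day1 = table.loc[table["day"] == 1]
    day2 = table.loc[table["day"] == 2]

    models: dict[str, GamModel] = {}
    traces: dict = {}
    reports: dict[str, dict] = {}
    for family in families:
        fit_tab, response = prepare_response(day1, family)
        if select:
            model, trace = forward_select(fit_tab, response, family,
                                          candidates=candidates, k=k, alpha=alpha)
        else:
            model = fit_gam(fit_tab, response, family, list(candidates), k=k)
            trace = None
        models[family] = model
        traces[family] = trace

        fit_rep = validation_metrics(model.y, model.fitted, phase="fitting",
                                     dev=deviance_explained(model))
        val_tab, _ = prepare_response(day2, family)
        pred = predict_gam(model, val_tab)["fit"].to_numpy()
        obs = val_tab[response].to_numpy(dtype=float)
        val_rep = validation_metrics(obs, pred, phase="validation")
        reports[family] = {"fitting": fit_rep, "validation": val_rep}
    return models, traces, reports


# ---------------------------------------------------------------------------
# diel summary and threshold detection


def diel_tradeoff(table: pd.DataFrame) -> pd.DataFrame:
    """Hourly means of Zpl, Pred and F plus standardized anomalies.

    Anomaly = (hourly mean - mean of hourly means) / sd of hourly means
    (sd with one delta dof; zero-variance series get zero anomalies).
    """
    hourly = table.groupby("Hour")[["Zpl", "Pred", "F"]].mean()

    def anom(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd < 1e-14:
            return s * 0.0
        return (s - s.mean()) / sd

    out = pd.DataFrame({
        "hour": hourly.index.to_numpy(),
        "mean_F": hourly["F"].to_numpy(),
        "zpl_anom": anom(hourly["Zpl"]).to_numpy(),
        "pred_anom": anom(hourly["Pred"]).to_numpy(),
        "f_anom": anom(hourly["F"]).to_numpy(),
    }).reset_index(drop=True)
    return out


@dataclass
class ThresholdResult:
    breakpoints: list[int]
    p_value: float
    sse_null: float
    sse_fit: float

    def to_dict(self) -> dict:
        return {"breakpoints": self.breakpoints, "p_value": self.p_value,
                "sse_null": self.sse_null, "sse_fit": self.sse_fit}


def _segment_sse(y: np.ndarray) -> np.ndarray:
    """A[i, j] = SSE of a constant fit on y[i:j] for all 0 <= i < j <= n."""
    n = y.size
    s = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y**2)])
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    ln = j - i
    with np.errstate(divide="ignore", invalid="ignore"):
        A = (s2[None, :] - s2[:, None]) - (s[None, :] - s[:, None]) ** 2 / np.where(ln > 0, ln, 1)
    A[ln <= 0] = np.inf
    return A


def _best_fit(y: np.ndarray):
    """Best piecewise-constant fits with 0, 1 and 2 changepoints."""
    n = y.size
    A = _segment_sse(y)
    sse0 = A[0, n]
    one = A[0, 1:n] + A[1:n, n]
    c1 = int(np.argmin(one)) + 1
    sse1 = float(one[c1 - 1])
    # rows index c1 in [1, n), cols index c2 in [1, n); require c1 < c2
    left = A[0, 1:n][:, None]
    mid = A[1:n, 1:n]
    right = A[1:n, n][None, :]
    tot = left + mid + right
    ii, jj = np.triu_indices(n - 1, 1)
    vals = tot[ii, jj]
    kbest = int(np.argmin(vals))
    c2pair = (int(ii[kbest]) + 1, int(jj[kbest]) + 1)
    sse2 = float(vals[kbest])
    return float(sse0), (sse1, c1), (sse2, c2pair)


def _threshold_stat(y: np.ndarray):
    sse0, (sse1, c1), (sse2, pair) = _best_fit(y)
    if sse0 < 1e-14:
        return 0.0, [], sse0, sse0
    # prefer the single changepoint unless two give a materially better fit
    if sse2 < sse1 * (1.0 - 1e-6):
        sse_fit, bps = sse2, list(pair)
    else:
        sse_fit, bps = sse1, [c1]
    return (sse0 - sse_fit) / sse0, bps, sse0, sse_fit


def detect_thresholds(series, n_perm: int = 999, seed: int = 0) -> ThresholdResult:
    """Changepoint detection on an hourly series.

    Fits piecewise-constant models with up to two changepoints by
    exhaustive SSE minimization and tests the relative SSE reduction
    against a permutation null of shuffled hour labels.  A constant
    series yields no breakpoints and p = 1.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 4:
        raise ValueError("series too short")
    stat_obs, bps, sse0, sse_fit = _threshold_stat(y)
    if not bps:
        return ThresholdResult([], 1.0, sse0, sse_fit)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        stat_p, _, _, _ = _threshold_stat(rng.permutation(y))
        count += stat_p >= stat_obs - 1e-15
    p = (count + 1) / (n_perm + 1)
    return ThresholdResult(bps, float(p), sse0, sse_fit)
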