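"""Synthetic two-day lake transect survey.

Generates already-detected single targets (prey fish and sparse large
predators), a gridded volume-backscatter field with diel vertical
migration of the scattering layer, and a per-bin truth table with the
generating intensity.  All randomness flows from one seed through
per-component substreams, so a survey is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .config import SceneConfig

__all__ = [
    "TrueResponse",
    "bathymetry",
    "par_cycle",
    "zooplankton_field",
    "temperature_profile",
    "predation_risk_field",
    "fish_intensity",
    "default_truth",
    "sample_survey",
]

PREY_TS_LO, PREY_TS_HI = -58.0, -41.0

_SV_FLOOR = -90.0
_SV_CEIL = -70.0

# observable water column (transducer near zone, bottom blanking zone):
# the generating intensity is defined per *observable* cell volume, and
# targets are placed inside it, so blanking removes no depth-dependent
# share of the generated counts
_TOP_BLANK = 1.0
_BOTTOM_BLANK = 2.5


def bathymetry(x, config: SceneConfig):
    """Bottom depth (m) at along-transect position ``x`` (m).

    Piecewise-linear through ``config.bathymetry_knots``; raises for
    positions outside the transect.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > config.transect_length):
        raise ValueError("position outside transect [0, transect_length]")
    xs = np.array([k[0] for k in config.bathymetry_knots])
    ds = np.array([k[1] for k in config.bathymetry_knots])
    out = np.interp(xa, xs, ds)
    return out if out.ndim else float(out)


def par_cycle(t, config: SceneConfig):
    """Relative surface irradiance in [0, 1] at hour-of-day ``t``.

    Zero outside [dawn_hour, dusk_hour], half-sinusoid between them with
    the maximum at midday.
    """
    ta = np.mod(np.asarray(t, dtype=float), 24.0)
    frac = (ta - config.dawn_hour) / (config.dusk_hour - config.dawn_hour)
    out = np.where((frac >= 0) & (frac <= 1), np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    return out if out.ndim else float(out)


def _shore_distance(x, config: SceneConfig):
    xa = np.asarray(x, dtype=float)
    return np.minimum(xa, config.transect_length - xa)


def daylight_response(t, config: SceneConfig, ramp_h: float = 1.0):
    """Plateaued daylight forcing in [0, 1]: a ``ramp_h``-hour ramp
    centered on dawn, a saturated plateau through the day, and a
    centered ramp down at dusk.

    Organism responses to light (zooplankton descent, visual predator
    activity) switch on quickly rather than tracking irradiance, which
    is what puts sharp diel thresholds at dawn and dusk.
    """
    ta = np.mod(np.asarray(t, dtype=float), 24.0)
    half = ramp_h / 2.0
    up = np.clip((ta - (config.dawn_hour - half)) / ramp_h, 0.0, 1.0)
    down = np.clip(((config.dusk_hour + half) - ta) / ramp_h, 0.0, 1.0)
    out = np.minimum(up, down)
    return out if out.ndim else float(out)


def zooplankton_field(t, x, z, config: SceneConfig, rng: np.random.Generator | None = None):
    """Volume backscattering strength Sv (dB) of the scattering layer.

    A Gaussian-in-depth layer whose centre slides from
    ``zpl_night_center`` (PAR = 0) to ``zpl_day_center`` (PAR = 1) and
    whose spread widens with PAR; linear-domain backscatter is enhanced
    nearshore at night by ``zpl_nearshore_factor``.  The noise-free
    field is clamped to the [-90, -70] dB band; Gaussian dB noise of sd
    ``noise_sd`` is added only when an ``rng`` is supplied, so calls
    without one are deterministic.
    """
    p = daylight_response(t, config)
    center = config.zpl_night_center + (config.zpl_day_center - config.zpl_night_center) * p
    sigma = config.zpl_sigma_night * (1.0 + config.zpl_day_spread * p)
    za = np.asarray(z, dtype=float)
    # daytime dispersal dilutes the layer in proportion to its spread
    layer = np.exp(-0.5 * ((za - center) / sigma) ** 2) * (config.zpl_sigma_night / sigma)
    shore = np.exp(-_shore_distance(x, config) / 300.0)
    gain = 1.0 + (config.zpl_nearshore_factor - 1.0) * (1.0 - p) * shore
    # background and peak chosen so field + patchiness + noise stays
    # inside the [-90, -70] dB band: out-of-band clipping would bias
    # the measured index exactly at the layer depths
    s_bg = 10.0 ** (-86.0 / 10.0)
    s_peak = 0.06 * 10.0 ** (_SV_CEIL / 10.0)
    s_lin = s_bg + s_peak * layer * gain
    sv = np.clip(10.0 * np.log10(s_lin), _SV_FLOOR, _SV_CEIL)
    if rng is not None and config.noise_sd > 0:
        sv = sv + rng.normal(0.0, config.noise_sd, size=np.shape(sv))
    return sv if np.ndim(sv) else float(sv)


def temperature_profile(z, config: SceneConfig):
    """Two-layer logistic temperature profile (°C) with inflection at the
    thermocline.  A deterministic function of depth only: it carries no
    information beyond Depth, so predictor selection should discard it."""
    za = np.asarray(z, dtype=float)
    t = config.temp_deep + (config.temp_surface - config.temp_deep) / (
        1.0 + np.exp((za - config.thermocline_depth) / config.temp_width)
    )
    return t if t.ndim else float(t)


def predation_risk_field(t, x, config: SceneConfig):
    """Deterministic predator pressure in [0, 1]: high in daylight and
    nearshore.  The column predator rate is
    ``pred_rate_coef * pred_fraction *`` this field (times a per-column
    lognormal patch factor inside :func:`sample_survey`)."""
    p = daylight_response(t, config)
    shore = np.exp(-_shore_distance(x, config) / 500.0)
    raw = (0.25 + 0.75 * p) * (0.5 + 0.5 * shore)
    return np.clip(raw, 0.0, 1.0)


@dataclass
class TrueResponse:
    """Generating link-scale response: lambda = exp(intercept + sum g_i)."""

    intercept: float
    curves: dict[str, Callable[[np.ndarray], np.ndarray]]
    shapes: dict[str, str]

    def linear_predictor(self, predictors: dict) -> float:
        eta = self.intercept
        for name, g in self.curves.items():
            eta += float(np.asarray(g(np.asarray(predictors[name], dtype=float))))
        return eta


def default_truth(config: SceneConfig) -> TrueResponse:
    """Default response shapes: dome in Zpl, linear link-scale decay in
    Pred (exponential on the response scale), a daylight-trough U in
    Hour, a dome peaking at the thermocline in Depth and a linear decay
    in distance from shore.

    The Hour and Depth curves are natural cubic interpolants on three
    knots, i.e. smooth low-complexity shapes of the same order the
    analysis is allowed to fit (k = 3), so neither carries structure a
    k = 3 smooth cannot express.  That matters for Temp: temperature is
    a deterministic profile of depth alone, and must carry no signal
    beyond what a depth smooth explains, or selection could not be
    expected to discard it.
    """
    from scipy.interpolate import CubicSpline

    zpl_opt = -83.0
    # dome with its interior maximum at ~42 m, close to the default
    # thermocline; knots sit at the extreme and median cell depths
    depth_ncs = CubicSpline([5.0, 50.0, 95.0],
                            np.array([0.2, 0.75, -0.9]) * 0.5, bc_type="natural")
    hour_ncs = CubicSpline([0.0, 11.5, 23.0], [0.0, -1.0, 0.0], bc_type="natural")
    curves = {
        "Zpl": lambda v: 0.9 * (1.0 - ((v - zpl_opt) / 9.0) ** 2),
        "Pred": lambda v: -3.5 * v,
        "Hour": lambda v: hour_ncs(np.asarray(v, float)),
        "Depth": lambda v: depth_ncs(np.asarray(v, float)),
        "Dist": lambda v: -0.7 * v / 1000.0,
    }
    shapes = {"Zpl": "dome", "Pred": "decreasing", "Hour": "ushape",
              "Depth": "dome", "Dist": "decreasing"}
    return TrueResponse(intercept=math.log(1.4), curves=curves, shapes=shapes)


def fish_intensity(predictors: dict, truth: TrueResponse) -> float:
    """Expected prey-fish count for one bin: exp(intercept + sum g_i(V_i))."""
    vals = [predictors[n] for n in truth.curves]
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("non-finite predictor value")
    lam = math.exp(truth.linear_predictor(predictors))
    return lam


def _bin_mvbs_truth(t: float, x0: float, x1: float, z0: float, z1: float,
                    config: SceneConfig) -> float:
    """Noise-free MVBS of a bin: linear-domain mean of the Sv field on a
    small quadrature grid, re-expressed in dB."""
    xs = np.linspace(x0, x1, 5)
    zs = np.linspace(z0, z1, 5)
    xg, zg = np.meshgrid(xs, zs)
    sv = zooplankton_field(t, xg, zg, config)
    return float(10.0 * np.log10(np.mean(10.0 ** (np.asarray(sv) / 10.0))))


def _place_in_observable(rng: np.random.Generator, x0: float, z0: float,
                         config: SceneConfig) -> tuple[float, float]:
    """Uniform position within the observable part of a grid cell."""
    for _ in range(50):
        xt = rng.uniform(x0, x0 + config.bin_dist)
        lo = max(z0, _TOP_BLANK)
        hi = min(z0 + config.bin_depth, bathymetry(xt, config) - _BOTTOM_BLANK)
        if hi > lo:
            return xt, rng.uniform(lo, hi)
    # sloping bottom can make the observable sliver vanish off-centre
    xt = x0 + 0.5 * config.bin_dist
    lo = max(z0, _TOP_BLANK)
    hi = max(min(z0 + config.bin_depth, bathymetry(xt, config) - _BOTTOM_BLANK), lo + 1e-6)
    return xt, rng.uniform(lo, hi)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):  # rejection; acceptance rate is high for defaults
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_survey(config: SceneConfig, truth: TrueResponse | None = None):
    """Simulate the full survey.

    Returns ``(targets, samples, truth_table)`` as DataFrames:

    * ``targets`` — t_hour, x_m, z_m, ts_db, latent_class
    * ``samples`` — t_hour, x_m, z_m, sv_db on a regular per-hour grid
    * ``truth_table`` — hour, dist_bin, depth_bin, lambda, true_count

    Prey counts per (hour, distance, depth) bin are negative binomial
    with mean ``lambda`` from the generating response (Poisson when
    ``dispersion`` is infinite).  Predators are Poisson per water
    column with a daylight/nearshore-biased, patch-varying rate; the
    risk value entering the generating response is the expected
    column-wise predator proportion, solved self-consistently, so the
    observed proportion of large targets estimates it directly.  Prey
    TS is truncated normal on [-58, -41] dB; predator TS uniform on
    ``pred_ts_range`` (open at -40), so a -40 dB cut separates the
    classes exactly.  ``truth_table`` also records that expected
    proportion (``pred_true``).
    """
    if truth is None:
        truth = default_truth(config)
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_place, rng_pred, rng_noise, rng_patch = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    L = config.transect_length
    nb_dist, nb_depth = config.n_dist_bins, config.n_depth_bins
    rows_t: list[tuple] = []
    rows_truth: list[tuple] = []

    # dB offsets giving the scattering layer patchiness that is not
    # explained by hour/depth/distance, so Zpl is identifiable
    patch = rng_patch.normal(0.0, config.zpl_patch_sd,
                             size=(config.n_hours, nb_dist, nb_depth))

    pred_lo, pred_hi = config.pred_ts_range
    pred_lo = max(pred_lo, -40.0 + 1e-9)

    # per-section lognormal risk patchiness: the component of predation
    # risk not explained by hour and distance, making Pred identifiable;
    # the section scale matches the pooling used for the observed index
    cols_per_sec = int(round(config.pred_section_m / config.bin_dist))
    n_sec = nb_dist // cols_per_sec
    risk_patch = np.exp(rng_patch.normal(0.0, config.pred_patch_sd,
                                         size=(config.n_hours, n_sec)))
    g_pred = truth.curves.get("Pred", lambda v: 0.0)

    for hour in range(config.n_hours):
        hod = hour % config.hours_per_day
        t_mid = hour + 0.5
        for s in range(n_sec):
            # collect every (distance bin, depth bin) cell of the section
            cells: list[tuple[int, int, float, float, float]] = []  # (i, j, x0, z0, eta0)
            for i in range(s * cols_per_sec, (s + 1) * cols_per_sec):
                x0, x1 = i * config.bin_dist, (i + 1) * config.bin_dist
                xc = 0.5 * (x0 + x1)
                bottom_c = bathymetry(xc, config)
                for j in range(nb_depth):
                    z0, z1 = j * config.bin_depth, (j + 1) * config.bin_depth
                    zc = 0.5 * (z0 + z1)
                    if zc < _TOP_BLANK or zc > bottom_c - _BOTTOM_BLANK:
                        continue
                    preds = {
                        "Zpl": _bin_mvbs_truth(t_mid, x0, x1, z0, z1, config)
                        + patch[hour, i, j],
                        "Pred": 0.0,
                        "Hour": hod + 0.5,
                        "Depth": zc,
                        "Dist": float(_shore_distance(xc, config)),
                    }
                    cells.append((i, j, x0, z0, truth.linear_predictor(preds)))
            if not cells:
                continue

            # expected predator proportion of the section, solved
            # self-consistently: P = mu_pred / (mu_pred + sum lambda(P))
            x_sec = (s + 0.5) * config.pred_section_m
            risk = float(predation_risk_field(t_mid, x_sec, config)) * risk_patch[hour, s]
            mu_pred = config.pred_rate_coef * config.pred_fraction * min(risk, 1.0)
            P = 0.0
            for _ in range(50):
                lam_sec = sum(math.exp(eta0 + float(g_pred(np.float64(P))))
                              for *_, eta0 in cells)
                P_new = mu_pred / (mu_pred + lam_sec) if mu_pred > 0 else 0.0
                if abs(P_new - P) < 1e-10:
                    P = P_new
                    break
                P = P_new

            lams = []
            for i, j, x0, z0, eta0 in cells:
                lam = math.exp(eta0 + float(g_pred(np.float64(P))))
                if not math.isfinite(lam):
                    raise ValueError(
                        f"non-finite intensity in bin hour={hour} dist={i} depth={j}"
                    )
                lams.append(lam)
                if math.isinf(config.dispersion):
                    n_prey = int(rng_counts.poisson(lam))
                else:
                    r = config.dispersion
                    n_prey = int(rng_counts.negative_binomial(r, r / (r + lam)))
                for _ in range(n_prey):
                    xt, zt = _place_in_observable(rng_place, x0, z0, config)
                    ts = float(_truncnorm(rng_place, config.prey_ts_mean,
                                          config.prey_ts_sd, PREY_TS_LO, PREY_TS_HI, 1)[0])
                    rows_t.append((hour + rng_place.uniform(0, 1), xt, zt, ts, "prey"))
                rows_truth.append((hour, i, j, lam, n_prey, P))

            # predators are drawn per section; each one occupies a cell
            # chosen in proportion to prey intensity (hunters go where
            # the prey are), so their echoes concentrate in cells that
            # are likely occupied anyway
            n_pred = int(rng_pred.poisson(mu_pred)) if config.pred_fraction > 0 else 0
            if n_pred:
                w = np.asarray(lams)
                w = w / w.sum() if w.sum() > 0 else np.full(len(cells), 1.0 / len(cells))
                for _ in range(n_pred):
                    idx = int(rng_pred.choice(len(cells), p=w))
                    i, j, x0, z0, _ = cells[idx]
                    xt, zt = _place_in_observable(rng_pred, x0, z0, config)
                    ts = float(rng_pred.uniform(pred_lo, pred_hi))
                    rows_t.append((hour + rng_pred.uniform(0, 1), xt, zt, ts, "predator"))

    targets = pd.DataFrame(rows_t, columns=["t_hour", "x_m", "z_m", "ts_db", "latent_class"])
    truth_table = pd.DataFrame(
        rows_truth,
        columns=["hour", "dist_bin", "depth_bin", "lambda", "true_count", "pred_true"],
    )

    # regular Sv sampling grid, one sheet per hour
    xs = np.arange(config.sample_dx / 2, L, config.sample_dx)
    zs_full = np.arange(config.sample_dz / 2, config.max_depth, config.sample_dz)
    bottoms = bathymetry(xs, config)
    srows = []
    for hour in range(config.n_hours):
        t_mid = hour + 0.5
        xg, zg = np.meshgrid(xs, zs_full)
        keep = zg <= bottoms[np.newaxis, :]
        xk, zk = xg[keep], zg[keep]
        sv = np.asarray(zooplankton_field(t_mid, xk, zk, config, rng=rng_noise))
        i_bin = np.minimum((xk / config.bin_dist).astype(int), nb_dist - 1)
        j_bin = np.minimum((zk / config.bin_depth).astype(int), nb_depth - 1)
        sv = sv + patch[hour, i_bin, j_bin]
        srows.append(pd.DataFrame({
            "t_hour": np.full(xk.size, float(t_mid)),
            "x_m": xk, "z_m": zk, "sv_db": np.asarray(sv, dtype=float),
        }))
    samples = pd.concat(srows, ignore_index=True)
    return targets, samples, truth_table
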