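"""Echo filtering and integration into the per-bin predictor table.

Pipeline: blanking (surface / bottom exclusion zones) -> target-strength
window for fish targets -> Sv window for zooplankton samples -> echo
integration on a (hour, 100 m distance, 10 m depth) grid -> predictor
rows F, presence, Zpl, Pred, Depth, Dist, Hour, Temp, day.

Conventions (documented, configurable): closed threshold intervals,
predators are targets strictly above the -40 dB cut, bins use half-open
[a, b) intervals, empty bins get Pred = 0, and rows without any in-band
Sv sample are dropped (and counted), never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingOptions",
    "apply_blanking",
    "filter_fish_targets",
    "predation_risk",
    "zooplankton_index",
    "integrate_bins",
    "build_predictor_table",
    "process_survey",
]


@dataclass(frozen=True)
class ProcessingOptions:
    surface_blank_m: float = 1.0
    bottom_blank_m: float = 2.5
    fish_ts_min: float = -58.0
    fish_ts_max: float = -20.0
    predator_ts_cut: float = -40.0
    zpl_sv_min: float = -90.0
    zpl_sv_max: float = -70.0
    # pooling width for the predation-risk proportion; wide enough that
    # the denominator is never a handful of targets
    pred_pool_dist_m: float = 500.0

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessingOptions":
        return cls(**d)


def apply_blanking(df: pd.DataFrame, bathymetry: Callable[[np.ndarray], np.ndarray],
                   options: ProcessingOptions = ProcessingOptions()) -> pd.DataFrame:
    """Drop records in the surface and bottom exclusion zones.

    Keeps rows with ``surface_blank <= z <= bottom(x) - bottom_blank``.
    """
    bottom = np.asarray(bathymetry(df["x_m"].to_numpy()))
    keep = (df["z_m"].to_numpy() >= options.surface_blank_m) & (
        df["z_m"].to_numpy() <= bottom - options.bottom_blank_m
    )
    removed = int((~keep).sum())
    if removed:
        logger.info("blanking removed %d of %d records", removed, len(df))
    return df.loc[keep].reset_index(drop=True)


def filter_fish_targets(targets: pd.DataFrame,
                        options: ProcessingOptions = ProcessingOptions()) -> pd.DataFrame:
    """Keep targets inside the closed fish TS window [-58, -20] dB."""
    ts = targets["ts_db"].to_numpy()
    keep = (ts >= options.fish_ts_min) & (ts <= options.fish_ts_max)
    removed = int((~keep).sum())
    if removed:
        logger.info("TS window removed %d of %d targets", removed, len(targets))
    return targets.loc[keep].reset_index(drop=True)


def predation_risk(ts_values: np.ndarray,
                   options: ProcessingOptions = ProcessingOptions()) -> float:
    """Proportion of accepted targets strictly above the predator cut.

    Empty input returns 0.0: no targets means no evidence of predators.
    """
    ts = np.asarray(ts_values, dtype=float)
    if ts.size == 0:
        return 0.0
    return float(np.mean(ts > options.predator_ts_cut))


def zooplankton_index(sv_values: np.ndarray,
                      options: ProcessingOptions = ProcessingOptions()) -> float:
    """MVBS (dB) of in-band Sv samples, averaged in the linear domain.

    Samples outside the closed [-90, -70] dB window are excluded; NaN is
    returned when nothing is in band (the row is dropped downstream).
    """
    sv = np.asarray(sv_values, dtype=float)
    sv = sv[(sv >= options.zpl_sv_min) & (sv <= options.zpl_sv_max)]
    if sv.size == 0:
        return float("nan")
    return float(10.0 * np.log10(np.mean(10.0 ** (sv / 10.0))))


def _grid_index(values: np.ndarray, width: float) -> np.ndarray:
    return np.floor(np.asarray(values, dtype=float) / width).astype(int)


def integrate_bins(targets: pd.DataFrame, samples: pd.DataFrame,
                   bin_dist: float, bin_depth: float,
                   transect_length: float, max_depth: float,
                   options: ProcessingOptions = ProcessingOptions()) -> pd.DataFrame:
    """Echo integration on the (hour, distance, depth) grid.

    Every accepted target lands in exactly one half-open cell; the sum
    of ``n_fish`` equals the accepted-target count.  ``mvbs`` is the
    per-cell zooplankton index.  The returned frame has one row per cell
    that holds at least one target or Sv sample.
    """
    for df, label in ((targets, "target"), (samples, "sample")):
        if len(df) == 0:
            continue
        x, z = df["x_m"].to_numpy(), df["z_m"].to_numpy()
        bad = (x < 0) | (x >= transect_length + bin_dist) | (z < 0) | (z >= max_depth)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(f"{label} record outside grid: x={x[i]}, z={z[i]}")

    def keys(df: pd.DataFrame) -> pd.DataFrame:
        t = df["t_hour"].to_numpy()
        return pd.DataFrame({
            "hour_abs": np.floor(t).astype(int),
            "i_dist": np.minimum(_grid_index(df["x_m"].to_numpy(), bin_dist),
                                 int(transect_length / bin_dist) - 1),
            "i_depth": _grid_index(df["z_m"].to_numpy(), bin_depth),
        }, index=df.index)

    tk = pd.concat([keys(targets), targets[["ts_db"]]], axis=1)
    grp = tk.groupby(["hour_abs", "i_dist", "i_depth"])["ts_db"]
    tstats = pd.DataFrame({
        "n_fish": grp.size(),
        "n_large": grp.apply(lambda s: int((s.to_numpy() > options.predator_ts_cut).sum())),
        "pred": grp.apply(lambda s: predation_risk(s.to_numpy(), options)),
    })

    sk = pd.concat([keys(samples), samples[["sv_db"]]], axis=1)
    sstats = (
        sk.groupby(["hour_abs", "i_dist", "i_depth"])["sv_db"]
        .apply(lambda s: zooplankton_index(s.to_numpy(), options))
        .to_frame("mvbs")
    )

    bins = tstats.join(sstats, how="outer")
    bins["n_fish"] = bins["n_fish"].fillna(0).astype(int)
    bins["n_large"] = bins["n_large"].fillna(0).astype(int)
    bins["pred"] = bins["pred"].fillna(0.0)
    return bins.reset_index()


def build_predictor_table(bins: pd.DataFrame,
                          temperature: Callable[[np.ndarray], np.ndarray],
                          bathymetry: Callable[[np.ndarray], np.ndarray],
                          bin_dist: float, bin_depth: float,
                          transect_length: float, max_depth: float,
                          hours_per_day: int = 24,
                          options: ProcessingOptions = ProcessingOptions()) -> pd.DataFrame:
    """Assemble the modelling table, one row per valid grid cell.

    The full cell grid (all hours x distance x depth cells whose centre
    lies in the blanked water column) is enumerated so that zero-count
    cells appear with F = 0; cells with no in-band Sv sample are dropped
    with a logged count.

    The Pred predictor is the proportion of large targets over the
    whole water column of each (hour, ``pred_pool_dist_m`` section),
    not the cell's own targets: a cell-level ratio would be
    mechanically tied to the response (any cell with a large target has
    F > 0) and would ride on tiny denominators, whereas the risk a prey
    fish faces is set by predators in its vicinity.
    """
    n_dist = int(round(transect_length / bin_dist))
    n_depth = int(round(max_depth / bin_depth))
    hours = np.sort(bins["hour_abs"].unique()) if len(bins) else np.array([], dtype=int)

    grid = pd.MultiIndex.from_product(
        [hours, range(n_dist), range(n_depth)], names=["hour_abs", "i_dist", "i_depth"]
    ).to_frame(index=False)
    xc = (grid["i_dist"].to_numpy() + 0.5) * bin_dist
    zc = (grid["i_depth"].to_numpy() + 0.5) * bin_depth
    bottom = np.asarray(bathymetry(xc))
    valid = (zc >= options.surface_blank_m) & (zc <= bottom - options.bottom_blank_m)
    grid = grid.loc[valid].reset_index(drop=True)

    cols_per_sec = max(int(round(options.pred_pool_dist_m / bin_dist)), 1)
    bins = bins.assign(i_sec=bins["i_dist"] // cols_per_sec)
    col = bins.groupby(["hour_abs", "i_sec"])[["n_fish", "n_large"]].sum()
    col["pred_col"] = np.where(col["n_fish"] > 0, col["n_large"] / col["n_fish"], 0.0)

    grid = grid.assign(i_sec=grid["i_dist"] // cols_per_sec)
    table = grid.merge(bins.drop(columns=["i_sec"]),
                       on=["hour_abs", "i_dist", "i_depth"], how="left")
    table = table.merge(col[["pred_col"]].reset_index(), on=["hour_abs", "i_sec"], how="left")
    table["n_fish"] = table["n_fish"].fillna(0).astype(int)
    table["pred"] = table["pred_col"].fillna(0.0)

    n_before = len(table)
    missing = table["mvbs"].isna()
    if missing.any():
        logger.info("dropping %d of %d cells without in-band Sv", int(missing.sum()), n_before)
    table = table.loc[~missing].reset_index(drop=True)

    xc = (table["i_dist"].to_numpy() + 0.5) * bin_dist
    zc = (table["i_depth"].to_numpy() + 0.5) * bin_depth
    out = pd.DataFrame({
        "F": table["n_fish"].to_numpy(),
        "presence": (table["n_fish"].to_numpy() > 0).astype(int),
        "Zpl": table["mvbs"].to_numpy(),
        "Pred": table["pred"].to_numpy(),
        "Depth": zc,
        "Dist": np.minimum(xc, transect_length - xc),
        "Hour": table["hour_abs"].to_numpy() % hours_per_day,
        "Temp": np.asarray(temperature(zc)),
        "day": table["hour_abs"].to_numpy() // hours_per_day + 1,
        "i_dist": table["i_dist"].to_numpy(),
        "i_depth": table["i_depth"].to_numpy(),
        "hour_abs": table["hour_abs"].to_numpy(),
    })
    return out


def process_survey(targets: pd.DataFrame, samples: pd.DataFrame, scene,
                   options: ProcessingOptions = ProcessingOptions()) -> pd.DataFrame:
    """Full survey -> predictor table, using the scene's bathymetry,
    geometry and temperature profile."""
    from .synthetic import bathymetry as bathy_fn, temperature_profile

    bathy = lambda x: bathy_fn(x, scene)
    temp = lambda z: temperature_profile(z, scene)
    t_blanked = apply_blanking(targets, bathy, options)
    s_blanked = apply_blanking(samples, bathy, options)
    t_fish = filter_fish_targets(t_blanked, options)
    bins = integrate_bins(t_fish, s_blanked, scene.bin_dist, scene.bin_depth,
                          scene.transect_length, scene.max_depth, options)
    return build_predictor_table(bins, temp, bathy, scene.bin_dist, scene.bin_depth,
                                 scene.transect_length, scene.max_depth,
                                 scene.hours_per_day, options)
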