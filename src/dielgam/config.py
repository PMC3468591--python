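"""Scene and run configuration.

:class:`SceneConfig` describes the virtual lake survey: geometry, light
cycle, zooplankton layer dynamics, target-strength classes and count
overdispersion.  :class:`RunConfig` bundles a scene with processing,
modelling and diagnostics options for the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = ["SceneConfig", "RunConfig", "load_run_config"]


def _default_knots() -> list[tuple[float, float]]:
    return [(0.0, 12.0), (400.0, 70.0), (1000.0, 100.0), (1600.0, 70.0), (2000.0, 12.0)]


@dataclass
class SceneConfig:
    """Parameters of the synthetic two-day transect survey.

    Distances are metres, times are hours, acoustic quantities are dB.
    ``dispersion`` is the negative-binomial size parameter for per-bin
    count draws; ``math.inf`` yields Poisson counts.
    """

    transect_length: float = 2000.0
    max_depth: float = 100.0
    bathymetry_knots: list[tuple[float, float]] = field(default_factory=_default_knots)
    n_days: int = 2
    hours_per_day: int = 24
    bin_depth: float = 10.0
    bin_dist: float = 100.0
    dawn_hour: float = 6.0
    dusk_hour: float = 18.0
    thermocline_depth: float = 40.0
    zpl_night_center: float = 40.0
    zpl_day_center: float = 70.0
    zpl_nearshore_factor: float = 3.0
    zpl_sigma_night: float = 6.0
    zpl_day_spread: float = 1.5
    zpl_patch_sd: float = 2.2
    prey_ts_mean: float = -50.0
    prey_ts_sd: float = 3.0
    pred_ts_range: tuple[float, float] = (-40.0, -20.0)
    pred_fraction: float = 0.08
    pred_rate_coef: float = 60.0
    pred_patch_sd: float = 1.1
    pred_section_m: float = 500.0
    noise_sd: float = 1.0
    dispersion: float = 4.0
    seed: int = 0

    # water temperature endpoints of the two-layer profile
    temp_surface: float = 17.0
    temp_deep: float = 7.0
    temp_width: float = 3.0

    # echo-sample grid spacing for the Sv field
    sample_dx: float = 25.0
    sample_dz: float = 2.5

    def __post_init__(self) -> None:
        if self.transect_length <= 0 or self.max_depth <= 0:
            raise ValueError("transect_length and max_depth must be positive")
        if not self.bathymetry_knots:
            raise ValueError("bathymetry_knots must be non-empty")
        self.bathymetry_knots = sorted((float(x), float(d)) for x, d in self.bathymetry_knots)
        for x, d in self.bathymetry_knots:
            if not (0.0 < d <= self.max_depth):
                raise ValueError(f"bottom depth {d} at x={x} outside (0, {self.max_depth}]")
        xs = [x for x, _ in self.bathymetry_knots]
        if xs[0] > 0.0 or xs[-1] < self.transect_length:
            raise ValueError("bathymetry knots must span [0, transect_length]")
        if self.max_depth % self.bin_depth != 0:
            raise ValueError("bin_depth must divide max_depth")
        if self.transect_length % self.bin_dist != 0:
            raise ValueError("bin_dist must divide transect_length")
        if not (0 <= self.dawn_hour < self.dusk_hour < 24):
            raise ValueError("require 0 <= dawn_hour < dusk_hour < 24")
        if not (0.0 <= self.pred_fraction <= 1.0):
            raise ValueError("pred_fraction must lie in [0, 1]")
        lo, hi = self.pred_ts_range
        if not (-40.0 <= lo < hi <= -20.0):
            raise ValueError("pred_ts_range must lie within [-40, -20] dB")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (use math.inf for Poisson)")
        if self.pred_section_m % self.bin_dist != 0 or self.transect_length % self.pred_section_m != 0:
            raise ValueError("pred_section_m must be a multiple of bin_dist dividing transect_length")

    @property
    def n_dist_bins(self) -> int:
        return int(round(self.transect_length / self.bin_dist))

    @property
    def n_depth_bins(self) -> int:
        return int(round(self.max_depth / self.bin_depth))

    @property
    def n_hours(self) -> int:
        return self.n_days * self.hours_per_day

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bathymetry_knots"] = [list(k) for k in self.bathymetry_knots]
        d["pred_ts_range"] = list(self.pred_ts_range)
        d["dispersion"] = "inf" if math.isinf(self.dispersion) else self.dispersion
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
        d = dict(d)
        if "bathymetry_knots" in d:
            d["bathymetry_knots"] = [tuple(k) for k in d["bathymetry_knots"]]
        if "pred_ts_range" in d:
            d["pred_ts_range"] = tuple(d["pred_ts_range"])
        if d.get("dispersion") in ("inf", "Infinity"):
            d["dispersion"] = math.inf
        return cls(**d)


_PROCESSING_DEFAULTS = {
    "surface_blank_m": 1.0,
    "bottom_blank_m": 2.5,
    "fish_ts_min": -58.0,
    "fish_ts_max": -20.0,
    "predator_ts_cut": -40.0,
    "zpl_sv_min": -90.0,
    "zpl_sv_max": -70.0,
    "pred_pool_dist_m": 500.0,
}

_MODEL_DEFAULTS = {
    "families": ["quasipoisson", "negbinomial", "binomial", "gaussian"],
    "k": 3,
    "alpha": 0.05,
    "candidates": ["Zpl", "Pred", "Depth", "Dist", "Hour", "Temp"],
}

_DIAG_DEFAULTS = {"n_perm": 999, "seed": 0, "max_mantel_n": 300}


@dataclass
class RunConfig:
    """Full pipeline configuration (scene + overrides + diagnostics)."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    processing: dict = field(default_factory=lambda: dict(_PROCESSING_DEFAULTS))
    models: dict = field(default_factory=lambda: dict(_MODEL_DEFAULTS))
    diagnostics: dict = field(default_factory=lambda: dict(_DIAG_DEFAULTS))

    def __post_init__(self) -> None:
        for name, defaults, got in (
            ("processing", _PROCESSING_DEFAULTS, self.processing),
            ("models", _MODEL_DEFAULTS, self.models),
            ("diagnostics", _DIAG_DEFAULTS, self.diagnostics),
        ):
            unknown = set(got) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
            merged = dict(defaults)
            merged.update(got)
            setattr(self, name, merged)
        p = self.processing
        if p["surface_blank_m"] < 0 or p["bottom_blank_m"] < 0:
            raise ValueError("blanking margins must be non-negative")
        if p["fish_ts_min"] >= p["fish_ts_max"]:
            raise ValueError("fish TS window is empty")
        if p["zpl_sv_min"] >= p["zpl_sv_max"]:
            raise ValueError("zooplankton Sv window is empty")
        if not (0 < self.models["alpha"] < 1):
            raise ValueError("selection alpha must lie in (0, 1)")
        if self.models["k"] < 3:
            raise ValueError("smooth basis dimension k must be >= 3")

    def to_dict(self) -> dict:
        return {
            "scene": self.scene.to_dict(),
            "processing": dict(self.processing),
            "models": dict(self.models),
            "diagnostics": dict(self.diagnostics),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"scene", "processing", "models", "diagnostics"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    scene = SceneConfig.from_dict(raw.get("scene", {}))
    return RunConfig(
        scene=scene,
        processing=raw.get("processing", {}),
        models=raw.get("models", {}),
        diagnostics=raw.get("diagnostics", {}),
    )
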