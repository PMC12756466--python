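"""Pipeline configuration: YAML parsing, defaulting, and range validation.

Defaults are the published analysis parameters: rolling background radius
30 px, median radius 1 px, morphological radius 25 px (midpoint of the stated
20-30 px), neurosphere gate 1,000-50,000 px² at circularity 0.5-1.0, nucleus
gate 10-1,000 px² at 0.3-1.0, and marker thresholds 10 a.u. (HU, green,
far-red) / 30 a.u. (red).  Unknown keys are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classification import MarkerThresholds
from .preprocessing import PreprocessParams
from .segmentation import ParticleGate

__all__ = ["StageConfig", "StatsConfig", "PipelineConfig", "validate_config"]

_DEFAULTS: dict = {
    "channels": ["DAPI", "HU", "green", "red", "far-red"],
    "neurosphere_channel": "HU",
    "dapi_channel": "DAPI",
    "roi_source": "auto",          # "auto" | "manual"
    "roi_file": None,
    "combinations": ["HU+", "green+", "red+", "green+red+"],
    "seed": 0,
    "neurosphere_stage": {
        "invert": True,
        "threshold_lo": 0,
        "threshold_hi": 200,
        "window_selects": "foreground",
        "morph_radius": 25,
        "watershed_min_distance": 50,
        "area_min": 1000.0,
        "area_max": 50000.0,
        "circ_min": 0.5,
        "circ_max": 1.0,
    },
    "nucleus_stage": {
        "rolling_radius": 30,
        "threshold_lo": 0,
        "threshold_hi": 13,
        "window_selects": "background",
        "median_radius": 1,
        "watershed_min_distance": 5,
        "area_min": 10.0,
        "area_max": 1000.0,
        "circ_min": 0.3,
        "circ_max": 1.0,
    },
    "markers": {
        "thresholds": {"HU": 10.0, "green": 10.0, "far-red": 10.0, "red": 30.0},
        "subtract_background": True,
        "rolling_radius": 30,
    },
    "migration": {
        "rolling_radius": 30,
        "threshold_lo": 0,
        "threshold_hi": 13,
        "window_selects": "background",
        "median_radius": 1,
        "watershed_min_distance": 5,
        "area_min": 10.0,
        "area_max": 1000.0,
        "circ_min": 0.3,
        "circ_max": 1.0,
    },
    "stats": {"omnibus": "kruskal", "posthoc": "dunn", "adjust_posthoc": True},
}

_STAGE_PARAM_KEYS = {
    "invert", "rolling_radius", "median_radius", "threshold_lo", "threshold_hi",
    "window_selects", "morph_radius", "watershed_min_distance",
}
_GATE_KEYS = {"area_min", "area_max", "circ_min", "circ_max"}


class ConfigurationError(ValueError):
    pass


@dataclass
class StageConfig:
    params: PreprocessParams
    gate: ParticleGate


@dataclass
class StatsConfig:
    omnibus: str = "kruskal"
    posthoc: str = "dunn"
    adjust_posthoc: bool = True

    def __post_init__(self) -> None:
        if self.omnibus not in ("kruskal", "anova"):
            raise ConfigurationError(f"stats.omnibus: unknown method {self.omnibus!r}")
        if self.posthoc not in ("dunn", "tukey", "mannwhitney"):
            raise ConfigurationError(f"stats.posthoc: unknown method {self.posthoc!r}")


@dataclass
class PipelineConfig:
    channels: list[str]
    neurosphere_channel: str
    dapi_channel: str
    roi_source: str
    roi_file: str | None
    combinations: list[str]
    seed: int
    neurosphere_stage: StageConfig
    nucleus_stage: StageConfig
    markers: MarkerThresholds
    subtract_marker_background: bool
    marker_rolling_radius: int
    migration: StageConfig
    stats: StatsConfig
    effective: dict = field(default_factory=dict, repr=False)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}{key}"
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key: {where!r}")
        if isinstance(defaults[key], dict) and key != "thresholds":
            if not isinstance(value, dict):
                raise ConfigurationError(f"{where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where + ".")
        else:
            out[key] = value
    return out


def _stage(block: dict, name: str) -> StageConfig:
    try:
        params = PreprocessParams(
            **{k: v for k, v in block.items() if k in _STAGE_PARAM_KEYS}
        )
        gate = ParticleGate(**{k: v for k, v in block.items() if k in _GATE_KEYS})
    except ValueError as exc:
        raise ConfigurationError(f"{name}: {exc}") from exc
    return StageConfig(params=params, gate=gate)


def config_from_dict(user: dict | None) -> PipelineConfig:
    """Build a validated PipelineConfig from a (possibly empty) mapping."""
    eff = _merge(_DEFAULTS, user or {})
    if eff["roi_source"] not in ("auto", "manual"):
        raise ConfigurationError(
            f"roi_source must be 'auto' or 'manual', got {eff['roi_source']!r}"
        )
    if eff["roi_source"] == "manual" and not eff["roi_file"]:
        raise ConfigurationError("roi_source 'manual' requires roi_file")
    try:
        thresholds = MarkerThresholds(
            thresholds={k: float(v) for k, v in eff["markers"]["thresholds"].items()}
        )
    except ValueError as exc:
        raise ConfigurationError(f"markers.thresholds: {exc}") from exc
    return PipelineConfig(
        channels=list(eff["channels"]),
        neurosphere_channel=eff["neurosphere_channel"],
        dapi_channel=eff["dapi_channel"],
        roi_source=eff["roi_source"],
        roi_file=eff["roi_file"],
        combinations=list(eff["combinations"]),
        seed=int(eff["seed"]),
        neurosphere_stage=_stage(eff["neurosphere_stage"], "neurosphere_stage"),
        nucleus_stage=_stage(eff["nucleus_stage"], "nucleus_stage"),
        markers=thresholds,
        subtract_marker_background=bool(eff["markers"]["subtract_background"]),
        marker_rolling_radius=int(eff["markers"]["rolling_radius"]),
        migration=_stage(eff["migration"], "migration"),
        stats=StatsConfig(**eff["stats"]),
        effective=eff,
    )


def validate_config(path) -> PipelineConfig:
    """Parse, default and range-check a YAML config file (empty file = all defaults)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigurationError("config root must be a mapping")
    return config_from_dict(user)
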