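"""Run configuration and geometry-file I/O.

Configurations and airway geometries are YAML (or JSON — YAML is a
superset) documents with declared units: geometry files carry lengths in mm
and areas in mm², configurations carry clinical units (°C, mL/s).  Loaders
are strict: unknown keys are rejected by name rather than ignored, so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ambient import AmbientConditions
from .cohort import CohortConfig
from .errors import ConfigError
from .geometry import (
    AirwaySegment,
    BilateralAirwayModel,
    CrossSection,
    Region,
    SubjectState,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_airway_file",
    "save_airway_file",
    "airway_from_dict",
    "airway_to_dict",
    "config_hash",
]

_MM = 1e-3
_MM2 = 1e-6

_MODES = ("SYNTHETIC_COHORT", "REFERENCE_FIXTURES", "SINGLE_SUBJECT")


# ---------------------------------------------------------------------------
# geometry files

_SEGMENT_KEYS = {
    "label",
    "region",
    "length_mm",
    "area_in_mm2",
    "area_out_mm2",
    "perimeter_in_mm",
    "perimeter_out_mm",
    "cross_section_kind",
    "wall_is_wet",
}
_MODEL_KEYS = {"subject_id", "state", "units", "left_path", "right_path", "shared_path"}
_EXPECTED_UNITS = {"length": "mm", "area": "mm2"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {unknown}")


def _segment_from_dict(d: dict, context: str) -> AirwaySegment:
    if not isinstance(d, dict):
        raise ConfigError(f"{context}: each segment must be a mapping")
    _check_keys(d, _SEGMENT_KEYS, context)
    missing = sorted(_SEGMENT_KEYS - {"wall_is_wet"} - set(d))
    if missing:
        raise ConfigError(f"{context}: missing keys {missing}")
    try:
        region = Region(d["region"])
        kind = CrossSection(d["cross_section_kind"])
    except ValueError as exc:
        raise ConfigError(f"{context}: {exc}") from None
    return AirwaySegment(
        label=str(d["label"]),
        region=region,
        length=float(d["length_mm"]) * _MM,
        area_in=float(d["area_in_mm2"]) * _MM2,
        area_out=float(d["area_out_mm2"]) * _MM2,
        perimeter_in=float(d["perimeter_in_mm"]) * _MM,
        perimeter_out=float(d["perimeter_out_mm"]) * _MM,
        cross_section_kind=kind,
        wall_is_wet=bool(d.get("wall_is_wet", region is not Region.AREA1_VESTIBULE)),
    )


def airway_from_dict(doc: dict) -> BilateralAirwayModel:
    _check_keys(doc, _MODEL_KEYS, "airway document")
    units = doc.get("units", _EXPECTED_UNITS)
    if units != _EXPECTED_UNITS:
        raise ConfigError(f"airway document: units must be {_EXPECTED_UNITS}, got {units}")
    try:
        state = SubjectState(doc.get("state", "PREOP"))
    except ValueError as exc:
        raise ConfigError(f"airway document: {exc}") from None
    paths = {}
    for name in ("left_path", "right_path", "shared_path"):
        if name not in doc or not isinstance(doc[name], list):
            raise ConfigError(f"airway document: {name} must be a list of segments")
        paths[name] = [
            _segment_from_dict(seg, f"{name}[{i}]") for i, seg in enumerate(doc[name])
        ]
    return BilateralAirwayModel(
        subject_id=str(doc.get("subject_id", "unnamed")), state=state, **paths
    )


def airway_to_dict(model: BilateralAirwayModel) -> dict:
    def seg_dict(s: AirwaySegment) -> dict:
        return {
            "label": s.label,
            "region": s.region.value,
            "length_mm": s.length / _MM,
            "area_in_mm2": s.area_in / _MM2,
            "area_out_mm2": s.area_out / _MM2,
            "perimeter_in_mm": s.perimeter_in / _MM,
            "perimeter_out_mm": s.perimeter_out / _MM,
            "cross_section_kind": s.cross_section_kind.value,
            "wall_is_wet": s.wall_is_wet,
        }

    return {
        "subject_id": model.subject_id,
        "state": model.state.value,
        "units": dict(_EXPECTED_UNITS),
        "left_path": [seg_dict(s) for s in model.left_path],
        "right_path": [seg_dict(s) for s in model.right_path],
        "shared_path": [seg_dict(s) for s in model.shared_path],
    }


def load_airway_file(path: str | Path) -> BilateralAirwayModel:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return airway_from_dict(doc)


def save_airway_file(model: BilateralAirwayModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(airway_to_dict(model), sort_keys=False))


# ---------------------------------------------------------------------------
# run configuration

_AMBIENT_KEYS = {"temperature_C", "relative_humidity", "pressure_Pa", "wall_temperature_C"}
_PROTOCOL_KEYS = {"target_flow_mL_s"}
_COHORT_KEYS = {
    "n_subjects",
    "deviation_severity",
    "compensatory_los_factor",
    "correction_fraction",
    "turbinate_reduction_factor",
    "nose_intercept",
    "nose_slope_pre",
    "nose_slope_improve",
    "nose_noise_sd_pre",
    "nose_noise_sd_improve",
    "compute_transport",
    "transport_steps",
}
_GEOMETRY_KEYS = {"template", "preop_file", "postop_file"}
_TOP_KEYS = {"mode", "seed", "output_dir", "log_level", "ambient", "protocol", "cohort", "geometry"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str
    seed: int = 0
    output_dir: str = "rhinoflow_output"
    log_level: str = "INFO"
    ambient: AmbientConditions = field(default_factory=AmbientConditions)
    target_flow: float = 250e-6  # m³/s
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preop_file: str | None = None
    postop_file: str | None = None

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.target_flow <= 0.0:
            raise ConfigError("target flow must be positive")
        self.ambient.validate()
        self.cohort.validate()


def _interval(value, name: str) -> tuple[float, float]:
    if not (isinstance(value, (list, tuple)) and len(value) == 2):
        raise ConfigError(f"cohort.{name} must be a [low, high] pair")
    return float(value[0]), float(value[1])


def _config_from_doc(doc: dict) -> RunConfig:
    _check_keys(doc, _TOP_KEYS, "configuration")
    if "mode" not in doc:
        raise ConfigError("configuration: missing required key 'mode'")
    amb = dict(doc.get("ambient") or {})
    _check_keys(amb, _AMBIENT_KEYS, "ambient")
    ambient = AmbientConditions(
        temperature=float(amb.get("temperature_C", 25.0)),
        relative_humidity=float(amb.get("relative_humidity", 0.35)),
        pressure=float(amb.get("pressure_Pa", 101325.0)),
        wall_temperature=float(amb.get("wall_temperature_C", 34.0)),
    )
    proto = dict(doc.get("protocol") or {})
    _check_keys(proto, _PROTOCOL_KEYS, "protocol")
    target_flow = float(proto.get("target_flow_mL_s", 250.0)) * 1e-6
    coh = dict(doc.get("cohort") or {})
    _check_keys(coh, _COHORT_KEYS, "cohort")
    seed = int(doc.get("seed", 0))
    cohort_kwargs: dict = {"seed": seed, "target_flow": target_flow}
    for name in ("deviation_severity", "compensatory_los_factor",
                 "correction_fraction", "turbinate_reduction_factor"):
        if name in coh:
            cohort_kwargs[name] = _interval(coh[name], name)
    for name in ("n_subjects", "transport_steps"):
        if name in coh:
            cohort_kwargs[name] = int(coh[name])
    for name in ("nose_intercept", "nose_slope_pre", "nose_slope_improve",
                 "nose_noise_sd_pre", "nose_noise_sd_improve"):
        if name in coh:
            cohort_kwargs[name] = float(coh[name])
    if "compute_transport" in coh:
        cohort_kwargs["compute_transport"] = bool(coh["compute_transport"])
    geo = dict(doc.get("geometry") or {"template": "default"})
    _check_keys(geo, _GEOMETRY_KEYS, "geometry")
    config = RunConfig(
        mode=str(doc["mode"]),
        seed=seed,
        output_dir=str(doc.get("output_dir", "rhinoflow_output")),
        log_level=str(doc.get("log_level", "INFO")),
        ambient=ambient,
        target_flow=target_flow,
        cohort=CohortConfig(**cohort_kwargs),
        preop_file=geo.get("preop_file"),
        postop_file=geo.get("postop_file"),
    )
    config.validate()
    return config


def load_config(path: str | Path) -> RunConfig:
    """Parse, schema-validate, and default-fill a run configuration file."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return _config_from_doc(doc)


def config_to_doc(config: RunConfig) -> dict:
    return {
        "mode": config.mode,
        "seed": config.seed,
        "output_dir": config.output_dir,
        "log_level": config.log_level,
        "ambient": {
            "temperature_C": config.ambient.temperature,
            "relative_humidity": config.ambient.relative_humidity,
            "pressure_Pa": config.ambient.pressure,
            "wall_temperature_C": config.ambient.wall_temperature,
        },
        "protocol": {"target_flow_mL_s": config.target_flow * 1e6},
        "cohort": {
            "n_subjects": config.cohort.n_subjects,
            "deviation_severity": list(config.cohort.deviation_severity),
            "compensatory_los_factor": list(config.cohort.compensatory_los_factor),
            "correction_fraction": list(config.cohort.correction_fraction),
            "turbinate_reduction_factor": list(config.cohort.turbinate_reduction_factor),
            "nose_intercept": config.cohort.nose_intercept,
            "nose_slope_pre": config.cohort.nose_slope_pre,
            "nose_slope_improve": config.cohort.nose_slope_improve,
            "nose_noise_sd_pre": config.cohort.nose_noise_sd_pre,
            "nose_noise_sd_improve": config.cohort.nose_noise_sd_improve,
            "compute_transport": config.cohort.compute_transport,
            "transport_steps": config.cohort.transport_steps,
        },
        "geometry": (
            {"preop_file": config.preop_file, "postop_file": config.postop_file}
            if config.preop_file
            else {"template": "default"}
        ),
    }


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_doc(config), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Stable hash of the canonicalized configuration document."""
    doc = json.dumps(config_to_doc(config), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]
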