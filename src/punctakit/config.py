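"""Run configuration: load, validate, and echo.

Every run writes its fully-resolved parameter set next to its results so
that any output directory is self-describing and re-runnable. Unknown keys
in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from punctakit.detection import DetectionParams

__all__ = ["RunConfig", "load_config", "dump_config"]

BASELINE_METHODS = ("global_median", "local_edges")
EDGE_POLICIES = ("exclude_from_means",)


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of an analysis/comparison run."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    line_width_px: int = 3
    baseline_method: str = "global_median"
    edge_policy: str = "exclude_from_means"
    um_per_px: float | None = None  # overrides sample sheet and TIFF tags
    alpha: float = 0.05
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.line_width_px < 1:
            raise ValueError("line_width_px must be a positive integer")
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(
                f"baseline_method must be one of {BASELINE_METHODS}, "
                f"got {self.baseline_method!r}"
            )
        if self.edge_policy not in EDGE_POLICIES:
            raise ValueError(f"edge_policy must be one of {EDGE_POLICIES}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.um_per_px is not None and self.um_per_px <= 0:
            raise ValueError("um_per_px override must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detection"] = dataclasses.asdict(self.detection)
        return d


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    ``overrides`` (e.g. from CLI flags) take precedence over file values;
    ``None`` overrides are ignored. Unknown keys raise.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = loaded
    for key, value in overrides.items():
        if value is None:
            continue
        if key in ("sigma_px", "radius_px", "min_size_px", "k", "r", "p", "q"):
            data.setdefault("detection", {})
            if not isinstance(data["detection"], dict):
                raise ValueError("config key 'detection' must be a mapping")
            data["detection"][key] = value
        else:
            data[key] = value

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    det_data = data.pop("detection", {})
    if isinstance(det_data, dict):
        det_known = {f.name for f in dataclasses.fields(DetectionParams)}
        det_unknown = set(det_data) - det_known
        if det_unknown:
            raise ValueError(f"unknown detection config keys: {sorted(det_unknown)}")
        detection = DetectionParams(**det_data)
    elif isinstance(det_data, DetectionParams):
        detection = det_data
    else:
        raise ValueError("config key 'detection' must be a mapping")
    return RunConfig(detection=detection, **data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as YAML (round-trips via load_config)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
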