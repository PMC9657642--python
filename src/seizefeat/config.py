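"""Run configuration: one flat key-value namespace over all parameter sets.

A config file is flat YAML (``lp_cutoff: 35``); CLI flags override file
values; defaults are the published operating point.  Unknown keys are
rejected so typos cannot silently fall back to defaults, and every report
embeds the full resolved parameter set plus a hash for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .detect import DetectionParams
from .feature import FeatureParams
from .preprocess import PreprocessParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Merged preprocessing, feature and detection parameters."""

    preprocess: PreprocessParams = PreprocessParams()
    feature: FeatureParams = FeatureParams()
    detection: DetectionParams = DetectionParams()
    localize_margin: float = 1.0

    def validate(self, fs: float = 256.0) -> None:
        self.preprocess.validate(fs)
        self.feature.validate(fs)
        self.detection.validate()
        if self.localize_margin <= 0:
            raise ValueError("localize_margin must be positive")

    def to_flat_dict(self) -> dict:
        out: dict = {}
        for group in (self.preprocess, self.feature, self.detection):
            out.update(dataclasses.asdict(group))
        out["localize_margin"] = self.localize_margin
        return out

    def param_hash(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _field_names(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def config_from_dict(flat: dict) -> RunConfig:
    """Build a RunConfig from a flat mapping; unknown keys are an error."""
    groups = {
        "preprocess": (PreprocessParams, {}),
        "feature": (FeatureParams, {}),
        "detection": (DetectionParams, {}),
    }
    extras: dict = {}
    for key, value in flat.items():
        placed = False
        for _, (cls, kwargs) in groups.items():
            if key in _field_names(cls):
                kwargs[key] = value
                placed = True
                break
        if not placed:
            if key == "localize_margin":
                extras[key] = float(value)
                placed = True
        if not placed:
            raise ValueError(f"unknown config key: {key!r}")
    cfg = RunConfig(
        preprocess=PreprocessParams(**groups["preprocess"][1]),
        feature=FeatureParams(**groups["feature"][1]),
        detection=DetectionParams(**groups["detection"][1]),
        **extras,
    )
    return cfg


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load flat YAML config (optional) and apply CLI overrides on top."""
    flat: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        flat.update(loaded)
    if overrides:
        flat.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_dict(flat)
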