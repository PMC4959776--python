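"""YAML pipeline configuration.

A config file holds the two parameter blocks of the pipeline::

    canny:
      smoothing_sigma: 2.0
      closing_radius: 3
      min_area_fraction: 0.05
    threshold:
      threshold: 0.5
      scope: batch
      restrict_to_disc: true

Absent keys fall back to the module defaults; unknown keys are rejected so
typos never silently change an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .disc_segmentation import CannyParams
from .errors import ValidationError
from .gfp_segmentation import ThresholdSpec


@dataclass(frozen=True)
class PipelineConfig:
    canny: CannyParams
    threshold: ThresholdSpec


def _build(cls, block: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValidationError(
            f"unknown key(s) in config section '{name}': {sorted(unknown)}"
        )
    return cls(**block)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config; ``None`` returns all defaults."""
    if path is None:
        return PipelineConfig(canny=CannyParams(), threshold=ThresholdSpec())
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a mapping")
    unknown = set(raw) - {"canny", "threshold"}
    if unknown:
        raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
    return PipelineConfig(
        canny=_build(CannyParams, raw.get("canny", {}) or {}, "canny"),
        threshold=_build(ThresholdSpec, raw.get("threshold", {}) or {}, "threshold"),
    )
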