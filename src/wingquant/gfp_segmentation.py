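"""GFP-positive region segmentation by a uniform brightness threshold.

The driver (*ptc*) stripe is segmented by a single intensity cutoff on the
normalized reporter channel, mirroring the manually-determined uniform
threshold of the original analysis. :func:`suggest_threshold` offers an
Otsu starting point for that manual choice; the recorded analysis threshold
is always the one in :class:`ThresholdSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from skimage.filters import threshold_otsu

from .errors import NoBimodalityError, ValidationError
from .masks import RegionMask

__all__ = ["ThresholdSpec", "segment_gfp", "suggest_threshold"]

OTSU_BINS = 256


@dataclass(frozen=True)
class ThresholdSpec:
    """The uniform brightness threshold and how it is applied.

    threshold : cutoff on the [0, 1] intensity scale; pixels with
        intensity >= threshold are GFP-positive (inclusive comparison).
    scope : "batch" applies one threshold to the whole experiment (the
        uniform choice); "per_image" is for exploratory use and is flagged
        as non-uniform in outputs.
    restrict_to_disc : intersect the GFP mask with the disc mask so the
        proliferation index is bounded by 1. The unrestricted area is
        recorded alongside either way.
    """

    threshold: float = 0.5
    scope: Literal["batch", "per_image"] = "batch"
    restrict_to_disc: bool = True

    def __post_init__(self):
        if not 0 <= self.threshold <= 1:
            raise ValidationError(
                f"threshold must be in [0, 1], got {self.threshold}"
            )
        if self.scope not in ("batch", "per_image"):
            raise ValidationError(f"unknown scope: {self.scope!r}")


def segment_gfp(
    reporter_channel: np.ndarray,
    spec: ThresholdSpec,
    disc_mask: RegionMask | None = None,
) -> RegionMask:
    """Threshold the reporter channel; optionally clip to the disc."""
    channel = np.asarray(reporter_channel, dtype=float)
    if channel.ndim != 2:
        raise ValidationError("reporter channel must be 2D")
    mask = channel >= spec.threshold
    if spec.restrict_to_disc:
        if disc_mask is None:
            raise ValidationError("restrict_to_disc requires a disc mask")
        if disc_mask.shape != channel.shape:
            raise ValidationError(
                f"disc mask shape {disc_mask.shape} does not match "
                f"reporter shape {channel.shape}"
            )
        mask &= disc_mask.mask
    return RegionMask(mask)


def suggest_threshold(reporter_channels: Iterable[np.ndarray] | np.ndarray) -> float:
    """Otsu's threshold on the pooled 256-bin intensity histogram.

    Offered as a reproducible starting point for the manual threshold
    choice; it is never applied automatically.
    """
    if isinstance(reporter_channels, np.ndarray):
        reporter_channels = [reporter_channels]
    pooled = np.concatenate([np.asarray(c, dtype=float).ravel() for c in reporter_channels])
    if pooled.size == 0:
        raise ValidationError("no pixels supplied")
    if pooled.min() < 0 or pooled.max() > 1:
        raise ValidationError("reporter channels must be normalized to [0, 1]")
    if np.ptp(pooled) == 0:
        raise NoBimodalityError(
            "constant intensity: no bimodality to threshold"
        )
    counts, edges = np.histogram(pooled, bins=OTSU_BINS, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    return float(threshold_otsu(hist=(counts, centers)))
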