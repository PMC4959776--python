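"""Whole-disc segmentation from the junction-marker channel.

The disc silhouette is recovered exactly the way the original quantification
describes it: run a Canny edge detector over the junctional (DE-cadherin)
stain, close small gaps in the detected outline, fill the enclosed interior,
and keep the largest filled component as the wing disc. The resulting mask
includes the outline pixels themselves.

Hysteresis thresholds default to quantiles of the gradient magnitude
(high = 90th percentile, low = half of high) so the detector adapts to
staining intensity; absolute thresholds may be given instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.measure import label
from skimage.morphology import disk

from .errors import NoDiscFoundError, ValidationError
from .masks import RegionMask

__all__ = [
    "CannyParams",
    "detect_edges",
    "close_and_fill",
    "select_disc",
    "segment_disc",
]


@dataclass(frozen=True)
class CannyParams:
    """Parameters of the edge-based disc segmentation.

    smoothing_sigma : Gaussian pre-smoothing, in pixels.
    low_threshold, high_threshold : hysteresis thresholds on the gradient
        magnitude of the [0, 1] image; ``None`` (the default) derives
        high from the 90th percentile of the gradient magnitude and
        low = 0.5 * high, per image.
    closing_radius : disk radius (pixels) used to bridge gaps in the
        detected outline before filling.
    min_area_fraction : smallest filled component (relative to image area)
        accepted as a disc; comparison is inclusive (>=).
    """

    smoothing_sigma: float = 2.0
    low_threshold: float | None = None
    high_threshold: float | None = None
    closing_radius: int = 3
    min_area_fraction: float = 0.05

    def __post_init__(self):
        if self.smoothing_sigma <= 0:
            raise ValidationError("smoothing_sigma must be positive")
        if (self.low_threshold is None) != (self.high_threshold is None):
            raise ValidationError(
                "low_threshold and high_threshold must be given together"
            )
        if self.low_threshold is not None:
            for name, t in (
                ("low_threshold", self.low_threshold),
                ("high_threshold", self.high_threshold),
            ):
                if not 0 <= t <= 1:
                    raise ValidationError(f"{name} must be in [0, 1], got {t}")
            if self.low_threshold >= self.high_threshold:
                raise ValidationError("low_threshold must be < high_threshold")
        if self.closing_radius < 0:
            raise ValidationError("closing_radius must be >= 0")
        if not 0 < self.min_area_fraction < 1:
            raise ValidationError("min_area_fraction must be in (0, 1)")


def _quantile_thresholds(channel: np.ndarray, sigma: float) -> tuple[float, float]:
    """Gradient-quantile hysteresis thresholds (high = p90, low = high / 2)."""
    smoothed = ndi.gaussian_filter(channel.astype(float), sigma)
    mag = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    high = float(np.percentile(mag, 90.0))
    return 0.5 * high, high


def detect_edges(junction_channel: np.ndarray, params: CannyParams) -> RegionMask:
    """Canny edge map of the junction channel.

    A constant image yields an empty edge map; the failure is reported
    downstream by :func:`select_disc`, not here.
    """
    channel = np.asarray(junction_channel, dtype=float)
    if channel.ndim != 2:
        raise ValidationError("junction channel must be 2D")
    if params.low_threshold is None:
        low, high = _quantile_thresholds(channel, params.smoothing_sigma)
        if high == 0.0:  # constant image: no gradient anywhere
            return RegionMask(np.zeros(channel.shape, dtype=bool))
    else:
        low, high = params.low_threshold, params.high_threshold
    edges = canny(
        channel,
        sigma=params.smoothing_sigma,
        low_threshold=low,
        high_threshold=high,
    )
    return RegionMask(edges)


def close_and_fill(edge_mask: RegionMask, params: CannyParams) -> RegionMask:
    """Close gaps in the edge map and fill enclosed interiors.

    A pixel is interior iff it cannot be reached from the image border
    through non-edge pixels (4-connected background walk); the result is the
    union of the closed edges and their interiors, hence always a superset
    of the input.

    The closing interleaves the hole filling: dilate by the closing disk,
    fill, then erode. A plain dilate-erode closing cannot reconnect thin
    edge curves across a gap (the eroded bridge collapses), whereas filling
    the dilated outline backs the bridge with interior before the erosion,
    so gaps up to ~2*closing_radius are bridged and the boundary
    displacement of the dilation is undone. At closing_radius 0 the
    operation is pure hole filling.
    """
    edges = edge_mask.mask
    r = params.closing_radius
    if r > 0:
        footprint = disk(r)
        grown = ndi.binary_dilation(edges, structure=footprint)
        filled = ndi.binary_fill_holes(grown)  # default structure = 4-connectivity
        result = ndi.binary_erosion(filled, structure=footprint, border_value=1)
        result |= edges  # guaranteed anyway; keeps the superset property explicit
    else:
        result = ndi.binary_fill_holes(edges)
    return RegionMask(result)


def select_disc(filled_mask: RegionMask, params: CannyParams) -> RegionMask:
    """Keep the largest 8-connected filled component as the disc.

    Components smaller than ``min_area_fraction`` of the image area are
    ignored; the comparison is inclusive, so a component exactly at the
    boundary is retained.
    """
    labels, n = label(filled_mask.mask, connectivity=2, return_num=True)
    n_pixels = filled_mask.mask.size
    if n == 0:
        raise NoDiscFoundError(0.0)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = int(np.argmax(sizes)) + 1
    largest_fraction = sizes[best - 1] / n_pixels
    if largest_fraction < params.min_area_fraction:
        raise NoDiscFoundError(largest_fraction)
    return RegionMask(labels == best)


def segment_disc(junction_channel: np.ndarray, params: CannyParams) -> RegionMask:
    """Full disc segmentation: detect_edges -> close_and_fill -> select_disc."""
    edges = detect_edges(junction_channel, params)
    filled = close_and_fill(edges, params)
    return select_disc(filled, params)
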