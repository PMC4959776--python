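"""Binary region masks with pixel-area bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class RegionMask:
    """A 2D boolean mask for a segmented region (whole disc or GFP stripe).

    ``area_px`` is stored alongside the array but is always recomputable as
    ``mask.sum()``; the constructor enforces agreement.
    """

    mask: np.ndarray
    area_px: int = field(default=-1)

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValidationError(f"mask must be 2D, got ndim={m.ndim}")
        if m.dtype != bool:
            m = m.astype(bool)
        object.__setattr__(self, "mask", m)
        n_true = int(m.sum())
        if self.area_px == -1:
            object.__setattr__(self, "area_px", n_true)
        elif self.area_px != n_true:
            raise ValidationError(
                f"area_px={self.area_px} disagrees with mask.sum()={n_true}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def area_um2(self, pixel_size_um: float) -> float:
        """Area in square microns given the pixel pitch in microns."""
        if pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        return self.area_px * pixel_size_um**2

    def intersect(self, other: "RegionMask") -> "RegionMask":
        if self.shape != other.shape:
            raise ValidationError(
                f"mask shapes differ: {self.shape} vs {other.shape}"
            )
        return RegionMask(self.mask & other.mask)

    def __eq__(self, other) -> bool:  # value semantics for tests
        if not isinstance(other, RegionMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.all(self.mask == other.mask))
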