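"""Image and manifest I/O.

Reads single-channel or multichannel TIFF/PNG files into :class:`DiscImage`
records with intensities normalized to [0, 1], loads batch manifests (CSV),
and writes binary masks and S1-style RGB overlays.

Conventions
-----------
* Arrays are row-major with origin at the top-left pixel.
* Intensities are divided by ``2**bit_depth - 1`` at load time; every
  downstream threshold is expressed on the resulting [0, 1] scale so a
  "uniform brightness threshold" is portable across 8- and 16-bit inputs.
* Areas are reported in pixels; conversion to square microns happens only
  when ``pixel_size_um`` is known.
* For multichannel files the plane indices come from the caller's channel
  assignment, never from file metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.morphology import erosion

from .errors import InputError, ValidationError
from .masks import RegionMask

_MAX_CHANNELS = 4  # planes beyond this are assumed to be a z-stack

REQUIRED_MANIFEST_COLUMNS = ("image_id", "genotype", "junction_path", "reporter_path")


@dataclass(frozen=True)
class DiscImage:
    """One imaged wing disc: two registered channels plus identity metadata.

    ``junction_channel`` carries the cell-outline stain (DE-cadherin in the
    source experiments) and ``reporter_channel`` the GFP fluorescence driven
    in the *ptc* stripe. Both are float arrays on [0, 1].
    """

    image_id: str
    genotype: str
    junction_channel: np.ndarray
    reporter_channel: np.ndarray
    bit_depth: int
    pixel_size_um: float | None = None

    def __post_init__(self):
        j = np.asarray(self.junction_channel, dtype=float)
        r = np.asarray(self.reporter_channel, dtype=float)
        if j.ndim != 2 or r.ndim != 2:
            raise ValidationError("channels must be 2D arrays")
        if j.shape != r.shape:
            raise ValidationError(
                f"channel shapes differ: junction {j.shape} vs reporter {r.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        for name, arr in (("junction", j), ("reporter", r)):
            if arr.min() < 0 or arr.max() > 1.0:
                raise ValidationError(
                    f"{name} channel has intensities outside [0, 1] after rescale"
                )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        object.__setattr__(self, "junction_channel", j)
        object.__setattr__(self, "reporter_channel", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.junction_channel.shape


def _read_raw(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path))
        return np.asarray(iio.imread(path))
    except InputError:
        raise
    except Exception as exc:  # noqa: BLE001 - report the offending path
        raise InputError(f"could not read image {path}: {exc}") from exc


def _extract_plane(arr: np.ndarray, channel: int | None, path: str | Path) -> np.ndarray:
    """Pull a single 2D plane out of a possibly multichannel array."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        # A small leading/trailing axis is a channel axis; anything else is a
        # z-stack, which the pipeline does not handle.
        if arr.shape[0] <= _MAX_CHANNELS:
            axis, n = 0, arr.shape[0]
        elif arr.shape[-1] <= _MAX_CHANNELS:
            axis, n = 2, arr.shape[-1]
        else:
            raise InputError(
                f"{path} looks like a z-stack ({arr.shape}); project to 2D first"
            )
        if channel is None:
            raise ValidationError(
                f"{path} is multichannel ({n} planes); a channel index is required"
            )
        if not 0 <= channel < n:
            raise ValidationError(
                f"channel index {channel} out of range for {n}-plane image {path}"
            )
        return np.take(arr, channel, axis=axis)
    raise InputError(f"{path} has {arr.ndim} dimensions; project to 2D first")


def _rescale(arr: np.ndarray, path: str | Path) -> tuple[np.ndarray, int]:
    """Normalize an integer image to [0, 1]; return (array, bit depth)."""
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif np.issubdtype(arr.dtype, np.floating):
        if arr.min() < 0 or arr.max() > 1.0:
            raise ValidationError(
                f"float image {path} must already be on [0, 1]"
            )
        return arr.astype(float), 16
    else:
        raise InputError(f"unsupported pixel type {arr.dtype} in {path}")
    return arr.astype(float) / (2**depth - 1), depth


def load_disc_image(
    junction_path: str | Path,
    reporter_path: str | Path,
    *,
    image_id: str,
    genotype: str,
    junction_channel: int | None = None,
    reporter_channel: int | None = None,
    pixel_size_um: float | None = None,
) -> DiscImage:
    """Load the two channels of one disc into a validated :class:`DiscImage`.

    ``junction_path`` and ``reporter_path`` may point at the same multichannel
    file, in which case the ``*_channel`` indices select the planes.
    """
    j_raw = _extract_plane(_read_raw(junction_path), junction_channel, junction_path)
    r_raw = _extract_plane(_read_raw(reporter_path), reporter_channel, reporter_path)
    if j_raw.shape != r_raw.shape:
        raise ValidationError(
            f"channel shapes differ: {j_raw.shape} ({junction_path}) vs "
            f"{r_raw.shape} ({reporter_path})"
        )
    j, depth_j = _rescale(j_raw, junction_path)
    r, depth_r = _rescale(r_raw, reporter_path)
    return DiscImage(
        image_id=image_id,
        genotype=genotype,
        junction_channel=j,
        reporter_channel=r,
        bit_depth=max(depth_j, depth_r),
        pixel_size_um=pixel_size_um,
    )


@dataclass(frozen=True)
class Manifest:
    """A validated batch manifest; rows preserved in file order."""

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self):
        return self.frame.itertuples(index=False)


def load_manifest(path: str | Path) -> Manifest:
    """Read and validate a batch manifest CSV.

    Required columns: image_id, genotype, junction_path, reporter_path.
    Optional columns: junction_channel, reporter_channel, pixel_size_um,
    threshold (a per-batch override read by the CLI).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    frame = pd.read_csv(path, dtype={"image_id": str, "genotype": str})
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"manifest is missing column(s): {', '.join(missing)}")
    dupes = frame["image_id"][frame["image_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate image_id(s) in manifest: {dupes}")
    base = path.parent
    for row in frame.itertuples():
        for col in ("junction_path", "reporter_path"):
            p = Path(getattr(row, col))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise InputError(
                    f"manifest row {row.Index} (image_id={row.image_id}): "
                    f"{col} does not exist: {p}"
                )
            frame.at[row.Index, col] = str(p)
    return Manifest(frame=frame)


def write_mask_png(mask: RegionMask, path: str | Path) -> None:
    """Write a binary mask as a single-channel 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), np.where(mask.mask, 255, 0).astype(np.uint8))


def read_mask_png(path: str | Path) -> RegionMask:
    arr = _read_raw(path)
    if arr.ndim != 2:
        raise InputError(f"mask file {path} is not single-channel")
    return RegionMask(arr > 127)


def write_channel_tiff(channel: np.ndarray, path: str | Path) -> None:
    """Write a normalized [0, 1] channel as a 16-bit grayscale TIFF."""
    arr = np.asarray(channel, dtype=float)
    if arr.min() < 0 or arr.max() > 1.0:
        raise ValidationError("channel must be on [0, 1]")
    tifffile.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def _outline(mask: np.ndarray) -> np.ndarray:
    return mask & ~erosion(mask)


def write_overlay_png(
    image: DiscImage,
    disc_mask: RegionMask,
    gfp_mask: RegionMask | None,
    path: str | Path,
) -> None:
    """Render the junction channel with the disc outline in red and the
    GFP region outline in green (the two-region output contract)."""
    base = (np.clip(image.junction_channel, 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    red = _outline(disc_mask.mask)
    rgb[red] = (255, 40, 40)
    if gfp_mask is not None:
        green = _outline(gfp_mask.mask)
        rgb[green] = (40, 255, 40)
    iio.imwrite(Path(path), rgb)
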