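"""Per-image proliferation index and batch assembly.

The proliferation index of one disc is the GFP-positive area divided by the
total disc area — a dimensionless ratio that normalizes away developmental
asynchrony between discs. ``quantify_batch`` runs the full segmentation over
a manifest and returns one record per image, keeping failures as explicit
rows so exclusions stay auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .disc_segmentation import CannyParams, segment_disc
from .errors import BatchError, ValidationError, WingquantError
from .gfp_segmentation import ThresholdSpec, segment_gfp
from .io_images import DiscImage, Manifest, load_disc_image, write_overlay_png
from .masks import RegionMask

log = logging.getLogger("wingquant")

RESULT_COLUMNS = [
    "image_id",
    "genotype",
    "status",
    "disc_area_px",
    "gfp_area_px",
    "gfp_area_unrestricted_px",
    "proliferation_index",
    "threshold_used",
    "params_fingerprint",
]


@dataclass(frozen=True)
class QuantRecord:
    """Quantification result for one successfully processed disc."""

    image_id: str
    genotype: str
    disc_area_px: int
    gfp_area_px: int
    gfp_area_unrestricted_px: int
    proliferation_index: float
    threshold_used: float
    params_fingerprint: str
    status: str = "ok"


@dataclass(frozen=True)
class FailureRecord:
    """An image that could not be quantified, with the reason; never dropped."""

    image_id: str
    genotype: str
    reason: str
    status: str = "failed"


def proliferation_index(gfp_mask: RegionMask, disc_mask: RegionMask) -> float:
    """GFP-positive area / total disc area."""
    if disc_mask.area_px == 0:
        raise ValidationError("disc area is 0: cannot normalize")
    return gfp_mask.area_px / disc_mask.area_px


def params_fingerprint(params: CannyParams, spec: ThresholdSpec) -> str:
    """Stable short hash of every segmentation parameter, for provenance."""
    payload = json.dumps(
        {"canny": asdict(params), "threshold": asdict(spec)}, sort_keys=True
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def quantify_image(
    image: DiscImage, params: CannyParams, spec: ThresholdSpec
) -> QuantRecord:
    """Segment one disc and compute its proliferation index.

    Returns the record together with nothing else; callers needing the masks
    (e.g. for overlays) use :func:`quantify_image_with_masks`.
    """
    record, _, _ = quantify_image_with_masks(image, params, spec)
    return record


def quantify_image_with_masks(
    image: DiscImage, params: CannyParams, spec: ThresholdSpec
) -> tuple[QuantRecord, RegionMask, RegionMask]:
    disc = segment_disc(image.junction_channel, params)
    gfp = segment_gfp(image.reporter_channel, spec, disc_mask=disc)
    unrestricted = segment_gfp(
        image.reporter_channel,
        ThresholdSpec(spec.threshold, spec.scope, restrict_to_disc=False),
    )
    record = QuantRecord(
        image_id=image.image_id,
        genotype=image.genotype,
        disc_area_px=disc.area_px,
        gfp_area_px=gfp.area_px,
        gfp_area_unrestricted_px=unrestricted.area_px,
        proliferation_index=proliferation_index(gfp, disc),
        threshold_used=spec.threshold,
        params_fingerprint=params_fingerprint(params, spec),
    )
    return record, disc, gfp


def quantify_batch(
    manifest: Manifest,
    params: CannyParams,
    spec: ThresholdSpec,
    *,
    overlay_dir: str | Path | None = None,
) -> list[QuantRecord | FailureRecord]:
    """Run the pipeline over every manifest row, in manifest order.

    Images that fail (unreadable file, no disc found, ...) yield
    :class:`FailureRecord` rows with the reason. If *every* image fails the
    whole batch errors out.
    """
    log.info(
        "quantify_batch: %d images, canny=%s, threshold=%s, fingerprint=%s",
        len(manifest), params, spec, params_fingerprint(params, spec),
    )
    if overlay_dir is not None:
        overlay_dir = Path(overlay_dir)
        overlay_dir.mkdir(parents=True, exist_ok=True)
    records: list[QuantRecord | FailureRecord] = []
    n_failed = 0
    for row in manifest.rows():
        try:
            image = load_disc_image(
                row.junction_path,
                row.reporter_path,
                image_id=row.image_id,
                genotype=row.genotype,
                junction_channel=_optional_int(row, "junction_channel"),
                reporter_channel=_optional_int(row, "reporter_channel"),
                pixel_size_um=_optional_float(row, "pixel_size_um"),
            )
            record, disc, gfp = quantify_image_with_masks(image, params, spec)
            if overlay_dir is not None:
                write_overlay_png(
                    image, disc, gfp, overlay_dir / f"{row.image_id}_overlay.png"
                )
            records.append(record)
        except WingquantError as exc:
            n_failed += 1
            log.warning("image %s failed: %s", row.image_id, exc)
            records.append(
                FailureRecord(image_id=row.image_id, genotype=row.genotype, reason=str(exc))
            )
    log.info("quantify_batch done: %d ok, %d failed", len(records) - n_failed, n_failed)
    if records and n_failed == len(records):
        raise BatchError(f"all {n_failed} images in the batch failed")
    return records


def _optional_int(row, name):
    v = getattr(row, name, None)
    return None if v is None or pd.isna(v) else int(v)


def _optional_float(row, name):
    v = getattr(row, name, None)
    return None if v is None or pd.isna(v) else float(v)


def results_frame(records: list[QuantRecord | FailureRecord]) -> pd.DataFrame:
    """Assemble the results table (one row per image, status column included)."""
    rows = []
    for rec in records:
        if isinstance(rec, QuantRecord):
            rows.append({c: getattr(rec, c) for c in RESULT_COLUMNS})
        else:
            rows.append(
                {
                    "image_id": rec.image_id,
                    "genotype": rec.genotype,
                    "status": f"failed: {rec.reason}",
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_csv(
    records: list[QuantRecord | FailureRecord], path: str | Path
) -> None:
    """Write the results table. Indices keep full precision in memory but are
    rendered to 3 decimals here; reruns with identical config are
    byte-identical."""
    frame = results_frame(records)
    frame.to_csv(path, index=False, float_format="%.3f")
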