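"""Seeded phantom wing-disc images with known ground truth.

A phantom emulates the input structure the pipeline assumes: one closed
junctional outline per image (a bright band along a star-convex boundary,
like DE-cadherin marking the outermost cells, plus a faint interior mesh
texture) and a uniformly bright reporter stripe through the disc (the
*ptc*-driven GFP domain). The stripe width is solved by bisection so the
stripe covers a requested fraction of the disc area. Poisson (photon) and
Gaussian (read) noise are applied afterwards; the ground-truth masks are
the noise-free geometric sets, so the true index is exact set arithmetic.

Every phantom is generated from a single RNG stream derived from its seed,
so batches are reproducible and each image individually regenerable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

from .errors import ValidationError
from .io_images import DiscImage, write_channel_tiff
from .masks import RegionMask

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "GroupSpec",
    "generate_phantom",
    "generate_experiment",
    "sample_experiment_phantoms",
]

_MARGIN_PX = 5
_BAND_WIDTH_PX = 3.0  # junction band thickness, drawn inside the boundary
_MESH_AMPLITUDE = 0.15  # interior texture, as a fraction of junction_contrast
_FRACTION_TOL = 0.02  # stripe discretization tolerance
_HARMONIC_ORDERS = (2, 3, 4, 5)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic disc image.

    boundary_irregularity is the amplitude of a smooth low-order harmonic
    radial perturbation, as a fraction of disc_radius (capped at 0.2 so the
    outline stays closed). noise_sd is Gaussian read noise on the [0, 1]
    scale; photon_scale > 0 adds Poisson noise with that many expected
    counts at intensity 1.0.
    """

    image_size: tuple[int, int] = (256, 256)
    disc_center: tuple[float, float] | None = None
    disc_radius: float = 80.0
    boundary_irregularity: float = 0.10
    stripe_fraction: float = 0.25
    junction_contrast: float = 0.8
    gfp_contrast: float = 0.8
    noise_sd: float = 0.02
    photon_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.image_size
        if rows < 16 or cols < 16:
            raise ValidationError("image_size too small")
        if self.disc_radius <= 0:
            raise ValidationError("disc_radius must be positive")
        if not 0 <= self.boundary_irregularity <= 0.2:
            raise ValidationError("boundary_irregularity must be in [0, 0.2]")
        if not 0 <= self.stripe_fraction <= 1:
            raise ValidationError("stripe_fraction must be in [0, 1]")
        for name in ("junction_contrast", "gfp_contrast"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.noise_sd < 0 or self.photon_scale < 0:
            raise ValidationError("noise levels must be >= 0")
        cr, cc = self.center
        max_r = self.disc_radius * (1 + self.boundary_irregularity)
        if (
            cr - max_r < _MARGIN_PX
            or cc - max_r < _MARGIN_PX
            or cr + max_r > rows - 1 - _MARGIN_PX
            or cc + max_r > cols - 1 - _MARGIN_PX
        ):
            raise ValidationError(
                "disc does not fit in the image with a 5 px margin"
            )

    @property
    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        rows, cols = self.image_size
        return ((rows - 1) / 2, (cols - 1) / 2)


@dataclass(frozen=True)
class GroundTruth:
    """The noise-free geometric masks a phantom encodes, and their ratio."""

    disc_mask: RegionMask
    gfp_mask: RegionMask
    true_index: float


def _boundary_radius(spec: PhantomSpec, theta: np.ndarray, rng: np.random.Generator):
    """Star-convex boundary r(theta) with seeded low-order harmonics,
    normalized so the perturbation's peak amplitude equals the requested
    irregularity."""
    amps = rng.uniform(0.3, 1.0, size=len(_HARMONIC_ORDERS))
    phases = rng.uniform(0, 2 * np.pi, size=len(_HARMONIC_ORDERS))

    def raw(t):
        return sum(
            a * np.cos(k * t + p)
            for a, k, p in zip(amps, _HARMONIC_ORDERS, phases)
        )

    norm = np.abs(raw(np.linspace(0, 2 * np.pi, 2048))).max()
    pert = raw(theta) / norm
    return spec.disc_radius * (1 + spec.boundary_irregularity * pert)


def _solve_stripe_width(
    disc: np.ndarray, xx: np.ndarray, cc: float, target: float
) -> np.ndarray:
    """Bisection on the stripe half-width so stripe∩disc / disc hits the
    target fraction within the discretization tolerance."""
    disc_area = disc.sum()

    def stripe(w):
        return np.abs(xx - cc) <= w / 2

    def frac(w):
        return (stripe(w) & disc).sum() / disc_area

    if target == 0:
        return np.zeros_like(disc)
    lo, hi = 0.0, float(xx.max() - xx.min() + 2)
    for _ in range(60):
        mid = (lo + hi) / 2
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    # column inclusion is discrete: take the bracket side closer to target
    w = min(lo, hi, key=lambda v: abs(frac(v) - target))
    if abs(frac(w) - target) > _FRACTION_TOL:
        raise ValidationError(
            f"stripe_fraction {target} unreachable for this geometry "
            f"(closest achievable: {frac(w):.3f})"
        )
    return stripe(w)


def _apply_noise(
    img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.photon_scale > 0:
        img = rng.poisson(img * spec.photon_scale) / spec.photon_scale
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_phantom(
    spec: PhantomSpec, *, image_id: str = "phantom", genotype: str = "phantom"
) -> tuple[DiscImage, GroundTruth]:
    """Render one phantom and its exact ground truth.

    The junction band occupies the outermost _BAND_WIDTH_PX pixels of the
    disc, so the outer edge of the band coincides with the true silhouette
    and an edge-based segmentation of the band recovers the true area.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    cr, cc = spec.center
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    dy, dx = yy - cr, xx - cc
    rad = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    rb = _boundary_radius(spec, theta, rng)

    disc = rad <= rb
    band = disc & (rad >= rb - _BAND_WIDTH_PX)
    interior = disc & ~band

    mesh = ndi.gaussian_filter(rng.random((rows, cols)), 1.5)
    mesh = (mesh - mesh.min()) / max(np.ptp(mesh), 1e-12)
    junction = np.where(
        band,
        spec.junction_contrast,
        np.where(interior, _MESH_AMPLITUDE * spec.junction_contrast * mesh, 0.0),
    )

    stripe = _solve_stripe_width(disc, xx, cc, spec.stripe_fraction)
    gfp = stripe & disc
    reporter = np.where(gfp, spec.gfp_contrast, 0.0)

    image = DiscImage(
        image_id=image_id,
        genotype=genotype,
        junction_channel=_apply_noise(junction, spec, rng),
        reporter_channel=_apply_noise(reporter, spec, rng),
        bit_depth=16,
    )
    disc_mask = RegionMask(disc)
    gfp_mask = RegionMask(gfp)
    truth = GroundTruth(
        disc_mask=disc_mask,
        gfp_mask=gfp_mask,
        true_index=gfp_mask.area_px / disc_mask.area_px,
    )
    return image, truth


@dataclass(frozen=True)
class GroupSpec:
    """One genotype/condition in a synthetic experiment: the mean target
    stripe fraction and its between-image standard deviation."""

    name: str
    mean_fraction: float
    sd_fraction: float

    def __post_init__(self):
        if not 0 <= self.mean_fraction <= 1:
            raise ValidationError("mean_fraction must be in [0, 1]")
        if self.sd_fraction < 0:
            raise ValidationError("sd_fraction must be >= 0")


def _sample_fraction(group: GroupSpec, rng: np.random.Generator) -> float:
    """Normal(mean, sd) truncated to [0, 1]."""
    if group.sd_fraction == 0:
        return group.mean_fraction
    a = (0 - group.mean_fraction) / group.sd_fraction
    b = (1 - group.mean_fraction) / group.sd_fraction
    return float(
        sps.truncnorm.rvs(
            a, b, loc=group.mean_fraction, scale=group.sd_fraction, random_state=rng
        )
    )


def sample_experiment_phantoms(
    group_specs: list[GroupSpec],
    n_per_group: int,
    seed: int,
    *,
    base_spec: PhantomSpec = PhantomSpec(),
    radius_range: tuple[float, float] = (60.0, 100.0),
):
    """Yield (DiscImage, GroundTruth, target_fraction) over a synthetic
    multi-genotype batch, without touching disk.

    Each phantom's RNG stream is derived from (seed, group index, image
    index), so any single image can be regenerated in isolation.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2 (the t test needs >= 2)")
    if not group_specs:
        raise ValidationError("at least one group is required")
    for gi, group in enumerate(group_specs):
        for i in range(n_per_group):
            ss = np.random.SeedSequence([int(seed), gi, i])
            child = np.random.default_rng(ss)
            phantom_seed = int(ss.generate_state(1)[0] % 2**31)
            fraction = _sample_fraction(group, child)
            radius = float(child.uniform(*radius_range))
            spec = replace(
                base_spec,
                disc_radius=radius,
                stripe_fraction=fraction,
                seed=phantom_seed,
            )
            image, truth = generate_phantom(
                spec,
                image_id=f"{group.name}_{i:03d}",
                genotype=group.name,
            )
            yield image, truth, fraction


def generate_experiment(
    group_specs: list[GroupSpec],
    n_per_group: int,
    seed: int,
    out_dir: str | Path,
    *,
    base_spec: PhantomSpec = PhantomSpec(),
    radius_range: tuple[float, float] = (60.0, 100.0),
) -> tuple[Path, Path]:
    """Write a phantom batch to disk: per-image channel TIFFs, a manifest
    CSV ready for ``quantify_batch``, and a ground-truth CSV.

    Returns (manifest_path, truth_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    for image, truth, fraction in sample_experiment_phantoms(
        group_specs, n_per_group, seed, base_spec=base_spec, radius_range=radius_range
    ):
        j_path = out_dir / f"{image.image_id}_junction.tif"
        r_path = out_dir / f"{image.image_id}_reporter.tif"
        write_channel_tiff(image.junction_channel, j_path)
        write_channel_tiff(image.reporter_channel, r_path)
        manifest_rows.append(
            {
                "image_id": image.image_id,
                "genotype": image.genotype,
                "junction_path": j_path.name,
                "reporter_path": r_path.name,
            }
        )
        truth_rows.append(
            {
                "image_id": image.image_id,
                "genotype": image.genotype,
                "true_index": truth.true_index,
                "disc_area_px": truth.disc_mask.area_px,
                "gfp_area_px": truth.gfp_mask.area_px,
                "target_fraction": fraction,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    return manifest_path, truth_path
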