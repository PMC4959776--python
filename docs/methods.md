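# Methods

## The measurement

Each image carries two registered 2D channels: a junction marker
(DE-cadherin immunofluorescence) that outlines the wing-disc tissue, and an
endogenous GFP reporter marking the *ptc*-GAL4 driver stripe. Intensities
are normalized to [0, 1] at load time (division by `2^bit_depth − 1`), so
every threshold in the pipeline is expressed on a common scale regardless
of whether the camera wrote 8- or 16-bit files.

The per-image statistic is the proliferation index
`PI = A_GFP / A_disc` — a pure ratio of pixel counts, so it is invariant to
magnification, pixel size, and rigid transformations applied to both
channels, and it normalizes away differences in overall disc size caused by
developmental asynchrony. By default the GFP mask is intersected with the
disc mask, bounding PI by 1; the unclipped GFP area is recorded alongside
because reporter bleed outside the detected outline can be of interest when
reviewing segmentation quality.

## Disc segmentation

1. **Canny edge detection** on the junction channel after Gaussian
   smoothing (`smoothing_sigma`, default 2 px). Hysteresis thresholds
   default to quantiles of the gradient magnitude — high = 90th percentile,
   low = high/2 — so the detector adapts to staining intensity and is
   invariant to linear intensity scaling; absolute thresholds can be given
   instead.
2. **Gap closing + filling** (`closing_radius`, default 3 px). Junctional
   staining yields slightly broken outlines, so gaps must be bridged before
   filling. The operator is: dilate the edge map by a disk of the closing
   radius, fill interior holes (a pixel is interior iff it cannot reach the
   image border through non-edge pixels, 4-connected), then erode by the
   same disk and re-add the original edges. A textbook closing
   (dilate→erode) *followed* by filling cannot reconnect thin edge curves —
   the eroded bridge collapses before the fill can use it — whereas filling
   the dilated outline backs the bridge with interior, so gaps up to about
   twice the closing radius are bridged while the dilation's boundary
   displacement is undone by the erosion. At radius 0 the operation is pure
   hole filling. The output provably contains the input edges, and the
   filled-component convention (8-connected foreground, 4-connected
   background walk) avoids the usual topological paradoxes.
3. **Component selection**: the largest 8-connected filled component is the
   disc; components below `min_area_fraction` of the image (default 5%,
   inclusive comparison) are ignored, and a "no disc found" error carries
   the largest observed fraction so the caller can adjust parameters. The
   disc mask includes the outline pixels themselves.

The detected silhouette sits on the outer flank of the smoothed junction
band, which biases recovered areas high by roughly one pixel of radius
(~3% of area for an 80 px disc). Shrinking the smoothing sigma removes this
bias on clean images but makes the detector collapse onto noise at low
signal-to-noise, so sigma 2 is kept; the bias is characterized in the test
suite (mean area error ~3.3% at noise sd ≤ 0.05, rising to ~5% at SNR 5)
and cancels almost entirely in the index, because the extra ring contains
no GFP signal (index errors stay below 0.02 in the same regimes).

## GFP segmentation

Pixels with normalized intensity **≥** the configured threshold (inclusive,
stated once here and tested) are GFP-positive. The threshold is uniform per
batch by default, matching how a single manually chosen brightness cutoff
is applied across an experiment; a per-image scope exists for exploration
and is flagged as non-uniform in outputs. `suggest_threshold` computes
Otsu's threshold on the pooled 256-bin histogram of a batch as a
reproducible starting point; it is printed, never silently applied, and the
recorded analysis threshold is always the configured one.

## Statistics

Groups are compared with an unpaired two-sided *t* test on per-image
indices. The default is the pooled-variance (Student) variant,
`t = (m_a − m_b) / (s_p √(1/n_a + 1/n_b))`, `df = n_a + n_b − 2`; Welch's
variant with Satterthwaite degrees of freedom is available and preferable
when group variances differ. Comparisons run against named reference
conditions (each reference vs every other genotype, never itself), not all
pairs. Significance stars follow the convention `*p < .05, **p < .01,
***p < .001` with strict boundaries (p = 0.05 exactly gets no star);
non-significant results render as an empty string in CSVs and "ns" in
plots. **No multiple-testing correction is applied** — each comparison is
at its nominal level, so with many genotypes the family-wise error rate is
larger; apply your own correction if that matters for your design.
Degenerate inputs are handled explicitly: groups smaller than 2 and
zero-variance groups with unequal means are errors; identical constant
groups give t = 0, p = 1.

## Phantoms

`generate_phantom` renders a disc as a star-convex region
`r(θ) = R·(1 + ε·h(θ))` with `h` a seeded mix of harmonics 2–5 normalized
to unit peak, `ε ≤ 0.2` (so the outline stays closed and the fill/closing
logic is exercised on non-circular shapes). The junction channel is a
bright 3 px band occupying the outermost pixels of the disc — the outer
band edge coincides with the true silhouette, as junctional staining marks
the outermost cells — plus a faint (15% of band contrast) smoothed random
mesh inside. The reporter channel is a uniform-intensity vertical stripe
clipped to the disc, its width solved by bisection so the stripe covers the
requested fraction of disc area to within ±0.02 (column discretization).
Poisson noise (at `photon_scale` expected counts) and Gaussian read noise
(`noise_sd`) are applied afterwards and clipped to [0, 1]; ground truth is
the noise-free geometry, so true indices are exact set arithmetic.
Defaults: 256×256 images, radius 80 px, irregularity 0.10, contrasts 0.8,
noise sd 0.02.

`generate_experiment` draws per-image stripe fractions from a normal
distribution truncated to [0, 1] per group, radii uniform in a configurable
range, and derives each phantom's RNG stream from (seed, group index,
image index) so any single image can be regenerated alone.

What the phantoms do **not** emulate: the cellular junction mesh at real
resolution, tissue folds, the peripodial layer, apoptotic debris,
out-of-focus light, or intensity gradients across the field. Passing the
phantom suite shows the algorithmic chain is correct and calibrated under
the stated geometry and noise; it does not certify segmentation accuracy on
real confocal data, where the threshold and Canny parameters must be chosen
by inspection (and are logged per run for that reason).

## Validation experiments and problem sizes

The validation module runs the full chain under controlled conditions:

- **Recovery sweep**: 20 phantoms, radius 60–100 px in 256×256 images,
  irregularity ≤ 0.15, noise sd ≤ 0.05, stripe fractions cycling
  0.1/0.2/0.3. Measured: mean absolute relative disc-area error (~3.4%) and
  per-image index error (< 0.02).
- **Type-I calibration**: two groups drawn from the same distribution
  (mean fraction 0.15, sd 0.03, n = 15 per group), 200 replicates through
  the full image pipeline; the rejection rate at p < .05 should sit near
  the nominal 5%.
- **Power**: mean fractions 0.10 vs 0.25, sd 0.03, n = 15 — an effect on
  the scale of a strong overgrowth phenotype — 100 replicates; essentially
  every replicate is flagged.

The Monte-Carlo runs use compact 128×128 phantoms (radii 38–50 px, noise
sd 0.03) so thousands of full-pipeline replicates complete in about a
minute; the statistical behaviour under test (calibration and power of the
index comparison) does not depend on the absolute image size, only on the
index distributions the pipeline recovers.

## Numerical conventions

- Threshold and star-boundary comparisons as stated above (≥ for
  intensity, strict < for stars).
- Component selection breaks ties by the first-labelled component;
  `min_area_fraction` comparison is ≥.
- Stripe-width bisection runs 60 iterations over continuous width and then
  takes the bracket side closer to the target (column inclusion is
  discrete).
- Indices are stored at full float precision and rendered to 3 decimals in
  CSVs; reruns with identical config produce byte-identical outputs.
- Seeds everywhere are plain integers; batch streams derive from
  `numpy.random.SeedSequence` spawning.
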