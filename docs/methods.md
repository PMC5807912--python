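# Methods

## Input model and coordinate conventions

The unit of analysis is one histologic cross section, represented as an
8-bit RGB raster in which vessel profiles have been painted by hand in
three reserved colors: central artery red, central vein blue, all other
vessels green, on a neutral (near-white) background. The software never
segments vessels from raw histology — the manual marking is the input, and
the pipeline's job is to measure it.

Calibration is a single isotropic scale (µm per pixel); anisotropic pixels
are not supported. The coordinate origin is the center of the top-left
pixel, x rightward, y downward; everything downstream of calibration is in
micrometres. Default reference colors are pure red/blue/green with a
per-channel tolerance of 40 — the field convention names colors, not RGB
values, so both are configurable. A valid color convention requires the
three references to be pairwise more than twice the tolerance apart
(Chebyshev distance), which also makes class membership unambiguous by
construction; the splitter still carries a defensive ambiguity check.

## Resampling

Rasters are resampled to a square working grid (default 2,500 px edge)
before analysis. Interpolation is nearest-neighbor only: any smoothing
interpolation would invent intermediate colors and corrupt class labels.
The scale is multiplied by `max(width, height) / target` so physical extent
is preserved to within one pixel. Non-square inputs keep their aspect ratio
and are padded with background to the square — a convention, since only a
square target size is part of the assay definition.

## Detection and shape measurement

Each 8-connected component of a class mask is one vessel mark;
4-connectivity would split diagonal strokes of hand-painted marks.
Components below `min_pixels` (default 4 at the working resolution) are
discarded as stray annotation pixels; 0 restores keep-everything behavior.

Shape is summarized by the moment-equivalent ellipse: eigenvalues λ₁ ≥ λ₂
of the pixel-coordinate covariance give full axis lengths `4√λᵢ · scale`.
Pixels are treated as unit squares (a +1/12 term on the covariance
diagonal), which keeps the minor axis strictly positive for one-pixel-wide
strokes and is exact for the union-of-squares region. Area is exactly
`pixel_count × scale²`. Alternatives (bounding box, Feret diameter) were
rejected: the marks are elliptical by instruction to the annotator, and
moment-equivalent ellipses are the standard realization.

Accuracy: for rasterized ellipses the axes are recovered with ~0.03–0.2%
bias and a quantization noise floor that grows as the minor axis shrinks —
sd ≈ 0.5% at a 20 px minor axis, ≈ 1.2% at 10 px, with worst-case errors
near 3% at the 10 px edge. Sub-pixel information simply does not survive
hard rasterization; consumers should treat per-vessel diameters below
~10 px as carrying a few-percent uncertainty. Centroids are sub-pixel
accurate at all sizes.

The largest blue component is the central vein, the largest red the
central artery; additional blue/red components are reclassified as
capillaries with a warning. A missing vein is an error for
distance-dependent metrics only — counts, areas and densities are still
reported and the sample is flagged, never silently dropped.

## Perfused area

Each mark's actual pixel footprint (not an equivalent disk) is expanded by
the perfusion radius, default 150 µm, representing the oxygen diffusion
range; the union is single-counted by construction. Implementation:
Euclidean distance transform of the background on a canvas padded by the
radius, thresholded at the radius in pixel units, pixel-counted, converted
to mm². This matches closed-form disk, annulus, and two-disk
inclusion–exclusion areas within 1% at raster scales ≤ 2 µm/px. The
central artery and vein halos are included in the union by default (their
marks carry the perfusion radius like any other vessel) while the count
always excludes the central pair; `exclude_central_from_area` flips the
area behavior, since either reading of the assay is defensible.

The density identity `ρ · A = N` holds to float round-off per sample and is
asserted in tests.

## Histograms

Diameter histograms default to 10 µm bins over (0, 300) µm; ingrowth
histograms to 250 µm bins over (0, 3000) µm. Normalization divides by the
in-range count so heights sum to one ("fraction of the total vessel
count"); the smoothed variant applies a centered moving average (default
window 3 bins) after normalization, with zero-padded edges. None of these
constants are intrinsic to the method; all are configurable.

## Group statistics

Means are reported with SEM (sample sd, n−1 denominator, over √n). Groups
are compared by classical fixed-effects one-way ANOVA; a group needs at
least two samples to enter, and samples missing a metric (e.g. no central
vein) are dropped per metric, not imputed.

Post hoc comparisons use Duncan's multiple range test: means ranked; a pair
spanning r ranks is significant when its difference exceeds
`q(1−α_r; r, df_within) · √(MS_within / n_h)` with protection levels
`α_r = 1−(1−α)^(r−1)` and `n_h` the harmonic mean of the two group sizes
(the standard unequal-n adaptation; the assay's groups suffer attrition).
A sub-range of a non-significant range is never significant (step-down
containment), keeping decisions transitive. Quantiles come from the
studentized range distribution directly rather than printed tables, cached
by (α, r, df); for r = 2 this is mathematically the pooled two-sample
t-test, which tests exploit as an independent oracle. Star levels (1/2/3)
re-run the procedure at α = 0.05/0.01/0.001; since Duncan's test natively
yields decisions rather than p-values, an optional per-pair p is defined as
the smallest α at which the pair turns significant, found by bisection
(the decision is monotone in α). No correction is applied across the five
metrics — each is reported as its own family, matching assay practice.

Validation: ANOVA agrees with an independently hand-computed table and
with `scipy.stats.f_oneway` to 1e-9; Duncan decisions with k = 2 agree with
the pooled t-test on every random fixture tested; null simulations (k = 4,
n = 10) put the ANOVA type-I error within binomial simulation error of
α = 0.05.

## Synthetic data: what it emulates, and what it does not

The generator renders one centric vein (default 300 µm diameter), one
centric artery (180 µm, offset 450 µm at a random angle), and a population
of elliptical capillary marks on a white 2,500 px field at 2 µm/px — a
5 mm field, matching the ~4–5 mm tissue cylinder of the implantation
assay. Capillary diameters are log-normal (median 15 µm, σ_log 0.5,
truncated to [5, 300] µm), qualitatively matching capillary-dominated
diameter histograms; this default is illustrative, not fitted. Radial
placement is uniform over a configurable annulus; orientations uniform;
axis ratios uniform in (0.6, 1.0). Placements are rejection-sampled
(bounding-circle test, 1000 attempts per mark) so distinct marks are
separated by ≥ 3 px and never touch the central pair — the analysis
assumes one component per vessel. Placements that would rasterize below
4 px are redrawn, so every ground-truth mark is resolvable at the raster
scale; at the default scale this truncates only the extreme lower tail of
the diameter distribution. Rendering is hard-edged by default (clean class
labels); an anti-aliased mode exists solely to exercise color-tolerance
handling. Every output is a pure function of the spec including its seed.

Multi-sample studies derive per-sample seeds deterministically from a study
seed and, by default, draw each sample's capillary count from a Poisson
around the group template — without between-sample variation, ANOVA on
vessel count would be degenerate. Real sections differ from these fixtures
in ways the generator does not model: staining artifacts, annotator
variability, non-elliptical and touching marks, spatially clustered
growth, and biologically overdispersed counts. Passing tests therefore
demonstrate correctness of the measurement pipeline on well-formed
annotations, not robustness to annotation error.

## Problem sizes in the test suite

Detection completeness is verified on 50 full-size samples (2,500 px,
20–250 marks each). Pipeline sensitivity uses a two-group study (60 vs 170
capillaries, n = 10) at 800 px / 4 µm/px; null calibration runs 200
replicate two-group studies at 300 px / 4 µm/px with 25-capillary samples
through the detection-to-count path. These sizes are the package's chosen
desk-scale study conditions; all are set in the test fixtures and scale up
without code changes.

## Known limitations

- Single-plane analysis only; no serial-section registration or 3-D
  reconstruction. Perfused area is a 2-D proxy for vascularized volume.
- The perfusion radius is a fixed geometric convention, not a diffusion
  model.
- Diameter accuracy is quantization-limited below ~10 px minor axis (see
  above); at the default working scale of ~1.3–2 µm/px this affects the
  smallest capillaries.
- The smoothing applied to "smoothed" histograms is a moving average; the
  assay definition names no method, so any comparison against differently
  smoothed figures should re-bin from the raw values.
- Duncan's test controls error rates less conservatively than Tukey's HSD
  by design; it is implemented because it is the assay's stated procedure.
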