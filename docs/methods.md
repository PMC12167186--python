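# Methods

## Coordinate model

All volumes are NIfTI-1 with a 4×4 affine mapping 0-based voxel indices
`(i, j, k)` (slice axis last) to scanner millimetres. The pipeline never
estimates a registration: volumes acquired in one session are assumed to
share the scanner frame, and every lookup composes the two affines. The
world frame is whatever the headers encode (RAS for conformant files); no
reorientation is applied, so oblique acquisitions work unchanged.

A slice's "centre" is the world image of its in-plane central voxel index
`((nx−1)/2, (ny−1)/2, k)`, not its world-z coordinate — the two coincide
for axial stacks but only the former stays meaningful for oblique ones.
Slice matching minimizes the Euclidean distance between map and source
slice centres; ties break to the lower source index, and map slices beyond
the source stack clamp to the terminal slice with the distance recorded
(the alternative, rejecting them, is available to callers by checking that
distance; nothing in the measurement model forces either choice).

## Label transfer

Labels are categorical, so interpolation is nearest-neighbour by
necessity. The default `slice` mode pins the through-plane coordinate to
the matched source slice and finds the nearest voxel in-plane within it,
matching a per-map-slice quantification design in which each map slice is
compared against exactly one anatomical slice; a free 3-D nearest-voxel
mode exists behind a flag for comparison. Map voxels whose world point
leaves the source field of view carry no ROI; vessel labels are excluded
from every segment ROI.

## Quality control

Order of application: erosion → NCC subselection → outlier removal →
entropy gate → minimum-size gate. The order is a design choice (the five
components are independent); size is gated last so the final count
reflects every removal. All gates are non-expanding.

* **Erosion**: per-slice 2-D binary erosion, 3×3 cross, 1 iteration
  (small) or 2 (large). At map resolution (~1.4–2.2 mm pixels) one
  iteration strips roughly the partial-volume rim.
* **Outlier removal**: the band is `median ± k·MAD` (default k = 3) of the
  *total liver* — the union of all segment ROIs on that map — computed
  before any per-segment removal, so a locally corrupted segment cannot
  widen its own band. MAD is the raw median absolute deviation (no 1.4826
  consistency factor). A zero MAD retains everything; the alternative
  (keep only exact-median voxels) would empty ROIs on quantized maps.
* **Entropy gate**: Shannon entropy (bits) of the ROI histogram over the
  sequence's nominal intensity range (12-bit for T1 maps, 0–409.5 for T2
  maps stored in 0.1 ms steps). Four variants: {32, 64} bins × {strict,
  lenient}, with thresholds log2(bins) − 1.5 (strict) and − 0.5 (lenient)
  bits, i.e. 4.5/5.5 bits at 64 bins. These thresholds are calibration
  parameters, not measured constants, and are exposed in configuration.
* **NCC subselection**: for each map slice of each segment, candidate
  source slices `matched ± neighbourhood` are scored by the Pearson
  correlation between the map intensities inside the ROI and the source
  intensities bilinearly sampled at the same world positions; ties break
  to the smaller offset, then the lower index. The correlation is computed
  on the ROI *interior* (the mask eroded by up to two iterations while at
  least 20 voxels remain): boundary voxels mix tissues and track the ROI
  outline rather than the tissue the map samples, and in diagnostics they
  produced a systematic one-slice bias in the argmax. A zero-variance ROI
  keeps the matched slice. When a different slice wins, the segment's mask
  on that map slice is re-transferred from it (and re-eroded).

The optimized preset (`QCConfig.optimized()`) enables minimum size
50, MAD±3 removal and strict 64-bin entropy detection, with no erosion and
subselection off — the configuration whose three active components won
the grid search in our experiments.

## Quantification

The segment statistic is the mean over all retained voxels pooled across
slices (the median is reported alongside). Pooling equals weighting
per-slice means by per-slice counts, which is the manual convention for
segments spanning several slices. Total liver is the union of the
*post-QC* voxel sets of passed segments; raw voxels of omitted segments do
not enter it, keeping the total consistent with what was actually deemed
measurable.

## Reliability statistics

ICC(1,1) is the one-way random-effects single-measure coefficient with
k = 2 raters: `(MSB − MSW) / (MSB + MSW)`, with the exact F-based 95% CI
and a p-value from `F = MSB/MSW` on `(n−1, n)` degrees of freedom (the
F-test was chosen over a bootstrap test; either is defensible and the
choice is documented here). Zero between-target variance reports ICC 0
with a warning; zero within-target variance reports 1. Deming regression
uses the closed-form errors-in-variables solution with error-variance
ratio δ = 1 by default (orthogonal; symmetric under axis swap). The paired
comparison uses the two-sided Wilcoxon signed-rank on `auto − manual`
differences with percentile-bootstrap CIs (B = 10,000, seeded;
differences are resampled for the median-of-differences CI, pairs for the
per-arm CIs). The agreement taxonomy counts positive agreement (both
measured), negative agreement (neither), human-only — subdivided into no
segment delineated, breathing misalignment, and QC omissions (min size /
entropy / outlier-emptied) — and algorithm-only.

## Configuration optimization

The grid spans erosion {none, small, large} × minimum size {50, 75, 100}
× outlier {off, MAD±3} × entropy {off, 4 variants} × subselection {off,
±2, ±3} (270 combinations). Each configuration is scored
`f = meanICC − α·sdICC + β·coverage` with α = β = 1 by default; the weights
are configurable so any site-specific trade-off can be expressed. ICC cells need at least 3
complete pairs; configurations with no valid cell are skipped with a
warning. Ranking is deterministic (f, then coverage, then the
configuration key) and independent of exam order.

## Synthetic phantom

The phantom is deliberately schematic — an ellipsoidal liver (semi-axes
46×38×80 mm) partitioned into a central caudate-like cylinder (segment I)
plus four angular wedges per axial half (II/IVa/VII/VIII above, III/IVb/
V/VI below), with a portal tube and two hepatic tubes overriding
parenchyma. Nothing downstream depends on anatomical realism, only on
labels, affines and values. Geometry defaults follow a typical liver mpMRI protocol:
96×96×80 source at 1.25 mm / 3 mm slices; 64×64×4 maps at 2.08 mm / 8 mm
thickness / 32 mm spacing (configurable over 20–32 mm).

Ground truth per sequence is one exam-level draw N(835, 50²) /
N(518, 30²) / N(37, 4²) ms (between-patient variation, matching
reference total-liver relaxometry ranges) plus per-segment offsets N(0, 5²) /
N(0, 3²) / N(0, 0.3²) ms: segmental relaxation times within one liver vary
far less than they do across patients, and an inter-segment spread
comparable to the population spread would make the total-liver MAD band
clip healthy segments. Voxel noise is Gaussian with σ a fraction (default
2%) of the local true value; map background is exactly zero so noiseless
maps equal their manifest truth bit-for-bit.

Artifacts are opt-in: speckle outliers (a fraction of liver voxels
multiplied by 1.8–2.5), full-range-noise segments (uniform over the
sequence intensity range), and breathing shifts (the source affine
translated along world z while the voxel content stays put — exactly the
mismatch NCC subselection must undo). A shared smooth "texture"
(multi-sinusoid modulation, amplitude a configurable fraction, source
amplitude 4× the map amplitude) gives map and source slices correlated
anatomy; it is off by default and is required for any NCC experiment,
since segment-constant maps carry no alignment signal. With 3 mm source
slices and 32 mm map spacing, two of the four map planes sit 1.5 mm from
the nearest source plane, so after a 3 mm shift two candidate slices are
exactly equidistant from the map plane; "corrected" in the breathing
experiments therefore means the selected slice attains the minimal
achievable anatomical distance, and an exam counts as corrected when the
majority of its ROIs do.

Synthetic manual readings are truth plus reader noise (σ = 5 ms for T1
sequences, 1 ms for T2). Note the implied ceiling: with a 4 ms
between-subject T2 spread and 1 ms reader noise, the best attainable
manual-vs-anything ICC is ≈ 0.97, so experiments that probe *pipeline*
fidelity compare against the manifest truth instead.

## What the phantom does and does not show

Passing tests demonstrate geometric correctness of the transfer (exact
agreement with a brute-force world-coordinate oracle), correct QC
semantics, deterministic behaviour, and recovery of known values under
noise, partial-volume mixing at segment borders, vessel exclusion and the
modelled artifacts. They do not demonstrate performance on real anatomy:
real livers have irregular segment boundaries, susceptibility and motion
artifacts with structure the phantom lacks, imperfect upstream
segmentations, and manual readings with reader-specific bias rather than
unbiased noise. The problem sizes (10–40 phantom exams per experiment,
~16k map voxels each) were chosen as the smallest at which the statistics
of interest stabilize.

## Numerical notes

Affines are rejected when |det| < 1e-12. Slice-match distances are
rounded to 9 decimals before argmin so the lower-index tie-break is not
defeated by float noise. Histogram entropy normalizes by the in-range
count; a ROI entirely outside its nominal range scores 0 bits. Deming
with zero covariance degenerates to slope 0 or ∞ depending on which axis
carries variance; zero variance on both axes is an error. Bootstrap
resampling uses `Generator.integers` row-wise so results are reproducible
from the seed alone.
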