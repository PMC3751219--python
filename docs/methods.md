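# Methods

This note documents the models and procedures implemented in `fracvasc`,
their assumptions, the parameters that matter, and the design choices made
where the problem left the design genuinely open.

## Micro-CT vessel morphometry

### Segmentation

Voxels are classified monotonically in gray value into air < tissue <
vessel < bone using three cut points. The automatic criterion is
mode/valley based: the gray-value histogram (256 bins, artifact slices
excluded) is log-transformed (`log1p`) and smoothed with a Gaussian kernel
(σ = 2 bins); its peaks are the class modes, and each cut is placed at the
histogram valley between consecutive modes.

A mass-weighted criterion such as multi-level Otsu is deliberately *not*
used: contrast-filled vessels are typically a fraction of a percent of the
voxels, and Otsu's between-class variance then prefers splitting a
dominant mode (e.g. halving the tissue peak) over isolating the vessel
band, which floods the vessel class with tissue noise. Valley positions do
not depend on class mass, only on mode separation.

When only three modes are present, the absent class is assumed to be the
vessel band — it is the rare class by nature, and by the contrast protocol
its density lies midway between soft tissue and bone — and its two cuts
are placed at 1/4 and 3/4 of the tissue-to-bone mode distance. Volumes
whose histogram shows fewer than three modes (e.g. constant volumes) raise
an explicit error naming the collapse rather than returning a degenerate
map. Users may always supply the three cut values directly
(`supplied_thresholds`); thresholds used are recorded in the label map's
provenance either way.

### Mask cleanup

Order: binarise the vessel class → in-plane morphological closing →
in-plane median smoothing → removal of small 3D connected components.
All three parameters default to (close_radius, median_radius, min_size) =
(1, 1, 2) and are recorded in the output provenance; with all parameters
zero the mask equals the raw vessel class exactly.

- Closing uses a square (Chebyshev) structuring element of half-width
  `close_radius`, so a gap of up to `close_radius` voxels between vessel
  fragments is bridged (a disk/cross element of radius 1 does not bridge a
  1-voxel gap).
- The minimum-size filter acts on **3D** components (26-connectivity), not
  per-slice areas. This is the one place 3D information is used: an
  isolated noise voxel is a 3D singleton, while a genuine sub-resolution
  vessel (1-voxel cross-section) persists across many slices as a long 3D
  component. A 2D area filter could not suppress speckle without deleting
  true small vessels — the very signal the small-vessel fraction measures.
- Artifact slices are always forced to zero.

For noiseless data the natural parameters are (0, 0, 0); for noisy data
(0, 0, 2) suppresses speckle with no effect on any structure at least two
voxels in 3D extent.

### Counting and size distribution

Each analysed slice is labelled independently by 2D connected components;
in-plane connectivity defaults to 8 (diagonally touching contrast blobs
are one vessel) and is configurable to 4. One component = one vessel
cross-section; counts and areas are summed over slices with no 3D
deduplication, so "vessel number" is a slice-wise aggregate — deliberately
so, as the per-slice sum is the measurement this pipeline standardises.

Areas are binned into right-closed decades (prev, upper] with upper bounds
1, 2, 5, 10, 50, 100, 500, 1000, 5000 voxels plus an overflow bin, so bin
counts always sum to the total count. The small-vessel fraction is the
number of cross-sections of area ≤ 2 voxels over the total; an empty
region reports 0 with an explicit `empty` flag rather than NaN.

Physical conversion: `area_um2 = area_voxels · voxel_size²` and the
equivalent diameter `2·sqrt(area/π)`; at 21 µm, 1- and 2-voxel
cross-sections correspond to ~23.7 and ~33.5 µm calibre. Both are
reported; no fixed area-to-calibre table is enforced.

### Region selection

Slice intervals are half-open and 0-based. `between_pins` takes the four
pin whiteout ranges (sorted) and selects from the end of pin 2's range to
the start of pin 3's (380 slices at 21 µm ≈ 7.98 mm ≈ the nominal 8 mm
fracture zone). `mid_third` selects [⌊n/3⌋, ⌈2n/3⌉) of an n-slice stack —
[500, 1000) for 1500 slices — as the level-matched region on intact limbs.

## Laser-Doppler perfusion analysis

Scans are 2D flux grids, by default 250×250 at 0.1 mm pitch. ROI
membership is pixel-centre based: rectangles are half-open pixel boxes;
polygon membership is centre-in-polygon with boundary centres excluded, so
abutting ROIs never double-count a pixel. Regional means drive all
downstream analysis (maxima are carried along).

The daily-variation correction is region-matched: cranial fractured is
divided by the cranial DailyVar of the same animal, and so on for each of
the four regions. The baseline convention is percent-of-baseline (pre-op
= 100, computed as `100·(x/x₀)` so the baseline entry is *exactly* 100 in
floating point); a percent-change convention (0 = unchanged) is available
as a formatting option. Missing timepoints are left missing — flagged by
absence, never interpolated — and day mismatches between the fractured
series and DailyVar are errors listing the unmatched days. No automatic
outlier rejection (e.g. for skin-nick hyperperfusion) is applied.

Repeatability: all rater pairs on the common scan set are Spearman
rank-correlated per region (mid-ranks for ties), with a per-region average
across pairs; fewer than three common scans is an error, since rank
correlation is meaningless there.

## Statistics

- **Paired t with Bonferroni**: t = mean(d)/(sd(d)/√n), df = n−1,
  p_adj = min(1, m·p). The family size m is always an explicit argument.
  Zero-variance differences are flagged degenerate (identical pairs → t=0,
  p=1; constant nonzero difference → infinite t, an exact difference).
- **One-way ANOVA + LSD**: classical between/within decomposition; LSD
  pairwise t-tests use the pooled MSE with df = N−k and no multiplicity
  adjustment (that is what LSD means).
- **Spearman**: mid-ranks then Pearson on ranks; undefined (NaN with a
  warning) under zero rank variance.
- **Growth model**: random-intercept linear mixed model via statsmodels
  MixedLM, fitted by **maximum likelihood** (not REML) so that
  likelihood-ratio tests between nested fixed-effect structures are valid.
  Fixed effects: time (linear or quadratic in days) plus optional
  covariates (matched intact-limb measure, cranial measure, body
  temperature) aligned by (animal, day); available-case handling for the
  staggered sacrifice schedule. Per-term tests report F = (β̂/se)² with 1
  numerator df and a between–within (containment) denominator df,
  n_obs − n_groups − (p_fixed − 1); this is an approximation and is
  labelled as such (software packages differ in their fractional-df
  approximations and no attempt is made to match any of them exactly).
  Optimiser fallbacks (lbfgs → bfgs → cg → powell) are tried in order; a
  non-converged solution is accepted only when the variance component is
  pinned at zero (a boundary solution, flagged, not an optimiser failure).
  One-observation-per-group designs are flagged as boundary cases since
  τ² and σ² are not separately identifiable.
- **LRT**: χ² = 2(ℓ_full − ℓ_reduced), df = parameter-count difference;
  requires nested fixed effects and equal observation counts; small
  negative statistics are clamped to zero with a warning.

## Synthetic data

### CT phantoms

A phantom is tissue everywhere, optionally air outside a limb radius and a
hollow cortical-bone cylinder, with tubular vessels on top. The
rasterisation rule is fixed and shared by the generator and every
ground-truth computation: a voxel belongs to a vessel iff its centre lies
within the vessel radius of the centerline segment (for slice-axis-aligned
vessels this is exactly the per-slice centre-in-disk rule). Ground truth
(per-slice per-vessel pixel areas, counts, decade histogram, small-vessel
fraction) is computed from this geometry alone and never touches the
segmentation code. Vessels with different labels that overlap are rejected;
sub-voxel radii are generated with a warning. Voxels are class mean +
Gaussian noise; artifact slices are rendered saturated white and excluded
from ground-truth totals.

Default class means 0/80/160/240 (vessel midway between tissue and bone),
voxel size 21 µm, noise tested up to 1/8 of the inter-class spacing
(sd 10). The random-spec generator places near-axial tubes (radii 0.6–6
voxels, 0–10 per phantom, small in-plane tilt) with enough clearance that
every vessel is one connected cross-section per slice; default volumes are
48×64×64 voxels with two pin-whiteout ranges near the stack ends. What the
phantoms do **not** emulate: reconstruction physics (beam hardening, ring
artifacts), branching trees, a biological callus, or intra-cortical
vessels — so passing recovery tests demonstrates correctness of the
measurement chain, not robustness to every real-scan pathology.

### Perfusion cohorts

Generative model for animal i, region r, day t:

    fractured mean  μ_r(t) = b_r(1 − δ_r) + c₁ᵣ t + c₂ᵣ t²   (t ≥ 0)
    intact mean     b_r (flat);  pre-op mean = b_r for both limbs
    observation     y = (μ + u_i) · m_{i,t} + ε,
                    u_i ~ N(0, τ²), log m_{i,t} ~ N(0, ω²), ε ~ N(0, σ²)

One multiplier m per (animal, day) is shared by both limbs and all
regions — exactly the fluctuation the DailyVar correction removes — and is
fixed at 1 on the pre-operative reference day; it is log-normal so
corrected values stay positive. The pre-operative timepoint is coded
day = −1 in numeric columns (labelled "preop"), measurement days are
0, 1, 2, 4, 7, 14, 28, 42 by default, and the schedule is configurable.

Default regional effects (flux units) encode an immediate post-operative
drop followed by a quadratic recovery peaking near two weeks and then
declining: cranial b=200, δ=0.40, c₁=18.9, c₂=−0.45 (peak ≈ 159 % of
baseline at day 21); femoral artery 400/0.35/12/−0.28; distal femoral
350/0.35/10/−0.24; caudal 180/0.25/6/−0.15 (the weakest responder).
Default τ=20, ω=0.1, σ=15, n=32 animals. Non-positive generated values
(possible only under pathological parameters) raise by default, or are
clipped with a warning under `strict_positive=False`.

## Problem sizes used in validation

The test suite and the acceptance script validate at sizes chosen to make
every Monte-Carlo bound sharp while remaining desk-scale: 200 random
64×64×8 masks against the flood-fill oracle (both connectivities); 20
random phantoms per noise level; 32-animal cohorts with 50 replicates for
fixed-effect bias, 100 for LRT power, 500 for null calibration. Observed
behaviour: exact recovery on noiseless phantoms; ≤ ~1 % count error and
≤ ~0.01 small-vessel-fraction error at noise sd = spacing/8; fixed-effect
bias well under 1 %; LRT power ~100 % at the default effect size and null
rejection within Monte-Carlo error of the nominal 5 %.

## Known limitations

- Per-slice counting over-weights long vessels relative to a 3D census;
  this is the intended, documented definition of "vessel number" here.
- The mode/valley segmentation assumes the four classes appear as
  separated histogram modes; heavy noise (mode overlap) or strong
  intensity gradients would need supplied thresholds or pre-correction.
- The containment denominator df for mixed-model F-tests is approximate;
  LRT-based conclusions are preferred for model comparison.
- ROI placement is explicit (files/coordinates); no image registration or
  automatic femoral-artery detection is attempted.
- Instrument-native LDI formats and DICOM are out of scope; scans travel
  as CSV grids or TIFF.
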