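# Methods

## Scope and model

The package analyses the regional organisation of mitochondrial function in
single adherent cells imaged by wide-field fluorescence microscopy, plus
plate-based respirometry, and combines both into a partition of scaled
ATP-linked respiration between the perinuclear and peripheral cytoplasm.
All processing is 2-D: the acquisition this targets is single-plane
wide-field imaging of flat, spread cells, so the 3-µm perinuclear shell is
measured in the image plane only.

## Region partition

The nucleus is segmented from the nuclear-stain channel by Otsu
thresholding, hole filling and largest-component selection; fields with no
bright object, or with a second object within 50% of the largest one's
area, raise an ambiguity error rather than guessing (the caller crops to a
single cell first).  The perinuclear band is defined on the exact Euclidean
distance transform of the nucleus mask: a cytoplasmic pixel is perinuclear
iff its distance to the nearest nucleus pixel, converted through the pixel
size, is in (0, 3000 nm].  The upper bound is closed — pixels at exactly
the band width belong to the band — which makes the tie-break
deterministic.  Pixels are addressed by their centers in 0-based raster
coordinates.  The band width (default 3000 nm) and pixel size are
parameters, so the partition is resolution independent.

## Detection and tracking

Per frame, a large-sigma Gaussian estimate of the background (default
sigma 12 px) is subtracted and the residual thresholded by Otsu.  Because
an Otsu split is unreliable when bright pixels are rare, the threshold is
floored at 5 scaled MADs above the background median; components smaller
than `min_area_px` (default 4) are discarded.  Centroids are
intensity-weighted over the component dilated 2 px past the threshold
contour — the smooth intensity tails then carry the sub-pixel information
and the frame-to-frame flicker of the threshold boundary does not move the
centroid (empirically ~10 nm median localization error at SNR 20 and
162.5 nm pixels).  Length and width are the extents of the half-maximum
subset of the component along its principal axes: under symmetric blur the
half-maximum of an edge sits on the true boundary, so these extents track
the physical rod rather than the threshold level (isolated-rod errors are
roughly −4% in length and +17% in width at the default optics).

Tracks are built by greedy mutual-nearest-neighbor linking between
consecutive frames: a link is accepted only when track and detection are
each other's nearest candidates within the gate `max_disp` (default
300 nm).  Gaps up to 2 frames are bridged by linear interpolation.  The
gate is deliberately tight — an order of magnitude above the per-frame
motion but below inter-mitochondrion spacing — so that the centroid jumps
produced when touching mitochondria merge and split are rejected instead
of contaminating tracks; the resulting fragments are then removed by the
track-span filter (default: tracks must span at least `n_frames − 4`
frames).  Motility therefore comes from the subpopulation of mitochondria
that remain individually resolvable through the epoch, which mirrors how
clearly defined organelles are selected in practice.

Net displacement is the Euclidean distance between a track's first and
last centroids.  Zero displacements are floored at 1 nm (half the nominal
localization precision) before log transforms.  The log-normal summary is
the geometric mean exp(mean(ln d)) and geometric SD exp(sd(ln d)); region
membership is frozen at the first-frame centroid even if a mitochondrion
crosses the band during the epoch, so each displacement carries exactly one
regional label.

## Volumes

Each mitochondrion is modeled as a spherocylinder of radius r = width/2:
V = π r² (L − W) + (4/3) π r³, a sphere when L = W.  A pure-cylinder
variant is exposed for sensitivity analysis.  Regional volumes are summed
over a single reference frame (the first), so every object is counted
exactly once regardless of later track fragmentation.  Touching
mitochondria can merge into one component whose principal-axis bounding
box — especially its width, for non-collinear pairs — grossly inflates the
spherocylinder volume; components wider than ``max_width_nm`` (default
900 nm, comfortably above any single mitochondrion at these optics) are
therefore excluded from volume sums as unresolved clusters.  With this
filter the regional volume fraction is accurate to a few percent at
moderate density; in heavily crowded perinuclear bands a residual bias
remains because clusters form there more often.  Group-level analyses
average over several cells, which is also how the validation tests treat
it.

## TMRM potential

Each detected (or supplied) mitochondrial component is one measurement: its
mean pixel intensity is paired with the mean of a local background ring
2–4 px beyond its outline, excluding all mitochondrial pixels, so local
illumination cancels.  The raw regional value is the mean mitochondrial
intensity minus the mean background over at least 12 measurements per
region (fewer is an error naming the region); negative differences are
clamped to zero with a logged count, since the potential proxy cannot be
negative.  Raw values are normalized by the control group's perinuclear
mean, making the control perinuclear value 1 by construction.  The "12
measurements" floor is interpreted per mitochondrion, matching the
per-organelle fluorescence readout.

## Respirometry

Plate CSVs carry one row per (well, stage, measurement): stages are
baseline, oligomycin, FCCP, rotenone, with (by default) three measurements
per stage, and at least three unseeded background wells.  Background wells
whose trace median deviates from the across-well median by more than
3 scaled MADs are excluded as erratic (a deterministic formalisation of
discarding extreme background readings); the surviving wells' mean is
subtracted per timepoint.  Stage values are the mean of the stage's
measurements.  The rotenone stage is the non-mitochondrial OCR and is
subtracted from the other stage values before derived parameters are
formed — the standard mito-stress-test convention; a flag restores the
uncorrected reading.  SRC = maximal − baseline and ATP-linked = baseline −
leak hold exactly by construction.  Per-well profiles are retained;
group mean ± SD is computed downstream.  Normalization by seeded cell
count is available (`per_cell=True`) but off by default so that outputs
stay in pmol O₂/min per well.

## Bioenergetic partition

The linearized association between normalized potential and respiration is
an affine map ψ ↦ aψ + b with default (a, b) = (1, 0).  Any map with b = 0
cancels in the partition (only weight ratios matter), so only a nonzero
intercept changes results; the constants are exposed in configuration and
maps that could produce negative factors are rejected when constructed.
The partition multiplies each region's weight ψ*L · V by the scaled
respiration R = Resp^ATP/Resp^ATP_control and divides by the total weight,
so the two components sum to R exactly and the control condition totals 1.
Group-level partitions use group means of potentials, volumes and
respiration, matching mean-based reporting; a per-cell mode is simply the
same function applied per cell.

## Statistics

Motility comparisons are two-sided Welch t-tests on log displacements (the
minimal test consistent with log-normal motility and unequal group sizes),
reported with the geometric-mean ratio as effect size.  Normality is tested
with the D'Agostino–Pearson omnibus K² (skewness + kurtosis z-scores
against χ²(2)), refused below n = 20 where the component approximations
are unreliable.  Multi-group designs use one-way ANOVA with Tukey–Kramer
post hoc pairwise comparisons (studentized range, valid for unequal n); in
calibration simulations the post hoc family is gated on ANOVA
significance, which keeps the family-wise error at or below the nominal
0.05.  A repeated-measures ANOVA keyed by replicate-day identifier is
provided for designs replicated on separate days.  No correction beyond
Tukey–Kramer is applied.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
cell morphology: cells are disks with disk nuclei (the region logic depends
only on masks), rendered in a single plane without photobleaching.
Defaults describe a realistic acquisition: 162.5 nm pixels (6.5 µm camera
pixels at 40×), PSF sigma 150 nm, SNR 20, a 30 µm cell with an 8 µm
nucleus, 200 mitochondria of 0.8–2.2 µm × 0.4–0.6 µm with 30% seeded in
the perinuclear band, and a 5-min epoch of 101 frames every 3 s.

Net displacements are drawn log-normal (median 80 nm, geometric SD 1.5 by
default, per-region medians configurable) and imposed *exactly*: the
endpoint is placed at the drawn distance in a direction keeping it inside
the cytoplasm, and intermediate frames follow a Brownian bridge (per-step
wiggle 30 nm) clamped to the cytoplasmic annulus.  The per-frame motion
model behind a net displacement is not observable from endpoint statistics,
so the bridge is an explicit stand-in; ground truth (the endpoint distance)
is exact by construction, which makes parameter recovery a sharp test.
Positions are seeded with a soft minimum separation of 0.8 median rod
lengths (dart throwing, falling back to the least-crowded candidate), since
mitochondria are solid bodies.  Rods are rendered with an error-function
edge profile centered on the true capsule boundary — the exact profile of
a blurred straight edge — so the half-maximum contour coincides with the
true outline and the intensity is symmetric about the true centroid.  TMRM
rods are additionally rescaled so their mean added intensity over the true
footprint equals the regional potential exactly.  Plate traces place stage
means at (baseline + nonmito, leak·fraction + nonmito, maximal·factor +
nonmito, nonmito) with i.i.d. Gaussian noise, and zero-mean noise in
background wells.

All randomness flows from one integer seed through named `SeedSequence`
substreams, so every artifact is reproducible independently of generation
order.  What the generator does *not* emulate — irregular morphology,
z-drift, photobleaching, spatially varying illumination, fission/fusion —
bounds what passing tests show about real data: they validate the
estimators under the assumed statistical model, not robustness to every
instrumental artifact.

## Validation conditions and problem sizes

Recovery tests run at the default acquisition conditions (200
mitochondria, 101 frames); the motility pipeline recovers the 80 nm
geometric mean within 10% (within 5% from ground-truth tracks), and the
regional ordering of medians (65 vs 95 nm) is recovered in 50/50 seeded
replicates at the track level.  Potential recovery uses 100 noise/layout
realizations (mean absolute relative error < 10%); respirometry uses 500
simulated plates of 10 wells (each parameter within 3 analytically derived
standard errors in ≥ 95% of replicates, and unbiased on average); the
partition conservation law is checked on 10⁴ random inputs at 10⁻¹²; the
end-to-end partition check averages four moderate-density cells (60
mitochondria each), reflecting the group-mean design of regional analyses.
Statistical calibration uses 1000 null replicates (Welch) and 1000
(acceptance suite) / 500 (script) ANOVA-gated Tukey families.  The
acceptance script reports the same quantities at sizes chosen to finish in
a few minutes on one CPU.

## Known limitations

- Tracking is 2-D nearest-neighbor with a fixed gate: it is intended for
  the low-density, clearly-resolvable regime and will fragment tracks in
  dense fields (by design, to protect the displacement statistics).
- Width estimates carry a systematic +15–20% at default optics; this
  cancels in volume *fractions* (common mode) but not in absolute volumes.
- The perinuclear volume fraction from images is biased upward when the
  band is crowded enough for components to merge.
- No fission/fusion calling, no diffusion-coefficient estimation, no 3-D
  confocal geometry, no absolute millivolt calibration of TMRM, and no
  instrument-native binary plate formats.
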