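# Methods

This note documents the models and procedures nanoorg implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Localization processing

A localization is a fitted emitter position `(frame, x, y, photons,
precision)`; coordinates are nm with origin at the field top-left, y
increasing downward, all geometry 2D (single-plane HILO imaging). Inputs
are assumed drift-corrected and filtered upstream; PSF fitting is out of
scope.

**Re-blink linking.** An emitter that stays on across frames produces one
localization per frame. Two localizations whose frames differ by
`1 … max_gap+1` and whose distance is ≤ `radius` are treated as the same
emitter; chains are merged by connected components, with photon-weighted
mean position and precision (the minimum-variance combination under
per-localization Gaussian error) and summed photons, keeping the first
frame. Defaults `radius = 30 nm`, `max_gap = 0` (strictly consecutive
frames). With 10 nm precision the duplicate-to-parent displacement is
Rayleigh(σ ≈ 10 nm), so a 30 nm radius captures ≈ 99% of duplicate pairs;
both knobs are exposed since the upstream software's values are not public.
Same-frame localizations are never linked (distinct emitters).

**Channel alignment.** Translation or affine least squares on index-matched
fiducial beads, reported with residual RMSE; the transform maps the
reference channel onto the moving channel. Affine requires ≥ 3 non-collinear
pairs (rank check, `DegeneracyError` otherwise).

## Synapse selection

The study's ROIs were hand-picked by criteria (VGAT colocalization,
two-channel overlap, high local density, ~100–800 nm size) that are stated
but not algorithmic. `import_rois` therefore accepts external polygons as a
first-class path, and `detect_candidates` provides an explicit automated
surrogate: the scaffold channel is binned at 20 nm, Gaussian-smoothed
(σ = 30 nm), and flood-labelled above a density floor (5×10⁻⁴ locs/nm²,
an order of magnitude above typical background and well below
within-synapse densities); each component large enough (≥ 25 scaffold
localizations) is bounded by its alpha shape. Candidates must have a
circle-equivalent diameter in [100, 800] nm, a receptor overlap fraction
≥ 0.5 (receptor localizations inside the scaffold footprint relative to
those within a 100 nm buffer — "significant overlap" is not quantified in
the source, so the fraction is configuration), and, when required, at least
one VGAT-mask pixel centre inside the polygon.

## Denoising

DBSCAN with the published per-channel parameters (γ2: ε = 40 nm,
minPts = 5; gephyrin: ε = 30 nm, minPts = 5), minPts counting the point
itself. Classical DBSCAN assigns border points reachable from two clusters
to whichever was expanded first; here border points go to the cluster of
their **nearest** core point, making labels independent of input order
(verified by permutation tests against an O(n²) oracle). Noise-labelled
localizations are removed; everything in any cluster is kept.

## Areas and subsynaptic domains

**Alpha shape.** Delaunay triangulation keeping triangles with circumradius
≤ α = 150 nm; the area is the summed triangle area. Degenerate inputs
(< 3 points, collinear) get area 0. The circle-equivalent diameter is
`2√(A/π)`.

**Local density.** Per point, the count of *other* points within
`density_radius` divided by π r². The source does not state its radius;
the default 30 nm matches the smaller DBSCAN ε in use and resolves SSDs of
the reported 36–82 nm diameters.

**SSD detection.** For each synapse: (1) per-point local density;
(2) `n_randomizations = 20` CSR re-placements of the same number of points
uniformly inside the synapse's alpha shape (rejection sampling), densities
pooled; (3) threshold at the `null_percentile` of the pooled null;
(4) supra-threshold points grouped by DBSCAN (ε = density_radius,
minPts = `min_ssd_locs = 5`); (5) groups of ≥ 5 become SSDs with their own
alpha-shape area and a peak at the maximal-local-density member (ties →
lowest index). Detection is seeded and deterministic.

The null percentile defaults to **99.5**, not 95. The detection unit is a
*cluster* of ≥ 5 supra-threshold points, and supra-threshold points are
spatially correlated (a random clump raises all its members' densities), so
a 95th-percentile point threshold lets CSR clumps through in ~20% of
synapses. 99.5 was calibrated on CSR synapses (4 × 100 seeded synapses,
200 localizations in a 400 nm disc) to keep the cluster-level false-positive
rate at ~2–5%, while planted SSDs (whose peak densities are an order of
magnitude above the null) remain detected in > 90% of runs.

**Enrichment index.** Numerator: mean over reference-channel SSD peaks of
the count of target-channel localizations within `range_radius = 60 nm`,
divided by π r². Denominator: `N_a / synapse area`. The exact normalization
of the original implementation is not public; this choice makes the CSR
expectation exactly 1 and is unit-free. No edge correction is applied, so
peaks closer than 60 nm to the synapse boundary bias the index slightly
downward; the CSR calibration therefore draws its reference peaks from the
interior eroded by the range radius, where the expectation is exact.

## Fixed-imaging masks

Synaptic receptor signal = receptor ∧ marker; extrasynaptic = receptor ∧
¬dilate(synaptic). The dilation runs once with a 3×3 cross (4-connected) —
the most conservative standard element, configurable since the acquisition
software's kernel is unspecified. Cluster counting uses 8-connectivity.
A PLA spot (typical diameter 0.50 μm) is synaptic iff any member pixel
overlaps the marker mask; extrasynaptic counts are total − synaptic by
construction. Thresholding raw fluorescence into binaries is
instrument-specific and out of scope; masks enter as rasters.

## FRAP

`recovery(t) = (F_t − F_0)/(F_i − F_0)` with `F_i` the arithmetic mean of
all pre-bleach samples. Values are not clipped (overshoot is biologically
meaningful); the plateau is the mean of the final three samples (nominally
26–30 min at 2-min spacing). An ROI is synaptic when its centre falls on a
scaffold-reporter mask component. Per-timepoint two-group comparisons use
unpaired t-tests without multiplicity correction, matching the original
per-timepoint policy; a Holm-corrected column is additionally emitted and
clearly labelled as an extension. Traces enter pre-aligned; background
subtraction, reference-ROI bleach correction and exponential model fits are
out of scope.

## Statistics

Values are normalized per independent culture to that culture's vehicle
mean (×100). The normality gate runs D'Agostino–Pearson (n ≥ 8),
Anderson–Darling (n ≥ 8), Shapiro–Wilk (n ≥ 3) and Lilliefors-corrected
Kolmogorov–Smirnov (n ≥ 4) at α = 0.05; tests below their minimum n are
skipped rather than failed, and the t-test is chosen only when **both**
groups pass **all** evaluable tests. This conjunction is deliberately
conservative — on clean Gaussian data the joint pass rate is ~80%, i.e. the
gate errs toward the rank test — and the aggregation rule is configurable.
Mann-Whitney uses the exact distribution up to n = 8 per group (no ties),
the tie-corrected normal approximation otherwise. Outliers: iterated
two-sided Grubbs (α = 0.05), one removal per iteration, stopping at the
critical G from the t-distribution; its false-removal rate on clean
Gaussian samples is ≈ α by construction. The proprietary ROUT method is not
implemented. A paired t-test supports before/after designs.

## Synthetic data

`generate_field` emulates what the pipeline consumes, not the microscope:
non-overlapping circular synapses with lognormal diameters (σ_log = 0.15 in
log-diameter, scale set so the **mean area** matches the group preset),
a concentric receptor disc clipped to the scaffold radius, 1–4 Gaussian
SSDs per channel holding 40% of the channel's localizations, uniform
within-synapse background, field-wide uniform noise (2×10⁻⁵ locs/nm²),
per-localization Gaussian error (precision 10 nm), re-blink duplication
(p = 0.3 per frame, chains ≤ 5, duplicates jittered by the precision), a
fixed receptor-channel registration offset (12, −8) nm, and a VGAT disc
mask. Group presets `vehicle` and `dzp` (data in
`src/nanoorg/data/presets.json`) carry the published group means: gephyrin
synapse area 130.1/98.9 ×10³ nm², γ2 area 50.1/35.4 ×10³ nm², γ2 density
4.3/6.5 ×10⁻³ locs/nm², gephyrin SSD area 5.2/4.2 ×10³ nm², γ2 SSD size
from the published 36–40 nm diameters. The gephyrin density is not printed
in the source; it is set to 4.0×10⁻³ locs/nm² — on the scale of the
printed γ2 densities, and high enough that the published DBSCAN(30 nm, 5)
parameters act as background removal rather than eroding the synapse
interior (at 2.5×10⁻³ the mean within-ε neighbour count falls below
minPts, which would be inconsistent with the published method's function).
SSD σ is the target SSD circle-equivalent radius divided by 2.

What the generator does **not** emulate: camera frames and PSFs, emitter
photophysics beyond re-blink duplication, drift, 3D structure, dendrite
morphology (synapses are placed in open field), and non-circular synapse
shapes. Passing recovery tests therefore show the pipeline's estimators are
calibrated for compact, roughly isotropic clusters at realistic densities —
not that they are unbiased on arbitrarily shaped real synapses.

Known estimator biases at the study's conditions, measured on synthetic
truth: alpha-shape areas under-cover the generating disc by ~3–7%
(finite-sample hull deficit, partially offset by localization error) and
densities are correspondingly ~5–7% high; both are well inside the 10%
recovery tolerance and stable across seeds. Measured SSD areas exceed the
planted Gaussian targets because the localization error (10 nm) adds in
quadrature to the SSD spread — γ2 SSDs at the published 36–40 nm diameter
are at the resolution limit, so their measured size is dominated by
precision. This mirrors the physics of the real measurement and is why SSD
sizes are reported but not used as recovery targets.

## Problem sizes and determinism

Recovery runs use 110 synapses per preset in a 21×21 μm field (~10⁵
localizations per channel per preset), CSR calibrations use 100 synapses /
200 enrichment replicates / 1000 Grubbs samples; these sizes hold the
relevant standard errors near or below 1% of the quantities compared. All
stochastic steps take explicit seeds (`numpy.random.default_rng`); identical
configuration and seed give identical output, including byte-identical
synthetic fields.

## Limitations

Manual ROI curation is approximated, not reproduced; the SSD null statistic
and enrichment normalization of the original MATLAB analysis are not
public, so this package's choices (percentile-of-null, uniform-expectation
denominator) are documented defaults rather than re-implementations;
trans-synaptic (3D) alignment to presynaptic nanodomains is out of scope;
electrophysiology (mIPSC detection), western densitometry and the wet-lab
group values are not computable from this package.
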