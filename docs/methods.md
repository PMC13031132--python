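# Methods

## Spatial model and coordinate conventions

All geometry is in pixel units, origin top-left, x right / y down. Polygons
are stored open (the closing vertex is implicit). A cell's position along a
porto–central trajectory is its **spatial ratio**

    S = d_central / (d_central + d_portal),

where the distances run from the cell centroid to the two vein anchor
points (the lumen-region centroid in automatic mode, the clicked point in
manual mode). S = 0 at the central vein and S = 1 at the portal vein; an
`orientation="portal_zero"` flag flips the convention. S is invariant under
rigid transforms of the scene. Note that S is a *ratio of anchor
distances*, not an arc-length coordinate: cells far lateral of the axis are
compressed toward S = 0.5.

## Vein detection and trajectory definition

Vein lumens are cell-free voids in the cell-boundary (phalloidin) channel.
The channel is Gaussian-blurred (default sigma 5 px) and grey-dilated
(disk radius 10 px) to erase small inter-cell voids, then thresholded at
the histogram minimum (the valley of the bimodal intensity histogram);
below-threshold connected components larger than `min_vein_area`
(default 900 px²) are vein candidates. A flat image has no valley and
raises an explicit no-threshold error. Each candidate is typed by the mean
of the image-wide-standardized pericentral vs periportal marker channel in
an annulus (default width 20 px) around its lumen, clipped at image
borders; an exact tie is an error rather than a silent guess. Central and
portal veins are paired greedily by anchor distance, each vein used once.

The trajectory ROI keeps cells whose centroid (a) projects onto the open
segment between the two anchors and (b) deviates from the axis by at most
the cone half-angle (default 65°), measured at the nearer anchor. This is
a deliberate reading of "cells between the veins up to an angle within the
axis": a two-sided cone, the natural geometry when both endpoints matter.
Cells whose centroid falls inside a vein mask are excluded. Manual mode
builds the same trajectory from two user points (degenerate point veins)
and is byte-identical downstream given identical anchors — it exists for
tissue whose marker staining cannot be trusted.

## Cell selection

Up to k = 44 cells per trajectory (double coverage of the ~20 hepatocytes
spanning a human lobule). If the ROI holds more, farthest-first traversal
maximizes the minimum pairwise centroid distance: initialization with the
exact diameter pair (O(n²), ties broken by lowest cell id), then greedy
augmentation. The greedy solution is never worse than half the exhaustive
max–min optimum; the test suite verifies this bound against brute force on
all instances up to n = 12, k = 4 and exact optimality on a collinear
benchmark. On the default synthetic scene the selected cells' S values
cover [0, 1] with a Kolmogorov–Smirnov statistic ≈ 0.13 against uniform;
perfect uniformity is unattainable because cells cannot sit inside the
lumens and the ratio definition of S compresses off-axis cells toward 0.5.

## Contour simplification and LMD export

Cutting contours are decimated to at most ceil(0.10 × n) vertices (floor
3). Uniform decimation is tried first; because a vertex-subset polygon is
inscribed and systematically undersized, the candidate is rescaled about
its centroid to preserve the original area before the quality check
(symmetric area difference ≤ 5% of the original). If that fails, a
Douglas–Peucker simplification is bisected on tolerance until both the
vertex budget and the area bound hold. Contours and exactly three stage
reference points are written in a Leica-LMD-style `ImageData` XML dialect;
`CapID` carries the cell id so the bundled reader round-trips losslessly.

## Intensity matrices and quality control

The container is a proteins × samples table with per-sample metadata
(patient, condition, S). "Detected" means a finite, *positive* value:
zeros and empty fields both read as missing, covering the two conventions
of DIA-NN/directLFQ-style exports. No imputation anywhere.

Sample filter: a sample is excluded when its protein-ID count falls below
median − 1.5 s.d. or above median + 3 s.d. of all counts, with the median
and the (n−1) standard deviation computed once, before any exclusion. The
rule is one-pass by design; re-applying it to its own output recomputes
tighter fences and may exclude further samples (for uniformly spread
counts the minimum always sits below median − 1.5 s.d.), so the pipeline
applies it exactly once. Protein filter: detected in ≥ 70% of samples
(inclusive). The pipeline order is samples first, then completeness; the
tests pin a fixture where reversing the order changes the outcome.
Optional per-patient z-scoring normalizes each protein within each patient;
groups with fewer than two observations or zero variance become missing.

Cell-type contamination scoring ranks each sample's detected proteins by
intensity ascending (average ranks on ties, top protein = number detected)
and reports the median rank of each marker panel, with undetected markers
ranked 0 — invariant under any strictly monotone transform of the sample's
intensities. Panels are built from a reference cell-type table: intensity
> 1×10⁸ and ≥ 5-fold above every other cell type, top 20 by intensity.

PCA (on proteins with no missing values, features standardized) first
excludes samples with any |z| > 3, then reports component coordinates with
a deterministic sign convention (first nonzero loading positive) and the
Spearman correlation of PC1 with S — the check that space, not batch or
patient, drives the variance.

## Gradient inference

Per protein, over the analyzed cohort's cells: Tukey's-fences outlier
removal (k = 1.5; quartiles by linear interpolation, the numpy default —
pinned in tests because conventions differ), robust scaling
((x − median)/IQR; zero IQR skips the protein with a logged reason), then
the random-intercept fit via statsmodels MixedLM, REML first with an ML
fallback on non-convergence. A single-patient cohort degenerates to OLS
with σ_u² = 0; a boundary estimate σ_u² = 0 is a valid fit. Degenerate S
(no spatial spread) and non-convergence are recorded as skip reasons and
excluded from multiple-testing correction.

The Wald statistic uses the standard normal reference rather than a t or
Satterthwaite approximation — adequate at hundreds of cells per fit and
matching the "estimate over its standard error" construction; at 14
patients × 44 cells the simulated 95% interval coverage is 0.94–0.95.
BH correction is applied within each analysis: once across all proteins
passing completeness for the zonation scan, and separately across the
scoped set for contrasts. Calls: significant = Q < 0.05; strong =
|β₁| > 1 and Q < 0.05, direction by the sign of β₁.

Condition contrasts test Δβ₁ = β₁(A) − β₁(B) with SE = √(SE_A² + SE_B²),
scoped by default to the proteins strong in cohort A and converged in
both; loss = |Δβ₁| > 1 and Q < 0.05. The per-direction summary reports the
median |Δβ₁|, a two-sided unpaired rank-sum test between the central and
portal groups' |Δβ₁| (p = 1 exactly when both groups are identical
constants, where the normal approximation is undefined), and the fractions
of scoped proteins lost (|β₁(B)| < 1), maintained (|β₁(B)| > 1 and
Q_B < 0.05) or not detected in B. Proteins are fitted independently; no
shrinkage across proteins.

## Binned comparator

20 equal-width bins of S; bin b covers [(b−1)/20, b/20), the last bin
right-closed. Per-(protein, bin) means over observed values; empty bins
are missing, not errors. Bin z-scores use the sample (n−1) standard
deviation across a protein's non-missing bins. Heatmap ordering sorts by
(mean of the last three bins) − (mean of the first three bins),
descending, ties by protein id — three-bin means rather than single
endpoint bins to damp single-bin noise. The per-protein one-way ANOVA
across bins uses scipy's F test (for a single factor the Type II
decomposition equals the plain one-way sum of squares; the tests verify
against an independent from-scratch decomposition to 1e-9), BH-corrected
across proteins; all-equal input returns F = 0, p = 1 explicitly. Pathway
profiles are per-(pathway, bin) medians of member-protein z-scores
(membership readable from GMT). The method comparison pairs −log₁₀Q of the
continuous and binned analyses over shared proteins, with Spearman
correlation and both/either significance counts.

## DIA window design

The precursor selection range (default 380–980 m/z) is split into
n_windows (default 60) contiguous [low, high) intervals whose edges sit at
equal-count chunk boundaries of the sorted in-range precursors
(boundary k at index n·k/n_windows, edge midway between the two flanking
precursors), so per-window counts differ by at most one — the
operationalization chosen for "window width follows precursor density".
Edges depend only on the empirical distribution: duplicating every
precursor leaves them unchanged whenever the chunk boundaries fall in the
same inter-precursor gaps (exactly guaranteed when the count divides
evenly by the window number). An optional minimum width (off by default;
2 m/z is a realistic instrument floor) pushes coincident edges apart, after
which counts are re-tallied and the ≤ 1 spread no longer binds. Heavy ties
across a boundary can also break the spread guarantee; with continuous m/z
values this does not occur.

## Synthetic generators: what they emulate, and what they do not

`generate_tissue` builds a long narrow field (700 × 360 px) with two
30-px-radius lumens 580 px apart — a trajectory spanning ~29 cell pitches,
matching the ~20-hepatocyte porto–central span of a human lobule with the
field cropped around one trajectory. Cells are Voronoi polygons of a
20-px jittered grid, clipped to the image and to the lumens (cell centres
stay half a pitch clear of the vein wall, so polygons abut but never cover
a lumen). Marker channels decay exponentially (length 150 px) from their
vein with additive Gaussian noise; the boundary channel is bright
parenchyma (0.7) with near-zero lumens, exactly the bimodal structure the
histogram-minimum threshold needs; nuclei are Gaussian blobs at cell
centroids. Not emulated: optics (PSF, tiling/stitching artifacts,
flat-field error), irregular vein shapes, multi-lobule scenes with more
than one trajectory, real segmentation errors. Passing tests therefore
validate the geometry and algorithms, not robustness to imaging artifacts.

`generate_proteome` draws, per protein, β₀ ~ N(12, 1) (log-intensity
scale), a zonated flag for a configurable fraction (default 0.5, matching
roughly half the proteome being zonated), |β₁| uniform on 0.5–2 with
random sign, patient intercepts u ~ N(0, 0.5²) and residuals
ε ~ N(0, 0.3²); disease-condition patients have β₁ multiplied by an
attenuation factor. Default cohort: 14 healthy patients × 44 cells (plus
optional disease patients), the study's sampling design. Dropout is
logistic missing-not-at-random on the *standardized* latent intensity
(scale-free parameters): P(observed) = expit((z − m)·s) with m = −1.5,
s = 1 by default, ≈ 80% observed overall and more missingness at low
abundance — the direction single-cell proteomics data show. The true
dropout mechanism of such data is unknown; this is a stand-in with exposed
parameters, and conclusions that depend on the exact missingness shape
should not be read off these fixtures. σ_u = 0.5 and σ_e = 0.3 put
patient-level variation above cell-level noise after normalization, the
regime the random intercept exists for.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data at
these sizes, chosen to estimate each quantity with comfortable margin:
200 proteins for slope bias / coverage / null error rates (binomial SE
≈ 0.015 on a 0.05 rate); 20–50 replicate cohorts of 8–12 strong proteins
for contrast power and the duplicate-cohort null; 100 proteins at
|β₁| = 0.5 for the continuous-vs-binned sensitivity fraction; 200 random
instances (n ≤ 12, k ≤ 4) against the exhaustive dispersion oracle.
Convergence follows statsmodels defaults with the REML→ML fallback;
quartiles are linearly interpolated everywhere; FFT ties break by lowest
cell id; PCA signs are fixed by the first nonzero loading; BH is the
standard step-up. All randomness flows through per-call
`numpy.random.Generator` instances — no global state, bit-identical
re-runs under a fixed seed.

## Known limitations

- The gradient model is linear in S; nonlinear (e.g. sigmoidal or
  mid-lobular) profiles are captured only as their best linear fit.
- One random intercept per patient: no random slopes, no spatial
  autocorrelation between neighbouring cells, no protein-level shrinkage.
- The Wald test is asymptotic; with very few patients and strong intercept
  variance its coverage degrades before the simulation regime tested here.
- S is anchor-based; in strongly curved or multi-vein architectures an
  arc-length or landmark-based coordinate would be more faithful.
- The MNAR generator is a modelling convenience, not a measured mechanism.
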