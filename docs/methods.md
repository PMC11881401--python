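# Methods

`cmhquant` quantifies cerebral microhemorrhages (CMH) — small focal brain
bleeds detected as Prussian-blue-positive hemosiderin deposits — in two
complementary ways: 3D vascular localization in cleared thick sections, and
2D histological quantification with cohort-level statistics. Because the
kind of raw data it targets (two-channel confocal stacks of cleared tissue,
scanned stained slides, per-animal tables) is rarely shareable, the package
carries a synthetic-data module that generates ground-truthed stand-ins with
the statistical structure the analysis assumes. This note documents the
models, the parameters that matter, and the design choices made where more
than one defensible option existed.

## 3D localization pipeline

**Vessel segmentation.** The fluorescence channel (lectin-labeled
vasculature) is segmented with the Ridler–Calvard *iterative selection*
threshold: the fixed point of `T ← (mean(x ≤ T) + mean(x > T)) / 2`,
computed on an intensity histogram (one bin per level for integer images,
4096 bins for float) so cost is independent of repeated values. Iteration
stops when the induced histogram partition is self-consistent — the update
computed from a cut lands back inside the same cut — at which point the
next update would move the threshold by exactly zero, so any `|ΔT| < tol`
stopping rule is satisfied simultaneously. The iteration is initialized at
the intensity mid-range rather than the global mean: when vessels occupy
only a few percent of the voxels the global mean sits inside the background
mode, which has a fixed point of its own (the one that merely splits the
background noise in half), and an iteration started there can be captured
by it. The mid-range start descends into the between-class valley instead.
Both choices were validated against an exhaustive fixed-point scan (every
candidate cut checked for self-consistency). Thresholding is applied
volumetrically, not per-slice; the fluorescence channel is acquired as one
stack and per-slice thresholds would wobble with local vessel content.

**Deposit segmentation.** The transmission channel shows deposits as dark
(absorbing) regions under nonuniform illumination, so a local *Sauvola*
threshold is used: `t(x) = m(x)·(1 + k·(s(x)/R − 1))` with window mean
`m` and standard deviation `s` computed over a square window with
edge-inclusive reflective padding. Defaults: window 61 px, k = 0.2, R =
half the image dynamic range — the method's conventional settings; all are
config-exposed. Polarity `dark-objects` keeps pixels *below* the local
threshold. The threshold is applied per slice (transmission images are
acquired per focal plane) followed by 3D connected components
(26-connectivity); a true 3D window is out of scope. Components smaller
than `min_deposit_volume` (default 65 µm³, a sphere of ~2.5 µm radius) are
discarded as speckle.

**Centerline tracing.** The binary vessel mask is reduced to a one-voxel
medial skeleton by homotopic 3D thinning (Lee's method). Skeleton voxels
become graph nodes at voxel centers (`(index + 0.5) × spacing`, (z, y, x)
order, µm units); 26-adjacent voxels are joined by edges; maximal paths
between junction/endpoint nodes form *segments*. The local radius at a node
is the anisotropy-aware Euclidean distance transform of the mask sampled at
that voxel. A segment's diameter is `2 × median(node radii)`, excluding
nodes lying within one local radius of a junction (their EDT values are
inflated by the junction blob); if no node qualifies the median falls back
to all nodes and logs it. Terminal branches shorter than 5 µm are pruned
iteratively to suppress thinning spurs. Skeletonization runs on the voxel
lattice; for stacks with spacing anisotropy above 2× a warning is logged.
On tube phantoms with true diameters 2–11 µm at 1 µm voxels this pipeline
recovers diameters with a maximum error below 1 µm and a slight systematic
underestimate (~0.3–0.8 µm) from EDT discretization — comfortably inside
the ~2 µm error that clearing-induced shrinkage alone contributes.

**Nearest-vessel attribution.** Deposits found in the transmission channel
are first removed (with one dilation) from the vessel mask before tracing:
an absorbing deposit locally masks the fluorescence signal, and tracing
through it would create phantom vessel ends inside the lesion. Deposits are
clustered into lesions by single-linkage at `lesion_linkage` (default
100 µm, half the ~200 µm axial extent a single lesion can span); the lesion
centroid is the volume-weighted mean of member centroids. The headline
statistic is computed *per deposit centroid*: the five nearest **distinct
vessel segments** (not skeleton nodes, which could all lie on one vessel),
where the distance to a segment is the minimum Euclidean distance from the
centroid to any of its centerline nodes, ties broken toward the lower
segment id. Centroid-to-centerline distance is used (wall distance =
centerline distance − radius is available as a derived quantity). Pooled
nearest-vessel diameters are summarized as a 1 µm-bin histogram and the
fraction strictly below the capillary cutoff (10 µm).

**Shrinkage.** Solvent clearing shrinks tissue by roughly 30% in surface
area; an isotropic in-plane correction would divide measured diameters by
`sqrt(1 − 0.30)` (a measured 10 µm maps to ≈ 11.95 µm). The correction is
off by default — reported diameters are raw measurements, with shrinkage
treated as a known error source rather than a calibration.

## 2D histology quantification

**Prussian-blue counting.** A pixel is blue-positive iff
`B/(R+ε) ≥ 1.2 AND B/(G+ε) ≥ 1.2 AND B ≥ 60` (8-bit scale, ε = 1). The
exact thresholds of the ratiometric rule used with real slides are not
published; these defaults are a reconstruction and are config-exposed.
8-connected components of at least `min_area` (default 100 µm²; no floor is
standard, so this is stated openly) are counted, and per-animal density is
total count over total analyzed tissue area, pooled across all of an
animal's sections, in CMH/cm². Tissue area itself comes from a near-white
background rule (all channels ≥ 230) followed by closing and
largest-component selection.

**DAB %-area.** The RGB brightfield image is unmixed against the standard
H-DAB absorbance matrix in natural-log Beer–Lambert units
(`OD = −ln(I/I₀) · M⁻¹`; the basis is completed with the cross-product
residual vector). The DAB channel is thresholded by iterative selection
within the tissue mask, with two guards: a *separation gate* (the two
classes must separate by more than 3× the pooled within-class SD, otherwise
a signal-free field would have its noise split in half) and an absolute OD
floor of 0.3 (above counterstain bleed-through, well below true DAB), which
also makes uniformly stained tissue report 100% where a threshold is
undefined. The same gated threshold drives the fluorescence area ratio
(positive pixels over cortex pixels within a user-supplied cortex mask;
atlas registration is out of scope — region masks are user input).

**Statistics.** Group summaries are mean ± SEM with the sample SD (n−1).
Four-group designs use two-way ANOVA (infusion × drug, with interaction,
type-II sums of squares for the mildly unbalanced n-per-group these cohorts
have); other designs use one-way ANOVA; both run through statsmodels OLS.
Pairwise comparisons are Tukey-HSD adjusted, with stars mapped * < 0.05,
** < 0.01, *** < 0.001, **** < 0.0001. Pearson correlations report the
two-tailed p from the t transform with n−2 df. Sexes are pooled by default
(sex can be added as a factor). With exactly two groups the one-way ANOVA p
equals the equal-variance t-test p, which the tests pin down.

## Synthetic data

**What it emulates.** Vessels are smooth random tubes: cubic splines
through waypoints jittered perpendicular to a random chord through the
volume (the `tortuosity` parameter scales the jitter; chords shorter than
half the volume extent are resampled so no degenerate stubs occur). The
default diameter profile is a log-normal (median ≈ 4.5 µm, σ_log = 0.35)
truncated to [2, 11] µm, putting ~98–99% of its mass below 10 µm —
capillary-dominant, as cortical microvasculature is; `uniform(2, 11)` and
fixed-diameter profiles are also available. Tubes are rendered by distance
to the centerline with a one-voxel linear edge so the half-maximum surface
sits at the true radius, then blurred by a Gaussian PSF (default σ 0.5 µm)
and given additive Gaussian noise (default σ 8 on a 20/160
background/vessel intensity scale — strong enough to be realistic, weak
enough to keep the two-class histogram bimodal, which is the thresholding
model's assumption); signal-dependent photon noise is optional. Deposits
are spherical absorbers clustered 1–10 per lesion inside a ball of half the
200 µm lesion extent, each lesion anchored at a sampled offset
(default uniform 0–4 µm) from a randomly chosen vessel's wall; the offset
distribution is a parameter, not a biological claim. The transmission
channel is `I₀·exp(−A·support)` with bright background. The
`fixed_diameter` phantom used for diameter validation chooses the vessel
count to hold a ~2% vascular volume fraction (the physiological range for
cortex) — this is also what keeps the global threshold well-posed, since a
single thin tube in a large volume leaves the histogram effectively
unimodal.

Histology sections are an ellipse of exactly the requested tissue area
(pixel-quantized) on a white background, with blue elliptical lesions of
areas drawn from `cmh_area_range` and, for immunostained sections,
DAB staining applied to an *exact* pixel count (quantile cut of a smoothed
Gaussian random field, ties resolved) and rendered through the same H-DAB
matrix the quantifier unmixes with. An optional concentric inner half-area
ellipse acts as a "subcortex" region label for region-assignment tests.

Cohorts draw per-animal CMH counts as Poisson with mean `density × area`
(area default 12 cm² of analyzed sections per animal), where the latent
density is Gaussian around the group mean (SD default 0.3 per cm² — small
enough that truncation at zero is negligible, large enough to carry
between-animal biological variability on top of Poisson counting noise).
The requested pooled Pearson correlation between CMH density and final MAP
is achieved *in expectation* by an analytic calibration: the pooled
covariance decomposes into a between-group part (fixed by the group means)
plus a within-group latent part, and the pooled variances include the
Poisson counting term `mean/area`, so the latent correlation that a shared
Gaussian factor must carry is solved for in closed form; an unattainable
target (|latent ρ| ≥ 1) raises. With zero measurement noise the generator
is fully deterministic: continuous variables equal their group means and
counts are rounded expectations.

**What it does not emulate.** No optical realism (refractive-index
artifacts, depth attenuation, shrinkage fields), no vascular network
topology (hierarchy, loops beyond incidental tube crossings), no
scanner-to-scanner color variation, no spatial autocorrelation in staining
beyond the smoothing of the DAB field. Passing tests therefore demonstrate
the *computational* fidelity of the pipeline — segmentation, tracing,
attribution, quantification and statistics recover known ground truth under
the stated noise — not robustness to every artifact of real acquisitions.

## Numerical choices and degenerate inputs

- Coordinates: 0-based voxel indices, physical positions at voxel centers,
  (z, y, x) axis order, µm everywhere; areas convert to cm² only at the
  density step.
- Iterative selection: histogram-based, mid-range initialization,
  partition-stability stopping, 500-iteration cap; constant or non-finite
  images raise.
- Sauvola: even windows raise; k outside (0, 1] warns but applies; windows
  larger than a slice are shrunk to the largest odd fit (logged).
- Morphological closing is implemented as dilation (background border)
  followed by erosion with a foreground border, i.e. true closing semantics
  at the image edge.
- Empty cases: an empty vessel mask yields an empty skeleton with a
  warning; zero deposits is a valid result, not an error; a graph with
  fewer than k segments yields a shorter, flagged nearest-vessel record.
- Determinism: every generator is bit-reproducible for a fixed spec + seed
  (deposits use a child seed stream so the two channels are independently
  reproducible); pipeline runs with equal config hashes write byte-identical
  CSVs.

## Validation problem sizes

The shipped validation studies (tests and `scripts/acceptance.py`) use
desk-scale phantoms chosen to exercise every code path at meaningful
statistics: diameter recovery on 30 tube phantoms of 48×72×72 voxels across
{2, 4, 6, 8, 10, 11} µm; end-to-end capillary-fraction runs on 110³-voxel
phantoms with 40 vessels and 5 lesions each; cohort calibration over 500
replicates of n = 54 animals. Larger volumes change none of the algorithms,
only the runtime.

## Known limitations

- Lattice skeletonization is approximate for strongly anisotropic stacks.
- The EDT radius estimate carries a ~half-voxel negative bias; diameters of
  2 µm vessels at 1 µm voxels are at the resolvability limit.
- The ratiometric blue rule and the DAB OD floor are reconstructions tuned
  on the synthetic renderer's color model; real slides may need the
  config-exposed thresholds adjusted.
- Single-linkage lesion clustering chains aggressively at the default
  100 µm in small volumes; lesion-level statistics are secondary to the
  per-deposit statistic for exactly this reason.
- Channel registration is assumed perfect; no alignment correction is
  performed.
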