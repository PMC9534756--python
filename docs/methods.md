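# Methods

This note documents the models, conventions, parameter choices, and known
limitations behind `engulf3d`. It is the package's own account of its
procedures; every empirical figure mentioned here is computed by the test
suite or by `scripts/acceptance.py`, not asserted from elsewhere.

## Geometry conventions

Arrays are ordered `(z, y, x)`; all physical quantities are µm / µm³.
Voxels are anisotropic — fixed-tissue confocal data are typically
(0.3, 0.132, 0.132) µm and in vivo two-photon volumes up to
(1.0, 0.264, 0.264) µm — so all distances and filters convert physical
lengths per axis through the spacing. Coordinates are voxel-center based;
an object's centroid is the intensity-weighted mean of its voxel centers.
Thresholds quoted in nm elsewhere are stored in µm (270 nm ≡ 0.270 µm) to
avoid unit drift.

**Signed distance.** The field is an anisotropic Euclidean distance to the
mask's *boundary voxels* (mask voxels with an outside 6-neighbor):
negative in the interior, exactly 0 on boundary voxels, positive outside.
Measuring to the boundary set rather than subtracting two distance
transforms makes "distance 0" an exactly representable state, which the
three-way input classification (below) relies on. Near the volume border
the complement's field references the border itself; tests therefore check
the mirror property only near the mask interface.

## Cell reconstruction

Interactive surface creation is replaced by a deterministic rule:
threshold the (optionally preprocessed) cell-marker channel — Otsu by
default, overridable and always recorded in the output sidecar — label
26-connected components, and keep only the component containing (or within
10 µm of) the soma seed. 26-connectivity is the most permissive choice and
lets thin processes survive anisotropic sampling. The soma seed defaults
to the intensity centroid of the largest blob after 2 µm Gaussian
smoothing, which erases processes and puncta. Discarding every other
component automates the manual rule of deleting fragments that cannot be
traced back to the soma; it is an automation of that judgment, not a claim
of equivalence for arbitrarily dim processes.

Surfaces are voxel masks, not meshes: every downstream statistic is a
voxel statistic, so oracle tests can demand exact agreement with
brute-force counting.

## Preprocessing

- `enhance_contrast` — symmetric two-tail linear stretch saturating a
  total fraction of voxels (default 0.1%), computed on the whole stack.
  Tail quantiles use order statistics (no interpolation) so the transform
  is idempotent. A constant image passes through unchanged.
- `mean_filter` — uniform average over an ellipsoidal neighborhood of
  physical radius (default 1.5 µm), voxel radius `round(r/spacing)` per
  axis, reflected borders. Applied to the cell channel ahead of
  reconstruction; puncta channels are segmented unfiltered, since a
  micron-scale mean filter would erase sub-micron objects.
- `gaussian_blur` — anisotropy-aware Gaussian; σ = 0 is the identity.

## Segmentation and thresholds

The low-level operations keep simple defaults: `internalized_objects` and
`detect_objects` binarize at Otsu over nonzero voxels (exact on clean
synthetic data) with a 2-voxel minimum object size to suppress
single-voxel noise. On realistic noisy data, however, puncta occupy tens
of voxels against ~10⁵ background voxels, and Otsu's between-class
criterion collapses into the background distribution under that class
imbalance. The *pipeline* entry points therefore default to:

- **Robust background threshold** — median + 5 × MAD-σ of the nonzero
  voxels. Signal contributes negligibly to median and MAD, so the estimate
  tracks the noise floor; when MAD is zero (clean data whose only nonzero
  voxels are signal) half the median separates flat objects from empty
  background exactly.
- **Half-peak (FWHM) volume estimation** (`detect_spots`) — seed
  components above the robust threshold are grown to the contour at 50% of
  their own peak. For a uniform-density object imaged through a symmetric
  PSF the half-peak contour sits at the true object edge, so measured
  volumes are approximately unbiased and invariant to global intensity
  scale. On clean, unblurred scenes the procedure returns the exact voxel
  sets. The acceptance run measures a recovered-vs-true engulfment-index
  regression slope of ≈ 0.95 on a 20-cell cohort at default SNR.

Time-lapse detection deliberately does **not** use half-peak volumes: one
absolute threshold from frame 0 is applied to the whole video (the
constant-creation-parameters convention), so photobleaching appears as
shrinking object volumes — the artifact the normalization below is
designed to remove. A bleaching-invariant estimator would hide it.

All thresholds actually used are echoed into JSON sidecars, making the
per-replicate-constancy convention auditable.

## Input classification and bleaching normalization

Detected inputs are partitioned by their relation to the cell surface:

| class | rule (signed distance d, most-interior voxel) |
|---|---|
| noncontacting | d > 0 |
| contacting | −0.270 µm ≤ d ≤ 0 |
| engulfed | d < −0.270 µm |

For an extended object an exact d = 0 is measure-zero, so "contact" must
be an interval; the three-way partition forces this reading, and the
most-interior voxel decides. Classification is geometry-only, hence
invariant to intensity scaling; raising the engulfed threshold can only
shrink the engulfed class (threshold monotonicity).

Per-frame, per-class mean volumes are normalized to the noncontacting
baseline. The default divides each frame's class means by *that frame's*
noncontacting mean: every class bleaches alike, so the common decay
cancels and the noncontacting trace is identically 1 — the property the
data contract demands. A `pooled` mode (dividing by the grand noncontacting
mean over the whole recording) is provided for the alternative reading in
which the common decay is preserved. Per-frame detection is independent;
no tracking is attempted, since the analysis reports per-frame class
means, not trajectories.

## Intact synapses and reporter ratiometry

The colocalization channel is `min(pre, post)` where both channels exceed
their whole-crop means; only the support affects counts, so the choice of
voxel value is benign. Synapses are scored at their centroid: internalized
iff the signed distance there is *strictly* below −0.132 µm (one lateral
pixel at 0.132 µm sampling) — a centroid at exactly −0.132 µm does not
count. Note the deliberate contrast with input classification, which uses
the punctum's most-interior voxel; both conventions are documented here
because they answer different questions (point-object filtering vs
extended-object contact).

For the digestion reporter, each channel is masked by the lysosome mask
(itself a mean-intensity threshold of the lysosome channel, ≥ 2-voxel
components, scale-invariant by construction), re-segmented at 0.75 × the
masked channel's mean — the coefficient applies to the *masked* mean, an
ambiguity resolved here and exposed as a knob — and summed; the outside
compartment is the original minus the masked signal at the same
thresholds. Raw masked sums are conserved exactly (within + outside =
total) before re-segmentation. The within/outside ratio-of-ratios
recovers the generator's quench factor exactly on clean scenes and
monotonically across quench ∈ {0.1, 0.25, 0.5, 1.0}.

## FISH counting

DAPI: Otsu → binarize → dilate by one lateral voxel (configurable) →
distance-transform watershed with seeds at distance-transform maxima
separated by ≥ 2 µm (plateau ties broken lexicographically for
determinism) → ROIs ≥ 30 voxels. Probe channels: robust background
threshold (plain Otsu is available explicitly), 26-connected
components, each assigned to the ROI containing its centroid voxel;
centroids in background stay unassigned, and assigned + unassigned equals
detected (conservation). A cell is positive for a transcript at ≥ 5
molecules — the scientifically load-bearing rule, exact at its boundary
(4 negative, 5 positive). Counting is full-3D throughout.

## ROUT outlier removal

For a single column of per-cell values the robust "regression" is a
constant: the location minimizes the Lorentzian loss
Σ log(1 + (r/RSDR)²) by IRLS, with RSDR re-estimated each iteration as the
68.27th percentile of |residuals| × n/(n − K), K = 1. Residuals are tested
outermost-inward with t = |r|/RSDR (df = n − K) against the
Benjamini–Hochberg-style schedule αᵢ = Q·i/n, stopping at the first
non-outlier, so the flagged set is always the outermost run. Q defaults to
1% (the maximum desired FDR). Identical values (RSDR = 0) flag nothing;
the procedure is permutation-invariant and affine-equivariant. Measured on
clean Gaussian data (n = 10⁴, 100 reps) the false-flag rate is ≪ 2% and a
single 10σ point is flagged in 100% of reps. Outlier removal is applied
*within* experimental groups (the conservative reading, since groups may
genuinely differ), configurable. Group-level inference (ANOVA, posthoc
tests) is intentionally out of scope: the package emits tidy per-cell
tables for external statistics software.

## The synthetic-scene generator

The generator emulates what the assays are sensitive to, with ground truth
recorded before blur and noise:

- **Cell** — ellipsoidal soma (default radii 2.5 × 4.5 × 3.5 µm, the
  oblong soma shape typical of OPCs) plus 5 polyline-tube processes
  (5–9 µm long, 0.4–0.7 µm radius) with random, mostly lateral branch
  angles, guaranteed connected to the soma. Morphological realism is
  limited to connectivity and arbor extent.
- **Puncta** — uniform-density spheres, radius 0.15–0.25 µm (diameter
  0.3–0.5 µm, diffraction-limited presynaptic puncta); their Gaussian
  appearance in images arises from the PSF step. Placement classes are
  defined on the true mask's signed distance field: *inside* puncta are
  deep enough that their most-interior voxel is unambiguously below the
  engulfed threshold; *contacting* puncta are centered on boundary voxels
  (true distance exactly 0), and their ≤ 0.25 µm radius keeps their
  deepest voxel above −0.270 µm, so placement classes and the
  classification rule are mutually consistent by construction; *outside*
  puncta keep ≥ 2 voxels clearance. Infeasible placement requests fail
  with an error naming the class.
- **Lysosomes** — strictly interior; the first wrap inside puncta
  (engulfed material resides in lysosomes), extras are placed in free
  interior space. The dual reporter shares punctum geometry: red is the
  punctum channel, green is red × quench inside the lysosome mask
  (quench ∈ [0, 1]), giving the exact linearity the ratiometry tests use.
- **Imaging model** — PSF blur → Poisson → Gaussian, the standard
  fluorescence forward model. Defaults: σ = (0.20, 0.08, 0.08) µm,
  Poisson at scale 1, Gaussian σ = 6 against punctum amplitude 150
  (SNR ≈ 10). The PSF default models *residual* blur after deconvolution,
  since the workflows this package mirrors deconvolve (e.g. Huygens)
  before quantification; ≈ 0.47 µm axial FWHM matches well-deconvolved
  confocal data. Noise can be disabled stage-by-stage for exactness tests.
- **Time-lapse** — static geometry, per-channel exponential bleaching
  exp(−rate·t) applied to the clean signal before per-frame noise; blur is
  linear, so it is computed once per unique geometry and scaled. Scripted
  disappearance events remove a named punctum from a given frame onward.
- **FISH fields** — flattened-ellipsoid nuclei (placeable touching, to
  exercise watershed splitting) and 0.15 µm molecules strictly inside
  their nucleus; truth records per-nucleus per-gene counts.

Everything is driven by one seeded generator: identical spec + seed gives
bit-identical channels.

**What passing tests do and do not show.** The generator's puncta are
non-overlapping, its background is empty apart from noise, its cell has no
neighboring cells, and frames are perfectly registered. Passing tests
therefore demonstrate that the *quantification* is correct and calibrated
under the stated imaging model — not that segmentation would survive
dense neuropil background, overlapping cells, chromatic offsets, or motion
artifacts, which real experiments handle upstream (cropping to single
cells, registration, deconvolution).

## Numerical choices and degenerate inputs

- Otsu on constant images is undefined; such inputs yield empty
  foregrounds (lysosome mask) or errors demanding a threshold
  (reconstruction), never silent zeros.
- Empty masked channels give empty object sets and engulfment index 0;
  an empty cell mask is an error (the index is undefined).
- Bounding-box extents for fewer than two loci are reported missing, not 0.
- Ratios with zero denominators (red sum 0, no synapses, no noncontacting
  inputs in a frame) are reported missing; a video with no noncontacting
  input at all is an error because the normalizer does not exist.
- CSV/JSON outputs are written with fixed line terminators, and OME-TIFFs
  with a fixed UUID and no timestamp, so seeded runs are byte-identical.

## Problem sizes

Default test scenes are 32 × 160 × 160 voxels (≈ 9.6 × 21 × 21 µm) — one
cell with ~20 puncta — chosen as the smallest volumes that hold the full
geometry with realistic clearances. Cohort-style checks use 10–20 cells,
time-lapse checks 30 frames × 10 seeds, and the ROUT calibration
10⁴ × 100 Gaussian draws.
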