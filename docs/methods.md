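# Methods

This note documents the algorithms, their assumptions, the parameter
defaults and why they are what they are, and what the synthetic phantoms do
and do not establish about real data.

## Data model and conventions

A channel stack is a `(z, y, x)` float64 volume tagged with its Raman shift
and a caller-supplied voxel geometry (`dx`, `dy` μm/pixel, `dz` μm/plane;
the shipped default is 0.3 × 0.3 × 1.0 μm, a typical laser-scanning SRS
z-stack geometry). Geometry is configuration, never inferred from file
metadata. Page order in a TIFF is z order; no reordering heuristics. All
user-facing coordinates are physical micrometres in `(x, y, z)` order.
Signed input is accepted: lock-in detection can go negative before baseline
handling.

The two channels are assumed co-registered; registration is out of scope.

## Baseline subtraction

Each z-plane has its own additive offset (lock-in DC level plus slow
drift), so the baseline is estimated and removed per plane.

The estimator is a **Gaussian-debiased low percentile**. A plain low
percentile (the classic choice; default anchor p = 0.05) of a plane whose
background carries zero-mean noise of scale σ sits z_p·σ *below* the true
offset — subtracting it leaves a spurious pedestal of +1.645σ in every
voxel of *both* channels, and because the 3010 channel's signal is ~3×
weaker than the 2900 channel's, the pedestal inflates the unsaturation
ratio non-uniformly (up to ~+30% for attenuated droplets at SNR 10). The
debiased form estimates σ̂ from the spacing of the p-th and 25th
percentiles and returns q_p + z_p·σ̂, which equals the plain percentile on
noise-free planes and targets the centre of the background distribution on
noisy ones. The plain percentile remains available (`debias_baseline:
false`).

The debiased anchor still assumes the lower quartile of the plane is
background. That drifts when the cell fills most of the field, so the
pipeline runs a **second pass**: once the cell body is segmented, each
plane's residual offset is re-estimated as the median over out-of-cell
pixels (clear of the boundary by a dilation of 1 plane / 4 px; at least
500 such pixels required, otherwise the coarse estimate stands). The
median of a pure-background sample is unbiased at any cell fill fraction.

Two clipping regimes exist. The public `subtract_baseline` clips negatives
to zero by default, which is what thresholding consumers expect. The
pipeline subtracts *unclipped*: rectifying zero-mean noise before smoothing
adds a +0.4σ pedestal wherever the signal is near zero, which again hits
the weak 3010 channel hardest. Since every downstream threshold is
strictly positive and the ratio map enforces nonnegativity itself, signed
residual noise is harmless and unbiased.

## Smoothing

Separable Gaussian, reflective boundaries, sigmas in μm converted to pixels
through the geometry. Two independent smoothing scales are used:

- **Detection smoothing** (default σ_xy = 0.45 μm, σ_z = 0.75 μm): sets
  the noise floor the adaptive threshold sees. At SNR 10 the flat-cytoplasm
  rejection margin must stay several noise standard deviations wide at the
  deepest (most attenuated) plane; mildly anisotropic 3D smoothing matched
  to the 0.3/0.3/1.0 μm voxel achieves ~4σ margins without erasing
  sub-micrometre droplets. Set σ_z = 0 for per-plane 2D smoothing.
- **Ratio smoothing** (default σ_xy = 0.3 μm, 2D only): a bias–variance
  compromise at ~¼ of the typical droplet radius. Heavier blur mixes
  cytoplasm into droplet boundary voxels and biases the per-voxel ratio;
  no smoothing leaves the ratio map noise-limited. The default per-droplet
  estimator (below) is itself blur-invariant, so this scale mostly affects
  the exported per-voxel ratio map.

## Droplet detection: masked Bradley threshold

A pixel is foreground iff its value exceeds the mean of its
(2w+1)² window (truncated at plane borders) times (1 + sensitivity),
computed per plane with an integral image. This is the bright-object form
of Bradley's adaptive rule; the local mean tracks slow variations —
depth attenuation, illumination bias — that defeat a global threshold.

Two aspects matter in practice:

- **Cell-body restriction.** A window straddling the cell boundary is
  diluted by the dark exterior, which pulls the threshold below the flat
  interior level and floods the cell's outer shell foreground. The local
  mean is therefore computed over in-mask pixels only (two integral
  images: masked values and mask counts), with the segmented cell body —
  eroded by 1 plane / 2 px so that tangential partial-volume slices of the
  cell surface cannot present as blobs — as the mask. Unmasked behaviour
  is unchanged and available.
- **Sensitivity 0.6.** The margin above the local mean is what rejects
  flat cytoplasm; it must exceed ~4 noise σ of the smoothed cytoplasm at
  the deepest plane while staying far below droplet peaks (≥ 3× the
  threshold at the defaults). Document-binarization folklore (15%) is far
  too permissive for this contrast regime.

The per-plane masks are stacked, 3D-labeled (default 26-connectivity:
droplets touching diagonally across the anisotropic z-step are one
physical aggregate), and components below `min_voxels` (default 4) are
dropped as noise. One labeled component is the operational definition of
an "LD aggregate"; unresolvable droplets inside it are not split.

## Half-maximum boundary refinement

With sparse droplets the window mean sits just above cytoplasm, far below
a droplet's half-maximum, so the raw Bradley boundary dilates every
blurred or partial-volume edge (measured: total volume +50–200%). Each
detected component is therefore re-thresholded at its half-maximum — the
standard unbiased boundary rule for blob volumetry — in a separable,
two-stage form that respects the anisotropic axial blur:

1. per plane of the component's padded box, keep voxels above
   bg + 0.5·(plane peak − bg), where bg is the median over unlabeled box
   voxels and peaks are taken from a 3×3 in-plane mean (a raw maximum over
   many noisy voxels carries an extreme-value bias that systematically
   erodes the boundary);
2. per connected piece of that candidate set, strip planes whose peak
   falls below half the piece's own peak (axial half-maximum; removes pole
   blur leakage);
3. relabel: the largest resulting piece keeps the component's label,
   other pieces of at least `min_voxels` become droplets of their own
   (two droplets whose sub-half-maximum skirts were bridged by the dilated
   detection mask are resolvable objects, not one aggregate), and smaller
   fragments rejoin the main piece.

Detection and counting happen before refinement; refinement adjusts
extents and can only split, never merge. `refine: none` disables it.

## Per-droplet unsaturation

The per-voxel map R = I₃₀₁₀/I₂₉₀₀ is defined where I₂₉₀₀ exceeds a floor
(default 3× a robust noise σ̂ taken from the negative-side MAD of the
baseline-subtracted 2900 stack; an aggressive floor at depth preferentially
admits positive-noise denominators and biases ratios down). Invalid voxels
are excluded from all statistics; droplets with no valid voxel are flagged
unmeasured and kept for geometry statistics only.

Three per-droplet estimators are provided (`unsaturation.mode`):

- `voxel_mean` — arithmetic mean of R over the droplet's valid voxels;
  matches a per-pixel ratio map, but partial-volume and blur mixing with
  cytoplasm biases it by several percent for μm-scale droplets.
- `summed` — Σ I₃₀₁₀ / Σ I₂₉₀₀; weights edge voxels by lipid content,
  reducing that bias ~3×.
- `background_corrected` (default) — both channels share one spatial
  structure b + A·S(x), with S the droplet support under any blur, so for
  any noise-independent nonnegative weights w:

  &nbsp;&nbsp;&nbsp;&nbsp;Σw·(I₃₀₁₀ − b₃₀₁₀) / Σw·(I₂₉₀₀ − b₂₉₀₀) = A₃₀₁₀/A₂₉₀₀

  exactly — independent of smoothing and of how the voxel set was drawn.
  The local pedestals b are medians over the unlabeled voxels of the
  droplet's padded box; the weights approximate a matched filter using the
  droplet's own segmented support softened by a Gaussian (weights built
  from measured intensities would correlate with the denominator noise and
  bias the ratio — measured −4%). The droplet's ratio u follows by
  rescaling with its 2900 amplitude from the peak; the result is
  first-order insensitive to that estimate. On noise-free phantoms this
  estimator is exact to <0.3%; at SNR 10 it is noise-limited at ~2.5%
  mean absolute error for ≥30-voxel droplets.

Depth correction is deliberately absent: attenuation and illumination
multiply both channels identically and cancel in every estimator; that
cancellation is verified as a test invariant (per-droplet values move
<1% across attenuation lengths 20–200 μm) rather than corrected for.

The C=C calibration (`fit_calibration`) is an ordinary least-squares line
ratio = slope·(#C=C) + intercept with R², for standards of known double-
bond count; the same operations serve a 3010/1445 normalization by passing
a 1445 cm⁻¹ stack as denominator. Hyperspectral stacks are reduced to
per-voxel peak heights (frame nearest the requested shift minus the mean
over a stated baseline band) so two-channel ratios can be validated
against full spectra.

## Cell segmentation and two-cell splitting

Whole-cell morphology comes from the 2900 channel: extra in-plane
smoothing at 1.5 μm (cell bodies are tens of μm wide; scale-matched
smoothing suppresses noise without moving the boundary), a per-plane
threshold, 2D opening with a 1 μm disk, 2D hole filling (interior
LD-free vacuoles are dark), and the largest 3D component. The default
per-plane threshold is Otsu's, floored at half the volume-wide Otsu so
planes with little or no cell cross-section cannot threshold into pure
noise; the fraction-of-robust-maximum rule (scale × per-plane 99th
percentile) is available as `method: relative_max`, but the acellular
background noise does not attenuate with depth, so a purely relative rule
cannot sit between background and deep cytoplasm at this geometry.

Two-cell splitting uses the neck concavity between touching blastomeres.
Contours of each plane's mask (subpixel, resampled to 1.5 px spacing) are
scanned for concave vertices: vertex v is concave iff the interior angle
formed with the vertices `arm_length` (default 5) before and after v
exceeds `angle_threshold` (default 1.2π; the neck cusps of two r = 25 μm
cells at 40 μm spacing subtend ≈1.4π). Points are pooled across z-planes —
the neck persists through depth while jagged-contour false positives do
not — but only from planes with at least 25% of the maximal cross-section
(small pole caps have wobbly outlines). The pooled points are partitioned
by 2-means (10 deterministic restarts, seeded); the cut line joins the two
cluster medians (robust to residual outliers) and extends parallel to z as
a cut plane. Voxels take the label of their side; cell 1 is the side with
the smaller mean x, so labeling is deterministic. The two labels partition
the mask exactly, and the construction fails loudly — "not a two-cell
morphology" — on convex masks (< 2 concave points). A marker-based
watershed on the distance transform is kept behind
`split_two_cells_watershed` purely as a comparison baseline.

Droplets are assigned to cells by the label at their centroid voxel;
centroids on background adopt the nearest cell within 2 voxels, otherwise
the droplet stays unassigned.

## Statistics

- Size binning: half-open [k·5, (k+1)·5) μm³ volume bins (the droplet at
  exactly 5 μm³ goes up); per-bin unweighted mean unsaturation; empty bins
  omitted.
- Regression: OLS with t-based (n−2 df) intervals for slope, intercept,
  and the mean-response band. Bin-mean regressions use weighted least
  squares with bin counts as weights — bin means are heteroscedastic
  (Var ∝ 1/n) and unweighted OLS on them under-covers and loses power.
  Regressions on raw (unbinned) droplets are produced alongside as a
  robustness output.
- Group comparison: Shapiro–Wilk on each group at α = 0.05; both pass →
  two-tailed equal-variance two-sample t-test (Welch optional); otherwise
  two-sided Mann–Whitney U, exact null when min(n) ≤ 8 and tie-free,
  tie-corrected normal approximation otherwise. The exact path is verified
  against exhaustive enumeration for all group sizes up to 8, and the full
  gated procedure's type-I error is calibration-tested under Gaussian and
  log-normal nulls (measured 0.05–0.06 at α = 0.05 over 1000 replicates).

## The phantom generator

Phantoms emulate the acquisition the pipeline consumes: spherical cells of
cytoplasm intensity 0.15 (in units of the droplet 2900 signal) and
cytoplasm ratio 0.2; per cell, 40 droplets with lognormal radii (median
1.1 μm, σ_log 0.25) and Gaussian unsaturation (0.30 ± 0.05, clipped
positive), placed with ≥2 μm surface clearance; a Gaussian copula imposes
an optional correlation ρ between log radius and unsaturation. Droplet
edges are rendered with 3× supersampled partial-volume weighting (bounds
volume quantisation error; voxelized and analytic volumes agree within
15%). Both channels are multiplied by exp(−z/L) (default L = 70 μm) and a
smooth illumination field (±10%), then receive independent Gaussian noise.
Noise is additive Gaussian, not Poisson: lock-in SRS detection noise is
approximately Gaussian at these fluxes. The default noise puts each
channel at SNR 10 *with respect to its own droplet signal* (the 3010
noise scales with the typical 3010 signal, u·I₂₉₀₀; an acquisition whose
weak channel sat at SNR 3 would not be called SNR 10, and per-droplet
composition estimates would be information-limited above 5% error no
matter the estimator — an explicit `noise_sigma_3010` overrides this).

The default grid is (40, 160, 160) voxels at 0.3/0.3/1.0 μm — a
48 × 48 × 40 μm field, scaled down from a full 120 × 120 × 60 μm
acquisition so that the complete validation battery (including 200
regression replicates and a two-cell fixture of two r = 25 μm cells at
40 μm spacing on a ~3M-voxel grid) runs in seconds to minutes.

What the phantom does **not** emulate — and hence what passing tests do
not establish about real embryos: non-spherical droplets and cells,
organelle texture and autofluorescence-like structured background,
scattering-induced PSF degradation with depth (attenuation is modeled as
purely multiplicative), chromatic or motion misregistration between
channels, Poisson photon statistics, and any systematic difference between
the 2900 cm⁻¹ signal and actual lipid mass. Recovery numbers on phantoms
are a necessary check of the code and the estimators, not a validation of
the imaging physics.

## Validation summary (what the suite measures)

On the default phantom conditions, across seeds: droplet count recovered
exactly (the rare exception is a sub-resolution r ≈ 0.5 μm droplet at the
detection margin), total LD volume within 10% (typically −5%), per-droplet
unsaturation MAE ≈ 2.5% for ≥30-voxel droplets, per-droplet values moving
<1% across attenuation lengths 20–200 μm, and two-cell voxel assignment
accuracy ≈ 95–97% per cell (the residual loss is partial-volume boundary
coverage of the mask, not the cut). `scripts/acceptance.py` recomputes all
of these from scratch for any seed.

## Known limitations

- "LD aggregate" = 3D connected component; a declumping of merged droplets
  beyond the half-maximum split is not attempted.
- The two-cell cut is a single z-parallel plane; strongly tilted or
  S-shaped necks would need a curved interface.
- Blastomere splitting is specialised to 2-cell morphology; 4- and 8-cell
  stages are not segmented per blastomere.
- The cell-mask Otsu floor assumes the stack contains a meaningful
  background/cell contrast; a field entirely filled by one cell would need
  an explicit threshold.
- Per-droplet unsaturation at SNR 10 is noise-limited near 2–3%; droplets
  under ~30 voxels carry proportionally larger errors.
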