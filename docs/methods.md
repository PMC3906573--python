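# Methods

This note records the models, default parameters and numerical choices
behind `dwiqc`, and the limits of what the synthetic phantom can and
cannot validate.

## Signal model and tensor estimation

Each voxel follows the single-tensor model

    S_i = S0 * exp(-b_i * g_i' D g_i)

with `D` a symmetric 3×3 diffusion tensor (units mm²/s), `b_i` the
diffusion weighting (s/mm²) and `g_i` the unit gradient direction.
Taking logs makes the model linear in `(ln S0, Dxx, Dxy, Dxz, Dyy, Dyz,
Dzz)`.  The fit is a **two-pass weighted least squares**: an ordinary
least-squares solve on the log-signals, then one weighted refit with
weights equal to the squared predicted signals — the standard
heteroscedasticity correction for log-transformed magnitude data.  The
design matrix doubles the off-diagonal columns (symmetry of `g g'`) and
requires at least six independent directions plus a baseline; a
rank-deficient gradient set raises an error naming the number of
independent directions.  Non-positive signals are clamped to a floor
(10⁻⁸ of the scan maximum) before the log and counted; negative
eigenvalues of the fitted tensor (a noise effect) are clamped to zero
and counted.

Scalar maps follow the usual eigenvalue formulas (λ₁ ≥ λ₂ ≥ λ₃):
MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2,
FA = √(3/2)·√Σ(λᵢ−MD)² / √Σλᵢ².  The principal direction (PD) is the
λ₁ eigenvector, sign-canonicalized to non-negative z (ties broken by y,
then x) because diffusion is axial: `v` and `−v` are the same
orientation.

The brain mask is an Otsu threshold on the mean baseline volume,
followed by largest-connected-component selection and hole filling,
with a half-maximum fallback for degenerate histograms.

## Protocol compliance checks

Dimensions must match exactly; spacing within `spacing_tolerance`
(default 0.01 mm); orientation within elementwise 10⁻³; per-volume
b-values within `bvalue_tolerance` (default 10 s/mm², scanner
rounding); gradient directions within `gradient_angle_tolerance`
(default 1°, measured as the **axial** angle min(∠(g, e), ∠(−g, e)),
since diffusion sensitization is symmetric under g → −g).

## Intensity checks

Both intensity stages use the normalized correlation
**without mean subtraction**,

    NC(a, b) = Σ a·b / √(Σ a² · Σ b²),

not the Pearson coefficient: a dropout changes the mean and the
magnitude of a slice, and subtracting means would hide part of that.
Note NC is exactly invariant under uniform rescaling of either
argument; what makes real dropouts detectable is that the receiver
noise keeps its full amplitude while the signal drops, so the affected
region decorrelates from its neighbours (see the phantom section).

* **Slice-wise check**: NC between each pair of successive slices gives
  a (volume × slice-pair) matrix.  For each slice-pair position the
  mean μ_j and stdev σ_j across the volumes of a contrast group define
  a lower bound μ_j − k·σ_j; any cell below it excludes its whole
  volume.  Default k = 3.5 (≈3.5-sigma one-sided outlier rule; a
  trade-off between dropout sensitivity and false positives from normal
  anatomy-driven variation).  A group of m volumes can push a single
  outlier at most (m−1)/√m standardized deviations from its own sample
  mean, so the rule needs m ≳ 14 at k = 3.5; typical schemes have 30+
  weighted volumes.
* **Interlace check**: NC between the odd and even slice substacks of
  each volume (slice 2i paired with 2i+1, a trailing slice ignored),
  thresholded at μ − k·σ of the contrast group, default k = 3.5.

Baseline (b≈0) and diffusion-weighted volumes have very different
contrast, so each group is thresholded against its own statistics; a
group with fewer than two volumes is skipped with a warning.  Volumes
are excluded whole — never slice-by-slice — so retained data keep a
spatially uniform number of measurements.

`rotate_gradients` is bookkeeping for externally supplied
motion-correction transforms: it rotates each volume's gradient
direction (renormalized) and touches nothing else.  Registration-based
motion/eddy correction itself is out of scope.

## Directional (entropy) detection and correction

Scanner-table vibration can bias the fitted PDs of a whole scan toward
one axis.  Healthy anatomy spreads PDs over many orientations, so the
artifact appears as clustering on the sphere:

* **Histogram**: the faces of a subdivided icosahedron, folded by
  antipodal symmetry — 20·4^L faces give 10/40/160 bins at levels
  0/1/2 (default level 2).  A PD joins the bin whose axis maximizes
  |axis · pd|.  Icosahedron subdivision keeps bins near-equal in solid
  angle (empirically, 10⁶ uniform axes give a max/min occupancy ratio
  of ~1.06 at level 1).
* **Entropy**: H = −Σ p ln p over bins (nats).  Training on
  artifact-free scans yields mean μ and stdev σ (sample, n−1); a scan
  scores z = (μ − H)/σ, so clustering (low H) gives high z.
* **Categories**: acceptable (z < 1.64), suspicious (1.64 ≤ z < 2.58),
  unacceptable (z ≥ 2.58) — one-sided 90th/99th-percentile boundaries
  of a normal reference.
* **Correction**: for suspicious scans, each retained weighted volume
  is tentatively omitted, the tensors refitted and the entropy
  recomputed; the omission with the largest entropy gain becomes a
  permanent exclusion, iterating until the z-score is acceptable, no
  candidate improves entropy, the retained fraction would fall below
  threshold, or fewer than 7 volumes remain (the last two reject the
  scan).  Entropy strictly increases per accepted removal, so the loop
  terminates.  Unacceptable scans are rejected whole: removing the
  many volumes needed would leave a strongly non-uniform scheme and a
  biased fit.  The raw removal loop is also exposed as
  `leave_one_out` without the category gate, for correction
  experiments independent of the categorization policy.

The region feeding the histogram is the whole brain mask by default;
`region_selector="wm-like"` restricts to FA > 0.25, and
`fa_weighted_histogram` weights each voxel's vote by its FA.

## Retained-fraction gate

A scan continues iff retained/original ≥ `retained_fraction_threshold`
(default 0.30, the lower end of the commonly used 30–40% range).  The
gate runs after the intensity stages and again after directional
correction.

## Monte-Carlo gradient-scheme bias

Magnitude MR noise is Rician, M = √((S+n₁)² + n₂²) with independent
zero-mean Gaussian n₁, n₂ of stdev σ, and at low SNR it biases the
fitted tensor — the more so the less uniformly the gradient directions
sample the sphere.  Per iteration: a prolate true tensor of chosen FA
and MD (closed-form construction diag(λ⊥, λ⊥, λ₁) with
d = FA/√(3−2FA²), λ₁ = MD(1+2d), λ⊥ = MD(1−d)) is rotated by a
Haar-uniform rotation (normalized Gaussian quaternions — exact Haar
measure, seedable); noise-free signals use S₀ = 1; Rician noise with
σ = S₀/SNR is added to every measurement; the tensor is refitted with
the same two-pass WLS estimator used for real data; the axial PD
angular error and the FA error are recorded and also aggregated by
true-PD orientation on a level-1 spherical histogram.  Defaults:
FA 0.4, MD 0.7×10⁻³ mm²/s, SNR 10, 200,000 iterations (20,000 in the
test suite and acceptance script — ordering margins are large and
stable at that size).

Scheme generators: electrostatic repulsion of antipodal charge pairs
(projected gradient descent with adaptive step, energy non-increasing),
the icosahedral 6-axis set, and a deliberately non-uniform
spherical-cap sampler for clustered-scheme experiments.

## Synthetic phantom

Every QC stage is exercised on generated data with a ground-truth
manifest:

* A brain-like **ellipsoid** containing a central cuboid split into
  three anisotropic "tract" blocks with PDs along (rotated) x, y, z,
  embedded in isotropic filler — echoing the left-right,
  anterior-posterior and inferior-superior fiber populations that make
  the entropy detector meaningful.  Tensors are physiologic:
  tract eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s, filler MD
  0.8×10⁻³ mm²/s, S₀ = 1000.
* **Inter-subject variability**, drawn per seed: Dirichlet tract
  proportions, a Haar-random rotation of the tract frame, ellipsoid
  scale, and within-tract orientation dispersion (~15°, emulating the
  orientation dispersion of real tracts).  Without it every phantom
  would be identical up to noise and the trained entropy stdev would be
  unrealistically small.
* **Noise**: Rician at a configurable baseline SNR, default 15 — a
  typical baseline SNR for b = 1000 s/mm² acquisitions.
* **Artifact injectors** scale the *clean* signal and re-apply Rician
  noise at full amplitude (signal loss happens during acquisition,
  before receiver noise), which is exactly what makes the artifacts
  detectable by correlation statistics; scaling the noisy signal would
  be invisible by the scale invariance noted above.  Injectors:
  single-slice dropout, venetian blind (every even slice of a volume),
  and directional bias (all volumes with |g·axis| > threshold scaled,
  dragging fitted PDs toward the axis).  Magnitude presets:
  mild 0.85, moderate 0.6, severe 0.35.  Repeated injections compose
  multiplicatively and every record is reconstructible from the
  manifest.

The phantom emulates *statistical* properties the QC stages key on —
slice correlation structure, interleave consistency, PD orientation
spread, Rician noise — and nothing anatomical: no gyri, no EPI
distortion, no eddy currents, no subject motion, no partial-volume
realism.  Detection rates measured on it validate the machinery, not
clinical performance.

## Numerical choices

* Two-pass WLS (not iterated to convergence): one reweighting captures
  most of the variance correction at a fraction of the cost.
* Batched voxel fits solve the 7×7 normal equations with
  `np.linalg.solve` over the voxel axis, falling back to per-voxel
  least squares on singular batches.
* PD angular error uses atan2(‖e₁×e₂‖, |e₁·e₂|) rather than
  arccos(|e₁·e₂|): arccos loses ~√ε of precision near parallel axes
  (one ulp below 1.0 already reads as 1.2×10⁻⁶ degrees), while the
  atan2 form is accurate to ~10⁻¹³ degrees in the noise-free limit.
* Entropy uses natural logs; 0·log 0 terms are dropped exactly.
* Histogram bin axes are deduplicated after antipodal folding with a
  10⁻⁶ rounding key; bin counts are asserted at construction.
* All randomness flows through `numpy.random.Generator` seeds; the QC
  pipeline itself contains no randomness at all.

## Problem sizes

Default sizes are chosen to make the full validation cycle quick on a
single CPU while keeping every statistic well-resolved: 24³-voxel
phantoms with 42-direction schemes (a scan fits and scores in ~0.15 s),
10-scan training sets, 20-scan evaluation groups, 100-phantom intensity
ensembles, 20,000-iteration Monte-Carlo runs, and 10⁶-draw sampler
checks.  All scale linearly if larger runs are wanted.

## Limitations

* Single-tensor model only; crossing fibers are out of scope.
* No DICOM conversion, denoising, registration-based motion or eddy
  correction, visual inspection, or tractography — upstream or
  downstream steps, deliberately excluded.
* The μ − k·σ intensity thresholds are non-robust sample statistics:
  with many corrupted volumes in one scan the group statistics inflate
  and sensitivity drops (the retained-fraction gate is the backstop).
* Entropy statistics must be trained per protocol/population; the
  categorization is only as good as the training cohort, and the
  synthetic cohort's entropy stdev (~0.006 nats) is far tighter than a
  clinical cohort's would be.
* A uniform whole-slice rescale without a noise floor is undetectable
  by design of the correlation statistic; real dropouts always come
  with noise, synthetic ones must too.
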