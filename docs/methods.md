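# Methods

This note documents the models and numerical choices behind `sinusid`:
what each stage computes, which knobs matter, what the synthetic data do
and do not emulate, and where the design was genuinely open.

## Problem setting

Identification compares a binarized antemortem (AM) axial CT silhouette
of the frontal sinus with a postmortem (PM) one. Both images are 200×100
two-level canvases with the sinus cavity black (0) on white (1). A
similarity score — the mean Hamming distance over brute-force matched
binary descriptors — is computed for every AM×PM pair of a cohort; the
same-individual (matched, diagonal) and cross-individual (mismatched,
off-diagonal) score distributions are then compared and thresholded.

## Preprocessing

A Hounsfield-unit raster is binarized at **200 HU** (values < 200 black,
≥ 200 white; air ≈ −1000 HU, compact bone ≳ 200 HU). The sinus is the
**largest 4-connected sub-threshold component inside an operator ROI that
does not touch the ROI border** — i.e. an air pocket fully enclosed by
bone; air connected to the outside is discarded by the border rule. The
delimitation of the cavity from adjacent air spaces in the real anatomy
is operator work; the ROI + enclosed-component rule is this package's
explicit, testable convention for it. Canvas normalization crops to the
foreground bounding box, scales aspect-preserving to fit the canvas minus
a fixed 4-px margin band, re-binarizes at 0.5 after bilinear
interpolation and centers. Fitting to (canvas − margin) rather than the
canvas itself makes a second normalization pass an exact no-op, which is
the behaviour a normalization step should have.

Coordinates are 0-based, origin top-left, x rightward, y downward; ROIs
are half-open. Boundary handling in all filtering is mirror reflection,
which is the discrete Neumann (zero-flux) condition and keeps the
diffusion and Gaussian references consistent.

## ORB-style extractor

FAST-9 segment test (16-pixel Bresenham circle of radius 3, arc of ≥ 9
contiguous pixels all brighter than I(p)+t or darker than I(p)−t,
t = 0.08 on [0,1] intensities), with the corner score defined as the
summed |difference| over the qualifying arc and strict 3×3 non-maximum
suppression. Corners are ranked by the Harris measure
det(M) − 0.04·tr(M)² over a 7×7 block and the global top 500 are kept
across a 4-level pyramid (scale factor 1.2). Orientation is the intensity
centroid θ = atan2(m01, m10) over a radius-15 disc (θ := 0 when both
moments vanish). The descriptor is steered BRIEF: 256 pairwise intensity
comparisons at pattern offsets drawn once from an isotropic Gaussian
(σ = patch/5, 31×31 patch, fixed pattern seed), rotated by θ and rounded
to the grid.

Two-level images make gradients and segment arcs degenerate, so the
silhouette is Gaussian-smoothed before detection (σ = 1) and description
(σ = 2). Keypoints are kept on the integer grid (no sub-pixel
refinement); keypoints without full 31×31 support are dropped. Bit-exact
parity with any third-party ORB build is a non-goal — the pattern is
self-generated, not the learned one.

## AKAZE-style extractor

A nonlinear diffusion scale space with scales σᵢ = 1.6·2^(o + s/4) over
octaves o and sublevels s (octaves work on 2× decimated copies; the
octave count is capped so the coarsest level keeps ≥ 32 px per side,
which on the 200×100 canvas means 2 octaves). Between consecutive
evolution times tᵢ = σᵢ²/2 the image advances by one Fast Explicit
Diffusion cycle: explicit steps L ← L + τⱼ·div(g∇L) with
τⱼ = τ_max / (2cos²(π(2j+1)/(4n+2))), τ_max = 0.25, n chosen as the
smallest with τ_max·n(n+1)/3 ≥ ΔT and the steps rescaled to sum to ΔT
exactly. The divergence is discretized in flux form with half-point
conductivities and zero-flux boundaries, which conserves total intensity
exactly (tested to < 0.5% drift including downsampling effects). The
conductivity is Perona–Malik g₂ = 1/(1 + |∇L|²/k²) with k the 70th
percentile of nonzero gradient magnitudes (300-bin histogram; fallback
k = 0.03 on zero-gradient images). With g ≡ 1 the evolution reduces to
Gaussian smoothing; this linear limit is verified to 0.02 of the
intensity range and is the main correctness anchor for the solver.

Keypoints are strict 26-neighbour maxima of the scale-normalized
determinant of Hessian. The response is (σ²Lxx)(σ²Lyy) − (σ²Lxy)², i.e.
**σ⁴-normalized**: per-derivative σ² is the normalization under which an
analytic Gaussian blob of width σ_b is detected at layer scale ≈ σ_b
(a σ²-normalized determinant would select σ_b/√3, ~1.9 sublevels off).
Derivatives are 3×3 Scharr; the detection threshold is 1e-4; plateau ties
yield no keypoint (strict inequality). Orientation is the
gradient-weighted dominant direction over a 6σ disc (σ-spaced samples,
Gaussian weights, sliding 60° sector in 64 steps). The descriptor is the
full (non-subsampled) M-LDB: over a θ-rotated patch of half-width 5σ,
2×2, 3×3 and 4×4 grids of cell means of intensity and the two steered
first derivatives, one bit per unordered cell pair per channel —
(6+36+120)×3 = 486 bits, padded to 61 bytes. This is deliberately an
"AKAZE-lite": g₂ only, no sub-pixel refinement, no descriptor channel
subsampling.

## Matching and scoring

Descriptors are packed bit rows; Hamming distances use vectorized
XOR + popcount. Brute-force matching pairs **every** AM (query)
descriptor with its nearest PM (target) descriptor — no Lowe ratio test
and no cross-check, because the score is defined over all matches and
filtering would change the statistic. Ties at equal distance go to the
lowest target index; together with the canonical keypoint order
(response desc, then y, then x) this makes the score independent of
storage order. The score is the arithmetic mean of matched distances,
direction AM→PM; a symmetric variant (mean of both directions) exists
behind a flag but is off by default, since symmetrization is an
interpretation the score's definition does not require. An image with no
keypoints raises "insufficient features"; the cohort layer records the
pair as missing (never 0) and a score matrix with > 10% missing entries
is rejected outright.

## Statistics

**Welch's t-test** (scipy, unequal variances, Satterthwaite fractional
df, two-sided p) compares matched vs mismatched scores; the report also
carries each group's n, range, mean and SD. **ROC analysis** treats
matched as the positive class with the rule "identify iff score ≤
threshold" (ties at the cutoff count positive). The AUC is the
Mann–Whitney pair statistic P(matched < mismatched) + ½P(equal), which
equals the trapezoid area under the threshold-sweep curve to 1e-9; the
reported cutoff maximizes Youden's J = TPR − FPR with ties resolved to
the smaller threshold. Whether published cutoffs in this field are
Youden-optimal is generally unstated; Youden is this package's fixed,
declared convention. Subgroups (sex; AM–PM interval < / ≥ 30 days; age
< / ≥ 60 years) are evaluated within-subgroup: mismatched pairs require
both members in the subgroup. No multiple-testing correction is applied
across subgroups and no AUC confidence intervals are computed.

**Reliability**: for two measurement sessions, TEM = √(Σdᵢ²/2n),
rTEM = TEM/grand mean × 100, and R = 1 − TEM²/s² with s² the sample
variance of all 2n pooled measurements (n−1 denominator). The pooled-2n
convention is the standard anthropometric one; a per-subject-mean variant
is exposed behind a flag because published R values rarely state their
s². Acceptability thresholds: rTEM < 1.5% intra-observer / < 2.0%
inter-observer, R > 0.75. Simulation with known variance components
(subjects ~ N(μ, σ_b²), sessions ~ N(0, σ_e²)) recovers TEM → σ_e and
R → σ_b²/(σ_b² + σ_e²) within 10% at n = 200.

## Synthetic cohorts

The generator emulates the features the analysis depends on, not sinus
anatomy per se:

* **Between-individual variance** — each case is a union of 1–4
  overlapping radial lobes (elliptical base, sinusoidal scallop of random
  frequency 4–9, phase and amplitude), joined by a septum-like bridge so
  the foreground is a single 4-connected region, scaled and centered to
  fit the canvas with a safety margin. Defaults: 2 lobes, scallop
  amplitude 0.25, left/right asymmetry 0.6.
* **Within-individual AM→PM perturbation** — rigid rotation
  ~U(±3°) about the centroid, translation ~U(±2 px) per axis
  (nearest-neighbour resampling), and a morphological erosion or dilation
  of radius U{0..1} px standing in for slice-selection jitter. The
  magnitudes default small because an examiner picks the most similar PM
  slice; off-canvas draws are retried up to 10 times.
* **The failure mode** — `simple_shape_frac` renders a fraction of cases
  as near-rectangles (bounding-box fill > 0.95), the shape class known to
  produce false-positive matches because it offers few distinctive
  keypoints. It is 0 by default and exists so tests can reproduce the
  failure mode on demand.
* **Covariates** — sex 135:45 M:F, interval < 30 days for 125/180, age
  < 60 years for 81/180 (proportions of the 180-case study design this
  package mirrors), with ages uniform within 19–59 / 60–98 and intervals
  within 3–29 / 30–1920 days.

Randomness: one root seed; per-case and per-purpose child streams are
derived as `default_rng([seed, stream, index])`, so cohorts are
extensible without reshuffling existing cases and the whole cohort is a
pure function of its parameters.

What the generator does **not** emulate: HU textures (it emits
already-binarized silhouettes; HU behaviour is covered by the
preprocessing phantom tests), anatomically realistic 3D pneumatization,
scanner/protocol differences, and the empirical score *magnitudes* of
real studies. Synthetic matched/mismatched distributions are calibrated
only to reproduce qualitative separation (default cohorts give
AUC ≈ 0.99 at n = 60), so passing tests demonstrate that the pipeline
measures shape similarity and separates the groups under the stated
perturbation model — not that real-world error rates equal the synthetic
ones.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of n = 60 (5 seeds,
both methods) for the separation property, n = 25 for the
perturbation-degradation trend, n = 20 for the simulated two-session
observer study and n = 200 for the reliability-recovery simulation —
sizes chosen to make the statistics stable at desk scale. The simulated
observer sessions apply small re-collection jitter (±1° rotation, ±1 px
shift) to the case's fixed PM image, modelling an examiner re-selecting
the same MPR slice rather than a fresh AM→PM difference; the resulting
rTEM is measured, not calibrated to any published value (synthetic score
scales differ from real ones). Everything — shapes, perturbations,
covariates, descriptor patterns — is a deterministic function of the
seeds, and end-to-end determinism is asserted in the tests.

## Known limitations

* The extractors are faithful minimal implementations of their published
  cores, not bit-compatible with any specific third-party build;
  absolute score values therefore differ from those of other
  implementations even on identical images.
* Descriptor support requirements (31×31 BRIEF patch, ~7σ M-LDB patch)
  drop keypoints near borders; very small or thin silhouettes can yield
  "insufficient features".
* The enclosed-component rule assumes the ROI encloses the cavity with a
  closed bony margin in the slice; pneumatization defects that open the
  cavity to the outside require a tighter ROI.
* Only the two-session TEM is implemented; multi-observer generalized
  TEM, ICC variants and Bland–Altman analyses are out of scope, as are
  geometric match verification (RANSAC), ratio-test filtering and 3D
  methods.
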