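# Methods

## Scope and model

`fansym` implements two-dimensional fan-beam filtered back-projection (FBP)
for a **flat, equispaced detector**, together with the quadrant-symmetry
acceleration of its back-projection stage, and the evaluation machinery
around it (analytic phantoms and projectors, MSE/PSNR/SSIM, two-group
summary statistics).

One geometric convention is used everywhere. At view angle β (degrees) the
source sits at polar angle β + 90° at distance D from the isocenter, i.e.
at Cartesian D·(−sin β, cos β); the detector coordinate s lives on the
*virtual detector*, the line through the isocenter along (cos β, sin β).
A point (r, φ) then projects to

- U(r, φ, β) = (D + r sin(β − φ)) / D — the dimensionless source–pixel
  distance ratio entering the back-projection as 1/U²;
- s′(r, φ, β) = D·r·cos(β − φ) / (D + r sin(β − φ)).

This convention is forced by two anchor cases: r = 0 must give s′ = 0, and
φ = β must give s′ = r. U > 0 is guaranteed for r < D; both factor
functions reject r ≥ D.

View angles are β_k = k·(360/n_views), k = 1…n_views, so the four angular
regions (0, 90], (90, 180], (180, 270], (270, 360] are half-open and the
360° view belongs to the fourth region. Degrees are used at every
interface; conversion to radians happens once on entry, and the
accumulation step Δβ is in radians.

### Filtering chain

Plain weighted back-projection of fan-beam data reconstructs a 1/|frequency|
blurred image, so the standard flat-detector FBP chain is applied ahead of
either back-projector:

1. cosine pre-weight D/√(D² + s²);
2. row-wise convolution with the discrete Ram-Lak kernel
   h(0) = 1/(4Δs²), h(m) = −1/(π²m²Δs²) for odd m, 0 otherwise, at full
   support (2·n_bins − 1 taps);
3. scaling by Δs/2 — Δs for the convolution quadrature and 1/2 because a
   full 360° turn measures every ray twice.

The back-projection step itself accumulates q(β, s′)/U²·Δβ with linear
interpolation between the two detector bins bracketing s′ and zero
contribution outside the detector support.

### Symmetry acceleration

With the centered-grid convention (pixel (i, j) center at
((j − (n−1)/2)·Δx, ((n−1)/2 − i)·Δx)), a 90° rotation about the isocenter
is the exact index permutation (i, j) → (n−1−j, i). The grid therefore
partitions into orbits of four pixels sharing one radius, at polar angles
φ, φ+90°, φ+180°, φ+270° — plus a singleton center pixel when n is odd.
Orbit count is (n² − c)/4 + c with c = n mod 2.

Because U and s′ depend on angles only through β − φ, advancing pixel angle
and view angle together by any multiple of 90° leaves them unchanged. The
accelerated back-projector exploits exactly this: per orbit and per view β
it evaluates sin(β − φ), cos(β − φ) and the single (U, s′) pair for the
representative member, then credits that same pair to member m at view
β + m·90° (which exists in the sampled set whenever n_views is divisible
by 4 — enforced with a clear error otherwise). The summands are identical
floating-point numbers, only regrouped, so the two methods agree to
reordering noise; the package's equivalence tests use a 1e−6 relative
max-difference bound and observe ~1e−14 in practice.

**Operation accounting.** The `OpCounter` counts 2 trig evaluations and 1
geometry evaluation per (pixel, view) for the naive method and per
(orbit, view) for the accelerated one. For even n (no singleton) both
ratios are exactly 1/4 — one computation serving the four quadrant
partners. A further refinement would compute the *cross*-quadrant pairs,
e.g. U(r, φ+90°, β) = (D − r cos(β − φ))/D, from the already-evaluated
sine/cosine by sign swaps alone, cutting the trigonometric count by another
factor of four; the package verifies those reflection identities to 1e−12
as exact invariants in its test suite but deliberately keeps the
accumulation loop in the one-pair-per-orbit-per-view form, where the
quarter ratio of *both* counters is the contract. The odd-n center pixel
(r = 0, U = 1, s′ = 0) is handled by the naive rule and counted as such.

## Phantoms and forward projection

Clinical evaluations of reconstruction algorithms use patient MRI sections,
which cannot be redistributed; the phantom module supplies the standard
stand-in — additive
ellipse phantoms (the Shepp–Logan tradition). `default_head_phantom()` is a
deterministic five-ellipse head section: a bright skull ring (two
concentric ellipses, the inner with negative value), a brain-tissue
ellipse, one small rotated hyperintense lesion, one hypointense lesion, all
inside a unit bounding disk. Rasterization samples pixel centers (no
antialiasing): the convention is exact, additive, and commutes exactly with
90° rotations, which is what the orbit machinery needs. No MR-intensity or
Hounsfield mapping is applied; values are dimensionless.

Two projectors provide independent data paths:

- `project_analytic` — exact chord lengths through each ellipse via the
  closed-form line/quadric intersection; the oracle.
- `project_numeric` — sampled line integrals over a rasterized grid with
  bilinear interpolation, converging to the analytic answer as the step and
  pixel size shrink.

Optional additive Gaussian noise (`add_noise`, seeded) is the only noise
model. What the synthetic stack deliberately does *not* emulate: MR physics
(k-space sampling, coil sensitivities, relaxation), scatter, beam
hardening, detector blur, or anatomical texture. Passing tests therefore
demonstrate the correctness and the operation-count savings of the
reconstruction machinery on well-posed inputs — not clinical image quality
on patient data.

## Image metrics

MSE is the plain 1/(mn) sum of squared differences. PSNR is
10·log₁₀(MAX²/MSE) with MAX an explicit argument (the package never guesses
a peak intensity; use 255 for 8-bit exports, the data range for float
grids); identical images return an infinite-PSNR sentinel rather than an
error. SSIM defaults to the **global single-window form** with population
(1/N) variance/covariance and stabilizers c₁ = (0.01·MAX)², c₂ =
(0.03·MAX)² — that printed formula is the package's evaluation contract;
the common 11×11 sliding-window variant is available behind
`windowed=True` (delegated to scikit-image) as an explicitly non-default
option.

Note an internal consistency anchor used in the tests: MAX = 255 with
MSE = 150 evaluates to 26.369 dB. Published clinical tables sometimes pair
MSE ≈ 150 with PSNR ≈ 32 dB, which is inconsistent with MAX = 255 and
implies an unstated peak or scaling; the package reproduces the formula,
not such unreproducible pairs.

## Trial statistics

The module works from published summaries only. Agitation is defined as
Riker SAS grade ≥ 5 (the scale's own semantics: 5 agitated, 6 very
agitated, 7 dangerously agitated); this cut uniquely reproduces both
bundled incidences. Incidence percentages are **truncated** toward zero
(5/30 → 16, 23/30 → 76), matching the evident reporting convention of such
tables — documented here because rounding would give 17/77. The χ² test is
the uncorrected Pearson 2×2 statistic by default (expected counts are
large); Yates' correction is a flag. The t tests are computed from
(mean, sd, n) triples, pooled or Welch; scipy's
`ttest_ind_from_stats` serves as the cross-check oracle in the tests, not
as the implementation, keeping the two routes independent.

## Numerical choices and degenerate inputs

- Linear interpolation at s′; zero outside the detector; detector bins
  centered symmetrically about s = 0.
- Geometry constructors validate that the detector covers the object's fan
  shadow, max|s′| = R/√(1 − (R/D)²), and reject grids whose corners reach
  the source distance.
- `FanBeamGeometry.for_object` sizes the detector with a 5% margin and
  defaults to D = 4× the object radius.
- Equivalence tolerance between back-projectors is 1e−6 relative
  max-difference (different summation order precludes bit-identity).
- Reference problem sizes used throughout the tests and the acceptance
  script: a 64-pixel grid at 360 views / 257 bins for the head phantom and
  a 128-pixel grid at 720 views / 513 bins for the uniform-disk recovery
  oracle (interior mean within 5% of truth; observed ≈ 0.003%). These sizes
  resolve the phantoms comfortably while keeping the whole suite in the
  seconds range.
- The per-view "mass" consistency property (view integral ≈ area × value)
  is checked at D = 8R: the fan-to-parallel Jacobian bias scales as
  (3/8)(R/D)², which at D = 4R sits at the edge of the 2% tolerance and at
  8R is comfortably below it.

## Known limitations

- No iterative or regularized ("compressed-sensing") reconstruction: only
  the symmetry-accelerated weighted back-projection chain is in scope.
- No curved (equiangular) detector, cone-beam geometry, or GPU path.
- The operation counters model work at the granularity of trig/geometry
  evaluations; they are not wall-clock benchmarks.
- The synthetic phantoms do not certify performance on clinical MRI data
  (see the synthetic-stack caveats above).
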