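# Methods

## Scope and design

`ovatex` implements a texture-classification pipeline for grayscale
ultrasound-like images — denoise, extract LBP and Laws' texture-energy
features, classify with logistic regression — together with a synthetic
two-class image generator and the summary-statistics comparisons of the
137-case clinical cohort the pipeline was designed around. The original
study images (contrast-enhanced ultrasound, 137 patients) are private, so
every empirical claim the package makes is measured on synthetic data or on
the published summary tables; nothing here should be read as a clinical
validation.

## Wavelet preprocessing

The decomposition is the separable 2-D DWT with symmetric (half-sample)
boundary extension, delegated to PyWavelets. Band naming follows the
package convention B/J/U/F = LL/LH/HL/HH; up to three stages recursively
split the approximation band. The default wavelet is Haar: it is
orthonormal, so a single stage on even-sized inputs conserves energy
exactly (Parseval), which makes the conservation and round-trip guarantees
testable at tight tolerance. Longer filters (e.g. `db2`) are supported; under
symmetric extension their band sizes exceed ⌈n/2^ℓ⌉ and the feasible depth
is the PyWavelets maximum-useful-level rule, reported in the error message
when a requested depth does not fit.

Denoising soft-thresholds every detail band and never the approximation.
The default rule is VisuShrink: `t = σ̂ √(2 ln N)` with the noise scale
estimated as `median(|F1|)/0.6745` (MAD of the finest diagonal band) and
`N` the pixel count. `manual_t = 0` is an exact identity up to transform
round-off (≤ 1e-8), and retained detail energy is monotone non-increasing
in `t`. The classifier consumes the denoised image (one level by default);
the three-stage decomposition is exposed for inspection but its bands are
not themselves classifier features.

## LBP features

Neighbors sit at angles `2πp/D` counterclockwise from the +column axis at
radius `r`; off-grid positions are bilinearly interpolated and positions
within 1e-9 of a grid node are read exactly. The threshold is `T(x) = 1`
for `x ≥ 0`; because interpolation can perturb an exact tie by
floating-point round-off, a neighbor within 1e-10 of the center counts as
a tie. This tolerance is part of the documented contract and mirrored by
the test oracle. The angular origin and direction are a fixed convention;
riu2 codes are invariant to them by construction (verified exhaustively
for all 8-bit patterns).

Two codings: the classic `orig` code `Σ bₚ 2^p` (the raw bit sum without
binomial weights would collapse onto the riu2 coding and cannot index the
`2^D` patterns, so the standard weighting is used), and `riu2`, the
rotation-invariant uniform coding implemented exactly as defined (bit
count if the circular transition count `U ≤ 2`, else `D+1`). Codes are
computed over the valid interior (margin `⌈r⌉`), histogrammed over `2^D`
or `D+2` bins, and summarized by histogram energy and entropy (base-2
logarithm, `0·log 0 := 0`). Histogram functionals — rather than
pixel-domain statistics of the code map — are the standard reading of
"energy and entropy of the LBP image" and are what the classifier uses.
Default scales `(8,1), (16,2), (24,3)`.

## Laws' texture energy

The nine 3×3 masks are outer products of `L3 = [1,2,1]` (level),
`B3 = [−1,0,1]` (edge) and `D3 = [−1,2,−1]` (spot); all but `L3L3` are
zero-mean. Filtering is cross-correlation (the mask applied as written,
not flipped) with symmetric padding and same-shape output; for the
symmetric masks the two conventions coincide, and for the antisymmetric
ones they differ only in sign, which the absolute-value aggregation
removes. Each zero-sum response is balanced by pointwise division by the
`L3L3` response, whose magnitude is floored at `ε = 1e-8` (sign
preserved; exact zeros divide by `+ε`), making the descriptors invariant
to positive rescaling of the image away from the floor. The texture
energy metric is a 7×7 moving-window sum of absolute values: a window sum
of raw zero-mean responses would cancel to ≈ 0 and carry no energy, so
the nonlinear magnitude sum — the standard Laws formulation — is used.
The per-mask descriptor is the mean of the TEM map; the eight symmetric
pairs are kept separate rather than pooled. Mean versus window-sum scaling
differs only by the constant 49 and is immaterial after standardization.

## Logistic classification

The classifier is binary logistic regression on z-scored features
(standardization statistics estimated on training data only and stored
with the model): `logit(π) = α + Σ βⱼ zⱼ`, `π = 1/(1+e^{−a})` computed
via `scipy.special.expit` for stability at extreme log-odds. Fitting is
Newton–Raphson on the Bernoulli log-likelihood with step-halving (the
penalized likelihood is non-decreasing across iterations), convergence at
max parameter change < 1e-8 or 100 iterations. A small ridge penalty
(default λ = 1e-6, intercept unpenalized) keeps the Hessian invertible
when the synthetic classes are linearly separable — as they typically are
at the default generator settings; at λ = 0 a separable fit is flagged
non-converged with a warning. No estimation procedure is prescribed by
the source formulation, which specifies only the linear-log-odds model
and its inverse transform; "upgraded" logistic regression is
operationally standard logistic regression here, and the package says so.

Evaluation: confusion counts with positive class = malignant (1);
accuracy `(tp+tn)/n`, precision, recall, F1, with zero-denominator ratios
reported as 0 plus an `undefined` flag so pooled cross-validation never
aborts. Classification threshold 0.5 with ties classified malignant (the
conservative clinical direction). The benchmark protocol is stratified
5-fold cross-validation: per class, indices are shuffled by a
seed-derived RNG and dealt round-robin, so fold sizes differ by at most
one per class and the whole evaluation is reproducible from one integer.

## Synthetic data

The generator targets the contrasts the features measure, not acoustic
physics. Benign-like images are Gaussian-blurred white-noise fields
(σ = 3 px) rescaled to [0.25, 0.75]; malignant-like images add bright
spots at density 0.02 (uniform +0.3–0.6) and 6 thin line segments
(length 20–50 % of the image side, uniform orientation) before both
classes receive multiplicative speckle `(1 + 0.15·N(0,1))` — the standard
multiplicative model for ultrasound speckle — and are clipped to [0,1].
Spot density, edge count and speckle level were chosen once as a
moderate-contrast regime in which the malignant class has visibly but not
trivially higher high-frequency energy. Per-image RNG substreams are keyed
on `(seed, index)` with a separate `(seed, index, 1)` stream for the
malignant additions, so images are independent of generation order and a
class-1 image with zero spots and edges degenerates exactly to its class-0
counterpart.

What the generator does *not* emulate: contrast-agent perfusion dynamics,
attenuation and shadowing, anatomical structure, scanner point-spread
functions, or inter-patient variability. Passing the benchmark therefore
shows that the implementation extracts and classifies the texture
contrasts it claims to — not that the pipeline reaches any particular
accuracy on clinical images. The default benchmark (100 images per class
at 128×128, 5-fold CV) is the package's stand-in for the original study's
reported accuracy on its private images; at these settings the synthetic
classes separate completely (pooled accuracy 1.0), comfortably above the
0.90 the package asserts in its acceptance test.

## Clinical statistics

The published cohort tables ship as verbatim CSV fixtures. The source
names no tests, so the package defaults to Pearson chi-square (no
continuity correction) for r×c counts, Fisher's exact test for sparse
2×2 collapses, and Welch's unequal-variance t for summary means —
standard choices, each flagged when its assumptions are strained
(expected counts < 5; zero cells). `validate_tables()` recomputes every
marginal sum and every test and flags disagreements with the printed
values instead of forcing them: the pregnancy-outcome rows (38
miscarriages) conflict with the stated abortion-group size (32); the
gestational-age-of-detection table recomputes to p ≈ 0.0106, not the
printed 0.026; the surgery-type table recomputes to p ≈ 0.028 against a
printed ">0.05"; and a printed p of "0" is interpreted as "<0.001", never
as an exact zero.

## Numerical choices and limitations

* Problem sizes: the benchmark uses 200 images of 128×128 and the
  denoising experiment 20 trials at 64×64 — large enough for stable
  Monte-Carlo checks while keeping the full suite fast on one CPU.
* Images smaller than 16×16 are rejected by the generator (the r=3 LBP
  circle plus the 7×7 TEM window must fit); the wavelet stage needs ≥ 2×2.
* `orig`-mode LBP at D = 24 would index 2²⁴ histogram bins and is
  supported but impractical; riu2 is the intended mode for features.
* The logistic fit requires n > k+1 observations and both classes
  present; with 14 features this means at least 16 training images.
* RGB inputs are collapsed by unweighted channel mean; 8- and 16-bit
  integer images are scaled by their type maximum.
* The clinical module operates on summary tables only — no patient-level
  reanalysis is possible from the published data.
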