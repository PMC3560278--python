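# Methods

This note documents the models behind `colonyscatter`, the defaults and why
they were chosen, and what the synthetic benchmark does and does not show.

## Colony phantoms

A colony is a non-negative thickness map h(x, y) on a square grid
(default 512 px at 2 μm/px, so a 1.024 mm field) with a single connected
footprint. The boundary is a circle of radius R₀ (drawn from a truncated
normal; default mean 400 μm — hESC colonies are sub-millimeter) perturbed by
a low-order Fourier ripple R(θ) = R₀(1 + a·g(θ)), where g sums harmonics
2–6 with 1/k amplitude decay, rescaled to unit peak, and a is the
`edge_irregularity` (0.03 good, 0.25 bad). The interior profile is a
flat-topped plateau H·(1 − (r/R(θ))²)^α with the peak height H drawn from a
truncated normal (good: 53 ± 4.2 μm; bad: 44 ± 13.9 μm, both truncated at
zero rather than resampled, which guarantees positivity without biasing the
mean at these parameter values — the truncation point lies >3 σ below the
mean). Bad colonies additionally receive Poisson(6) Gaussian surface lumps
(width 20–50 μm, signed amplitudes ~ N(0, 12 μm)) that model non-uniform
cell stacking; the map is clipped at zero. A light Gaussian smoothing
(`edge_smooth_um`) rounds the rim, and material thinner than 0.5 μm is
discarded from the footprint.

**Calibration of α and the rim smoothing.** The two class height statistics
are the only quantitative morphology anchors, so the free shape parameters
were set once so that the z-stack height estimator (below) recovers the
generating class means without bias: α = 0.005 and edge smoothing 1.0 μm
give a measured estimator bias of +0.09 ± 0.40 μm on good-class colonies.
Two effects cancel by construction here: a dome-ish profile and the rim
pixels pull the footprint-mean height *below* the peak H, while slice
quantization (occupancy uses ceil(h/z_step)) pushes the estimate *up* by
about z_step/2. A very flat plateau with a narrow rim balances the two.
These are generator defaults, fixed before the statistical tests were run
and not tuned per test.

Confocal-like z-stacks place unit signal at slice k wherever
k·z_step < h(x, y) (k = 0, 1, …), plus optional clipped Gaussian noise.
Fluorescence pairs scatter nuclei (density 0.004/μm², ≈ 16 μm spacing) over
the footprint as Gaussian blobs (σ = 5 μm); every nucleus stains in the
DAPI channel, and an independent Bernoulli(fraction) subset contributes the
same per-nucleus brightness to the Oct-4 channel, so the expected
integrated-intensity ratio equals the generating fraction.

## Scattering model

The colony is treated as a thin phase object:
t(x, y) = exp(i·2π·Δn·h(x, y)/λ) with Δn = 0.04 (typical cell-vs-medium
refractive-index contrast) and λ = 633 nm. A 53 μm colony therefore imposes
about 3.3 waves of delay; the pattern is dominated by the colony outline
and its surface structure, exactly the features that differ between
classes. Multiple scattering and volumetric effects are ignored — the
colony acts as a superposition of phase apertures.

Propagation to the detector (z = 20 mm, same grid as the object plane, no
lens) uses the band-limited angular-spectrum method: the exact scalar
transfer function exp(i·2πz/λ·√(1 − (λf_x)² − (λf_y)²)) applied in the FFT
domain, with evanescent components removed and the Matsushima–Shimobaba
frequency cutoff f_lim = 1/(λ√((2Δf·z)² + 1)) suppressing the
transfer-function aliasing a periodic grid would otherwise fold into the
detector window. Within the retained band the operator is unitary, so
energy is conserved to numerical precision for fields whose spectrum fits
the band (a Gaussian beam conserves to ~1e−9). Hard colony rims scatter a
few percent of the light to angles beyond the cutoff (measured ≈3.5% for a
default good colony); physically that light would miss the detector region,
and the band limit discards it by design. An optional `pad_factor`
zero-pads the FFT for finer frequency sampling — the analytic Airy-pattern
check (40 μm hard aperture at z = 20 mm, first minimum at 1.22λz/D,
reproduced to <1 px) uses pad_factor = 4.

Illumination is a Gaussian beam (1/e² intensity radius 600 μm). Detector
readout adds Poisson shot noise (default 10⁴ photons at the brightest
pixel) and quantizes onto the 16-bit sensor range.

## Pseudo-Zernike features

Patterns are mapped onto the unit disk at the geometric image center with
the inscribed-circle radius (the optical axis is the pattern center by
construction; an intensity-centroid option was rejected as noise-sensitive).
Intensities are log-compressed, log(1 + I), before max-one normalization:
the unscattered central lobe is orders of magnitude brighter than the
information-carrying rings and would otherwise dominate every moment.

Moments use the standard pseudo-Zernike radial polynomials

    R(n, m, ρ) = Σ_{s=0}^{n−|m|} (−1)^s (2n+1−s)! /
                 [s! (n−|m|−s)! (n+|m|+1−s)!] · ρ^{n−s}

(e.g. R(1,0) = 3ρ − 2, R(1,1) = ρ, R(n,n) = ρⁿ), orthogonal on the disk
with weight ρ. A(n, m) is the discrete projection with midpoint pixel
sampling, pixel area ΔA = 1/radius² in unit-disk units, and pixels whose
centers fall outside ρ = 1 excluded; the fast implementation accumulates
the polar power table M(m, k) = Σ f·e^(−imθ)·ρ^k·ΔA in one pass and
assembles every moment from it (verified against a brute-force per-moment
sum to ~1e−10 relative at n ≤ 6). Only m ≥ 0 magnitudes are kept —
A(n, −m) is the complex conjugate, so negative repetitions are redundant.
The order cap n_max = 17 is the smallest giving at least 161 features
((17+1)(17+2)/2 = 171). Coefficients are computed in exact integer
arithmetic and converted to float; at n = 17 the alternating sums lose a
few digits near ρ = 1, which is harmless at feature-extraction precision
but worth revisiting before pushing n_max much higher.

Fisher's criterion F(j) = (μ₁ − μ₂)²/(s₁² + s₂² + ε) uses sample variances
(ddof = 1) and ε = 1e−12 so that a zero-variance, separated feature gets
the finite ceiling 1/ε rather than overflowing; ties break toward the lower
feature index. Selection keeps the top 161 by default.

## Classification

Features are standardized with training-set mean/sd only (test-set leakage
is explicitly tested against) and fed to an SVM. The default kernel is
linear with C = 1: with 161 features and ~140 training samples the classes
are linearly separable, and a linear margin is reproducible and
inspectable; RBF is available through the hyperparameters. Trained models
are stored as plain arrays (support vectors, dual coefficients, intercept,
scaler, feature identities) so the decision function is computed by the
package itself and JSON round trips predict bit-identically. Evaluation
reports the 2×2 confusion matrix (rows: human-assigned class) and
row-percent distinguish rates, printed to one decimal. Stratified k-fold
cross-validation is provided for desk-scale experiments where a separate
test set is not affordable.

## Morphometry

Per-colony height: each slice of a z-stack is segmented by a global Otsu
threshold (a half-max alternative is available), the colony mask is the
union of occupied pixels, and the height is the mean over mask pixels of
(top occupied slice − bottom occupied slice + 1)·z_step — exact on
noiseless slabs whose height is a multiple of z_step, and with a 'peak'
statistic flag for the maximal extent instead of the mean. Group
comparison uses the two-sample t-test; the pooled-variance (Student)
variant is the default, with Welch available — and preferable in
principle, since the bad class's height variance is roughly ten times the
good class's.

Oct-4/DAPI ratio: the colony footprint is segmented from the smoothed DAPI
channel by Otsu's threshold, the per-channel background (median intensity
outside the footprint) is subtracted, and the two integrals over the
footprint are divided. The estimator recovers the generating positive
fraction within binomial error across fractions 0.2–0.8.

## Statistical power of the height comparison at n = 18

With the published class statistics (53 ± 4.2 vs 44 ± 13.9 μm), the
noncentrality of the pooled t-test at 18 colonies per class is
9/√((4.2² + 13.9²)/18) ≈ 2.63, against a two-sided α = 0.01 critical value
of 2.73 (df = 34): analytic power ≈ 0.47. Replicated synthetic experiments
at that size therefore reach p < 0.01 in roughly half the runs, not nearly
always — a single significant result at n = 18 is entirely plausible, but
it is not a reproducible property of these effect sizes. The corresponding
stringent acceptance test documents this gap rather than hiding it.

## What the synthetic benchmark shows — and does not

The phantoms idealize the two morphology classes: every good colony is a
clean plateau, every bad colony visibly lumpy, with no intermediate grades,
no debris, no dish reflections or beam misalignment, and no uncertainty in
the "human" labels. Under those conditions the pipeline separates the
classes completely, which demonstrates that the measurement chain
(diffraction physics → rotation-invariant moments → selection → SVM) is
implemented coherently and is sensitive to exactly the morphological
differences it targets. It does *not* demonstrate field performance on
real colonies, where the published per-class rates (87.3% / 83.6%) reflect
borderline morphologies and label noise that the generator deliberately
omits. The benchmark's published-rate bounds should be read as "the
idealized pipeline must clear the real instrument's bar", not as a claim
of superiority.

## Problem sizes and determinism

Default study sizes: 100 colonies per class for the classification
benchmark (stratified 70/30 split) and for the height survey; 100
replicates at 18/class for the significance-rate experiment (run on a
coarse 64-px grid — height statistics are grid-independent). All drivers
take a single master seed and spawn per-stage generators from it
(`numpy.random.SeedSequence`), so every artifact — phantoms, shot noise,
splits, folds — regenerates bit-identically from the seed.
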