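# Methods

This note documents the models and numerical choices behind `ictal`: what
each stage computes, which parameters matter, what the synthetic data
emulate, and where the design was genuinely open.

## Signal model and preprocessing

The unit of analysis is a single-channel EEG segment with a declared
sampling rate (the canonical geometry is 4097 samples at 173.6 Hz, i.e. a
23.6 s segment; a second supported geometry is 256 Hz with 4 s windows).
Segments are band-pass filtered with a Butterworth filter, 0.5–40 Hz, order
4, applied forward–backward (`sosfiltfilt`) so the features see no phase
distortion; the effective magnitude response is the squared one-pass
response (−6 dB at the corners). The pad length is set to three periods of
the low corner (≈ 3 · fs / 0.5 samples) because the 0.5 Hz corner has a time
constant far longer than scipy's default padding; without this the edge
transients dominate stop-band measurements.

Filtered segments are cut into non-overlapping analysis windows of
`round(seconds × rate)` samples — 5 s × 173.6 Hz = 868 exactly, 4 s ×
256 Hz = 1024 — with trailing partial windows dropped, and labels inherited
from the segment. Whether windows may overlap is configurable
(`step_samples`); the default is non-overlapping, and filtering precedes
windowing. Each window is further split into 50-sample sub-windows with
stride 25 for the convolutional branch (33 per 868-sample window, 39 per
1024-sample window; the 18 samples of an 868-window not covered by the last
full sub-window are discarded).

Cross-validation splits windows, not segments, by default; the stricter
regime that keeps all windows of one source segment in the same fold is
available via `CVConfig(group_by_segment=True)`.

## Tunable-Q wavelet transform

The TQWT is an iterated two-channel oversampled filter bank with quality
factor Q, redundancy r and J levels, giving J + 1 sub-bands (band 1 =
highest frequency, band J + 1 = low-pass residue; defaults Q = 1, r = 3,
J = 8). Scale factors are β = 2/(Q+1) and α = 1 − β/r. The level filters
are defined in the frequency domain with transition function
θ(ω) = ½(1 + cos ω)√(2 − cos ω), for which T0² + T1² = 1 exactly: the
low-pass response is flat below (1−β)π, transitions on [(1−β)π, απ), and is
zero above απ; the high-pass response is complementary. These edges are
the ones consistent with the branch resampling factors (low-pass branch
scaled by α, high-pass by β); a bank whose low-pass support extended beyond
απ could not be rate-reduced by α and remain invertible.

Implementation is DFT-based on the unitary FFT, with band lengths rounded
to even integers per level from the original length (N0_j = 2·round(α^j
N/2), N1_j = 2·round(β α^{j−1} N/2)). Odd-length inputs are zero-padded by
one sample internally; the original length is recorded and restored on
reconstruction. With this construction the round trip is exact to
floating-point rounding (measured ~1e−15 relative) and sub-band energies
sum exactly to the signal energy. Feasibility requires every level to keep
at least 4 coefficients; `decompose` reports the maximal feasible J when
asked for more.

Nominal band centers are reported as f_j = (2−β)/4 · α^{j−1} · fs — the
midpoint of band j's support [(1−β)α^{j−1}, α^{j−1}]·fs/2 — with the
low-pass band continuing the geometric sequence; this is strictly
decreasing for every valid (Q, r).

## Feature battery

All features are computed per TQWT sub-band and on the raw window (both
togglable), giving 27 × (J+2) = 270 values per window under the defaults.
Cells where an estimator is undefined on a degenerate sub-band (for
example DFA on a 34-sample low-pass band, or an infinite sample entropy)
are imputed to 0 and counted; a row is never discarded for one bad cell.

Statistical moments use the N−1 denominator throughout, including
*non-excess* kurtosis Σ(x−x̄)⁴/((N−1)·sd⁴) and the analogous skewness —
deliberately different from scipy's N-normalised excess kurtosis, and
tested against it through the exact conversion factor. Spectral features
are the intensity-weighted mean frequency (first moment of the normalised
single-taper periodogram of the zero-mean window) and intensity-weighted
bandwidth. IWBW is reported as the weighted standard deviation (square
root applied); the un-rooted second moment is available separately.

Fractal estimators:

* **Higuchi** — curve lengths L_m(k) with the (N−1)/(⌊(N−m)/k⌋k)
  normalisation, averaged over offsets m = 1..k, slope of ln L(k) vs
  ln(1/k); default k_max = 10. Line → 1, white noise → 2 (verified as
  20-seed means).
* **Katz** — planar-curve convention on (i, x_i): L = Σ√(1+Δx²), d = max
  distance from the first point, D = log₁₀n/(log₁₀(d/L)+log₁₀n) with
  n = N−1. Exactly 1 for a uniformly sampled monotone line. Like the
  original construction it is *not* amplitude-scale invariant (the abscissa
  carries its own unit); the alternative amplitude-only convention is
  singular on alternating sequences, which decided the choice.
* **Petrosian** — D = log₁₀n/(log₁₀n + log₁₀(n/(n+0.4·N_Δ))) with N_Δ the
  sign changes of the first difference, zero differences breaking toward
  "no change".
* **DFA** — profile integration, non-overlapping segments per scale,
  per-segment linear detrending, F(n) = RMS residual, exponent = slope of
  log F vs log n; default dyadic scales 8..N/4. White noise → 0.5,
  integrated noise → 1.5, and the exponent is monotone in the Hurst index
  of fractional Gaussian noise (tested).

Entropy estimators (15): histogram Shannon (64 bins, bits), log-energy
(Σ log(x²+1e−12)), normalised spectral entropy (−ΣP log P / log #bins ∈
[0,1]), sample entropy (−log(A/B), Chebyshev distance, self-matches
excluded, N−m templates at both lengths, infinite sentinel when no
matches), permutation entropy (ordinal patterns by stable sort — ties
broken by order of appearance — bits, plus the ln(m!)-normalised form) and
its Rényi generalisation (natural log), averaged Shannon/Rényi/Tsallis
wavelet entropies over sub-band energy distributions, horizontal-
visibility-graph entropy, and the fuzzy family below. Defaults: m = 2,
n = 2, r = 0.2·sd, permutation m = 3, L = 1, Rényi/Tsallis α = 2,
fractional α = 0.5, multiscale scales 1..5.

Conventions worth flagging:

* The tolerance r is a fraction of the window standard deviation,
  converted to absolute units once per call (for the multiscale variants,
  from the original series so scales are comparable).
* Fuzzy entropy mean-subtracts each template and uses the membership
  exp(−dⁿ/r); Φ averages over N−m start positions at both template
  lengths. RCMFE averages Φ over all τ coarse-graining offsets before the
  log ratio; the σ variant coarse-grains by windowed standard deviation
  (ddof = 1, defined for τ ≥ 2 only), the μ variant by windowed mean.
* Inherent fuzzy entropy removes the slow trend by EMD (cubic-spline
  envelopes anchored at the endpoints, sifting stop SD < 0.2, ≤ 10 sifts
  per IMF, ≤ 12 IMFs; the signal is rebuilt from all IMFs minus the final
  residue) and then applies coarse-grained fuzzy entropy.
* Averaged fuzzy entropy compares templates against transformed templates
  (translation, reflection, inversion, glide reflection). Translation and
  glide use an offset of 1 sample; index reflection uses the template-index
  midpoint (a reflection "at offset 1" would leave almost no valid pairs).
  Out-of-range pairs are skipped.
* Fractional fuzzy entropy is −ρ^{−α}(ln ρ + ψ(1) − ψ(1−α))/Γ(1+α) with
  ρ = Φ^{m+1}/Φ^m; it reduces to fuzzy entropy exactly at α = 0 and may be
  negative for α > 0.
* The wavelet entropies average two series; for single-channel input these
  are the two halves of the analysis window, each decomposed at the
  deepest feasible J.
* The graph entropy is our documented interpretation of a link-weight
  entropy: horizontal visibility graph (strictly lower intermediate
  samples), W_ij = |x_i − x_j|, per-node entropy of normalised link
  weights, averaged over nodes with positive weight sum. The printed
  source formula for this feature is not recoverable, so this definition
  is asserted as the package's, not anyone else's.

Every estimator with a non-trivial implementation is checked against a
literal brute-force oracle on short inputs (≤ 1e−9), and the permutation/
fuzzy/Rényi limit identities are tested.

## Classification

Classical models: SVM with linear/RBF/polynomial kernel and KNN (k = 3, 5),
each behind a per-fold `StandardScaler` so standardisation uses training-
fold statistics only. Stratified 10-fold cross-validation with a fixed
seed; metrics are reported both pooled (one confusion matrix over all test
windows — the headline number) and per fold (mean ± sd), since either
aggregation is defensible.

The fusion network has two inputs. The raw branch takes the window's
sub-window stack (33 × 50), applies three 1-D convolutions (32 filters,
kernel 3, relu) with a size-2 max-pool after the second — shared weights
across the 33 steps — flattens each step, and feeds the step sequence to a
64-unit LSTM. The layer list places Flatten before the LSTM, which only
type-checks if the convolutions are applied per sub-window and the flatten
produces the per-step feature vector; that is the reading implemented. The
LSTM's final state is concatenated with the z-scored handcrafted vector
and classified by dense 128 → 128 → softmax (2 or 3 units). Training:
categorical cross-entropy, Adam (lr 1e−3, β₁ 0.9, β₂ 0.999), batch 32,
default 100 epochs (configurable; the test suite uses 20). The raw branch
is per-window amplitude-scaled (each window divided by its own standard
deviation).

The network is implemented directly in numpy: im2col convolutions,
argmax-cached max-pooling, full backpropagation through time, Glorot
initialisation with forget-gate bias 1, float32 by default. Analytic
gradients are verified against central finite differences (float64) in the
test suite, and training is bit-deterministic under a fixed seed.

Metrics follow the standard confusion-matrix definitions (accuracy,
sensitivity, specificity, precision, F1, all in percent); multi-class
matrices are reduced one-vs-rest and macro-averaged, accuracy is the
pooled trace ratio, and zero denominators yield 0 with a degenerate flag.

## Synthetic data

The generator is a statistical fixture, not an epilepsy simulator: it
exists so every downstream stage is testable without external recordings,
and it makes no attempt to mimic real EEG amplitude statistics, artifacts,
electrode effects, or inter-patient variability — passing tests on it
demonstrate the pipeline's mechanics and sensitivity, not clinical
performance.

Both classes share a stationary AR(2) background (resonance near 10 Hz,
pole radius 0.9, unit innovation sd) so band-pass filtering and sub-band
decomposition are non-trivial; the averaged periodogram is tested against
the theoretical AR(2) spectrum. Ictal-like segments add spike-wave bursts:
rectified 3 Hz sinusoids (the classic discharge rate) with Poisson onsets
at 30 events/min, 8 s duration, amplitude = separability × background sd.
Onsets are drawn from [−duration, n) so coverage is stationary from the
first sample; with the defaults, discharge is present through nearly all
of an ictal-like segment, mirroring the fact that ictal reference segments
are recorded during ongoing seizure activity. `separability` is the single
dial: at 0 the classes are distributionally identical (the chance-level
null), at 2 (default) the line-length and entropy features separate the
classes nearly perfectly. A three-class option adds a healthy-like class
with a 6 Hz resonance, and a Freiburg-like mode produces 4096-sample
segments at 256 Hz.

## Problem sizes and verification

The end-to-end checks use 25 segments per class (200 five-second windows),
the cheap feature subset (`FeatureConfig.fast()`: moments, spectral
moments, Higuchi/Katz/Petrosian, Shannon/log-energy/spectral/permutation
entropy — no O(N²) fuzzy family, no EMD), 10-fold CV, and 20 training
epochs for the fusion network; the chance-level null is averaged over 3
seeds on the SVM path. These sizes were chosen so a full verification run
completes in minutes on one core while leaving wide margins: measured
pooled accuracies are ≈ 98–99% for both svm_rbf and the fusion network at
separability 2, and ≈ 50% at separability 0. The full 27-feature battery
is exercised per window in the unit tests and available throughout the
API; it is simply slower (the fuzzy family is quadratic in window length).

## Known limitations

* The synthetic separability is injected by construction; no claim about
  real Bonn/Freiburg accuracy follows from these tests.
* The fuzzy-family estimators materialise (N−m)² distance matrices; for
  windows much longer than ~2000 samples a blocked implementation would be
  needed.
* EMD endpoint handling (envelopes anchored at the signal endpoints) is
  the simplest defensible choice; mirror extensions would change IMFs near
  the edges.
* The graph-entropy definition is package-specific (see above).
* `rcmfe_sigma` is undefined at scale 1 and raises rather than returning a
  placeholder.
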