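# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs.

## Signal model and the synthetic cohort

Real recordings for this protocol (14-channel 10–20 montage at 128
samples/s, a 36 s resting baseline followed by a cognitive task, 0–800
skill scores) are not publicly available, so the package ships a generator
that reproduces the *statistical structure* the analysis depends on rather
than physiological EEG morphology. Each channel is built as:

* **Background**: random-phase spectral synthesis with amplitude ∝ 1/√f
  (power ∝ 1/f) between 0.5 and 43 Hz, flattened below 1 Hz to bound slow
  drift; RMS 10 µV. The 43 Hz ceiling emulates the headset's anti-aliasing
  low-pass, which is also why all spectral analysis is truncated there.
* **Oscillations**: independent band-limited noise in θ (4–8 Hz, 6 µV RMS),
  α (8–12, 8 µV), β (12–30, 4 µV) and γ (30–43, 2 µV). During the *task*
  segment each band's amplitude is multiplied by
  `1 + effect_size × shift(class, band)`; the *baseline* segment always uses
  multiplier 1, so baseline-normalized features isolate the planted effect.
  Default signatures: focused attention shifts θ by ∓0.35 (low/high),
  working memory shifts α likewise. With the within-class amplitude jitter
  (SD 0.08, multiplicative, per channel) this separates adjacent classes by
  ≈ 4 within-class SDs at effect size 1 — "clearly different classes", the
  qualitative regime the analysis assumes. A per-subject log-normal global
  gain (log-SD 0.2) models skull/hair/contact differences; it cancels in dB
  features but not in raw power, which is the argument for baseline
  normalization in the first place.
* **Soft clipping**: the artifact-free signal is compressed with
  c·tanh(x/c), c = 2σ per channel. This guarantees by construction that no
  clean sample exceeds 3× the channel's mean |amplitude| (for a Gaussian
  profile the clipped mean |x| ≈ 0.75σ, so the 3× threshold sits at ≈ 2.25σ,
  above the 2σ ceiling), which makes the outlier rule's behaviour on clean
  vs. artifact-bearing data deterministic and testable.
* **Spikes**: Poisson-placed (default 2 per channel-minute), 1–3 samples
  wide, amplitude 4–8× the channel RMS, either sign — far above the 3×-mean
  threshold, so every spike is removable by the outlier stage. The mean
  removed fraction lands near a few tenths of a percent at default rates.
* **DC offset**: a constant (default 200 µV) added to every channel,
  representing the acquisition offset the `NoDC` variant removes.

**Scores.** The standalone score sampler uses bounded Beta families:
800·Beta(2, 5) for the positively skewed attention scores, 800·Beta(5, 2)
for the negatively skewed memory scores. Cohorts support two modes.
`balanced` (default, used by all cross-validated experiments) assigns the
three levels round-robin per skill and draws each score from a Beta(2, 2)
within its level's range — balance is what stratified 10-fold CV at n = 90
needs. `empirical` draws scores from the skewed families and derives labels
from the 200/400 thresholds, reproducing the study-population shape
(at the cost of small high-FA / low-WM cells). Note that a *balanced*
three-level design over the asymmetric ranges [0,200)/[200,400)/[400,800]
is necessarily right-skewed as a mixture, so the skew signs are a property
of the score families, not of the balanced design.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: eye-blink/EMG artifact morphology, non-stationary
drowsiness drift, channel cross-correlation from volume conduction, contact
-quality variation, and any genuine coupling between EEG dynamics and
cognition. Effect recovery here demonstrates that the *pipeline* detects
band-power class structure of realistic size under realistic noise; it
cannot validate the neuroscientific claim itself.

## Preprocessing

* **DC removal** is the one-pole leaky high-pass
  `y[n] = x[n] − x[n−1] + a·y[n−1]` with `a = exp(−2π·0.16/fs)`, putting
  the −3 dB point at 0.16 Hz. A literal first-order FIR cannot realize that
  cutoff at 128 Hz (its first null is at fs/2); the leaky-differentiator
  form is the standard headset-firmware scheme with the stated cutoff. The
  filter is linear; attenuation at 10 Hz is ≈ 0.01 %. Its time constant is
  ≈ 1 s, so the first second after filter start is trimmed before feature
  extraction; a large DC step has decayed to numerical zero within ~11 s,
  which matters only for pathological constant inputs, not for features
  computed on minute-scale windows. The filter is *not* exactly idempotent:
  a second pass re-attenuates residual sub-cutoff content and adds ~fc/f
  phase lag, an O(1 %) RMS change at 10–20 Hz.
* **Outlier rejection** drops every time point at which any channel exceeds
  k × mean |amplitude| of that channel (k = 3 default). The mean of the
  *absolute* amplitude is used — on zero-mean signals the signed mean is ≈ 0
  and would flag everything — and whole cross-channel time points are
  dropped to keep the matrix rectangular for windowed spectral analysis.
  The rule always operates on DC-removed data: with a 200 µV offset the
  threshold would otherwise sit near 600 µV and no spike would ever trip it.
  The baseline span is re-indexed to the retained samples.
* **Variants**: `raw` (identity), `nodc` (filter + 1 s trim), `nooutliers`
  (filter + trim + rejection). `nodc` is the default analysis variant.

## Features

Conventions are fixed so independent implementations agree to machine
precision: sample variance (n−1) everywhere including the Hjorth ratios;
forward differences for derivatives; Fisher excess kurtosis and adjusted
Fisher–Pearson skewness, both bias-corrected; quantiles by linear
interpolation. The Shapiro–Wilk test is applied to an evenly spaced,
deterministic subsample of at most 5000 points, the range where the W
statistic's null calibration is trustworthy. A constant channel or a
zero-mean channel (undefined coefficient of variation) is a named error,
not a NaN.

Spectral features use a Hann window of 256 samples (2 s, 0.5 Hz bins — the
smallest power of two resolving the 4 Hz θ edge cleanly) with 50 % overlap;
segment periodograms |FFT|²/N are averaged over the whole segment (the
textbook averaged-modified-periodogram PSD estimate; equivalence with
`scipy.signal.welch` is asserted in the tests to 1e-6). No Hann amplitude
correction is applied: every exported quantity is a ratio (relative power
or task/baseline) in which the window constant cancels. Band edges are
half-open [low, high) so the shared 8, 12 and 30 Hz edges are counted once;
all sums stop below 43 Hz. Per channel, five features: four relative band
powers and the total average power. Both the raw-relative and the
dB-baseline-normalized variants are computed; the exported default is the
dB set, since baseline normalization is what removes 1/f scaling and
subject-specific gain. Aggregation is one row per subject (the
segment-averaged periodogram of the full task period) because the
classification tables are subject-level.

## Selection and classification

The selector fits a one-vs-rest ℓ1- (or ℓ2-) regularized logistic
regression on standardized features (standardization is what makes
coefficients comparable across µV², dB and p-value units), ranks features
by their maximum |coefficient| across classes, and retains those at or
above the mean importance — the common default for model-based
meta-transformation selection. λ defaults to 1. Selection is fitted
*inside each training fold* by default; the leakage-prone whole-dataset
variant is available behind `leaky_selection=True` for protocol
comparison only.

The zoo's eleven rows keep their printed hyperparameters (200 trees,
K = 15, 40+40 logistic network with α = 0.001, 271/180/280 logistic
network with η = 0.002, β₁ = 0.9, β₂ = 0.999, ℓ1 logistic regression with
C = 1, …). Two adaptations were required:

* **Linear SVC** uses the joint multiclass hinge (Crammer–Singer). With an
  *ordered* three-level target whose discriminative signal is concentrated
  along one spectral direction, the middle class is not linearly separable
  from the union of the outer two, and one-vs-rest linear SVMs
  systematically lose it (observed: outer classes ≈ 87 % correct, moderate
  ≈ 40 %). The joint formulation partitions the discriminant axis into
  intervals and recovers it. It remains a linear, ℓ2-penalized SVC.
* **The dropout network** is realized with scikit-learn's MLP (no dropout
  layer exists there); the 271/180/280 logistic architecture and the
  Adam-family optimizer settings are kept, and the regularizing role of
  dropout is played by the ℓ2 term (α = 0.01). Early stopping was rejected:
  with 90-subject folds its validation split contains ~5 subjects and it
  aborts training essentially at random.

Grid search (the comparison protocol's tuning method) wraps only the
classifier step — the selector does not depend on classifier
hyperparameters, so it is fitted once per outer fold — with small
documented grids; the linear SVC's grid spans C = 1e-3…1 in half-decade
steps with inner 5-fold CV. Folds are stratified, shuffled with the run
seed, and shared across classifiers so comparisons are paired. All seeds
(folds, network initialization, under-sampling) are explicit.

A random-under-sampling AdaBoost variant (all classes cut to the minority
size before boosting) is provided for skewed targets but is not part of
the default eleven-row zoo.

## Experiment sizes and degenerate inputs

Cross-validated experiments use 90-subject balanced cohorts with 60 s task
+ 36 s baseline per subject — enough for ~58 half-overlapping STFT windows
per task segment, which puts the band-power estimation error well below the
planted between-class separation, while keeping a full multi-seed sweep in
the minutes range on one core. Degenerate inputs raise typed errors with
the offending channel/column named: constant channels, zero-variance first
differences (ramp: mobility is 0, complexity undefined), all-zero spectra,
zero/negative baseline power, penalties that zero every coefficient,
classes smaller than the fold count, and sampling-rate or montage
mismatches on file input (no silent resampling).

## Known limitations

The generator's independence assumptions (channels, bands) make the
feature covariance simpler than real EEG's; classifier rankings observed on
synthetic cohorts should not be read as predictions of rankings on real
data. The dB features assume a stationary baseline; a contaminated baseline
propagates into every spectral feature of that subject. EDF files are
read (via `mne`) but not written; the delimited dialect is the native
interchange format.
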