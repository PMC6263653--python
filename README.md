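# eegskill

Classify three levels (low / moderate / high) of two cognitive skills —
**focused attention (FA)** and **working memory (WM)** — from 14-channel,
128 Hz consumer-headset EEG. The package implements the complete analysis
chain for researchers in educational neuroscience and cognitive-state
monitoring who want a tested, reproducible reference pipeline:

1. **Preprocessing** — DC-offset removal with a first-order high-pass
   (−3 dB at 0.16 Hz), rejection of time points whose amplitude exceeds
   3× the channel's mean |amplitude|, and segmentation into a 36 s resting
   baseline and the task period. Three data variants are produced:
   `raw`, `NoDC`, `NoOutliers`.
2. **Feature extraction** — 280 features per subject:
   - 15 time-domain statistics × 14 channels = **210**: min, max, mean,
     variance, σ, coefficient of variation, excess kurtosis, skewness,
     quartiles, the Shapiro–Wilk W and p, and the Hjorth parameters
     mobility = √(var(Δx)/var(x)) and complexity = mobility(Δx)/mobility(x);
   - 5 spectral features × 14 channels = **70**: relative power of
     θ (4–8 Hz), α (8–12 Hz), β (12–30 Hz), γ (30 Hz up, clipped at the
     43 Hz analysis ceiling) plus the total average power, each reported as
     the decibel change of the task segment relative to the resting
     baseline, 10·log₁₀(P_task/P_baseline), from a Hann-windowed STFT
     (256-sample windows, 50 % overlap) and averaged periodograms
     per(ω) = |FFT(ω)|²/N.
3. **Feature selection** — a regularized multiclass logistic regression
   (objective: cross-entropy + λ‖ω‖₁ or ‖ω‖₂) is fitted to standardized
   features inside each training fold; features whose largest absolute
   coefficient across classes reaches the mean importance are retained.
4. **Classification** — stratified 10-fold cross-validation of an
   11-classifier zoo (linear SVC, RBF SVC, random forest with 200 trees,
   KNN with K = 15, two neural networks, decision tree, Gaussian process,
   Gaussian naive Bayes, ℓ1 logistic regression, AdaBoost) on shared folds,
   with optional inner grid search per classifier.

Because no public corpus with this exact montage/protocol is available, the
package ships a first-class **synthetic cohort generator**: 1/f background
EEG band-limited below 43 Hz, class-dependent band-limited oscillations
(attention planted in θ, memory in α), acquisition DC offset, spike
artifacts calibrated to trip the 3×-mean outlier rule, and 0–800 cognitive
scores with the observed skew signs (FA positively, WM negatively skewed).
Every downstream claim is tested as *planted-effect recovery* on this
generator.

## Worked example

```bash
python examples/simulate_cohort.py
```

prints the cohort's scores and the planted spectral signal:

```
subject  FA score  FA level   WM score  WM level
S000      253.1  moderate      340.8  moderate
S001      316.2  moderate      696.2  high
S002      530.7  high          299.9  moderate
...

mean task-vs-baseline theta power by FA level (dB):
  low        -1.86 dB
  moderate   -0.03 dB
  high       +1.66 dB
```

Scores below 200 encode `low`, 200–399 `moderate`, 400+ `high`. The dB
values are the task segment's θ-band power relative to the resting
baseline: subjects planted as low-attention show ~1.9 dB *less* θ power
during the task, high-attention ~1.7 dB more — exactly the kind of
baseline-normalized band-power shift the classifiers must detect.
The other examples (`preprocess_and_features.py`, `spectral_analysis.py`,
`compare_classifiers.py`) walk through the preprocessing variants, the
spectral reference values (a 10 Hz tone yields α relative power 1.0000; a
3× task/baseline power ratio reads 4.7712 dB) and a small classifier
comparison table.

The same chain is scriptable from the shell:

```bash
eegskill run --simulate --subjects 90 --effect-size 1 --seed 1 --out run1
eegskill simulate --subjects 10 --out cohort/      # write recordings as CSV
eegskill classify --features-file run1/features.csv --scores-file run1/scores.csv --skill fa
```

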