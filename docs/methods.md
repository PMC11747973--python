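# Methods

## Model

The encoding model is the standard forward TRF: the EEG at channel c is a
lagged linear readout of one or more stimulus features,
`r(t,c) = Σ_τ w(τ,c) s(t−τ) + ε(t,c)`. The lagged design matrix holds each
feature at every integer sample lag from `round(tmin·fs/1000)` to
`round(tmax·fs/1000)` inclusive (default −100…500 ms at 100 Hz → 61 lags;
sign convention: positive τ means the stimulus precedes the response, column
(f, τ) holds `s_f(t − τ)`). Rows shifted past the data are zero-filled, so
the design is causal with respect to the padding and an adjoint identity
⟨Sx, y⟩ = ⟨x, Sᵀy⟩ holds exactly — this is what makes the explainable-sample
mask (below) coincide with the design's support.

Weights solve `w = (SᵀS + λI)⁻¹ Sᵀr` per channel. The penalty is a plain
λI on all lag columns with no intercept (the EEG is z-scored per segment,
and Pearson correlation — the scoring metric — is offset-invariant anyway).
λ is **not** rescaled by design variance; the search grid is wide enough to
absorb feature-scale differences. The grid is the nine log-spaced values
10⁻⁴…10⁴ (multiplicative steps of 10).

## Evaluation protocol

The recording is split into contiguous near-equal segments (6 by default;
10 for the nested comparisons). EEG is z-scored per channel within each
segment so segments are comparable. Each segment serves as the held-out
test set once; on the remaining segments an inner leave-one-segment-out
search selects λ (ties toward smaller λ), the model is refit on all
training segments, and the mean channel correlation on the test segment is
recorded. Per-segment designs are built independently (zero-padded at
segment edges) so the normal equations of any training set are sums of
cached per-segment cross-products; this makes the inner λ search and the
100-permutation noise floors cheap.

Statistics operate on channel-averaged scores: fold-score distributions are
compared with the two-sided Wilcoxon signed-rank test (zero differences
dropped; exact enumeration below 10 nonzero pairs without ties, otherwise a
tie-corrected normal approximation; W reported as the smaller rank sum) and
corrected with Benjamini–Hochberg FDR. The chance level is an onset-shuffle
noise floor: the inter-onset-interval multiset is permuted and the train
re-anchored uniformly in the feasible slack, the full fit/predict protocol
is re-run per permutation (100 by default), and the 2.5/97.5 percentiles of
the null fold-mean scores form the 95% CI. TRF weight differences between
conditions are tested with a cluster-based permutation test restricted to
the lag axis (paired t per lag, sign-consistent contiguous supra-threshold
clusters scored by summed t, null via random condition flips within unit;
cluster-forming α = 0.05, 1000 permutations). Spatial (channel-neighborhood)
clustering is deliberately out of scope.

## Variance partitioning

Correlations convert to explained variance as the signed square
R² = sign(r)·r², so an anti-correlated prediction cannot masquerade as
explained variance. Two-set decomposition: shared = A + B − A∪B, uniques
A∪B − B and A∪B − A. Three-set: the triple intersection is
A∪B∪C + A + B + C − A∪B − B∪C − A∪C, pairwise intersections A + B − A∪B
(etc.), uniques by inclusion–exclusion. Reconstruction of any union from
the partition terms is exact to floating-point round-off, and this is
enforced in tests at 1e−12.

Because the R² inputs are estimates, raw partition terms can go negative.
The bias correction is formalized as the smallest-magnitude uniform
adjustment b subtracted from every union-model R² such that all partition
terms are ≥ 0; b = 0 whenever the raw partition is already nonnegative. In
the two-set case b may be negative (the joint model *underfit*, so credit is
returned to the union) — the b ≥ 0 subtraction alone cannot repair a
negative unique term. In the three-set case uniques are invariant under
uniform union subtraction (each pairwise intersection gains +b, the triple
+2b, and the signs cancel), so a genuinely negative unique is reported as
an infeasibility naming the binding constraint rather than silently
patched.

## Features

- **Energy novelty / acoustic onsets.** Squared waveform → Hann smoothing
  (window 2048, hop 128 audio samples) → log(1 + γx) with γ = 10 → first
  difference → Hann smoothing at one-quarter window length (one smoothing
  family, fewer knobs) → half-wave rectification → polyphase resampling to
  the EEG rate. Onsets are the local maxima of this curve above a threshold
  (plateaus resolve to their first sample), emitted as a binary vector. The
  threshold is irreducibly arbitrary; the default (0.05) is calibrated on
  the synthetic tone bank to recover ≥ 95% of true event onsets within
  ±50 ms, and lives in `FeatureConfig`, not in code.
- **Hilbert envelope.** |analytic signal| → zero-phase 3rd-order Butterworth
  low-pass at 30 Hz → resample to the EEG rate.
- **Power envelope.** x² → non-overlapping moving-average resampling (window
  = rate ratio) → pointwise compression with exponent log10(2) ≈ 0.301. The
  textual description of this compression is ambiguous ("square root …
  parameter of log10 2"); it is implemented as the pointwise exponent,
  which is close to a square root, and isolated behind config.
- **Mel-spectrogram.** 25 ms Hann windows hopped at the EEG rate, power
  spectra through a 40-filter triangular mel bank (HTK mel scale,
  0…Nyquist), trimmed/padded to the EEG length. The filterbank is
  implemented in-package (a small, fully specified primitive).
- **SI markers / condition splits.** One binary column per category (or per
  category × condition), a single 1 at `round(onset·fs)`; collisions at the
  sample resolution are an error rather than a silent merge.
- **Combination.** Columns are concatenated; non-binary columns are min–max
  scaled to [0, 1] (a constant column maps to zeros); binary columns pass
  through untouched, so mixed models share a common scale.

Stereo audio is converted to mono by channel average before any feature.

## Synthetic data generator

The generator emulates the study conditions the analyses target:

- **Event trains**: n events with a minimum gap (default 0.6 s), placed by
  stick-breaking so gaps are guaranteed by construction and every
  admissible configuration has positive density; categories and
  narrow/wide condition labels assigned per requested proportions.
  Defaults for the simulation: 396 events in 600 s.
- **Soundscape**: per-category tones (800 Hz / 60 ms beep, 200 ms two-tone
  monitor sound, 200 ms FM alarm), each RMS-normalized to the bank-average
  RMS before placement; overlaps sum; silence is exactly zero.
- **ERP kernel**: triphasic P1–N1–P2 as the sum of three Gaussian bumps
  (defaults: latencies 50/100/200 ms, amplitudes +1/−2/+1, width 15 ms,
  span 0.5 s, forced to zero at both ends). The true component waveform is
  not constrained by anything beyond "triphasic", so amplitudes and widths
  are declared defaults, not inferences.
- **Pink noise**: white Gaussian noise shaped to amplitude ∝ f^(−1/2) (DC
  zeroed), variance-normalized per channel; log-log spectral slope within
  [−1.2, −0.8] over 1–40 Hz.
- **EEG**: the kernel placed at every onset (identical response per trial
  and channel, as the simulation assumes; optional per-trial amplitude
  jitter is off by default) plus pink noise scaled to a target single-trial
  SNR.

**SNR targeting.** The single-trial SNR convention is
`20·log10(mean|x_response| / sd(x_baseline))` with response window 0…0.5 s
and baseline −0.1…−0.01 s. The noise gain realizes the target as an
amplitude ratio: σ = mean|kernel| · 10^(−snr/20), which is strictly
monotone in the target and keeps sweeps ordered. Re-reading the realized
SNR with the estimator is biased upward on 1/f noise — the 10-sample
baseline underestimates the sd of a process whose variance sits at low
frequencies, and the slow drift inflates mean|x_response| — and saturates
near +4 dB on pure pink noise at these window lengths. The estimator is
therefore a read-out with a known bias, not the definition of the noise
gain; `estimate_trial_snr` also exposes a 10·log10 option.

What the generator does **not** emulate: trial-to-trial response
variability (by default), eye/muscle artifacts, channel-specific
topographies, drift, or realistic head geometry. Passing tests therefore
show protocol correctness and recoverability under the stated model, not
robustness to real-data nuisance structure.

## Masked (explainable-sample) evaluation

A discrete-feature model predicts exactly zero outside the design's
support. Sample t is *explainable* iff some event e satisfies
t ∈ [e + lag_min, e + lag_max] — the union over events and discrete
columns, using the full lag window including the acausal −100 ms portion
(the design has support there, so the mask is the exact support set). Any
continuous column makes every sample explainable. Masked scores correlate
prediction and EEG over mask-true samples concatenated within each test
segment (no per-event averaging), averaged across folds afterwards;
whole-segment and masked scoring differ only in the mask.

## Simulation (correlation vs SNR)

For each SNR on the −30…10 dB grid (5 dB steps) and each of 10 replicates
(5 in the acceptance run): place 396 events in 600 s, synthesize 22-channel
EEG at 100 Hz, run the standard 6-segment protocol on the true-onset
feature, and record whole-segment and masked fold-mean correlations. Both
curves rise monotonically with SNR and the masked curve dominates the whole
curve at every SNR, quantifying the dilution of whole-segment scores for
sparse discrete features. At the −30 dB end both scores are small (~0.03
and ~0.05) but remain above the onset-shuffle noise floor: with 396
averaged trials, an amplitude ratio of 1/31.6 still leaves a detectable
regression signal at this recording length. Reaching the shuffle floor
would require roughly 8× weaker signal than the 20·log10 amplitude
convention assigns to −30 dB.

## Numerical and design choices

- Ridge solves use a symmetric positive-definite solver; a singular SᵀS at
  λ = 0 is an error advising λ > 0, not a pseudo-inverse fallback.
- Correlations over < 3 samples or zero-variance inputs are NaN, flagged
  and excluded from averages (nanmean), never silently zero.
- λ ties break toward the smaller value (first argmax on an ascending
  grid).
- Cross-prediction requires single-column features (weight matrices must
  be dimensionally consistent to swap); the mel-spectrogram is excluded
  for that reason. The within/cross score association is Spearman's ρ
  (rank-based, robust to scale differences between features); Pearson is
  available via config. Latency-shift estimation cross-correlates
  channel-RMS lag profiles and applies one global shift per feature pair.
- Permutation p-values are plain proportions of null maxima ≥ the observed
  statistic, so they live on the k/n_perm grid.
- Pipeline outputs are stamped with a hash of the semantically meaningful
  config fields; all randomness funnels through per-stage seeds.

## Problem sizes

Module tests run on 1–2 minute recordings with 4–8 channels and a reduced
λ grid; the acceptance checks use the full study-scale conditions (600 s,
396 events, 22 channels, 9-value λ grid, 5 sweep replicates, 100 noise-floor
permutations), chosen to keep a complete run in the minutes range on one
CPU.

## Known limitations

- The bias correction is one of several defensible formalizations of the
  nonnegativity constraint (per-term corrections are an alternative); only
  the constraint itself is guaranteed.
- Selected λ values are protocol-internal and not comparable to toolboxes
  that rescale λ by design variance.
- The onset detector's threshold trades recall against spurious detections;
  the calibrated default is specific to the synthetic tone bank's loudness
  statistics.
- The cluster permutation test ignores channel topology by design.
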