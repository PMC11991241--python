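# Methods

This note documents the models, parameter choices and numerical
conventions behind `engageeg`, and what the synthetic benchmarks do and
do not demonstrate.

## Game-difficulty calibration

The Performance Index combines three per-level in-game counts after
min–max normalisation across the player's ten levels:
PI = a_tc·TC′ − a_tm·TM′ − a_oh·OH′. Collected rings reward performance;
misses and obstacle hits penalise it (the worked-example datasheet is
numerically consistent only under this sign convention, which we
therefore adopt). Two weight modes exist:

* `paper-rounded-4dp` (default): the adjusted weights are the published
  4-decimal constants 0.4167 / 0.4167 / 0.1666. Note 2/12 was
  *truncated*, not rounded, in the original datasheet — uniform rounding
  gives 0.1667 and shifts PI values by ~1e-5 — so the constants are
  stored explicitly rather than derived.
* `exact-fraction`: weights 5/12, 5/12, 2/12. Invariant under scaling of
  the raw weights; preferred for principled use, but it does not
  reproduce the published datasheet bit-for-bit.

Degenerate min–max ranges (a metric constant across levels) normalise to
0 rather than NaN, so one flat metric cannot poison the index; a table
where *all three* metrics are flat raises a degenerate-calibration
error. Ties in %PI′ resolve to the lowest level (the most conservative
difficulty). The hard level is optimal + 4, capped at the top level with
a warning — the capping rule is this package's choice, flagged in the
output, since optimal levels ≥ 7 leave no room for +4.

## Flow-scale labeling

Rated score = Σ(14 items)/14 ∈ [0, 7]. Labels: high if ≥ 4.5, low
otherwise, except that scores inside the neutral band (default
[3.75, 4.25], configurable, centred on the scale's "undecided" midpoint
4) yield *neutral*. The band reconciles the binary ≥4.5 threshold with
the exclusion of undecided respondents from classification: neutral
sessions are dropped from the feature table (logged), and a subject is
excluded from within-subject classification when their remaining
sessions do not contain both a high and a low label — binary
classification is undefined otherwise. Exclusion is per-participant by
default; a per-session mode keeps subjects with any usable session for
pooled analyses.

## EEG preprocessing

* Band-pass: 4th-order Butterworth, 0.5–45 Hz, applied
  forwards–backwards (`sosfiltfilt`) — zero phase, magnitude response of
  an 8th-order filter. At 128 Hz sampling the 60 Hz line lies near
  Nyquist, where bilinear pre-warping makes the stop-band attenuation
  > 30 dB. Zero-phase filtering keeps band-power epochs aligned with
  gameplay time; the alternative (causal, group-delayed) filtering has
  no advantage offline.
* ICA (optional, off by default in tests, available in the pipeline):
  extended infomax — the extension is required because oscillatory and
  line components are sub-Gaussian and plain infomax fails to isolate
  them. Components whose 20–45 Hz / 0.5–20 Hz Welch power ratio exceeds
  a threshold (default 1.0) are flagged as muscle; flagged plus manually
  listed components are zeroed before reconstruction. The per-component
  ratios and exclusions are reported, never silent. ICA runs per
  session. Rank-deficient data (duplicated or silent channels) raises a
  decomposition error rather than returning an ill-posed unmixing.
* Epoching: contiguous, non-overlapping 1-s windows; epoch *k* covers
  samples [k·128, (k+1)·128). Trailing remainders are dropped and
  logged. No amplitude-based epoch rejection is applied.

## Spectral features

Per epoch and channel, the PSD is estimated with DPSS multitapers.
The time–bandwidth product defaults to **NW = 2** (3 tapers, low-bias
selection, no adaptive weighting): on a 1-s, 128-sample epoch this
concentrates a spectral line within ±2 Hz, so a mid-alpha oscillation
stays inside the 5-Hz-wide alpha band. NW = 4 would halve the estimator
variance but smears ±4 Hz — wider than the theta band itself — and
misattributes alpha power to its neighbours. NW is configurable and
recorded in the feature-table metadata sidecar so runs are comparable.

Band powers integrate the PSD by the trapezoid rule over the band
interval with interpolated edge values; bands sharing an edge therefore
partition the spectrum exactly (θ+α+β+rest = total). Band membership
elsewhere (labels, simulation) follows the half-open convention
[lo, hi), making 8 Hz alpha and 13 Hz beta unambiguous.

Engagement indices: E₁ = P_β/(P_θ+P_α), E₂ = P_β/P_α, E₃ = 1/P_α, with
denominators floored at 1e-12 µV² (degenerate epochs produce finite,
flagged values instead of infinities). E₁/E₂ are invariant to overall
signal scale; E₃ scales inversely with squared amplitude, which is why
it tracks alpha suppression under load.

The feature table emits per-channel features for classification
(3 indices × 14 channels = 42 columns for the combined set) and
channel-mean features for the group statistics — classification
benefits from spatial information, whereas the condition comparison is
defined on the channel-averaged indices.

## Signal quality

SNR per channel = 10·log₁₀(signal/noise), signal = θ+α+β band power of
the Welch-averaged trial spectrum, noise = 30–45 Hz power plus a ±1 Hz
window around 60 Hz. The SNR is computed on the **unfiltered**
recording: after the 45 Hz low-pass the line and most muscle content are
gone and the ratio would no longer measure acquisition quality. Only the
60 Hz line is included by default (North-American mains). Channel SNRs
are averaged (in dB) over the easy/optimal/hard sessions; subject
average is the arithmetic channel mean. Flags: ≤ 0 dB bad, < 3 dB
marginal, > 10 dB excellent. Zero-noise channels are capped at 60 dB
and flagged.

## Statistics

The group comparison is a tie-corrected Friedman test (ties are the norm
for Likert-derived scores) with p from the χ²(k−1) reference
distribution, followed by SPSS-style Dunn comparisons of mean ranks,
z = (R̄ᵢ−R̄ⱼ)/√(k(k+1)/(6n)), two-sided normal p multiplied by the number
of pairs (capped at 1). Shapiro–Wilk screening is reported but the
pipeline proceeds nonparametrically regardless; α = 0.05 throughout.
The χ² approximation is accurate in the rejection-relevant region even
at n = 5–6 (verified against full permutation enumeration in the test
suite); mid-distribution p-values at such small n can deviate by > 0.1,
which affects no decision at conventional α.

## Classification design

* Stratified 80/20 split; the holdout provides the reported metrics.
* Hyperparameter search (grids: RF n_estimators {100,200,300},
  max_depth {None,10,20,30}, min_samples_split {2,5,10},
  min_samples_leaf {1,2,4}, bootstrap {True,False}; SVM C
  {0.1,1,10,100}, gamma {scale,auto}, kernel {rbf,linear}) runs only on
  the training 80%: 10-fold for single-index within-subject models,
  5-fold for combined/cross-subject, or nested outer-5/inner-3 for
  combined within-subject models. The nested outer folds additionally
  yield a CV-mean F1 reported next to the holdout metrics, since either
  could be regarded as the primary estimate.
* Scaling (StandardScaler) lives inside the scikit-learn Pipeline, so it
  is refit on every training fold — no information from validation or
  test rows reaches the scaler or the search. Zero-variance columns are
  flagged and passed through unchanged.
* Tuning optimises F1 with *high* as the positive class (recorded in the
  report metadata); the classes are imbalanced by design (2:1), so
  accuracy alone is misleading and both are reported with the confusion
  matrix.
* Cross-subject default pools all epochs before splitting. This mirrors
  the study design but lets one subject contribute epochs to both
  partitions; the report carries an explicit validity caveat, and a
  leave-one-subject-out mode measures true subject transfer.

## Synthetic data

The generator reproduces the *statistical structure* the analysis
assumes, not biophysics:

* EEG = Σ bands amplitude-modulated sinusoids at band centres (θ 6 Hz,
  α 10.5 Hz, β 21.5 Hz; modulation depth 0.5 at 0.1–0.3 Hz, random
  phases per channel) + 1/f background (spectral shaping of white noise,
  exponent 1, SD 8 µV) + optional 60 Hz line (2 µV) and 0.3-s
  30–44 Hz muscle bursts (2/min, 5 µV). An amplitude-A oscillator
  contributes A²/2·(1+depth²/2) µV² of band power.
* Class effect: high engagement uses amplitudes θ 3 / α 3.5 / β 7 µV,
  low engagement θ 3 / α 8 / β 2.5 µV — more beta and less alpha when
  engaged, the direction established for mental activation. No effect
  sizes are published for this paradigm, so these are tuning knobs
  chosen once to yield clearly separable classes at realistic SNR
  (subject-average SQI lands at 4–10 dB, inside the range reported for
  consumer saline-electrode headsets); they are explicitly *not*
  empirical claims.
* Older-adult subjects get a global 0.7 amplitude attenuation plus a
  3 µV white-noise floor — a phenomenological stand-in for the poorer
  effective SNR of aged recordings that lets age-group comparisons run,
  without claiming a physiological model.
* Game metrics: collected rings grow concavely and saturate at the
  configured peak level; misses and hits stay flat until the peak and
  grow after it. Under min–max normalisation this provably places the
  PI maximum exactly at the configured level for every peak 1–10 in the
  noise-free default; optional count noise is followed by a running
  maximum to preserve monotonicity.
* Flow responses: items ~ round(N(μ_session + subject offset, 1)),
  clipped to 0–7, with session means easy 4.9 / optimal 5.5 / hard 4.6
  (the reported cohort means for this paradigm) and subject SD 0.6 —
  enough spread that some subjects lack a class and are excluded,
  reproducing the retained-subject mechanics and the 2:1 imbalance.
* Determinism: every draw derives from `SeedSequence(seed, subject,
  substream, session)`; identical configs are bit-identical and adding a
  generator never perturbs another's stream.

**What passing means.** The synthetic benchmark shows the pipeline
recovers engineered class structure without leakage and at the correct
chance level under the null — it says nothing about effect sizes,
artifact profiles, non-stationarity or inter-subject variability of real
EEG, where performance will be lower.

## Problem sizes and numerical choices

Tests run on reduced cohorts (3–6 subjects, 20–40 s trials) with the
default effect sizes; the class-recovery checks use a 6-subject cohort
within-subject and pooled, the feature-set comparison 3 subjects × 10
seeds, and the Friedman calibration 1000 null replicates at n = 27. The
design-arithmetic checks (120 epochs/trial, 5760 feature rows) run at
the full 16-subject, 2-minute scale. Tolerances: worked-example PI to
1e-5 and %PI′ to 1e-3; sinusoid band power to 10%; Parseval to 5%
(deterministic signals and epoch-averaged estimates — single-epoch
multitaper integrals fluctuate by ~1/√(tapers·bins)); SNR oracles to
0.5 dB.

## Known limitations

* EDF can be read (via mne) but not written; CSV is the interchange
  format.
* The Performance Index is specific to the stunt-plane game's metric
  set; no attempt is made to generalise it.
* Gamma-band indices are deliberately out of scope.
* The ICA muscle-flagging threshold (power ratio 1.0) is an
  operationalisation chosen here; it is reported in every ICA report and
  should be revisited for real recordings.
* Cross-subject "pooled" results overstate deployment performance for
  unseen users; use the leave-one-subject-out mode for that question.
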