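# Methods

This note documents the models, parameter choices and numerical
conventions behind `stressreport`, and what the bundled simulator does
and does not emulate.

## Signal simulator

The simulator produces six-channel recordings under an ordered schedule
of three conditions — baseline, amusement, stress — with instantaneous
transitions (no physiological carry-over), so window labels are
unambiguous. Default sampling rates are 256 Hz for the chest channels
(ECG, EMG, EDA, respiration) and 4 Hz for the wrist channels (EDA,
temperature), mirroring chest-strap vs wristband hardware. The default
cohort protocol is 20 min baseline, 6.5 min amusement, 10 min stress.

**Channel models.**

* *ECG* — a train of stylised 80 ms biphasic QRS pulses (40 ms triangular
  R wave of 1 mV, then a shallow negative lobe). Beat-to-beat intervals
  are Gaussian with mean 60000/HR ms and standard deviation SDNN ms for
  the active condition. Only R-peak timing matters downstream, so no
  P/T-wave morphology is attempted.
* *EDA* (both sites) — a tonic conductance level plus Poisson-timed
  phasic responses with a 1 s linear rise and exponential decay
  (τ = 4 s, amplitude ≈ 0.3 µS chest / 0.15 µS wrist, truncated at 8τ).
  The wrist site runs at 0.3× the chest tonic level.
* *EMG* — zero-mean Gaussian noise at the condition's RMS amplitude.
* *Respiration* — a continuous-phase unit sinusoid at the condition's
  rate.
* *Temperature* — the condition level plus the slow wander described
  below.

**Condition physiology.** Centres follow experimentally reported stress
effects: heart rate 78.45 bpm (baseline/amusement) vs 95.54 bpm
(stress); SDNN 28.28 vs 21.21 ms, chosen so that with independent
Gaussian beat intervals RMSSD = √2·SDNN lands on the reported ≈40 ms vs
≈30 ms and pNN50 near its reported ≈23% vs ≈7%; chest tonic EDA 3.7 vs
10.7 µS with 2 vs 8 phasic responses/min; trapezius EMG RMS 0.02 vs
0.06 mV; respiration 14 vs 19 breaths/min; wrist temperature 34.9 vs
31.7 °C. Amusement is modelled at baseline levels: the source protocol
describes it only as watching funny videos, and no quantitative
amusement physiology is reported, so the neutral choice is no shift.

**Within-subject wander.** Each parameter is additionally modulated by a
slow zero-mean sinusoid (e.g. heart rate ±4 bpm with a 311 s period,
tonic EDA ±20%, temperature ±0.7 °C; full table in
`synthetic.MODULATION`, with per-subject random phases). This emulates
the tonic drift real physiology shows across a 35-minute session and has
two structural consequences: window-level feature values spread
realistically around the condition centres (so no single feature
separates the classes perfectly and the forest must consult many
features), while segment means stay on the centres because the
modulation integrates to ≈0 over a segment (so parameter-recovery checks
remain meaningful). Periods are deliberately incommensurate with the
90 s window and with each other. Depths live on `SubjectParams`; setting
them to zero yields the stationary model (used by the degenerate
"metronome" tests).

**Between-subject variation.** A single Gaussian subject-level offset
per parameter, applied to all conditions (so every subject keeps the
population effect direction), with standard deviations of roughly half
the within-subject wander (heart rate ±1.5 bpm, temperature ±0.25 °C,
…). This is deliberately smaller than the population spreads printed in
stress-range tables, which fold in protocol and sensor variation the
simulator does not model; keeping between-subject spread below the
within-subject spread is what lets a reference interval learned on one
subject group retain close-to-nominal coverage on new subjects.

**What the simulator does not emulate** — motion artifacts and sensor
dropout, realistic ECG morphology, respiratory sinus arrhythmia and
other structured HRV rhythms (beat intervals are independent draws, so
LF/HF power is broadband rather than peaked), EDA non-negativity
constraints under extreme noise, accelerometry, and circadian trends.
Tests passing on this generator therefore demonstrate correctness of the
pipeline's statistics and algorithms under known ground truth, not
field performance on real wearable data.

## Windows and features

Windows are 90 s with a 30 s stride by default, placed maximally inside
each condition interval; a window's label is 1 iff its condition is
stress (baseline and amusement are no-stress). The 42 features, their
canonical order and units are frozen in `registry.py`.

Numerical conventions, chosen once and used everywhere:

* R-peaks: amplitude threshold at half the maximum of the
  median-centred signal with a 200 ms refractory distance. Adequate for
  wearable-grade signals where the R deflection dominates; a flat signal
  yields no peaks.
* NN artifact rejection: drop intervals outside [300, 2000] ms or
  differing by more than 25% from the previously accepted interval. The
  source work only states that faulty data were eliminated; this
  concrete rule is this package's choice.
* pNN20/pNN50 are percentages (0–100) of successive differences
  strictly exceeding the threshold: the published no-stress pNN50 of
  22.89 ± 19.44 is only consistent with a percentage reading.
* Frequency-domain HRV: the beat-interval series is linearly resampled
  to a uniform 4 Hz grid and Welch's method (segments ≤ 256 samples,
  constant detrend) is integrated over LF = [0.04, 0.15) Hz and
  HF = [0.15, 0.40) Hz, in ms². Published tables print LF/HF magnitudes
  around 10¹¹–10¹², irreconcilable with ms² conventions; the unit used
  there is unknown and this package keeps ms².
* EMG "normalized RMS" is RMS after mean removal; RMS50P/RMS90P are the
  50th/90th percentiles of rank-ordered RMS values over non-overlapping
  1 s sub-windows; the peak count threshold is mean + 2 sd.
* Chest EDA tonic level (SCL) is a 2nd-order Butterworth low-pass at
  0.05 Hz applied forward-backward; SCR is the residual.
* Respiration is band-passed to 0.1–0.5 Hz before breath-peak detection
  (minimum 1 s spacing, prominence half the filtered sd).
* All quantiles (RMS percentiles, reference intervals) use linear
  interpolation between order statistics.

## Classifier

Balanced random forest: per tree, a bootstrap of n rows is drawn with
replacement, the bootstrap's majority class is randomly under-sampled to
its minority count, and a CART tree is fit to the balanced sample.
Probability is the fraction of trees voting stress (majority-vote
semantics, not leaf-probability averaging). Hyper-parameters are chosen
by mean subject-grouped validation F1 on the stress class over a grid
(default: 100/300 trees × depth 4/8/∞ × min leaf 1/5); evaluation is
grouped k-fold (default 4) or leave-one-subject-out. The fixed
90/10/10 split described alongside those schemes in the source material
is internally inconsistent (it sums to 110%) and is not implemented.

Two configurations matter:

* *Discriminative* (default for `fit_balanced_rf`): √M candidate
  features per split.
* *Attribution coverage* (default for the pipeline and the cohort
  studies): 300 trees, depth ≤ 8, min leaf 5, **one** random candidate
  feature per split. With 42 strongly correlated physiological features,
  greedy √M-trees satisfy themselves with a small sufficient subset and
  the remaining features never appear on any path — leaving them with
  zero Shapley mass and no derivable interval. Single-feature candidate
  splits (random-subspace style) spread splits over all informative
  features at negligible cost in ensemble accuracy, which is what a
  per-feature explanation report requires.

## Shapley attribution and IMPACT

Feature removal uses the interventional (marginal) convention: for a
coalition S, features outside S take their values from a background row,
and f_S(x) is averaged over a seeded background sample (default 100
training rows). This makes the additive identity
`P_X = base + Σφᵢ` hold exactly for tree ensembles, with `base` the
background-mean model output. Note `base` is a property of the model and
background — it is reported separately from the label prevalence
Mean(y_train), which is the "average probability of stress" in the
historical-data sense; conflating the two would break the identity.

The fast route walks each tree's leaves once. For background row z and
instance x, a leaf's path features split into A (only x inside the
leaf's box), B (only z inside), both-inside (unconstrained) and
neither-inside (leaf unreachable, contributes nothing). The Shapley
value of the induced 0/1 coalition game is closed-form:
φᵢ = (a−1)!·b!/(a+b)! for i ∈ A and −a!·(b−1)!/(a+b)! for i ∈ B with
a = |A|, b = |B|. Summing leaf values with these coefficients and
averaging over the background gives exact interventional Shapley values
in O(T·L·D) per background row — verified to < 1e-8 against brute-force
enumeration of all 2^M coalitions (the enumeration oracle refuses
M > 15). The batch implementation vectorises the per-leaf counts as
matrix products over (instances × background), so explaining ~1300
windows against 100 background rows takes a few seconds.

IMPACT is the signed share `100·φᵢ/Σ|φⱼ|`; absolute impacts total 100%
unless every φ is zero, which is flagged as a degenerate explanation
(rendered with neutral impacts) rather than raised.

## Reference intervals

Per feature, training observations route by sign of φ: positive to the
Stress Group, negative to the No-Stress Group, exactly zero excluded
from both. A two-sided Welch (unequal-variance) t-test validates the
separation; two identical constant groups return p = 1 with a warning.
Intervals are the 2.5–97.5 percentiles of each group, published only
when both groups have ≥ 20 observations (percentile stability; the
source is silent on a floor). The stress-effect direction is the sign of
the group-mean difference. Intervals are stored as (lo, hi) and rendered
as centre ± half-width.

Coverage semantics: the reference interval is a percentile interval *of
the attribution-partitioned no-stress group*, so its nominal 95%
coverage statement applies to that group — on a held-out window split,
the training-derived intervals cover ≈ 95% of the held-out group values
(the acceptance suite requires ≥ 93% on average). Coverage of
*label-defined* no-stress windows is systematically lower (≈ 89–90% on
the synthetic cohort) because the partition truncates each feature at
its attribution boundary; this is a property of the published derivation
itself, worth remembering when reading the intervals clinically.

## Report

Rows appear in canonical registry order with result, unit, interval
(centre ± half-width), IMPACT and two flags. The star flag uses the
closed interval [lo, hi] and fires on either side — the literal reading
of "outside the reference interval"; a one-sided variant that fires only
on the interval's stress side is available behind a switch. The circle
flag is red iff IMPACT > 0; a zero impact renders green. USER STRESS
LEVEL is round(100·P_X); SYSTEM CONFIDENCE LEVEL is 100× the model's
stored mean cross-validated F1 — the only "historic accuracy" the
method actually computes. OLAP aggregation keeps all rows (`full`), the
12 heart-rate/respiration/temperature tests (`simple`), or a custom
subset; headers and surviving rows are never altered. JSON rendering is
lossless; text and HTML mirror the TESTS / RESULT / UNIT / REFERENCE
INTERVAL / IMPACT / FLAGS layout.

## Evaluation statistics

* **RPD** between two derivations of a feature's reference interval:
  `100·|μ_A − μ_B| / (2·|μ_B|)` on interval midpoints, exactly the
  printed formula (denominator 2·μ_B, not the symmetric mean; the
  absolute value keeps RPD ≥ 0 for negative-valued features). The total
  is the mean over defined features by default (a sum variant is
  configurable); undefined features (unavailable interval, zero
  denominator) are dropped and counted.
* **Flag consistency**: pooled percentage of rows whose star and circle
  flags agree, plus a per-feature breakdown; rows without an available
  interval are not counted.
* **Chi-squared concordance**: Pearson's test without continuity
  correction on the 2×2 table {IMPACT > 0, < 0} × {outside, inside
  reference interval}; zero-impact observations are excluded and
  degenerate margins return an undefined marker.
* **F1-binary**: precision/recall harmonic mean on the stress class
  only, 0 when precision + recall is 0.

A packaged CSV carries the literature ground truth: five heart-derived
features with numeric stress/no-stress ranges (mean ± sd and p-values)
plus direction-only entries for trapezius EMG amplitude and respiration
rate. The ground-truth section of the source reports respiration rate
*increasing* under stress while its model-derived table lists the mean
respiration rate as decreasing; the generator follows the ground truth.

## Problem sizes

The test and acceptance studies use a 20-subject cohort under the
default 36.5-minute protocol (≈ 1340 windows of 90 s at a 30 s stride,
≈ 27% stress prevalence), a 100-row background sample, the
attribution-coverage forest, 50 random small ensembles (≤ 5 trees,
3–10 features, 64 background rows) for the oracle-equivalence study, and
a single centre-parameter subject over 20 min baseline + 10 min stress
for parameter recovery. The full suite runs in a few minutes on one CPU.
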