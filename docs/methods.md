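# Methods

## Measurement model

The package treats brain biological age (BBA) as the age predicted from a
single quantitative-EEG feature: the alpha-band (7–13 Hz) spectral centre of
gravity, averaged over posterior electrodes.  The underlying assumptions are

* the individual alpha frequency declines approximately linearly with age
  over the adult span;
* a linear regression of chronological age (CA) on the feature, fitted on a
  reference (normative) cohort, is an adequate brain-age predictor;
* brain aging is continuous — no stages or jumps — so a subject's state can
  be summarized by a single scalar at each visit.

Derived scores are affine in the prediction: the brain-age gap `BBA − CA`
and brain resources `BR = 100·(CA − BBA)/(100 − 16)`.  The denominator is
the meaningful adult age span: 16 y marks the maturation of adult EEG
patterns, 100 y a practical maximum.  BR is therefore a percentage of that
span, positive when the brain phenotype is younger than CA.  The bounds also
clamp predictions: estimates outside [16, 100] y are clipped and flagged
rather than rejected, since values beyond the span carry no additional
meaning.

### Feature choice

The centre of gravity `f_cog = Σ f·P(f) / Σ P(f)` over 7 ≤ f ≤ 13 Hz is
used instead of the spectral peak because it is defined for flat or split
alpha peaks and varies smoothly with the underlying rhythm.  The electrode
set defaults to the posterior sites {O1, O2, P3, P4, Pz, T5, T6}, which
carry the dominant resting alpha rhythm; both band and electrode set are
arguments of `extract_alpha_feature` / `AlphaFeatureExtractor`.

### Calibration direction and attenuation

`BrainAgeRegressor` regresses CA on the feature (prediction-ready), not the
feature on CA inverted.  A consequence worth stating: with per-visit feature
noise σ the OLS slope converges to the inverse-mapping slope multiplied by
the reliability `var(f_true)/(var(f_true)+σ²)`, so predictions regress
slightly toward the reference-cohort mean — exactly as real brain-age models
do.  With the default noise (0.05 Hz) and a reference spanning 16–100 y the
attenuation is ≈ 0.5% and negligible against the Monte-Carlo error of the
recovery runs; the regression-dilution algebra is asserted as a closed-form
oracle in the calibration tests.  The reference cohort used by
`fit_reference_calibration` draws CA uniformly over [16, 100] y (n = 500 by
default), maximizing feature variance and hence reliability; it is generated
from a seed stream disjoint from every analysis cohort.

## Signal chain

* **Filters.** 0.5–30 Hz 4th-order Butterworth bandpass and a Q = 30 IIR
  notch at 50 Hz, both applied forward–backward (`sosfiltfilt`/`filtfilt`)
  so the alpha band suffers no group delay.  The effective contracts —
  ≤ 1 dB passband ripple, ≥ 20 dB one octave outside the band, ≥ 20 dB at
  the line frequency with ≤ 1 dB at ±5 Hz — are asserted on tones in the
  tests, measured in steady state (the forward–backward edge transients are
  excluded from the RMS).
* **Segmentation.** 2-s segments with 50% overlap (the conventional choice
  for averaged spectra; the overlap is configurable).  With `L = round(2·fs)`
  and `step = round(L·(1−overlap))`, a 6-min 256 Hz recording yields exactly
  359 segments.
* **Artifact rejection.** A segment is rejected when any channel shows
  peak-to-peak > 100 µV, a sample-to-sample jump > 50 µV, or a flatline
  (range < 0.5 µV).  These thresholds stand in for the study's unpublished
  rejection algorithm; they are deliberately simple so they can be tested
  against the generator's injected-event ground truth (≥ 80% of segments
  sharing ≥ 50 ms with an injected event are rejected under the default
  profile).  Recordings with fewer than 30 retained segments are flagged
  low-confidence.  Rejecting *all* segments is a hard error, since the
  averaged spectrum would be undefined.
* **Spectrum.** Per retained segment: mean subtraction, periodic Hann
  window, one-sided periodogram normalized by the window power (µV²/Hz),
  averaged across segments.  No zero padding, so the 0.5 Hz grid puts the 7
  and 13 Hz band edges exactly on bins and the band sum is unambiguous.
  Parseval (`Σ P·df ≈ var`) holds within 2% for stationary inputs, and the
  whole chain is cross-checked against `scipy.signal.welch` to machine
  precision when no segments are rejected.

## Synthetic cohort generator

The generator emulates the study conditions, not resting EEG in general.

**Demographics and design.**  Two arms with exact rounded sex counts
(31/42 and 25/47 females), CA from truncated normals (54.1 ± 13 and
45.2 ± 7.3 y on [25, 77] y — the truncation moves the realized means by a
few tenths of a year, which is accepted), follow-up from truncated normals
(13 ± 1.13 and 13.5 ± 1.10 months on [6, 18]), and
`CA_post = CA_pre + followup/12` exactly.

**Baseline gaps.**  Two models:

* `normal` — gap ~ N(mean, sd), range-clipped so true BBA stays in
  [16, 100] (a warning is emitted if clipping is material);
* `stratified` (used by the shipped profile) — the stratum (older- vs
  younger-than-CA brain) is drawn first with the configured probability,
  then the gap from a truncated normal component on (0, 100−CA] or
  [16−CA, 0).  Component dispersions (7.73 / 9.24 y) and anchor locations
  (+9.2 / −15.4 y) follow the published per-stratum summaries; a common
  location shift is solved numerically (Gauss–Legendre quadrature over the
  CA distribution + Brent root find) so the realized arm-mean gap equals the
  configured value exactly.  The stratified model exists because a single
  normal cannot simultaneously reproduce the arm-mean gap, the observed
  older-stratum fractions (15/42, 13/47) and the [16, 100] range: the SD
  required by the fraction (≈ 21 y) pushes ~8% of draws below a 16-year
  brain age, and clipping there would shift the realized mean by close to a
  year.

**Effects.**  True BBA changes are stratum-specific
(−6.77 / −0.64 y in the nutraceuticals arm, +0.25 / −0.13 y in the
lifestyle arm) with a common SD of 2.0 y for response heterogeneity.  The
arm-level effect is then an emergent mixture: (15·6.77 + 27·0.64)/42 =
2.83 y of rejuvenation in the nutraceuticals arm and ≈ 0.02 y in the
lifestyle arm — and the post-intervention gap is likewise emergent
(baseline gap + effect − CA drift), which is what the acceptance suite
checks.

**Alpha–age mapping.**  `f(BBA) = 10.8 − 0.03·(BBA − 16)` Hz, spanning
10.8 → 8.3 Hz over 16–100 y, comfortably inside the 7–13 Hz analysis band;
configurations that map the age range outside the open band are rejected.
Both anchor and slope are configuration fields.

**Feature noise.**  Per visit the observed feature is
`f(true BBA) + u + ε` with `Var(u) = ρσ²` (a stable subject offset) and
`Var(ε) = (1−ρ)σ²`, so the marginal noise SD is σ = 0.05 Hz with pre/post
correlation ρ = 0.8.  The values reflect that a centre-of-gravity feature
averaged over ~350 segments and 7 electrodes is a very stable statistic and
that the individual alpha frequency has high test–retest reliability;
σ = 0.05 Hz corresponds to ≈ 1.7 y of single-visit BBA uncertainty and
≈ 1.05 y SD on paired differences.

**Signal fidelity.**  Each channel carries an alpha oscillation at
`f(true BBA)` with slow (≤ 0.2 Hz) random amplitude modulation, posterior
channels at 20 µV amplitude and anterior at 40% of that, a 1/f background
(4 µV SD), a 2 µV line component at 50 Hz, and Poisson-timed artifacts:
blinks (1–2 Hz half-sines, 150–300 µV, frontal channels) and muscle bursts
(20–28 Hz noise, 50 µV SD, temporal channels, Hann-tapered).  Event times
are kept in `Recording.annotations` so rejection can be scored against
truth.  What this signal does **not** emulate: spatial correlation beyond
the two amplitude tiers, non-stationary alpha frequency, sleep phenomena,
ERPs, realistic artifact morphology.  Passing tests therefore demonstrate
correctness of the measurement chain, not performance on clinical EEG.

**Fidelity bridge.**  With noise and artifacts off, the feature extracted
from synthesized recordings equals the feature-mode value to well within
one 0.5 Hz bin, and arm-mean BBA from the two modes agrees to < 0.5 y on
matched subjects.  With noise on, the two modes draw independent noise, so
agreement at that precision is not expected and not asserted.

## Statistics

* **Wilcoxon signed-rank**: zero differences dropped (Pratt behind a flag),
  mid-ranks on tied |d|; exact two-sided p by enumerating all 2ⁿ sign
  assignments for n ≤ 12; otherwise the normal approximation with the exact
  conditional variance `Σ rᵢ²/4` (which equals the textbook tie-corrected
  formula).  z is reported from `min(T⁺, T⁻)` — the convention matching the
  reported study values, always ≤ 0 — with the effect direction carried in
  `method_notes`.
* **Mann–Whitney U**: U from rank sums with mid-ranks; exact enumeration of
  all C(n₁+n₂, n₁) assignments for n₁+n₂ ≤ 12; otherwise the tie-corrected
  normal approximation.  z is signed by `U − n₁n₂/2`, so exchanging the
  groups flips its sign and leaves p unchanged.
* **No continuity correction** anywhere: the study's reported pairs satisfy
  p = 2Φ(z) exactly, which a continuity correction would break.  The cost is
  a worst-case exact/approx gap of ≈ 0.07 at n₁ = n₂ = 6 (mean ≈ 0.05),
  measured and asserted in the tests; the signed-rank approximation stays
  within 0.05 at n = 12.
* **Chi-square**: Pearson statistic without continuity correction by
  default (flag available), df = k−1 for a 2×k table; delegated to
  `scipy.stats.chi2_contingency`.  **Pearson r**: `scipy.stats.pearsonr`.
* **Multiplicity**: p-values are reported uncorrected by default, matching
  the study's analysis plan; `run_battery(..., correction="holm")` switches
  on an optional adjustment column.
* The exact enumeration cutoff (12) keeps every small-sample p testable
  against brute-force oracles at negligible cost.

The battery runs, in a fixed order: within-arm signed-rank tests (BBA
pre/post, BR pre/post, BBA vs CA at each visit), between-arm rank-sum tests
(ΔBBA, Δgap, ΔCA, and the gap at each visit), the ΔBBA/ΔCA contrasts
repeated within sex and baseline-gap strata, per-arm Pearson correlation of
ΔBBA with intervention duration, a sex-by-arm chi-square and per-arm
symptom-proportion chi-squares.  Subjects with an incomplete visit pair are
excluded with a log entry; a baseline gap of exactly 0 stratifies as
"younger" (BBA ≤ CA).

## Problem sizes and numerical choices

* Monte-Carlo recovery uses feature fidelity: 200 replicates of the full
  89-subject profile for the main quantities and 1000 replicates of the
  47-subject lifestyle arm for its small (≈ 0.02 y) effect, a few seconds
  to half a minute on one core.  Signal-fidelity tests use 2–10 subjects at
  20–60 s per recording, which is enough to pin the chain down to a fraction
  of a frequency bin.
* All randomness flows through `numpy.random.SeedSequence`; identical
  configuration and seed give bit-identical cohorts, recordings and pipeline
  outputs (the run manifest records seed, config hash and per-file SHA-256).
* The stratified-gap location shift is solved with Brent's method to 1e-10
  on a 64-node Gauss–Legendre quadrature of the CA distribution.
* EDF export quantizes to 16 bits over a symmetric per-channel physical
  range; round-trip error is bounded by one quantization step.  The writer
  emits plain EDF (1-s records, integer sampling rates); in-memory
  annotations are not serialized.
* Degenerate inputs are errors, not silent results: constant features in
  calibration, all-zero paired differences, zero-marginal contingency
  tables, all-rejected recordings, band mappings outside (7, 13) Hz.

## Worked numbers

The README example was produced by:

```python
import numpy as np
import neuroage as na

config = na.study_profile(seed=42)
cohort, truth = na.generate_cohort(config)
model = na.fit_reference_calibration(config.eeg, n=500, rng=np.random.default_rng(1))
print(f"calibration: BBA = {model.intercept_:.1f} {model.slope_:+.1f} * f_alpha (n=500)")
wide = na.to_wide(na.score_cohort(cohort, model))
for _, row in na.group_summary(wide).iterrows():
    print(f"{row['arm']:>14}: n={row['n']:2d}  gap_pre={row['gap_pre_mean']:+6.2f} y  "
          f"gap_post={row['gap_post_mean']:+6.2f} y  BR_pre={row['br_pre_mean']:+5.1f} %")
battery = na.run_battery(wide).to_frame()
for arm in ("nutraceuticals", "lifestyle"):
    row = battery[(battery.comparison == "bba_pre_vs_post") & (battery.stratum == arm)].iloc[0]
    print(f"{arm:>14} BBA pre vs post: z = {row.z_value:.2f}, p = {row.p_value:.5f}")
```

## Known limitations

* The calibration is a stand-in fitted on synthetic normative data; it does
  not reproduce any previously published coefficient set, and no claim of
  equivalence with the original (unpublished) rejection algorithm or feature
  definition is made.
* Feature noise in the generator is smaller than published test–retest
  variability of EEG brain-age scores; detection power on real data will be
  lower than in these simulations.
* Sex enters the generator only through counts — effects are stratified by
  baseline gap, not by sex — so sex-stratified recovered effects center on
  the arm means rather than the slightly different published sex-specific
  values.
* Effects are independent of intervention duration, so the duration
  correlation recovers 0 (consistent with the study's non-significant
  finding, but not calibrated to its point estimate).
* The intervention content itself (nutraceuticals, lifestyle) is out of
  scope; arms differ only in their configured effect distributions.
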