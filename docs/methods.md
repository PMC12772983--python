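# Methods

This note documents the models, conventions and numerical choices behind
`ehgtrends`, and what the synthetic validation does and does not establish.

## Scientific setting

The electrohysterogram (EHG) records uterine myoelectrical activity from the
abdominal surface. Its analytically useful content sits in two "fast-wave"
bands: fast-wave-low (FWL, 0.13–0.26 Hz), linked to signal propagation, and
fast-wave-high (FWH, 0.34–4 Hz), linked to cellular excitability. Across the
third trimester the uterus becomes progressively more excitable and
synchronised; the pipeline quantifies that progression per recording with
four whole-window features and compares singleton (SG) and twin (MG)
pregnancies across gestational age (GA, weeks of gestation, WoG).

Whole-window analysis deliberately avoids contraction detection: antepartum
contractions are often indistinguishable from basal activity, so every
recording is cut into fixed 120-s windows (50 % overlap) and the
per-recording value of each feature is the median across windows.

## Preprocessing

1. **Band-pass 0.1–4 Hz**: 5th-order Butterworth applied forward–backward
   (zero-phase), at the native sampling rate (500 Hz by default). Zero-phase
   filtering preserves burst timing; the first/last ~10 s carry the edge
   transient and are never asserted on in tests.
2. **Resampling to 20 Hz**: polyphase decimation, preceded by an explicit
   zero-phase 8th-order low-pass at 0.35 × target rate. The extra guard
   filter matters because a polyphase decimator's own anti-alias filter has
   its transition band centred on the new Nyquist frequency and passes
   tones just below it (e.g. 9 Hz when resampling to 20 Hz) essentially
   unattenuated.
3. **Artifact exclusion**: annotated intervals (half-open `[start_s, end_s)`,
   seconds from recording start) are removed; analysis windows are cut only
   inside the remaining clean segments, so no window spans an artifact. In
   the full pipeline each interval is widened by 10 s per side before
   exclusion: high-amplitude artifacts excite the 0.1 Hz high-pass edge,
   which rings for a few time constants past the annotation boundary.
   A window touching an (padded) artifact is discarded, never repaired —
   interpolation would invent signal.
4. **Windowing**: a segment of duration `D` yields
   `floor((D − 120)/60) + 1` windows of exactly 2400 samples; segments under
   120 s yield none.

Order of operations is filter → resample → exclude → window. Amplitudes are
treated as arbitrary units throughout; every downstream feature is either
unit-free or reported in the recording's own units.

## Features

| feature | band (Hz) | definition |
|---|---|---|
| PPA | 0.1–4 | max − min of the window |
| KHE | 0.1–4 | Pearson kurtosis of the Hilbert-envelope magnitude |
| MDF | 0.2–1 | half-power frequency of the Welch spectrum restricted to the band |
| SampEn | 0.34–4 | −ln(A/B), template length m = 2, tolerance r = 0.2 × SD |

Numerical conventions:

* **KHE** uses the non-excess (Pearson) kurtosis, so a Gaussian envelope
  background scores 3 and a Rayleigh envelope (band-limited Gaussian noise)
  scores ≈ 3.245. The envelope's first and last 2 s are discarded before the
  moment computation — analytic-signal edge artifacts otherwise inflate the
  fourth moment.
* **MDF** uses Welch with 256-sample (12.8 s) Hann segments at 50 % overlap,
  giving ~0.078 Hz bins inside a 2400-sample window; the half-power crossing
  is interpolated linearly within the crossing bin. Windows with zero
  in-band power return NaN.
* **SampEn** is computed on a per-window zero-phase Butterworth re-filter to
  the FWH band. The tolerance r is 0.2 × the SD of that re-filtered window
  (the universal convention when "r = 0.2" is quoted), parameterised in case
  a recording-level SD is preferred. Both template lengths use the N − m
  templates that admit an (m+1)-extension and matches use Chebyshev distance
  ≤ r with self-matches excluded. The production path counts template pairs
  with a k-d tree; tests hold it to an O(N²) brute-force count at 1e-12.
* Undefined feature values (constant windows, zero in-band power, zero
  template matches) are NaN and are excluded per feature at the median
  aggregation, never imputed. A recording with zero windows is excluded with
  a logged reason.

## Synthetic cohort generator

No public dataset matches the cohort structure analysed here, so validation
runs on a seeded generator. One recording is

```
x(t) = A · (b + e(t)) · c(t) + drift(t) + noise(t)
```

* `e(t)`: Gaussian-tapered contraction bursts (default 0.7/min, 50 s,
  envelope sigma = duration/5), onsets from a Poisson process thinned to
  forbid overlap.
* `b`: `background_level`, continuous activity between bursts — myometrial
  activity does not vanish between contractions, and the feature pipeline
  needs the inter-burst signal to carry structure rather than silence.
* `c(t)`: unit-variance content, `sqrt(1−f)·FWL + sqrt(f)·FWH` with
  `f = fwh_fraction = 0.6`. FWL is band-limited Gaussian noise. FWH is a
  0.55 Hz carrier with a phase random walk of intensity
  `2.0 · (1 − regularity)` rad/√s, band-limited to 0.34–4 Hz after
  synthesis — without that re-filter the phase-noise oscillator's
  Lorentzian tails leak below 0.34 Hz at low regularity and break the
  spectral-placement guarantee (≥ 95 % of activity power inside FWL ∪ FWH).
* `drift(t)`: three random sinusoids below 0.1 Hz; `noise(t)`: white noise,
  SD 0.4 raw (≈ 0.05 inside 0.1–4 Hz at 500 Hz).

All random variates are drawn in a fixed order, so changing an amplitude
parameter with the seed held fixed changes nothing else — paired
experiments (e.g. doubling `burst_amplitude` exactly doubles the activity
term) are exact.

Knob → feature mapping, each chosen for monotone, decoupled control:

* `burst_amplitude` → PPA (linear).
* `background_level` → KHE (scale-free: kurtosis responds to how strongly
  bursts stand out of the background, not to overall gain).
* `regularity` → SampEn (more phase jitter → higher entropy). The mapping is
  monotone but makes no biophysical claim.
* `fwh_carrier_hz = 0.55` keeps MDF mid-band and GA-stable, mirroring the
  expectation that median frequency changes little before labour.

The default cohort mirrors the target study design: 53 SG and 63 MG women,
1–3 recordings each, GA 26–41 WoG (SG) and 26–37 (MG); recordings at
GA ≥ 37 are labelled TNL (term, not in labour) or APL (active phase of
labour) at 50/50. A lognormal per-woman amplitude factor (SD 0.12)
introduces repeated-measures structure. Programmed GA trends:

* SG: amplitude 0.25→0.6, regularity 0.25→0.85, background 0.80→0.13
  (linear in GA over 26–41) — PPA and KHE rise, SampEn falls.
* MG: amplitude ≈ 0.42 (near-flat), regularity 0.55→0.63, background 0.42 —
  higher amplitude, higher regularity and more prominent bursts than SG
  *before* 32 WoG, converging with SG by the mid-30s. This encodes the
  "earlier activation, later plateau" pattern the analysis is meant to
  detect: group differences are largest in the early third trimester.

Artifacts for exclusion tests are clipped sawtooth ramps (~20 × signal SD)
in random non-overlapping episodes of 30–90 s; morphology is deliberately
crude because annotated intervals are excluded, not repaired.

What the generator does **not** emulate: electrode geometry and propagation,
mains interference, fetal/maternal ECG residues, heteroscedastic noise,
circadian contraction patterning, and any physiological coupling between
features beyond the programmed trends. Passing tests therefore demonstrate
that the pipeline recovers known structure of this class — not that the
clinical effect sizes would be reproduced on real recordings.

## GA balancing

SG and MG recordings arrive with different GA distributions, and every
feature trends with GA, so raw group comparisons are confounded. GA is cut
into 1-week bins (width exposed as a parameter); within each bin the larger
group is downsampled without replacement to the smaller group's count, with
one seeded generator consumed in ascending bin order for reproducibility.
Bins where either group is empty are dropped from both. Strict per-bin
equalisation is a deliberate, reproducible approximation of "dynamic"
downsampling schemes that trade strictness for information retention;
consequently the two balanced groups here are exactly equal in size, which
such schemes do not guarantee. Sampling is at the recording level, matching
the recording-level unit of analysis.

## Trend statistics

* **Stages**: routine recordings split at the clinical thresholds into
  Early3T (GA < 32) and Late3T (32 ≤ GA < 37), half-open intervals; TNL/APL
  labels from metadata take precedence. A routine recording at GA ≥ 37 is a
  data error and raises.
* **GAM**: per feature and group, a Gaussian-response penalized cubic
  B-spline smooth of the feature on GA (≤ 10 basis functions), penalty
  selected by generalized cross-validation, 95 % pointwise intervals on a
  0.25-week grid. Separate per-group fits (rather than one model with a
  group-by-GA interaction) match the independent-curves presentation the
  analysis targets. When the data lie exactly in the spline span (noiseless
  or constant input) the penalized IRLS loop aborts; the fit falls back to
  unpenalized spline least squares, which is exact there.
* **Spearman**: average-rank ties; two-sided p-value by exact enumeration
  for n ≤ 8, seeded Monte-Carlo permutation (10 000 resamples) for n ≤ 30,
  t-approximation beyond. Full enumeration is infeasible past ~10
  observations, so the seeded permutation test stands in for it at the
  small-stratum sizes where the t-approximation is least trustworthy.
* **Wilcoxon rank-sum**: two-sided; full enumeration of rank assignments
  (average ranks, so ties are exact) whenever n_a + n_b ≤ 20, otherwise the
  normal approximation with tie and continuity corrections. α = 0.05, raw
  p-values without multiplicity correction — the stage-wise comparisons are
  reported the way exploratory EHG studies report them, and the comparison
  table carries everything needed to apply Holm afterwards.
* Repeated recordings from the same woman are treated as independent
  observations (the recording is the unit of analysis); this caveat is
  logged whenever duplicated woman IDs are present.
* Comparison families: SG vs MG within each stage, and all stage pairs
  within each gestation type. Correlations by default include the TNL/APL
  recordings (`include_term=False` restricts to routine recordings).

## Problem sizes and determinism

Validation uses the full default cohort (~225 recordings of 30 min at
500 Hz) for the end-to-end directional check, 100 simulated cohorts of
n = 200 for GAM calibration, 2000 null replications for Wilcoxon type-I
error, and 100 windows up to N = 3000 for the SampEn oracle. Every stochastic
step (generator, balancing, permutation p-values) takes an explicit integer
seed; identical seeds give bitwise-identical outputs.

## Known limitations

* The generator's trend shapes are linear in GA; the GAM layer is validated
  on nonlinear truths separately, but the end-to-end directional check
  cannot distinguish spline fits from straight lines.
* Amplitude units are arbitrary; absolute feature levels (e.g. PPA in µV)
  are not comparable to hardware-calibrated recordings.
* Strict per-bin balancing discards more data than information-retaining
  dynamic sampling would; with very sparse bins it can drop whole strata.
* The exact-permutation Spearman regime is Monte-Carlo for 8 < n ≤ 30;
  p-values there carry resampling noise of order 1/√10000.
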