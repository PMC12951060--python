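# Methods

## Signal model

A single pulse beat, resampled to `L` uniform points covering exactly one
period, is modelled as a truncated Fourier series in cosine-delay convention:

    f(x) = A(0) + Σ_{n=1..11} A(n) · cos(2πnx/L − θ(n)),   x = 0..L−1

`A(0)` is the beat mean (kept, not detrended: the zeroth-order term is the
mean arterial level of the beat), `A(n) ≥ 0` the n-th harmonic amplitude and
`θ(n) ∈ (−π, π]` its phase delay. Orders 0–11 are used throughout; for
arterial pressure waves they carry over 98 % of the spectral energy, and the
analyzer verifies this on the default synthetic beat by full-spectrum
Parseval accounting. Amplitudes and phases are read off the discrete Fourier
transform of the beat (`A(n) = 2|F[n]|/L`, `θ(n) = −arg F[n]`), which makes
synthesis → analysis exact to machine precision for band-limited beats.

Per-beat energy fractions are Parseval terms normalized by total beat power
`mean(f²)`: `E(0) = A0²/P`, `E(n) = A(n)²/2/P`. They are dimensionless and
sum to ≤ 1, with equality iff the beat is band-limited to order 11.

## Record-level indices

For the `M ≥ 5` accepted beats of one hand:

* `Cn` — mean over beats of `a(n,m) = A(n,m)/A(0,m)`. Normalizing by the
  per-beat mean makes the index dimensionless and invariant to sensor gain,
  which is essential when two hands are recorded by two sensors. By
  construction `C0 ≡ 1` and `P0 ≡ 0`; both are dropped from candidate
  predictors (they carry no information), which the selection stage logs.
* `Pn` — circular mean of `θ(n,·)` (the mean direction of the unit vectors),
  so antipodal phases near ±π average to ±π rather than 0.
* `Dn` — mean of `E(n,·)`.
* `CnCV`, `DnCV` — sample SD / mean over beats.
* `PnCV` — phases are first re-branched to within π of the circular mean,
  then the linear SD/|mean| is taken; a plain linear CV is ill-defined for
  circular data. When |mean| < 1e−6 the denominator is floored at 1e−6 and
  the order is flagged (`near_zero_phase_mean`).

Difference features are signed left − right for every index (the study
convention fixes only the order "left- and right-hand"; this package defines
the sign as left minus right), with phase differences wrapped to (−π, π]
*before* absolute values are taken. The candidate pool for modelling
contains both the signed and the absolute versions (144 columns; final
clinical models of this kind mix signed and absolute terms), with
`DnCV` includable or excludable by config (`include_dncv`, default on).

## Beat segmentation

The study protocol presumes beat-wise decomposition but fixes no
segmentation algorithm, so a standard, deliberately simple foot detector is
used:

1. zero-phase low-pass (4th-order Butterworth, 10 Hz cutoff) smoothing used
   only for localization — beats are cut from the raw signal;
2. dominant period estimated from the autocorrelation of the smoothed
   record within the physiological window 0.3–2.0 s; the minimum upstroke
   spacing is 0.7× that period, which stops dicrotic waves from being
   counted as extra beats;
3. systolic upstrokes as peaks of the smoothed derivative above 0.3× the
   median candidate peak slope (a median, not a maximum, so one grossly
   rescaled beat cannot mask the rest);
4. the foot is the smoothed-signal minimum between consecutive upstrokes and
   must be a local minimum — record-edge minima (partial beats) are
   discarded.

Quality flags reject beats with period outside 0.3–2.0 s or peak-to-peak
amplitude more than 4 MAD from the record median; fewer than 5 accepted
beats is an error. Beats are resampled to `L = 256` points (power of two,
comfortably above the 2×11+1 minimum for order 11) with a periodic cubic
spline — foot-to-foot beats are one period, so periodic boundary conditions
are the natural choice and keep single-harmonic content accurate to ~1e−8.

## Synthetic cohort generator

The generator defines the study conditions; every downstream stage is
developed and tested against it because the clinical recordings this
pipeline targets are not publicly available.

* **Template.** The default beat template (amplitudes decaying from
  `A1 = 0.42` to `A11 = 0.003` on a unit mean, phases shaped to give a sharp
  systolic upstroke and a dicrotic-notch-like inflection from orders 2–4) is
  a plausibility choice; no waveform parameters are published for the target
  device. It is band-limited to order 11, so the ≥ 98 % energy-concentration
  property holds by construction and is machine-checked.
* **Cohort.** Defaults mirror the target study population: 249 male / 99
  female subjects with exactly 32 / 13 events (SYNTAX ≥ 22) in exact-count
  mode (a Bernoulli-prevalence mode exists); ages ~N(59.8, 9) male and
  N(67.5, 9) female; SYNTAX scores uniform on [1, 21] / [22, 45] for
  non-events / events. Event counts are reproduced exactly; all generation
  is deterministic given the config seed.
* **Between-subject variability.** Per-order lognormal (σ = 0.10) amplitude
  and wrapped-normal (σ = 0.10 rad) phase scatter around the template.
* **Disease link.** Every subject receives additive per-order offsets on the
  right hand (amplitude and phase, Gaussian) on the orders that appear in
  the final clinical models (1–6, 8–10); event subjects draw them at full
  scale (SD = 0.10 × template amplitude; 0.12 rad), non-events at half
  scale. The 2× SD ratio is a one-time realism choice: inter-hand asymmetry
  exists physiologically in everyone and is amplified, not created, by
  disease. No published generative mechanism exists; this is the package's
  own design.
* **Within-record structure.** Beat-to-beat lognormal amplitude jitter
  (CV 0.08), wrapped-normal phase jitter (0.06 rad), lognormal period jitter
  (CV 0.04) — the simplest strictly-positive/circular families; additive
  Gaussian noise (SD 0.02 on a unit-mean signal) and a slow sinusoidal
  baseline drift (amplitude 0.05, 0.05–0.2 Hz). Both hands share the beat
  period sequence (one heart) but draw independent jitter and noise.
  Partial beats at record edges are generated and left for the segmenter.
* **Acquisition.** 200 Hz for 60 s per hand at 70 bpm by default. The
  target protocol reports roughly one minute of recording but no sampling
  rate; 200 Hz is an assumption, flagged here and in the config docs.

What the generator does **not** emulate: motion artifacts, sensor
saturation, respiratory modulation, arrhythmia, inter-hand timing (pulse
arrival delay), or any hemodynamic mechanism linking lesions to waveforms.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the *pipeline*, not clinical validity on real recordings.

## Model fitting and selection

Logistic regressions are fitted by Newton/IRLS (statsmodels) to gradient
tolerance 1e−8, max 100 iterations, always with an intercept (the clinical
tables never report intercepts, but omitting them is statistically
indefensible for rare outcomes). Complete separation is detected (perfect
prediction or log-likelihood above −1e−3) and raised as an explicit error,
never returned as silently diverged coefficients; rank-deficient designs
raise an error naming the collinear columns. Reported per-variable
statistics are Wald: SE, t = coefficient/SE, normal two-sided P.

The three searches are greedy AIC minimizers: forward (start empty, add the
best variable while AIC strictly decreases), backward (start full, remove;
falls back to forward with a recorded warning when the full model is
unfittable — which at 136 candidates and ≤ 249 subjects is the norm), and
bidirectional stepwise (best single add-or-drop move until no move lowers
AIC). Moves must beat a 1e−10 margin; ties are broken lexicographically on
the moved variable's name, so selection is deterministic. The across-search
winner is minimum AIC, then fewer parameters, then name. AIC retention is
the operative rule even where a variable's Wald P exceeds 0.05 (an optional
post-hoc significance filter exists but is off by default, since published
models of this kind retain P ≈ 0.06–0.11 terms). The events-per-variable
advisory warns — never blocks — when parameters exceed events/10.

With ~136 candidates and 32 (male) or 13 (female) events, greedy AIC
selection overfits by construction: the best of 136 null χ²₁ improvements is
~10 deviance units, so many noise variables clear the +2 AIC hurdle. The
default study run therefore shows near-perfect apparent AUC with a much
lower bootstrap AUC. This mirrors the methodological reality of the design
and is reported, not hidden: the EPV advisory fires, and the bootstrap is
the honest discrimination estimate.

## Validation

* **AUC** is the Mann–Whitney pairwise concordance (midranks; ties count ½),
  with the trapezoidal ROC integral kept as an independent equal-by-theorem
  cross-check. ROC points come from scikit-learn.
* **Hosmer–Lemeshow**: subjects ranked by predicted risk into `g = 10`
  equal-count groups (stable sort, ties to the lower group);
  `H = Σ (O−E)²/(n π̄(1−π̄))`; df = g − 2 (in-sample convention); P from the
  χ² upper tail. Groups with π̄ ∈ {0, 1} are ε-guarded (1e−10) and flagged.
* **Bootstrap internal validation** (default 2000 resamples): draw n
  subjects with replacement, refit coefficients of the *fixed* selected
  variable set, score the original sample, record the AUC; report the mean
  and the 2.5–97.5 percentile interval. Variables are *not* re-selected per
  resample (the study design gives no sign of it), so selection optimism is
  only partially captured — a documented limitation. One-class resamples
  are redrawn and counted; a resample whose refit separates is scored
  through a weakly L2-capped fit (C = 1e4) — AUC is rank-based, so the cap
  does not bias discrimination — and counted as degenerate. With
  few-event strata and rich selected models, most resamples are degenerate
  in this sense; the report says so rather than failing.
* **Calibration curve**: per risk decile, (mean predicted, observed rate).

## Determinism and problem sizes

One global seed drives cohort generation, per-subject waveform synthesis
(each subject carries a derived seed), and the bootstrap; identical configs
give byte-identical outputs, and re-running selection from the serialized
feature table reproduces the identical models (feature CSVs are written at
17 significant digits for an exact float64 round-trip; waveform CSVs use 12).

Study-scale runs in this repository use the full default cohort
(348 subjects, 60 s × 200 Hz per hand, 2000 bootstrap resamples). The
statistical property checks in the test suite use the sizes stated in their
docstrings (e.g. 200 replicates for Wald coverage at n = 2000, 200
resamples × 20 replicates for bootstrap conservatism at the 249-subject
stratum scale) — chosen as the package's own balance between Monte-Carlo
resolution and suite runtime.

## Known limitations

* The exact published formulas for `Cn`/`Dn` normalization and the CV
  denominators appear only in a figure not available as text; the
  A0-normalized amplitude, Parseval energy fraction, and re-branched
  circular-CV definitions above are this package's reconstruction, chosen
  for dimensional soundness and inter-hand comparability.
* Single contact pressure per hand is assumed; multi-pressure acquisition
  (if the target device aggregates across pressures) is not modelled.
* Wald (not likelihood-ratio or profile) inference; no penalized or
  cross-validated selection; no interaction terms — all outside the
  design being implemented.
* The female stratum (13 events) frequently separates under rich fixed
  variable sets; the pipeline reports this explicitly rather than forcing a
  penalized fit into the clinical-table format.
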