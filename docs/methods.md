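# Methods

This note documents the models, conventions and numerical choices behind
`calslice`, in the order data flows through the pipeline.

## Normalization and photobleaching correction

**ΔF/F₀.** F₀ is the arithmetic mean of each raw trace over
[t₀, first valve opening); at least 5 pre-stimulus samples are required,
and cells with F₀ ≤ 0 are rejected with a reason rather than propagated.
ΔF/F₀ = (F(t) − F₀)/F₀ elementwise. ΔF/F₀ is invariant to rescaling raw
fluorescence by any positive constant, and the mean ΔF/F₀ over the F₀
window is zero by construction (both are property-tested).

**Bleach model.** Illumination bleaches the indicator; the observable is a
slow multiplicative decay shared by signal and baseline. The correction
fits

    F̄(t) = C + B·exp(−t/τ_b)

by least squares (`scipy.optimize.curve_fit`) to the *pooled mean* of
per-F₀-normalized non-responding traces — pooling is deliberately preferred
to per-cell fits for noise robustness. The bleached fraction is reported as
A = B₀/(B₀ + C) with B₀ the exponential term at the first sample.
Correction divides every raw trace by the fitted decay normalized to 1 at
the first sample, then recomputes F₀ and ΔF/F₀.

Numerical choices:

- Initial guesses: C from the last-decile mean, B from the first-decile
  mean minus C, τ_b = recording span / 3.
- τ_b is bounded to [0.5 s, 10 × recording span]. The upper bound is an
  identifiability guard: a flat trace fits equally well with τ_b → ∞ and B
  absorbing the constant, which corrupts the amplitude estimate; within the
  bound, flat data force B → 0 instead. Fits with τ_b outside (1 s, 10⁵ s)
  are additionally flagged implausible and correction is disabled.
- Samples inside any stimulus search window are excluded from the fit, even
  for nominal non-responders (sub-threshold stimulus contamination).

**Which cells are "non-responding"?** The pipeline is two-pass: responses
are first called on uncorrected ΔF/F₀; cells with zero responsive calls and
no exclusion flag feed the bleach fit; if the fitted A exceeds a threshold
(default 0.05 — correcting a near-flat decay is a no-op not worth an extra
model) the recording is re-normalized and re-called. This makes the
correction self-contained, with no manual labels. A fixed pre-computed fit
can be supplied instead, or correction disabled (`bleach_correction =
auto | off | BleachFit`).

## Response calling

Threshold: prestimulus mean + k·SD with k = 3, over the 15 s immediately
before valve opening, re-anchored per stimulus; SD uses the n−1 sample
estimator. If the window would overlap a previous stimulus's search window
it shifts earlier to the nearest clean 15 s segment; with no clean segment
the call is marked insufficient-baseline.

A pair is responsive iff one run of *consecutive* samples, all *strictly*
above threshold, begins within [valve, valve + search window] (default
60 s, covering the ≈10–12 s second-messenger delay plus transient width)
and spans at least 5 s. Conventions fixed here, shared with the brute-force
oracle in the test suite:

- Consecutive run, not cumulative supra-threshold time (the stricter
  reading, matching transient morphology).
- Ties at the threshold do not count.
- Run span is inclusive: (t_last − t_first) + one sample period, so a 5 s
  square pulse at 2 Hz meets a 5 s minimum.
- Peak ΔF/F₀ is the maximum over the search window; suprathreshold
  duration is the span of the longest qualifying run.

**Onset.** The reported onset time is the linear interpolation of the
threshold crossing between the last sub-threshold sample and the first
sample of the earliest qualifying run. The first-sample convention (config
`interpolate_onset = False`) carries a mean +dt/2 discretization bias
(≈0.25 s at 2 Hz), which is comparable to the standard error of an
onset-delay mean at realistic n; interpolation removes it while using only
quantities the criterion already defines. A small positive bias remains in
either convention (the trace must rise from the true onset to the
threshold before it can cross); with the default transient shape this is
≲ 0.1 s.

**Exclusions.** Cells responsive in a Ringer (vehicle) epoch are flagged
`ringer_responsive`; cells with supra-threshold activity outside all
stimulus windows are flagged `spontaneous_activity`. The spontaneous
detector uses a rolling threshold (mean + k·SD over the trailing 15 s) and
requires ≥ 3 consecutive supra-threshold samples wholly outside every
search window; no quantitative community definition of "spontaneous
activity" exists, so this detector is a stated assumption of the package.
Flagged cells have *all* their calls forced non-responsive and are dropped
from population analysis; exclusions never convert a non-responsive call
to responsive.

## Population aggregation

- All tastant percentages are conditioned on the ATP-responsive (viable)
  denominator; profile/overlap tables include only cells responding to
  ≥ 1 of the compared compounds. Report tables round half-up to integer
  percent; machine outputs keep raw fractions.
- Dose-response normalizes each cell's peak to its own peak at the
  reference (largest tested) concentration, then averages across cells
  (mean ± sem). Per-cell normalization is assumed (rather than a ratio of
  group means).
- Repeated-stimulation pharmacology normalizes each cell's peaks to its
  first-stimulation peak; the first value is exactly 1, and cells whose
  first stimulation was not responsive are dropped.
- Retention after a treatment is (cells responsive before and after) /
  (cells responsive before), matched by cell id.
- Heat maps sort cells by profile key, then by peak amplitude descending;
  group-boundary indices accompany the matrix.

## Statistics

- **χ² on 2×2 responder tables:** Pearson, df = 1, *without* Yates
  continuity correction — the variant that reproduces published
  responder-frequency statistics in this preparation; with the correction
  the values differ materially. Zero expected cells raise a degenerate-
  table error.
- **Mann-Whitney U:** midrank ties; exact permutation null when
  min(n₁, n₂) ≤ 8 with no ties, tie-corrected normal approximation with
  continuity correction otherwise. Exactness is reported on the result.
- **One-sample sign test:** exact binomial, ties with the null median
  dropped, two-sided p = min(1, 2·min tail). The default null for
  dose-response comparisons is median = 1 (the reference dose), a
  documented assumption.
- **Normality gate:** non-normal iff Shapiro-Wilk *or* Jarque-Bera rejects
  at α = 0.05; comparisons are then routed to the nonparametric tests.
  Being a union of two tests, its false-positive rate sits slightly above
  the nominal α (measured ≈ 0.05–0.09 on Gaussian data).
- No multiple-testing correction is applied anywhere, matching the
  analysis practice this pipeline reproduces.

## Synthetic recordings

The generator is the test bench: it draws a class per cell and synthesizes

    F(t) = F₀·(1 − A + A·e^(−t/τ_b))·(1 + ΔF/F₀(t)) + ε(t)·F₀

with ε i.i.d. Gaussian. Defaults define the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 2 Hz | upper end of the 1–2 Hz acquisition range |
| duration | 480 s | ATP, Ringer, denatonium, saccharin epochs at 120 s pitch |
| perfusion | 4 s delay, 10 s full exchange | fluorescein calibration of slice perfusion |
| onset delay | Gaussian, mean 11 s (ATP) / 12 s (tastants), SD 1.5 s, truncated at the 4 s perfusion delay | measured second-messenger delays |
| transient | difference of exponentials, rise 1 s, decay 8 s | standard Ca²⁺-indicator surrogate; returns to baseline within tens of seconds |
| peak ΔF/F₀ | N(1.0, 0.25) truncated at 0.35, then Hill-scaled | analyzed responses are unambiguous transients |
| Hill dose scaling | denatonium EC50 = 1 mM, n = 1; saccharin EC50 = 10 mM, n = 2; ATP EC50 = 3 µM | reproduce ≈50% response at 1 vs 10 mM denatonium and ≈40% at 5 vs 10 mM saccharin; 30 µM ATP near saturation |
| bleaching | A = 0.1, τ_b = 600 s | modest decay; exercised harder (A = 0.2–0.3) in tests |
| noise | SD 0.02 ΔF/F₀ | realistic confocal SNR at low laser power |
| classes | 28.5% non-responder, 35.2% ATP-only, 14% +denatonium, 5.3% +sweetener, 12% +both, 2% Ringer-artifact, 3% spontaneous | 70% viable among artifact-free cells; 39%/26% denatonium/sweetener responders with 18% overlap among the viable |
| spontaneous cells | 1–3 transients at uniform non-epoch times, peak ~N(0.5, 0.15) clipped at 0.25 | prevalence and amplitude are not quantified anywhere; stated assumption |

Transients are normalized so their maximum over the *sampled* time axis is
exactly the drawn peak; this makes the ground-truth peak recoverable to
1e-6 from noiseless sampled data (analytic normalization would leave an
O(dt²) gap). The argmax still lands at the grid point nearest the
closed-form time-to-peak t* = ln(τ_d/τ_r)·τ_rτ_d/(τ_d − τ_r).

Optional image stacks render each trace into a disk-shaped ROI on a grid
(non-overlap enforced), with independent per-pixel Gaussian noise, so
ROI-mean extraction recovers traces within SE = σ_pixel/√n_pixels.

**What the generator does not emulate** — and hence what passing recovery
tests do *not* establish for real data: optical point-spread and photon
shot noise, pink/drift noise, slice movement beyond the Ringer-artifact
class, overlapping or moving ROIs, sub-cellular (ciliary vs somatic)
compartments, and cell-to-cell Ca²⁺ waves. Recovery results certify the
analysis logic, not robustness to those physical effects.

## Problem sizes in tests

The recovery experiments run at the sizes the checks are stated for:
400 cells × 960 samples for call sensitivity/specificity (≥ 0.95 required;
measured 1.0) and onset-delay recovery (within 2 sem of the configured
12 s); 20 noisy non-responders for bleach recovery (τ_b within 5%);
10,000 cells (short schedule) for class-frequency goodness of fit; 1,000
random traces for caller/oracle equivalence; exhaustive enumeration for
the exact tests (all no-tie U-test cases with n₁, n₂ ≤ 6; all sign-test
(n, k) with n ≤ 20).

## Known limitations

- Single-exponential bleaching only; dual-exponential decays will leave a
  residual trend (flagged by the fit's RMS residual, not corrected).
- The caller assumes near-uniform sampling (1% jitter tolerance) and takes
  dt as the median sample interval.
- Onset estimation is threshold-based; for very slow-rising responses the
  crossing lags the true onset.
- The spontaneous-activity detector cannot see the first 15 s of the
  recording (no trailing baseline exists yet).
- Frequencies pool cells across slices; no per-slice mixed-effects
  modelling.
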