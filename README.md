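# calslice

Calcium-imaging trace analysis for perfused acute-slice recordings.

Chemosensory experiments on acute airway tissue slices record intracellular
Ca²⁺ with a fluorescent indicator while tastants (a bitter compound such as
denatonium benzoate, artificial sweeteners such as sucralose, saccharin and
acesulfame-K) are washed over the tissue through a perfusion valve. The
questions such experiments answer are population questions: what fraction of
viable (ATP-responsive) cells responds to each compound, how much the
responder sets overlap, how responses scale with dose, and whether a
pharmacological treatment changes responder frequency. `calslice` implements
the full analysis chain for this kind of experiment, together with a
ground-truth synthetic recording generator so every stage is testable without
experimental data.

## The analysis

Per-ROI fluorescence traces F(t) are normalized as

    ΔF/F₀ = (F(t) − F₀) / F₀

with F₀ the mean fluorescence before the first stimulus. Photobleaching is
corrected by fitting C + B·exp(−t/τ_b) to the pooled mean of
baseline-normalized *non-responding* traces and dividing every raw trace by
the fitted decay (a two-pass scheme identifies the non-responders
automatically).

A (cell, stimulus) pair is called **responsive** iff

1. ΔF/F₀ exceeds the prestimulus mean + 3·SD (15 s window, n−1 SD) in one
   consecutive run lasting at least 5 s that begins within the post-valve
   search window,
2. the cell shows no response to the vehicle (Ringer's solution) application,
   and
3. the cell shows no spontaneous activity outside stimulus windows.

Calls aggregate into responder frequencies conditioned on ATP viability,
pairwise overlap (Venn) profiles, profile-grouped heat maps, within-cell
dose-response curves, and before/after treatment retention fractions. The
statistics layer provides Pearson χ² on 2×2 responder tables (no continuity
correction), the exact Wilcoxon-Mann-Whitney U test, the one-sample sign
test, and a Shapiro-Wilk/Jarque-Bera normality gate.

The synthetic generator emulates the recording physics: 1–2 Hz sampling,
per-cell baseline F₀, multiplicative exponential bleaching, Gaussian noise, a
piecewise-linear perfusion kernel (≈4 s valve-to-tissue delay, ≈10 s full
bath exchange), difference-of-exponentials Ca²⁺ transients with ≈11–12 s
second-messenger onset delays, Hill-scaled dose dependence, and cell classes
with overlapping response profiles — including movement-artifact
(Ringer-responsive) and spontaneously active cells that the exclusion rules
must catch.

## Worked example

```python
import calslice as cs

cfg = cs.default_config(n_cells=120, seed=42)
rec, truth = cs.generate_recording(cfg)       # Recording + GroundTruth
result = cs.analyze_recording(rec)            # normalize, bleach-correct, call

s = result.summary()
score = cs.score_against_truth(result.calls, truth)
```

which prints (via the formatting in the repository's example snippet):

```
cells analyzed: 115 of 120 (5 excluded)
ATP-responsive (viable): 83
bleach fit: A = 0.110, tau_b = 679 s (correction applied: True)
 denatonium: 31/83 = 37.3% of viable cells
  saccharin: 19/83 = 22.9% of viable cells
denatonium onset delay: 11.7 +/- 0.3 s (n = 31)
recovery vs ground truth: sensitivity 1.00, specificity 1.00
```

The 5 excluded cells are the simulated Ringer-responsive movement artifacts
and spontaneously active cells; the generator placed 37% denatonium and 23%
saccharin responders among the viable cells of this draw, and the pipeline
recovered every (cell, epoch) ground-truth label. The bleach fit recovers the
simulated decay (A = 0.1) from the non-responding cells alone.

The same pipeline runs from the shell on CSV trace tables (wide:
`time_s` + one column per cell; schedule sidecar) or TIFF stacks + label
masks:

```sh
calslice simulate --seed 1 --out-dir run/           # synthetic data + truth
calslice extract  --stack stack.tif --mask mask.tif --out-dir run/
calslice call     --traces run/traces.csv --out-dir run/
calslice analyze  --traces run/traces.csv --out-dir run/
```

Published count statistics are one call away:

```python
from calslice.stats import ContingencyTable2x2, chisq_2x2
chisq_2x2(ContingencyTable2x2(44, 5, 40, 7))
# TestResult(statistic=0.4824..., p_value=0.4874..., method='pearson-chi2 ...')
```

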