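# neuromon

Multimodal bedside brain-function monitoring analysis for **severe acute
supratentorial intracerebral hemorrhage** (ICH with coma: GCS ≤ 8 within
72 h of onset): quantitative EEG spectral indices, transcranial Doppler
(TCD) waveform indices, and a prognostic pipeline predicting death at 90
days. It is aimed at clinical neurophysiologists and biostatisticians who
want the full analysis chain — from raw multichannel signals to a fitted
prognostic model with ROC comparisons — as tested, scriptable Python.

No patient-level data are publicly available for this setting, so the
package ships a first-class synthetic-data module that generates EEG,
Doppler envelopes and cohort tables with the statistical structure the
analysis assumes; every downstream stage is exercised end to end without
any download.

## The indices and the model

**QEEG** (`neuromon.qeeg`). From a 16-channel 10–20 recording, band-pass
filtered 0.3–30 Hz and cleaned of high-amplitude artifact epochs, Welch
spectra give the relative powers of delta (1–3 Hz), theta (4–7 Hz), alpha
(8–13 Hz) and beta (14–30 Hz) — RDP, RTP, RAP, RBP — and the ratios

```
DAR = RDP / RAP          DTABR = (RDP + RTP) / (RAP + RBP)
```

which rise as cerebral blood flow and metabolism fall. The brain symmetry
index over N homologous left/right bipolar pairs and M frequency bins,

```
BSI = (1/M) Σ_j | (1/N) Σ_i (R_ij − L_ij) / (R_ij + L_ij) |,
```

ranges from 0 (symmetric) to 1 (one hemisphere silent).

**TCD** (`neuromon.tcd`). Per cardiac cycle of the middle-cerebral-artery
velocity envelope, the systolic peak Vs and end-diastolic minimum Vd give

```
Vm = (Vs − Vd)/3 + Vd        PI = (Vs − Vd) / Vm
```

with PI (Gosling pulsatility index) rising with downstream resistance and
intracranial pressure. Indices are labelled by hemisphere relative to the
hematoma: API/UPI are the affected/unaffected-side pulsatility indices.

**Prognosis** (`neuromon.prognosis`). A statsmodels-style model pair:
`MortalityModel.from_dataframe(df, candidates=...)` with 90-day death as
the outcome, whose `fit()` runs backward stepwise logistic regression
(Wald criterion, removal threshold p > 0.10) and returns a results object
with odds ratios, Wald 95 % CIs, the elimination log and `summary()`.
ROC curves use the Mann–Whitney AUC (ties ½) with DeLong variance;
`delong_test` compares correlated AUCs, and `compare_five_models` pits
GCS, hematoma volume, UPI and DAR alone against the combined UPI+DAR
logistic score.

**Cohort** (`neuromon.cohort`). Eligibility filtering with an itemised
exclusion tally, the bedside hematoma volume rule (length×width×depth / 2
for regular clots, / 3 for irregular), and the univariate screen: Pearson
chi-squared without continuity correction for binary variables, Student's
t or Wilcoxon rank-sum for continuous ones (Shapiro–Wilk gate), selection
at p ≤ 0.001.

## Worked example

```python
import numpy as np
from neuromon import synth, qeeg, prognosis

# EEG with the nonsurvivor band profile; recover the indices
t = np.array([0.744, 0.084, 0.095, 0.064]); t /= t.sum()
rec = synth.gen_eeg(synth.EEGGenSpec(target_relative_powers=tuple(t),
                                     duration=60.0, seed=1))
print(qeeg.summarize(rec).as_dict())
# {'rdp': 0.751, 'rtp': 0.088, 'rap': 0.096, 'rbp': 0.065,
#  'dar': 7.803, 'dtabr': 5.197, 'bsi': 0.030}

# cohort at the study's group sizes; stepwise model on UPI and DAR
df = synth.gen_cohort(synth.default_cohort_spec(seed=0))
fit = prognosis.MortalityModel.from_dataframe(
    df, candidates=["upi", "dar"]).fit()
print(fit.summary())
```

The recovered DAR (7.80) sits within 1 % of the construction target
0.744/0.095 = 7.83; BSI ≈ 0.03 because the generated hemispheres are
symmetric. The fit retains both predictors — at n = 47 with these group
separations both carry independent information — and reports, for this
seed:

```
  retained: upi, dar
       coef    se        or  or_ci_low  or_ci_high     p
  upi 9.821 3.098 18416.321     42.476 7984732.534 0.002
  dar 1.012 0.435     2.750      1.173       6.448 0.020
```

(The UPI odds ratio is per unit of PI; a unit is five times the
within-group SD of 0.2, hence the large number.) The five-model ROC
comparison on the same cohort:

```
  GCS              AUC 0.788 (0.661-0.916)
  hematoma volume  AUC 0.868 (0.770-0.967)
  UPI              AUC 0.903 (0.809-0.997)
  DAR              AUC 0.797 (0.670-0.923)
  UPI+DAR          AUC 0.952 (0.894-1.000)
```

The combined UPI+DAR score ranks first; at n = 47 its DeLong advantage
over each single model varies seed to seed, stabilising at larger n.

The same chain runs from a shell:

```bash
neuromon synth --kind cohort --out cohort.csv --seed 0
neuromon prognosis cohort.csv
neuromon run --seed 0 --out report/        # full pipeline + provenance
```

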