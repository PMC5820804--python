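# Methods

This note documents the models, numerical choices and known limitations of
the package; it is the place where genuinely open design decisions are
recorded. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Quantitative EEG chain

The processing chain is: zero-phase Butterworth band-pass 0.3–30 Hz
(order 4, applied forward–backward with even-reflection padding — odd
reflection kinks at signal extrema and leaks broadband transients through
the 0.3 Hz edge), per-epoch amplitude-based artifact rejection, Welch
spectra, band integration.

**Spectral estimation.** Welch with 2 s epochs, 50 % overlap, Hann window:
0.5 Hz resolution, enough to resolve the 1 Hz lower band edge. Epochs
intersecting the artifact mask are dropped before averaging. All three
settings are configurable; the values used are recorded in every output's
metadata.

**Band definitions.** The clinical band labels (delta 1–3, theta 4–7,
alpha 8–13, beta 14–30 Hz) leave the gap frequencies 3–4, 7–8 and 13–14 Hz
unassigned. We close each gap upward — delta [1,4), theta [4,8),
alpha [8,14), beta [14,30] — and assign a frequency bin to the band
containing its center. Both conventions are in the output metadata.

**Artifact rejection.** The criterion is ±200 µV on any channel within a
1 s epoch, the common clinical default; clinical reports rarely specify
more than that artifact-free segments were analysed. Both limit and epoch length are
parameters. An amplitude limit of 0 masks everything and raises an
explicit "no analyzable data" error rather than returning an empty
spectrum.

**Global relative power** is the unweighted mean of per-channel relative
powers; the pooled-power alternative (total band power over total 1–30 Hz
power across channels) is available behind `channel_mean=False`. The two
differ only when channels have very different total power. DAR and DTABR
are formed from the global fractions; because each channel's four
fractions share a denominator, forming DAR from channel-mean fractions or
from pooled powers coincides whenever channel totals are equal, and the
choice is recorded in metadata.

**BSI.** The printed formula places 1/N outside the norm with the inner
sum unnormalized; we implement the standard reading — the channel *mean*
asymmetry inside the absolute value — which keeps the index in [0,1]
regardless of N. Pairs default to the eight homologous left/right bipolar
derivations along the anterior–posterior chains of the 16-channel 10–20
montage (Fp1–F3 vs Fp2–F4, …); the pair list is explicit configuration,
never inferred from labels at runtime. Bins whose summed pair power falls
below 1e-12 of the median bin power are skipped and M reduced, avoiding
0/0 without biasing the index toward ±1. A time-resolved variant
(`bsi_timecourse`) averages window-wise BSI(t) over the recording.

Note a finite-sample property: with independent hemispheres the per-bin
asymmetry fluctuates around zero, so the absolute value gives a positive
floor that shrinks as (epochs × pairs)^(-1/2) — about 0.03 for 60 s
recordings at the default settings. Clinical BSI values (≈ 0.3–0.4) sit
far above this floor.

## TCD chain

Input is the device-exported velocity envelope, not raw Doppler spectra.
Beats are segmented by prominence-based systolic peak picking (prominence
one quarter of the envelope range, minimum spacing 60/max_rate s) with
diastolic minima between successive peaks and at the recording edges; a
beat is the interval between successive minima. Beats outside the
40–150 bpm physiologic window, or failing Vs > Vd, are dropped and
counted. Fewer than three valid beats raises an "unreadable waveform"
error.

**Noise-adaptive conditioning.** The envelope's measurement noise is
estimated from the Savitzky–Golay residual (window 21, order 2, robust
sigma from the median absolute residual). When it exceeds 0.1 % of the
envelope range, the trace is low-passed at 8 Hz (zero-phase) before
extreme extraction; otherwise the raw trace is used. Rationale: taking the
maximum of noisy samples biases Vs upward (and Vd downward) by the
expected extreme of the noise, inflating PI by several percent at 1 %
noise; smoothing removes the bias, while the gate keeps noiseless
round trips exact to machine precision. A clean envelope's residual sits
orders of magnitude below the gate.

**Averaging convention.** Vm and PI are computed per beat and then
averaged ("per-beat-first", the standard clinical convention); the
ratio-of-means alternative is behind `beat_first=False`. The two differ
because a mean of ratios is not the ratio of means; on identical beats
they coincide. Indices are averaged over the full valid recording; a
windowed variant is a matter of slicing the envelope before calling
`detect_beats`.

## Synthetic data

The generators define the conditions under which the pipeline is tested;
their defaults encode the source cohort's published group summaries.

**EEG.** A recording is the sum of four independent Gaussian processes,
one per band, each brick-wall band-limited in the frequency domain (a
zero-phase FFT filter) and scaled to a target share of the 1–30 Hz power.
Because the analysis chain itself smears power across band edges — the
Hann main lobe spans ±1 Hz at 2 s epochs, and the 0.3–30 Hz prefilter
attenuates the top of the beta band — the component weights are
pre-multiplied by the inverse of the analytically expected band-mixing
matrix (window kernel convolved with each band's flat spectrum, times the
squared zero-phase power response |H|⁴ of the prefilter). With this
compensation the *recovered* relative powers equal the targets to ≈ 0.01
absolute and DAR to ≈ 1 % at 60 s, shrinking with duration. The
compensation assumes the default analysis settings (recorded in the
recording's metadata) and is solved non-negatively, so extreme targets
(e.g. a pure single band) degrade gracefully. Asymmetry scales
right-hemisphere channels by √ratio per band, making the interhemispheric
power ratio — and hence the closed-form BSI |(r−1)/(r+1)| — controllable.

An earlier design band-limited the components with Butterworth filters;
its skirts plus the estimator's smearing biased recovered DAR low by
≈ 10 %, violating the generator's own round-trip contract, which is why
the brick-wall + compensation construction is used.

**TCD.** One cardiac cycle is a half-cosine systolic upstroke over 15 % of
the cycle followed by an exponential decay (time constant one third of the
cycle) re-pinned so it reaches Vd exactly at end-diastole. The period and
rise time are snapped to whole samples, so the noiseless sampled waveform
attains Vs and Vd exactly and round trips through beat detection to
machine precision; the realised heart rate (within one sample of the
requested one) is in the metadata. The template is a waveform-shape
stand-in, not a hemodynamic model: it reproduces the Vs/Vd semantics the
indices need and nothing else.

**Cohorts.** Within each outcome group, variables are sampled
independently from: normal (mean, SD) for symmetric variables; log-normal
for right-skewed ones, with µ = ln(median) and σ = ln(q3/q1)/(2·z₀.₇₅)
solved from the published median and IQR (non-negative, right-skewed,
matches a median-IQR summary); Bernoulli for proportions. The defaults
encode the published survivor/nonsurvivor summaries, including three
oddities kept as printed and flagged here rather than corrected: the
calcium and sodium rows carry each other's plausible ranges; age is
summarised as "median … ± SD" and is modeled normal; GCS is a median/IQR
summary of a discrete 3–8 score and is modeled as a rounded normal with
SD = IQR/1.349 clipped to the enrolment range. An optional `correlator`
hook can impose within-group correlation; the default is independence
because no correlation structure is published. Consequently the synthetic
combined-model advantage (UPI ⊥ DAR) is an *assumption*, and published
side/IVH rows inconsistent with the group sizes are not used anywhere.

**Screening roster.** Pseudo-patients each carry at most one exclusion
flag, matching the published funnel tallies (4 late admission, 2 surgical,
7 macrovascular stenosis, 5 prior cerebrovascular disease, 6 deficient
temporal window, 3 signal artifacts, 2 lost to follow-up; 47 enrolled of
76 screened). Records with several flags — possible for real data fed to
the filter — are counted once, itemised under the first-listed criterion.

What passing tests on these generators shows: the estimators recover known
truth under the assumed marginal structure. What they cannot show:
behaviour under real EEG nonstationarity, artifact morphology, correlated
covariates, or informative missingness — none of which the generators
emulate.

## Statistics

**Univariate screen.** Binary variables: Pearson chi-squared on the 2×2
table without Yates continuity correction — the convention that reproduces
the published contingency p-values exactly (the corrected variant is a
flag). Continuous variables: Shapiro–Wilk in each group at α = 0.05
decides Student's t (equal variances) versus Wilcoxon rank-sum. Selection is
p ≤ 0.001, inclusive. The reference analysis is ambiguous about which
test family serves normal variables; we implement the conventional
reading. Zero-variance variables are flagged and skipped; missing values
raise (no imputation by design).

**Backward stepwise logistic regression.** Starting from the screen's
survivors, the variable with the largest Wald p above the removal
threshold (default 0.10) is dropped and the model refit until all remain
below it — the reference analysis says only "backward stepwise", so the
Wald criterion and the 0.10 threshold are this package's conventional
choices; a likelihood-ratio elimination criterion is available
(`criterion="lr"`). Boundary contracts: removal_alpha = 1 keeps the full
model, 0 reduces to intercept-only. Fits use Newton with a BFGS fallback;
perfect prediction (all in-sample probabilities within 1e-4 of their
labels), non-convergence or a singular Hessian raise a separation error
naming the most-separating candidate (highest single-variable AUC). At
n = 47 with several strong predictors quasi-separation is a real
occurrence; the pipeline responds by dropping the named variable and
refitting, with a warning in the provenance log. Odds-ratio CIs are Wald
(matching the single-line OR/CI/p reporting style); fewer than five events
per candidate triggers a stability warning.

**ROC and DeLong.** The AUC is the Mann–Whitney estimator with ties ½,
computed from midranks; its variance, and the covariance of AUCs of paired
scores, use DeLong's placement-value estimator (variance of per-positive
and per-negative placements over their group sizes). The comparison
statistic is z = ΔAUC/SE with a two-sided normal p. Identical scores give
an estimated variance of zero; this degenerate case returns ΔAUC = 0,
z = 0, p = 1 explicitly instead of dividing by zero. CIs are Wald on the
AUC scale, clipped to [0,1]. The five-model comparison scores GCS
negatively (lower score = higher risk) and uses the in-sample fitted
probability of the UPI+DAR logistic fit as the combined score — no
cross-validation, matching the apparent published procedure; DeLong
p-values are reported unadjusted, and a Bonferroni factor is the caller's
one-liner. The published patient-level ORs (2.373, 5.306) and AUROCs
(0.776–0.949) are not reproducible without the patient data; the package
checks the qualitative claim (the combined model out-ranks each single
variable) on calibrated synthetic cohorts instead.

**Sensitivity mode.** Whether "excluding GCS and hematoma volume" in the
source analysis meant a sensitivity refit or a forced-exclusion rerun is
ambiguous; both are trivially expressible by editing `candidates`, so no
dedicated switch exists.

## Pipeline, formats, determinism

EEG travels as a plain-text multichannel CSV dialect (header comments with
sampling rate, units and JSON metadata; one column per channel), Doppler
envelopes as `time,velocity` CSV, cohorts as RFC-4180 CSV with a column
dictionary (`neuromon.cohort.COLUMN_DICTIONARY`). A binary biosignal
container was deliberately not used: the text dialect keeps fixtures
reviewable and diffs meaningful, and the source device's native format is
undocumented.

`RunConfig` (pydantic, unknown keys rejected) round-trips losslessly
through YAML; every output embeds the SHA-256 hash of the canonical config
(output directory excluded), and two runs with the same hash produce
byte-identical CSVs. All generator randomness flows from the single config
seed. The pipeline simulates raw signals for a configurable number of
patients per run (`n_signal_patients`, default 0) and re-measures their
Doppler indices through the full signal path, using table-level draws for
the rest — the signal path is exercised without simulating 47 × 30 min of
raw data on every run. Test and acceptance problem sizes (60 s EEG,
30 s envelopes, 2000/group cohorts, 200 stepwise replicates) were chosen
as the smallest at which the Monte-Carlo error is comfortably inside each
contract's tolerance.

## Known limitations

- The generators sample covariates independently within group; real
  neurophysiologic covariates are correlated (API with UPI, RDP with DAR).
- The EEG generator's compensation targets the default analysis settings;
  analysing its output with a different window or epoch length reintroduces
  a band-edge bias of a few percent.
- The TCD template has one systolic peak per cycle; dicrotic notches,
  arrhythmia and probe drift are out of scope, as is envelope extraction
  from raw Doppler spectra.
- In-sample fitted probabilities overstate the combined model's ROC
  advantage relative to out-of-sample evaluation; the package reproduces
  the published procedure and leaves cross-validation to the caller.
- No imputation: cohorts with missing covariates are rejected, not
  repaired.
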