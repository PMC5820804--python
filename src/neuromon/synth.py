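"""Synthetic EEG, Doppler envelopes and cohorts for the monitoring pipeline.

No patient-level data accompany the study this package operationalises, so
every downstream stage is exercised on synthetic inputs whose *statistical
structure* matches what the analysis assumes:

* :func:`gen_eeg` — multichannel scalp EEG built as a sum of independent
  band-limited noise processes (one per delta/theta/alpha/beta band), each
  scaled so its integrated 1–30 Hz power equals a target fraction.
  Right-hemisphere channels can be scaled per band to impose a controlled
  interhemispheric power ratio (for BSI round-trips).
* :func:`gen_tcd` — a pulsatile middle-cerebral-artery velocity envelope
  with a prescribed per-beat systolic peak Vs and end-diastolic minimum Vd:
  half-cosine systolic upstroke, exponential decay pinned to reach Vd at
  end-diastole.  Cardiac period and rise time are snapped to whole samples
  so the sampled waveform attains Vs and Vd exactly (the realised heart
  rate is recorded in metadata).
* :func:`gen_cohort` — per-patient covariate tables for survivors and
  nonsurvivors of severe supratentorial intracerebral hemorrhage, with the
  group marginals of the source cohort: normal for mean±SD variables,
  log-normal matched to median and IQR for right-skewed variables
  (hematoma volume, DAR, onset-to-monitoring time, ...), Bernoulli for
  proportions.  Covariates are sampled independently within group; an
  optional ``correlator`` hook can impose structure.
* :func:`gen_screening_roster` — the enrolment funnel: pseudo-patients
  carrying exactly one exclusion flag each, matching printed tallies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from .qeeg import DEFAULT_BANDS, MONTAGE_16, RIGHT_CHANNELS, EEGRecording
from .tcd import TCDEnvelope

__all__ = [
    "EEGGenSpec", "TCDGenSpec", "VariableSpec", "CohortGenSpec",
    "ExclusionTally", "EXCLUSION_CRITERIA",
    "gen_eeg", "gen_tcd", "gen_cohort", "gen_screening_roster",
    "default_cohort_spec", "lognormal_params_from_median_iqr",
]

BAND_NAMES = tuple(DEFAULT_BANDS)  # ("delta", "theta", "alpha", "beta")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass
class EEGGenSpec:
    """Recipe for a synthetic 10–20 EEG segment.

    ``target_relative_powers`` are the desired (delta, theta, alpha, beta)
    fractions of 1–30 Hz power, summing to 1.  ``asymmetry`` is the
    right/left power ratio, a scalar applied to every band or a per-band
    4-tuple; 1 means symmetric.  ``total_power`` sets the per-channel
    variance in µV² (cosmetic — every index downstream is gain-invariant).

    ``compensate_analysis`` pre-weights the band components for the known
    spectral smearing of the analysis chain (prefilter + Hann/Welch at the
    settings below), so the *recovered* relative powers — not merely the
    constructed ones — equal the targets.  The analysis settings assumed
    are the package defaults and are recorded in the output metadata.
    """

    target_relative_powers: tuple[float, float, float, float]
    fs: float = 250.0
    duration: float = 60.0
    n_channels: int = 16
    channel_labels: tuple[str, ...] = tuple(MONTAGE_16)
    asymmetry: float | tuple[float, float, float, float] = 1.0
    total_power: float = 100.0
    seed: int = 0
    compensate_analysis: bool = True
    analysis_epoch_len: float = 2.0
    analysis_window: str = "hann"
    analysis_prefilter: tuple[float, float] = (0.3, 30.0)
    analysis_prefilter_order: int = 4

    def __post_init__(self) -> None:
        t = np.asarray(self.target_relative_powers, dtype=float)
        if t.shape != (4,) or np.any(t < 0):
            raise ValueError("need 4 non-negative band fractions")
        if abs(t.sum() - 1.0) > 1e-9:
            raise ValueError("band fractions must sum to 1")
        if not self.fs >= 60.0:
            raise ValueError("fs must be at least 2 x 30 Hz")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("label count must match n_channels")
        a = self.asymmetry_per_band()
        if np.any(a < 0):
            raise ValueError("asymmetry ratios must be >= 0")

    def asymmetry_per_band(self) -> np.ndarray:
        a = np.asarray(self.asymmetry, dtype=float)
        return np.full(4, float(a)) if a.ndim == 0 else a


def _welch_band_mixing(fs: float, epoch_len: float, window: str,
                       prefilter: tuple[float, float] | None,
                       prefilter_order: int,
                       edges: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Expected measured band power per unit-variance brick-wall component.

    ``M[i, j]`` is the power the analysis chain attributes to band *i* when
    fed a unit-power process flat on band *j*'s support: the expected Welch
    periodogram is the true PSD (times the prefilter's squared zero-phase
    power response) convolved with the window's spectral kernel, summed over
    the 1–30 Hz bins assigned to each band by the bin-center rule.  Columns
    need not sum to 1 — power smeared outside 1–30 Hz, or removed by the
    prefilter, is genuinely lost to the measurement.
    """
    nper = int(round(epoch_len * fs))
    pad = 16 * nper
    w = sps.get_window(window, nper)
    Wk = np.abs(np.fft.fft(w, pad)) ** 2
    sumw2 = float(np.sum(w ** 2))
    nu = np.fft.fftfreq(pad, 1.0 / fs)
    if prefilter is not None:
        sos = sps.butter(prefilter_order, list(prefilter), btype="bandpass",
                         fs=fs, output="sos")
        _, H = sps.sosfreqz(sos, worN=np.abs(nu), fs=fs)
        filt_pow = np.abs(H) ** 4          # filtfilt doubles the response
    else:
        filt_pow = np.ones_like(nu)
    bins = np.arange(1.0, 30.0 + 1e-9, 1.0 / epoch_len)
    shifts = np.round(bins * pad / fs).astype(int)
    M = np.zeros((len(edges), len(edges)))
    for j, (lo, hi) in enumerate(edges):
        S2 = ((np.abs(nu) >= lo) & (np.abs(nu) < hi)).astype(float)
        S2 /= S2.sum() * (fs / pad)        # unit total variance
        S2 *= filt_pow
        ep = np.array([np.sum(S2 * np.roll(Wk, s)) for s in shifts])
        ep *= 2.0 * (fs / pad) / (fs * sumw2)   # one-sided density at bins
        for i, (a, b) in enumerate(edges):
            sel = (bins >= a) & ((bins < b) if i < len(edges) - 1
                                 else (bins <= b))
            M[i, j] = ep[sel].sum() / epoch_len
    return M


def _component_weights(spec: EEGGenSpec) -> np.ndarray:
    """Per-band component variances realising the target fractions."""
    t = np.asarray(spec.target_relative_powers, dtype=float)
    if not spec.compensate_analysis:
        return t.copy()
    M = _welch_band_mixing(spec.fs, spec.analysis_epoch_len,
                           spec.analysis_window, spec.analysis_prefilter,
                           spec.analysis_prefilter_order,
                           tuple(DEFAULT_BANDS.values()))
    from scipy.optimize import nnls
    w, _ = nnls(M, t)        # = exact solve when the solution is feasible
    if w.sum() <= 0:
        return t.copy()
    return w / w.sum()


def gen_eeg(spec: EEGGenSpec) -> EEGRecording:
    """Synthesise EEG as a sum of independent band-limited noise processes.

    Each band component is white Gaussian noise brick-wall limited to the
    band's support in the frequency domain (a zero-phase FFT filter), then
    rescaled so its realised variance — its integrated 1–30 Hz power, since
    the component lives inside the band — matches its weight.  With
    ``compensate_analysis`` the weights additionally undo the analysis
    chain's expected band mixing so the recovered fractions hit the targets
    (see :func:`_welch_band_mixing`).  Right-hemisphere channels are scaled
    by ``sqrt(asymmetry)`` per band so the interhemispheric *power* ratio
    equals the requested asymmetry.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    asym = spec.asymmetry_per_band()
    right = {lab for lab in spec.channel_labels if lab in RIGHT_CHANNELS}
    weights = _component_weights(spec)
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    data = np.zeros((spec.n_channels, n))
    for b, (name, wgt) in enumerate(zip(BAND_NAMES, weights)):
        if wgt == 0:
            continue
        lo, hi = DEFAULT_BANDS[name]
        white = rng.standard_normal((spec.n_channels, n))
        X = np.fft.rfft(white, axis=1)
        X[:, ~((freqs >= lo) & (freqs < hi))] = 0.0
        comp = np.fft.irfft(X, n=n, axis=1)
        sd = comp.std(axis=1, keepdims=True)
        comp /= np.where(sd > 0, sd, 1.0)                  # unit power
        comp *= math.sqrt(wgt * spec.total_power)
        for c, lab in enumerate(spec.channel_labels):
            if lab in right:
                comp[c] *= math.sqrt(asym[b])
        data += comp
    meta = {
        "generator": "gen_eeg",
        "seed": spec.seed,
        "targets": list(spec.target_relative_powers),
        "component_weights": weights.tolist(),
        "asymmetry": asym.tolist(),
        "band_edges_hz": {k: list(v) for k, v in DEFAULT_BANDS.items()},
        "filter": {"family": "fft-brickwall", "zero_phase": True},
        "compensated_for": None if not spec.compensate_analysis else {
            "epoch_len_s": spec.analysis_epoch_len,
            "window": spec.analysis_window,
            "prefilter_hz": list(spec.analysis_prefilter),
            "prefilter_order": spec.analysis_prefilter_order,
        },
    }
    return EEGRecording(data=data, fs=spec.fs,
                        channel_labels=list(spec.channel_labels), meta=meta)


# ---------------------------------------------------------------------------
# TCD
# ---------------------------------------------------------------------------

@dataclass
class TCDGenSpec:
    """Recipe for a pulsatile velocity envelope (cm/s)."""

    vs: float
    vd: float
    heart_rate: float = 72.0
    fs: float = 100.0
    duration: float = 30.0
    velocity_noise_sd: float = 0.0
    side: str = "left"
    rise_fraction: float = 0.15   # systolic upstroke as fraction of the cycle
    decay_tau_fraction: float = 1 / 3  # decay time constant / cycle length
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.vs > self.vd >= 0):
            raise ValueError("require vs > vd >= 0")
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        if self.duration <= 0 or self.fs <= 20:
            raise ValueError("need positive duration and fs > 20 Hz")


def _beat_template(n_period: int, n_rise: int, vs: float, vd: float,
                   tau: float) -> np.ndarray:
    """One cardiac cycle sampled on ``n_period`` points, starting at
    end-diastole (vd), peaking at sample ``n_rise`` (vs), decaying back so
    the next cycle starts again exactly at vd."""
    t = np.arange(n_period, dtype=float)
    beat = np.empty(n_period)
    rise = t[:n_rise + 1] / n_rise
    beat[:n_rise + 1] = vd + (vs - vd) * 0.5 * (1 - np.cos(np.pi * rise))
    s = t[n_rise:] - n_rise
    n_decay = n_period - n_rise
    e = np.exp(-s / tau)
    e_end = math.exp(-n_decay / tau)
    beat[n_rise:] = vd + (vs - vd) * (e - e_end) / (1.0 - e_end)
    return beat


def gen_tcd(spec: TCDGenSpec) -> TCDEnvelope:
    """Synthesise a velocity envelope with per-beat extremes (vs, vd).

    Shape: half-cosine systolic upstroke over ``rise_fraction`` of the
    cycle, then an exponential decay (time constant ``decay_tau_fraction``
    of the cycle) pinned to hit vd exactly at end-diastole.  The period and
    rise time are rounded to whole samples, so with zero noise every
    sampled beat attains vs and vd exactly; the realised heart rate is in
    ``meta['heart_rate_realised']``.
    """
    rng = np.random.default_rng(spec.seed)
    n_period = max(int(round(spec.fs * 60.0 / spec.heart_rate)), 4)
    n_rise = min(max(int(round(spec.rise_fraction * n_period)), 1), n_period - 2)
    tau = spec.decay_tau_fraction * n_period
    beat = _beat_template(n_period, n_rise, spec.vs, spec.vd, tau)
    n = int(round(spec.duration * spec.fs))
    reps = int(np.ceil(n / n_period)) + 1
    v = np.tile(beat, reps)[:n]
    if spec.velocity_noise_sd > 0:
        v = v + rng.normal(0.0, spec.velocity_noise_sd, size=n)
    meta = {
        "generator": "gen_tcd", "seed": spec.seed,
        "vs": spec.vs, "vd": spec.vd,
        "heart_rate_requested": spec.heart_rate,
        "heart_rate_realised": 60.0 * spec.fs / n_period,
        "template": {"shape": "half-cosine rise / pinned exponential decay",
                     "rise_fraction": spec.rise_fraction,
                     "decay_tau_fraction": spec.decay_tau_fraction},
        "velocity_noise_sd": spec.velocity_noise_sd,
    }
    return TCDEnvelope(velocity=v, fs=spec.fs, side=spec.side, meta=meta)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def lognormal_params_from_median_iqr(median: float, q1: float, q3: float
                                     ) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and interquartile
    range: mu = ln(median), sigma = ln(q3/q1) / (2 * z_0.75)."""
    if not (0 < q1 <= median <= q3) or q1 == q3:
        raise ValueError("require 0 < q1 <= median <= q3 with q1 < q3")
    z75 = norm.ppf(0.75)
    return math.log(median), math.log(q3 / q1) / (2.0 * z75)


@dataclass
class VariableSpec:
    """Marginal distribution of one covariate, per outcome group.

    ``dist`` is one of:

    * ``"normal"`` — params ``(mean, sd)`` per group;
    * ``"lognormal"`` — params ``(median, q1, q3)`` per group, converted via
      :func:`lognormal_params_from_median_iqr`;
    * ``"binary"`` — params ``(proportion,)`` per group.

    ``survivors`` / ``nonsurvivors`` hold the group parameter tuples.
    ``integer`` rounds the draws; ``clip`` bounds them (applied after
    rounding, e.g. GCS limited to the enrolment range).
    """

    dist: str
    survivors: tuple
    nonsurvivors: tuple
    integer: bool = False
    clip: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "lognormal", "binary"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        for p in (self.survivors, self.nonsurvivors):
            if self.dist == "normal" and not p[1] > 0:
                raise ValueError("normal sd must be > 0")
            if self.dist == "binary" and not 0 <= p[0] <= 1:
                raise ValueError("proportion must be in [0, 1]")
            if self.dist == "lognormal":
                lognormal_params_from_median_iqr(*p)  # validates

    def sample(self, n: int, group: str, rng: np.random.Generator) -> np.ndarray:
        p = self.survivors if group == "survivor" else self.nonsurvivors
        if self.dist == "normal":
            x = rng.normal(p[0], p[1], n)
        elif self.dist == "lognormal":
            mu, sigma = lognormal_params_from_median_iqr(*p)
            x = rng.lognormal(mu, sigma, n)
        else:
            x = rng.binomial(1, p[0], n).astype(float)
        if self.integer:
            x = np.round(x)
        if self.clip is not None:
            x = np.clip(x, *self.clip)
        return x


@dataclass
class CohortGenSpec:
    """Group sizes plus the per-variable marginal map."""

    n_survivors: int
    n_nonsurvivors: int
    variables: Mapping[str, VariableSpec]
    correlator: Callable[[pd.DataFrame, str, np.random.Generator],
                         pd.DataFrame] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survivors <= 0 or self.n_nonsurvivors <= 0:
            raise ValueError("group sizes must be positive")


def default_cohort_spec(n_survivors: int = 21, n_nonsurvivors: int = 26,
                        seed: int = 0) -> CohortGenSpec:
    """Generator defaults calibrated to the study cohort's group summaries.

    Mean±SD rows are normal, median(IQR) rows log-normal, counts Bernoulli;
    group order in each VariableSpec is (survivors, nonsurvivors).  The
    printed calcium/sodium rows carry each other's plausible units; they
    are reproduced as printed (the screen treats them like any covariate).
    """
    V = VariableSpec
    variables = {
        "age": V("normal", (68.8, 12.5), (64.1, 12.4)),
        "male": V("binary", (9 / 21,), (14 / 26,)),
        "hypertension": V("binary", (18 / 21,), (23 / 26,)),
        "diabetes": V("binary", (3 / 21,), (4 / 26,)),
        "hyperlipidemia": V("binary", (8 / 21,), (5 / 26,)),
        "coronary_disease": V("binary", (6 / 21,), (7 / 26,)),
        "smoking": V("binary", (5 / 21,), (10 / 26,)),
        "excessive_drinking": V("binary", (4 / 21,), (7 / 26,)),
        "onset_to_monitor_h": V("lognormal", (39.0, 19.0, 65.0),
                                (26.0, 18.8, 46.0)),
        "gcs": V("normal", (7.0, (8.0 - 7.0) / 1.349), (6.0, (7.0 - 4.0) / 1.349),
                 integer=True, clip=(3, 8)),
        "sbp": V("normal", (175.3, 25.9), (162.7, 32.4)),
        "dbp": V("normal", (90.5, 18.1), (80.9, 23.0)),
        "wbc": V("normal", (12.5, 4.2), (13.3, 2.8)),
        "platelet": V("normal", (205.4, 74.5), (192.5, 83.2)),
        "aptt": V("normal", (29.1, 3.7), (29.0, 3.1)),
        "inr": V("normal", (0.98, 0.09), (1.01, 0.10)),
        "glucose": V("lognormal", (7.2, 6.8, 9.6), (7.7, 6.7, 9.2)),
        "potassium": V("normal", (3.6, 0.4), (3.7, 0.4)),
        "calcium": V("normal", (141.6, 6.2), (141.0, 4.9)),
        "sodium": V("lognormal", (2.2, 2.1, 2.3), (2.2, 2.1, 2.3)),
        "hematoma_volume": V("lognormal", (25.0, 19.6, 39.6),
                             (62.8, 44.1, 90.1)),
        # TCD, affected (A*) and unaffected (U*) hemisphere
        "avs": V("normal", (84.9, 18.4), (85.6, 23.9)),
        "uvs": V("normal", (89.5, 21.8), (91.2, 23.0)),
        "avm": V("normal", (46.3, 10.5), (43.8, 13.6)),
        "uvm": V("normal", (51.7, 12.7), (48.0, 12.9)),
        "avd": V("normal", (27.6, 7.0), (23.6, 9.9)),
        "uvd": V("normal", (33.0, 8.9), (26.6, 8.7)),
        "api": V("normal", (1.2, 0.2), (1.5, 0.2)),
        "upi": V("normal", (1.1, 0.2), (1.4, 0.2)),
        # QEEG (relative powers in percent, as reported)
        "rdp": V("lognormal", (70.0, 67.7, 73.1), (74.4, 72.5, 78.2)),
        "rtp": V("lognormal", (9.5, 8.2, 12.0), (8.4, 7.2, 10.1)),
        "rap": V("lognormal", (11.9, 10.2, 13.2), (9.5, 8.4, 10.8)),
        "rbp": V("lognormal", (7.1, 4.2, 8.7), (6.4, 5.0, 7.5)),
        "dar": V("lognormal", (6.1, 5.4, 6.9), (7.8, 6.8, 9.4)),
        "dtabr": V("lognormal", (4.3, 3.7, 4.8), (5.1, 4.6, 6.0)),
        "bsi": V("lognormal", (0.36, 0.31, 0.40), (0.38, 0.33, 0.40)),
    }
    return CohortGenSpec(n_survivors=n_survivors, n_nonsurvivors=n_nonsurvivors,
                         variables=variables, seed=seed)


def gen_cohort(spec: CohortGenSpec) -> pd.DataFrame:
    """Sample a cohort table; ``died90`` is 1 for the nonsurvivor group.

    Covariates are independent within group unless ``spec.correlator`` is
    set, in which case it receives each group's frame and may reshape it.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in (("survivor", spec.n_survivors),
                     ("nonsurvivor", spec.n_nonsurvivors)):
        cols = {name: vs.sample(n, group, rng)
                for name, vs in spec.variables.items()}
        df = pd.DataFrame(cols)
        if spec.correlator is not None:
            df = spec.correlator(df, group, rng)
        df["died90"] = int(group == "nonsurvivor")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "patient_id", np.arange(1, len(out) + 1))
    return out


# ---------------------------------------------------------------------------
# screening funnel
# ---------------------------------------------------------------------------

#: Exclusion criteria in the order the funnel reports them.
EXCLUSION_CRITERIA = [
    "late_admission",            # admission beyond 72 h from onset
    "surgical_procedure",
    "macrovascular_stenosis",
    "previous_cerebrovascular_disease",
    "deficient_temporal_window",
    "signal_artifacts",
    "lost_to_follow_up",
]


@dataclass
class ExclusionTally:
    """Counts per exclusion criterion, in reporting order."""

    late_admission: int = 0
    surgical_procedure: int = 0
    macrovascular_stenosis: int = 0
    previous_cerebrovascular_disease: int = 0
    deficient_temporal_window: int = 0
    signal_artifacts: int = 0
    lost_to_follow_up: int = 0

    def __post_init__(self) -> None:
        if any(getattr(self, c) < 0 for c in EXCLUSION_CRITERIA):
            raise ValueError("tallies must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return {c: int(getattr(self, c)) for c in EXCLUSION_CRITERIA}

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())


#: The printed enrolment funnel of the source cohort: 76 screened, 29
#: excluded, 47 enrolled.
PRINTED_FUNNEL = ExclusionTally(4, 2, 7, 5, 6, 3, 2)


def gen_screening_roster(tally: ExclusionTally, n_enrolled: int,
                         seed: int = 0) -> pd.DataFrame:
    """Roster of screened pseudo-patients with one exclusion flag each.

    Returns a frame with ``patient_id`` plus one boolean column per
    criterion; eligible records carry no flag.  Row order is shuffled
    deterministically by ``seed`` so eligibility filtering cannot rely on
    block structure.
    """
    if n_enrolled < 0:
        raise ValueError("n_enrolled must be non-negative")
    rows = []
    for crit in EXCLUSION_CRITERIA:
        rows += [crit] * getattr(tally, crit)
    rows += [None] * n_enrolled
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    df = pd.DataFrame({"patient_id": np.arange(1, len(rows) + 1)})
    for crit in EXCLUSION_CRITERIA:
        df[crit] = False
    for new_pos, old in enumerate(order):
        if rows[old] is not None:
            df.loc[new_pos, rows[old]] = True
    return df
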