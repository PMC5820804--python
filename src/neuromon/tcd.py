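"""Transcranial Doppler (TCD) waveform indices.

Works on middle-cerebral-artery velocity *envelopes* (the device-exported
peak-velocity trace, cm/s), not raw Doppler spectra.  Per beat the systolic
peak velocity Vs and end-diastolic velocity Vd are read off the waveform;
from them:

    Vm = (Vs - Vd)/3 + Vd        (mean flow velocity)
    PI = (Vs - Vd)/Vm            (Gosling pulsatility index)

PI rises with downstream cerebrovascular resistance and intracranial
pressure, which is why the unaffected-hemisphere PI (UPI) is a mortality
marker in severe intracerebral hemorrhage.  Sides are labelled affected
(hematoma-bearing) / unaffected from the hematoma side, giving the AVs/AVm/
AVd/API and UVs/UVm/UVd/UPI summaries.

Summary indices use the per-beat-first convention: Vm and PI are computed
for every beat and then averaged (mean-of-ratios), the standard clinical
reading; ``beat_first=False`` gives the ratio-of-means alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TCDEnvelope", "BeatSet", "SideIndices", "TCDIndices",
    "UnreadableWaveformError",
    "detect_beats", "mean_velocity", "pulsatility_index", "hemisphere_summary",
]


class UnreadableWaveformError(ValueError):
    """Raised when an envelope yields fewer than three valid cardiac cycles."""


@dataclass
class TCDEnvelope:
    """One hemisphere's velocity envelope.

    ``velocity`` is in cm/s at sampling rate ``fs`` (> 20 Hz).  The optional
    ``insonation_depth`` (mm) is metadata; the optimal MCA signal is found at
    50–60 mm and values outside that range are rejected when provided.
    """

    velocity: np.ndarray
    fs: float
    side: str = "left"
    insonation_depth: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 1:
            raise ValueError("velocity must be 1-D")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity must be finite")
        if not self.fs > 20.0:
            raise ValueError("sampling rate must exceed 20 Hz")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.insonation_depth is not None and not (
                50.0 <= self.insonation_depth <= 60.0):
            raise ValueError("insonation depth must lie in [50, 60] mm")

    @property
    def duration(self) -> float:
        return self.velocity.size / self.fs


@dataclass
class BeatSet:
    """Beat boundaries (diastolic-minimum sample indices) and per-beat Vs/Vd."""

    boundaries: np.ndarray       # len n_beats+1, strictly increasing
    vs: np.ndarray               # per-beat systolic peak, cm/s
    vd: np.ndarray               # per-beat end-diastolic minimum, cm/s
    fs: float = np.nan
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        self.vs = np.asarray(self.vs, dtype=float)
        self.vd = np.asarray(self.vd, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("beat boundaries must be strictly increasing")
        if len(self.vs) != len(self.vd) or len(self.vs) != len(self.boundaries) - 1:
            raise ValueError("need one (vs, vd) pair per beat interval")
        if np.any(self.vs <= self.vd):
            raise ValueError("each beat requires vs > vd")

    @property
    def n_beats(self) -> int:
        return len(self.vs)


@dataclass
class SideIndices:
    """Beat-averaged indices for one hemisphere."""

    vs: float
    vd: float
    vm: float
    pi: float
    n_beats: int

    def __post_init__(self) -> None:
        if not (self.vd <= self.vm <= self.vs):
            raise ValueError("require vd <= vm <= vs")


@dataclass
class TCDIndices:
    """Bilateral indices with affected/unaffected assignment.

    ``affected_side`` is the hematoma-bearing hemisphere.  ``labelled()``
    returns the clinical A*/U* naming (AVs, AVm, AVd, API; UVs, UVm, UVd,
    UPI).  A missing hemisphere (failed insonation) leaves that side None
    and sets ``unilateral``.
    """

    left: SideIndices | None
    right: SideIndices | None
    affected_side: str

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        if self.left is None and self.right is None:
            raise ValueError("at least one hemisphere required")

    @property
    def unilateral(self) -> bool:
        return self.left is None or self.right is None

    @property
    def affected(self) -> SideIndices | None:
        return self.left if self.affected_side == "left" else self.right

    @property
    def unaffected(self) -> SideIndices | None:
        return self.right if self.affected_side == "left" else self.left

    def labelled(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for prefix, side in (("a", self.affected), ("u", self.unaffected)):
            if side is None:
                continue
            out[f"{prefix}vs"] = side.vs
            out[f"{prefix}vm"] = side.vm
            out[f"{prefix}vd"] = side.vd
            out[f"{prefix}pi"] = side.pi
        return out


# ---------------------------------------------------------------------------

def mean_velocity(vs: float, vd: float) -> float:
    """Mean flow velocity, Vm = (Vs - Vd)/3 + Vd."""
    if vd < 0 or vs < vd:
        raise ValueError("require vs >= vd >= 0")
    return (vs - vd) / 3.0 + vd


def pulsatility_index(vs: float, vd: float, vm: float | None = None) -> float:
    """Gosling pulsatility index, PI = (Vs - Vd)/Vm.

    ``vm`` defaults to the mean velocity computed from vs and vd.
    """
    if vm is None:
        vm = mean_velocity(vs, vd)
    if vm <= 0:
        raise ValueError("mean velocity must be positive")
    return (vs - vd) / vm


def detect_beats(env: TCDEnvelope, min_rate: float = 40.0,
                 max_rate: float = 150.0) -> BeatSet:
    """Segment a velocity envelope into cardiac cycles.

    Systolic peaks are found by prominence-based peak picking (prominence a
    quarter of the envelope's amplitude range, minimum inter-peak distance
    ``60/max_rate`` s); a beat is the interval between successive diastolic
    minima, each containing one systolic peak.  Beats whose duration falls
    outside the [min_rate, max_rate] bpm window or which fail vs > vd are
    dropped and counted.  Fewer than three valid beats raises
    :class:`UnreadableWaveformError`.
    """
    v = env.velocity
    if min_rate <= 0 or max_rate <= min_rate:
        raise ValueError("require 0 < min_rate < max_rate")
    vrange = float(np.ptp(v))
    if vrange <= 0:
        raise UnreadableWaveformError("constant velocity trace — no beats")
    # Noise-adaptive conditioning: estimate measurement noise from the
    # Savitzky-Golay residual; a clean envelope's residual is orders of
    # magnitude below this gate, so noiseless traces are analysed verbatim
    # (keeping per-beat extremes exact) while noisy ones are low-passed to
    # suppress the extreme-value bias of picking maxima of noise.
    if v.size >= 25:
        resid = v - sps.savgol_filter(v, 21, 2)
        noise_sd = 1.4826 * float(np.median(np.abs(resid)))
        if noise_sd > 1e-3 * vrange:
            sos = sps.butter(4, min(8.0, 0.4 * env.fs / 2), btype="low",
                             fs=env.fs, output="sos")
            v = sps.sosfiltfilt(sos, v, padtype="even")
    dist = max(int(round(env.fs * 60.0 / max_rate)), 1)
    peaks, _ = sps.find_peaks(v, distance=dist, prominence=0.25 * vrange)
    if len(peaks) < 3:
        raise UnreadableWaveformError(
            f"only {len(peaks)} systolic peaks found; need >= 3 cycles")
    # diastolic minima: between consecutive systolic peaks, plus the edge
    # segments before the first and after the last peak (the rate-window
    # filter below drops truncated edge beats)
    minima = [p0 + int(np.argmin(v[p0:p1]))
              for p0, p1 in zip(peaks[:-1], peaks[1:])]
    if peaks[0] > 0:
        minima.insert(0, int(np.argmin(v[:peaks[0]])))
    if peaks[-1] < v.size - 1:
        minima.append(peaks[-1] + int(np.argmin(v[peaks[-1]:])))
    minima = np.array(minima)
    lo_len, hi_len = env.fs * 60.0 / max_rate, env.fs * 60.0 / min_rate
    kept, dropped = [], 0
    for m0, m1 in zip(minima[:-1], minima[1:]):
        beat_vs = float(np.max(v[m0:m1 + 1]))
        beat_vd = float(v[m1])  # end-diastolic: minimum before next upstroke
        if (lo_len <= m1 - m0 <= hi_len) and beat_vs > beat_vd:
            kept.append((int(m0), int(m1), beat_vs, beat_vd))
        else:
            dropped += 1
    if len(kept) < 3:
        raise UnreadableWaveformError(
            f"only {len(kept)} valid beats (dropped {dropped}); need >= 3")
    # Boundary i..i+1 delimits kept beat i; after a dropped beat the interval
    # also spans the gap, but the stored (vs, vd) are the kept beat's values.
    boundaries = np.array([kept[0][0]] + [k[1] for k in kept])
    return BeatSet(boundaries=boundaries,
                   vs=np.array([k[2] for k in kept]),
                   vd=np.array([k[3] for k in kept]),
                   fs=env.fs, n_dropped=dropped)


def beat_indices(beats: BeatSet, beat_first: bool = True) -> SideIndices:
    """Average per-beat indices into one hemisphere summary.

    With ``beat_first`` (default) Vm and PI are computed per beat and then
    averaged; otherwise they are derived from the averaged Vs and Vd.
    """
    vs_m = float(beats.vs.mean())
    vd_m = float(beats.vd.mean())
    if beat_first:
        vm_b = np.array([mean_velocity(s, d) for s, d in zip(beats.vs, beats.vd)])
        pi_b = np.array([pulsatility_index(s, d, m)
                         for s, d, m in zip(beats.vs, beats.vd, vm_b)])
        vm_m, pi_m = float(vm_b.mean()), float(pi_b.mean())
    else:
        vm_m = mean_velocity(vs_m, vd_m)
        pi_m = pulsatility_index(vs_m, vd_m, vm_m)
    return SideIndices(vs=vs_m, vd=vd_m, vm=vm_m, pi=pi_m, n_beats=beats.n_beats)


def hemisphere_summary(beats_left: BeatSet | None, beats_right: BeatSet | None,
                       hematoma_side: str, beat_first: bool = True) -> TCDIndices:
    """Bilateral summary with affected/unaffected labelling.

    Either side may be ``None`` (failed insonation); the result is then
    explicitly unilateral.  Each present side needs >= 3 valid beats.
    """
    def side(beats):
        if beats is None:
            return None
        if beats.n_beats < 3:
            raise UnreadableWaveformError("need >= 3 valid beats per side")
        return beat_indices(beats, beat_first=beat_first)

    return TCDIndices(left=side(beats_left), right=side(beats_right),
                      affected_side=hematoma_side)
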