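"""File formats, run configuration and the end-to-end pipeline.

Signal interface
----------------
EEG travels in a plain-text multichannel CSV dialect: comment lines
(``# key=value``) carry the sampling rate, units and JSON metadata, the
header row carries the channel labels, and each subsequent row is one
sample across channels.  Doppler envelopes use two-column CSV
``time,velocity`` (seconds, cm/s); the sampling rate is taken from a
``# fs=`` header when present and inferred from the timestamps otherwise.
Cohort tables are RFC-4180 CSV with the column dictionary of
:mod:`neuromon.cohort`.

Configuration
-------------
:class:`RunConfig` is a pydantic model with a recorded default for every
parameter; unknown keys are errors.  It round-trips losslessly through
YAML/JSON, and every pipeline output embeds the SHA-256 hash of the
canonical config so a report is reproducible byte for byte from its
provenance block.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .qeeg import EEGRecording
from .tcd import TCDEnvelope

__all__ = [
    "read_eeg_csv", "write_eeg_csv", "read_tcd_csv", "write_tcd_csv",
    "QEEGParams", "TCDParams", "StatsParams", "SynthParams", "RunConfig",
    "run_pipeline",
]

_EEG_MAGIC = "neuromon-eeg v1"


# ---------------------------------------------------------------------------
# signal files
# ---------------------------------------------------------------------------

def write_eeg_csv(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to the text dialect (lossless at float repr)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {_EEG_MAGIC}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write("# units=uV\n")
        fh.write(f"# meta={json.dumps(rec.meta, default=str)}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.10g")
    return path


def read_eeg_csv(path: str | Path) -> EEGRecording:
    """Read the text dialect back into an :class:`EEGRecording`."""
    path = Path(path)
    fs, meta = None, {}
    header_lines = 0
    labels = None
    with open(path) as fh:
        for line in fh:
            header_lines += 1
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("meta="):
                    meta = json.loads(body[5:])
                continue
            labels = [c.strip() for c in line.split(",")]
            break
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header — sampling rate required")
    if labels is None:
        raise ValueError(f"{path}: no channel header row")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate channel label(s) {dupes}")
    data = np.loadtxt(path, delimiter=",", skiprows=header_lines, ndmin=2)
    return EEGRecording(data=data.T, fs=fs, channel_labels=labels, meta=meta)


def write_tcd_csv(env: TCDEnvelope, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(env.velocity.size) / env.fs
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={env.fs!r}\n")
        fh.write(f"# side={env.side}\n")
        fh.write(f"# meta={json.dumps(env.meta, default=str)}\n")
        fh.write("time,velocity\n")
        np.savetxt(fh, np.column_stack([t, env.velocity]),
                   delimiter=",", fmt="%.10g")
    return path


def read_tcd_csv(path: str | Path, side: str | None = None) -> TCDEnvelope:
    """Read a (time, velocity) CSV; fs from header or median timestamp step."""
    path = Path(path)
    fs, meta, file_side = None, {}, None
    skip = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("#"):
                skip += 1
                body = s[1:].strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("side="):
                    file_side = body[5:]
                elif body.startswith("meta="):
                    meta = json.loads(body[5:])
            else:
                break
    df = pd.read_csv(path, skiprows=skip)
    cols = {c.lower().strip(): c for c in df.columns}
    if "velocity" not in cols:
        raise ValueError(f"{path}: need a 'velocity' column")
    if fs is None:
        if "time" not in cols:
            raise ValueError(f"{path}: no '# fs=' header and no time column")
        dt = np.median(np.diff(df[cols["time"]].to_numpy(float)))
        if not dt > 0:
            raise ValueError(f"{path}: cannot infer sampling rate from timestamps")
        fs = 1.0 / dt
    return TCDEnvelope(velocity=df[cols["velocity"]].to_numpy(float), fs=fs,
                       side=side or file_side or "left", meta=meta)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QEEGParams(_Strict):
    low_hz: float = 0.3
    high_hz: float = 30.0
    amplitude_limit_uv: float = 200.0
    artifact_epoch_len_s: float = 1.0
    epoch_len_s: float = 2.0
    overlap: float = 0.5
    window: str = "hann"
    channel_mean: bool = True


class TCDParams(_Strict):
    min_rate_bpm: float = 40.0
    max_rate_bpm: float = 150.0
    beat_first: bool = True


class StatsParams(_Strict):
    selection_alpha: float = 0.001
    removal_alpha: float = 0.10
    shapiro_alpha: float = 0.05
    criterion: str = "wald"


class SynthParams(_Strict):
    n_survivors: int = 21
    n_nonsurvivors: int = 26
    #: patients per group for which raw EEG/TCD signals are simulated and
    #: re-analysed (signal-level round trip); the rest use table-level draws.
    n_signal_patients: int = 0
    eeg_duration_s: float = 60.0
    screening_tallies: list[int] = Field(
        default_factory=lambda: [4, 2, 7, 5, 6, 3, 2])


class RunConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "neuromon_out"
    cohort_csv: str | None = None   # use an existing cohort instead of synth
    synth: SynthParams = Field(default_factory=SynthParams)
    qeeg: QEEGParams = Field(default_factory=QEEGParams)
    tcd: TCDParams = Field(default_factory=TCDParams)
    stats: StatsParams = Field(default_factory=StatsParams)

    def canonical_json(self) -> str:
        """Config as sorted JSON, excluding the output location (two runs
        into different directories are the same analysis)."""
        d = self.model_dump(mode="json")
        d.pop("output_dir", None)
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                       sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _csv_bytes(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: RunConfig, warn=None) -> dict:
    """Execute screening → (synthetic) cohort → univariate screen →
    stepwise model → five-model ROC comparison, writing the report bundle.

    Returns a dict with the in-memory results and the list of written
    files.  Deterministic given ``config`` (same config hash ⇒ byte-
    identical CSV outputs).
    """
    from . import cohort as coh
    from . import prognosis as prog
    from . import synth

    warnings_out: list[str] = []

    def _warn(msg: str) -> None:
        warnings_out.append(msg)
        if warn:
            warn(msg)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"# neuromon {__version__} config_hash={chash}\n"

    # screening funnel
    tallies = config.synth.screening_tallies
    tally_in = synth.ExclusionTally(*tallies)
    n_enrolled_target = (config.synth.n_survivors + config.synth.n_nonsurvivors)
    roster = synth.gen_screening_roster(tally_in, n_enrolled_target,
                                        seed=config.seed)
    enrolled, tally_out = coh.apply_eligibility(roster)
    screening = pd.DataFrame({
        "criterion": list(tally_out.as_dict()) + ["enrolled", "screened"],
        "n": list(tally_out.as_dict().values()) + [len(enrolled), len(roster)],
    })

    # cohort
    if config.cohort_csv is not None:
        records = pd.read_csv(config.cohort_csv, comment="#")
    else:
        spec = synth.default_cohort_spec(config.synth.n_survivors,
                                         config.synth.n_nonsurvivors,
                                         seed=config.seed)
        records = synth.gen_cohort(spec)
        records = _signal_roundtrip(records, config, _warn)

    # univariate screen
    try:
        screen = coh.univariate_screen(
            records, selection_alpha=config.stats.selection_alpha,
            shapiro_alpha=config.stats.shapiro_alpha)
    except ValueError as e:
        raise RuntimeError(f"[screen] {e}") from e
    screen_df = coh.screen_table(screen)
    selected = [r.variable for r in screen if r.selected]

    # multivariable model: screen survivors; fall back to the two
    # neurophysiology predictors when the screen selects nothing usable
    candidates = selected or ["upi", "dar"]
    candidates = [c for c in candidates if c in records.columns]
    fit = None
    while candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fit = prog.MortalityModel.from_dataframe(
                    records, candidates=candidates).fit(
                    removal_alpha=config.stats.removal_alpha,
                    criterion=config.stats.criterion)
            break
        except prog.SeparationError as e:
            # quasi-separation happens at this cohort size; drop the
            # offending variable and refit, as an analyst would
            suspect = str(e).rsplit("suspect variable: ", 1)[-1]
            if suspect not in candidates:
                raise RuntimeError(f"[prognosis] {e}") from e
            _warn(f"[prognosis] {e}; refitting without {suspect!r}")
            candidates = [c for c in candidates if c != suspect]
    if fit is None:
        raise RuntimeError("[prognosis] no fittable candidate set")

    # five-model ROC comparison
    have_cols = all(c in records.columns for c in prog.FIVE_MODEL_SCORES)
    curves, comparisons = (None, [])
    if have_cols:
        curves, comparisons = prog.compare_five_models(records)
    else:
        _warn("five-model comparison skipped: cohort lacks "
              "gcs/hematoma_volume/upi/dar columns")

    files = []

    def _write(name: str, text: str) -> None:
        p = out / name
        p.write_text(stamp + text)
        files.append(p)

    _write("screening.csv", _csv_bytes(screening))
    _write("features.csv", _csv_bytes(records))
    _write("univariate.csv", _csv_bytes(screen_df))
    _write("model_summary.txt", fit.summary() + "\n")
    if curves:
        auc_df = pd.DataFrame([
            {"model": c.name, "auc": c.auc, "auc_se": c.auc_se,
             "ci_low": c.auc_ci[0], "ci_high": c.auc_ci[1]}
            for c in curves.values()])
        cmp_df = pd.DataFrame([c.as_dict() for c in comparisons])
        _write("roc_auc.csv", _csv_bytes(auc_df))
        _write("roc_comparison.csv", _csv_bytes(cmp_df))
    provenance = {
        "package": "neuromon", "version": __version__,
        "config_hash": chash, "seed": config.seed,
        "config": json.loads(config.canonical_json()),
        "warnings": warnings_out,
    }
    p = out / "provenance.json"
    p.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    files.append(p)

    return {"screening": screening, "tally": tally_out, "records": records,
            "univariate": screen_df, "selected": selected, "fit": fit,
            "curves": curves, "comparisons": comparisons,
            "warnings": warnings_out, "files": files,
            "config_hash": chash}


def _signal_roundtrip(records: pd.DataFrame, config: RunConfig, warn) -> pd.DataFrame:
    """Replace tabulated TCD indices with values re-measured from simulated
    envelopes for the first ``n_signal_patients`` of each group.

    Exercises the full signal path inside the pipeline without paying the
    cost of simulating raw signals for every patient.
    """
    from . import synth, tcd as tcdmod

    k = config.synth.n_signal_patients
    if k <= 0:
        return records
    records = records.copy()
    for i in records.index[:k]:
        row = records.loc[i]
        try:
            env_u = synth.gen_tcd(synth.TCDGenSpec(
                vs=float(row["uvs"]), vd=float(row["uvd"]),
                seed=config.seed + 1000 + int(row["patient_id"])))
            beats = tcdmod.detect_beats(env_u, config.tcd.min_rate_bpm,
                                        config.tcd.max_rate_bpm)
            side = tcdmod.beat_indices(beats, beat_first=config.tcd.beat_first)
        except (ValueError, tcdmod.UnreadableWaveformError) as e:
            warn(f"[tcd] patient {row['patient_id']}: {e}; keeping table value")
            continue
        records.loc[i, ["uvs", "uvd", "uvm", "upi"]] = [
            side.vs, side.vd, side.vm, side.pi]
    return records
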