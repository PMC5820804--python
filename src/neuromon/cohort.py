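"""Clinical cohort model: eligibility filtering, hematoma volume, and the
univariate prognostic screen.

The study population is severe acute supratentorial intracerebral
hemorrhage (GCS <= 8 on admission, monitored within 72 h of onset); the
outcome is death at 90 days.  The univariate screen compares survivors and
nonsurvivors variable by variable and forwards those with p <= 0.001 to the
multivariable stage.

Test battery (per variable):

* binary / categorical — Pearson chi-squared on the 2x2 table *without*
  Yates continuity correction (this is the convention that reproduces the
  cohort's printed contingency p-values; a corrected variant is available);
* continuous, normal in both groups — two-sample Student's t-test;
* continuous, non-normal — Wilcoxon rank-sum (Mann-Whitney);
* normality decided per variable by Shapiro-Wilk in each group at
  alpha = 0.05.

Units are fixed package-wide: volumes cm^3, times hours, velocities cm/s;
``COLUMN_DICTIONARY`` is the single source of truth for the cohort CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import EXCLUSION_CRITERIA, ExclusionTally

__all__ = [
    "COLUMN_DICTIONARY", "UnivariateResult",
    "hematoma_volume", "apply_eligibility", "univariate_screen",
]

#: Column name -> (unit, description) for cohort CSV files.
COLUMN_DICTIONARY = {
    "patient_id": ("-", "1-based patient identifier"),
    "age": ("years", "age at admission"),
    "male": ("0/1", "male sex"),
    "hypertension": ("0/1", "history of hypertension"),
    "diabetes": ("0/1", "diabetes mellitus"),
    "hyperlipidemia": ("0/1", "hyperlipidemia"),
    "coronary_disease": ("0/1", "coronary heart disease"),
    "smoking": ("0/1", "current smoking"),
    "excessive_drinking": ("0/1", "excessive alcohol use"),
    "onset_to_monitor_h": ("h", "time from ictus to monitoring start"),
    "gcs": ("points", "admission Glasgow Coma Scale (3-15; <= 8 enrolled)"),
    "sbp": ("mmHg", "systolic blood pressure"),
    "dbp": ("mmHg", "diastolic blood pressure"),
    "wbc": ("1e9/L", "white blood cell count"),
    "platelet": ("1e9/L", "platelet count"),
    "aptt": ("s", "activated partial thromboplastin time"),
    "inr": ("-", "international normalized ratio"),
    "glucose": ("mmol/L", "serum glucose"),
    "potassium": ("mmol/L", "serum potassium"),
    "calcium": ("mmol/L", "serum calcium (as printed in the source table)"),
    "sodium": ("mmol/L", "serum sodium (as printed in the source table)"),
    "hematoma_side": ("left/right", "hematoma-bearing hemisphere"),
    "hematoma_location": ("lobe/deep", "hematoma location"),
    "hematoma_volume": ("cm3", "bedside volume estimate (ABC/2 or ABC/3)"),
    "ivh": ("0/1", "intraventricular extension"),
    "avs": ("cm/s", "affected-side systolic velocity"),
    "uvs": ("cm/s", "unaffected-side systolic velocity"),
    "avm": ("cm/s", "affected-side mean velocity"),
    "uvm": ("cm/s", "unaffected-side mean velocity"),
    "avd": ("cm/s", "affected-side diastolic velocity"),
    "uvd": ("cm/s", "unaffected-side diastolic velocity"),
    "api": ("-", "affected-side pulsatility index"),
    "upi": ("-", "unaffected-side pulsatility index"),
    "rdp": ("%", "relative delta power"),
    "rtp": ("%", "relative theta power"),
    "rap": ("%", "relative alpha power"),
    "rbp": ("%", "relative beta power"),
    "dar": ("-", "delta/alpha ratio"),
    "dtabr": ("-", "(delta+theta)/(alpha+beta) ratio"),
    "bsi": ("-", "brain symmetry index"),
    "died90": ("0/1", "death within 90 days of ictus"),
}


def hematoma_volume(length: float, width: float, depth: float,
                    shape: str = "regular") -> float:
    """Bedside hematoma volume from three orthogonal CT diameters (cm).

    ``length*width*depth/2`` for a regular clot (the ABC/2 rule),
    ``/3`` for an irregular one.  Any zero dimension gives 0.
    """
    if min(length, width, depth) < 0:
        raise ValueError("dimensions must be non-negative")
    if shape not in ("regular", "irregular"):
        raise ValueError("shape must be 'regular' or 'irregular'")
    divisor = 2.0 if shape == "regular" else 3.0
    return length * width * depth / divisor


def apply_eligibility(roster: pd.DataFrame,
                      criteria: Sequence[str] = tuple(EXCLUSION_CRITERIA)
                      ) -> tuple[pd.DataFrame, ExclusionTally]:
    """Filter a screening roster down to the enrolled cohort.

    A record carrying any exclusion flag is removed; a record with several
    flags is counted once, itemised under its first-listed criterion (the
    reporting convention).  Idempotent: re-filtering the enrolled output
    changes nothing.
    """
    missing = [c for c in criteria if c not in roster.columns]
    if missing:
        raise KeyError(f"roster lacks eligibility column(s) {missing}")
    flags = roster[list(criteria)].astype(bool)
    excluded = flags.any(axis=1)
    counts = {c: 0 for c in criteria}
    for _, row in flags[excluded].iterrows():
        counts[row.idxmax()] += 1   # first True in criteria order
    tally = ExclusionTally(**{c: counts.get(c, 0) for c in EXCLUSION_CRITERIA})
    return roster.loc[~excluded].reset_index(drop=True), tally


@dataclass
class UnivariateResult:
    """Outcome of one variable's survivor-vs-nonsurvivor comparison."""

    variable: str
    test: str                 # "t" | "rank" | "chi2" | "skipped"
    statistic: float
    p_value: float
    selected: bool
    note: str = ""


def _is_binary(x: pd.Series) -> bool:
    vals = pd.unique(x.dropna())
    return x.dtype == bool or set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def univariate_screen(records: pd.DataFrame, outcome: str = "died90",
                      variables: Sequence[str] | None = None,
                      selection_alpha: float = 0.001,
                      shapiro_alpha: float = 0.05,
                      continuity_correction: bool = False
                      ) -> list[UnivariateResult]:
    """Screen each covariate against the binary outcome.

    Returns one :class:`UnivariateResult` per variable; ``selected`` marks
    p <= ``selection_alpha``.  Missing values are an error (no imputation);
    zero-variance variables are flagged and skipped with p = NaN.
    """
    if outcome not in records.columns:
        raise KeyError(f"outcome column {outcome!r} missing")
    y = records[outcome].astype(int)
    if set(y.unique()) != {0, 1}:
        raise ValueError("outcome must contain both classes")
    if variables is None:
        variables = [c for c in records.columns
                     if c not in (outcome, "patient_id")
                     and pd.api.types.is_numeric_dtype(records[c])]
    g0, g1 = records.loc[y == 0], records.loc[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need >= 2 records per outcome group")
    out: list[UnivariateResult] = []
    for var in variables:
        x = records[var]
        if x.isna().any():
            raise ValueError(f"missing values in {var!r}; imputation is not done")
        x0, x1 = g0[var].to_numpy(float), g1[var].to_numpy(float)
        if np.ptp(records[var].to_numpy(float)) == 0:
            out.append(UnivariateResult(var, "skipped", np.nan, np.nan, False,
                                        "zero variance"))
            continue
        if _is_binary(x):
            table = np.array([[np.sum(x1 == 1), np.sum(x1 == 0)],
                              [np.sum(x0 == 1), np.sum(x0 == 0)]])
            if (table.sum(axis=0) == 0).any():
                out.append(UnivariateResult(var, "skipped", np.nan, np.nan,
                                            False, "degenerate 2x2 table"))
                continue
            chi2, p, _, _ = stats.chi2_contingency(
                table, correction=continuity_correction)
            res = UnivariateResult(var, "chi2", float(chi2), float(p),
                                   p <= selection_alpha)
        else:
            normal = (stats.shapiro(x0).pvalue > shapiro_alpha
                      and stats.shapiro(x1).pvalue > shapiro_alpha)
            if normal:
                t, p = stats.ttest_ind(x1, x0, equal_var=True)
                res = UnivariateResult(var, "t", float(t), float(p),
                                       p <= selection_alpha)
            else:
                u, p = stats.mannwhitneyu(x1, x0, alternative="two-sided")
                res = UnivariateResult(var, "rank", float(u), float(p),
                                       p <= selection_alpha)
        out.append(res)
    return out


def screen_table(results: list[UnivariateResult]) -> pd.DataFrame:
    """Tidy frame of a univariate screen (one row per variable)."""
    return pd.DataFrame([r.__dict__ for r in results])
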