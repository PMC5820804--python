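"""Prognostic modelling: backward stepwise logistic regression, ROC curves,
and DeLong comparison of correlated AUCs.

The centrepiece is a statsmodels-style pair of objects:

* :class:`MortalityModel` — built from a cohort table
  (:meth:`MortalityModel.from_dataframe`) with 90-day death as the
  dependent variable and the univariate-screen survivors as candidates;
* :meth:`MortalityModel.fit` — backward stepwise elimination (Wald
  criterion by default, likelihood-ratio optional) returning a
  :class:`MortalityResults` carrying coefficients, odds ratios with Wald
  95 % CIs, the full step log, in-sample fitted probabilities and a
  ``summary()`` table.

ROC machinery is implemented here rather than delegated: the AUC is the
Mann–Whitney estimator (ties count 1/2), its variance and the covariance
between two AUCs computed on the same subjects come from DeLong's
placement-value estimator, and :func:`delong_test` compares two correlated
ROC curves with a normal z-test.  :func:`compare_five_models` reproduces
the five-model comparison used to judge whether combining the unaffected-
side pulsatility index (UPI) with the delta/alpha ratio (DAR) beats GCS,
hematoma volume, UPI and DAR alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "MortalityModel", "MortalityResults", "ROCCurve", "ModelComparison",
    "SeparationError", "auc_mann_whitney", "roc", "delong_cov", "delong_test",
    "compare_five_models", "FIVE_MODEL_SCORES",
]


class SeparationError(RuntimeError):
    """Logistic fit failed to converge / separated; names the likely culprit."""


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    return y


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann–Whitney U statistic: the proportion of
    (positive, negative) pairs ranked concordantly, ties counting 1/2."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    from scipy.stats import rankdata
    r = rankdata(s)   # midranks
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placements(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values: V10[i] = P(score_i > random negative),
    V01[j] = P(random positive > score_j), ties at 1/2."""
    pos, neg = scores[y == 1], scores[y == 0]
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg)
                    for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / len(pos)
                    for n in neg])
    return v10, v01


def delong_cov(score_list: Sequence[np.ndarray], labels) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for k paired score vectors."""
    y = _check_labels(labels)
    k = len(score_list)
    m, n = int(y.sum()), int((1 - y).sum())
    V10 = np.empty((k, m))
    V01 = np.empty((k, n))
    aucs = np.empty(k)
    for i, s in enumerate(score_list):
        s = np.asarray(s, dtype=float)
        if s.shape != y.shape:
            raise ValueError("scores and labels must be paired per subject")
        V10[i], V01[i] = _placements(s, y)
        aucs[i] = V10[i].mean()
    s10 = np.cov(V10) if k > 1 else np.atleast_2d(np.var(V10[0], ddof=1))
    s01 = np.cov(V01) if k > 1 else np.atleast_2d(np.var(V01[0], ddof=1))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


@dataclass
class ROCCurve:
    """Empirical ROC of one score with DeLong CI on the AUC."""

    name: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1 - self.specificity, self.sensitivity,
                label=f"{self.name} (AUC {self.auc:.3f})", **kw)
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax


def roc(scores, labels, name: str = "score", ci_level: float = 0.95) -> ROCCurve:
    """Empirical ROC over all observed thresholds.

    Higher score = higher predicted risk.  AUC is the Mann–Whitney
    estimator; its standard error and CI come from the DeLong variance
    (CI clipped to [0, 1]).
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    thr = np.concatenate(([np.inf], np.unique(s)[::-1]))
    pos, neg = (y == 1).sum(), (y == 0).sum()
    sens = np.array([(s[y == 1] >= t).sum() / pos for t in thr])
    spec = np.array([(s[y == 0] < t).sum() / neg for t in thr])
    aucs, cov = delong_cov([s], y)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = norm.ppf(0.5 + ci_level / 2)
    lo, hi = np.clip([aucs[0] - z * se, aucs[0] + z * se], 0.0, 1.0)
    return ROCCurve(name=name, thresholds=thr, sensitivity=sens,
                    specificity=spec, auc=float(aucs[0]), auc_se=se,
                    auc_ci=(float(lo), float(hi)))


@dataclass
class ModelComparison:
    """DeLong comparison of two correlated ROC curves."""

    name_a: str
    name_b: str
    auc_a: float
    auc_b: float
    delta: float     # auc_a - auc_b
    z: float
    p_value: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {"model_a": self.name_a, "model_b": self.name_b,
                "auc_a": self.auc_a, "auc_b": self.auc_b,
                "delta_auc": self.delta, "z": self.z, "p": self.p_value}


def delong_test(scores_a, scores_b, labels, name_a: str = "A",
                name_b: str = "B") -> ModelComparison:
    """Two-sided DeLong test of AUC(a) = AUC(b) on paired scores.

    Identical score vectors (zero estimated variance of the difference)
    return the degenerate result ΔAUC = 0, z = 0, p = 1.
    """
    y = _check_labels(labels)
    aucs, cov = delong_cov([np.asarray(scores_a, float),
                            np.asarray(scores_b, float)], y)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = float(aucs[0] - aucs[1])
    if var <= np.finfo(float).eps:
        return ModelComparison(name_a, name_b, float(aucs[0]), float(aucs[1]),
                               delta, 0.0, 1.0, degenerate=True)
    z = delta / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return ModelComparison(name_a, name_b, float(aucs[0]), float(aucs[1]),
                           delta, float(z), float(p))


# ---------------------------------------------------------------------------
# backward stepwise logistic regression
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    step: int
    variables: list[str]
    removed: str | None
    removed_p: float | None
    llf: float


class MortalityModel:
    """Logistic model for a binary outcome with backward stepwise selection.

    Parameters
    ----------
    endog : array-like of 0/1
        Outcome (death at 90 days).
    exog : DataFrame
        Candidate predictors (no constant column; one is added internally).

    Use :meth:`from_dataframe` to build from a cohort table, typically with
    the univariate-screen survivors as candidates.
    """

    def __init__(self, endog, exog: pd.DataFrame):
        self.endog = np.asarray(endog).astype(float)
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog),
                                columns=[f"x{i+1}" for i in
                                         range(np.asarray(exog).shape[1])])
        self.exog = exog.astype(float).reset_index(drop=True)
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        n_min = min(int(self.endog.sum()), int(len(self.endog) - self.endog.sum()))
        if self.exog.shape[1] and n_min < 5 * self.exog.shape[1]:
            warnings.warn(
                f"only {n_min} events in the smaller outcome group for "
                f"{self.exog.shape[1]} candidates (< 5 per variable); "
                "estimates may be unstable", UserWarning, stacklevel=2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "died90",
                       candidates: Sequence[str] | None = None
                       ) -> "MortalityModel":
        if candidates is None:
            candidates = [c for c in df.columns
                          if c not in (outcome, "patient_id")]
        return cls(df[outcome], df[list(candidates)])

    def _fit_once(self, cols: list[str]):
        X = sm.add_constant(self.exog[cols], has_constant="add")
        res, err = None, None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # Newton first; BFGS as fallback when the Hessian degenerates
            for method in ("newton", "bfgs"):
                try:
                    res = sm.Logit(self.endog, X).fit(
                        disp=0, maxiter=500, method=method)
                except (PerfectSeparationError, np.linalg.LinAlgError) as e:
                    err = e
                    continue
                fitted = np.asarray(res.predict())
                if np.all(np.abs(self.endog - fitted) < 1e-4):
                    # perfect prediction: the MLE does not exist
                    break
                if (res.mle_retvals.get("converged", True)
                        and np.all(np.isfinite(res.bse))):
                    return res
        worst = self._suspect_variable(cols)
        detail = f"{type(err).__name__}: {err}" if err else "did not converge"
        raise SeparationError(
            f"logistic fit failed ({detail}); suspect variable: {worst}")

    def _suspect_variable(self, cols: list[str]) -> str:
        # the variable most nearly separating the classes
        best, best_auc = cols[0] if cols else "(none)", 0.0
        for c in cols:
            try:
                a = auc_mann_whitney(self.exog[c], self.endog)
            except ValueError:
                continue
            a = max(a, 1 - a)
            if a > best_auc:
                best, best_auc = c, a
        return best

    def fit(self, removal_alpha: float = 0.10, criterion: str = "wald"
            ) -> "MortalityResults":
        """Backward stepwise elimination.

        Starting from the full candidate set, iteratively drop the variable
        with the largest p-value above ``removal_alpha`` (Wald p by
        default; ``criterion='lr'`` uses the likelihood-ratio test of the
        dropped term) and refit, until every remaining variable is
        significant at the threshold.  ``removal_alpha=1`` keeps the full
        model; ``removal_alpha=0`` reduces to intercept-only.
        """
        if criterion not in ("wald", "lr"):
            raise ValueError("criterion must be 'wald' or 'lr'")
        cols = list(self.exog.columns)
        res = self._fit_once(cols)
        log = [StepRecord(0, list(cols), None, None, float(res.llf))]
        step = 0
        while cols:
            if criterion == "wald":
                pvals = res.pvalues.drop("const")
            else:
                pvals = pd.Series({c: self._lr_drop_p(res, cols, c)
                                   for c in cols})
            worst = pvals.idxmax()
            if pvals[worst] <= removal_alpha:
                break
            cols = [c for c in cols if c != worst]
            step += 1
            new_res = self._fit_once(cols)
            log.append(StepRecord(step, list(cols), str(worst),
                                  float(pvals[worst]), float(new_res.llf)))
            res = new_res
        return MortalityResults(self, res, cols, log)

    def _lr_drop_p(self, full_res, cols: list[str], drop: str) -> float:
        from scipy.stats import chi2
        reduced = self._fit_once([c for c in cols if c != drop])
        lr = 2 * (full_res.llf - reduced.llf)
        return float(chi2.sf(max(lr, 0.0), df=1))


class MortalityResults:
    """Fitted backward-stepwise logistic model.

    Attributes
    ----------
    params, bse, pvalues : Series
        Coefficients (log-odds), standard errors and Wald p-values,
        including the intercept ``const``.
    retained : list of str
        Variables surviving elimination.
    step_log : list of StepRecord
        One record per elimination step (step 0 = full model).
    fittedvalues : ndarray
        In-sample predicted death probabilities.
    """

    def __init__(self, model: MortalityModel, res, retained: list[str],
                 step_log: list[StepRecord]):
        self.model = model
        self._res = res
        self.retained = retained
        self.step_log = step_log
        self.params = res.params
        self.bse = res.bse
        self.pvalues = res.pvalues
        self.llf = float(res.llf)
        self.fittedvalues = np.asarray(res.predict())

    def odds_ratios(self, ci_level: float = 0.95) -> pd.DataFrame:
        """OR = exp(beta) with Wald confidence limits, per retained variable."""
        ci = self._res.conf_int(alpha=1 - ci_level)
        out = pd.DataFrame({
            "coef": self.params,
            "se": self.bse,
            "or": np.exp(self.params),
            "or_ci_low": np.exp(ci[0]),
            "or_ci_high": np.exp(ci[1]),
            "p": self.pvalues,
        })
        return out.drop(index="const")

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(exog[self.retained].astype(float),
                            has_constant="add")
        return np.asarray(self._res.predict(X))

    def roc(self, name: str = "model") -> ROCCurve:
        """ROC of the in-sample fitted probabilities."""
        return roc(self.fittedvalues, self.model.endog, name=name)

    def summary(self) -> str:
        """Human-readable fit report: retained variables, ORs, step log."""
        lines = ["Backward stepwise logistic regression",
                 f"  n = {len(self.model.endog)}, "
                 f"events = {int(self.model.endog.sum())}, "
                 f"log-likelihood = {self.llf:.3f}",
                 f"  retained: {', '.join(self.retained) or '(intercept only)'}",
                 ""]
        if self.retained:
            ors = self.odds_ratios()
            lines.append(ors.to_string(float_format=lambda v: f"{v:.3f}"))
            lines.append("")
        lines.append("Elimination path:")
        for rec in self.step_log:
            if rec.removed is None:
                lines.append(f"  step {rec.step}: full model "
                             f"[{', '.join(rec.variables) or '-'}]")
            else:
                lines.append(f"  step {rec.step}: removed {rec.removed} "
                             f"(p = {rec.removed_p:.3f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# five-model comparison
# ---------------------------------------------------------------------------

#: score column -> (display name, risk direction). GCS is inverted because a
#: *lower* score predicts death.
FIVE_MODEL_SCORES = {
    "gcs": ("GCS", -1.0),
    "hematoma_volume": ("hematoma volume", 1.0),
    "upi": ("UPI", 1.0),
    "dar": ("DAR", 1.0),
}


def compare_five_models(records: pd.DataFrame, outcome: str = "died90"
                        ) -> tuple[dict[str, ROCCurve], list[ModelComparison]]:
    """The five-model prognostic comparison.

    Models: GCS alone, hematoma volume alone, UPI alone, DAR alone, and the
    combined UPI+DAR logistic score (in-sample fitted death probability).
    Returns the five ROC curves plus DeLong tests of the combined model
    against each single-variable model (unadjusted, as conventionally
    reported; apply a Bonferroni factor downstream if desired).
    """
    y = records[outcome].to_numpy()
    curves: dict[str, ROCCurve] = {}
    for col, (label, direction) in FIVE_MODEL_SCORES.items():
        if col not in records.columns:
            raise KeyError(f"records lack required column {col!r}")
        curves[label] = roc(direction * records[col].to_numpy(float), y,
                            name=label)
    combined_fit = MortalityModel.from_dataframe(
        records, outcome=outcome, candidates=["upi", "dar"]).fit(removal_alpha=1.0)
    combined_score = combined_fit.fittedvalues
    curves["UPI+DAR"] = roc(combined_score, y, name="UPI+DAR")
    comparisons = []
    for col, (label, direction) in FIVE_MODEL_SCORES.items():
        comparisons.append(delong_test(
            combined_score, direction * records[col].to_numpy(float), y,
            name_a="UPI+DAR", name_b=label))
    return curves, comparisons
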