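"""ROC/AUC estimation, DeLong comparison, and backward stepwise logistic
regression, checked against independent oracles (exhaustive pair
enumeration, bootstrap, closed forms, and parameter-recovery simulations)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from neuromon import prognosis as prog
from neuromon import synth


def auc_brute_force(scores, labels):
    """Oracle: enumerate every (positive, negative) pair; ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_tie_example(self):
        assert prog.auc_mann_whitney([1, 2, 2, 3], [0, 1, 0, 1]) == 0.875

    def test_perfect_separation(self):
        assert prog.auc_mann_whitney([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    @pytest.mark.parametrize("n, seed", [(10, 0), (57, 1), (200, 2)])
    def test_matches_exhaustive_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 15, size=n).astype(float)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert prog.auc_mann_whitney(scores, labels) == pytest.approx(
            auc_brute_force(scores, labels), abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        scores = rng.normal(size=120)
        labels = rng.integers(0, 2, size=120)
        labels[:2] = [0, 1]
        assert prog.auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        a = prog.auc_mann_whitney(scores, labels)
        b = prog.auc_mann_whitney(np.exp(3 * scores) + 5, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=4000)
        labels = np.r_[np.zeros(2000, int), np.ones(2000, int)]
        assert prog.auc_mann_whitney(scores, labels) == pytest.approx(
            0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            prog.auc_mann_whitney([1.0, 2.0], [1, 1])


class TestROCCurve:
    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        curve = prog.roc(scores, labels)
        assert curve.sensitivity[0] == 0.0 and curve.sensitivity[-1] == 1.0
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)
        assert 0.0 <= curve.auc <= 1.0
        assert curve.auc_ci[0] <= curve.auc <= curve.auc_ci[1]

    def test_auc_equals_trapezoid_under_curve(self):
        rng = np.random.default_rng(6)
        scores = np.r_[rng.normal(0, 1, 80), rng.normal(1.2, 1, 80)]
        labels = np.r_[np.zeros(80, int), np.ones(80, int)]
        curve = prog.roc(scores, labels)
        fpr = 1 - curve.specificity
        trapz = np.trapezoid(curve.sensitivity, fpr)
        assert curve.auc == pytest.approx(trapz, abs=1e-12)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=30)
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        cmp = prog.delong_test(s, s, y)
        assert cmp.delta == 0.0
        assert cmp.p_value == 1.0
        assert cmp.degenerate

    def test_antisymmetric(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        a = rng.normal(size=40) + y
        b = rng.normal(size=40) + 0.3 * y
        ab = prog.delong_test(a, b, y)
        ba = prog.delong_test(b, a, y)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_se_within_15pct_of_bootstrap(self):
        rng = np.random.default_rng(9)
        n = 30
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        a = rng.normal(size=n) + 1.0 * y
        b = 0.6 * a + rng.normal(size=n) * 0.8 + 0.4 * y
        _, cov = prog.delong_cov([a, b], y)
        se_delong = np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        boots = []
        for _ in range(2000):
            idx = np.concatenate([
                rng.choice(np.where(y == 0)[0], n // 2),
                rng.choice(np.where(y == 1)[0], n // 2)])
            boots.append(prog.auc_mann_whitney(a[idx], y[idx])
                         - prog.auc_mann_whitney(b[idx], y[idx]))
        se_boot = np.std(boots, ddof=1)
        assert se_delong == pytest.approx(se_boot, rel=0.15)

    def test_variance_shrinks_with_n(self):
        rng = np.random.default_rng(10)
        ses = []
        for n in (50, 200, 800):
            y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            s = rng.normal(size=n) + y
            _, cov = prog.delong_cov([s], y)
            ses.append(cov[0, 0])
        assert ses[0] > ses[1] > ses[2]
        # 1/n rate: quadrupling n divides the variance by about 4
        assert ses[0] / ses[1] == pytest.approx(4.0, rel=0.5)


class TestBackwardStepwise:
    def _sim(self, rng, n=500, beta=(1.0, 0.0)):
        x = rng.normal(size=(n, len(beta)))
        logit = -2.0 + x @ np.array(beta)
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        df = pd.DataFrame(x, columns=[f"x{i+1}" for i in range(len(beta))])
        df["died90"] = y
        return df

    def test_null_predictor_dropped_or_covered(self):
        rng = np.random.default_rng(11)
        dropped, covered = 0, 0
        n_rep = 50
        for _ in range(n_rep):
            df = self._sim(rng)
            fit = prog.MortalityModel.from_dataframe(
                df, candidates=["x1", "x2"]).fit(removal_alpha=0.10)
            if "x2" not in fit.retained:
                dropped += 1
            if "x1" in fit.retained:
                ors = fit.odds_ratios()
                lo, hi = ors.loc["x1", ["or_ci_low", "or_ci_high"]]
                covered += int(lo <= np.e <= hi)
        assert dropped >= 0.8 * n_rep          # null variable rarely kept
        assert covered >= 0.9 * n_rep          # Wald CI covers the truth

    def test_two_true_predictors_both_retained_at_large_n(self):
        rng = np.random.default_rng(12)
        df = self._sim(rng, n=2000, beta=(0.8, 0.8))
        fit = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit()
        assert set(fit.retained) == {"x1", "x2"}

    def test_independent_outcome_gives_intercept_only(self):
        rng = np.random.default_rng(13)
        df = self._sim(rng, n=400, beta=(0.0, 0.0))
        fit = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit()
        assert fit.retained == []
        assert len(fit.params) == 1

    def test_alpha_one_keeps_full_model(self):
        rng = np.random.default_rng(14)
        df = self._sim(rng, n=200, beta=(0.5, 0.0))
        fit = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit(removal_alpha=1.0)
        assert set(fit.retained) == {"x1", "x2"}

    def test_alpha_zero_gives_intercept_only(self):
        rng = np.random.default_rng(15)
        df = self._sim(rng, n=200, beta=(2.0, 1.0))
        fit = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit(removal_alpha=0.0)
        assert fit.retained == []

    def test_or_equals_exp_coef_and_ci_brackets(self):
        rng = np.random.default_rng(16)
        df = self._sim(rng, n=600, beta=(1.0,))
        fit = prog.MortalityModel.from_dataframe(
            df, candidates=["x1"]).fit()
        ors = fit.odds_ratios()
        assert ors.loc["x1", "or"] == pytest.approx(
            np.exp(fit.params["x1"]), rel=1e-9)
        assert ors.loc["x1", "or_ci_low"] < ors.loc["x1", "or"] < \
            ors.loc["x1", "or_ci_high"]
        assert (ors[["or_ci_low", "or_ci_high"]] > 0).all().all()

    def test_fitted_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(17)
        df = self._sim(rng, n=300, beta=(1.0, 0.5))
        fit = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit(removal_alpha=1.0)
        assert np.all((fit.fittedvalues > 0) & (fit.fittedvalues < 1))

    def test_separation_reports_offending_variable(self):
        df = pd.DataFrame({"x1": np.arange(20.0),
                           "x2": np.random.default_rng(18).normal(size=20),
                           "died90": (np.arange(20) >= 10).astype(int)})
        with pytest.raises(prog.SeparationError, match="x1"):
            prog.MortalityModel.from_dataframe(
                df, candidates=["x1", "x2"]).fit()

    def test_step_log_records_path(self):
        rng = np.random.default_rng(19)
        df = self._sim(rng, n=500, beta=(1.5, 0.0))
        fit = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit()
        assert fit.step_log[0].removed is None
        removed = [r.removed for r in fit.step_log[1:]]
        assert all(r is not None for r in removed)
        assert "Backward stepwise" in fit.summary()

    def test_lr_criterion_agrees_on_clear_case(self):
        rng = np.random.default_rng(20)
        df = self._sim(rng, n=800, beta=(1.2, 0.0))
        wald = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit(criterion="wald")
        lr = prog.MortalityModel.from_dataframe(
            df, candidates=["x1", "x2"]).fit(criterion="lr")
        assert wald.retained == lr.retained == ["x1"]


class TestFiveModels:
    @pytest.fixture(scope="class")
    def big_cohort(self):
        return synth.gen_cohort(synth.default_cohort_spec(
            n_survivors=2000, n_nonsurvivors=2000, seed=21))

    def test_upi_auc_matches_closed_form(self, big_cohort):
        curves, _ = prog.compare_five_models(big_cohort)
        expected = norm.cdf(0.3 / np.sqrt(0.08))   # ≈ 0.856
        assert curves["UPI"].auc == pytest.approx(expected, abs=0.02)

    def test_combined_beats_singles_with_independent_signals(self, big_cohort):
        curves, comparisons = prog.compare_five_models(big_cohort)
        combined = curves["UPI+DAR"].auc
        assert combined > curves["UPI"].auc
        assert combined > curves["DAR"].auc
        for cmp in comparisons:
            if cmp.name_b in ("UPI", "DAR"):
                assert cmp.p_value < 0.05
                assert cmp.delta > 0

    def test_null_dar_adds_nothing(self):
        spec = synth.default_cohort_spec(n_survivors=1500,
                                         n_nonsurvivors=1500, seed=22)
        vars2 = dict(spec.variables)
        v = vars2["dar"]
        vars2["dar"] = synth.VariableSpec(v.dist, v.survivors, v.survivors)
        df = synth.gen_cohort(synth.CohortGenSpec(1500, 1500, vars2, seed=22))
        curves, _ = prog.compare_five_models(df)
        assert curves["DAR"].auc == pytest.approx(0.5, abs=0.03)
        assert curves["UPI+DAR"].auc == pytest.approx(curves["UPI"].auc,
                                                      abs=0.02)

    def test_gcs_direction_handled(self, big_cohort):
        # lower GCS predicts death; the model must score it as risk
        curves, _ = prog.compare_five_models(big_cohort)
        assert curves["GCS"].auc > 0.5

    def test_missing_column_is_keyerror(self, big_cohort):
        with pytest.raises(KeyError):
            prog.compare_five_models(big_cohort.drop(columns=["upi"]))
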