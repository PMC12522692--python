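"""Oracle equivalences, parameter recovery and error calibration for the
statistics toolkit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from memgs import (LinearWald, LogisticWald, MultinomialWald, auc,
                   confusion_metrics, delong_test, fit_interaction,
                   interaction_scan, linear_fit, logistic_fit, multinomial_fit,
                   pearson_chi_square, two_prop_z)
from memgs.stats import SeparationError, _placements, _placements_naive, auc_variance


class TestContingency:
    def test_homogeneous_table(self):
        x2, df, p = pearson_chi_square([[10, 10], [10, 10]])
        assert x2 == 0 and df == 1 and p == pytest.approx(1.0)

    def test_clinic_gender_table(self):
        """4x2 female/male counts of the four clinic groups: X2 ~ 22.4, df 3
        (direct evaluation of the Pearson formula)."""
        counts = [[91, 128], [21, 66], [174, 188], [115, 213]]
        x2, df, p = pearson_chi_square(counts)
        assert df == 3
        assert x2 == pytest.approx(22.4, abs=0.15)
        assert 1e-6 < p < 1e-3   # printed order of magnitude 5.6E-05

    def test_matches_scipy_no_correction(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(0)
        t = rng.integers(1, 60, size=(3, 4))
        x2, df, p = pearson_chi_square(t)
        ref = chi2_contingency(t, correction=False)
        assert x2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi_square([[0, 0], [5, 5]])

    def test_equal_proportions_z_zero(self):
        z, p = two_prop_z(5, 10, 50, 100)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = two_prop_z(30, 100, 20, 80)
        z2, p2 = two_prop_z(20, 80, 30, 100)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_prop_z(0, 10, 0, 10)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40),
           st.integers(1, 40))
    @settings(max_examples=100, derandomize=True)
    def test_z_squared_equals_chi_square(self, a, b, c, d):
        """z^2 == X^2 on every 2x2 table (no continuity corrections)."""
        z, _ = two_prop_z(a, a + b, c, c + d)
        x2, _, _ = pearson_chi_square([[a, b], [c, d]])
        assert z ** 2 == pytest.approx(x2, rel=1e-10)


class TestLogistic:
    def test_two_by_two_closed_form(self):
        """The fitted OR equals ad/bc and se(log OR) equals
        sqrt(1/a + 1/b + 1/c + 1/d)."""
        a, b, c, d = 30, 15, 12, 40
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        res = logistic_fit(np.column_stack([np.ones_like(x), x]), y,
                           names=["intercept", "exposed"])
        t = res.term("exposed")
        assert t["OR"] == pytest.approx(a * d / (b * c), rel=1e-8)
        assert t["se"] == pytest.approx(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-8)

    @given(st.integers(5, 40), st.integers(5, 40), st.integers(5, 40),
           st.integers(5, 40))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_two_by_two_closed_form_property(self, a, b, c, d):
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        res = logistic_fit(np.column_stack([np.ones_like(x), x]), y)
        assert res.table.iloc[1]["OR"] == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_constant_outcome_errors(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(np.ones((10, 1)), np.ones(10))

    def test_perfect_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises(SeparationError):
            logistic_fit(np.column_stack([np.ones_like(x), x]), y)

    def test_parameter_recovery(self):
        """n=2000 simulation with true slope 0.6 recovered within 3 se."""
        rng = np.random.default_rng(17)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < expit(-0.3 + 0.6 * x)).astype(float)
        res = logistic_fit(np.column_stack([np.ones_like(x), x]), y,
                           names=["intercept", "x"])
        t = res.term("x")
        assert abs(t["beta"] - 0.6) < 3 * t["se"]

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        y = (rng.random(300) < expit(X @ [0.2, 0.8, -0.5])).astype(float)
        est = LogisticWald().fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(est.coef_, ref.params, atol=1e-6)
        assert np.allclose(est.se_, ref.bse, rtol=1e-4)

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        X = np.column_stack([np.ones(200), x, 2 * x])
        y = (rng.random(200) < expit(0.5 * x)).astype(float)
        est = LogisticWald().fit(X, y, names=["intercept", "x", "x_dup"])
        assert len(est.coef_) == 2


class TestInteraction:
    def test_recovery_of_negative_interaction(self):
        """Built-in product effect beta = -1.2 recovered within 3 se."""
        rng = np.random.default_rng(23)
        n = 3000
        prs = rng.normal(size=n)
        carrier = (rng.random(n) < 0.2).astype(float)
        eta = -0.2 + 0.7 * prs + 0.5 * carrier - 1.2 * prs * carrier
        y = (rng.random(n) < expit(eta)).astype(float)
        res = fit_interaction(y, prs, carrier)
        t = res.term(res.interaction_term)
        assert abs(t["beta"] - (-1.2)) < 3 * t["se"]
        assert t["beta"] < 0

    def test_constant_carrier_errors(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="constant"):
            fit_interaction(rng.integers(0, 2, 50), rng.normal(size=50),
                            np.zeros(50))

    def test_scan_skips_degenerate_genes_and_adjusts(self):
        rng = np.random.default_rng(6)
        n = 400
        prs = rng.normal(size=n)
        y = (rng.random(n) < expit(0.5 * prs)).astype(float)
        flags = pd.DataFrame({
            "GENE1": rng.random(n) < 0.2,
            "EMPTY": np.zeros(n, dtype=bool),
            "GENE2": rng.random(n) < 0.3,
        })
        out = interaction_scan(y, prs, flags)
        assert list(out.index) == ["GENE1", "GENE2"]
        assert (out["p_bonferroni"] >= out["p"]).all()
        assert (out["p_bonferroni"] <= 1).all()

    def test_type_one_error_calibrated(self):
        """Null product term rejected at ~5% over 600 replicates."""
        rng = np.random.default_rng(31)
        n, reps, alpha = 400, 600, 0.05
        rejections = 0
        for _ in range(reps):
            prs = rng.normal(size=n)
            carrier = (rng.random(n) < 0.2).astype(float)
            y = (rng.random(n) < expit(0.4 * prs + 0.3 * carrier)).astype(float)
            res = fit_interaction(y, prs, carrier)
            rejections += res.term("prs:carrier")["p"] < alpha
        rate = rejections / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se


class TestMultinomial:
    @staticmethod
    def _data(seed=7, n=400, k=3):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        B = np.array([[0.0, 0.3], [0.5, -0.6]])[:, :k - 1]
        eta = np.column_stack([np.zeros(n), X @ B])
        p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        y = np.array([rng.choice(k, p=pi) for pi in p])
        return X, y

    def test_probabilities_sum_to_one(self):
        X, y = self._data()
        est = MultinomialWald(reference=0).fit(X, y)
        probs = est.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_two_categories_reduce_to_logistic(self):
        X, y = self._data(k=2)
        mult = MultinomialWald(reference=0).fit(X, y)
        logi = LogisticWald().fit(X, (y == 1).astype(float))
        assert np.allclose(mult.coef_[:, 0], logi.coef_, atol=1e-6)
        assert np.allclose(mult.se_[:, 0], logi.se_, atol=1e-6)

    def test_loglik_matches_numeric_optimizer(self):
        """Three-category fit agrees with an independent BFGS maximization
        of the multinomial likelihood."""
        X, y = self._data(seed=12, n=200)
        est = MultinomialWald(reference=0).fit(X, y)

        Y = np.column_stack([(y == k).astype(float) for k in range(3)])

        def nll(theta):
            B = theta.reshape(2, 2, order="F")
            eta = np.column_stack([np.zeros(len(X)), X @ B])
            eta -= eta.max(axis=1, keepdims=True)
            logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
            return -(Y * logp).sum()

        opt = minimize(nll, np.zeros(4), method="BFGS")
        assert est.loglik_ == pytest.approx(-opt.fun, abs=1e-6)
        assert np.allclose(est.coef_.ravel(order="F"), opt.x, atol=1e-3)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = self._data(seed=3)
        est = MultinomialWald(reference=0).fit(X, y)
        ref = sm.MNLogit(y, X).fit(disp=0)
        assert np.allclose(est.coef_, ref.params, atol=1e-5)

    def test_empty_category_errors(self):
        X, y = self._data(k=2)
        with pytest.raises(ValueError, match="empty"):
            MultinomialWald(reference=0).fit(X, y, categories=[0, 1, 2])


class TestLinear:
    def test_exact_fit(self):
        x = np.arange(1.0, 11.0)
        res = linear_fit(np.column_stack([np.ones_like(x), x]), 2 * x,
                         names=["intercept", "x"])
        assert res.term("x")["beta"] == pytest.approx(2.0)
        assert res.term("intercept")["beta"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(14)
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        y = rng.normal(size=60)
        res = LinearWald().fit(X, y)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(res.coef_, beta)
        sigma2 = ((y - X @ beta) ** 2).sum() / (60 - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(res.se_, se)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(15)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.normal(size=50)
        perm = rng.permutation(50)
        a = LinearWald().fit(X, y).coef_
        b = LinearWald().fit(X[perm], y[perm]).coef_
        assert np.allclose(a, b)

    def test_rank_deficiency_errors(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            linear_fit(np.column_stack([np.ones_like(x), x, x]), x)


class TestConfusion:
    def test_perfect_prediction(self):
        cm = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.se, cm.sp, cm.ppv, cm.npv) == (100.0, 100.0, 100.0, 100.0)

    def test_direct_ratios(self):
        pred = np.r_[np.ones(90), np.zeros(10), np.ones(50), np.zeros(50)]
        act = np.r_[np.ones(100), np.zeros(100)]
        cm = confusion_metrics(pred, act)
        assert (cm.se, cm.sp, cm.ppv, cm.npv) == (90.0, 50.0, 64.29, 83.33)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(19)
        pred = rng.random(200) < 0.4
        act = rng.random(200) < 0.5
        cm = confusion_metrics(pred, act)
        sw = confusion_metrics(~pred, ~act)
        assert (cm.se, cm.sp, cm.ppv, cm.npv) == (sw.sp, sw.se, sw.npv, sw.ppv)

    def test_undefined_ratio_is_missing(self):
        cm = confusion_metrics([0, 0], [1, 1])
        assert cm.ppv is None and cm.se == 0.0


class TestAuc:
    def test_perfect_separation(self):
        r = auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_all_ties(self):
        r = auc(np.ones(20), np.r_[np.ones(10), np.zeros(10)])
        assert r.auc == 0.5

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 2, 3], [1, 1, 1])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=40, derandomize=True)
    def test_matches_exhaustive_pair_counting(self, seed):
        """Midrank AUC equals brute force over all pos x neg pairs (n<=50)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        fast = _placements(scores, labels)
        slow = _placements_naive(scores, labels)
        assert fast.auc == pytest.approx(slow.auc, abs=1e-12)
        assert np.allclose(np.sort(fast.v_pos), np.sort(slow.v_pos))
        assert np.allclose(np.sort(fast.v_neg), np.sort(slow.v_neg))


class TestDeLong:
    def test_identical_models(self):
        rng = np.random.default_rng(21)
        s = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        labels[:2] = [True, False]
        r = delong_test(s, s, labels)
        assert r.delta == 0.0 and r.p == 1.0

    def test_delta_is_auc_difference(self):
        rng = np.random.default_rng(22)
        labels = np.r_[np.ones(60, bool), np.zeros(60, bool)]
        a = rng.normal(size=120) + labels
        b = rng.normal(size=120)
        r = delong_test(a, b, labels)
        assert r.delta == pytest.approx(auc(a, labels).auc - auc(b, labels).auc)

    def test_midrank_equals_structural_components(self):
        rng = np.random.default_rng(25)
        labels = rng.random(150) < 0.5
        labels[:2] = [True, False]
        a = rng.normal(size=150) + 0.8 * labels
        b = rng.normal(size=150) + 0.4 * labels
        fast = delong_test(a, b, labels)
        slow = delong_test(a, b, labels, placements=_placements_naive)
        assert fast.z == pytest.approx(slow.z, abs=1e-10)
        assert fast.p == pytest.approx(slow.p, abs=1e-10)

    def test_variance_against_bootstrap(self):
        """DeLong variance of one AUC within 10% of a 2000-rep bootstrap."""
        rng = np.random.default_rng(29)
        n = 200
        labels = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
        scores = rng.normal(size=n) + 0.7 * labels
        var_dl = auc_variance(auc(scores, labels))
        pos, neg = scores[labels], scores[~labels]
        boots = np.empty(2000)
        for i in range(2000):
            bp = rng.choice(pos, size=len(pos))
            bn = rng.choice(neg, size=len(neg))
            boots[i] = (bp[:, None] > bn[None, :]).mean() \
                + 0.5 * (bp[:, None] == bn[None, :]).mean()
        var_boot = boots.var(ddof=1)
        assert var_dl == pytest.approx(var_boot, rel=0.10)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            delong_test([1, 2], [1, 2, 3], [True, False, True])

    def test_type_one_error_calibrated(self):
        """Two equally uninformative models: ~5% rejections over 600 reps."""
        rng = np.random.default_rng(41)
        n, reps, alpha = 200, 600, 0.05
        rejections = 0
        labels = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
        for _ in range(reps):
            signal = rng.normal(size=n) + 0.5 * labels
            a = signal + rng.normal(size=n)
            b = signal + rng.normal(size=n)
            rejections += delong_test(a, b, labels).p < alpha
        rate = rejections / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se
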