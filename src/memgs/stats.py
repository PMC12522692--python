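"""Statistical toolkit implemented from defining formulas.

Contingency tests (Pearson chi-square, two-proportion z), binary logistic
regression by IRLS with Wald inference, multinomial logistic regression by
Newton's method, ordinary least squares, confusion metrics, the
Mann-Whitney AUC and the paired DeLong test (midrank formulation).

Conventions: Wald 95% intervals use the 1.96 multiplier; no continuity
corrections anywhere, so ``z^2 == X^2`` holds exactly on 2x2 tables; the
classification threshold on fitted probabilities is 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from scipy.special import expit
from sklearn.base import BaseEstimator

logger = logging.getLogger("memgs.stats")

Z95 = 1.96


class SeparationError(RuntimeError):
    """The likelihood diverges: a term perfectly separates the outcome."""


# ---------------------------------------------------------------------------
# contingency tests
# ---------------------------------------------------------------------------

def pearson_chi_square(table):
    """Pearson chi-square test of independence on an RxC count table.

    ``X^2 = sum (O - E)^2 / E`` with expectations from the margins;
    ``df = (R-1)(C-1)``; no continuity correction. A zero margin is an
    error (expected counts must be positive).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    expected = np.outer(rows, cols) / t.sum()
    x2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return x2, df, float(sps.chi2.sf(x2, df))


def two_prop_z(x1: int, n1: int, x2: int, n2: int):
    """Two-proportion z-test (pooled variance, no continuity correction)."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("require 0 <= x <= n with n > 0 in both groups")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1); z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# regression results
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Per-term Wald summary plus model-level diagnostics.

    ``table`` columns: beta, se, stat, p, OR, ci_low, ci_high (OR and its
    CI are on the exp scale; NaN for linear models).
    """

    table: pd.DataFrame
    loglik: float
    n: int
    converged: bool
    interaction_term: str | None = None

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _wald_table(names, beta, se, dist="z", df=None, exp_scale=True):
    beta, se = np.asarray(beta, float), np.asarray(se, float)
    stat = beta / se
    if dist == "z":
        p = 2 * sps.norm.sf(np.abs(stat))
    else:
        p = 2 * sps.t.sf(np.abs(stat), df)
    tab = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "stat": stat,
            "p": p,
            "OR": np.exp(beta) if exp_scale else np.nan,
            "ci_low": np.exp(beta - Z95 * se) if exp_scale else beta - Z95 * se,
            "ci_high": np.exp(beta + Z95 * se) if exp_scale else beta + Z95 * se,
        },
        index=pd.Index(names, name="term"),
    )
    return tab


def _drop_collinear(X: np.ndarray, names):
    """Return indices of a full-rank column subset (pivoted QR), log drops."""
    if X.shape[1] == 0:
        return []
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        logger.warning("design: dropped collinear columns %s", dropped)
    return keep


def _as_design(X, names):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


# ---------------------------------------------------------------------------
# binary logistic regression (IRLS)
# ---------------------------------------------------------------------------

class LogisticWald(BaseEstimator):
    """Binary logistic regression, maximum likelihood by IRLS.

    Convergence when ``max|score| < tol`` (default 1e-8) or ``max_iter``
    iterations; Wald standard errors from the inverse observed
    information. Collinear design columns are dropped with a log.
    Diverging coefficients with a non-vanishing score raise
    :class:`SeparationError` naming the term.

    Fitted attributes: ``coef_``, ``se_``, ``cov_``, ``loglik_``,
    ``names_``, ``converged_``, ``n_used_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 separation_bound: float = 15.0):
        self.tol = tol
        self.max_iter = max_iter
        self.separation_bound = separation_bound

    def fit(self, X, y, names=None):
        X, names = _as_design(X, names)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome is constant; logistic model undefined")
        keep = _drop_collinear(X, names)
        Xk = X[:, keep]
        kept_names = [names[i] for i in keep]
        beta = np.zeros(Xk.shape[1])
        converged = False
        for _ in range(self.max_iter):
            eta = Xk @ beta
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            score = Xk.T @ (y - mu)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            info = (Xk * w[:, None]).T @ Xk
            try:
                step = linalg.solve(info, score, assume_a="pos")
            except linalg.LinAlgError as exc:
                raise SeparationError(f"singular information matrix: {exc}") from exc
            beta = beta + step
            if np.max(np.abs(beta)) > self.separation_bound:
                worst = kept_names[int(np.argmax(np.abs(beta)))]
                raise SeparationError(
                    f"perfect separation suspected: |beta| > "
                    f"{self.separation_bound} for term {worst!r}"
                )
        if not converged:
            eta = Xk @ beta
            mu = expit(eta)
            score = Xk.T @ (y - mu)
            converged = bool(np.max(np.abs(score)) < self.tol)
        mu = expit(Xk @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        info = (Xk * w[:, None]).T @ Xk
        cov = linalg.inv(info)
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.loglik_ = float(np.sum(y * np.log(np.clip(mu, 1e-300, None))
                                    + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None))))
        self.names_ = kept_names
        self.keep_ = keep
        self.n_features_in_ = X.shape[1]
        self.converged_ = converged
        self.n_used_ = int(X.shape[0])
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return expit(X[:, self.keep_] @ self.coef_)

    def result(self) -> RegressionResult:
        return RegressionResult(
            table=_wald_table(self.names_, self.coef_, self.se_),
            loglik=self.loglik_, n=self.n_used_, converged=self.converged_,
        )


def logistic_fit(X, y, names=None) -> RegressionResult:
    """Functional wrapper over :class:`LogisticWald`."""
    return LogisticWald().fit(X, y, names=names).result()


def fit_interaction(outcome, prs, carrier, covariates=None,
                    covariate_names=None, model=None):
    """Fit ``Status ~ PRS * Carrier (+ covariates)`` and flag the product term.

    ``carrier`` is a binary indicator (e.g. carries a rare variant in one
    gene); a constant carrier vector is an error (scan mode skips and logs
    it). Returns a :class:`RegressionResult` whose ``interaction_term``
    names the product row.
    """
    prs = np.asarray(prs, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if carrier.min() == carrier.max():
        raise ValueError("carrier indicator is constant; interaction undefined")
    cols = [np.ones_like(prs), prs, carrier, prs * carrier]
    names = ["intercept", "prs", "carrier", "prs:carrier"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
        names.extend(covariate_names or [f"cov{i}" for i in range(cov.shape[1])])
    est = (model or LogisticWald()).fit(np.column_stack(cols), outcome, names=names)
    res = est.result()
    res.interaction_term = "prs:carrier"
    return res


def interaction_scan(outcome, prs, carrier_flags: pd.DataFrame,
                     covariates=None, covariate_names=None,
                     min_carriers: int = 5) -> pd.DataFrame:
    """Per-gene interaction scan with Bonferroni-adjusted p-values.

    Genes with a constant carrier vector, fewer than ``min_carriers``
    carriers, or non-estimable models are skipped with a log;
    ``p_bonferroni = min(1, m * p)`` over the m genes actually tested.
    """
    rows = {}
    for gene in carrier_flags.columns:
        flags = carrier_flags[gene].to_numpy(dtype=float)
        if flags.sum() < min_carriers:
            logger.info("interaction scan: gene %s skipped (%d carriers < %d)",
                        gene, int(flags.sum()), min_carriers)
            continue
        try:
            res = fit_interaction(outcome, prs, flags,
                                  covariates, covariate_names)
        except (ValueError, SeparationError) as exc:
            logger.info("interaction scan: gene %s skipped (%s)", gene, exc)
            continue
        t = res.term("prs:carrier")
        rows[gene] = {"beta": t["beta"], "se": t["se"], "p": t["p"],
                      "OR": t["OR"], "ci_low": t["ci_low"], "ci_high": t["ci_high"]}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    if len(out):
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out


# ---------------------------------------------------------------------------
# multinomial logistic regression (Newton)
# ---------------------------------------------------------------------------

class MultinomialWald(BaseEstimator):
    """Multinomial logit with a reference category, fit by Newton's method.

    The reference category's coefficients are fixed at zero; one
    coefficient block per non-reference category. With two categories the
    model reduces exactly to binary logistic regression. Wald standard
    errors come from the inverse observed information of the full
    parameter vector.
    """

    def __init__(self, reference=None, tol: float = 1e-8, max_iter: int = 100):
        self.reference = reference
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, names=None, categories=None):
        X, names = _as_design(X, names)
        y = np.asarray(y)
        observed = pd.unique(y)
        if categories is not None:
            empty = [c for c in categories if c not in observed]
            if empty:
                raise ValueError(f"empty outcome categories: {empty}")
            cats = list(categories)
        else:
            cats = sorted(observed.tolist())
        if len(cats) < 2:
            raise ValueError("need at least two outcome categories")
        ref = self.reference if self.reference is not None else cats[0]
        if ref not in cats:
            raise ValueError(f"reference category {ref!r} not observed")
        cats = [ref] + [c for c in cats if c != ref]
        keep = _drop_collinear(X, names)
        Xk = X[:, keep]
        kept_names = [names[i] for i in keep]
        n, p = Xk.shape
        K = len(cats)
        Y = np.zeros((n, K))
        for k, c in enumerate(cats):
            Y[:, k] = (y == c).astype(float)
        B = np.zeros((p, K - 1))
        ll_prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            mu = self._probs(Xk, B)
            grad = Xk.T @ (Y[:, 1:] - mu[:, 1:])  # (p, K-1)
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            H = self._hessian(Xk, mu)
            try:
                step = linalg.solve(H, grad.ravel(order="F"), assume_a="pos")
            except linalg.LinAlgError as exc:
                raise SeparationError(f"singular information matrix: {exc}") from exc
            B_new = B + step.reshape((p, K - 1), order="F")
            ll_new = self._loglik(Xk, Y, B_new)
            halvings = 0
            while ll_new < ll_prev and halvings < 20:
                step *= 0.5
                B_new = B + step.reshape((p, K - 1), order="F")
                ll_new = self._loglik(Xk, Y, B_new)
                halvings += 1
            B, ll_prev = B_new, ll_new
        mu = self._probs(Xk, B)
        H = self._hessian(Xk, mu)
        cov = linalg.inv(H)
        se = np.sqrt(np.diag(cov)).reshape((p, K - 1), order="F")
        self.coef_ = B
        self.se_ = se
        self.cov_ = cov
        self.categories_ = cats
        self.names_ = kept_names
        self.keep_ = keep
        self.loglik_ = self._loglik(Xk, Y, B)
        self.converged_ = converged
        self.n_used_ = n
        return self

    @staticmethod
    def _probs(X, B):
        eta = np.column_stack([np.zeros(X.shape[0]), X @ B])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    @staticmethod
    def _loglik(X, Y, B):
        mu = MultinomialWald._probs(X, B)
        return float(np.sum(Y * np.log(np.clip(mu, 1e-300, None))))

    @staticmethod
    def _hessian(X, mu):
        p = X.shape[1]
        Km1 = mu.shape[1] - 1
        H = np.empty((p * Km1, p * Km1))
        for a in range(Km1):
            for b in range(Km1):
                w = mu[:, a + 1] * ((1.0 if a == b else 0.0) - mu[:, b + 1])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = (X * w[:, None]).T @ X
        return H

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._probs(X[:, self.keep_], self.coef_)

    def result(self) -> dict:
        """Per non-reference category :class:`RegressionResult`."""
        out = {}
        for k, cat in enumerate(self.categories_[1:]):
            out[cat] = RegressionResult(
                table=_wald_table(self.names_, self.coef_[:, k], self.se_[:, k]),
                loglik=self.loglik_, n=self.n_used_, converged=self.converged_,
            )
        return out


def multinomial_fit(X, y, reference=None, names=None) -> dict:
    """Functional wrapper over :class:`MultinomialWald`."""
    return MultinomialWald(reference=reference).fit(X, y, names=names).result()


# ---------------------------------------------------------------------------
# linear regression (OLS)
# ---------------------------------------------------------------------------

class LinearWald(BaseEstimator):
    """Ordinary least squares with Wald t inference."""

    def fit(self, X, y, names=None):
        X, names = _as_design(X, names)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need n > p terms ({n} rows, {p} columns)")
        keep = _drop_collinear(X, names)
        if len(keep) < p:
            raise ValueError(
                f"rank-deficient design (kept {[names[i] for i in keep]})"
            )
        beta, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        cov = sigma2 * linalg.inv(X.T @ X)
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.df_resid_ = n - p
        self.names_ = names
        self.n_used_ = n
        self.resid_ = resid
        ll = -0.5 * n * (np.log(2 * np.pi * max(sigma2 * (n - p) / n, 1e-300)) + 1)
        self.loglik_ = float(ll)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def result(self) -> RegressionResult:
        return RegressionResult(
            table=_wald_table(self.names_, self.coef_, self.se_,
                              dist="t", df=self.df_resid_, exp_scale=False),
            loglik=self.loglik_, n=self.n_used_, converged=True,
        )


def linear_fit(X, y, names=None) -> RegressionResult:
    return LinearWald().fit(X, y, names=names).result()


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    """2x2 classification metrics in percent (2 decimals); undefined -> None."""

    tp: int
    fp: int
    fn: int
    tn: int
    se: float | None = field(init=False)
    sp: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)

    def __post_init__(self):
        self.se = _pct(self.tp, self.tp + self.fn)
        self.sp = _pct(self.tn, self.tn + self.fp)
        self.ppv = _pct(self.tp, self.tp + self.fp)
        self.npv = _pct(self.tn, self.tn + self.fn)


def _pct(num, den):
    return None if den == 0 else round(100.0 * num / den, 2)


def confusion_metrics(predicted, actual) -> ConfusionMetrics:
    """SE/SP/PPV/NPV from binary predicted and actual labels."""
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    if p.shape != a.shape:
        raise ValueError("predicted and actual labels must have equal length")
    return ConfusionMetrics(
        tp=int((p & a).sum()), fp=int((p & ~a).sum()),
        fn=int((~p & a).sum()), tn=int((~p & ~a).sum()),
    )


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Mann-Whitney AUC with per-subject placement values.

    ``v_pos[i]`` is the fraction of negatives scored below positive i (ties
    half); ``v_neg[j]`` the fraction of positives scored above negative j.
    The placements feed the DeLong covariance machinery.
    """

    auc: float
    n_pos: int
    n_neg: int
    v_pos: np.ndarray
    v_neg: np.ndarray


def _placements(scores, labels) -> ROCResult:
    """Midrank (O(n log n)) placement values and AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for the AUC")
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    tz = sps.rankdata(np.concatenate([pos, neg]))
    v_pos = (tz[:m] - tx) / n
    v_neg = 1.0 - (tz[m:] - ty) / m
    return ROCResult(auc=float(v_pos.mean()), n_pos=m, n_neg=n,
                     v_pos=v_pos, v_neg=v_neg)


def auc(scores, labels) -> ROCResult:
    """AUC as the probability of correct ordering, ties counted half."""
    return _placements(scores, labels)


def _placements_naive(scores, labels) -> ROCResult:
    """O(n^2) structural-components formulation (test oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for the AUC")
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return ROCResult(auc=float(psi.mean()), n_pos=m, n_neg=n,
                     v_pos=psi.mean(axis=1), v_neg=psi.mean(axis=0))


def auc_variance(roc: ROCResult) -> float:
    """DeLong variance of a single AUC from its placement values."""
    s10 = np.var(roc.v_pos, ddof=1) if roc.n_pos > 1 else 0.0
    s01 = np.var(roc.v_neg, ddof=1) if roc.n_neg > 1 else 0.0
    return s10 / roc.n_pos + s01 / roc.n_neg


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels, placements=_placements) -> DeLongResult:
    """Paired DeLong test for the difference of two correlated AUCs.

    Variance of the difference from the placement-value covariance;
    two-sided normal p. Identical placements (zero variance) report
    delta 0, p 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("score vectors and labels must have equal length")
    ra = placements(scores_a, labels)
    rb = placements(scores_b, labels)
    delta = ra.auc - rb.auc
    d_pos = ra.v_pos - rb.v_pos
    d_neg = ra.v_neg - rb.v_neg
    var = (np.var(d_pos, ddof=1) / ra.n_pos if ra.n_pos > 1 else 0.0) \
        + (np.var(d_neg, ddof=1) / ra.n_neg if ra.n_neg > 1 else 0.0)
    if var <= 0:
        return DeLongResult(ra.auc, rb.auc, 0.0, 0.0, 1.0)
    z = delta / np.sqrt(var)
    return DeLongResult(ra.auc, rb.auc, float(delta), float(z),
                        float(2 * sps.norm.sf(abs(z))))


def lrt_pvalue(loglik_full: float, loglik_null: float, df: int) -> float:
    """Likelihood-ratio test p-value for nested models."""
    stat = 2.0 * (loglik_full - loglik_null)
    return float(sps.chi2.sf(max(stat, 0.0), df))
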