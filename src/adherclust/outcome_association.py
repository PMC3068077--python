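"""Relating adherence clusters (or feature vectors) to a binary outcome.

Provides the downstream epidemiological toolkit: cluster-by-outcome
contingency tables, odds ratios against a reference cluster with 95%
confidence intervals, Pearson chi-square tests, logistic linear predictors
over feature vectors, and ROC curves with trapezoid AUC (equal to the
Mann-Whitney concordance probability with half credit for ties).

Odds-ratio CIs default to profile-likelihood intervals — the interval R's
``confint`` produces for a binomial GLM, and noticeably asymmetric when
event counts are small — with the classical Wald interval
exp(log OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)) available via
``ci_method="wald"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as _stats
from sklearn import metrics as _skm

from .clustering import ClusterAssignment

__all__ = [
    "OutcomeTable",
    "ORResult",
    "ROCCurve",
    "LinearPredictorFit",
    "reconstruct_event_counts",
    "odds_ratios_vs_reference",
    "chi_square_independence",
    "cluster_risk_scores",
    "fit_logistic",
    "roc_curve",
]


@dataclass(frozen=True)
class OutcomeTable:
    """Per-cluster subject and event counts, with a designated reference."""

    cluster_ids: tuple[int, ...]
    n: tuple[int, ...]
    events: tuple[int, ...]
    reference: int

    def __post_init__(self) -> None:
        if len({len(self.cluster_ids), len(self.n), len(self.events)}) != 1:
            raise ValueError("cluster_ids, n and events must align")
        for c, n_c, e_c in zip(self.cluster_ids, self.n, self.events):
            if not (0 <= e_c <= n_c):
                raise ValueError(f"cluster {c}: events {e_c} outside 0..{n_c}")
        if self.reference not in self.cluster_ids:
            raise ValueError(f"reference cluster {self.reference} not present")

    @classmethod
    def from_assignment(
        cls,
        assignment: ClusterAssignment,
        outcomes: np.ndarray,
        reference: int | str = "last",
    ) -> "OutcomeTable":
        """Tabulate events by cluster. ``reference`` is a cluster id, or
        ``"last"`` (the highest label, i.e. the smallest cluster under the
        size-ordered labelling) or ``"lowest_rate"``."""
        labels = np.asarray(assignment.labels)
        y = np.asarray(outcomes, dtype=int)
        if labels.shape != y.shape:
            raise ValueError("outcomes do not align with assignment")
        ids = tuple(range(1, assignment.k + 1))
        n = tuple(int((labels == c).sum()) for c in ids)
        ev = tuple(int(y[labels == c].sum()) for c in ids)
        if reference == "last":
            ref = ids[-1]
        elif reference == "lowest_rate":
            rates = [e / max(m, 1) for e, m in zip(ev, n)]
            ref = ids[int(np.argmin(rates))]
        else:
            ref = int(reference)
        return cls(ids, n, ev, ref)


@dataclass(frozen=True)
class ORResult:
    """Odds ratios vs the reference cluster with Wald 95% CIs.

    ``or_``, ``ci_low`` and ``ci_high`` are keyed by cluster id; the
    reference cluster carries OR exactly 1 with no interval. A zero cell in
    a comparison cluster leaves its OR (possibly 0 or inf) with NaN CI and
    the cluster listed in ``flagged``.
    """

    or_: dict[int, float]
    ci_low: dict[int, float]
    ci_high: dict[int, float]
    reference: int
    flagged: tuple[int, ...] = ()


def reconstruct_event_counts(n: int, proportion: float) -> int:
    """Round n * proportion to the nearest integer, half away from zero.

    Used to recover integer event counts from a published (size, rate)
    pair, e.g. (309, 0.061) -> 19.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must lie in [0, 1]")
    return int(math.floor(n * proportion + 0.5))


#: chi-square(1) critical value at 95%, for profile-likelihood inversion
_CHI2_1_95 = 3.841458820694124


def _binom_ll(a: int, n1: int, c: int, n0: int, alpha: float, beta: float) -> float:
    """Log-likelihood of logit(p) = alpha + beta*x on two binomial groups."""
    return (
        a * (alpha + beta)
        - n1 * np.log1p(np.exp(alpha + beta))
        + c * alpha
        - n0 * np.log1p(np.exp(alpha))
    )


def _profile_ll(beta: float, a: int, n1: int, c: int, n0: int) -> float:
    """Maximize the two-group binomial log-likelihood over the intercept."""
    from scipy import optimize as _opt

    def dll(alpha: float) -> float:
        p1 = 1.0 / (1.0 + math.exp(-(alpha + beta)))
        p0 = 1.0 / (1.0 + math.exp(-alpha))
        return (a + c) - n1 * p1 - n0 * p0

    alpha = _opt.brentq(dll, -40.0, 40.0, xtol=1e-12)
    return _binom_ll(a, n1, c, n0, alpha, beta)


def _profile_ci_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """95% profile-likelihood CI for the odds ratio of a 2x2 table.

    Inverts the likelihood-ratio test: the bounds are the values of
    log OR whose profile log-likelihood drops chi2_1(0.95)/2 below the
    maximum. Requires all four cells positive.
    """
    from scipy import optimize as _opt

    n1, n0 = a + b, c + d
    beta_hat = math.log((a * d) / (b * c))
    ll_max = _profile_ll(beta_hat, a, n1, c, n0)
    target = ll_max - _CHI2_1_95 / 2.0

    def g(beta: float) -> float:
        return _profile_ll(beta, a, n1, c, n0) - target

    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    step = 4.0 * se
    low_bracket = beta_hat - step
    while g(low_bracket) > 0:
        low_bracket -= step
    high_bracket = beta_hat + step
    while g(high_bracket) > 0:
        high_bracket += step
    lo = _opt.brentq(g, low_bracket, beta_hat, xtol=1e-10)
    hi = _opt.brentq(g, beta_hat, high_bracket, xtol=1e-10)
    return math.exp(lo), math.exp(hi)


def odds_ratios_vs_reference(
    table: OutcomeTable, ci_method: str = "profile"
) -> ORResult:
    """Odds ratio of each cluster against the reference, with 95% CI.

    OR_c = (e_c / (n_c - e_c)) / (e_r / (n_r - e_r)). ``ci_method`` is
    ``"profile"`` (likelihood-ratio inversion, asymmetric, matches R's
    ``confint`` on a binomial GLM) or ``"wald"``
    (exp(log OR +/- 1.96 * SE) with SE = sqrt(1/a + 1/b + 1/c + 1/d)).
    """
    if ci_method not in ("profile", "wald"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    i_ref = table.cluster_ids.index(table.reference)
    e_r, n_r = table.events[i_ref], table.n[i_ref]
    if e_r == 0 or e_r == n_r:
        raise ValueError(
            "reference cluster needs at least one event and one non-event"
        )
    odds_ref = e_r / (n_r - e_r)
    or_, lo, hi, flagged = {}, {}, {}, []
    for c, n_c, e_c in zip(table.cluster_ids, table.n, table.events):
        if c == table.reference:
            or_[c] = 1.0
            lo[c] = hi[c] = float("nan")
            continue
        a, b = e_c, n_c - e_c
        if a == 0 or b == 0:
            or_[c] = 0.0 if a == 0 else float("inf")
            lo[c] = hi[c] = float("nan")
            flagged.append(c)
            continue
        or_[c] = (a / b) / odds_ref
        if ci_method == "wald":
            se = math.sqrt(1 / a + 1 / b + 1 / e_r + 1 / (n_r - e_r))
            lo[c] = or_[c] * math.exp(-1.96 * se)
            hi[c] = or_[c] * math.exp(1.96 * se)
        else:
            lo[c], hi[c] = _profile_ci_2x2(a, b, e_r, n_r - e_r)
    return ORResult(or_, lo, hi, table.reference, tuple(flagged))


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    res = _stats.chi2_contingency(tab, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cluster_risk_scores(
    table: OutcomeTable, assignment: ClusterAssignment
) -> np.ndarray:
    """Per-subject score = in-sample event rate of the subject's cluster.

    This makes the categorical cluster variable usable in a ROC analysis;
    it equals the fitted probability of a logistic model on cluster
    indicators.
    """
    labels = np.asarray(assignment.labels)
    rates = {
        c: e / n for c, n, e in zip(table.cluster_ids, table.n, table.events)
    }
    return np.array([rates[c] for c in labels])


@dataclass(frozen=True)
class LinearPredictorFit:
    """Logistic-regression coefficients over a feature matrix Z."""

    intercept: float
    coefficients: np.ndarray
    converged: bool

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(X)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(features, outcomes) -> LinearPredictorFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``features`` is an (N, d) matrix (or list of FeatureVector); an
    intercept is added. Complete separation or other non-convergence is
    reported through the ``converged`` flag rather than raised.
    """
    from .clustering import _as_matrix

    X = _as_matrix(features)
    y = np.asarray(outcomes, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("outcomes do not align with features")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    converged = True
    try:
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = model.fit(maxiter=100, tol=1e-8)
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        converged = (
            bool(res.converged)
            and np.isfinite(res.params).all()
            and not separated
        )
        params = np.asarray(res.params, dtype=float)
    except Exception:
        converged = False
        params = np.full(design.shape[1], np.nan)
    return LinearPredictorFit(
        intercept=float(params[0]),
        coefficients=params[1:],
        converged=converged,
    )


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve points (FPR, TPR) from (0,0) to (1,1) and trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        f, t = np.asarray(self.fpr, float), np.asarray(self.tpr, float)
        object.__setattr__(self, "fpr", f)
        object.__setattr__(self, "tpr", t)
        if not (f[0] == 0 and t[0] == 0 and f[-1] == 1 and t[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if (np.diff(f) < 0).any() or (np.diff(t) < 0).any():
            raise ValueError("ROC coordinates must be non-decreasing")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def roc_curve(scores, outcomes) -> ROCCurve:
    """ROC curve over all cutoffs of a real-valued score, tied scores grouped.

    The trapezoid AUC equals the probability that a random event subject
    scores above a random non-event subject, counting ties as 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores do not align with outcomes")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return ROCCurve(fpr, tpr, thr, auc)
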