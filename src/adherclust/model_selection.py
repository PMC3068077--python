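"""Conditional log-likelihoods under the nested models and LRTs.

The three models form a nested family: iid states (M1) are a homogeneous
first-order chain (M2) with identical rows, which is a non-homogeneous
chain (M3) with equal period matrices. To keep the likelihoods comparable,
all models are scored CONDITIONALLY on each subject's first state: every
model assigns a probability to the same events X_2..X_T, using pooled
plug-in maximum-likelihood estimates over the supplied subjects. An
order-2 chain is also supported; it scores X_3..X_T and so must be
compared against an order-1 fit restricted to the same visits
(``first_scored_visit=3``).

Under plug-in MLEs an observed event can never receive probability zero;
unobserved cells simply contribute no terms. Optional additive smoothing
(``alpha``) is available for predictive use, off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .trajectories import Cohort

__all__ = ["ModelFit", "LRTResult", "conditional_loglik", "likelihood_ratio_test"]

#: which model strictly contains which (small -> set of larger models)
_NESTS_IN = {
    "M1": {"M2", "M3", "ORDER2"},
    "M2": {"M3", "ORDER2"},
    "M3": set(),
    "ORDER2": set(),
}


@dataclass(frozen=True)
class ModelFit:
    model: str
    loglik: float
    n_params: int
    n_used_transitions: int
    first_scored_visit: int

    def __post_init__(self) -> None:
        if self.loglik > 1e-9:
            raise ValueError("log-likelihood of a discrete model cannot exceed 0")


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def _param_count(model: str, S: int) -> int:
    return {
        "M1": S - 1,
        "M2": S * (S - 1),
        "M3": 2 * S * (S - 1),
        "ORDER2": S * S * (S - 1),
    }[model]


def conditional_loglik(
    cohort: Cohort,
    model: str,
    t1: int | None = None,
    first_scored_visit: int | None = None,
    alpha: float = 0.0,
) -> ModelFit:
    """Pooled-MLE conditional log-likelihood of a cohort under one model.

    Visits ``first_scored_visit..T`` are scored (default 2; 3 for the
    order-2 chain). M1 uses pooled state proportions over the scored
    visits; M2 pooled conditional transition MLEs; M3 per-period MLEs with
    the transition into visit t in period 1 iff t <= t1; ORDER2 pooled
    second-order conditional MLEs. ``alpha`` adds a pseudo-count to every
    cell before normalizing (0 = pure MLE).
    """
    if model not in _NESTS_IN:
        raise ValueError(f"unknown model {model!r}")
    codes = cohort.codes
    N, T = codes.shape
    if N == 0:
        raise ValueError("empty cohort")
    S = cohort.state_space.n_states
    default_first = 3 if model == "ORDER2" else 2
    first = default_first if first_scored_visit is None else int(first_scored_visit)
    if first < default_first or first > T:
        raise ValueError(
            f"first_scored_visit={first} invalid for model {model} with T={T}"
        )
    scored = np.arange(first, T + 1)  # 1-based visit indices being scored
    n_events = N * len(scored)

    if model == "M1":
        counts = np.bincount(codes[:, first - 1 :].ravel(), minlength=S).astype(float)
        probs = (counts + alpha) / (counts + alpha).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.nansum(counts * np.where(counts > 0, np.log(probs), 0.0)))
    elif model in ("M2", "M3"):
        if model == "M3":
            if t1 is None:
                raise ValueError("model M3 requires the change point t1")
            if not (2 <= t1 <= T - 1):
                raise ValueError(f"change point t1={t1} must satisfy 2 <= t1 <= T-1")
            periods = [scored[scored <= t1], scored[scored > t1]]
        else:
            periods = [scored]
        ll = 0.0
        for visits in periods:
            if len(visits) == 0:
                continue
            counts = np.zeros((S, S))
            cols = visits - 1
            np.add.at(counts, (codes[:, cols - 1].ravel(), codes[:, cols].ravel()), 1.0)
            ll += _conditional_ll(counts, alpha)
        ll = float(ll)
    else:  # ORDER2
        counts = np.zeros((S * S, S))
        cols = scored - 1
        pair = codes[:, cols - 2].ravel() * S + codes[:, cols - 1].ravel()
        np.add.at(counts, (pair, codes[:, cols].ravel()), 1.0)
        ll = float(_conditional_ll(counts, alpha))

    return ModelFit(
        model=model,
        loglik=min(ll, 0.0),
        n_params=_param_count(model, S),
        n_used_transitions=n_events,
        first_scored_visit=first,
    )


def _conditional_ll(counts: np.ndarray, alpha: float) -> float:
    row_sums = (counts + alpha).sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(row_sums > 0, (counts + alpha) / row_sums, 0.0)
        terms = np.where(counts > 0, counts * np.log(probs), 0.0)
    return float(terms.sum())


def likelihood_ratio_test(fit_small: ModelFit, fit_big: ModelFit) -> LRTResult:
    """LRT between two nested fits on the same cohort and scored visits.

    statistic = 2 (loglik_big - loglik_small) >= 0; df = difference in
    free-parameter counts; p from the chi-square upper tail.
    """
    if fit_big.model not in _NESTS_IN[fit_small.model]:
        raise ValueError(
            f"model {fit_small.model} is not nested in {fit_big.model}"
        )
    if (
        fit_small.n_used_transitions != fit_big.n_used_transitions
        or fit_small.first_scored_visit != fit_big.first_scored_visit
    ):
        raise ValueError(
            "fits score different events; refit both with the same cohort "
            "and first_scored_visit"
        )
    stat = 2.0 * (fit_big.loglik - fit_small.loglik)
    if stat < -1e-7:
        raise ValueError(
            f"negative LRT statistic {stat}: fits are not from the same data"
        )
    stat = max(stat, 0.0)
    df = fit_big.n_params - fit_small.n_params
    p = float(_stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=df, p_value=p)
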