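"""Cluster characterization: pooled proportions and transition tables.

Pooling is by counts, not by averaging member probability matrices: within
a cluster the transition probabilities are assumed shared, so summing
member transition counts and row-normalizing is the maximum-likelihood
estimate and stays well defined when some members never visit a state.
Tables render with 3 decimals and "." for undefined cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clustering import ClusterAssignment
from .markov_features import ConditionalTransitionMatrix, ProportionVector
from .trajectories import Cohort, StateSpace

__all__ = [
    "ClusterProfile",
    "pooled_proportions",
    "pooled_transitions",
    "characterize",
    "render_profiles",
]

#: default retention-probability thresholds for captioning
DEFAULT_THRESHOLDS = {
    "optimal": 0.995,  # retention of the good state ~ 1
    "good": 0.85,
    "moderate": 0.60,
    "trend": 0.05,  # |period2 - period1| beyond this is a trend
}


@dataclass(frozen=True)
class ClusterProfile:
    cluster_id: int
    n: int
    proportions: ProportionVector | None = None
    transitions: tuple[ConditionalTransitionMatrix, ...] = ()
    caption: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cluster size must be >= 1")


def _cluster_indices(assignment: ClusterAssignment):
    labels = np.asarray(assignment.labels)
    for c in range(1, assignment.k + 1):
        yield c, np.flatnonzero(labels == c)


def pooled_proportions(
    cohort: Cohort, assignment: ClusterAssignment
) -> list[ClusterProfile]:
    """Per-cluster state proportions from pooled visit counts.

    Because all trajectories share one T, this equals the unweighted mean
    of the members' individual proportion vectors.
    """
    if len(assignment.labels) != cohort.n_subjects:
        raise ValueError("assignment does not align with cohort")
    S = cohort.state_space.n_states
    out = []
    for c, idx in _cluster_indices(assignment):
        counts = np.bincount(cohort.codes[idx].ravel(), minlength=S).astype(float)
        out.append(
            ClusterProfile(
                cluster_id=c,
                n=len(idx),
                proportions=ProportionVector(counts / counts.sum(), cohort.state_space),
            )
        )
    return out


def _pooled_pair_counts(codes: np.ndarray, S: int, start: int, stop: int) -> np.ndarray:
    prev = codes[:, start : stop - 1].ravel()
    nxt = codes[:, start + 1 : stop].ravel()
    counts = np.zeros((S, S))
    np.add.at(counts, (prev, nxt), 1.0)
    return counts


def _conditional(counts: np.ndarray, space: StateSpace) -> ConditionalTransitionMatrix:
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    values = np.full_like(counts, np.nan)
    values[defined] = counts[defined] / row_sums[defined, None]
    return ConditionalTransitionMatrix(values, defined, space)


def pooled_transitions(
    cohort: Cohort,
    assignment: ClusterAssignment,
    model: str = "M2",
    t1: int | None = None,
) -> list[ClusterProfile]:
    """Per-cluster conditional transition tables from pooled pair counts.

    ``model="M2"`` gives one table per cluster over all T-1 transitions;
    ``model="M3"`` gives two (period 1 = transitions ending at visits
    2..t1, period 2 = the rest). Rows whose source state is never occupied
    are undefined.
    """
    if len(assignment.labels) != cohort.n_subjects:
        raise ValueError("assignment does not align with cohort")
    if model not in ("M2", "M3"):
        raise ValueError("pooled transitions are defined for models M2 and M3")
    T = cohort.n_visits
    if model == "M3":
        if t1 is None:
            raise ValueError("model M3 requires the change point t1")
        if not (2 <= t1 <= T - 1):
            raise ValueError(f"change point t1={t1} must satisfy 2 <= t1 <= T-1")
        spans = [(0, t1), (t1 - 1, T)]
    else:
        spans = [(0, T)]
    S = cohort.state_space.n_states
    out = []
    for c, idx in _cluster_indices(assignment):
        mats = tuple(
            _conditional(
                _pooled_pair_counts(cohort.codes[idx], S, a, b), cohort.state_space
            )
            for a, b in spans
        )
        prof = ClusterProfile(cluster_id=c, n=len(idx), transitions=mats)
        out.append(replace(prof, caption=""))
    return out


def characterize(
    profile: ClusterProfile,
    good_state: str = "1",
    thresholds: dict | None = None,
) -> str:
    """Deterministic rule-based caption from good-state retention per period.

    Retention = P(good -> good) in each period's conditional table. Levels:
    optimal / good / moderate / poor by the configured thresholds; a
    between-period change beyond the trend threshold adds "getting better"
    or "getting worse"; retention ~ 1 in every period with no other defined
    dynamics reads "optimal in both periods".
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if not profile.transitions:
        raise ValueError("profile has no transition tables to characterize")
    space = profile.transitions[0].state_space
    g = space.index(good_state)
    retention = []
    for mat in profile.transitions:
        retention.append(mat.values[g, g] if mat.defined_rows[g] else np.nan)

    def level(r: float) -> str:
        if np.isnan(r):
            return "undefined"
        if r >= th["optimal"]:
            return "optimal"
        if r >= th["good"]:
            return "good"
        if r >= th["moderate"]:
            return "moderate"
        return "poor"

    levels = [level(r) for r in retention]
    if len(retention) == 1:
        return f"{levels[0]} adherence"
    r1, r2 = retention[0], retention[1]
    l1, l2 = levels
    if l1 == "optimal" and l2 == "optimal":
        return "optimal in both periods"
    if np.isnan(r1) or np.isnan(r2):
        return f"period 1 {l1}, period 2 {l2}"
    rank = {"poor": 0, "moderate": 1, "good": 2, "optimal": 3}
    jump = rank[l2] - rank[l1]
    if abs(jump) >= 2:
        return f"first {l1}, then {l2}"
    if r2 - r1 > th["trend"]:
        return f"{l1} adherence, getting better"
    if r1 - r2 > th["trend"]:
        return f"{l1} adherence, getting worse"
    if l1 == l2:
        return f"{l1} adherence, stable"
    return f"first {l1}, then {l2}"


def _fmt(x: float) -> str:
    return "." if np.isnan(x) else f"{x:.3f}"


def render_profiles(profiles: list[ClusterProfile]) -> str:
    """Plain-text report of cluster profiles, one block per cluster.

    Probabilities print with 3 decimals; undefined cells print ".". Every
    defined row closes with its sum (1.000 up to rounding).
    """
    lines = []
    for p in profiles:
        header = f"Cluster {p.cluster_id} (n = {p.n})"
        if p.caption:
            header += f": {p.caption}"
        lines.append(header)
        if p.proportions is not None:
            space = p.proportions.state_space
            lines.append("  state " + "  ".join(f"{l:>6}" for l in space.labels) + "       Σ")
            vals = "  ".join(f"{v:6.3f}" for v in p.proportions.values)
            lines.append(f"  P     {vals}   {p.proportions.values.sum():6.3f}")
        for period, mat in enumerate(p.transitions, start=1):
            space = mat.state_space
            if len(p.transitions) > 1:
                lines.append(f"  period {period}")
            lines.append("    " + "  ".join(f"{l:>6}" for l in space.labels) + "       Σ")
            for i, lab in enumerate(space.labels):
                row = mat.values[i]
                cells = "  ".join(f"{_fmt(v):>6}" for v in row)
                sigma = f"{row.sum():6.3f}" if mat.defined_rows[i] else "     ."
                lines.append(f"  {lab:>2}  {cells}   {sigma}")
        lines.append("")
    return "\n".join(lines)
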