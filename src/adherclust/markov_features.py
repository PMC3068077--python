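"""Per-subject Markov-chain feature vectors for trajectory clustering.

Each subject's state sequence is condensed into a probability vector Z
under one of three nested models:

* ``M1`` — states independent and identically distributed: Z is the
  length-S vector of state proportions.
* ``M2`` — homogeneous first-order Markov chain: Z = vec(Q), the
  column-stacked S x S matrix of *joint* consecutive-pair proportions
  q_ij = #{t : X_{t-1}=i, X_t=j} / (T-1).
* ``M3`` — non-homogeneous chain with a known change point t1: Z =
  vec(Q1, Q2) of length 2*S^2, one joint matrix per period.

Joint (not conditional) matrices are used so that subjects who never visit
a state still get a well-defined vector — no division by zero. Conditional
transition matrices P = row-normalized Q are used only for interpretation.
Feature vectors are never standardized: every coordinate is already a
probability on the same scale.

The change-point convention: the transition ending at visit t belongs to
period 1 iff t <= t1, so the straddling step t1 -> t1+1 counts in period 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectories import Cohort, StateSpace, Trajectory

__all__ = [
    "ProportionVector",
    "JointTransitionMatrix",
    "ConditionalTransitionMatrix",
    "FeatureVector",
    "Order2JointArray",
    "estimate_state_proportions",
    "estimate_joint_transition_matrix",
    "row_normalize",
    "vectorize",
    "devectorize",
    "build_feature_vector",
    "estimate_order2_joint",
    "feature_matrix",
    "MODELS",
]

MODELS = ("M1", "M2", "M3")


@dataclass(frozen=True)
class ProportionVector:
    """Length-S vector of state occupancy proportions; sums to 1."""

    values: np.ndarray
    state_space: StateSpace

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.state_space.n_states,):
            raise ValueError("proportion vector length must equal S")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions sum to {v.sum()}, not 1")


@dataclass(frozen=True)
class JointTransitionMatrix:
    """S x S joint pair-proportion matrix Q; entries sum to 1."""

    values: np.ndarray
    n_transitions: int
    state_space: StateSpace

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        S = self.state_space.n_states
        if v.shape != (S, S):
            raise ValueError("Q must be S x S")
        if self.n_transitions > 0 and abs(v.sum() - 1.0) > 1e-12:
            raise ValueError(f"Q entries sum to {v.sum()}, not 1")


@dataclass(frozen=True)
class ConditionalTransitionMatrix:
    """Row-conditional matrix P(X_t=j | X_{t-1}=i) with undefined-row flags.

    A row is undefined when the subject (or pooled cluster) never occupied
    the source state; such rows carry NaN and are rendered "." in reports.
    """

    values: np.ndarray
    defined_rows: np.ndarray
    state_space: StateSpace

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        d = np.asarray(self.defined_rows, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "defined_rows", d)
        for i, ok in enumerate(d):
            if ok and abs(v[i].sum() - 1.0) > 1e-12:
                raise ValueError(f"defined row {i} sums to {v[i].sum()}, not 1")


@dataclass(frozen=True)
class FeatureVector:
    """Model-tagged clustering vector Z of length S, S^2, or 2*S^2."""

    model: str
    values: np.ndarray
    state_space: StateSpace
    change_point: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        S = self.state_space.n_states
        expected = {"M1": S, "M2": S * S, "M3": 2 * S * S}[self.model]
        if v.shape != (expected,):
            raise ValueError(
                f"{self.model} vector must have length {expected}, got {v.shape}"
            )
        if self.model == "M3" and self.change_point is None:
            raise ValueError("M3 feature vector requires its change point")


@dataclass(frozen=True)
class Order2JointArray:
    """S x S x S joint proportions over consecutive state triples."""

    values: np.ndarray
    n_triples: int
    state_space: StateSpace


def estimate_state_proportions(
    traj: Trajectory, space: StateSpace
) -> ProportionVector:
    """Proportion of visits spent in each state: entry s = #{t: X_t=s} / T."""
    codes = space.encode(traj.states)
    counts = np.bincount(codes, minlength=space.n_states).astype(float)
    return ProportionVector(counts / len(codes), space)


def estimate_joint_transition_matrix(
    traj: Trajectory,
    space: StateSpace,
    from_visit: int = 1,
    to_visit: int | None = None,
) -> JointTransitionMatrix:
    """Joint pair proportions over transitions ending at visits
    ``from_visit+1 .. to_visit`` (1-based, inclusive).

    Entry (i, j) = #{t in span : X_{t-1}=i, X_t=j} / (to_visit - from_visit).
    The default span is the whole trajectory, i.e. denominator T-1.
    """
    T = len(traj)
    if to_visit is None:
        to_visit = T
    if not (1 <= from_visit < to_visit <= T):
        raise ValueError(
            f"invalid span ({from_visit}, {to_visit}] for T={T}; "
            "need at least one transition"
        )
    codes = space.encode(traj.states)
    return _joint_from_codes(codes, space, from_visit, to_visit)


def _joint_from_codes(
    codes: np.ndarray, space: StateSpace, from_visit: int, to_visit: int
) -> JointTransitionMatrix:
    S = space.n_states
    prev = codes[from_visit - 1 : to_visit - 1]
    nxt = codes[from_visit:to_visit]
    counts = np.zeros((S, S))
    np.add.at(counts, (prev, nxt), 1.0)
    n = to_visit - from_visit
    return JointTransitionMatrix(counts / n, n, space)


def row_normalize(q: JointTransitionMatrix) -> ConditionalTransitionMatrix:
    """Divide each row of Q by its row sum; all-zero rows become undefined."""
    row_sums = q.values.sum(axis=1)
    defined = row_sums > 0
    values = np.full_like(q.values, np.nan)
    values[defined] = q.values[defined] / row_sums[defined, None]
    return ConditionalTransitionMatrix(values, defined, q.state_space)


def vectorize(q: JointTransitionMatrix) -> FeatureVector:
    """Stack the columns of Q into the M2 clustering vector Z = vec(Q)."""
    return FeatureVector("M2", q.values.flatten(order="F"), q.state_space)


def devectorize(z: np.ndarray | FeatureVector, space: StateSpace) -> np.ndarray:
    """Invert :func:`vectorize`: rebuild the S x S matrix from vec(Q)."""
    v = z.values if isinstance(z, FeatureVector) else np.asarray(z, dtype=float)
    S = space.n_states
    if v.shape != (S * S,):
        raise ValueError(f"expected length {S * S}, got {v.shape}")
    return v.reshape((S, S), order="F")


def build_feature_vector(
    traj: Trajectory,
    space: StateSpace,
    model: str,
    t1: int | None = None,
) -> FeatureVector:
    """The model-appropriate clustering vector Z for one subject.

    For M3, ``t1`` is the (known, fixed) change point: period 1 covers the
    t1-1 transitions ending at visits 2..t1, period 2 the T-t1 transitions
    ending at visits t1+1..T, each half normalized within its period.
    """
    if model == "M1":
        return FeatureVector("M1", estimate_state_proportions(traj, space).values, space)
    if model == "M2":
        return vectorize(estimate_joint_transition_matrix(traj, space))
    if model == "M3":
        T = len(traj)
        if t1 is None:
            raise ValueError("model M3 requires the change point t1")
        if not (2 <= t1 <= T - 1):
            raise ValueError(f"change point t1={t1} must satisfy 2 <= t1 <= T-1={T - 1}")
        q1 = estimate_joint_transition_matrix(traj, space, 1, t1)
        q2 = estimate_joint_transition_matrix(traj, space, t1, T)
        values = np.concatenate(
            [q1.values.flatten(order="F"), q2.values.flatten(order="F")]
        )
        return FeatureVector("M3", values, space, change_point=t1)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def estimate_order2_joint(traj: Trajectory, space: StateSpace) -> Order2JointArray:
    """Joint proportions of consecutive triples, for the order-2 chain.

    Entry (i, j, k) = #{t >= 3 : X_{t-2}=i, X_{t-1}=j, X_t=k} / (T-2).
    """
    T = len(traj)
    if T < 3:
        raise ValueError(f"order-2 estimation needs T >= 3, got T={T}")
    codes = space.encode(traj.states)
    S = space.n_states
    counts = np.zeros((S, S, S))
    np.add.at(counts, (codes[:-2], codes[1:-1], codes[2:]), 1.0)
    return Order2JointArray(counts / (T - 2), T - 2, space)


def feature_matrix(
    cohort: Cohort, model: str, t1: int | None = None
) -> np.ndarray:
    """(N, d) matrix of feature vectors Z for a whole cohort.

    Vectorized over the cohort's code array; row order matches
    ``cohort.subject_ids``. Emits a warning if some M3 period would have
    zero transitions (cannot happen for 2 <= t1 <= T-1).
    """
    codes = cohort.codes
    N, T = codes.shape
    S = cohort.state_space.n_states
    if model == "M1":
        out = np.zeros((N, S))
        rows = np.repeat(np.arange(N), T)
        np.add.at(out, (rows, codes.ravel()), 1.0)
        return out / T
    if model == "M2":
        return _pair_features(codes, S, 0, T)
    if model == "M3":
        if t1 is None:
            raise ValueError("model M3 requires the change point t1")
        if not (2 <= t1 <= T - 1):
            raise ValueError(f"change point t1={t1} must satisfy 2 <= t1 <= T-1={T - 1}")
        if t1 - 1 == 0 or T - t1 == 0:  # defensive; excluded by the bound above
            warnings.warn("an M3 period has no transitions; its half is all zero")
        z1 = _pair_features(codes, S, 0, t1)
        z2 = _pair_features(codes, S, t1 - 1, T)
        return np.hstack([z1, z2])
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _pair_features(codes: np.ndarray, S: int, start: int, stop: int) -> np.ndarray:
    """Per-subject vec(Q) over transitions within columns [start, stop)."""
    N = codes.shape[0]
    prev = codes[:, start : stop - 1]
    nxt = codes[:, start + 1 : stop]
    n = stop - start - 1
    counts = np.zeros((N, S, S))
    rows = np.repeat(np.arange(N), n)
    np.add.at(counts, (rows, prev.ravel(), nxt.ravel()), 1.0)
    # column-major vec of each S x S slice
    return counts.transpose(0, 2, 1).reshape(N, S * S) / n
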