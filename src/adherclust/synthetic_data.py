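"""Latent-cluster Markov-mixture cohort simulator.

Generates cohorts from K latent clusters, each with its own initial state
distribution and (optionally two-period) transition matrix over the
adherence states, plus cluster-linked Bernoulli outcomes. This makes every
pipeline stage testable end to end: the generating partition is returned
alongside the cohort, so recovery can be scored with the adjusted Rand
index, and the generating dynamics are known for likelihood-ratio
calibration.

Randomness contract: one root seed; every subject draws from its own
deterministic substream (``SeedSequence.spawn``), so cohort content does
not depend on generation order.

``dart_like_spec`` returns a ready-made 6-cluster, 3-state, 12-visit,
change-point-at-6 specification whose per-period transition rows, cluster
sizes (519, 309, 408, 441, 433, 850; total 2960) and death probabilities
(0.033, 0.061, 0.034, 0.048, 0.020, 0.024; ~100 expected deaths) mirror a
published ART-adherence cohort's fitted cluster structure. Printed rows
are renormalized to sum exactly to one (they are rounded to 3 decimals at
the source). Rows printed as undefined ("." — the source state is never
occupied) are encoded as NaN rows that raise if ever reached; the one
undefined-but-reachable case (states other than the good state at the
change point in the first-good-then-optimal cluster) is filled with a
point mass on the good state, which is the observed behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectories import Cohort, StateSpace, default_state_space

__all__ = [
    "ClusterSpec",
    "SimSpec",
    "generate_cohort",
    "generate_outcomes",
    "dart_like_spec",
    "three_cluster_recovery_spec",
    "dynamics_only_spec",
    "homogeneous_spec",
]


@dataclass(frozen=True)
class ClusterSpec:
    """One latent cluster: size, initial law, per-period transition rows.

    ``transition2`` is used for transitions into visits t1+1..T when the
    simulation has a change point; otherwise ``transition`` governs the
    whole follow-up. Rows of all NaN mark states the cluster can never
    occupy; reaching one raises at generation time.
    """

    size: int
    initial: np.ndarray
    transition: np.ndarray
    transition2: np.ndarray | None = None
    outcome_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        init = np.asarray(self.initial, dtype=float)
        object.__setattr__(self, "initial", init)
        if abs(init.sum() - 1.0) > 1e-9 or (init < 0).any():
            raise ValueError("initial distribution must be a probability vector")
        for name in ("transition", "transition2"):
            mat = getattr(self, name)
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=float)
            object.__setattr__(self, name, mat)
            S = len(init)
            if mat.shape != (S, S):
                raise ValueError(f"{name} must be {S}x{S}")
            for i, row in enumerate(mat):
                if np.isnan(row).all():
                    continue  # unreachable state
                if np.isnan(row).any() or (row < 0).any() or abs(row.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{name} row {i} is not a probability vector")
        if not (0.0 <= self.outcome_prob <= 1.0):
            raise ValueError("outcome probability must lie in [0, 1]")


@dataclass(frozen=True)
class SimSpec:
    """K-cluster Markov-mixture cohort description."""

    state_space: StateSpace
    n_visits: int
    clusters: tuple[ClusterSpec, ...]
    change_point: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 2:
            raise ValueError("need at least 2 visits")
        if not self.clusters:
            raise ValueError("need at least one cluster")
        if self.change_point is not None and not (
            2 <= self.change_point <= self.n_visits - 1
        ):
            raise ValueError("change point must satisfy 2 <= t1 <= T-1")
        S = self.state_space.n_states
        for c in self.clusters:
            if len(c.initial) != S:
                raise ValueError("cluster dimension does not match state space")

    @property
    def n_subjects(self) -> int:
        return sum(c.size for c in self.clusters)

    def expected_events(self) -> float:
        return sum(c.size * c.outcome_prob for c in self.clusters)


def _cumulative(mat: np.ndarray) -> np.ndarray:
    return np.cumsum(mat, axis=1)


def _draw(cum_row: np.ndarray, u: float, what: str) -> int:
    if np.isnan(cum_row).any():
        raise ValueError(
            f"simulation reached {what}, which the spec marks unreachable"
        )
    return int(np.searchsorted(cum_row, u, side="right"))


def generate_cohort(
    spec: SimSpec, seed: int | None = None
) -> tuple[Cohort, np.ndarray]:
    """Simulate a cohort; returns (cohort, true cluster labels 1..K).

    Each subject: X_1 from the cluster's initial law, then X_t given
    X_{t-1} from the period-appropriate transition row (the step into
    visit t uses period 2 iff t > t1). ``seed`` overrides the spec's.
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    N, T = spec.n_subjects, spec.n_visits
    t1 = spec.change_point
    streams = root.spawn(N)
    codes = np.empty((N, T), dtype=np.intp)
    labels = np.empty(N, dtype=int)
    row = 0
    for c_idx, cl in enumerate(spec.clusters, start=1):
        cum_init = np.cumsum(cl.initial)
        cum1 = _cumulative(cl.transition)
        cum2 = (
            _cumulative(cl.transition2) if cl.transition2 is not None else cum1
        )
        for _ in range(cl.size):
            rng = np.random.default_rng(streams[row])
            u = rng.random(T)
            s = int(np.searchsorted(cum_init, u[0], side="right"))
            codes[row, 0] = s
            for t in range(2, T + 1):  # 1-based visit being entered
                cum = cum2 if (t1 is not None and t > t1) else cum1
                s = _draw(cum[s], u[t - 1], f"state {spec.state_space.labels[s]}")
                codes[row, t - 1] = s
            labels[row] = c_idx
            row += 1
    cohort = Cohort.from_codes(spec.state_space, codes)
    return cohort, labels


def generate_outcomes(
    labels: np.ndarray, event_probs, seed: int
) -> np.ndarray:
    """Independent Bernoulli outcome per subject, probability by cluster.

    ``event_probs`` maps cluster label -> probability (dict or sequence
    indexed by label-1).
    """
    labels = np.asarray(labels, dtype=int)
    if isinstance(event_probs, dict):
        probs = {int(k): float(v) for k, v in event_probs.items()}
    else:
        probs = {i + 1: float(p) for i, p in enumerate(event_probs)}
    for c in np.unique(labels):
        if c not in probs:
            raise ValueError(f"no outcome probability for cluster {c}")
        if not (0.0 <= probs[c] <= 1.0):
            raise ValueError(f"invalid probability for cluster {c}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = rng.random(len(labels))
    p = np.array([probs[c] for c in labels])
    return (u < p).astype(int)


def _stationary(P: np.ndarray, n_iter: int = 500) -> np.ndarray:
    """Stationary law of a fully defined stochastic matrix (power iteration)."""
    S = P.shape[0]
    pi = np.full(S, 1.0 / S)
    for _ in range(n_iter):
        pi = pi @ P
    return pi / pi.sum()


def _norm_rows(rows: list[list[float] | None], S: int = 3) -> np.ndarray:
    """Rows rounded to 3 decimals -> exact stochastic matrix; None -> NaN row."""
    out = np.full((S, S), np.nan)
    for i, r in enumerate(rows):
        if r is None:
            continue
        r = np.asarray(r, dtype=float)
        out[i] = r / r.sum()
    return out


def dart_like_spec(seed: int = 0) -> SimSpec:
    """Six-cluster, three-state, T=12, t1=6 spec mirroring the published
    fitted cluster structure of a large ART-adherence cohort (N=2960).

    Initial distributions (not published) are the stationary laws of each
    cluster's period-1 matrix; clusters whose only defined row is the good
    state start there with probability one.
    """
    space = default_state_space()
    GOOD = space.index("1")

    # per cluster: (size, period-1 rows, period-2 rows, death probability);
    # row order follows the state labels ("0", "1", "9"); None = unreachable
    raw = [
        (519,
         [[0.027, 0.960, 0.133], [0.034, 0.953, 0.013], [0.117, 0.860, 0.023]],
         [[0.095, 0.866, 0.039], [0.115, 0.824, 0.061], [0.051, 0.800, 0.149]],
         0.033),
        (309,
         [[0.431, 0.526, 0.043], [0.497, 0.458, 0.045], [0.264, 0.373, 0.364]],
         [[0.403, 0.549, 0.048], [0.279, 0.672, 0.049], [0.123, 0.352, 0.519]],
         0.061),
        (408,
         [[0.275, 0.684, 0.041], [0.246, 0.690, 0.063], [0.226, 0.598, 0.177]],
         [[0.000, 1.000, 0.000], [0.015, 0.978, 0.007], [0.067, 0.933, 0.000]],
         0.034),
        (441,
         [[0.285, 0.681, 0.035], [0.163, 0.799, 0.039], [0.202, 0.556, 0.242]],
         [[0.191, 0.781, 0.028], [0.273, 0.697, 0.030], [0.261, 0.620, 0.120]],
         0.048),
        (433,
         [[0.000, 1.000, 0.000], [0.118, 0.853, 0.029], [0.000, 1.000, 0.000]],
         # source prints only the good-state row for period 2; other states
         # are still reachable at the change point, so send them to good
         [[0.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 1.0, 0.0]],
         0.020),
        (850,
         [None, [0.0, 1.0, 0.0], None],
         [None, [0.0, 1.0, 0.0], None],
         0.024),
    ]

    clusters = []
    for size, p1, p2, death in raw:
        t1_mat = _norm_rows(p1)
        t2_mat = _norm_rows(p2)
        if any(r is None for r in p1):
            init = np.zeros(3)
            init[GOOD] = 1.0
        else:
            init = _stationary(t1_mat)
        clusters.append(
            ClusterSpec(size, init, t1_mat, t2_mat, outcome_prob=death)
        )
    return SimSpec(space, 12, tuple(clusters), change_point=6, seed=seed)


def three_cluster_recovery_spec(
    n_per_cluster: int = 100, n_visits: int = 12, seed: int = 0
) -> SimSpec:
    """Three well-separated adherence archetypes for recovery benchmarking.

    * good: retention P(1 -> 1) = 0.96 with brief lapses and quick return;
    * poor: fast-mixing chain with good-state retention 0.40 and 10%
      missingness;
    * dropout: absorbed in the missing state from the first visit (lost to
      follow-up).

    Separation is structural, not incidental: the absorbing cluster sits
    at the missing-state vertex of feature space, which no other cluster
    approaches, and the poor cluster's retention is low enough that a
    chance run of 10+ good months (which would be indistinguishable from
    the good cluster at T = 12) is rare. A high-retention cluster next to
    an absorbing-*optimal* cluster is NOT well separated at T = 12: a 0.96
    retention chain produces its all-good profile, the absorbing cluster's
    only profile, for a third of its subjects.
    """
    space = default_state_space()
    good = np.array(
        [[0.25, 0.75, 0.00],
         [0.02, 0.96, 0.02],
         [0.05, 0.90, 0.05]]
    )
    poor = np.array(
        [[0.50, 0.40, 0.10],
         [0.50, 0.40, 0.10],
         [0.50, 0.40, 0.10]]
    )
    dropout = np.array(
        [[np.nan] * 3,
         [np.nan] * 3,
         [0.0, 0.0, 1.0]]
    )
    clusters = (
        ClusterSpec(n_per_cluster, np.array([0.0, 1.0, 0.0]), good, outcome_prob=0.04),
        ClusterSpec(n_per_cluster, np.array([0.50, 0.40, 0.10]), poor, outcome_prob=0.10),
        ClusterSpec(n_per_cluster, np.array([0.0, 0.0, 1.0]), dropout, outcome_prob=0.20),
    )
    return SimSpec(space, n_visits, clusters, seed=seed)


def dynamics_only_spec(
    n_per_cluster: int = 100, n_visits: int = 12, seed: int = 0
) -> SimSpec:
    """Clusters identical in marginal state proportions, different in dynamics.

    All three chains are doubly stochastic with the uniform initial law,
    so every cluster has exactly uniform marginals and proportion-based
    (iid-model) features carry no cluster signal. The dynamics differ
    sharply: one chain cycles 0 -> 1 -> 9 -> 0 (90% on-cycle), one cycles
    in the opposite direction, and one draws states independently — so
    their joint-transition features concentrate on disjoint matrix
    entries.
    """
    space = default_state_space()
    leak = 0.05
    cyclic = np.array(
        [[leak, 0.90, leak],
         [leak, leak, 0.90],
         [0.90, leak, leak]]
    )
    uniform = np.full(3, 1.0 / 3.0)
    chains = (cyclic, cyclic.T.copy(), np.full((3, 3), 1.0 / 3.0))
    clusters = tuple(
        ClusterSpec(n_per_cluster, uniform, P, outcome_prob=0.05) for P in chains
    )
    return SimSpec(space, n_visits, clusters, seed=seed)


def homogeneous_spec(
    n_subjects: int = 200, n_visits: int = 12, seed: int = 0
) -> SimSpec:
    """Single time-homogeneous chain, for likelihood-ratio calibration.

    Rows keep every cell well populated at T=12 so chi-square asymptotics
    for the change-point test are adequate.
    """
    space = default_state_space()
    P = np.array(
        [[0.40, 0.45, 0.15],
         [0.25, 0.60, 0.15],
         [0.30, 0.40, 0.30]]
    )
    init = _stationary(P)
    return SimSpec(
        space,
        n_visits,
        (ClusterSpec(n_subjects, init, P, outcome_prob=0.05),),
        seed=seed,
    )
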