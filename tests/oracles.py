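"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (exhaustive
search, O(n^2) pair counting, direct summation) and share no code with the
library paths they check.
"""

import itertools

import numpy as np


def exhaustive_ward(X: np.ndarray):
    """Greedy minimum-variance agglomeration by exhaustive pair search.

    At every step evaluates the within-SS increase of every candidate pair
    and merges the cheapest. Returns [(frozenset_of_leaves, cost), ...] in
    merge order.
    """
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma = X[clusters[a]].mean(axis=0)
            mb = X[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            cost = na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
            if best is None or cost < best[0] - 1e-15:
                best = (cost, a, b)
        cost, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        merges.append((frozenset(members), cost))
        clusters[next_id] = members
        next_id += 1
    return merges


def pairwise_auc(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann-Whitney concordance by explicit pair counting, ties worth 1/2."""
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson_chi2(table: np.ndarray) -> float:
    """Direct O/E summation of the Pearson statistic."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat
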