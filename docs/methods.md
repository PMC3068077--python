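# Methods

## Data model

A cohort holds N subjects, each observed at the same T visits over a
finite state alphabet of size S (default `("0", "1", "9")`: missed a
dose / no dose missed / visit missing). Missingness is a state, not
absent data, so all sequences are complete and of equal length; subjects
whose every visit is missing are legitimate members, not exclusions. The
sequence space has S^T profiles (531,441 for S=3, T=12); clustering is a
principled way of collapsing it. Visit indices are 1-based everywhere in
the interface. Cohorts whose subjects enrolled for different lengths are
rejected rather than padded: the feature definitions below assume a
common denominator of T−1 transitions, and mixing denominators would
silently distort distances.

## Feature vectors

Let I(·) be the indicator. Per subject:

* M1: P̂_s = (1/T) Σ_t I(X_t = s), an S-vector summing to 1.
* M2: q̂_ij = (1/(T−1)) Σ_{t≥2} I(X_{t−1}=i, X_t=j), an S×S joint matrix;
  Z = vec(Q) stacks *columns* (and `devectorize` inverts with the same
  convention). The joint matrix is used instead of the conditional one to
  avoid dividing by the row sums, which are zero for never-visited
  states; the conditional matrix P = Q / rowsums is computed only for
  reporting, with all-zero rows flagged undefined and rendered ".".
* M3: the same construction on two periods around a *known, fixed*
  change point t₁ (estimation of t₁ is out of scope): Q₁ uses the t₁−1
  transitions ending at visits 2..t₁, Q₂ the T−t₁ transitions ending at
  t₁+1..T. The straddling step t₁ → t₁+1 belongs to period 2; some
  convention is required, and assigning the step *into* the new period to
  the new period keeps every transition labelled by the visit it enters.
* Order-2 (optional): joint proportions over the T−2 consecutive triples.

Features are never standardized before clustering: every coordinate is a
probability on the same scale, and rescaling would reweight transitions
arbitrarily. Weighting transition probabilities in the distance is a
known possible refinement and deliberately not implemented.

## Clustering

Ward's minimum-variance linkage: the cost of merging clusters I, J is
ΔSS = n_I n_J/(n_I+n_J) · ‖Z̄_I − Z̄_J‖², and heights are reported on this
SS-increment scale (two singletons merge at ½‖z₁−z₂‖²). The
implementation delegates to `scipy.cluster.hierarchy.linkage(method="ward")`
— whose heights are √(2·ΔSS) — and squares-and-halves them; the transform
is strictly monotone, so the merge sequence, node numbering and every cut
are unchanged. Agreement with an exhaustive greedy oracle that evaluates
the within-SS increase of every candidate pair is asserted (to 1e-9) for
200 random small cohorts in the test suite. Note the two R dialects of
Ward differ only in whether input distances are pre-squared; the
criterion implemented here is the textbook minimum-variance one.

Cutting the tree to k clusters undoes the last k−1 merges. Cluster labels
are assigned 1..k by decreasing size (ties: smallest member index), so
labelling is deterministic and independent of input order; comparisons
between clusterings should use partition structure (cross-tabulation,
adjusted Rand index), not label identity. The dendrogram exports to
Newick with branch lengths equal to height gaps, making every leaf's
root distance equal to the root height.

## Cluster profiles

Profiles pool *counts*, not per-subject probabilities: a cluster's
proportion vector comes from the pooled visit counts of its members, and
its per-period conditional tables from cell-wise summed transition counts,
row-normalized. Pooling counts is the maximum-likelihood estimate under
the model that members of a cluster share transition probabilities, and
it remains well defined when individual members have undefined rows. For
equal T the pooled proportion vector coincides with the mean of member
M1 vectors; pooled conditional rows are transition-count-weighted means
of member rows (both identities are tested). Tables render to 3 decimals
with "." for undefined cells. Captions are generated from the good-state
retention probability per period with configurable thresholds (defaults:
optimal ≥ 0.995, good ≥ 0.85, moderate ≥ 0.60; a between-period change
of more than 0.05 reads "getting better/worse"; a jump of two or more
levels reads "first …, then …").

## Outcome association

Cluster-by-outcome tables feed:

* Odds ratios versus a reference cluster, OR_c = odds_c / odds_ref. CIs
  default to 95% *profile-likelihood* intervals — obtained by inverting
  the likelihood-ratio test for the log-odds-ratio in a two-group
  binomial model, the same interval R's `confint` yields for a logistic
  GLM — because the Wald interval exp(log OR ± 1.96·√(1/a+1/b+1/c+1/d))
  is visibly inaccurate when a cluster has few events (for 9 events the
  two upper bounds differ by ~0.05). Wald remains available via
  `ci_method="wald"`. A zero cell in a comparison cluster yields a
  flagged OR with NaN CI; a degenerate reference raises.
* `reconstruct_event_counts(n, p)` rounds n·p half-away-from-zero, for
  recovering integer event counts from published (size, rate) tables.
* Pearson chi-square tests of independence (scipy, no continuity
  correction).
* ROC/AUC: scikit-learn curves over all cutoffs with tied scores
  grouped; the trapezoid AUC equals Mann-Whitney concordance with half
  credit for ties (asserted against an O(n²) pair-counting oracle). A
  categorical clustering is scored by each subject's in-sample cluster
  event rate, which equals the fitted probability of a logistic model on
  cluster indicators (also asserted).
* Logistic linear predictors β'Z by IRLS (statsmodels GLM/Binomial,
  tolerance 1e-8, max 100 iterations); complete separation is reported
  via a `converged=False` flag, never silently.

## Model selection

All models are scored *conditionally on X₁*, so M1, M2, M3 and the
order-2 chain assign probabilities to the same events X₂..X_T (the
order-2 model scores X₃..X_T and must be compared against an order-1 fit
restricted to the same visits). This is the standard device for making
iid-vs-Markov likelihoods comparable; an unconditional M1 likelihood
would also score X₁ and break the nesting. Plug-in pooled MLEs mean
observed events never get probability zero; additive smoothing is
available but off by default. Free-parameter counts: S−1, S(S−1),
2S(S−1), S²(S−1). The LRT uses 2Δloglik against the chi-square upper
tail. Calibration of the change-point test (M3 vs M2) under a truly
homogeneous generator is verified by simulation: at n=200, T=12 and
well-populated transition cells the nominal-5% rejection rate lands in
[0.03, 0.07] over 1000 replicates. The test suite also checks that the
per-transition log-likelihood gain of M3 over M2 under a non-homogeneous
generator matches the occupancy-weighted KL divergence between period
laws and the pooled law, computed exactly by forward recursion.

## Synthetic cohorts

`SimSpec` describes K latent clusters, each with a size, an initial state
law, one or two transition matrices and an outcome probability. One root
seed is split into per-subject substreams (`SeedSequence.spawn`), so a
cohort's content does not depend on generation order. Rows of all-NaN
mark states a cluster can never occupy; generation raises if such a row
is ever reached, which guards the spec against silent inconsistency.

`dart_like_spec()` mirrors a published six-cluster, 2960-patient,
twelve-visit structure with change point at month six: cluster sizes
(519, 309, 408, 441, 433, 850), per-period transition rows as published,
and per-cluster two-year death probabilities (.033, .061, .034, .048,
.020, .024), giving ~100 expected deaths. Published rows are rounded to
3 decimals and are renormalized here to sum exactly to one. Two gaps had
to be filled: initial distributions are not published, so each cluster
starts from the stationary law of its period-1 matrix (point mass on the
good state where that is the only defined row); and the
first-good-then-optimal cluster's period-2 rows for states other than
the good state are undefined in the source yet reachable at the change
point, so they are filled with a point mass on the good state — the
behavior the cluster's description implies. The always-optimal cluster's
undefined rows are genuinely unreachable and left undefined.

### What the simulator does and does not emulate

It reproduces the *fitted* cluster structure — a mixture of Markov
chains — not the raw trial data: real cohorts have covariates, informative
missingness, deaths during follow-up and cluster-assignment uncertainty,
none of which are modelled. Passing recovery tests therefore demonstrates
that the pipeline correctly identifies Markov-mixture structure when it
is present, not that real adherence data contain exactly six such
clusters.

### Benchmark scenarios and identifiability at T = 12

`three_cluster_recovery_spec` (n=300, T=12) contains a good cluster
(retention 0.96, brief lapses, quick return), a poor cluster (fast-mixing,
retention 0.40, 10% missingness) and a dropout cluster absorbed in the
missing state. The design respects a hard identifiability limit of short
follow-up: with 11 observed transitions, a high-retention chain emits an
*all-good* sequence for a substantial fraction of its subjects (0.95¹¹ ≈
0.57 of those starting adherent), and such subjects are *mathematically
indistinguishable* from members of an absorbing-optimal cluster — no
clustering method can assign them correctly. Likewise a 0.55-retention
chain produces near-all-good subjects at a few percent. Robust recovery
(adjusted Rand ≥ 0.9) therefore requires the absorbing cluster to sit at
the missing-state vertex, which no other cluster approaches, and the
poor cluster's retention to be low enough that ten consecutive good
months are rare. With this geometry the M2+Ward pipeline recovers the
partition with ARI ≥ 0.91 across 100 independent replicate cohorts
(median 0.97). Slow-mixing ("sticky") chains make poor cluster
archetypes at T=12 for a second reason: their empirical transition
matrices are extremely variable across subjects, and a sticky cluster is
multi-modal in feature space, one mode per starting state.

`dynamics_only_spec` holds marginal behavior fixed — three doubly
stochastic chains (cyclic, anti-cyclic, iid) started uniformly, so every
cluster has exactly uniform expected state proportions — while the
transition laws concentrate on disjoint matrix entries. Proportion
features (M1) carry no signal there (ARI ≈ 0.05) while transition
features (M2) recover the partition (ARI ≈ 0.9), which is the cleanest
demonstration of why transition-based clustering exists.

## Numerical conventions

* Proportion/joint-matrix unit sums are enforced at 1e-12.
* LRT statistics are clipped at zero; a statistic below −1e-7 (impossible
  for nested MLEs on the same data) raises instead of clipping.
* Profile-likelihood CI bounds are found by Brent root-finding on the
  profiled log-likelihood (inner intercept maximization also by Brent on
  the score), bracket expanded in 4-Wald-SE steps; tolerance 1e-10 on the
  log scale.
* Ties in Ward merge costs are resolved by scipy's nearest-neighbor-chain
  order; for continuous features exact ties occur with probability zero,
  and determinism for fixed input is guaranteed regardless.
* `reconstruct_event_counts` rounds half away from zero (so 20.4 → 20,
  18.849 → 19, 8.66 → 9), matching how published rates with rounded
  decimals recombine into integer counts.

## Problem sizes used in the checked examples

Oracle-agreement checks run 200 random cohorts of N ≤ 8 (Ward) and 200
score sets of n ≤ 60 (AUC). Recovery benchmarks use n = 300, T = 12.
LRT calibration uses 1000 replicates of n = 200, T = 12. The full-scale
simulation uses the published 2960-subject, six-cluster configuration.

## Known limitations

* The change point t₁ is assumed known; no estimation is provided.
* Odds ratios are unadjusted; covariate-adjusted logistic models are out
  of scope (the motivating analysis found adjustment changed nothing).
* Chi-square and LRT p-values rely on asymptotics; with sparse transition
  cells (short T, rare states) the calibration band verified here need
  not hold.
* In-sample AUC of cluster-rate scores is optimistic; no cross-validation
  is implemented.
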