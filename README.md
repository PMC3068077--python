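# adherclust

Markov-chain clustering of longitudinal categorical adherence data.

## The problem

Adherence to a long-term treatment (the motivating setting is
antiretroviral therapy for HIV) is typically recorded at every scheduled
clinic visit as a categorical state — here `0` = missed a dose since the
last visit, `1` = no dose missed, and `9` = the visit was missed or the
questionnaire incomplete, with missingness deliberately treated as a state
of its own. Averaging these states over a year throws away the *dynamics*:
a patient who lapses for three months and then recovers looks identical,
on average, to one who misses every third visit. `adherclust` instead
treats each patient's sequence X₁,…,X_T as a realization of a Markov
chain and clusters patients on their estimated transition behavior.

## The models

For S states observed at T visits, each subject is condensed into a
feature vector Z under one of three nested models:

* **M1** (iid): Z = (P̂₁,…,P̂_S), the state proportions, P̂_s = #{t: X_t=s}/T.
* **M2** (homogeneous chain): Z = vec(Q), where Q = (q̂_ij) is the *joint*
  matrix of consecutive-pair proportions q̂_ij = #{t: X_{t−1}=i, X_t=j}/(T−1)
  and vec stacks its columns. Joint rather than conditional probabilities
  are used so that never-visited states cause no division by zero.
* **M3** (non-homogeneous chain): the transition law is allowed to change
  at a known change point t₁; Z = vec(Q₁, Q₂) with one joint matrix per
  period (dimension 2S²).

Subjects are clustered by Ward's minimum-variance method on the raw Z
vectors (no standardization — every coordinate is already a probability):
merging clusters I and J costs n_I·n_J/(n_I+n_J)·‖Z̄_I − Z̄_J‖², the increase
in within-cluster sum of squares. Cutting the dendrogram at k clusters,
each cluster is profiled by pooled state proportions and per-period
conditional transition tables, and related to a later binary outcome
(e.g. death in the following two years) through odds ratios with 95%
profile-likelihood confidence intervals, chi-square tests, and ROC/AUC.
The nested models M1 ⊂ M2 ⊂ M3 (and an order-2 chain) are compared by
likelihood-ratio tests on conditional log-likelihoods.

A latent-cluster Markov-mixture simulator (`synthetic_data`) generates
cohorts with known cluster structure and cluster-linked outcomes, so the
whole pipeline is testable end to end; `dart_like_spec()` mirrors the
published six-cluster structure of a 2960-patient ART cohort.

## Worked example

Three subjects followed for 12 monthly visits:

```python
import adherclust as ac

space = ac.default_state_space()          # states ("0", "1", "9")
trajs = [
    ac.Trajectory("i1", tuple("999000001111")),
    ac.Trajectory("i2", tuple("901119100009")),
    ac.Trajectory("i3", tuple("910009001119")),
]
for t in trajs:
    print(t.subject_id, ac.estimate_state_proportions(t, space).values)
```

```
i1 [0.417 0.333 0.25 ]
i2 [0.417 0.333 0.25 ]
i3 [0.417 0.333 0.25 ]
```

All three subjects spend exactly 5/12 of visits in state 0, 4/12 in
state 1 and 3/12 missing, so under the iid model they are
indistinguishable — despite obviously different behavior (i1 recovers
and stays adherent; i2 and i3 oscillate). The homogeneous-chain features
separate i1 but still confuse i2 with i3 (their transition-pair counts
coincide); only the two-period features with change point t₁ = 6 tell all
three apart:

```python
m2 = [ac.build_feature_vector(t, space, "M2").values for t in trajs]
m3 = [ac.build_feature_vector(t, space, "M3", t1=6).values for t in trajs]
# m2: i2 == i3 != i1        m3: all three pairwise distinct
```

Downstream, cluster-level event counts give odds ratios against a
reference cluster. Recovering integer death counts from a published
(size, death-rate) table of six clusters and comparing each cluster with
the optimal-adherence reference:

```python
sizes = (519, 309, 408, 441, 433, 850)
rates = (.033, .061, .034, .048, .020, .024)
events = tuple(ac.reconstruct_event_counts(n, p) for n, p in zip(sizes, rates))
table = ac.OutcomeTable(tuple(range(1, 7)), sizes, events, reference=6)
ors = ac.odds_ratios_vs_reference(table)   # profile-likelihood 95% CIs
```

```
cluster 1: OR=1.41  95% CI (0.72, 2.71)
cluster 2: OR=2.72  95% CI (1.42, 5.18)
cluster 3: OR=1.47  95% CI (0.72, 2.93)
cluster 4: OR=2.08  95% CI (1.11, 3.89)
cluster 5: OR=0.88  95% CI (0.38, 1.90)
```

The 100 reconstructed deaths split so that the poorest-adherence cluster
(cluster 2, frequent misses and missing data) carries 2.7 times the odds
of death of the optimal cluster.

## Command line

```sh
adherclust simulate --seed 1 --outdir sim/
adherclust features --input sim/cohort.csv --model M3 --t1 6 --out z.csv
adherclust cluster  --input sim/cohort.csv --model M3 --t1 6 --k 6 --outdir clus/
adherclust associate --assignments clus/assignments.csv \
                     --outcomes sim/outcomes.csv --outdir assoc/
adherclust select-model --input sim/cohort.csv --t1 6 --out fits.json
```

Outputs are plain CSV/JSON plus a Newick dendrogram; all commands are
deterministic given inputs and seed, and options can come from a flat
YAML config file (`--config`, explicit flags win).

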