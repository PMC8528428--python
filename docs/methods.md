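# Methods

`ddnrewire` tests whether the gene–gene dependency structure of a small gene
cluster differs between two cohorts of samples — drug-sensitive and
drug-resistant cell lines — and assembles the results over a drug × cluster
grid into a rewiring landscape.  This note documents the statistical model,
the tunable parameters, the synthetic-data generator used for validation,
and the design decisions taken where several reasonable choices existed.

## The rewiring model

**Cohort formation.**  For each compound, samples are dichotomized by the
area under the dose–response curve (AUC, unitless, consumed precomputed).
Samples at or below the empirical `lower_q` quantile (type-7, linearly
interpolated) are *sensitive* (lower area = stronger kill), samples at or
above the `1 − upper_q` quantile are *resistant*, and the middle is
excluded.  The default is a tertile split (`lower_q = upper_q = 1/3`),
which balances the two groups; ties at a boundary all go to the extreme
group, and a compound whose ties make the two groups overlap, or whose
groups fall below `min_group_size` (default 15), is skipped rather than
analyzed.

**Discretization.**  Expression is reduced per gene to equal-frequency
tertiles (levels {0, 1, 2}) over non-missing values, with stable ranking
(sample-index tie-break), so bin counts differ by at most one.  Genes with
zero interquartile range are *degenerate*: they keep all-middle levels,
stay in the cluster for bookkeeping, and contribute no dependence tests.
Missing entries fall into the middle bin; genes with more than 20% missing
entries are dropped at read time.

**Per-condition structure ensembles.**  The candidate pair space of a
cluster is every unordered pair of usable members (*novel* pairs) together
with the prior-knowledge interaction edges (*known* pairs, from the SIF
input).  For each condition, `n_resamples` (R, default 100) seeded
bootstrap draws are taken; in each draw every candidate pair is tested for
independence with a G-test (likelihood-ratio statistic
G = 2·Σ O·ln(O/E) on the 3×3 contingency table, df reduced for empty
rows/columns, chi-square upper tail) and included when p < `alpha_known`
(default 0.05) for known pairs or p < `alpha_novel` (default 0.01) for
novel pairs — the prior-knowledge assistance is exactly this laxer
threshold for curated interactions.  The ensemble summarizes each pair by
its inclusion frequency across the R draws.

A bootstrap draw is taken with replacement at full group size, but each
*distinct* drawn sample enters the contingency table once.  Duplicated
draws carry no new evidence about dependence, and counting them roughly
doubles the G statistic, which would destroy the nominal level of the
per-pair test (measured ≈0.15 rejection at α = 0.01 under independence
when duplicates are counted, vs ≈0.01 with the support-only rule).  The
retained support covers ≈63% of the group per draw, so the ensemble still
expresses structure uncertainty through subsampling.

**Rewiring statistic.**  Between the sensitive and resistant ensembles the
divergence is the edge-wise Jensen–Shannon sum, in bits:

    D = Σ_pairs JSD( Bernoulli(p_sens), Bernoulli(p_res) ),
    JSD(P, Q) = H((P+Q)/2) − (H(P)+H(Q))/2.

D is symmetric, non-negative, bounded by one bit per candidate pair, and
zero iff the two frequency profiles coincide.

**Significance.**  The null is "the two cohorts share one dependency
structure".  Sensitive/resistant labels are permuted over the union of the
two groups, sizes preserved, `n_permutations` (N, default 999) times; both
ensembles are rebuilt per permutation and p = (1 + #{D_perm ≥ D_obs}) /
(N + 1), with ties counted conservatively.  Benjamini–Hochberg q-values
are then computed across all non-skipped cells of the drug × cluster grid
(skipped cells produce no p-value and stay out of the denominator);
`significant ⇔ q ≤ fdr_alpha` (default 0.05).

All bootstrap and permutation seeds derive deterministically from
(config seed, drug id, cluster id, permutation index, condition), so the
whole analysis is a pure function of its inputs and one seed, and adding a
drug to a run never perturbs other cells' results.

## DDN annotation and mediators

For a significant cell, each candidate pair with inclusion frequency at
least `presence_theta` (default 0.5) in either condition becomes a DDN
edge, classified *sensitive* or *resistant* when the frequency difference
exceeds `specific_tau` (default 0.3) in that direction, else *both*.
Edges keep their known/novel flag.  Isolated cluster members remain as
zero-metric nodes so mediator counting has a stable denominator.

Two mediator classes are flagged per node:

* **Specificity mediators** — nodes whose incident edges are
  disproportionately condition-specific: one-sided binomial tail
  P(X ≥ k_specific | n = k_total, p = background) < `mediator_alpha`
  (default 0.05), where the background is the DDN-wide specific-edge
  fraction.  With background 0 any specific edge flags the node; with
  background 1 no node can be flagged.
* **Essentiality mediators** — nodes whose normalized betweenness
  centrality (Brandes, fractional credit for tied shortest paths, scaled
  by (n−1)(n−2)/2) differs between the sensitive-side subgraph
  (sensitive + both edges) and the resistant-side subgraph by at least
  `bc_delta_cutoff` (default 0.3, absolute difference).  Including the
  *both* edges in each side reflects that those dependencies exist in both
  conditions' networks.

The "significant proportion" and "centrality difference" rules are this
package's concrete operationalizations; a binomial tail against the
network-wide background and an absolute normalized-centrality cutoff were
chosen for being parameter-light, order-invariant and exactly testable.
Both cutoffs are configurable.

## Landscape, hotspots, drug classes

The landscape cell for (drug, cluster) holds the test result and, when
significant, the DDN's mediator count.  The rewiring score of a drug is
the sum of mediator counts over its significant cells (clusters
symmetrically); the frequency is the significant-cell count.  Scores are
deliberately pluggable — the score ties cell intensity (mediator count) to
the marginal bars, and alternatives (significant-cell count, Σ(1−q)) can
be swapped without touching the grid machinery.  Sorting is descending by
score with ascending lexicographic tie-break; the hotspot view selects the
top 15 drugs × top 5 clusters by default and reports, per selected
cluster, how many selected drugs hit it.

A drug class (drugs sharing a target) gets the intersection of its
members' significant-cluster sets; for each shared cluster one combined
DDN is built from the arithmetic mean of the members' per-condition edge
frequencies (order-invariant), and mediator detection runs on the pooled
profiles.  Pooling then building one network — rather than intersecting
per-drug DDNs — keeps the combined network's mediator statistics
well-defined.

## Synthetic data

The generator plants known dependency structure so every stage is testable
without external data.  Each condition has its own edge set over the
cluster's genes; edges orient low-index → high-index (acyclic by
construction) and a gene with several parents copies only its lowest-index
parent.  Roots draw levels uniformly from {0, 1, 2}; a child copies its
parent with probability `rho`, else redraws uniformly from all three
levels.  Thus `rho = 0` is exact independence, marginals stay uniform at
any `rho`, the parent–child agreement rate is `rho + (1 − rho)/3`, and the
copy rate is identified by the moment estimator (3·agreement − 1)/2.
Continuous mode emits level − 1 plus Gaussian noise (`noise_sd` default
0.4), a three-component location mixture that per-gene tertile
discretization approximately inverts.

Ground truth: the rewired pairs are the symmetric difference of the two
edge sets, and planted mediators are genes with at least two rewired
incidences.

The full-pipeline fixture lays out a drug × cluster grid with one or more
planted cells.  Shared structure uses *disjoint* parent–child pairs — a
chain would add second-order (grandparent) dependencies of intermediate
strength, which sit in the G-test's mid-power region and inject avoidable
variance into both the observed statistic and its permutation null.  A
planted cell's cluster carries two extra pairs dependent only in that
drug's sensitive tertile.  AUC values are strictly separated so the
tertile partition recovers the intended groups exactly.  The default
cohort (250 samples per tertile, 750 total) mirrors the scale of a large
pharmacogenomic screen split into response tertiles; this scale matters
statistically: a permuted half-and-half mixture of a planted dependency
must still be detected reliably, otherwise the mixture sits mid-power and
the permutation null of D becomes heavy-tailed.

What the generator does **not** emulate: transcriptome-scale covariance,
batch and lineage effects, dose–response curve noise, non-uniform
expression marginals, and linkage between clusters.  Passing the synthetic
studies therefore demonstrates the statistical machinery (calibration,
power, determinism) under the stated generative model, not performance on
real screens.

## Validation studies

The `ddnrewire.validation` module, exercised by the test suite and by
`scripts/acceptance.py`, recomputes:

* analytic oracles (closed-form divergence, G, binomial-tail, BH values);
* brute-force equivalence — betweenness vs exhaustive shortest-path
  enumeration on random ≤6-node graphs, and the G-test vs an independent
  log-likelihood-ratio contingency computation on random 3×3 tables;
* null calibration — 200 simulated null (drug, cluster) datasets (6 genes,
  60+60 samples, R = 50, N = 99): the fraction of p ≤ 0.05 must sit in the
  binomial band [0.02, 0.08];
* planted-edge power — 50 runs with one sensitive-only dependency at
  rho = 0.8, 60+60 samples, R = 100, N = 199: the cell must be significant
  and the edge classified sensitive-specific in ≥ 80% of runs;
* mediator recovery — 50 runs of a hub design (one gene carrying five
  rewired edges, a child backbone and twelve shared filler pairs
  stabilizing the specific-edge background): the hub must be flagged as a
  specificity mediator in ≥ 80% of runs;
* end-to-end — a 3-drug × 2-cluster fixture: byte-identical artifacts
  across identical invocations, and the planted cell as the grid's only
  significant cell in ≥ 80% of 20 seeded repeats (full-pipeline runs use
  R = 50, N = 499 — enough permutation resolution for grid-wide BH at
  α = 0.05 over six cells).

## Numerical and degenerate-input choices

* Uninformative pairs (fewer than two non-empty rows or columns in the
  contingency table) are treated as independent (G = 0, df = 0, p = 1).
* JSD values are clipped at zero against floating-point underflow; the
  binary entropy uses the 0·log 0 = 0 convention.
* Permutation ties count as ≥ (conservative); the plus-one estimator
  keeps p in (0, 1].
* Clusters with more than `max_cluster_genes` (default 60) usable members
  are rejected to bound the quadratic pair space; the cell is recorded as
  skipped, never silently dropped.
* A cluster with no testable pairs yields D = 0, p = 1 without spending
  permutations.
* All artifacts are written deterministically (sorted nodes/edges/keys);
  the run manifest's wall-clock timing entry is the single documented
  exception to byte-identity across reruns.

## Known limitations

* The per-edge Bernoulli ensemble treats candidate pairs independently; a
  likelihood over whole structures (as in full Bayesian-network scoring)
  could share strength across edges but is deliberately out of scope.
* The G-test's chi-square tail is mildly anticonservative for small
  groups (expected cell counts below ~10); the permutation layer absorbs
  this for significance calls, but per-edge inclusion frequencies in
  small cohorts are slightly inflated.
* Pairs whose dependence sits near the inclusion threshold ("mid-power"
  pairs) dominate the variance of D; clusters made of many weak
  dependencies therefore need larger cohorts than clusters with few
  strong ones.
* Directed or causal structure, and GPU-scale screens, are non-goals.
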