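# ddnrewire

Differential dependency network (DDN) rewiring analysis for drug-response
pharmacogenomics.

Given an expression matrix over cancer cell lines, a per-compound
drug-response table (area under the dose–response curve), and a catalog of
prior-knowledge-annotated gene clusters, `ddnrewire` finds the clusters
whose gene–gene dependency structure is significantly *rewired* between
drug-sensitive and drug-resistant cell lines, identifies the mediator genes
that carry the rewiring, and assembles the drug × cluster rewiring
landscape with hotspot selection and drug-class aggregation.  It is aimed
at computational biologists screening large pharmacogenomic panels for
pathway-level drug mechanisms — e.g. mapping cancer-drug activity onto gene
clusters relevant to another disease.

## The method

For each compound, cell lines are split into response tertiles: sensitive
(AUC ≤ Q(1/3)), resistant (AUC ≥ Q(2/3)), middle excluded.  Expression is
discretized to per-gene equal-frequency tertiles.  For each cluster and
condition, R seeded bootstrap resamples learn a structure over the
candidate pair space — all member pairs, with prior-knowledge edges
admitted at a laxer G-test level (α_known = 0.05) than novel pairs
(α_novel = 0.01) — giving each pair an inclusion frequency
p̂ ∈ [0, 1].  Rewiring between conditions is the edge-wise Jensen–Shannon
sum, in bits:

    D = Σ_pairs JSD( Bern(p̂_sens), Bern(p̂_res) ),
    JSD(P, Q) = H((P+Q)/2) − (H(P) + H(Q))/2

Significance comes from N label permutations (group sizes preserved,
p = (1 + #{D_perm ≥ D_obs})/(N + 1)) with Benjamini–Hochberg control
across the full drug × cluster grid.  Significant cells get an annotated
DDN: edges classified sensitive / resistant / both by their frequency
difference, plus two mediator classes per gene — *specificity* mediators
(binomial tail of condition-specific incident edges against the DDN-wide
background) and *essentiality* mediators (betweenness-centrality shift
≥ 0.3 between the condition subnetworks).  Landscape scores sum mediator
counts over significant cells; the hotspot view selects the top 15 drugs ×
top 5 clusters.  See `docs/methods.md` for the full model, parameter
table and validation studies.

## Worked example

Simulate a 3-drug × 2-cluster screen in which drug `D01` rewires cluster
`C00` (two dependencies present only in its sensitive tertile), then run
the full analysis:

```bash
ddnrewire simulate --n-drugs 3 --n-clusters 2 --planted 1 0 --seed 7 --out fixture
printf 'n_resamples: 50\nn_permutations: 499\nseed: 7\n' > config.yaml
ddnrewire run --expression fixture/expression.tsv --response fixture/response.tsv \
  --gmt fixture/clusters.gmt --sif fixture/priors.sif --config config.yaml --out run
# analyzed 6/6 (drug, cluster) pairs -> run
```

`run/scores.tsv` holds one row per grid cell plus score marginals:

```
row_type  drug_id  cluster_id  statistic  p_value  q_value  significant  ...
cell      D00      C00         0.4996     0.400    0.663    False
cell      D00      C01         0.2358     0.144    0.432    False
cell      D01      C00         2.0663     0.008    0.048    True
cell      D01      C01         0.0302     0.950    0.990    False
cell      D02      C00         0.0813     0.990    0.990    False
cell      D02      C01         0.0716     0.442    0.663    False
```

The planted cell is the only significant one: drug `D01` on cluster `C00`
shows D = 2.07 bits of rewiring (roughly one bit per planted dependency),
permutation p = 0.008, q = 0.048 ≤ 0.05 after BH over the six cells.  Its
DDN (`run/ddn/D01__C00.sif`) recovers exactly the planted wiring — the two
rewired pairs as sensitive-specific edges, the shared pair as "both":

```
C00G0   sensitive   C00G1
C00G2   sensitive   C00G3
C00G4   both        C00G5
```

`run/ddn/D01__C00.nodes.tsv` carries per-gene centralities, specific/total
edge counts, the binomial specificity p-value and both mediator flags
(here no gene concentrates enough specific edges to be flagged — each
endpoint holds one of four DDN edges, binomial tail 0.67);
`run/landscape/` holds the sorted heatmap, score/frequency marginals and
`hotspot.json`; `run/manifest.json` records the config snapshot, input
digests and per-pair status.  Re-running the same command reproduces every
artifact byte-for-byte (the manifest's wall-clock timing entry aside).

Other subcommands: `partition` (export one compound's sensitive/resistant
split), `landscape` / `hotspot` (re-export views from a finished run),
`class-ddn` (shared clusters and pooled DDNs for a drug class defined in a
YAML file), `simulate` (fixtures as above).

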