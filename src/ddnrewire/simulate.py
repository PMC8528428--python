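"""Two-condition synthetic expression with planted, condition-specific dependencies.

Each condition has its own ground-truth edge set over ``n_genes`` genes.
Edges are oriented by gene index (lower index = parent), which is acyclic
by construction; a gene with several parents copies only its lowest-index
parent.  Root genes draw levels uniformly from {0, 1, 2}; a child copies
its parent's level with probability ``rho`` and otherwise draws uniformly
from all three levels, so rho = 0 is exact independence, every marginal
stays uniform, and the parent-child agreement rate is rho + (1 - rho)/3
(the copy rate is identified by the moment estimator (3*agreement - 1)/2).
Continuous mode maps level l to
a Gaussian draw with mean (l - 1) and standard deviation ``noise_sd``, a
three-component location mixture that per-gene tertile discretization
approximately inverts.

The symmetric difference of the two edge sets is the planted rewiring;
genes incident to at least two rewired edges are the planted mediators.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .io import ExpressionMatrix
from .core import DiscretizedMatrix

def _normalize_edges(edges, n_genes: int) -> frozenset:
    out = set()
    for a, b in edges:
        a, b = int(a), int(b)
        if a == b:
            raise ValidationError(f"self edge ({a}, {b})")
        if not (0 <= a < n_genes and 0 <= b < n_genes):
            raise ValidationError(f"edge ({a}, {b}) references a gene >= n_genes={n_genes}")
        out.add((min(a, b), max(a, b)))
    return frozenset(out)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of one simulated two-condition cluster."""

    n_genes: int
    n_sens: int
    n_res: int
    edges_sens: frozenset = frozenset()
    edges_res: frozenset = frozenset()
    rho: float = 0.8
    continuous: bool = False
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges_sens", _normalize_edges(self.edges_sens, self.n_genes))
        object.__setattr__(self, "edges_res", _normalize_edges(self.edges_res, self.n_genes))
        if not (0.0 <= self.rho <= 1.0):
            raise ValidationError("rho must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.n_genes < 2 or self.n_sens < 1 or self.n_res < 1:
            raise ValidationError("need >= 2 genes and >= 1 sample per condition")


@dataclass(frozen=True)
class GroundTruth:
    """What a perfect analysis should recover, derivable from the SyntheticSpec alone."""

    rewired_pairs: frozenset
    planted_mediators: frozenset

    @classmethod
    def from_spec(cls, spec: SyntheticSpec) -> "GroundTruth":
        rewired = spec.edges_sens ^ spec.edges_res
        incidence: dict[int, int] = {}
        for a, b in rewired:
            incidence[a] = incidence.get(a, 0) + 1
            incidence[b] = incidence.get(b, 0) + 1
        mediators = frozenset(g for g, k in incidence.items() if k >= 2)
        return cls(rewired_pairs=frozenset(rewired), planted_mediators=mediators)


@dataclass
class SimulatedCluster:
    """Simulated data plus its ground truth and the condition split."""

    data: ExpressionMatrix | DiscretizedMatrix
    truth: GroundTruth
    sensitive_ids: list[str]
    resistant_ids: list[str]


def gene_id(i: int) -> str:
    return f"G{i:03d}"


def _simulate_levels(
    n_genes: int, n_samples: int, edges: frozenset, rho: float, rng: np.random.Generator
) -> np.ndarray:
    parent = np.full(n_genes, -1, dtype=int)
    for a, b in sorted(edges):
        if parent[b] < 0 or a < parent[b]:
            parent[b] = a
    levels = np.empty((n_genes, n_samples), dtype=np.int8)
    for g in range(n_genes):
        if parent[g] < 0:
            levels[g] = rng.integers(0, 3, size=n_samples)
        else:
            copy = rng.random(n_samples) < rho
            fresh = rng.integers(0, 3, size=n_samples)
            levels[g] = np.where(copy, levels[parent[g]], fresh)
    return levels


def simulate_cluster_data(spec: SyntheticSpec) -> tuple:
    """Simulate both conditions of one cluster; returns (SimulatedCluster, GroundTruth)."""
    rng = np.random.default_rng(spec.seed)
    ls = _simulate_levels(spec.n_genes, spec.n_sens, spec.edges_sens, spec.rho, rng)
    lr = _simulate_levels(spec.n_genes, spec.n_res, spec.edges_res, spec.rho, rng)
    levels = np.concatenate([ls, lr], axis=1)
    gene_ids = [gene_id(i) for i in range(spec.n_genes)]
    sens_ids = [f"sens{i:04d}" for i in range(spec.n_sens)]
    res_ids = [f"res{i:04d}" for i in range(spec.n_res)]
    sample_ids = sens_ids + res_ids
    truth = GroundTruth.from_spec(spec)
    if spec.continuous:
        values = levels.astype(float) - 1.0 + rng.normal(0.0, spec.noise_sd, size=levels.shape)
        data = ExpressionMatrix(
            gene_ids=gene_ids,
            sample_ids=sample_ids,
            values=values,
            missing_mask=np.zeros(values.shape, dtype=bool),
        )
    else:
        data = DiscretizedMatrix(
            gene_ids=gene_ids,
            sample_ids=sample_ids,
            levels=levels,
            bin_edges=np.full((spec.n_genes, 2), np.nan),
        )
    sim = SimulatedCluster(
        data=data, truth=truth, sensitive_ids=sens_ids, resistant_ids=res_ids
    )
    return sim, truth


def simulate_null(spec: SyntheticSpec) -> tuple:
    """Both conditions drawn from one identical structure (no rewiring)."""
    if spec.edges_sens != spec.edges_res:
        raise ContractError("simulate_null requires identical edge sets in both conditions")
    sim, truth = simulate_cluster_data(spec)
    assert not truth.rewired_pairs
    return sim, truth


# ---------------------------------------------------------------------------
# full-pipeline landscape fixture
# ---------------------------------------------------------------------------

@dataclass
class LandscapeFixture:
    """File bundle for an end-to-end run plus the expected significance mask."""

    expression_path: Path
    response_path: Path
    gmt_path: Path
    sif_path: Path
    drug_ids: list[str]
    cluster_ids: list[str]
    expected_mask: np.ndarray          # (n_drugs, n_clusters) bool
    intended_partitions: dict = field(default_factory=dict)  # drug -> (sens, res) id lists


def simulate_landscape_fixture(
    n_drugs: int,
    n_clusters: int,
    planted_cells: Sequence[tuple[int, int]],
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: int = 250,
    genes_per_cluster: int = 6,
    rho: float = 0.9,
    noise_sd: float = 0.4,
) -> LandscapeFixture:
    """Emit expression, response, GMT and SIF files with planted rewired cells.

    Samples split into AUC tertiles per drug.  For a planted (drug, cluster)
    cell, that cluster's genes follow disjoint pairwise dependencies shared
    by both conditions plus two extra pairs dependent only in the drug's
    sensitive tertile; for every other cell the structure is identical
    across conditions.  AUC values are strictly separated so the tertile partition
    recovers the intended groups exactly.  Each cluster may be planted for
    at most one drug.

    The default cohort size (250 samples per tertile, 750 total) mirrors the
    scale of a large pharmacogenomic screen split into response tertiles;
    at that scale a permuted half-and-half mixture of the planted
    dependency is still detected reliably, which keeps the permutation
    null of the rewiring statistic tight.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genes_per_cluster < 6:
        raise ValidationError("need at least 6 genes per cluster")
    planted = list(planted_cells)
    for di, ci in planted:
        if not (0 <= di < n_drugs and 0 <= ci < n_clusters):
            raise ValidationError(f"planted cell ({di}, {ci}) outside the grid")
    if len({ci for _, ci in planted}) != len(planted):
        raise ValidationError("each cluster may be planted for at most one drug")

    rng = np.random.default_rng(seed)
    n_samples = 3 * n_per_group
    sample_ids = [f"CL{i:04d}" for i in range(n_samples)]
    drug_ids = [f"D{d:02d}" for d in range(n_drugs)]
    cluster_ids = [f"C{c:02d}" for c in range(n_clusters)]

    # per-drug intended condition assignment (sens / excluded / res thirds)
    assignment: dict[str, np.ndarray] = {}
    for d in range(n_drugs):
        order = rng.permutation(n_samples)
        lab = np.empty(n_samples, dtype="<U9")
        lab[order[:n_per_group]] = "sensitive"
        lab[order[n_per_group:2 * n_per_group]] = "excluded"
        lab[order[2 * n_per_group:]] = "resistant"
        assignment[drug_ids[d]] = lab

    planted_by_cluster = {ci: di for di, ci in planted}
    # shared structure = disjoint parent-child pairs: no indirect (second-order)
    # dependencies, so shared edges stay cleanly "both" downstream; the planted
    # cell rewires the two leading pairs (present in the sensitive tertile only)
    pairs_full = [(i, i + 1) for i in range(0, genes_per_cluster - 1, 2)]
    pairs_shared = [(i, i + 1) for i in range(4, genes_per_cluster - 1, 2)]
    rewired_edges = {(0, 1), (2, 3)}

    gene_rows: list[str] = []
    value_rows: list[np.ndarray] = []
    members: dict[str, list[str]] = {}
    prior_edges: list[tuple[str, str, str]] = []
    for c in range(n_clusters):
        cid = cluster_ids[c]
        gids = [f"{cid}G{g}" for g in range(genes_per_cluster)]
        members[cid] = gids
        levels = np.empty((genes_per_cluster, n_samples), dtype=np.int8)
        if c in planted_by_cluster:
            drug = drug_ids[planted_by_cluster[c]]
            lab = assignment[drug]
            sens_cols = np.flatnonzero(lab == "sensitive")
            other_cols = np.flatnonzero(lab != "sensitive")
            e_sens = frozenset(pairs_shared) | rewired_edges
            e_res = frozenset(pairs_shared)
            levels[:, sens_cols] = _simulate_levels(
                genes_per_cluster, sens_cols.size, e_sens, rho, rng
            )
            levels[:, other_cols] = _simulate_levels(
                genes_per_cluster, other_cols.size, e_res, rho, rng
            )
            shared_edges = pairs_shared
        else:
            levels[:] = _simulate_levels(
                genes_per_cluster, n_samples, frozenset(pairs_full), rho, rng
            )
            shared_edges = pairs_full
        for a, b in shared_edges:
            prior_edges.append((gids[a], cid, gids[b]))
        values = levels.astype(float) - 1.0 + rng.normal(0.0, noise_sd, size=levels.shape)
        gene_rows.extend(gids)
        value_rows.append(values)

    expr = pd.DataFrame(
        np.concatenate(value_rows, axis=0), index=gene_rows, columns=sample_ids
    )
    expression_path = out_dir / "expression.tsv"
    expr.to_csv(expression_path, sep="\t", index_label="gene_id", float_format="%.6f")

    # AUC values: evenly spread, with the intended sensitive third strictly lowest
    base = np.linspace(0.05, 0.95, n_samples)
    response_path = out_dir / "response.tsv"
    with open(response_path, "w") as fh:
        fh.write("compound_id\tsample_id\tauc\n")
        for d, drug in enumerate(drug_ids):
            lab = assignment[drug]
            auc = np.empty(n_samples)
            for block, sel in (
                (base[:n_per_group], lab == "sensitive"),
                (base[n_per_group:2 * n_per_group], lab == "excluded"),
                (base[2 * n_per_group:], lab == "resistant"),
            ):
                auc[np.flatnonzero(sel)] = rng.permutation(block)
            for s, a in zip(sample_ids, auc):
                fh.write(f"{drug}\t{s}\t{a:.6f}\n")

    gmt_path = out_dir / "clusters.gmt"
    with open(gmt_path, "w") as fh:
        for cid in cluster_ids:
            fh.write("\t".join([cid, f"synthetic cluster {cid}"] + members[cid]) + "\n")
    sif_path = out_dir / "priors.sif"
    with open(sif_path, "w") as fh:
        for a, cid, b in prior_edges:
            fh.write(f"{a}\t{cid}\t{b}\n")

    mask = np.zeros((n_drugs, n_clusters), dtype=bool)
    for di, ci in planted:
        mask[di, ci] = True
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "planted_cells": [[drug_ids[di], cluster_ids[ci]] for di, ci in planted],
                "drug_ids": drug_ids,
                "cluster_ids": cluster_ids,
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    intended = {
        drug: (
            [s for s, l in zip(sample_ids, assignment[drug]) if l == "sensitive"],
            [s for s, l in zip(sample_ids, assignment[drug]) if l == "resistant"],
        )
        for drug in drug_ids
    }
    return LandscapeFixture(
        expression_path=expression_path,
        response_path=response_path,
        gmt_path=gmt_path,
        sif_path=sif_path,
        drug_ids=drug_ids,
        cluster_ids=cluster_ids,
        expected_mask=mask,
        intended_partitions=intended,
    )
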