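"""Annotated differential dependency networks and mediator detection.

A DDN is built from the two condition ensembles of a significant
(drug, cluster) cell.  Each candidate pair whose inclusion frequency
reaches ``presence_theta`` in at least one condition becomes an edge,
classified sensitive / resistant / both by the frequency difference
against ``specific_tau``.  Nodes get normalized betweenness centralities
computed separately on the sensitive-side subgraph (sensitive + both
edges) and the resistant-side subgraph, and two mediator flags:

* specificity mediators carry a disproportionate share of
  condition-specific edges (one-sided binomial tail against the DDN-wide
  specific-edge fraction);
* essentiality mediators shift betweenness centrality between the two
  condition subnetworks by at least ``bc_delta_cutoff``.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
from scipy.stats import binom

from .core import (
    ConditionNetworkEnsemble,
    EddyConfig,
    RESISTANT,
    SENSITIVE,
)
from .errors import ContractError

BOTH = "both"


def classify_edge(p_sens: float, p_res: float, cfg: EddyConfig) -> str | None:
    """Condition class of one pair from its two inclusion frequencies.

    ``None`` (absent) when neither frequency reaches presence_theta; else
    sensitive / resistant when the frequency difference exceeds
    specific_tau in that direction, otherwise both.
    """
    if max(p_sens, p_res) < cfg.presence_theta:
        return None
    if p_sens - p_res > cfg.specific_tau:
        return SENSITIVE
    if p_res - p_sens > cfg.specific_tau:
        return RESISTANT
    return BOTH


@dataclass
class DDNEdge:
    gene_a: str
    gene_b: str
    p_sens: float
    p_res: float
    condition_class: str
    known: bool


@dataclass
class DDNNode:
    gene_id: str
    bc_sens: float = 0.0
    bc_res: float = 0.0
    specific_edge_count: int = 0
    total_edge_count: int = 0
    specificity_p: float = 1.0
    specificity_mediator: bool = False
    essentiality_mediator: bool = False


@dataclass
class DDN:
    """A rewired network for one (drug, cluster) cell, fully annotated."""

    drug_id: str
    cluster_id: str
    edges: list[DDNEdge]
    nodes: list[DDNNode]
    background_specific_fraction: float = 0.0

    def node(self, gene_id: str) -> DDNNode:
        for n in self.nodes:
            if n.gene_id == gene_id:
                return n
        raise KeyError(gene_id)

    def mediators(self) -> list[str]:
        """Genes flagged as specificity or essentiality mediators, sorted."""
        return sorted(
            n.gene_id for n in self.nodes
            if n.specificity_mediator or n.essentiality_mediator
        )

    @property
    def mediator_count(self) -> int:
        return len(self.mediators())

    def to_dict(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "cluster_id": self.cluster_id,
            "background_specific_fraction": self.background_specific_fraction,
            "edges": [
                {
                    "gene_a": e.gene_a, "gene_b": e.gene_b,
                    "p_sens": e.p_sens, "p_res": e.p_res,
                    "condition_class": e.condition_class, "known": e.known,
                }
                for e in sorted(self.edges, key=lambda e: (e.gene_a, e.gene_b))
            ],
            "nodes": [
                {
                    "gene_id": n.gene_id,
                    "bc_sens": n.bc_sens, "bc_res": n.bc_res,
                    "specific_edge_count": n.specific_edge_count,
                    "total_edge_count": n.total_edge_count,
                    "specificity_p": n.specificity_p,
                    "specificity_mediator": n.specificity_mediator,
                    "essentiality_mediator": n.essentiality_mediator,
                }
                for n in sorted(self.nodes, key=lambda n: n.gene_id)
            ],
        }

    def write_node_table(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tbc_sens\tbc_res\tspecific_edge_count\ttotal_edge_count\t"
                "specificity_p\tspecificity_mediator\tessentiality_mediator\n"
            )
            for n in sorted(self.nodes, key=lambda n: n.gene_id):
                fh.write(
                    f"{n.gene_id}\t{n.bc_sens!r}\t{n.bc_res!r}\t{n.specific_edge_count}\t"
                    f"{n.total_edge_count}\t{n.specificity_p!r}\t{n.specificity_mediator}\t"
                    f"{n.essentiality_mediator}\n"
                )
        return path


def betweenness(node_ids: Iterable[str], edges: Iterable[tuple[str, str]]) -> dict[str, float]:
    """Shortest-path betweenness per node, normalized to [0, 1].

    Brandes accumulation with fractional credit for tied shortest paths,
    scaled by (n-1)(n-2)/2 pairs; graphs with fewer than 3 nodes give all
    zeros.  Computed with networkx; an exhaustive path-enumeration oracle
    cross-checks it in the test suite.
    """
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    g.add_edges_from(edges)
    if g.number_of_nodes() < 3:
        return {n: 0.0 for n in g.nodes}
    return {n: float(v) for n, v in nx.betweenness_centrality(g, normalized=True).items()}


def build_ddn(
    ens_s: ConditionNetworkEnsemble,
    ens_r: ConditionNetworkEnsemble,
    cfg: EddyConfig,
    drug_id: str,
    cluster_id: str,
    members: Iterable[str] | None = None,
) -> DDN:
    """Assemble and annotate the DDN for one significant cell.

    ``members`` may list extra cluster genes (e.g. degenerate ones) to keep
    as isolated zero-metric nodes so mediator counting has a stable
    denominator; candidate-pair genes are always included.
    """
    if not ens_s.cand.same_space(ens_r.cand):
        raise ContractError("ensembles were built over different candidate pair spaces")
    cand = ens_s.cand
    node_ids = list(cand.gene_ids)
    if members is not None:
        for m in members:
            if m not in node_ids:
                node_ids.append(m)

    edges: list[DDNEdge] = []
    for k, (a, b) in enumerate(cand.pair_ids()):
        ps, pr = float(ens_s.edge_freq[k]), float(ens_r.edge_freq[k])
        cls = classify_edge(ps, pr, cfg)
        if cls is None:
            continue
        edges.append(DDNEdge(a, b, ps, pr, cls, bool(cand.known[k])))

    n_specific = sum(1 for e in edges if e.condition_class in (SENSITIVE, RESISTANT))
    background = n_specific / len(edges) if edges else 0.0

    bc_s = betweenness(
        node_ids, [(e.gene_a, e.gene_b) for e in edges if e.condition_class in (SENSITIVE, BOTH)]
    )
    bc_r = betweenness(
        node_ids, [(e.gene_a, e.gene_b) for e in edges if e.condition_class in (RESISTANT, BOTH)]
    )

    nodes = []
    for gid in node_ids:
        total = sum(1 for e in edges if gid in (e.gene_a, e.gene_b))
        specific = sum(
            1 for e in edges
            if gid in (e.gene_a, e.gene_b) and e.condition_class in (SENSITIVE, RESISTANT)
        )
        nodes.append(
            DDNNode(
                gene_id=gid,
                bc_sens=bc_s.get(gid, 0.0),
                bc_res=bc_r.get(gid, 0.0),
                specific_edge_count=specific,
                total_edge_count=total,
            )
        )
    ddn = DDN(
        drug_id=drug_id,
        cluster_id=cluster_id,
        edges=edges,
        nodes=nodes,
        background_specific_fraction=background,
    )
    find_specificity_mediators(ddn, cfg)
    find_essentiality_mediators(ddn, cfg)
    return ddn


def find_specificity_mediators(ddn: DDN, cfg: EddyConfig) -> dict[str, bool]:
    """Flag genes whose incident edges are disproportionately condition-specific.

    For each node with at least one edge, the one-sided binomial tail
    P(X >= specific | n = total, p = background_specific_fraction) is
    compared against mediator_alpha.  A zero background with any specific
    edge gives tail 0 and flags the node (limit case); a background of 1
    gives tail 1 for every node, so no flags.
    """
    p0 = ddn.background_specific_fraction
    flags: dict[str, bool] = {}
    for n in ddn.nodes:
        if n.total_edge_count < 1:
            n.specificity_p = 1.0
            n.specificity_mediator = False
        else:
            tail = float(binom.sf(n.specific_edge_count - 1, n.total_edge_count, p0))
            n.specificity_p = tail
            n.specificity_mediator = bool(tail < cfg.mediator_alpha)
        flags[n.gene_id] = n.specificity_mediator
    return flags


def find_essentiality_mediators(ddn: DDN, cfg: EddyConfig) -> dict[str, bool]:
    """Flag genes whose betweenness centrality shifts between the condition subnetworks."""
    flags: dict[str, bool] = {}
    for n in ddn.nodes:
        n.essentiality_mediator = bool(abs(n.bc_sens - n.bc_res) >= cfg.bc_delta_cutoff)
        flags[n.gene_id] = n.essentiality_mediator
    return flags
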