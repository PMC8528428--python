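"""Drug x cluster rewiring landscape: scores, sorting, hotspots, drug classes.

The landscape cell for (drug, cluster) holds the rewiring test result and,
when significant, the number of mediator genes in the cell's DDN.  The
rewiring score of a drug (or cluster) is the sum of mediator counts over
its significant cells; the frequency is the count of significant cells.
Drugs sharing a target form a class whose shared clusters (significant for
every member) get one combined DDN built from mean-pooled edge frequencies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ConditionNetworkEnsemble, EddyConfig, RewiringResult
from .ddn import DDN, build_ddn
from .errors import ContractError, ValidationError


@dataclass
class LandscapeCell:
    drug_id: str
    cluster_id: str
    result: RewiringResult
    mediator_count: int = 0

    def __post_init__(self) -> None:
        if not self.result.significant and self.mediator_count != 0:
            raise ValidationError("non-significant cells carry no DDN, so no mediators")


@dataclass
class LandscapeMatrix:
    """The full drug x cluster grid with per-id scores and frequencies."""

    drugs: list[str]
    clusters: list[str]
    cells: dict = field(default_factory=dict)  # (drug, cluster) -> LandscapeCell
    drug_score: dict = field(default_factory=dict)
    cluster_score: dict = field(default_factory=dict)
    drug_freq: dict = field(default_factory=dict)
    cluster_freq: dict = field(default_factory=dict)

    def cell(self, drug_id: str, cluster_id: str) -> LandscapeCell:
        return self.cells[(drug_id, cluster_id)]

    def iter_cells(self) -> Iterable[LandscapeCell]:
        for d in self.drugs:
            for c in self.clusters:
                yield self.cells[(d, c)]

    def significant_clusters(self, drug_id: str) -> set:
        return {
            c for c in self.clusters if self.cells[(drug_id, c)].result.significant
        }


def build_landscape(cells: Sequence[LandscapeCell], drugs=None, clusters=None) -> LandscapeMatrix:
    """Assemble the grid and compute marginal scores and frequencies.

    Every (drug, cluster) pair must be attempted exactly once (skipped cells
    carry a skipped_reason in their result).  drug_score(d) = sum of
    mediator counts over d's significant cells; drug_freq(d) = number of
    significant cells; symmetrically for clusters.
    """
    if drugs is None:
        drugs = sorted({c.drug_id for c in cells})
    if clusters is None:
        clusters = sorted({c.cluster_id for c in cells})
    grid: dict = {}
    for cell in cells:
        key = (cell.drug_id, cell.cluster_id)
        if key in grid:
            raise ValidationError(f"duplicate landscape cell {key!r}")
        grid[key] = cell
    missing = [(d, c) for d in drugs for c in clusters if (d, c) not in grid]
    if missing:
        raise ValidationError(f"landscape is missing cell(s) {missing[:3]}")

    m = LandscapeMatrix(drugs=list(drugs), clusters=list(clusters), cells=grid)
    for d in drugs:
        sig = [grid[(d, c)] for c in clusters if grid[(d, c)].result.significant]
        m.drug_score[d] = sum(c.mediator_count for c in sig)
        m.drug_freq[d] = len(sig)
    for c in clusters:
        sig = [grid[(d, c)] for d in drugs if grid[(d, c)].result.significant]
        m.cluster_score[c] = sum(x.mediator_count for x in sig)
        m.cluster_freq[c] = len(sig)
    return m


def sort_landscape(m: LandscapeMatrix) -> tuple[list[str], list[str]]:
    """Drugs and clusters in descending score order, ties ascending by id."""
    drugs = sorted(m.drugs, key=lambda d: (-m.drug_score[d], d))
    clusters = sorted(m.clusters, key=lambda c: (-m.cluster_score[c], c))
    return drugs, clusters


@dataclass
class HotspotSelection:
    drugs: list[str]
    clusters: list[str]
    #: per selected cluster, (hits, n_selected_drugs) of selected drugs significant for it
    cluster_drug_fraction: dict = field(default_factory=dict)


def select_hotspot(
    m: LandscapeMatrix, top_drugs: int = 15, top_clusters: int = 5
) -> HotspotSelection:
    """Top-k drugs and clusters by rewiring score.

    Defaults mirror the headline hotspot view: 15 small molecules by 5
    clusters.  Also reports, per selected cluster, how many of the selected
    drugs are significant for it (the "7 of 15" style convergence
    statistic).  Oversized k is truncated with a warning.
    """
    drugs, clusters = sort_landscape(m)
    if top_drugs > len(drugs):
        warnings.warn(f"top_drugs={top_drugs} exceeds {len(drugs)} drugs; truncating")
        top_drugs = len(drugs)
    if top_clusters > len(clusters):
        warnings.warn(f"top_clusters={top_clusters} exceeds {len(clusters)} clusters; truncating")
        top_clusters = len(clusters)
    sel_drugs = drugs[:top_drugs]
    sel_clusters = clusters[:top_clusters]
    frac = {
        c: (
            sum(1 for d in sel_drugs if m.cells[(d, c)].result.significant),
            len(sel_drugs),
        )
        for c in sel_clusters
    }
    return HotspotSelection(drugs=sel_drugs, clusters=sel_clusters, cluster_drug_fraction=frac)


def shared_class_clusters(
    significant_sets: dict, member_drug_ids: Sequence[str]
) -> set:
    """Clusters significantly rewired for EVERY drug in the class (set intersection)."""
    if len(member_drug_ids) < 2:
        raise ContractError("a drug class needs at least 2 member drugs")
    missing = [d for d in member_drug_ids if d not in significant_sets]
    if missing:
        raise ContractError(f"member drug(s) without analyzed results: {missing}")
    shared = set(significant_sets[member_drug_ids[0]])
    for d in member_drug_ids[1:]:
        shared &= set(significant_sets[d])
    return shared


def combine_class_ddn(
    per_drug_ensembles: Sequence[tuple[ConditionNetworkEnsemble, ConditionNetworkEnsemble]],
    cfg: EddyConfig,
    class_id: str,
    cluster_id: str,
) -> DDN:
    """One DDN for a drug class on a shared cluster, via frequency pooling.

    Pooled edge frequency = arithmetic mean of the member drugs' per-condition
    frequencies (order-invariant); edge classification and mediator detection
    then run on the pooled profiles.
    """
    if not per_drug_ensembles:
        raise ContractError("no ensembles to combine")
    cand = per_drug_ensembles[0][0].cand
    for ens_s, ens_r in per_drug_ensembles:
        if not (ens_s.cand.same_space(cand) and ens_r.cand.same_space(cand)):
            raise ContractError("member ensembles cover different candidate pair spaces")
    pooled_s = np.mean([e[0].edge_freq for e in per_drug_ensembles], axis=0)
    pooled_r = np.mean([e[1].edge_freq for e in per_drug_ensembles], axis=0)
    ens_s = ConditionNetworkEnsemble(
        condition=per_drug_ensembles[0][0].condition, cand=cand, edge_freq=pooled_s,
        n_samples=per_drug_ensembles[0][0].n_samples,
    )
    ens_r = ConditionNetworkEnsemble(
        condition=per_drug_ensembles[0][1].condition, cand=cand, edge_freq=pooled_r,
        n_samples=per_drug_ensembles[0][1].n_samples,
    )
    return build_ddn(ens_s, ens_r, cfg, drug_id=class_id, cluster_id=cluster_id)


def export_landscape(m: LandscapeMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the heatmap matrix (mediator counts) and marginal tables as TSV.

    Rows/columns follow the sorted (descending-score) order; bytes are
    deterministic for identical landscapes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    drugs, clusters = sort_landscape(m)
    heat = pd.DataFrame(
        [[m.cells[(d, c)].mediator_count for d in drugs] for c in clusters],
        index=pd.Index(clusters, name="cluster_id"),
        columns=drugs,
    )
    paths = {}
    paths["heatmap"] = out_dir / "heatmap.tsv"
    heat.to_csv(paths["heatmap"], sep="\t")
    drug_tab = pd.DataFrame(
        {
            "drug_id": drugs,
            "score": [m.drug_score[d] for d in drugs],
            "freq": [m.drug_freq[d] for d in drugs],
        }
    )
    paths["drug_marginals"] = out_dir / "drug_marginals.tsv"
    drug_tab.to_csv(paths["drug_marginals"], sep="\t", index=False)
    clust_tab = pd.DataFrame(
        {
            "cluster_id": clusters,
            "score": [m.cluster_score[c] for c in clusters],
            "freq": [m.cluster_freq[c] for c in clusters],
        }
    )
    paths["cluster_marginals"] = out_dir / "cluster_marginals.tsv"
    clust_tab.to_csv(paths["cluster_marginals"], sep="\t", index=False)
    return paths


def landscape_from_scores(df: pd.DataFrame) -> LandscapeMatrix:
    """Rebuild a LandscapeMatrix from a score table written by io.write_scores."""
    cells = []
    cell_rows = df[df["row_type"] == "cell"]
    for _, row in cell_rows.iterrows():
        res = RewiringResult(
            drug_id=row["drug_id"],
            cluster_id=row["cluster_id"],
            statistic=None if pd.isna(row["statistic"]) else float(row["statistic"]),
            p_value=None if pd.isna(row["p_value"]) else float(row["p_value"]),
            q_value=None if pd.isna(row["q_value"]) else float(row["q_value"]),
            significant=bool(row["significant"]),
            skipped_reason=(row["skipped_reason"] if isinstance(row["skipped_reason"], str)
                            and row["skipped_reason"] else None),
        )
        cells.append(
            LandscapeCell(
                drug_id=row["drug_id"], cluster_id=row["cluster_id"], result=res,
                mediator_count=int(row["mediator_count"]),
            )
        )
    drugs = list(dict.fromkeys(cell_rows["drug_id"]))
    clusters = list(dict.fromkeys(cell_rows["cluster_id"]))
    return build_landscape(cells, drugs=drugs, clusters=clusters)
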