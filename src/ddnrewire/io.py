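"""Readers and writers for every external format the pipeline touches.

Expression matrices arrive as delimited text (genes x samples), drug
response as a three-column (compound, sample, auc) table, gene clusters as
GMT with prior-knowledge interactions in SIF, and results leave as
SIF/GraphML/JSON network exports plus TSV score tables.  Delimiters are
auto-detected from the header line (tab preferred, comma fallback).  All
writers are deterministic: identical in-memory objects yield identical
bytes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: fraction of missing entries beyond which a gene row is dropped on read
DEFAULT_MAX_MISSING_FRAC = 0.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of (log-scale) expression values.

    ``values[i, j]`` is finite wherever ``missing_mask[i, j]`` is False;
    missing cells hold NaN and are True in the mask.  Identifiers are unique
    and kept in file order.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("expression values shape does not match identifiers")
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("missing_mask shape does not match values")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValidationError("non-finite expression value outside the missing mask")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_positions(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Column indices of ``sample_ids``, sorted into matrix order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = np.array(sorted(lookup[s] for s in sample_ids), dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from exc
        return cols


class ResponseRecord(NamedTuple):
    compound_id: str
    sample_id: str
    auc: float


@dataclass
class DrugResponseTable:
    """Area-under-dose-response-curve summaries, one row per (compound, sample)."""

    records: list[ResponseRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.compound_id, rec.sample_id)
            if key in seen:
                raise ValidationError(f"duplicate (compound, sample) pair {key!r}")
            seen.add(key)
            if not np.isfinite(rec.auc):
                raise ValidationError(f"non-finite auc for {key!r}")

    def compounds(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.compound_id not in out:
                out.append(rec.compound_id)
        return out

    def for_compound(self, compound_id: str) -> list[ResponseRecord]:
        return [r for r in self.records if r.compound_id == compound_id]

    def restrict_samples(self, keep: Iterable[str]) -> "DrugResponseTable":
        keep_set = set(keep)
        return DrugResponseTable([r for r in self.records if r.sample_id in keep_set])


class PriorEdge(NamedTuple):
    gene_a: str
    gene_b: str
    cluster_id: str


@dataclass
class GeneCluster:
    cluster_id: str
    description: str
    member_gene_ids: list[str]


@dataclass
class GeneClusterCatalog:
    """GMT gene clusters plus prior-knowledge edges attached to them."""

    clusters: list[GeneCluster]
    prior_edges: list[PriorEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([c.cluster_id for c in self.clusters], "cluster")
        members = {c.cluster_id: set(c.member_gene_ids) for c in self.clusters}
        for c in self.clusters:
            if not c.member_gene_ids:
                raise ValidationError(f"cluster {c.cluster_id!r} has no members")
            _check_unique(c.member_gene_ids, f"member of cluster {c.cluster_id}")
        for e in self.prior_edges:
            if e.cluster_id not in members:
                raise ValidationError(
                    f"prior edge ({e.gene_a}, {e.gene_b}) tagged with unknown cluster {e.cluster_id!r}"
                )
            mem = members[e.cluster_id]
            if e.gene_a not in mem or e.gene_b not in mem:
                raise ValidationError(
                    f"prior edge ({e.gene_a}, {e.gene_b}) has an endpoint outside "
                    f"cluster {e.cluster_id!r}"
                )

    def cluster_ids(self) -> list[str]:
        return [c.cluster_id for c in self.clusters]

    def get(self, cluster_id: str) -> GeneCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def prior_pairs(self, cluster_id: str) -> set[frozenset]:
        return {
            frozenset((e.gene_a, e.gene_b))
            for e in self.prior_edges
            if e.cluster_id == cluster_id
        }


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} identifier {i!r}")
        seen.add(i)


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    missing_token: str = "NA",
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (header of sample ids, first column gene ids).

    Cells equal to ``missing_token`` become missing; genes with more than
    ``max_missing_frac`` missing entries are dropped and logged.  Any other
    non-numeric cell raises :class:`FormatError` with its coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _detect_sep(header)
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g).strip() for g in df.index]
    sample_ids = [str(s).strip() for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")

    raw = df.to_numpy(dtype=str)
    raw = np.char.strip(raw)
    miss = raw == missing_token
    flat = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    values = flat.reshape(raw.shape)
    bad = ~np.isfinite(values) & ~miss
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-numeric cell {raw[i, j]!r} at gene {gene_ids[i]!r} (row {i + 2}), "
            f"sample {sample_ids[j]!r} (column {j + 2})"
        )
    values = np.where(miss, np.nan, values)

    frac_missing = miss.mean(axis=1)
    keep = frac_missing <= max_missing_frac
    dropped = [g for g, k in zip(gene_ids, keep) if not k]
    if dropped:
        log.warning(
            "dropping %d gene(s) with > %.0f%% missing entries: %s",
            len(dropped), 100 * max_missing_frac, ", ".join(dropped),
        )
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(gene_ids, keep) if k],
        sample_ids=sample_ids,
        values=values[keep],
        missing_mask=miss[keep],
    )


def read_response(path: str | Path) -> DrugResponseTable:
    """Read a three-column (compound, sample, auc) table, with or without a header."""
    path = Path(path)
    records: list[ResponseRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        sep = _detect_sep(lines[0])
        first = [f.strip() for f in lines[0].split(sep)]
        if len(first) == 3:
            try:
                float(first[2])
            except ValueError:
                start = 1  # header row
        elif first == [""]:
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        sep = _detect_sep(line)
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != 3:
            raise FormatError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        compound, sample, auc_text = fields
        try:
            auc = float(auc_text)
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric auc value {auc_text!r}") from None
        if not np.isfinite(auc):
            raise FormatError(f"line {lineno}: non-finite auc value {auc_text!r}")
        records.append(ResponseRecord(compound, sample, auc))
    try:
        return DrugResponseTable(records)
    except ValidationError as exc:
        raise FormatError(str(exc)) from None


def read_clusters(gmt_path: str | Path, sif_path: str | Path) -> GeneClusterCatalog:
    """Read a GMT cluster catalog and a SIF file of prior edges.

    GMT lines are ``cluster_id <TAB> description <TAB> member...``.  SIF lines
    are ``geneA <TAB-or-space> cluster_id <TAB-or-space> geneB``: the middle
    token names the cluster the prior edge belongs to, and both endpoints must
    be members of that cluster.
    """
    clusters: list[GeneCluster] = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh.read().splitlines(), start=1):
            if line.strip() == "":
                raise FormatError(f"{gmt_path}: empty GMT line {lineno}")
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}: GMT line {lineno} needs cluster id, description and >= 1 member"
                )
            clusters.append(GeneCluster(fields[0], fields[1], [f for f in fields[2:] if f]))

    edges: list[PriorEdge] = []
    with open(sif_path) as fh:
        for lineno, line in enumerate(fh.read().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) != 3:
                raise FormatError(f"{sif_path}: SIF line {lineno} expected 3 fields")
            a, tag, b = fields
            edges.append(PriorEdge(a, b, tag))
    return GeneClusterCatalog(clusters=clusters, prior_edges=edges)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_ddn(ddn, path_stem: str | Path) -> list[Path]:
    """Write a DDN as ``<stem>.sif``, ``<stem>.graphml`` and ``<stem>.json``.

    SIF relation tokens are the edge condition classes (sensitive / resistant
    / both).  GraphML carries edge attributes ``condition_class``, ``known``,
    ``p_sens``, ``p_res`` and node attributes ``bc_sens``, ``bc_res``,
    ``specificity_mediator``, ``essentiality_mediator``.  Output bytes are
    identical across repeated calls on an identical DDN.
    """
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    edges = sorted(ddn.edges, key=lambda e: (e.gene_a, e.gene_b))
    nodes = sorted(ddn.nodes, key=lambda n: n.gene_id)

    sif_path = stem.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.condition_class}\t{e.gene_b}\n")

    g = nx.Graph()
    for n in nodes:
        g.add_node(
            n.gene_id,
            bc_sens=float(n.bc_sens),
            bc_res=float(n.bc_res),
            specificity_mediator=bool(n.specificity_mediator),
            essentiality_mediator=bool(n.essentiality_mediator),
        )
    for e in edges:
        g.add_edge(
            e.gene_a,
            e.gene_b,
            condition_class=e.condition_class,
            known=bool(e.known),
            p_sens=float(e.p_sens),
            p_res=float(e.p_res),
        )
    graphml_path = stem.with_suffix(".graphml")
    nx.write_graphml_xml(g, graphml_path)

    json_path = stem.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(ddn.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [sif_path, graphml_path, json_path]


_SCORE_COLUMNS = [
    "row_type", "drug_id", "cluster_id", "statistic", "p_value", "q_value",
    "significant", "mediator_count", "score", "freq", "skipped_reason",
]


def write_scores(landscape, path: str | Path) -> Path:
    """Write the landscape as one TSV: per-cell rows plus score/frequency marginals."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for cell in landscape.iter_cells():
        r = cell.result
        rows.append({
            "row_type": "cell",
            "drug_id": cell.drug_id,
            "cluster_id": cell.cluster_id,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": bool(r.significant),
            "mediator_count": cell.mediator_count,
            "skipped_reason": r.skipped_reason or "",
        })
    for d in landscape.drugs:
        rows.append({
            "row_type": "drug_marginal",
            "drug_id": d,
            "score": landscape.drug_score[d],
            "freq": landscape.drug_freq[d],
        })
    for c in landscape.clusters:
        rows.append({
            "row_type": "cluster_marginal",
            "cluster_id": c,
            "score": landscape.cluster_score[c],
            "freq": landscape.cluster_freq[c],
        })
    df = pd.DataFrame(rows, columns=_SCORE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read back a score table written by :func:`write_scores`."""
    return pd.read_csv(path, sep="\t", dtype={"drug_id": str, "cluster_id": str})
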