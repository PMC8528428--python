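"""End-to-end orchestration: inputs -> per-cell rewiring tests -> DDNs -> landscape.

For every (drug, cluster) pair the pipeline partitions samples by drug
response, builds the two bootstrap ensembles, runs the permutation test,
then applies Benjamini-Hochberg control across the whole grid.  Significant
cells get an annotated DDN (SIF/GraphML/JSON plus a node table); the
landscape, its sorted exports and the hotspot selection are written under a
single run directory together with a machine-readable manifest.

Determinism: with a fixed config (including its seed), every artifact is
byte-identical across runs, except the manifest's wall-clock timing block.
Per-cell seeds are derived from (seed, drug id, cluster id), so adding a
drug never perturbs existing cells' results.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohort import partition_by_response
from .core import (
    CandidatePairs,
    EddyConfig,
    RewiringResult,
    discretize,
    fdr_adjust,
    observed_ensembles,
    permutation_test,
)
from .ddn import build_ddn
from .errors import ValidationError
from .io import (
    read_clusters,
    read_expression,
    read_response,
    write_ddn,
    write_scores,
)
from .landscape import (
    LandscapeCell,
    build_landscape,
    combine_class_ddn,
    export_landscape,
    select_hotspot,
    shared_class_clusters,
)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    inputs: dict
    version: str
    seed: int
    pairs: list = field(default_factory=list)  # per (drug, cluster) status records
    timing_seconds: float | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "inputs": self.inputs,
            "version": self.version,
            "seed": self.seed,
            "pairs": self.pairs,
            "timing_seconds": self.timing_seconds,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            config=data["config"], inputs=data["inputs"], version=data["version"],
            seed=data["seed"], pairs=data["pairs"],
            timing_seconds=data.get("timing_seconds"),
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _safe_name(token: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_." else "_" for ch in str(token))


def run_pipeline(
    expression_path: str | Path,
    response_path: str | Path,
    gmt_path: str | Path,
    sif_path: str | Path,
    out_dir: str | Path,
    config: EddyConfig | None = None,
    config_path: str | Path | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Run the full analysis and write all artifacts under ``out_dir``."""
    t0 = time.monotonic()
    if config is not None and config_path is not None:
        raise ValidationError("pass either config or config_path, not both")
    cfg = config or (EddyConfig.from_file(config_path) if config_path else EddyConfig())
    if seed is not None:
        cfg = cfg.with_seed(seed)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    x = read_expression(expression_path)
    response = read_response(response_path)
    catalog = read_clusters(gmt_path, sif_path)

    expr_samples = set(x.sample_ids)
    shared = {r.sample_id for r in response.records} & expr_samples
    if not shared:
        raise ValidationError("expression and response tables share no sample ids")
    response = response.restrict_samples(expr_samples)

    d = discretize(x)
    drugs = sorted(response.compounds())
    cluster_ids = catalog.cluster_ids()

    manifest = RunManifest(
        config=cfg.to_dict(),
        inputs={
            "expression": {"path": str(expression_path), "sha256": _sha256(expression_path)},
            "response": {"path": str(response_path), "sha256": _sha256(response_path)},
            "gmt": {"path": str(gmt_path), "sha256": _sha256(gmt_path)},
            "sif": {"path": str(sif_path), "sha256": _sha256(sif_path)},
        },
        version=__version__,
        seed=cfg.seed,
    )

    results = []
    ensembles = {}
    member_map = {}
    for drug in drugs:
        partition = partition_by_response(
            response, drug, cfg.lower_q, cfg.upper_q, cfg.min_group_size
        )
        partition.write_tsv(out_dir / "partitions" / f"{_safe_name(drug)}.tsv")
        for cid in cluster_ids:
            cluster = catalog.get(cid)
            member_map[cid] = cluster.member_gene_ids
            try:
                cand = CandidatePairs.build(
                    d, cluster.member_gene_ids, catalog.prior_pairs(cid), cfg
                )
            except ValidationError as exc:
                res = RewiringResult(drug_id=drug, cluster_id=cid,
                                     skipped_reason=f"oversized_cluster: {exc}")
                results.append(res)
                manifest.pairs.append({"drug_id": drug, "cluster_id": cid,
                                       "status": "skipped", "reason": res.skipped_reason})
                continue
            res, ens_s, ens_r = permutation_test(
                d, partition, cand, cfg, cluster_id=cid, return_ensembles=True
            )
            results.append(res)
            if res.skipped_reason is None:
                ensembles[(drug, cid)] = (ens_s, ens_r)
                status = {"drug_id": drug, "cluster_id": cid, "status": "done"}
            else:
                status = {"drug_id": drug, "cluster_id": cid, "status": "skipped",
                          "reason": res.skipped_reason}
                log.info("skipping (%s, %s): %s", drug, cid, res.skipped_reason)
            manifest.pairs.append(status)

    fdr_adjust(results, cfg.fdr_alpha)

    cells = []
    for res in results:
        mediator_count = 0
        if res.significant:
            ens_s, ens_r = ensembles[(res.drug_id, res.cluster_id)]
            ddn = build_ddn(
                ens_s, ens_r, cfg, drug_id=res.drug_id, cluster_id=res.cluster_id,
                members=member_map[res.cluster_id],
            )
            stem = out_dir / "ddn" / f"{_safe_name(res.drug_id)}__{_safe_name(res.cluster_id)}"
            write_ddn(ddn, stem)
            ddn.write_node_table(stem.parent / (stem.name + ".nodes.tsv"))
            mediator_count = ddn.mediator_count
        cells.append(
            LandscapeCell(
                drug_id=res.drug_id, cluster_id=res.cluster_id, result=res,
                mediator_count=mediator_count,
            )
        )

    m = build_landscape(cells, drugs=drugs, clusters=cluster_ids)
    write_scores(m, out_dir / "scores.tsv")
    export_landscape(m, out_dir / "landscape")
    hotspot = select_hotspot(
        m,
        top_drugs=min(cfg.top_drugs, len(drugs)),
        top_clusters=min(cfg.top_clusters, len(cluster_ids)),
    )
    with open(out_dir / "landscape" / "hotspot.json", "w") as fh:
        json.dump(
            {
                "drugs": hotspot.drugs,
                "clusters": hotspot.clusters,
                "cluster_drug_fraction": {
                    c: {"hits": h, "of": n} for c, (h, n) in hotspot.cluster_drug_fraction.items()
                },
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    manifest.timing_seconds = round(time.monotonic() - t0, 3)
    manifest.write(out_dir / "manifest.json")
    return manifest


def run_class(
    run_dir: str | Path,
    class_file: str | Path,
) -> dict:
    """Shared clusters and combined DDNs for one drug class, from a finished run.

    The class definition file (YAML or JSON) holds ``class_id`` and
    ``members`` (>= 2 drug ids present in the run).  Member ensembles are
    recomputed deterministically from the manifest's config and inputs.
    """
    run_dir = Path(run_dir)
    manifest = RunManifest.load(run_dir / "manifest.json")
    cfg = EddyConfig.from_mapping(manifest.config)

    text = Path(class_file).read_text()
    spec = json.loads(text) if str(class_file).endswith(".json") else yaml.safe_load(text)
    class_id = spec.get("class_id")
    members = spec.get("members", [])
    if not class_id:
        raise ValidationError("class definition needs a class_id")
    if len(members) < 2:
        raise ValidationError("a drug class needs at least 2 member drugs")
    run_drugs = {p["drug_id"] for p in manifest.pairs}
    absent = [m for m in members if m not in run_drugs]
    if absent:
        raise ValidationError(f"member drug(s) missing from the run: {absent}")

    from .io import read_scores
    from .landscape import landscape_from_scores

    m = landscape_from_scores(read_scores(run_dir / "scores.tsv"))
    sig_sets = {drug: m.significant_clusters(drug) for drug in members}
    shared = shared_class_clusters(sig_sets, members)

    x = read_expression(manifest.inputs["expression"]["path"])
    response = read_response(manifest.inputs["response"]["path"]).restrict_samples(
        set(x.sample_ids)
    )
    catalog = read_clusters(manifest.inputs["gmt"]["path"], manifest.inputs["sif"]["path"])
    d = discretize(x)

    class_dir = run_dir / f"class_{_safe_name(class_id)}"
    class_dir.mkdir(parents=True, exist_ok=True)
    report = {"class_id": class_id, "members": list(members),
              "shared_clusters": sorted(shared), "combined_ddns": {}}
    for cid in sorted(shared):
        cluster = catalog.get(cid)
        cand = CandidatePairs.build(d, cluster.member_gene_ids, catalog.prior_pairs(cid), cfg)
        per_drug = []
        for drug in members:
            partition = partition_by_response(
                response, drug, cfg.lower_q, cfg.upper_q, cfg.min_group_size
            )
            per_drug.append(observed_ensembles(d, partition, cand, cfg, cluster_id=cid))
        ddn = combine_class_ddn(per_drug, cfg, class_id=class_id, cluster_id=cid)
        stem = class_dir / f"{_safe_name(class_id)}__{_safe_name(cid)}"
        write_ddn(ddn, stem)
        report["combined_ddns"][cid] = {
            "n_edges": len(ddn.edges),
            "mediators": ddn.mediators(),
        }
    with open(class_dir / "class_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
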