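"""Calibration and power experiments for the rewiring test, plus independent oracles.

These are the package's own validation studies: null calibration of the
permutation p-values, power to recover a planted condition-specific edge
and a planted mediator hub, end-to-end recovery on a full synthetic
landscape, and brute-force cross-checks of the graph and contingency-table
primitives.  The oracles here deliberately avoid the code paths they
check: betweenness is recomputed by exhaustive shortest-path enumeration,
and the G-test is compared against an independent log-likelihood-ratio
contingency computation.
"""
from __future__ import annotations

import itertools
import json
import tempfile
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import ConditionPartition
from .core import (
    CandidatePairs,
    EddyConfig,
    g_test_pair,
    observed_ensembles,
    permutation_test,
)
from .ddn import betweenness, build_ddn
from .pipeline import run_pipeline
from .simulate import (
    SyntheticSpec,
    simulate_cluster_data,
    simulate_landscape_fixture,
    simulate_null,
)

#: shared dependency structure used by the null-calibration study (6 genes,
#: three disjoint dependent pairs, identical in both conditions)
NULL_EDGES = frozenset({(0, 1), (2, 3), (4, 5)})


def _partition_for(sim) -> ConditionPartition:
    return ConditionPartition(
        compound_id="drug",
        sensitive_ids=frozenset(sim.sensitive_ids),
        resistant_ids=frozenset(sim.resistant_ids),
        excluded_ids=frozenset(),
        quantile_bounds=(1 / 3, 1 / 3),
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_betweenness(node_ids, edges) -> dict:
    """Betweenness by exhaustive enumeration of all shortest paths (tiny graphs).

    For every ordered node pair, all simple paths are enumerated, the
    shortest retained, and each interior node credited with its fraction of
    those paths; the total is normalized by (n-1)(n-2)/2 unordered pairs.
    """
    nodes = list(node_ids)
    adj = defaultdict(set)
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    score = {v: 0.0 for v in nodes}
    n = len(nodes)
    if n < 3:
        return score

    def all_simple_paths(s, t):
        out = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return out

    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        paths = [p for p in paths if len(p) == shortest]
        for p in paths:
            for v in p[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: score[v] / norm for v in nodes}


def betweenness_max_error(n_graphs: int = 200, seed: int = 0, max_nodes: int = 6) -> float:
    """Largest |betweenness - brute force| over random graphs of <= max_nodes nodes."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(3, max_nodes + 1))
        nodes = [f"n{i}" for i in range(n)]
        possible = list(itertools.combinations(nodes, 2))
        k = int(rng.integers(1, len(possible) + 1))
        chosen = [possible[i] for i in rng.choice(len(possible), size=k, replace=False)]
        got = betweenness(nodes, chosen)
        want = brute_force_betweenness(nodes, chosen)
        worst = max(worst, max(abs(got[v] - want[v]) for v in nodes))
    return worst


def g_test_max_error(n_tables: int = 1000, seed: int = 0, max_n: int = 30) -> float:
    """Largest |p - oracle p| of the G-test over random 3x3 tables with n <= max_n.

    The oracle is an independent log-likelihood-ratio contingency
    computation on the table with all-zero rows/columns removed; tables
    that reduce below 2x2 are uninformative on both routes (p = 1).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(10, max_n + 1))
        cells = rng.multinomial(n, rng.dirichlet(np.ones(9)))
        table = cells.reshape(3, 3)
        a = np.repeat(np.arange(3), table.sum(axis=1))
        b = np.concatenate([np.repeat(np.arange(3), row) for row in table])
        _, _, p = g_test_pair(a, b)
        reduced = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if reduced.shape[0] < 2 or reduced.shape[1] < 2:
            p_oracle = 1.0
        else:
            p_oracle = chi2_contingency(
                reduced, correction=False, lambda_="log-likelihood"
            ).pvalue
        worst = max(worst, abs(p - p_oracle))
    return worst


# ---------------------------------------------------------------------------
# calibration and power studies
# ---------------------------------------------------------------------------

def null_calibration_fraction(
    n_datasets: int = 200,
    seed: int = 0,
    n_per_group: int = 60,
    n_resamples: int = 50,
    n_permutations: int = 99,
) -> float:
    """Fraction of permutation p-values <= 0.05 over simulated null datasets.

    Both conditions share one 6-gene dependency structure, so the labels
    are exchangeable and the p-values should be uniform (fraction ~ 0.05).
    """
    hits = 0
    for i in range(n_datasets):
        s = seed + i
        spec = SyntheticSpec(
            n_genes=6, n_sens=n_per_group, n_res=n_per_group,
            edges_sens=NULL_EDGES, edges_res=NULL_EDGES, rho=0.8, seed=s,
        )
        sim, _ = simulate_null(spec)
        cfg = EddyConfig(n_resamples=n_resamples, n_permutations=n_permutations, seed=s)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), cfg)
        res = permutation_test(sim.data, _partition_for(sim), cand, cfg, cluster_id="null")
        hits += res.p_value <= 0.05
    return hits / n_datasets


def planted_edge_power(
    n_runs: int = 50,
    seed: int = 0,
    rho: float = 0.8,
    n_per_group: int = 60,
    n_resamples: int = 100,
    n_permutations: int = 199,
) -> float:
    """Fraction of runs recovering a single planted condition-specific edge.

    A 6-gene cluster carries one dependency present only in the sensitive
    condition; a run succeeds when the cell's permutation p-value is <= 0.05
    AND the planted pair is classified sensitive-specific in the DDN.
    """
    edges_s = frozenset({(0, 1)})
    hits = 0
    for i in range(n_runs):
        s = seed + i
        spec = SyntheticSpec(
            n_genes=6, n_sens=n_per_group, n_res=n_per_group,
            edges_sens=edges_s, edges_res=frozenset(), rho=rho, seed=s,
        )
        sim, _ = simulate_cluster_data(spec)
        cfg = EddyConfig(n_resamples=n_resamples, n_permutations=n_permutations, seed=s)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), cfg)
        res, ens_s, ens_r = permutation_test(
            sim.data, _partition_for(sim), cand, cfg, cluster_id="planted",
            return_ensembles=True,
        )
        ddn = build_ddn(ens_s, ens_r, cfg, "drug", "planted")
        classes = {
            frozenset((e.gene_a, e.gene_b)): e.condition_class for e in ddn.edges
        }
        ok = classes.get(frozenset(("G000", "G001"))) == "sensitive"
        hits += (res.p_value <= 0.05) and ok
    return hits / n_runs


def hub_spec() -> SyntheticSpec:
    """Hub-rewiring design: gene 0 carries all rewired edges.

    Sensitive-only star from the hub to genes 1..5, a backbone chain among
    the children in both conditions, and twelve disjoint dependent pairs
    (genes 6..29) shared by both conditions to stabilize the DDN-wide
    specific-edge background.
    """
    star = {(0, c) for c in range(1, 6)}
    backbone = {(i, i + 1) for i in range(1, 5)}
    filler = {(i, i + 1) for i in range(6, 30, 2)}
    return SyntheticSpec(
        n_genes=30, n_sens=60, n_res=60,
        edges_sens=frozenset(star | backbone | filler),
        edges_res=frozenset(backbone | filler),
        rho=0.8,
    )


def hub_mediator_recovery(
    n_runs: int = 50, seed: int = 0, n_resamples: int = 100
) -> float:
    """Fraction of runs flagging the planted hub as a specificity mediator."""
    base = hub_spec()
    hits = 0
    for i in range(n_runs):
        s = seed + i
        spec = SyntheticSpec(
            n_genes=base.n_genes, n_sens=base.n_sens, n_res=base.n_res,
            edges_sens=base.edges_sens, edges_res=base.edges_res,
            rho=base.rho, seed=s,
        )
        sim, truth = simulate_cluster_data(spec)
        assert truth.planted_mediators == frozenset({0})
        cfg = EddyConfig(n_resamples=n_resamples, seed=s)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), cfg)
        ens_s, ens_r = observed_ensembles(
            sim.data, _partition_for(sim), cand, cfg, cluster_id="hub"
        )
        ddn = build_ddn(ens_s, ens_r, cfg, "drug", "hub")
        hits += ddn.node("G000").specificity_mediator
    return hits / n_runs


# ---------------------------------------------------------------------------
# end-to-end landscape studies
# ---------------------------------------------------------------------------

#: analysis scale used for full-pipeline studies: enough permutation
#: resolution for grid-wide BH at alpha = 0.05 over a 3 x 2 grid
E2E_CONFIG = dict(n_resamples=50, n_permutations=499)


def _run_fixture(tmp: str, seed: int) -> pd.DataFrame:
    fixture = simulate_landscape_fixture(
        3, 2, [(1, 0)], Path(tmp) / "fixture", seed=seed
    )
    cfg = EddyConfig(seed=seed, **E2E_CONFIG)
    run_pipeline(
        fixture.expression_path, fixture.response_path,
        fixture.gmt_path, fixture.sif_path, Path(tmp) / "run", config=cfg,
    )
    df = pd.read_csv(Path(tmp) / "run" / "scores.tsv", sep="\t")
    return df[df.row_type == "cell"]


def planted_cell_unique_fraction(n_repeats: int = 20, seed: int = 0) -> float:
    """Fraction of seeded end-to-end runs where the planted cell is the grid's
    only significant cell (3 drugs x 2 clusters, one planted cell)."""
    hits = 0
    for i in range(n_repeats):
        with tempfile.TemporaryDirectory() as tmp:
            cells = _run_fixture(tmp, seed + i)
            sig = cells[cells.significant == True]  # noqa: E712
            planted = (sig.drug_id == "D01") & (sig.cluster_id == "C00")
            hits += bool(planted.any() and len(sig) == 1)
    return hits / n_repeats


def e2e_byte_identical(seed: int = 0) -> bool:
    """Whether two identical invocations produce byte-identical artifacts.

    All files are compared byte-for-byte except the manifest, which is
    compared with its wall-clock timing entry removed.
    """
    with tempfile.TemporaryDirectory() as tmp:
        fixture = simulate_landscape_fixture(3, 2, [(1, 0)], Path(tmp) / "fixture", seed=seed)
        cfg = EddyConfig(seed=seed, **E2E_CONFIG)
        for name in ("run_a", "run_b"):
            run_pipeline(
                fixture.expression_path, fixture.response_path,
                fixture.gmt_path, fixture.sif_path, Path(tmp) / name, config=cfg,
            )
        return runs_identical(Path(tmp) / "run_a", Path(tmp) / "run_b")


def runs_identical(dir_a: Path, dir_b: Path) -> bool:
    files_a = sorted(p.relative_to(dir_a) for p in Path(dir_a).rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(dir_b) for p in Path(dir_b).rglob("*") if p.is_file())
    if files_a != files_b:
        return False
    for rel in files_a:
        pa, pb = Path(dir_a) / rel, Path(dir_b) / rel
        if rel.name == "manifest.json":
            da, db = json.loads(pa.read_text()), json.loads(pb.read_text())
            da.pop("timing_seconds", None)
            db.pop("timing_seconds", None)
            if da != db:
                return False
        elif pa.read_bytes() != pb.read_bytes():
            return False
    return True
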