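"""The rewiring test.

Expression is discretized to per-gene equal-frequency tertiles.  For each
condition (drug-sensitive, drug-resistant) the dependency structure over a
prior-knowledge-assisted candidate pair space is learned on bootstrap
resamples: a pair enters a resampled structure when a G-test of independence
on its 3x3 contingency table rejects, at a laxer level for known (prior)
edges than for novel pairs.  The per-condition ensembles summarize each pair
by its inclusion frequency; rewiring between conditions is the sum over
pairs of the Jensen-Shannon divergence (in bits) between the two Bernoulli
inclusion profiles.  Significance comes from a label-permutation null with
group sizes preserved, and Benjamini-Hochberg control is applied across the
drug x cluster grid.

Everything here is a pure function of (inputs, config seed): bootstrap and
permutation seeds are derived deterministically from the config seed, the
drug id, the cluster id, the permutation index and the condition.
"""
from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.special import entr
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .cohort import ConditionPartition
from .errors import ContractError, ValidationError
from .io import ExpressionMatrix

N_LEVELS = 3
SENSITIVE = "sensitive"
RESISTANT = "resistant"

_LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EddyConfig:
    """All tunables of the rewiring analysis.

    alpha_known / alpha_novel are the per-pair G-test inclusion levels for
    prior-knowledge edges and novel pairs (prior-knowledge assistance =
    laxer threshold for known edges, so alpha_novel <= alpha_known).
    n_resamples (R) bootstrap draws build each condition ensemble;
    n_permutations (N) label permutations calibrate the rewiring statistic.
    presence_theta is the minimum inclusion frequency for an edge to appear
    in the DDN at all; specific_tau the frequency difference that makes it
    condition-specific.  bc_delta_cutoff, mediator_alpha drive the two
    mediator definitions; fdr_alpha the grid-wide significance level.
    """

    n_bins: int = 3
    alpha_known: float = 0.05
    alpha_novel: float = 0.01
    n_resamples: int = 100
    n_permutations: int = 999
    presence_theta: float = 0.5
    specific_tau: float = 0.3
    bc_delta_cutoff: float = 0.3
    mediator_alpha: float = 0.05
    fdr_alpha: float = 0.05
    seed: int = 7
    # cohort / grid-level knobs used by the pipeline
    lower_q: float = 1 / 3
    upper_q: float = 1 / 3
    min_group_size: int = 15
    max_cluster_genes: int = 60
    top_drugs: int = 15
    top_clusters: int = 5

    def __post_init__(self) -> None:
        if self.n_bins != N_LEVELS:
            raise ValidationError("n_bins is fixed at 3")
        if not (0 < self.alpha_novel <= self.alpha_known < 1):
            raise ValidationError("require 0 < alpha_novel <= alpha_known < 1")
        if self.n_resamples < 20:
            raise ValidationError("n_resamples must be >= 20")
        if self.n_permutations < 19:
            raise ValidationError("n_permutations must be >= 19")
        for name in ("presence_theta", "specific_tau", "mediator_alpha", "fdr_alpha",
                     "lower_q", "upper_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not (0.0 < self.bc_delta_cutoff <= 1.0):
            raise ValidationError("bc_delta_cutoff must lie in (0, 1]")
        if self.min_group_size < 2:
            raise ValidationError("min_group_size must be >= 2")
        self.seed = int(self.seed)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "EddyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "EddyConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_seed(self, seed: int) -> "EddyConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# seed derivation (stable across runs and platforms)
# ---------------------------------------------------------------------------

def _crc(token) -> int:
    return zlib.crc32(str(token).encode()) & 0x7FFFFFFF


def _seed_key(cfg_seed: int, *parts) -> list[int]:
    key = [int(cfg_seed) % (2 ** 31)]
    key.extend(p % (2 ** 31) if isinstance(p, (int, np.integer)) else _crc(p) for p in parts)
    return key


def derive_seeds(cfg_seed: int, *parts, n: int = 1) -> np.ndarray:
    """``n`` deterministic 31-bit seeds keyed by the config seed and context tokens."""
    ss = np.random.SeedSequence(_seed_key(cfg_seed, *parts))
    return ss.generate_state(n) % (2 ** 31)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedMatrix:
    """Per-gene tertile levels in {0, 1, 2} plus the bin thresholds used.

    Genes whose interquartile range is zero are degenerate: they carry
    all-middle levels and contribute no candidate pairs.  Missing entries
    also fall in the middle bin (they never dominate: rows with > 20%
    missing are dropped on read).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    levels: np.ndarray
    bin_edges: np.ndarray
    degenerate_genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int8)
        if self.levels.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("levels shape does not match identifiers")
        if self.levels.size and (self.levels.min() < 0 or self.levels.max() > 2):
            raise ValidationError("levels must lie in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def sample_positions(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"sample id(s) not in matrix: {missing[:3]}")
        return np.array(sorted(lookup[s] for s in sample_ids), dtype=np.intp)


def discretize(x: ExpressionMatrix) -> DiscretizedMatrix:
    """Equal-frequency tertiles per gene over non-missing values.

    Ranking is stable (ties broken by sample index); sample j of gene i gets
    level ``floor(3 * rank / n)``, so bin counts differ by at most one.
    """
    if x.n_samples < 6:
        raise ValidationError("discretization needs at least 6 samples")
    g, s = x.values.shape
    levels = np.ones((g, s), dtype=np.int8)
    bin_edges = np.full((g, 2), np.nan)
    degenerate: set = set()
    for i, gid in enumerate(x.gene_ids):
        obs = ~x.missing_mask[i]
        v = x.values[i, obs]
        if v.size == 0:
            degenerate.add(gid)
            continue
        q1, q3 = np.percentile(v, [25, 75])
        if q3 - q1 == 0:
            degenerate.add(gid)
            continue
        order = np.argsort(v, kind="stable")
        lv = np.empty(v.size, dtype=np.int8)
        lv[order] = (3 * np.arange(v.size)) // v.size
        levels[i, obs] = lv
        sv = v[order]
        n0 = int(np.searchsorted(lv[order], 1))
        n1 = int(np.searchsorted(lv[order], 2))
        bin_edges[i] = (sv[n0 - 1] if n0 > 0 else sv[0], sv[n1 - 1] if n1 > 0 else sv[-1])
    return DiscretizedMatrix(
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
        levels=levels,
        bin_edges=bin_edges,
        degenerate_genes=degenerate,
    )


# ---------------------------------------------------------------------------
# pairwise dependence: G-test of independence on 3x3 tables
# ---------------------------------------------------------------------------

def _g_from_tables(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized G statistic, df and p for contingency tables (..., 3, 3).

    All-zero rows/columns are removed from the df count; tables with fewer
    than two non-empty rows or columns are uninformative (G=0, df=0, p=1).
    """
    t = np.asarray(tables, dtype=float)
    n = t.sum(axis=(-1, -2))
    rows = t.sum(axis=-1)
    cols = t.sum(axis=-2)
    nzr = (rows > 0).sum(axis=-1)
    nzc = (cols > 0).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = rows[..., :, None] * cols[..., None, :] / np.where(n > 0, n, 1.0)[..., None, None]
        ratio = np.where(t > 0, t / np.where(e > 0, e, 1.0), 1.0)
        g = 2.0 * np.where(t > 0, t * np.log(ratio), 0.0).sum(axis=(-1, -2))
    informative = (nzr >= 2) & (nzc >= 2)
    df = np.where(informative, (nzr - 1) * (nzc - 1), 0)
    g = np.where(informative, g, 0.0)
    p = np.where(informative, chi2.sf(np.maximum(g, 0.0), np.maximum(df, 1)), 1.0)
    return g, df, p


def g_test_pair(levels_a: Sequence[int], levels_b: Sequence[int]) -> tuple[float, int, float]:
    """G-test of independence between two discretized genes.

    Returns ``(G, df, p)`` where G = 2 * sum O ln(O/E) over non-empty cells
    of the 3x3 table and p is the chi-square upper tail.  A pair whose table
    has fewer than two non-empty rows or columns is uninformative and is
    treated as independent: ``(0.0, 0, 1.0)``.
    """
    a = np.asarray(levels_a, dtype=np.int64)
    b = np.asarray(levels_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("level vectors must be 1-D and equal length")
    if a.size and (a.min() < 0 or a.max() > 2 or b.min() < 0 or b.max() > 2):
        raise ValidationError("levels must lie in {0, 1, 2}")
    table = np.bincount(3 * a + b, minlength=9).reshape(3, 3)
    g, df, p = _g_from_tables(table)
    return float(g), int(df), float(p)


# ---------------------------------------------------------------------------
# candidate pair space
# ---------------------------------------------------------------------------

@dataclass
class CandidatePairs:
    """Unordered gene pairs tested for a cluster, with known/novel flags.

    The space is all unordered pairs of usable cluster members (novel),
    with pairs listed among the prior-knowledge edges flagged known.
    Usable = present in the expression matrix and not degenerate.
    """

    gene_ids: list[str]
    rows: np.ndarray          # row index of each gene in the discretized matrix
    pairs: np.ndarray         # (P, 2) indices into gene_ids
    known: np.ndarray         # (P,) bool

    @classmethod
    def build(
        cls,
        d: DiscretizedMatrix,
        members: Sequence[str],
        prior_pairs: set | None = None,
        cfg: EddyConfig | None = None,
    ) -> "CandidatePairs":
        prior_pairs = prior_pairs or set()
        present = set(d.gene_ids)
        usable = [g for g in members if g in present and g not in d.degenerate_genes]
        if cfg is not None and len(usable) > cfg.max_cluster_genes:
            raise ValidationError(
                f"cluster has {len(usable)} usable genes, above the "
                f"{cfg.max_cluster_genes}-gene bound on the quadratic pair space"
            )
        rows = np.array([d.gene_row(g) for g in usable], dtype=np.intp)
        pair_list = list(itertools.combinations(range(len(usable)), 2))
        pairs = np.array(pair_list, dtype=np.intp).reshape(-1, 2)
        known = np.array(
            [frozenset((usable[i], usable[j])) in prior_pairs for i, j in pair_list],
            dtype=bool,
        )
        return cls(gene_ids=usable, rows=rows, pairs=pairs, known=known)

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    def alphas(self, cfg: EddyConfig) -> np.ndarray:
        return np.where(self.known, cfg.alpha_known, cfg.alpha_novel)

    def pair_ids(self) -> list[tuple[str, str]]:
        return [(self.gene_ids[i], self.gene_ids[j]) for i, j in self.pairs]

    def same_space(self, other: "CandidatePairs") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and np.array_equal(self.pairs, other.pairs)
            and np.array_equal(self.known, other.known)
        )


# ---------------------------------------------------------------------------
# resampled structure learning
# ---------------------------------------------------------------------------

def _pair_pvalues(levels_sub: np.ndarray, masks: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Independence-test p-values for every (resample, candidate pair).

    ``levels_sub`` is (m, s) for the group's samples; ``masks`` (R, s) marks
    which samples each resample retains.  All R x P contingency tables are
    formed in one batched matmul of one-hot indicators; returns p of shape
    (R, P).
    """
    R, s = masks.shape
    onehot = (levels_sub[..., None] == np.arange(N_LEVELS, dtype=levels_sub.dtype))
    a = onehot.transpose(0, 2, 1).reshape(-1, s).astype(np.float64)   # (3m, s)
    masked = a[None, :, :] * masks[:, None, :]                         # (R, 3m, s)
    full = masked @ a.T                                                # (R, 3m, 3m)
    r3 = np.arange(N_LEVELS)
    rows_idx = (N_LEVELS * pairs[:, 0][:, None] + r3)[:, :, None]
    cols_idx = (N_LEVELS * pairs[:, 1][:, None] + r3)[:, None, :]
    tables = full[:, rows_idx, cols_idx]                               # (R, P, 3, 3)
    return _g_from_tables(tables)[2]


def _resample_mask(n: int, rng: np.random.Generator) -> np.ndarray:
    """Support of one with-replacement draw of size ``n``.

    The draw itself is a size-preserving bootstrap, but each distinct drawn
    sample enters the dependence tests once: duplicated draws carry no new
    evidence, and counting them would inflate the G statistic (roughly
    doubling it) and wreck the nominal level of the per-pair test.  The
    retained support covers ~63% of the samples on average.
    """
    idx = rng.integers(0, n, size=n)
    mask = np.zeros(n, dtype=np.float64)
    mask[idx] = 1.0
    return mask


def _bootstrap_masks(n: int, seeds: np.ndarray) -> np.ndarray:
    """One resample support per seed, stacked (R, n)."""
    return np.stack([_resample_mask(n, np.random.default_rng(int(s))) for s in seeds])


def sample_structure(
    d: DiscretizedMatrix,
    sample_ids: Iterable[str],
    cand: CandidatePairs,
    cfg: EddyConfig,
    draw_seed: int,
) -> frozenset:
    """One resampled structure: bootstrap the samples, test every candidate pair.

    The seeded draw resamples the given samples with replacement (size
    preserved) and keeps each distinct drawn sample once for testing; a pair
    is included when its G-test p-value falls below alpha_known (prior
    edges) or alpha_novel (novel pairs).
    """
    cols = d.sample_positions(sample_ids)
    if cols.size < 2:
        raise ValidationError("need at least 2 samples to resample")
    if cand.n_pairs == 0:
        return frozenset()
    rng = np.random.default_rng(int(draw_seed))
    mask = _resample_mask(cols.size, rng)
    p = _pair_pvalues(d.levels[np.ix_(cand.rows, cols)], mask[None, :], cand.pairs)[0]
    include = p < cand.alphas(cfg)
    ids = cand.pair_ids()
    return frozenset(ids[k] for k in np.flatnonzero(include))


@dataclass
class ConditionNetworkEnsemble:
    """Per-condition edge inclusion frequencies from R resampled structures."""

    condition: str
    cand: CandidatePairs
    edge_freq: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.edge_freq = np.asarray(self.edge_freq, dtype=float)
        if self.edge_freq.shape != (self.cand.n_pairs,):
            raise ContractError("edge_freq length does not match candidate pairs")
        if self.edge_freq.size and (self.edge_freq.min() < 0 or self.edge_freq.max() > 1):
            raise ContractError("edge frequencies must lie in [0, 1]")

    def freq_of(self, gene_a: str, gene_b: str) -> float:
        target = frozenset((gene_a, gene_b))
        for k, (a, b) in enumerate(self.cand.pair_ids()):
            if frozenset((a, b)) == target:
                return float(self.edge_freq[k])
        raise KeyError((gene_a, gene_b))


def _ensemble_freq(
    levels_sub: np.ndarray,
    group_cols: np.ndarray,
    cand: CandidatePairs,
    cfg: EddyConfig,
    seeds: np.ndarray,
) -> np.ndarray:
    """Inclusion frequency per candidate pair over len(seeds) bootstrap draws."""
    if cand.n_pairs == 0:
        return np.zeros(0)
    masks = _bootstrap_masks(group_cols.size, seeds)
    p = _pair_pvalues(levels_sub[:, group_cols], masks, cand.pairs)
    return (p < cand.alphas(cfg)[None, :]).mean(axis=0)


def build_ensemble(
    d: DiscretizedMatrix,
    sample_ids: Iterable[str],
    condition: str,
    cand: CandidatePairs,
    cfg: EddyConfig,
    seeds: np.ndarray | None = None,
) -> ConditionNetworkEnsemble:
    """Run R seeded resamples of :func:`sample_structure`; edge_freq = inclusions / R."""
    cols = d.sample_positions(sample_ids)
    if cols.size < cfg.min_group_size:
        raise ValidationError(
            f"group of {cols.size} samples is below min_group_size={cfg.min_group_size}"
        )
    if seeds is None:
        seeds = derive_seeds(cfg.seed, condition, n=cfg.n_resamples)
    freq = _ensemble_freq(d.levels[cand.rows], cols, cand, cfg, seeds)
    return ConditionNetworkEnsemble(
        condition=condition, cand=cand, edge_freq=freq, n_samples=int(cols.size)
    )


# ---------------------------------------------------------------------------
# divergence statistic
# ---------------------------------------------------------------------------

def _binary_entropy_bits(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return (entr(p) + entr(1.0 - p)) / _LN2


def _jsd_bernoulli_bits(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    m = 0.5 * (np.asarray(p, float) + np.asarray(q, float))
    jsd = _binary_entropy_bits(m) - 0.5 * (_binary_entropy_bits(p) + _binary_entropy_bits(q))
    return np.maximum(jsd, 0.0)


def divergence_stat(
    ens_s: ConditionNetworkEnsemble, ens_r: ConditionNetworkEnsemble
) -> float:
    """Total rewiring between two ensembles, in bits.

    D = sum over candidate pairs of JSD(Bernoulli(p_sens), Bernoulli(p_res));
    symmetric, non-negative, at most one bit per pair, and zero iff the two
    inclusion-frequency profiles coincide.
    """
    if not ens_s.cand.same_space(ens_r.cand):
        raise ContractError("ensembles were built over different candidate pair spaces")
    return float(np.sum(_jsd_bernoulli_bits(ens_s.edge_freq, ens_r.edge_freq)))


# ---------------------------------------------------------------------------
# permutation significance and FDR
# ---------------------------------------------------------------------------

@dataclass
class RewiringResult:
    """Outcome of the rewiring test for one (drug, cluster) cell."""

    drug_id: str
    cluster_id: str
    statistic: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    significant: bool = False
    skipped_reason: str | None = None


def _group_seeds(cfg: EddyConfig, drug, cluster, k: int, cond_idx: int) -> np.ndarray:
    ss = np.random.SeedSequence(_seed_key(cfg.seed, drug, cluster, k, cond_idx))
    return ss.generate_state(cfg.n_resamples) % (2 ** 31)


def _perm_seed(cfg: EddyConfig, drug, cluster, k: int) -> int:
    return int(derive_seeds(cfg.seed, drug, cluster, k, "perm")[0])


def permutation_test(
    d: DiscretizedMatrix,
    partition: ConditionPartition,
    cand: CandidatePairs,
    cfg: EddyConfig,
    cluster_id: str,
    return_ensembles: bool = False,
):
    """Observed rewiring D plus a permutation p-value for one (drug, cluster).

    The sensitive/resistant labels are permuted over the union of the two
    groups with group sizes preserved; each permuted split rebuilds both
    bootstrap ensembles with seeds derived from (config seed, drug, cluster,
    permutation index, condition), so the whole test is reproducible.
    p = (1 + #{D_perm >= D_obs}) / (N + 1), ties counting against rejection.
    """
    drug = partition.compound_id
    result = RewiringResult(drug_id=drug, cluster_id=cluster_id)
    if partition.skip_reason is not None:
        result.skipped_reason = partition.skip_reason
        return (result, None, None) if return_ensembles else result

    cols_s = d.sample_positions(partition.sensitive_ids)
    cols_r = d.sample_positions(partition.resistant_ids)
    ns, nr = cols_s.size, cols_r.size
    if ns < cfg.min_group_size or nr < cfg.min_group_size:
        result.skipped_reason = "underpowered"
        return (result, None, None) if return_ensembles else result

    def make_ens(tag: str, freq: np.ndarray, n: int) -> ConditionNetworkEnsemble:
        return ConditionNetworkEnsemble(condition=tag, cand=cand, edge_freq=freq, n_samples=n)

    if cand.n_pairs == 0:
        result.statistic, result.p_value = 0.0, 1.0
        empty = np.zeros(0)
        if return_ensembles:
            return result, make_ens(SENSITIVE, empty, ns), make_ens(RESISTANT, empty, nr)
        return result

    union = np.concatenate([cols_s, cols_r])
    union.sort()
    pos = {c: i for i, c in enumerate(union)}
    obs_s = np.array([pos[c] for c in cols_s], dtype=np.intp)
    obs_r = np.array([pos[c] for c in cols_r], dtype=np.intp)
    levels_sub = d.levels[np.ix_(cand.rows, union)]

    n_perm = cfg.n_permutations
    d_stats = np.empty(n_perm + 1)
    obs_freqs: list[np.ndarray] = []
    for k in range(n_perm + 1):
        if k == 0:
            grp_s, grp_r = obs_s, obs_r
        else:
            rng = np.random.default_rng(_perm_seed(cfg, drug, cluster_id, k))
            perm = rng.permutation(union.size)
            grp_s, grp_r = perm[:ns], perm[ns:]
        freqs = []
        for cond_idx, grp in enumerate((grp_s, grp_r)):
            seeds = _group_seeds(cfg, drug, cluster_id, k, cond_idx)
            freqs.append(_ensemble_freq(levels_sub, grp, cand, cfg, seeds))
        d_stats[k] = float(np.sum(_jsd_bernoulli_bits(freqs[0], freqs[1])))
        if k == 0:
            obs_freqs = freqs
    result.statistic = float(d_stats[0])
    result.p_value = float((1 + np.sum(d_stats[1:] >= d_stats[0])) / (n_perm + 1))
    if return_ensembles:
        return (
            result,
            make_ens(SENSITIVE, obs_freqs[0], ns),
            make_ens(RESISTANT, obs_freqs[1], nr),
        )
    return result


def observed_ensembles(
    d: DiscretizedMatrix,
    partition: ConditionPartition,
    cand: CandidatePairs,
    cfg: EddyConfig,
    cluster_id: str,
) -> tuple[ConditionNetworkEnsemble, ConditionNetworkEnsemble]:
    """The two true-label ensembles, seeded exactly as in :func:`permutation_test`."""
    drug = partition.compound_id
    out = []
    for cond_idx, (tag, ids) in enumerate(
        ((SENSITIVE, partition.sensitive_ids), (RESISTANT, partition.resistant_ids))
    ):
        cols = d.sample_positions(ids)
        freq = _ensemble_freq(
            d.levels[cand.rows], cols, cand, cfg, _group_seeds(cfg, drug, cluster_id, 0, cond_idx)
        )
        out.append(
            ConditionNetworkEnsemble(
                condition=tag, cand=cand, edge_freq=freq, n_samples=int(cols.size)
            )
        )
    return out[0], out[1]


def fdr_adjust(results: list[RewiringResult], fdr_alpha: float) -> list[RewiringResult]:
    """Benjamini-Hochberg q-values across all non-skipped cells of the grid.

    Skipped cells produce no p-value and are excluded from the denominator.
    ``significant`` is set to ``q <= fdr_alpha``.
    """
    tested = [r for r in results if r.skipped_reason is None]
    if tested:
        pvals = np.array([r.p_value for r in tested], dtype=float)
        _, qvals, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
        for r, q in zip(tested, qvals):
            r.q_value = float(q)
            r.significant = bool(q <= fdr_alpha)
    return results
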