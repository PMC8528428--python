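import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ddnrewire as dr

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_cfg():
    """A fast config for unit tests (minimum legal resampling effort)."""
    return dr.EddyConfig(n_resamples=20, n_permutations=19, min_group_size=5, seed=7)


@pytest.fixture
def expression_3x6():
    values = np.arange(18, dtype=float).reshape(3, 6)
    return dr.ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=[f"s{i}" for i in range(6)],
        values=values,
        missing_mask=np.zeros((3, 6), dtype=bool),
    )


def make_ensembles(freq_s, freq_r, gene_ids=None, known=None):
    """Two ensembles over the same candidate space from explicit frequencies."""
    freq_s = np.asarray(freq_s, dtype=float)
    freq_r = np.asarray(freq_r, dtype=float)
    n_pairs = freq_s.size
    # smallest gene set whose pair count covers n_pairs
    m = 2
    while m * (m - 1) // 2 < n_pairs:
        m += 1
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(m)]
    import itertools

    pairs = np.array(list(itertools.combinations(range(len(gene_ids)), 2))[:n_pairs])
    cand = dr.CandidatePairs(
        gene_ids=list(gene_ids),
        rows=np.arange(len(gene_ids)),
        pairs=pairs.reshape(-1, 2),
        known=np.zeros(n_pairs, dtype=bool) if known is None else np.asarray(known, bool),
    )
    ens_s = dr.ConditionNetworkEnsemble("sensitive", cand, freq_s, 30)
    ens_r = dr.ConditionNetworkEnsemble("resistant", cand, freq_r, 30)
    return ens_s, ens_r


@pytest.fixture
def ensemble_factory():
    return make_ensembles
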