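import numpy as np
import pytest
from hypothesis import given, strategies as st

import ddnrewire as dr
from ddnrewire.cohort import ConditionPartition
from ddnrewire.core import (
    CandidatePairs,
    derive_seeds,
    discretize,
    g_test_pair,
)


def make_partition(sim):
    return ConditionPartition(
        "drug", frozenset(sim.sensitive_ids), frozenset(sim.resistant_ids),
        frozenset(), (1 / 3, 1 / 3),
    )


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(dr.ValidationError, match="unknown config key"):
            dr.EddyConfig.from_mapping({"alpha_knwon": 0.1})

    @pytest.mark.parametrize(
        "bad",
        [
            {"alpha_known": 0.01, "alpha_novel": 0.05},  # novel laxer than known
            {"n_resamples": 5},
            {"n_permutations": 5},
            {"presence_theta": 1.5},
        ],
    )
    def test_invariants_enforced(self, bad):
        with pytest.raises(dr.ValidationError):
            dr.EddyConfig(**bad)

    def test_yaml_round_trip(self, tmp_path):
        cfg = dr.EddyConfig(seed=13, n_resamples=33)
        import yaml

        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        assert dr.EddyConfig.from_file(p) == cfg


class TestDiscretize:
    def test_nine_values_split_into_tertiles(self):
        x = dr.ExpressionMatrix(
            ["g"], [f"s{i}" for i in range(9)],
            np.arange(1.0, 10.0).reshape(1, 9), np.zeros((1, 9), bool),
        )
        d = discretize(x)
        assert d.levels.tolist() == [[0, 0, 0, 1, 1, 1, 2, 2, 2]]

    def test_rank_order_not_magnitude(self):
        x = dr.ExpressionMatrix(
            ["g", "pad"], [f"s{i}" for i in range(6)],
            np.array([[5.0, 1.0, 9.0, 2.0, 8.0, 4.0], np.arange(6.0)]),
            np.zeros((2, 6), bool),
        )
        d = discretize(x)
        # sorted: 1,2,4,5,8,9 -> bins {1,2},{4,5},{8,9}
        assert d.levels[0].tolist() == [1, 0, 2, 0, 2, 1]

    def test_constant_gene_degenerate_all_middle(self):
        x = dr.ExpressionMatrix(
            ["flat", "ok"], [f"s{i}" for i in range(6)],
            np.array([[3.0] * 6, np.arange(6.0)]), np.zeros((2, 6), bool),
        )
        d = discretize(x)
        assert d.degenerate_genes == {"flat"}
        assert (d.levels[0] == 1).all()

    @given(st.integers(6, 60), st.integers(0, 2 ** 31 - 1))
    def test_bin_counts_balanced(self, n, seed):
        """Per gene, the three level counts never differ by more than one."""
        rng = np.random.default_rng(seed)
        x = dr.ExpressionMatrix(
            ["g"], [f"s{i}" for i in range(n)],
            rng.normal(size=(1, n)), np.zeros((1, n), bool),
        )
        counts = np.bincount(discretize(x).levels[0], minlength=3)
        assert counts.max() - counts.min() <= 1


class TestGTest:
    def test_exact_independence_gives_zero(self):
        # table = outer product of margins: every combination 4 times, n = 36
        a = np.repeat([0, 1, 2], 12)
        b = np.tile(np.repeat([0, 1, 2], 4), 3)
        g, df, p = g_test_pair(a, b)
        assert abs(g) < 1e-9
        assert df == 4
        assert p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        a = np.repeat([0, 1, 2], 10)
        g, df, p = g_test_pair(a, a)
        assert g == pytest.approx(60 * np.log(3), rel=1e-12)
        assert df == 4
        assert p < 1e-12

    def test_constant_vector_uninformative(self):
        g, df, p = g_test_pair([1] * 12, [0, 1, 2] * 4)
        assert (g, df, p) == (0.0, 0, 1.0)

    def test_matches_loglikelihood_contingency_oracle(self):
        from ddnrewire.validation import g_test_max_error

        assert g_test_max_error(n_tables=200, seed=1) < 1e-9


class TestStructureSampling:
    def planted(self, seed=0, rho=1.0):
        spec = dr.SyntheticSpec(
            n_genes=3, n_sens=60, n_res=60,
            edges_sens=frozenset({(0, 1)}), edges_res=frozenset({(0, 1)}),
            rho=rho, seed=seed,
        )
        sim, _ = dr.simulate_cluster_data(spec)
        return sim

    def test_deterministic_pair_always_included(self, small_cfg):
        sim = self.planted()
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), small_cfg)
        for seed in (1, 2, 99):
            edges = dr.sample_structure(sim.data, sim.sensitive_ids, cand, small_cfg, seed)
            assert ("G000", "G001") in edges

    def test_same_seed_same_structure(self, small_cfg):
        sim = self.planted(rho=0.5)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), small_cfg)
        e1 = dr.sample_structure(sim.data, sim.sensitive_ids, cand, small_cfg, 5)
        e2 = dr.sample_structure(sim.data, sim.sensitive_ids, cand, small_cfg, 5)
        assert e1 == e2

    def test_empty_candidate_set_empty_structure(self, small_cfg):
        sim = self.planted()
        cand = CandidatePairs.build(sim.data, [], set(), small_cfg)
        assert dr.sample_structure(sim.data, sim.sensitive_ids, cand, small_cfg, 1) == frozenset()

    def test_ensemble_equals_repeated_single_draws(self, small_cfg):
        """build_ensemble's batched engine reproduces R independent draws."""
        sim = self.planted(rho=0.6)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), small_cfg)
        ens = dr.build_ensemble(sim.data, sim.sensitive_ids, "cond", cand, small_cfg)
        seeds = derive_seeds(small_cfg.seed, "cond", n=small_cfg.n_resamples)
        ids = [tuple(p) for p in cand.pair_ids()]
        counts = np.zeros(len(ids))
        for s in seeds:
            edges = dr.sample_structure(sim.data, sim.sensitive_ids, cand, small_cfg, int(s))
            for k, pair in enumerate(ids):
                counts[k] += pair in edges
        np.testing.assert_allclose(ens.edge_freq, counts / small_cfg.n_resamples)

    def test_planted_deterministic_pair_freq_one(self, small_cfg):
        sim = self.planted(rho=1.0)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), small_cfg)
        ens = dr.build_ensemble(sim.data, sim.sensitive_ids, "sensitive", cand, small_cfg)
        assert ens.freq_of("G000", "G001") == 1.0

    def test_independent_pair_freq_near_alpha(self):
        """Null-pair inclusion frequency behaves like Binomial(R, ~alpha_novel)/R."""
        cfg = dr.EddyConfig(min_group_size=5)
        low = 0
        reps = 30
        for rep in range(reps):
            spec = dr.SyntheticSpec(n_genes=2, n_sens=60, n_res=6, seed=rep)
            sim, _ = dr.simulate_cluster_data(spec)
            cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), cfg)
            ens = dr.build_ensemble(
                sim.data, sim.sensitive_ids, "c", cand, cfg.with_seed(rep)
            )
            low += ens.edge_freq[0] <= 0.05
        assert low >= 27  # ~binomial(100, 0.01) tail: freq > 0.05 is rare

    def test_oversized_cluster_rejected(self, small_cfg):
        spec = dr.SyntheticSpec(n_genes=65, n_sens=30, n_res=6, seed=0)
        sim, _ = dr.simulate_cluster_data(spec)
        with pytest.raises(dr.ValidationError, match="bound"):
            CandidatePairs.build(sim.data, sim.data.gene_ids, set(), small_cfg)


class TestDivergence:
    def test_identical_profiles_zero(self, ensemble_factory):
        s, r = ensemble_factory([0.3, 0.8, 0.5], [0.3, 0.8, 0.5])
        assert dr.divergence_stat(s, r) == 0.0

    def test_opposite_deterministic_one_bit(self, ensemble_factory):
        s, r = ensemble_factory([1.0], [0.0])
        assert dr.divergence_stat(s, r) == pytest.approx(1.0)

    def test_half_vs_one_binary_entropy_oracle(self, ensemble_factory):
        s, r = ensemble_factory([1.0], [0.5])
        # H(0.75) - 0.5 computed from the binary-entropy definition
        h75 = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert dr.divergence_stat(s, r) == pytest.approx(h75 - 0.5)
        assert dr.divergence_stat(s, r) == pytest.approx(0.311278, abs=1e-6)

    def test_mismatched_pair_spaces_rejected(self, ensemble_factory):
        s, _ = ensemble_factory([0.5], [0.5])
        _, r = ensemble_factory([0.5, 0.1], [0.5, 0.1])
        with pytest.raises(dr.ContractError):
            dr.divergence_stat(s, r)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=8),
        st.lists(st.floats(0, 1), min_size=1, max_size=8),
    )
    def test_symmetric_nonnegative_bounded(self, p, q):
        from conftest import make_ensembles

        n = min(len(p), len(q))
        p, q = p[:n], q[:n]
        s, r = make_ensembles(p, q)
        d = dr.divergence_stat(s, r)
        assert 0.0 <= d <= n
        s2, r2 = make_ensembles(q, p)
        assert dr.divergence_stat(s2, r2) == pytest.approx(d, abs=1e-12)


class TestPermutationTest:
    def test_zero_divergence_gives_p_one(self, small_cfg):
        """No candidate pairs -> D = 0 observed and in every permutation."""
        spec = dr.SyntheticSpec(n_genes=2, n_sens=10, n_res=10, seed=0)
        sim, _ = dr.simulate_cluster_data(spec)
        cand = CandidatePairs.build(sim.data, [], set(), small_cfg)
        res = dr.permutation_test(sim.data, make_partition(sim), cand, small_cfg, "c")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_underpowered_partition_skipped(self, small_cfg):
        spec = dr.SyntheticSpec(n_genes=3, n_sens=3, n_res=10, seed=0)
        sim, _ = dr.simulate_cluster_data(spec)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), small_cfg)
        res = dr.permutation_test(sim.data, make_partition(sim), cand, small_cfg, "c")
        assert res.skipped_reason == "underpowered"
        assert res.p_value is None

    def test_same_seed_identical_result(self, small_cfg):
        spec = dr.SyntheticSpec(
            n_genes=4, n_sens=20, n_res=20,
            edges_sens=frozenset({(0, 1)}), edges_res=frozenset(), rho=0.9, seed=3,
        )
        sim, _ = dr.simulate_cluster_data(spec)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), small_cfg)
        r1 = dr.permutation_test(sim.data, make_partition(sim), cand, small_cfg, "c")
        r2 = dr.permutation_test(sim.data, make_partition(sim), cand, small_cfg, "c")
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_strong_rewiring_detected(self):
        cfg = dr.EddyConfig(n_resamples=30, n_permutations=99, min_group_size=15, seed=1)
        spec = dr.SyntheticSpec(
            n_genes=4, n_sens=60, n_res=60,
            edges_sens=frozenset({(0, 1)}), edges_res=frozenset(), rho=0.95, seed=1,
        )
        sim, _ = dr.simulate_cluster_data(spec)
        cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), cfg)
        res = dr.permutation_test(sim.data, make_partition(sim), cand, cfg, "c")
        assert res.p_value <= 0.05


def test_expected_divergence_monotone_in_dependence_strength():
    """Mean D over replicates never decreases along a planted-strength grid.

    One sensitive-only edge at rho in {0.3, 0.6, 0.9}; 50 replicates per
    point; stronger planted dependence must not lower the expected
    rewiring statistic.
    """
    cfg = dr.EddyConfig(n_resamples=30, min_group_size=15, seed=0)
    means = []
    for rho in (0.3, 0.6, 0.9):
        ds = []
        for rep in range(50):
            spec = dr.SyntheticSpec(
                n_genes=4, n_sens=60, n_res=60,
                edges_sens=frozenset({(0, 1)}), edges_res=frozenset(),
                rho=rho, seed=1000 + rep,
            )
            sim, _ = dr.simulate_cluster_data(spec)
            cand = CandidatePairs.build(sim.data, sim.data.gene_ids, set(), cfg)
            ens_s = dr.build_ensemble(
                sim.data, sim.sensitive_ids, "sensitive", cand, cfg.with_seed(rep)
            )
            ens_r = dr.build_ensemble(
                sim.data, sim.resistant_ids, "resistant", cand, cfg.with_seed(rep)
            )
            ds.append(dr.divergence_stat(ens_s, ens_r))
        means.append(np.mean(ds))
    assert means[0] <= means[1] <= means[2]


class TestFdr:
    def test_step_up_oracle(self):
        results = [
            dr.RewiringResult("d", str(i), statistic=0.1, p_value=p)
            for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
        ]
        dr.fdr_adjust(results, 0.05)
        assert [r.q_value for r in results] == pytest.approx([0.04] * 4)
        assert all(r.significant for r in results)

    def test_single_test_q_equals_p(self):
        r = dr.RewiringResult("d", "c", statistic=0.1, p_value=0.2)
        dr.fdr_adjust([r], 0.05)
        assert r.q_value == pytest.approx(0.2)
        assert not r.significant

    def test_p_one_maps_to_q_one(self):
        results = [
            dr.RewiringResult("d", "a", statistic=0.0, p_value=1.0),
            dr.RewiringResult("d", "b", statistic=0.1, p_value=0.3),
        ]
        dr.fdr_adjust(results, 0.05)
        assert results[0].q_value == pytest.approx(1.0)

    def test_skipped_cells_excluded_from_denominator(self):
        results = [
            dr.RewiringResult("d", "a", statistic=0.1, p_value=0.05),
            dr.RewiringResult("d", "b", skipped_reason="underpowered"),
        ]
        dr.fdr_adjust(results, 0.05)
        assert results[0].q_value == pytest.approx(0.05)  # m = 1, not 2
        assert results[1].q_value is None
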