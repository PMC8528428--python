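import numpy as np
import pytest

import ddnrewire as dr
from ddnrewire.io import read_scores
from ddnrewire.landscape import landscape_from_scores


def cell(drug, cluster, significant=False, mediators=0, p=0.5):
    res = dr.RewiringResult(
        drug_id=drug, cluster_id=cluster, statistic=0.1, p_value=p,
        q_value=p if significant else 0.9, significant=significant,
    )
    return dr.LandscapeCell(drug, cluster, res, mediator_count=mediators)


def grid(sig_map, drugs, clusters):
    """sig_map: (drug, cluster) -> mediator count for significant cells."""
    cells = []
    for d in drugs:
        for c in clusters:
            if (d, c) in sig_map:
                cells.append(cell(d, c, significant=True, mediators=sig_map[(d, c)], p=0.001))
            else:
                cells.append(cell(d, c))
    return dr.build_landscape(cells, drugs=drugs, clusters=clusters)


class TestBuildLandscape:
    def test_drug_score_sums_mediators_over_significant_cells(self):
        m = grid({("d1", "c1"): 3, ("d1", "c2"): 2}, ["d1", "d2"], ["c1", "c2", "c3"])
        assert m.drug_score["d1"] == 5
        assert m.drug_freq["d1"] == 2
        assert m.drug_score["d2"] == 0 and m.drug_freq["d2"] == 0

    def test_empty_landscape_all_zero(self):
        m = grid({}, ["d1", "d2"], ["c1"])
        assert all(v == 0 for v in m.drug_score.values())
        assert all(v == 0 for v in m.cluster_freq.values())

    def test_cluster_convergence_count(self):
        """One cluster significant for 8 of 20 drugs -> cluster_freq = 8."""
        drugs = [f"d{i:02d}" for i in range(20)]
        sig = {(d, "c1"): 1 for d in drugs[:8]}
        m = grid(sig, drugs, ["c1", "c2"])
        assert m.cluster_freq["c1"] == 8

    def test_missing_cell_rejected(self):
        with pytest.raises(dr.ValidationError, match="missing"):
            dr.build_landscape([cell("d1", "c1")], drugs=["d1", "d2"], clusters=["c1"])

    def test_nonsignificant_cell_cannot_carry_mediators(self):
        with pytest.raises(dr.ValidationError):
            dr.LandscapeCell("d", "c", dr.RewiringResult("d", "c", p_value=0.9), mediator_count=2)


class TestSortAndHotspot:
    def test_ties_broken_lexicographically(self):
        m = grid({("A", "c1"): 5, ("B", "c1"): 5, ("C", "c1"): 2}, ["C", "B", "A"], ["c1"])
        drugs, _ = dr.sort_landscape(m)
        assert drugs == ["A", "B", "C"]

    def test_all_zero_scores_pure_lexicographic(self):
        m = grid({}, ["z", "a", "m"], ["c2", "c1"])
        drugs, clusters = dr.sort_landscape(m)
        assert drugs == ["a", "m", "z"]
        assert clusters == ["c1", "c2"]

    def test_default_hotspot_is_15_by_5(self):
        drugs = [f"d{i:02d}" for i in range(20)]
        clusters = [f"c{i:02d}" for i in range(10)]
        sig = {(d, c): 1 for d in drugs[:4] for c in clusters[:3]}
        m = grid(sig, drugs, clusters)
        sel = dr.select_hotspot(m)
        assert len(sel.drugs) == 15 and len(sel.clusters) == 5

    def test_zero_k_empty_selection(self):
        m = grid({}, ["d1", "d2"], ["c1"])
        sel = dr.select_hotspot(m, top_drugs=0, top_clusters=0)
        assert sel.drugs == [] and sel.clusters == []

    def test_hotspot_convergence_fraction(self):
        """A cluster hit by 7 of the 15 selected drugs reports 7/15."""
        drugs = [f"d{i:02d}" for i in range(20)]
        clusters = [f"c{i}" for i in range(6)]
        sig = {(d, "c0"): 2 for d in drugs[:7]}
        sig.update({(d, "c1"): 1 for d in drugs[:3]})
        m = grid(sig, drugs, clusters)
        sel = dr.select_hotspot(m)
        assert sel.cluster_drug_fraction["c0"] == (7, 15)

    def test_oversized_k_truncates_with_warning(self):
        m = grid({}, ["d1", "d2"], ["c1"])
        with pytest.warns(UserWarning, match="truncating"):
            sel = dr.select_hotspot(m, top_drugs=10, top_clusters=10)
        assert len(sel.drugs) == 2 and len(sel.clusters) == 1

    def test_hotspot_after_sort_idempotent(self):
        drugs = [f"d{i:02d}" for i in range(20)]
        clusters = [f"c{i}" for i in range(8)]
        sig = {(drugs[i], clusters[i % 8]): i % 3 + 1 for i in range(12)}
        m = grid(sig, drugs, clusters)
        s1 = dr.select_hotspot(m)
        s2 = dr.select_hotspot(m, top_drugs=len(s1.drugs), top_clusters=len(s1.clusters))
        assert (s1.drugs, s1.clusters) == (s2.drugs, s2.clusters)


class TestSharedClassClusters:
    def test_intersection_of_member_sets(self):
        sets = {
            "bet1": {"3", "15", "27", "35", "40"},
            "bet2": {"3", "15", "27", "35"},
            "bet3": {"2", "3", "15", "27", "35"},
        }
        assert dr.shared_class_clusters(sets, ["bet1", "bet2", "bet3"]) == {"3", "15", "27", "35"}

    def test_disjoint_sets_empty(self):
        assert dr.shared_class_clusters({"a": {"1"}, "b": {"2"}}, ["a", "b"]) == set()

    def test_identical_sets_returned(self):
        s = {"5", "9"}
        assert dr.shared_class_clusters({"a": set(s), "b": set(s)}, ["a", "b"]) == s

    def test_single_member_class_rejected(self):
        with pytest.raises(dr.ContractError):
            dr.shared_class_clusters({"a": {"1"}}, ["a"])

    def test_adding_member_never_grows_shared_set(self):
        rng = np.random.default_rng(3)
        universe = [str(i) for i in range(12)]
        sets = {
            f"m{i}": set(rng.choice(universe, size=rng.integers(2, 10), replace=False))
            for i in range(5)
        }
        members = list(sets)
        prev = None
        for k in range(2, 6):
            shared = dr.shared_class_clusters(sets, members[:k])
            for i in range(k):
                assert shared <= sets[members[i]]
            if prev is not None:
                assert shared <= prev
            prev = shared


class TestCombineClassDDN:
    def test_identical_profiles_identical_ddn(self, ensemble_factory):
        cfg = dr.EddyConfig()
        pair = ensemble_factory([1.0, 0.2], [0.0, 0.2])
        combined = dr.combine_class_ddn([pair, pair], cfg, "class", "c")
        single = dr.build_ddn(pair[0], pair[1], cfg, "class", "c")
        assert combined.to_dict()["edges"] == single.to_dict()["edges"]

    def test_pooled_frequency_is_mean(self, ensemble_factory):
        cfg = dr.EddyConfig()
        a = ensemble_factory([1.0], [0.4])
        b = ensemble_factory([0.0], [0.4])
        combined = dr.combine_class_ddn([a, b], cfg, "class", "c")
        # pooled p_sens = 0.5, p_res = 0.4 -> present, class both
        assert combined.edges[0].p_sens == pytest.approx(0.5)
        assert combined.edges[0].condition_class == "both"

    def test_pooling_order_invariant(self, ensemble_factory):
        cfg = dr.EddyConfig()
        members = [
            ensemble_factory([1.0, 0.3], [0.1, 0.3]),
            ensemble_factory([0.6, 0.9], [0.2, 0.8]),
            ensemble_factory([0.8, 0.1], [0.0, 0.2]),
        ]
        fwd = dr.combine_class_ddn(members, cfg, "k", "c")
        rev = dr.combine_class_ddn(members[::-1], cfg, "k", "c")
        fwd_e = {(e.gene_a, e.gene_b): e for e in fwd.edges}
        rev_e = {(e.gene_a, e.gene_b): e for e in rev.edges}
        assert fwd_e.keys() == rev_e.keys()
        for k, e in fwd_e.items():
            assert rev_e[k].condition_class == e.condition_class
            assert rev_e[k].p_sens == pytest.approx(e.p_sens)
            assert rev_e[k].p_res == pytest.approx(e.p_res)


class TestExportRoundTrip:
    def test_scores_round_trip_exact(self, tmp_path):
        drugs = ["d1", "d2", "d3"]
        clusters = ["c1", "c2"]
        m = grid({("d1", "c1"): 3, ("d2", "c2"): 1}, drugs, clusters)
        p = dr.write_scores(m, tmp_path / "scores.tsv")
        m2 = landscape_from_scores(read_scores(p))
        assert m2.drug_score == m.drug_score
        assert m2.cluster_score == m.cluster_score
        assert m2.drug_freq == m.drug_freq
        assert m2.cluster_freq == m.cluster_freq

    def test_export_deterministic_bytes(self, tmp_path):
        m = grid({("d1", "c1"): 2}, ["d1", "d2"], ["c1", "c2"])
        p1 = dr.export_landscape(m, tmp_path / "a")
        p2 = dr.export_landscape(m, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_landscape_header_only(self, tmp_path):
        m = dr.build_landscape([], drugs=[], clusters=[])
        paths = dr.export_landscape(m, tmp_path / "empty")
        heat = paths["heatmap"].read_text().strip().splitlines()
        assert len(heat) == 1  # header only
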