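import networkx as nx
import numpy as np
import pytest

from pathcover import (
    Params,
    SyntheticScenario,
    connected_components,
    coverage,
    find_common_subpathways,
    grow_common_subpathway,
    marginal_gain,
    simulate_common_scenario,
)

from conftest import brute_force_best_coverage, make_pathway, make_profile


class TestConnectedComponents:
    def test_bridge_plus_isolate(self):
        pw = make_pathway("P1", ["a", "b", "c", "d"], [("a", "b"), ("b", "c")])
        assert connected_components(pw) == [frozenset("abc"), frozenset("d")]

    def test_edgeless_pathway_gives_singletons(self):
        pw = make_pathway("P1", list("abcde"), [])
        comps = connected_components(pw)
        assert len(comps) == 5 and all(len(c) == 1 for c in comps)

    def test_random_graph_matches_union_find_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:02d}" for i in range(30)]
        edges = [
            (genes[i], genes[j])
            for i in range(30)
            for j in range(i + 1, 30)
            if rng.random() < 0.05
        ]
        pw = make_pathway("P1", genes, edges)

        # independent union-find oracle
        parent = {g: g for g in genes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        oracle = {}
        for g in genes:
            oracle.setdefault(find(g), set()).add(g)
        assert set(connected_components(pw)) == {frozenset(c) for c in oracle.values()}


class TestCoverageAndGain:
    def test_empty_set_covers_nothing(self, toy_profile):
        assert coverage(toy_profile, set()) == 0.0

    def test_enumerated_fraction(self):
        prof = make_profile({"g1": ["s1", "s2"]}, [f"s{i}" for i in range(1, 6)])
        assert coverage(prof, {"g1"}) == pytest.approx(0.4)

    def test_monotone_under_addition(self, toy_profile):
        assert coverage(toy_profile, {"g1", "g2"}) >= coverage(toy_profile, {"g1"})

    def test_redundant_candidate_gains_zero(self):
        prof = make_profile({"g1": ["s1"], "g2": ["s1"]}, ["s1", "s2"])
        assert marginal_gain(prof, {"g1"}, "g2") == 0.0

    def test_enumerated_gain(self):
        prof = make_profile({"g1": ["s1"], "g2": ["s2", "s3"]}, ["s1", "s2", "s3", "s4"])
        assert marginal_gain(prof, {"g1"}, "g2") == pytest.approx(0.5)

    def test_unmutated_candidate_gains_zero(self, toy_profile):
        assert marginal_gain(toy_profile, {"g1"}, "g9") == 0.0

    def test_candidate_already_in_set_is_error(self, toy_profile):
        with pytest.raises(ValueError):
            marginal_gain(toy_profile, {"g1"}, "g1")


class TestGrowCommon:
    def test_threshold_gates_single_gene_component(self):
        prof = make_profile({"g1": ["s1", "s2"]}, ["s1", "s2"])
        pw = make_pathway("P1", ["g1"], [])
        sp, _ = grow_common_subpathway(
            frozenset({"g1"}), pw, prof, Params(min_genes=1, coverage_threshold=0.9)
        )
        assert sp is not None and sp.coverage == 1.0
        sp5, _ = grow_common_subpathway(frozenset({"g1"}), pw, prof, Params())  # min_genes=5
        assert sp5 is None

    def test_hand_trace_path_graph(self, path_pathway):
        # N=5; g1 covers {1,2}, g2 {3}, g3 {4,5}; seed tie f=0.4 -> g1
        prof = make_profile(
            {"g1": ["s1", "s2"], "g2": ["s3"], "g3": ["s4", "s5"]},
            [f"s{i}" for i in range(1, 6)],
        )
        sp, trace = grow_common_subpathway(
            frozenset({"g1", "g2", "g3"}), path_pathway, prof,
            Params(coverage_threshold=0.9, min_genes=3),
        )
        assert sp is not None
        assert sp.genes == ("g1", "g2", "g3")
        assert sp.coverage == 1.0
        kinds = {t.gene: t.kind for t in trace}
        assert kinds == {"g1": "seed", "g2": "GI", "g3": "GI"}

    def test_gn_rescue_retains_bridge_gene(self):
        # star: g1-g2, g2-g3; g2 adds no coverage but bridges to g3
        prof = make_profile(
            {"g1": [f"s{i}" for i in range(1, 9)], "g2": ["s1", "s2"], "g3": ["s9", "s10"]},
            [f"s{i}" for i in range(1, 11)],
        )
        pw = make_pathway("P1", ["g1", "g2", "g3"], [("g1", "g2"), ("g2", "g3")])
        sp, trace = grow_common_subpathway(
            frozenset({"g1", "g2", "g3"}), pw, prof, Params(coverage_threshold=0.9, min_genes=3)
        )
        assert sp is not None
        assert set(sp.genes) == {"g1", "g2", "g3"}
        assert sp.coverage == 1.0
        kinds = {t.gene: t.kind for t in trace}
        assert kinds["g2"] == "GN-retained"

    def test_gn_without_gaining_neighbor_is_excluded(self):
        prof = make_profile(
            {"g1": [f"s{i}" for i in range(1, 10)], "g2": ["s1"], "g3": ["s2"]},
            [f"s{i}" for i in range(1, 11)],
        )
        pw = make_pathway("P1", ["g1", "g2", "g3"], [("g1", "g2"), ("g2", "g3")])
        sp, trace = grow_common_subpathway(
            frozenset({"g1", "g2", "g3"}), pw, prof, Params(coverage_threshold=0.5, min_genes=1)
        )
        assert sp is not None and set(sp.genes) == {"g1"}
        kinds = {t.gene: t.kind for t in trace}
        assert kinds["g2"] == "GN-rejected"

    def test_trace_gains_sum_to_final_coverage(self, path_pathway):
        prof = make_profile(
            {"g1": ["s1", "s2"], "g2": ["s3"], "g3": ["s4", "s5"]},
            [f"s{i}" for i in range(1, 6)],
        )
        sp, trace = grow_common_subpathway(
            frozenset({"g1", "g2", "g3"}), path_pathway, prof,
            Params(coverage_threshold=0.9, min_genes=3),
        )
        retained = set(sp.genes)
        assert sum(t.gain for t in trace if t.gene in retained) == pytest.approx(sp.coverage)


class TestFindCommonSubpathways:
    def test_below_threshold_emits_nothing(self):
        prof = make_profile({"g1": ["s1"]}, [f"s{i}" for i in range(1, 11)])
        pw = make_pathway("P1", ["g1", "g2"], [("g1", "g2")])
        assert find_common_subpathways(prof, [pw], Params(min_genes=1)) == []

    def test_planted_signal_recovered_with_connectivity(self):
        data = simulate_common_scenario(SyntheticScenario(rng_seed=11))
        subs = find_common_subpathways(data.profile, data.pathways)
        assert len(subs) >= 1
        hit = [s for s in subs if set(data.planted) <= set(s.genes)]
        assert hit, "planted module not recovered"
        sp = hit[0]
        assert sp.coverage >= 0.90
        # connectivity audit on the emitted gene set
        pw = next(p for p in data.pathways if p.pathway_id == sp.pathway_id)
        assert nx.is_connected(pw.to_graph().subgraph(sp.genes))
        # coverage audit: reported value equals from-scratch recomputation
        assert sp.coverage == pytest.approx(coverage(data.profile, sp.genes))

    def test_two_pathways_sharing_genes_report_separately(self, toy_profile):
        prof = make_profile({"g1": ["s1", "s2", "s3"]}, ["s1", "s2", "s3"])
        pws = [make_pathway(pid, ["g1"], []) for pid in ("P1", "P2")]
        subs = find_common_subpathways(prof, pws, Params(min_genes=1))
        assert {s.pathway_id for s in subs} == {"P1", "P2"}

    def test_greedy_never_beats_small_instance_oracle(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(12)]
        genes = [f"g{i}" for i in range(8)]
        for trial in range(10):
            cover = {g: [s for s in samples if rng.random() < 0.2] for g in genes}
            prof = make_profile(cover, samples)
            edges = [
                (genes[i], genes[j])
                for i in range(8)
                for j in range(i + 1, 8)
                if rng.random() < 0.3
            ]
            pw = make_pathway("P1", genes, edges)
            params = Params(coverage_threshold=0.6, min_genes=1)
            for comp in connected_components(pw):
                sp, _ = grow_common_subpathway(comp, pw, prof, params)
                best = brute_force_best_coverage(prof, comp, edges)
                if sp is not None:
                    assert sp.coverage <= best + 1e-12
                if best < params.coverage_threshold:
                    assert sp is None
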