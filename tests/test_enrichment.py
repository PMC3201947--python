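import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathgwas.errors import ValidationError
from pathgwas.enrichment import (
    EnrichmentResult,
    build_annotation_network,
    compare_term_sets,
    drug_target_overlap,
    enrich_module,
    group_terms,
    hypergeom_two_sided,
    kappa,
    pairwise_kappa,
)
from pathgwas.io_formats import GeneSet, GeneSetCollection

from _oracles import hypergeom_two_sided_bruteforce


def make_result(term_id, genes, p_corr, k_found=None, p_raw=None):
    genes = tuple(sorted(genes))
    return EnrichmentResult(
        term_id=term_id,
        term_name=term_id,
        k_found=k_found if k_found is not None else len(genes),
        K=max(len(genes), 1),
        n=10,
        N=100,
        p_raw=p_raw if p_raw is not None else p_corr,
        p_corr=p_corr,
        genes_found=genes,
    )


class TestHypergeomTwoSided:
    def test_worked_example(self):
        # one-sided enrichment tail C(5,4)C(5,0)/C(10,4) = 5/210, doubled
        p = hypergeom_two_sided(4, 4, 5, 10)
        assert p == pytest.approx(2 * 5 / 210, rel=1e-12)

    def test_mode_capped_at_one(self):
        # k at the distribution mode: both tails > 0.5, doubling caps at 1
        assert hypergeom_two_sided(2, 4, 5, 10) == 1.0

    def test_term_equals_universe(self):
        assert hypergeom_two_sided(4, 4, 10, 10) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_two_sided(5, 4, 5, 10)
        with pytest.raises(ValidationError):
            hypergeom_two_sided(0, 6, 5, 10)  # k below max(0, n+K-N)

    def test_matches_enumeration_small(self):
        for N in (5, 8, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert hypergeom_two_sided(k, n, K, N) == pytest.approx(
                            hypergeom_two_sided_bruteforce(k, n, K, N), rel=1e-9
                        ), (k, n, K, N)


class TestEnrichModule:
    def _collection(self):
        terms = [GeneSet("T00", "planted", frozenset(f"P{i}" for i in range(8)))]
        for t in range(1, 11):
            terms.append(
                GeneSet(
                    f"T{t:02d}",
                    f"rand{t}",
                    frozenset(f"X{t}_{i}" for i in range(9)),
                )
            )
        # pad universe to ~100 genes with an extra catch-all term
        terms.append(GeneSet("T99", "pad", frozenset(f"Z{i}" for i in range(10))))
        return GeneSetCollection(terms=tuple(terms))

    def test_full_term_ranks_first(self):
        coll = self._collection()
        results = enrich_module([f"P{i}" for i in range(8)], coll, min_genes=3)
        assert results[0].term_id == "T00"
        assert results[0].k_found == 8
        assert results[0].percent == 100.0

    def test_min_genes_zero_depletion_boundary(self):
        coll = self._collection()
        results = enrich_module([f"P{i}" for i in range(8)], coll, min_genes=0)
        depleted = [r for r in results if r.k_found == 0]
        assert depleted
        for r in depleted:
            expected = hypergeom_two_sided_bruteforce(0, r.n, r.K, r.N)
            assert r.p_raw == pytest.approx(expected, rel=1e-9)

    def test_disjoint_module_empty_result(self):
        coll = self._collection()
        assert enrich_module(["NOT_THERE"], coll) == []

    def test_bonferroni_properties(self):
        coll = self._collection()
        results = enrich_module([f"P{i}" for i in range(8)], coll, min_genes=0)
        m = len(results)
        for r in results:
            assert r.p_corr == pytest.approx(min(1.0, r.p_raw * m), rel=1e-12)
            assert r.p_corr >= r.p_raw

    def test_monotone_in_added_term_gene(self):
        # adding a module gene inside term T never increases T's p
        coll = self._collection()
        module = [f"P{i}" for i in range(5)] + ["Z0", "Z1"]
        base = {r.term_id: r.p_raw for r in enrich_module(module, coll, min_genes=0)}
        grown = {
            r.term_id: r.p_raw
            for r in enrich_module(module + ["P5"], coll, min_genes=0)
        }
        assert grown["T00"] <= base["T00"]


class TestKappa:
    UNIVERSE = [f"g{i}" for i in range(100)]

    def test_identical_sets(self):
        a = set(self.UNIVERSE[:7])
        assert kappa(a, set(a), self.UNIVERSE) == 1.0

    def test_disjoint_hand_value(self):
        a = set(self.UNIVERSE[:5])
        b = set(self.UNIVERSE[5:10])
        # p_o = 0.90, p_e = 0.905 -> kappa = -0.005/0.095
        assert kappa(a, b, self.UNIVERSE) == pytest.approx(-1 / 19, rel=1e-12)

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, data):
        a = data.draw(st.sets(st.sampled_from(self.UNIVERSE), max_size=30))
        b = data.draw(st.sets(st.sampled_from(self.UNIVERSE), max_size=30))
        assert kappa(a, b, self.UNIVERSE) == kappa(b, a, self.UNIVERSE)

    def test_relabeling_invariance(self):
        a, b = set(self.UNIVERSE[:5]), set(self.UNIVERSE[3:12])
        mapping = {g: f"R_{g}" for g in self.UNIVERSE}
        assert kappa(
            {mapping[g] for g in a},
            {mapping[g] for g in b},
            [mapping[g] for g in self.UNIVERSE],
        ) == pytest.approx(kappa(a, b, self.UNIVERSE), rel=1e-12)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValidationError):
            kappa({"outside"}, set(), self.UNIVERSE)


class TestGroupTerms:
    def test_all_below_threshold_singletons(self):
        results = [
            make_result("A", ["g1", "g2", "g3"], 0.01),
            make_result("B", ["g4", "g5", "g6"], 0.02),
        ]
        groups = group_terms(results, kappa_threshold=0.3)
        assert sorted(g.term_ids for g in groups) == [("A",), ("B",)]

    def test_identical_sets_grouped_with_leading(self):
        results = [
            make_result("A", ["g1", "g2"], 0.05),
            make_result("B", ["g1", "g2"], 0.01),
        ]
        (group,) = group_terms(results, kappa_threshold=0.3)
        assert set(group.term_ids) == {"A", "B"}
        assert group.leading_term == "B"

    def test_block_structure_matches_bruteforce_components(self, rng):
        # 12 terms in 3 blocks of 4; within-block sets share most genes
        results = []
        for block in range(3):
            core = [f"b{block}_{i}" for i in range(8)]
            for t in range(4):
                extra = [f"b{block}_x{t}"]
                results.append(
                    make_result(f"T{block}{t}", core + extra, 0.01 * (t + 1))
                )
        kmat = pairwise_kappa(results)
        groups = group_terms(results, kappa_threshold=0.3, kappa_matrix=kmat)
        # brute-force connected components on the same kappa graph
        ids = sorted(r.term_id for r in results)
        adj = {i: set() for i in ids}
        for (a, b), v in kmat.items():
            if v >= 0.3:
                adj[a].add(b)
                adj[b].add(a)
        seen, comps = set(), []
        for start in ids:
            if start in seen:
                continue
            comp, stack = set(), [start]
            while stack:
                node = stack.pop()
                if node in comp:
                    continue
                comp.add(node)
                stack.extend(adj[node] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        assert {frozenset(g.term_ids) for g in groups} == set(comps)

    def test_order_invariance(self):
        results = [
            make_result("A", ["g1", "g2", "g3"], 0.01),
            make_result("B", ["g1", "g2", "g4"], 0.02),
            make_result("C", ["g9", "g8"], 0.03),
        ]
        forward = group_terms(results, kappa_threshold=0.2)
        backward = group_terms(list(reversed(results)), kappa_threshold=0.2)
        assert forward == backward


class TestAnnotationNetwork:
    def test_single_term(self):
        results = [make_result("A", ["g1", "g2", "g3"], 0.01)]
        groups = group_terms(results)
        net = build_annotation_network(results, groups, pairwise_kappa(results))
        assert len(net.nodes) == 1 and len(net.edges) == 0
        assert net.nodes[0].size == pytest.approx(-math.log10(0.01))
        assert net.nodes[0].leading

    def test_identical_terms_share_full_edge(self):
        results = [
            make_result("A", ["g1", "g2", "g3"], 0.01),
            make_result("B", ["g1", "g2", "g3"], 0.02),
        ]
        kmat = pairwise_kappa(results)
        net = build_annotation_network(results, group_terms(results, 0.3, kmat), kmat)
        (edge,) = net.edges
        assert edge.kappa == 1.0
        assert edge.shared_genes == 3

    def test_edges_match_pairwise_recomputation(self, rng):
        genes = [f"g{i}" for i in range(40)]
        results = []
        for t in range(6):
            idx = rng.choice(40, size=12, replace=False)
            results.append(make_result(f"T{t}", [genes[i] for i in idx], 0.01 * (t + 1)))
        kmat = pairwise_kappa(results)
        net = build_annotation_network(results, group_terms(results, 0.3, kmat), kmat, 0.3)
        expected = {
            (a, b): v for (a, b), v in kmat.items() if v >= 0.3
        }
        got = {(e.term_a, e.term_b): e.kappa for e in net.edges}
        assert got == expected


class TestCompareTermSets:
    def test_one_sided_term(self):
        a = []
        b = [make_result("T", ["g1"] * 1, 0.01, k_found=7)]
        assert compare_term_sets(a, b)["T"] == 0.0

    def test_equal_counts_white(self):
        a = [make_result("T", ["g1", "g2"], 0.01, k_found=5)]
        b = [make_result("T", ["g3", "g4"], 0.01, k_found=5)]
        assert compare_term_sets(a, b)["T"] == 0.5

    def test_hand_ratio(self):
        a = [make_result("T", ["g1"], 0.01, k_found=3)]
        b = [make_result("T", ["g2"], 0.01, k_found=1)]
        assert compare_term_sets(a, b)["T"] == pytest.approx(0.75)


class TestDrugTargetOverlap:
    def test_targets_subset_of_gwas(self):
        report = drug_target_overlap(["A", "B", "C"], ["A", "B"], ["A", "B"])
        assert report.gained == ()

    def test_disjoint_targets(self):
        report = drug_target_overlap(["A"], ["B"], ["X", "Y"])
        assert report.gwas_hits == () and report.pathway_hits == ()

    def test_counts_and_gained(self):
        targets = [f"t{i}" for i in range(10)]
        gwas = ["t0", "t1", "t2", "o1"]
        union = ["t0", "t1", "t2", "t3", "t4", "o2"]
        report = drug_target_overlap(gwas, union, targets)
        assert len(report.gwas_hits) == 3
        assert len(report.pathway_hits) == 5
        assert report.gained == ("t3", "t4")
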