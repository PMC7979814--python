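"""Proximity, degree-matched nulls, and Gene Ontology overlap baselines."""

import math

import numpy as np
import pytest

import msinet as ms
from msinet.baselines import (
    FUNCTIONAL_BASELINES,
    AnnotationCorpus,
    PPILayer,
    closest_distance,
    degree_matched_sample,
    functional_baseline,
    mica,
    protein_overlap,
    proximity_zscore,
    shared_function_distance_zscore,
    term_overlap,
    term_sets,
    zscored_term_overlap,
)


@pytest.fixture(scope="module")
def ppi():
    data = ms.default_fixture(seed=0)
    return data, PPILayer(data.graph)


@pytest.fixture(scope="module")
def corpus_graph():
    """Small annotated hierarchy: root <- mid <- {leafA, leafB}; 4 proteins."""
    kinds = {
        "root": ms.FUNCTION, "mid": ms.FUNCTION,
        "leafA": ms.FUNCTION, "leafB": ms.FUNCTION,
        "p1": ms.PROTEIN, "p2": ms.PROTEIN, "p3": ms.PROTEIN, "p4": ms.PROTEIN,
        "c": ms.DRUG,
    }
    edges = [
        ("mid", "root"), ("leafA", "mid"), ("leafB", "mid"),
        ("p1", "leafA"), ("p2", "leafA"), ("p3", "leafB"), ("p4", "mid"),
        ("c", "p1"),
        ("p1", "p2"), ("p2", "p3"), ("p3", "p4"),
    ]
    hierarchy = [("mid", "root"), ("leafA", "mid"), ("leafB", "mid")]
    g = ms.MultiscaleGraph(kinds, edges, hierarchy)
    return g, AnnotationCorpus(g)


class TestProteinOverlap:
    def test_jaccard_values(self):
        assert protein_overlap({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)
        assert protein_overlap({"A"}, {"A"}) == 1.0
        assert protein_overlap({"A"}, {"B"}) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            protein_overlap(set(), {"A"})


class TestClosestDistance:
    def test_path_graph_distances(self):
        kinds = {"s": ms.PROTEIN, "x": ms.PROTEIN, "t": ms.PROTEIN}
        g = ms.MultiscaleGraph(kinds, [("s", "x"), ("x", "t")])
        layer = PPILayer(g)
        assert closest_distance({"s"}, {"t"}, layer) == 2.0
        assert closest_distance({"s"}, {"x"}, layer) == 1.0
        assert closest_distance({"s"}, {"s"}, layer) == 0.0

    def test_mean_over_targets(self):
        kinds = {f"p{i}": ms.PROTEIN for i in range(4)}
        g = ms.MultiscaleGraph(kinds, [("p0", "p1"), ("p1", "p2"), ("p2", "p3")])
        layer = PPILayer(g)
        # targets p1 (distance 1) and p3 (distance 3) from S = {p0}
        assert closest_distance({"p0"}, {"p1", "p3"}, layer) == 2.0


class TestDegreeMatchedSampling:
    def test_sample_preserves_cardinality_and_bins(self, ppi):
        data, layer = ppi
        nodes = set(layer.proteins[:10])
        samples = degree_matched_sample(nodes, layer, 20, seed=0, min_bin_size=40)
        from msinet.baselines import _degree_bins

        bins = _degree_bins(layer, min_bin_size=40)
        bin_id = {i: id(b) for i, b in bins.items()}
        for s in samples:
            assert len(s) == len(nodes)
        # spot check: each replacement is drawn from the original node's bin
        one = degree_matched_sample({layer.proteins[0]}, layer, 50, seed=1,
                                    min_bin_size=40)
        pool = set(bins[layer.pos[layer.proteins[0]]])
        for s in one:
            assert layer.pos[next(iter(s))] in pool

    def test_mean_degree_approximately_preserved(self, ppi):
        data, layer = ppi
        rng = np.random.default_rng(0)
        nodes = set(np.array(layer.proteins)[rng.choice(len(layer.proteins), 12,
                                                        replace=False)])
        orig = np.mean([layer.degree[layer.pos[v]] for v in nodes])
        samples = degree_matched_sample(nodes, layer, 200, seed=2, min_bin_size=30)
        sampled = np.mean(
            [np.mean([layer.degree[layer.pos[v]] for v in s]) for s in samples]
        )
        assert abs(sampled - orig) / orig < 0.25

    def test_too_small_graph_suggests_smaller_floor(self):
        kinds = {"a": ms.PROTEIN, "b": ms.PROTEIN}
        g = ms.MultiscaleGraph(kinds, [("a", "b")])
        with pytest.raises(ValueError, match="min_bin_size"):
            degree_matched_sample({"a"}, PPILayer(g), 1, seed=0, min_bin_size=100)


class TestProximityZscore:
    def test_null_drawn_sets_calibrate_to_zero(self, ppi):
        data, layer = ppi
        rng = np.random.default_rng(99)
        zs = []
        for rep in range(40):
            base_s = set(rng.choice(layer.proteins, 8, replace=False))
            base_t = set(rng.choice(layer.proteins, 3, replace=False))
            s = degree_matched_sample(base_s, layer, 1, seed=30_000 + rep,
                                      min_bin_size=50)[0]
            t = degree_matched_sample(base_t, layer, 1, seed=60_000 + rep,
                                      min_bin_size=50)[0]
            zs.append(proximity_zscore(s, t, layer, n_perm=100, seed=rep,
                                       min_bin_size=50).z)
        # mean of 40 z's: gross bias would show far outside +-0.45
        assert abs(np.mean(zs)) < 0.45

    def test_planted_drug_strongly_negative(self, ppi):
        data, layer = ppi
        adj = data.graph.adjacency
        # a molecular-route drug targets inside its disease module
        drug = next(c for c, r in data.drug_route.items() if r == "molecular")
        disease = next(d for d in data.treatments.diseases
                       if (drug, d) in data.treatments.pairs)
        targets = {v for v in adj[drug] if data.graph.kinds[v] == ms.PROTEIN}
        dis_prot = {v for v in adj[disease] if data.graph.kinds[v] == ms.PROTEIN}
        z = proximity_zscore(dis_prot, targets, layer, n_perm=200, seed=0,
                             min_bin_size=50).z
        assert z < -1.0

    def test_single_permutation_rejected(self, ppi):
        data, layer = ppi
        with pytest.raises(ValueError, match="n_perm"):
            proximity_zscore({"P0000"}, {"P0001"}, layer, n_perm=1, seed=0)


class TestAnnotationCorpus:
    def test_p_propagates_through_descendants(self, corpus_graph):
        g, corpus = corpus_graph
        # 4 annotated proteins; leafA covers p1,p2; mid covers all 4 (p4 direct)
        assert corpus.p("leafA") == pytest.approx(0.5)
        assert corpus.p("mid") == 1.0
        assert corpus.p("root") == 1.0

    def test_ic_monotone_child_to_parent(self, fixture_data):
        corpus = AnnotationCorpus(fixture_data.graph)
        for child, parents in fixture_data.graph.parents.items():
            for parent in parents:
                if corpus.term_protein_count(child) > 0:
                    assert corpus.ic(child) >= corpus.ic(parent) - 1e-12

    def test_term_sets_closure_and_multiset(self, corpus_graph):
        g, corpus = corpus_graph
        assert term_sets({"p1"}, corpus, "set_with_descendant_closure") == {
            "leafA", "mid", "root"
        }
        assert term_sets({"p1"}, corpus, "direct_set") == {"leafA"}
        counts = term_sets({"p1", "p2"}, corpus, "multiset")
        assert counts["leafA"] == 2 and counts["root"] == 2

    def test_enrichment_hypergeometric(self, fixture_data):
        from scipy.stats import hypergeom

        corpus = AnnotationCorpus(fixture_data.graph)
        g = fixture_data.graph
        # query = all proteins annotated to one deep term -> that term enriched
        term = next(
            t for t in g.nodes_of_kind(ms.FUNCTION)
            if 3 <= corpus.term_protein_count(t) <= 10
        )
        query = set(corpus._term_proteins[term])
        enriched = term_sets(query, corpus, "enriched")
        assert term in enriched
        # oracle: raw hypergeometric p for that term is tiny
        p = hypergeom.sf(
            len(query) - 1, len(corpus.background),
            corpus.term_protein_count(term), len(query),
        )
        assert p < 1e-4


class TestTermOverlap:
    def test_multiset_jaccard_and_intersection(self):
        u = {"a": 2, "b": 1}
        v = {"a": 1, "c": 1}
        assert term_overlap(u, v, "jaccard") == pytest.approx(1 / 4)
        assert term_overlap(u, v, "intersection") == 1.0

    def test_identity_and_disjoint(self):
        assert term_overlap({"a", "b"}, {"a", "b"}, "jaccard") == 1.0
        assert term_overlap({"a"}, {"b"}, "jaccard") == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            term_overlap(set(), set())

    def test_jaccard_bounded(self, corpus_graph):
        g, corpus = corpus_graph
        u = term_sets({"p1", "p4"}, corpus, "set_with_descendant_closure")
        v = term_sets({"p3"}, corpus, "set_with_descendant_closure")
        assert 0.0 <= term_overlap(u, v, "jaccard") <= 1.0


class TestSemanticSimilarity:
    def test_resnik_self_similarity(self, corpus_graph):
        g, corpus = corpus_graph
        # leafA covers 2 of 4 annotated proteins -> Resnik(u,u) = -ln 0.5
        assert ms.semantic_similarity("leafA", "leafA", corpus) == pytest.approx(
            -math.log(0.5)
        )

    def test_resnik_at_root_is_zero(self, corpus_graph):
        g, corpus = corpus_graph
        # MICA of the two leaves is mid with p=1 -> IC 0
        assert ms.semantic_similarity("leafA", "leafB", corpus) == 0.0
        assert mica("leafA", "leafB", corpus) in ("mid", "root")

    def test_resnik_bounded_by_term_ic(self, corpus_graph):
        g, corpus = corpus_graph
        for u in ("leafA", "leafB", "mid"):
            for v in ("leafA", "leafB", "mid"):
                assert ms.semantic_similarity(u, v, corpus) <= min(
                    corpus.ic(u), corpus.ic(v)
                ) + 1e-12

    def test_sim_gic_identity(self, corpus_graph):
        g, corpus = corpus_graph
        u = {"leafA", "leafB"}
        assert ms.sim_gic(u, u, corpus) == 1.0

    def test_sim_gic_bounded(self, corpus_graph):
        g, corpus = corpus_graph
        val = ms.sim_gic({"leafA"}, {"leafB"}, corpus)
        assert 0.0 <= val <= 1.0

    def test_aggregation_modes(self, corpus_graph):
        g, corpus = corpus_graph
        # single-term sets: all three modes coincide
        for mode in ("average", "max", "best_match_average"):
            assert ms.aggregate_similarity(
                {"leafA"}, {"leafB"}, corpus, "resnik", mode
            ) == ms.semantic_similarity("leafA", "leafB", corpus)

    def test_bma_versus_average_on_diagonal_sim(self):
        # sim matrix [[1,0],[0,1]]: average 0.5, max 1, BMA 1 (hand-computed)
        sim = {("u1", "v1"): 1.0, ("u1", "v2"): 0.0,
               ("u2", "v1"): 0.0, ("u2", "v2"): 1.0}
        u, v = {"u1", "u2"}, {"v1", "v2"}
        avg = sum(sim.values()) / 4
        mx = max(sim.values())
        bma = (sum(max(sim[(a, b)] for b in v) for a in u)
               + sum(max(sim[(a, b)] for a in u) for b in v)) / 4
        assert (avg, mx, bma) == (0.5, 1.0, 1.0)


class TestBaselineEnumeration:
    def test_seventeen_variants(self):
        assert len(FUNCTIONAL_BASELINES) == 17

    @pytest.mark.parametrize("name", FUNCTIONAL_BASELINES)
    def test_every_baseline_finite_on_fixture(self, name, ppi):
        data, layer = ppi
        adj = data.graph.adjacency
        corpus = AnnotationCorpus(data.graph)
        drug = data.treatments.drugs[0]
        disease = data.treatments.diseases[0]
        targets = {v for v in adj[drug] if data.graph.kinds[v] == ms.PROTEIN}
        dis_prot = {v for v in adj[disease] if data.graph.kinds[v] == ms.PROTEIN}
        score = functional_baseline(
            name, targets, dis_prot, corpus, layer, n_perm=30, seed=0, min_bin_size=50
        )
        assert np.isfinite(score)

    def test_zscored_overlap_seed_reproducible(self, ppi):
        data, layer = ppi
        adj = data.graph.adjacency
        corpus = AnnotationCorpus(data.graph)
        drug, disease = data.treatments.drugs[0], data.treatments.diseases[0]
        targets = {v for v in adj[drug] if data.graph.kinds[v] == ms.PROTEIN}
        dis_prot = {v for v in adj[disease] if data.graph.kinds[v] == ms.PROTEIN}
        a = zscored_term_overlap(targets, dis_prot, corpus, layer, n_perm=25,
                                 seed=5, min_bin_size=50)
        b = zscored_term_overlap(targets, dis_prot, corpus, layer, n_perm=25,
                                 seed=5, min_bin_size=50)
        assert a.z == b.z


class TestOverlapProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    counts = st.dictionaries(st.sampled_from("abcdefgh"),
                             st.integers(min_value=0, max_value=9))

    @given(u=counts, v=counts)
    @settings(derandomize=True, max_examples=200)
    def test_multiset_jaccard_bounded_and_symmetric(self, u, v):
        if not any(u.values()) and not any(v.values()):
            return
        j = term_overlap(u, v, "jaccard")
        assert 0.0 <= j <= 1.0
        assert j == term_overlap(v, u, "jaccard")
        if any(u.values()):
            assert term_overlap(u, u, "jaccard") == 1.0


class TestSharedFunctionDistance:
    def test_adjacent_pair_negative_z(self, ppi):
        data, layer = ppi
        g = data.graph
        adj = g.adjacency
        # find an adjacent protein pair sharing a direct annotation
        pair = None
        for u, v in g.edges:
            if g.kinds[u] == ms.PROTEIN and g.kinds[v] == ms.PROTEIN:
                fu = {f for f in adj[u] if g.kinds[f] == ms.FUNCTION}
                fv = {f for f in adj[v] if g.kinds[f] == ms.FUNCTION}
                if fu & fv:
                    pair = (u, v)
                    break
        assert pair is not None
        z = shared_function_distance_zscore(pair, layer, n_perm=200, seed=0,
                                            min_bin_size=50).z
        assert z < 0

    def test_null_pair_calibrates(self, ppi):
        data, layer = ppi
        rng = np.random.default_rng(1)
        zs = []
        for rep in range(30):
            u, v = rng.choice(layer.proteins, 2, replace=False)
            zs.append(
                shared_function_distance_zscore((str(u), str(v)), layer, n_perm=100,
                                                seed=rep, min_bin_size=50).z
            )
        assert abs(np.mean(zs)) < 0.35

    def test_zero_permutations_rejected(self, ppi):
        data, layer = ppi
        with pytest.raises(ValueError, match="n_perm"):
            shared_function_distance_zscore(("P0000", "P0001"), layer, n_perm=0, seed=0)
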