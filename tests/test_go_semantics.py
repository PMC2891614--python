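"""Information-content similarity measures, aggregation and enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from constellation.go_semantics import (
    AnnotationCorpus,
    GoDag,
    combined_similarity,
    functional_enrichment,
    gene_pair_similarity,
    group_similarity_profile,
    overrepresented_gene_flags,
    propagate_annotations,
    read_annotation_table,
    read_obo,
    term_similarity,
)
from constellation.synthetic_data import (
    simulate_genome,
    simulate_go,
    write_annotation_table,
    write_obo,
)
from constellation.classify import classify_genome

LN2 = math.log(2.0)


class TestPropagation:
    def test_hand_counted_frequencies(self, toy_dag_corpus):
        _, corpus = toy_dag_corpus
        assert corpus.p == {"R": 1.0, "A": 0.5, "B": 0.5, "X": 0.25, "Y": 0.25}

    def test_leaf_annotation_gains_all_ancestors(self, toy_dag_corpus):
        _, corpus = toy_dag_corpus
        assert corpus.propagated["g1"] == {"X", "A", "R"}

    def test_root_frequency_one_ic_zero(self, toy_dag_corpus):
        _, corpus = toy_dag_corpus
        assert corpus.p["R"] == 1.0
        assert corpus.ic("R") == 0.0

    def test_ic_monotone_child_geq_parent(self):
        dag, corpus, _ = simulate_go(n_terms=30, n_genes=100, seed=6)
        corpus = propagate_annotations(corpus, dag)
        for child, parent in dag.graph.edges:
            if child in corpus.p and parent in corpus.p:
                assert corpus.ic(child) >= corpus.ic(parent) - 1e-12

    def test_unknown_term_dropped_with_warning(self, toy_dag_corpus):
        dag, _ = toy_dag_corpus
        corpus = AnnotationCorpus(direct={"g1": {"X", "NOPE"}})
        with pytest.warns(UserWarning, match="absent"):
            out = propagate_annotations(corpus, dag)
        assert out.propagated["g1"] == {"X", "A", "R"}


class TestTermSimilarity:
    def test_toy_dag_hand_values(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        # MICA of X and Y is A with p = 0.5
        assert term_similarity("X", "Y", "res", corpus, dag) == pytest.approx(LN2, abs=1e-12)
        assert term_similarity("X", "Y", "lin", corpus, dag) == pytest.approx(0.5, abs=1e-12)
        assert term_similarity("X", "Y", "rel", corpus, dag) == pytest.approx(0.25, abs=1e-12)
        assert term_similarity("X", "Y", "jc", corpus, dag) == pytest.approx(
            1.0 / (1.0 + 2 * LN2), abs=1e-12
        )

    def test_identity_cases(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        assert term_similarity("X", "X", "lin", corpus, dag) == 1.0
        assert term_similarity("X", "X", "rel", corpus, dag) == pytest.approx(1 - 0.25)
        assert term_similarity("X", "X", "jc", corpus, dag) == pytest.approx(1.0)

    def test_root_only_common_ancestor(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        # X and B meet only at the root
        assert term_similarity("X", "B", "res", corpus, dag) == 0.0
        assert term_similarity("X", "B", "rel", corpus, dag) == 0.0

    def test_symmetry(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        for m in ("res", "lin", "jc", "rel"):
            assert term_similarity("X", "B", m, corpus, dag) == term_similarity(
                "B", "X", m, corpus, dag
            )

    def test_cross_root_is_an_error(self):
        ns = {"R1": "biological_process", "R2": "molecular_function"}
        dag = GoDag([], ns)
        corpus = propagate_annotations(
            AnnotationCorpus(direct={"g1": {"R1"}, "g2": {"R2"}}), dag
        )
        with pytest.raises(ValueError):
            term_similarity("R1", "R2", "lin", corpus, dag)


class TestGenePairSimilarity:
    def test_identical_term_sets_score_one(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        for agg in ("BM", "max", "avg"):
            assert gene_pair_similarity(
                "g1", "g1", "biological_process", "lin", agg, corpus, dag
            ) == pytest.approx(1.0)

    def test_single_term_genes_all_aggregations_equal(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        expected = term_similarity("X", "Y", "rel", corpus, dag)
        for agg in ("BM", "max", "avg"):
            assert gene_pair_similarity(
                "g1", "g2", "biological_process", "rel", agg, corpus, dag
            ) == pytest.approx(expected)

    def test_two_by_one_best_match_hand_value(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        corpus2 = propagate_annotations(
            AnnotationCorpus(
                direct={"ga": {"X", "B"}, "gb": {"Y"}, "g1": {"X"}, "g2": {"Y"}}
            ),
            dag,
        )
        s_xy = term_similarity("X", "Y", "lin", corpus2, dag)
        s_by = term_similarity("B", "Y", "lin", corpus2, dag)
        # BM = (max over rows + max over cols) / (|T1| + |T2|)
        expected = (max(s_xy, 0) + max(s_by, 0) + max(s_xy, s_by)) / 3.0
        got = gene_pair_similarity("ga", "gb", "biological_process", "lin", "BM", corpus2, dag)
        assert got == pytest.approx(expected)

    def test_unannotated_gene_gives_none_not_zero(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        assert gene_pair_similarity("g1", "gX", "biological_process", "lin", "BM", corpus, dag) is None
        assert combined_similarity("g1", "g2", "lin", "BM", corpus, dag) is None  # MF/CC missing

    def test_bm_between_avg_and_max(self):
        dag, corpus, _ = simulate_go(n_terms=30, n_genes=60, n_planted_pairs=5, seed=7)
        corpus = propagate_annotations(corpus, dag)
        rng = np.random.default_rng(0)
        genes = corpus.genes
        checked = 0
        while checked < 100:
            g1, g2 = rng.choice(genes, 2, replace=False)
            tri = [
                gene_pair_similarity(g1, g2, "biological_process", "lin", a, corpus, dag)
                for a in ("avg", "BM", "max")
            ]
            if tri[0] is None:
                continue
            avg, bm, mx = tri
            assert avg - 1e-12 <= bm <= mx + 1e-12
            checked += 1


class TestGroupProfile:
    @staticmethod
    def _setup(seed=0):
        sim = simulate_genome({"5PP": 10, "SG": 40}, seed=seed)
        calls = classify_genome(sim.genes, sim.config, sim.chrom_lengths)
        dag, _, truth = simulate_go(n_terms=30, n_genes=0, n_planted_pairs=0, seed=seed)
        # annotate partner pairs with the shared rare markers; every other
        # gene draws one random leaf per root
        rng = np.random.default_rng(seed)
        leaves_by_ns = {}
        for t in sorted(dag.terms):
            if dag.graph.in_degree(t) == 0:
                leaves_by_ns.setdefault(dag.namespace(t), []).append(t)
        direct = {}
        for call in calls:
            if call.group == "5PP":
                direct[call.gene_id] = set(truth["marker_terms"].values())
            else:
                direct[call.gene_id] = {
                    leaves[rng.integers(0, len(leaves))] for leaves in leaves_by_ns.values()
                }
        corpus = propagate_annotations(AnnotationCorpus(direct=direct), dag)
        return calls, corpus, dag

    def test_planted_partner_pairs_beat_background(self):
        calls, corpus, dag = self._setup()
        profile = group_similarity_profile(calls, corpus, dag, n_pairs=300, seed=1)
        bg = profile.loc[profile["group"] == "background"].iloc[0]
        pp = profile.loc[profile["group"] == "5PP"].iloc[0]
        assert pp["mean"] > bg["mean"]
        assert pp["p_vs_background"] < 0.01

    def test_seeded_determinism(self):
        calls, corpus, dag = self._setup()
        a = group_similarity_profile(calls, corpus, dag, n_pairs=200, seed=7)
        b = group_similarity_profile(calls, corpus, dag, n_pairs=200, seed=7)
        assert a.equals(b)


class TestEnrichment:
    def test_set_equal_to_background_all_p_one(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        result = functional_enrichment(corpus.genes, corpus.genes, corpus, dag)
        assert (result["p"] == 1.0).all()

    def test_hand_hypergeometric_value(self):
        ns = {"R": "biological_process", "T": "biological_process"}
        dag = GoDag([("T", "R")], ns)
        genes = [f"g{i}" for i in range(100)]
        direct = {g: ({"T"} if i < 20 else {"R"}) for i, g in enumerate(genes)}
        corpus = propagate_annotations(AnnotationCorpus(direct=direct), dag)
        result = functional_enrichment(genes[:10], genes, corpus, dag).set_index("term")
        expected = math.comb(20, 10) * math.comb(80, 0) / math.comb(100, 10)
        assert result.loc["T", "p"] == pytest.approx(expected, rel=1e-9)
        assert result.loc["T", "p"] == pytest.approx(1.07e-8, rel=0.01)

    def test_matches_exhaustive_summation(self):
        # upper-tail mass summed term by term on a small population
        n_bg, big_k, n_set, k = 60, 18, 12, 7
        exact = sum(
            math.comb(big_k, i) * math.comb(n_bg - big_k, n_set - i) / math.comb(n_bg, n_set)
            for i in range(k, min(big_k, n_set) + 1)
        )
        assert stats.hypergeom.sf(k - 1, n_bg, big_k, n_set) == pytest.approx(exact, rel=1e-10)

    def test_empty_set_rejected(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        with pytest.raises(ValueError):
            functional_enrichment([], corpus.genes, corpus, dag)

    def test_gene_flags(self, toy_dag_corpus):
        dag, corpus = toy_dag_corpus
        import pandas as pd

        enrichment = pd.DataFrame([{"term": "X", "p": 0.001}])
        flags = overrepresented_gene_flags(enrichment, corpus.genes, corpus)
        assert flags == {"g1": 1, "g2": 0, "g3": 0, "g4": 0}


class TestObo:
    def test_obo_round_trip(self, tmp_path):
        dag, corpus, _ = simulate_go(n_terms=15, n_genes=20, seed=3)
        obo = tmp_path / "toy.obo"
        write_obo(dag, obo)
        back = read_obo(obo)
        assert back.terms == dag.terms
        assert set(back.graph.edges) == set(dag.graph.edges)
        assert back.namespaces == dag.namespaces

    def test_annotation_table_round_trip(self, tmp_path):
        _, corpus, _ = simulate_go(n_terms=15, n_genes=20, seed=3)
        path = tmp_path / "ann.tsv"
        write_annotation_table(corpus, path)
        back = read_annotation_table(path)
        assert back.direct == corpus.direct
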