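"""Shared fixtures: toy ontology, gene-model builders, brute-force classifier."""

from __future__ import annotations

import numpy as np
import pytest

from constellation.annotation_io import GeneModel, Interval
from constellation.classify import ClassificationConfig, ConstellationCall, _evaluate_pair
from constellation.go_semantics import AnnotationCorpus, GoDag, propagate_annotations
from constellation.synthetic_data import _jittered_exons


def make_gene(gene_id, start, end, strand="+", chrom="chr1", exons=None):
    span = Interval(start, end)
    if exons is None:
        exons = (span,)
    else:
        exons = tuple(Interval(a, b) for a, b in exons)
    return GeneModel(gene_id, chrom, strand, span, exons)


@pytest.fixture
def toy_dag_corpus():
    """Root R with children A and B; A has leaves X and Y.

    Genes: g1 -> X, g2 -> Y, g3 -> B, g4 -> B.  Hand-counted propagated
    frequencies: p(R) = 1, p(A) = 0.5, p(B) = 0.5, p(X) = p(Y) = 0.25.
    """
    ns = {t: "biological_process" for t in "RABXY"}
    dag = GoDag([("A", "R"), ("B", "R"), ("X", "A"), ("Y", "A")], ns)
    corpus = AnnotationCorpus(direct={"g1": {"X"}, "g2": {"Y"}, "g3": {"B"}, "g4": {"B"}})
    return dag, propagate_annotations(corpus, dag)


def brute_force_classify(genes, config=None, chrom_lengths=None):
    """O(n^2) all-pairs reference classifier (no spatial indexing)."""
    config = config or ClassificationConfig()
    genes = sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id))
    relations = {g.gene_id: [] for g in genes}
    conflicted = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if a.chrom != b.chrom:
                continue
            chrom_len = chrom_lengths.get(a.chrom) if chrom_lengths else None
            rels, conflict = _evaluate_pair(a, b, config, chrom_len)
            if conflict:
                conflicted.update((a.gene_id, b.gene_id))
            for rel in rels:
                relations[a.gene_id].append(rel)
                relations[b.gene_id].append(rel)
    groups = {}
    for g in genes:
        if g.gene_id in conflicted:
            groups[g.gene_id] = "CONFLICT"
        elif relations[g.gene_id]:
            groups[g.gene_id] = min(relations[g.gene_id], key=config.rank)
        else:
            groups[g.gene_id] = "SG"
    return groups


def random_genome(n_genes, seed, chrom_span=3_000_000, n_chroms=2):
    """Unstructured random gene placements exercising every geometry."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(2000, chrom_span))
        length = int(rng.integers(500, 30000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _jittered_exons(start, start + length, rng)
        genes.append(GeneModel(f"g{i:04d}", chrom, strand, Interval(start, start + length), exons))
    return genes
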