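"""Information-content GO term similarity, gene-pair similarity and enrichment.

The annotation corpus is propagated under the true-path rule within each of
the three ontology roots (biological_process, molecular_function,
cellular_component).  Term frequency p(t) is the fraction of genes annotated
(after propagation) to t within its root; information content is
IC(t) = -ln p(t).  Term similarity measures (Resnik, Lin, Jiang-Conrath and
the Relevance measure) all derive from the most informative common ancestor
(MICA).  Gene pairs aggregate term scores by best-match (BM), maximum or
average; BM is the default reported measure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "AnnotationCorpus",
    "propagate_annotations",
    "term_similarity",
    "gene_pair_similarity",
    "combined_similarity",
    "group_similarity_profile",
    "functional_enrichment",
    "read_obo",
    "read_annotation_table",
]

ROOT_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
MEASURES = ("res", "lin", "jc", "rel")
AGGREGATIONS = ("BM", "max", "avg")


class GoDag:
    """Directed acyclic graph of is_a relations (child -> parent edges)."""

    def __init__(self, edges: Iterable[tuple[str, str]], namespaces: Mapping[str, str]):
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(namespaces)
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("is_a graph contains a cycle")
        self.namespaces = dict(namespaces)
        self.roots = {t for t in self.graph if self.graph.out_degree(t) == 0}
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def namespace(self, term: str) -> str:
        return self.namespaces[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of a term, including the term itself."""
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestors[term] = cached
        return cached


def read_obo(path: str | Path) -> GoDag:
    """Load an OBO 1.2 ontology, keeping only is_a edges."""
    import obonet

    graph = obonet.read_obo(str(path))
    edges = [
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a"
    ]
    namespaces = {
        node: data.get("namespace", "unknown") for node, data in graph.nodes(data=True)
    }
    return GoDag(edges, namespaces)


@dataclass
class AnnotationCorpus:
    """Gene -> GO term annotations, optionally ancestor-propagated.

    ``direct`` holds the terms as annotated; after propagation the
    ``propagated`` sets are closed under is_a ancestors per root and the
    term frequencies/IC become available.
    """

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] | None = None
    p: dict[str, float] = field(default_factory=dict)
    _genes_per_root: dict[str, int] = field(default_factory=dict)

    def ic(self, term: str) -> float:
        return -float(np.log(self.p[term]))

    def terms_in_root(self, gene: str, root_ns: str, dag: GoDag) -> set[str]:
        """A gene's directly annotated terms within one root namespace."""
        return {t for t in self.direct.get(gene, ()) if t in dag and dag.namespace(t) == root_ns}

    @property
    def genes(self) -> list[str]:
        return sorted(self.direct)


def read_annotation_table(path: str | Path) -> AnnotationCorpus:
    """Read a gene_id<TAB>term_id table (GAF-like two-column subset)."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "!")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            direct.setdefault(parts[0], set()).add(parts[1])
    return AnnotationCorpus(direct=direct)


def propagate_annotations(corpus: AnnotationCorpus, dag: GoDag) -> AnnotationCorpus:
    """Close annotations under ancestors and compute term frequencies.

    p(t) = (genes annotated to t or any descendant) / (genes annotated in
    t's root).  Terms absent from the DAG are dropped with a warning.
    """
    propagated: dict[str, set[str]] = {}
    dropped = 0
    for gene, terms in corpus.direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag:
                dropped += 1
                continue
            closed |= dag.ancestors(t)
        propagated[gene] = closed
    if dropped:
        warnings.warn(f"dropped {dropped} annotations to terms absent from the ontology")

    genes_per_root: dict[str, int] = {ns: 0 for ns in set(dag.namespaces.values())}
    term_counts: dict[str, int] = {}
    for gene, terms in propagated.items():
        roots_hit = {dag.namespace(t) for t in terms}
        for ns in roots_hit:
            genes_per_root[ns] += 1
        for t in terms:
            term_counts[t] = term_counts.get(t, 0) + 1

    p = {}
    for t, count in term_counts.items():
        denom = genes_per_root[dag.namespace(t)]
        p[t] = count / denom
    return AnnotationCorpus(
        direct={g: set(ts) for g, ts in corpus.direct.items()},
        propagated=propagated,
        p=p,
        _genes_per_root=genes_per_root,
    )


def _mica(t1: str, t2: str, corpus: AnnotationCorpus, dag: GoDag) -> str:
    if dag.namespace(t1) != dag.namespace(t2):
        raise ValueError(f"terms {t1} and {t2} belong to different roots")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common = [t for t in common if t in corpus.p]
    if not common:
        raise ValueError(f"terms {t1} and {t2} share no annotated common ancestor")
    # maximise IC = minimise p; ties broken by term id for determinism
    return min(common, key=lambda t: (corpus.p[t], t))


def term_similarity(
    t1: str, t2: str, measure: str, corpus: AnnotationCorpus, dag: GoDag
) -> float:
    """Similarity of two terms under the same root.

    res = IC(MICA); lin = 2 IC(MICA) / (IC(t1) + IC(t2)); jc = 1/(1 + d_JC)
    with d_JC = IC(t1) + IC(t2) - 2 IC(MICA); rel = lin * (1 - p(MICA)).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if corpus.propagated is None:
        raise ValueError("corpus must be propagated first")
    mica = _mica(t1, t2, corpus, dag)
    ic_m = corpus.ic(mica)
    if measure == "res":
        return ic_m
    ic1, ic2 = corpus.ic(t1), corpus.ic(t2)
    if measure == "jc":
        return 1.0 / (1.0 + ic1 + ic2 - 2.0 * ic_m)
    lin = 0.0 if ic1 + ic2 == 0 else 2.0 * ic_m / (ic1 + ic2)
    if measure == "lin":
        return lin
    return lin * (1.0 - corpus.p[mica])


def _aggregate(matrix: np.ndarray, aggregation: str) -> float:
    if aggregation == "max":
        return float(matrix.max())
    if aggregation == "avg":
        return float(matrix.mean())
    if aggregation == "BM":
        row_best = matrix.max(axis=1)
        col_best = matrix.max(axis=0)
        return float((row_best.sum() + col_best.sum()) / (matrix.shape[0] + matrix.shape[1]))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def gene_pair_similarity(
    g1: str,
    g2: str,
    root_ns: str,
    measure: str,
    aggregation: str,
    corpus: AnnotationCorpus,
    dag: GoDag,
) -> float | None:
    """Aggregate term-pair similarity between two genes within one root.

    Returns None (undefined, not zero) when either gene carries no
    annotation in the root.
    """
    t1 = sorted(corpus.terms_in_root(g1, root_ns, dag))
    t2 = sorted(corpus.terms_in_root(g2, root_ns, dag))
    if not t1 or not t2:
        return None
    matrix = np.array(
        [[term_similarity(a, b, measure, corpus, dag) for b in t2] for a in t1]
    )
    return _aggregate(matrix, aggregation)


def combined_similarity(
    g1: str,
    g2: str,
    measure: str,
    aggregation: str,
    corpus: AnnotationCorpus,
    dag: GoDag,
    roots: Sequence[str] = ROOT_NAMESPACES,
) -> float | None:
    """The All score: mean of the per-root scores, defined only when the
    pair is annotated in every root."""
    scores = []
    for ns in roots:
        s = gene_pair_similarity(g1, g2, ns, measure, aggregation, corpus, dag)
        if s is None:
            return None
        scores.append(s)
    return float(np.mean(scores))


def group_similarity_profile(
    calls,
    corpus: AnnotationCorpus,
    dag: GoDag,
    measure: str = "rel",
    aggregation: str = "BM",
    root_ns: str | None = None,
    n_pairs: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group partner-pair similarity versus a random-pair background.

    For groups defined by pairing (overlap and territory relations) the
    scores are computed over the actual partner pairs; the genomic
    background is ``n_pairs`` uniformly random gene pairs.  Each group is
    compared to the background with a two-sided Mann-Whitney U test.
    """

    def score(g1: str, g2: str) -> float | None:
        if root_ns is None:
            return combined_similarity(g1, g2, measure, aggregation, corpus, dag)
        return gene_pair_similarity(g1, g2, root_ns, measure, aggregation, corpus, dag)

    rng = np.random.default_rng(seed)
    annotated = [g for g in corpus.genes if corpus.direct.get(g)]
    if len(annotated) < 2:
        raise ValueError("need at least two annotated genes for a background")
    background: list[float] = []
    while len(background) < n_pairs:
        g1, g2 = rng.choice(annotated, size=2, replace=False)
        s = score(g1, g2)
        if s is not None:
            background.append(s)

    pair_scores: dict[str, list[float]] = {}
    seen: set[tuple[str, str]] = set()
    for call in calls:
        if call.group in ("SG", "CONFLICT"):
            continue
        for ev in call.partners:
            if ev.relation != call.group:
                continue
            key = tuple(sorted((call.gene_id, ev.partner_id)))
            if key in seen:
                continue
            seen.add(key)
            s = score(*key)
            if s is not None:
                pair_scores.setdefault(call.group, []).append(s)

    rows = [
        {
            "group": "background",
            "n_pairs": len(background),
            "mean": float(np.mean(background)),
            "sd": float(np.std(background, ddof=1)),
            "p_vs_background": np.nan,
        }
    ]
    for group in sorted(pair_scores):
        scores = pair_scores[group]
        if len(scores) < 2:
            warnings.warn(f"group {group}: fewer than two scored pairs; skipped")
            continue
        u, p = stats.mannwhitneyu(scores, background, alternative="two-sided")
        rows.append(
            {
                "group": group,
                "n_pairs": len(scores),
                "mean": float(np.mean(scores)),
                "sd": float(np.std(scores, ddof=1)),
                "p_vs_background": float(p),
            }
        )
    return pd.DataFrame(rows)


def functional_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    corpus: AnnotationCorpus,
    dag: GoDag,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of propagated terms.

    P-values are uncorrected by default (a configurable choice); the gene
    flag marks genes carrying at least one term with p below ``alpha``.
    """
    gene_set = sorted(set(gene_set))
    background = sorted(set(background))
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = set(gene_set) - set(background)
    if missing:
        raise ValueError(f"gene set contains genes absent from background: {sorted(missing)[:5]}")
    if corpus.propagated is None:
        raise ValueError("corpus must be propagated first")

    n_bg = len(background)
    n_set = len(gene_set)
    term_bg: dict[str, set[str]] = {}
    for g in background:
        for t in corpus.propagated.get(g, ()):
            term_bg.setdefault(t, set()).add(g)

    rows = []
    set_genes = set(gene_set)
    for term, bg_genes in sorted(term_bg.items()):
        hits = bg_genes & set_genes
        if not hits:
            continue
        k, big_k = len(hits), len(bg_genes)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_set))
        fold = (k / n_set) / (big_k / n_bg)
        rows.append({"term": term, "set_hits": k, "background_hits": big_k, "fold": fold, "p": p})
    result = pd.DataFrame(rows)
    if bh_correct and len(result):
        from statsmodels.stats.multitest import multipletests

        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    return result


def overrepresented_gene_flags(
    enrichment: pd.DataFrame,
    gene_set: Iterable[str],
    corpus: AnnotationCorpus,
    alpha: float = 0.05,
) -> dict[str, int]:
    """1 for genes carrying at least one term enriched at p < alpha."""
    if corpus.propagated is None:
        raise ValueError("corpus must be propagated first")
    hot_terms = set(enrichment.loc[enrichment["p"] < alpha, "term"])
    return {
        g: int(bool(corpus.propagated.get(g, set()) & hot_terms)) for g in gene_set
    }
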