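"""Seeded generators for every input class, with known ground truth.

These generators stand in for the real genome annotation, ontology,
polymorphism and expression downloads: each one emits standard-format
files (GFF3, OBO, FASTA, TSV) together with the truth used to build them,
so every analysis stage can be tested for recovery without any network
access.  A single top-level seed fans out to stable per-generator child
seeds; regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, Interval, write_gff3
from .classify import ClassificationConfig
from .evo_stats import HaplotypeSample
from .go_semantics import AnnotationCorpus, GoDag

__all__ = [
    "derive_seed",
    "SyntheticGenome",
    "simulate_genome",
    "simulate_go",
    "write_obo",
    "simulate_haplotypes",
    "write_haplotype_fasta",
    "ExpressionSim",
    "simulate_expression",
    "simulate_regression",
]


def derive_seed(seed: int, name: str) -> int:
    """Stable child seed for a named generator (always < 2**31)."""
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# genome geometries


def _jittered_exons(start: int, end: int, rng: np.random.Generator, max_exons: int = 3) -> tuple[Interval, ...]:
    """1-3 exons filling [start, end), introns at least ~100 bp."""
    length = end - start
    if length < 1500:
        return (Interval(start, end),)
    k = int(rng.integers(1, max_exons + 1))
    if k == 1:
        return (Interval(start, end),)
    # 2k-1 alternating exon/intron segments with jittered boundaries
    bounds = np.linspace(0, length, 2 * k)
    jitter = rng.uniform(-0.3, 0.3, size=2 * k - 2) * (length / (2 * k))
    cuts = sorted(int(b + j) for b, j in zip(bounds[1:-1], jitter))
    cuts = [min(max(c, 100 * (i + 1)), length - 100 * (2 * k - 2 - i)) for i, c in enumerate(cuts)]
    points = [0] + cuts + [length]
    exons = []
    for i in range(0, len(points) - 1, 2):
        a, b = points[i], points[i + 1]
        if b <= a:
            return (Interval(start, end),)
        exons.append(Interval(start + a, start + b))
    return tuple(exons)


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    truth: dict[str, str]
    chrom_lengths: dict[str, int]
    config: ClassificationConfig
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene_id": g, "true_group": grp} for g, grp in sorted(self.truth.items())]
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gff = out_dir / "genome.gff3"
        write_gff3(self.genes, gff)
        truth = out_dir / "truth.tsv"
        self.truth_frame().to_csv(truth, sep="\t", index=False)
        sizes = out_dir / "chrom.sizes"
        with open(sizes, "w") as fh:
            for chrom, length in sorted(self.chrom_lengths.items()):
                fh.write(f"{chrom}\t{length}\n")
        return {"gff": gff, "truth": truth, "chrom_sizes": sizes}


def simulate_genome(
    quotas: Mapping[str, int],
    promoter_len: int = 1000,
    territory_dist: int = 20000,
    seed: int = 0,
    n_chroms: int = 4,
    max_chrom_length: int | None = None,
) -> SyntheticGenome:
    """Place genes in prescribed constellation configurations.

    ``quotas`` maps group labels to gene counts; paired groups (everything
    but SG) must be even since each configuration is built as an isolated
    pair.  Geometries are generated strictly inside the decision
    boundaries (e.g. territory gaps uniform in [0.2 D, 0.9 D], 5' overlaps
    well away from zero), and configurations are separated by at least
    1.5 D so they cannot interact.
    """
    P, D = promoter_len, territory_dist
    rng = np.random.default_rng(derive_seed(seed, "genome"))
    configs: list[str] = []
    for group in ("SG", "5PP", "EE", "5PI_EI", "COS", "CSS"):
        count = int(quotas.get(group, 0))
        if count < 0:
            raise ValueError(f"negative quota for {group}")
        if group == "SG":
            configs += ["SG"] * count
        else:
            if count % 2:
                raise ValueError(f"quota for paired group {group} must be even, got {count}")
            configs += [group] * (count // 2)
    unknown = set(quotas) - {"SG", "5PP", "EE", "5PI_EI", "COS", "CSS"}
    if unknown:
        raise ValueError(f"unknown groups in quotas: {sorted(unknown)}")
    rng.shuffle(configs)  # mix groups along chromosomes

    def territory_gap() -> int:
        lo = max(int(0.2 * D), 2 * P + 500)
        hi = max(lo + 1, int(0.9 * D))
        return int(rng.integers(lo, hi + 1))

    def build(group: str, origin: int) -> tuple[list[tuple[str, Interval, tuple[Interval, ...]]], int]:
        """Gene tuples (strand, span, exons) at absolute coordinates, plus extent."""
        if group == "SG":
            length = int(rng.integers(2000, 6001))
            span = Interval(origin, origin + length)
            return [(rng.choice(["+", "-"]), span, _jittered_exons(span.start, span.end, rng))], length
        if group == "5PP":
            # head-to-head: '-' gene then '+' gene, 5' regions meeting in the gap
            len_a = int(rng.integers(2000, 5001))
            gap = int(rng.integers(max(1, int(0.2 * P)), max(2, int(1.6 * P))))
            len_b = int(rng.integers(2000, 5001))
            span_a = Interval(origin, origin + len_a)
            span_b = Interval(span_a.end + gap, span_a.end + gap + len_b)
            return [
                ("-", span_a, _jittered_exons(span_a.start, span_a.end, rng)),
                ("+", span_b, _jittered_exons(span_b.start, span_b.end, rng)),
            ], span_b.end - origin
        if group == "EE":
            j = int(rng.integers(0, 801))
            span_a = Interval(origin, origin + 4000)
            exons_a = (Interval(origin, origin + 1500), Interval(origin + 2500, origin + 4000))
            span_b = Interval(origin + 3000 + j, origin + 7000 + j)
            exons_b = (
                Interval(origin + 3000 + j, origin + 4500 + j),
                Interval(origin + 6000 + j, origin + 7000 + j),
            )
            return [("+", span_a, exons_a), ("-", span_b, exons_b)], 7000 + j
        if group == "5PI_EI":
            # nested gene inside the host's long intron
            span_a = Interval(origin, origin + 30000)
            exons_a = (Interval(origin, origin + 2000), Interval(origin + 25000, origin + 30000))
            j = int(rng.integers(0, 8001))
            span_b = Interval(origin + 8000 + j, origin + 12000 + j)
            strand_b = rng.choice(["+", "-"])
            return [
                ("+", span_a, exons_a),
                (strand_b, span_b, (span_b,)),
            ], 30000
        if group in ("COS", "CSS"):
            len_a = int(rng.integers(2000, 6001))
            len_b = int(rng.integers(2000, 6001))
            gap = territory_gap()
            span_a = Interval(origin, origin + len_a)
            span_b = Interval(span_a.end + gap, span_a.end + gap + len_b)
            strand_a = rng.choice(["+", "-"])
            strand_b = ({"+": "-", "-": "+"}[strand_a]) if group == "COS" else strand_a
            return [
                (strand_a, span_a, _jittered_exons(span_a.start, span_a.end, rng)),
                (strand_b, span_b, _jittered_exons(span_b.start, span_b.end, rng)),
            ], span_b.end - origin
        raise AssertionError(group)

    margin = max(int(1.5 * D), 2 * P + 1000)
    cursors = {f"chr{i + 1}": margin for i in range(n_chroms)}
    genes: list[GeneModel] = []
    truth: dict[str, str] = {}
    counter = 0
    for idx, group in enumerate(configs):
        chrom = f"chr{(idx % n_chroms) + 1}"
        origin = cursors[chrom]
        placed, extent = build(group, origin)
        for strand, span, exons in placed:
            counter += 1
            gid = f"g{counter:05d}"
            genes.append(GeneModel(gid, chrom, strand, span, exons))
            truth[gid] = group
        cursors[chrom] = origin + extent + margin
    chrom_lengths = {c: cursor + margin for c, cursor in cursors.items()}
    if max_chrom_length is not None:
        too_long = {c: l for c, l in chrom_lengths.items() if l > max_chrom_length}
        if too_long:
            raise ValueError(f"quotas infeasible within chromosome length {max_chrom_length}: {too_long}")
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return SyntheticGenome(
        genes=genes,
        truth=truth,
        chrom_lengths=chrom_lengths,
        config=ClassificationConfig(promoter_len=P, territory_dist=D),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# toy ontology


_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


def simulate_go(
    n_terms: int = 40,
    depth: int = 4,
    n_genes: int = 200,
    n_planted_pairs: int = 10,
    terms_per_gene: int = 2,
    seed: int = 0,
) -> tuple[GoDag, AnnotationCorpus, dict]:
    """Random tree-like DAG per root plus annotations with planted pairs.

    Each root namespace receives ``n_terms`` terms attached at depths up to
    ``depth``.  Planted gene pairs share a rare deep term in every root and
    therefore have high pairwise similarity; background genes draw terms
    uniformly.  Truth records the planted pairs.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if 2 * n_planted_pairs > n_genes:
        raise ValueError("need n_genes >= 2 * n_planted_pairs")
    rng = np.random.default_rng(derive_seed(seed, "go"))
    edges: list[tuple[str, str]] = []
    namespaces: dict[str, str] = {}
    leaves_by_ns: dict[str, list[str]] = {}
    term_no = 0

    def new_term(ns: str) -> str:
        nonlocal term_no
        term_no += 1
        tid = f"GO:{term_no:07d}"
        namespaces[tid] = ns
        return tid

    depth_of: dict[str, int] = {}
    for ns in _NAMESPACES:
        root = new_term(ns)
        depth_of[root] = 0
        pool = [root]
        for _ in range(n_terms - 1):
            parent = pool[int(rng.integers(0, len(pool)))]
            if depth_of[parent] >= depth:
                parent = root
            child = new_term(ns)
            edges.append((child, parent))
            depth_of[child] = depth_of[parent] + 1
            pool.append(child)
        leaves_by_ns[ns] = [t for t in pool if depth_of[t] >= 2] or pool[1:] or pool
    dag = GoDag(edges, namespaces)

    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    direct: dict[str, set[str]] = {g: set() for g in gene_ids}
    for g in gene_ids:
        for ns in _NAMESPACES:
            picks = rng.choice(leaves_by_ns[ns], size=min(terms_per_gene, len(leaves_by_ns[ns])), replace=False)
            direct[g].update(picks)

    planted: list[tuple[str, str]] = []
    shuffled = list(gene_ids)
    rng.shuffle(shuffled)
    marker_terms = {ns: leaves_by_ns[ns][int(rng.integers(0, len(leaves_by_ns[ns])))] for ns in _NAMESPACES}
    for i in range(n_planted_pairs):
        g1, g2 = shuffled[2 * i], shuffled[2 * i + 1]
        shared = {marker_terms[ns] for ns in _NAMESPACES}
        direct[g1] = set(shared)
        direct[g2] = set(shared)
        planted.append((g1, g2))

    corpus = AnnotationCorpus(direct=direct)
    truth = {"planted_pairs": planted, "marker_terms": marker_terms}
    return dag, corpus, truth


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialise a DAG as minimal OBO 1.2 (is_a edges only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {dag.namespace(term)}\n")
            for parent in sorted(dag.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {parent}\n")


def write_annotation_table(corpus: AnnotationCorpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(corpus.direct):
            for term in sorted(corpus.direct[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# coalescent haplotypes


def simulate_haplotypes(
    n_per_pop: Sequence[int] = (10, 40),
    L: int = 1000,
    theta: float = 0.005,
    split_depth: float = 0.0,
    seed: int = 0,
    gene_id: str = "gene",
    pop_names: Sequence[str] = ("African", "American"),
) -> tuple[list[HaplotypeSample], dict]:
    """Kingman coalescent (no recombination) with infinite-sites mutations.

    Two populations coalesce only internally until ``split_depth`` (in
    coalescent time units), then merge into one ancestral pool - a clean
    split with no migration.  Mutations fall on branches at rate
    theta/2 per site, so at split depth 0 the expected number of
    segregating sites is theta * a1 * L.
    """
    if len(n_per_pop) != 2:
        raise ValueError("expected two population sizes")
    if min(n_per_pop) < 1 or theta <= 0:
        raise ValueError("need n >= 1 per population and theta > 0")
    rng = np.random.default_rng(derive_seed(seed, f"haplotypes:{gene_id}"))

    n_total = int(sum(n_per_pop))
    times = [0.0] * n_total
    parent: dict[int, int] = {}
    pops = [[i for i in range(n_per_pop[0])], [i + n_per_pop[0] for i in range(n_per_pop[1])]]
    next_node = n_total
    t = 0.0

    def coalesce(pool: list[int], now: float) -> float:
        nonlocal next_node
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        node = next_node
        next_node += 1
        times.append(now)
        parent[a] = node
        parent[b] = node
        pool.remove(a)
        pool.remove(b)
        pool.append(node)
        return now

    # island phase: independent coalescence within each population
    while t < split_depth and (len(pops[0]) > 1 or len(pops[1]) > 1):
        rates = [len(p) * (len(p) - 1) / 2.0 for p in pops]
        total_rate = sum(rates)
        if total_rate == 0:
            break
        wait = rng.exponential(1.0 / total_rate)
        if t + wait > split_depth:
            break
        t += wait
        which = 0 if rng.random() < rates[0] / total_rate else 1
        coalesce(pops[which], t)
    t = max(t, split_depth) if split_depth > 0 else t
    pool = pops[0] + pops[1]
    while len(pool) > 1:
        rate = len(pool) * (len(pool) - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        coalesce(pool, t)

    # branch lengths and leaf sets
    total_nodes = next_node
    branch = np.zeros(total_nodes)
    for node, par in parent.items():
        branch[node] = times[par] - times[node]
    leaf_sets: list[set[int]] = [set() for _ in range(total_nodes)]
    for leaf in range(n_total):
        node = leaf
        leaf_sets[leaf].add(leaf)
        while node in parent:
            node = parent[node]
            leaf_sets[node].add(leaf)

    # infinite-sites mutations mapped onto L discrete columns
    total_branch = float(branch.sum())
    n_mut = int(rng.poisson(theta / 2.0 * L * total_branch))
    if n_mut > L:
        raise ValueError(f"{n_mut} mutations exceed {L} sites; lower theta or raise L")
    carriers = np.zeros((n_total, L), dtype=bool)
    sites = rng.choice(L, size=n_mut, replace=False)
    if n_mut:
        probs = branch / total_branch
        hit_nodes = rng.choice(total_nodes, size=n_mut, p=probs)
        for site, node in zip(sites, hit_nodes):
            for leaf in leaf_sets[node]:
                carriers[leaf, site] = True

    bases = np.array(list("ACGT"))
    anc_idx = rng.integers(0, 4, size=L)
    der_idx = (anc_idx + rng.integers(1, 4, size=L)) % 4
    ancestral = bases[anc_idx]
    derived = bases[der_idx]
    seqs = []
    for leaf in range(n_total):
        row = np.where(carriers[leaf], derived, ancestral)
        seqs.append("".join(row))

    samples = [
        HaplotypeSample(gene_id, pop_names[0], seqs[: n_per_pop[0]]),
        HaplotypeSample(gene_id, pop_names[1], seqs[n_per_pop[0] :]),
    ]
    truth = {
        "theta": theta,
        "L": L,
        "split_depth": split_depth,
        "n_mutations": n_mut,
        "tmrca": times[-1] if total_nodes > n_total else 0.0,
    }
    return samples, truth


def write_haplotype_fasta(samples: Iterable[HaplotypeSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in samples:
            for i, seq in enumerate(sample.sequences, start=1):
                fh.write(f">{sample.gene_id}_{sample.population}_{i} pop={sample.population}\n")
                fh.write(seq + "\n")


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSim:
    matrix: pd.DataFrame
    sample_populations: dict[str, str]
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_r: float = 0.0
    pop_effect_sd: float = 0.0
    strain_sd: float = 1.0


def simulate_expression(
    n_genes: int = 200,
    n_samples: int = 40,
    n_planted_pairs: int = 0,
    planted_r: float = 0.8,
    pop_effect_sd: float = 0.0,
    strain_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionSim:
    """Gaussian expression with planted pair correlations and pop structure.

    Samples split evenly into populations A and B.  Each gene's values are
    pop_mean + strain noise; per-gene population means are N(0,
    pop_effect_sd^2), so the planted variance components are sigma2_b =
    pop_effect_sd^2 and sigma2_w = strain_sd^2.  Planted pairs are drawn
    bivariate-normal with correlation ``planted_r`` (no pop structure).
    """
    if abs(planted_r) >= 1:
        raise ValueError("|planted_r| must be < 1")
    rng = np.random.default_rng(derive_seed(seed, "expression"))
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    pops = {s: ("A" if j < n_samples // 2 else "B") for j, s in enumerate(samples)}

    values = np.empty((n_genes, n_samples))
    for i in range(n_genes):
        mu = {p: rng.normal(0.0, pop_effect_sd) for p in ("A", "B")}
        values[i] = [mu[pops[s]] + rng.normal(0.0, strain_sd) for s in samples]

    planted: list[tuple[str, str]] = []
    order = rng.permutation(n_genes)
    for k in range(n_planted_pairs):
        i, j = order[2 * k], order[2 * k + 1]
        z1 = rng.standard_normal(n_samples)
        z2 = planted_r * z1 + np.sqrt(1 - planted_r**2) * rng.standard_normal(n_samples)
        values[i], values[j] = z1, z2
        planted.append((genes[i], genes[j]))

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionSim(matrix, pops, planted, planted_r, pop_effect_sd, strain_sd)


# ---------------------------------------------------------------------------
# regression datasets


def simulate_regression(
    n: int = 2000,
    coefficients: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    extra_predictors: Sequence[str] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Standardized-coefficient regression dataset with planted effects.

    Generates a 0-5 ordinal constellation code, binary chromosome-class and
    GO flags, and continuous predictors; y is the sum of planted
    standardized effects plus N(0, noise_sd) noise.  ``extra_predictors``
    adds pure-noise candidate columns.  Returns (table, truth betas).
    """
    if n < 50:
        raise ValueError("need n >= 50")
    coefficients = dict(coefficients or {})
    rng = np.random.default_rng(derive_seed(seed, "regression"))

    columns: dict[str, np.ndarray] = {
        "const_code": rng.integers(0, 6, size=n).astype(float),
        "chrom_x": (rng.random(n) < 0.2).astype(float),
        "go_flag": (rng.random(n) < 0.3).astype(float),
        "recomb": rng.standard_normal(n),
    }
    for name in list(coefficients) + list(extra_predictors):
        if name not in columns:
            columns[name] = rng.standard_normal(n)

    y = rng.normal(0.0, noise_sd, size=n)
    for name, beta in coefficients.items():
        x = columns[name]
        y = y + beta * (x - x.mean()) / x.std(ddof=1)

    table = pd.DataFrame({"y": y, **columns})
    return table, dict(coefficients)
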