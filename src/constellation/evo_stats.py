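"""Per-gene evolutionary and expression correlates.

Implements the codon adaptation index (CAI), the classical neutral-theory
polymorphism summaries (Watterson's theta, pairwise nucleotide diversity,
Tajima's D), Hudson's F_ST between two population samples, Q_ST from
between/within-population variance components of expression, pairwise
expression correlation with a co-expression flag, and a rank-product test
for between-group differential expression with a permutation-based
percentage of false prediction (pfp).

Sequence statistics treat '-', 'N' and '?' as missing and exclude such
sites pairwise-complete.  Ka/Ks-style divergence values are consumed as
input columns elsewhere in the pipeline, never computed here.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CodonWeights",
    "HaplotypeSample",
    "DiversityStats",
    "cai_weights",
    "cai",
    "diversity_stats",
    "fst_hudson",
    "qst",
    "qst_pooled",
    "expression_correlation",
    "rank_product_de",
    "tajima_constants",
    "read_haplotype_fasta",
]

MISSING_CHARS = frozenset("-N?n")

_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: Codons excluded from the CAI geometric mean: the single-codon amino
#: acids Met and Trp carry no usage-bias information.
_UNINFORMATIVE = frozenset({"ATG", "TGG"}) | _STOP_CODONS


# ---------------------------------------------------------------------------
# codon adaptation index


@dataclass(frozen=True)
class CodonWeights:
    """Relative adaptiveness w per codon, max 1 within each synonymous family."""

    weights: Mapping[str, float]
    reference: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


def _codons(seq: str) -> list[str]:
    seq = str(seq).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def cai_weights(
    reference_cds: Iterable[str], reference: str = "", zero_floor: float = 0.01
) -> CodonWeights:
    """Relative adaptiveness from a reference set of in-frame CDS.

    w_c = count(c) / max count within c's synonymous family; codons unseen
    in the reference are floored at ``zero_floor`` so downstream geometric
    means stay finite.  Sequences with internal stop codons are rejected
    with a warning.
    """
    counts: dict[str, int] = {c: 0 for c in _STANDARD_TABLE}
    n_used = 0
    for seq in reference_cds:
        codons = _codons(seq)
        body = codons[:-1] if codons and codons[-1] in _STOP_CODONS else codons
        if any(c in _STOP_CODONS for c in body):
            warnings.warn("reference CDS with internal stop codon rejected")
            continue
        n_used += 1
        for c in body:
            if c in counts:
                counts[c] += 1
    if n_used == 0:
        raise ValueError("no usable reference CDS")

    families: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.items():
        families.setdefault(aa, []).append(codon)

    weights: dict[str, float] = {}
    for aa, codons in families.items():
        top = max(counts[c] for c in codons)
        for c in codons:
            if top == 0:
                weights[c] = zero_floor
            else:
                weights[c] = max(counts[c] / top, zero_floor)
    return CodonWeights(weights=weights, reference=reference or f"{n_used} reference CDS")


def cai(cds: str, weights: CodonWeights) -> float:
    """Geometric mean of codon weights, excluding Met, Trp and stop codons."""
    codons = _codons(cds)
    informative = [c for c in codons if c in _STANDARD_TABLE and c not in _UNINFORMATIVE]
    if not informative:
        raise ValueError("sequence contains no informative codons")
    logs = [math.log(weights[c]) for c in informative]
    return math.exp(sum(logs) / len(logs))


# ---------------------------------------------------------------------------
# polymorphism statistics


@dataclass
class HaplotypeSample:
    """Aligned haplotype sequences for one gene in one population."""

    gene_id: str
    population: str
    sequences: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths {sorted(lengths)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        return np.array([list(s.upper()) for s in self.sequences])


@dataclass(frozen=True)
class DiversityStats:
    theta_w: float  #: Watterson's estimator per site
    theta_pi: float  #: mean pairwise diversity per site
    tajimas_d: float | None  #: None when S = 0
    s: int  #: segregating sites


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for sample size n."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _pairwise_diffs_per_site(m1: np.ndarray, m2: np.ndarray | None = None) -> float:
    """Mean per-site difference over sequence pairs, pairwise-complete sites.

    With one matrix: all within-sample pairs.  With two: all cross pairs.
    """
    valid1 = ~np.isin(m1, list(MISSING_CHARS))
    if m2 is None:
        pairs = [(i, j) for i in range(len(m1)) for j in range(i + 1, len(m1))]
        get = lambda i, j: (m1[i], m1[j], valid1[i], valid1[j])
    else:
        valid2 = ~np.isin(m2, list(MISSING_CHARS))
        pairs = [(i, j) for i in range(len(m1)) for j in range(len(m2))]
        get = lambda i, j: (m1[i], m2[j], valid1[i], valid2[j])
    rates = []
    for i, j in pairs:
        s1, s2, v1, v2 = get(i, j)
        ok = v1 & v2
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        rates.append(float(((s1 != s2) & ok).sum()) / n_ok)
    return float(np.mean(rates)) if rates else 0.0


def _segregating_sites(m: np.ndarray) -> int:
    s = 0
    for col in m.T:
        alleles = {c for c in col if c not in MISSING_CHARS}
        if len(alleles) >= 2:
            s += 1
    return s


def diversity_stats(h: HaplotypeSample) -> DiversityStats:
    """Watterson's theta, pairwise diversity (both per site) and Tajima's D."""
    if h.n < 2:
        raise ValueError("need at least two sequences")
    m = h.matrix()
    L = h.length
    s = _segregating_sites(m)
    const = tajima_constants(h.n)
    theta_w = s / (const["a1"] * L)
    pi_site = _pairwise_diffs_per_site(m)
    if s == 0:
        return DiversityStats(0.0, 0.0, None, 0)
    k_hat = pi_site * L  # per-locus mean pairwise differences
    var = const["e1"] * s + const["e2"] * s * (s - 1)
    d = (k_hat - s / const["a1"]) / math.sqrt(var) if var > 0 else None
    return DiversityStats(theta_w, pi_site, d, s)


def fst_hudson(h1: HaplotypeSample, h2: HaplotypeSample) -> float | None:
    """Hudson's F_ST = 1 - Hw/Hb.

    Hw is the mean within-population pairwise diversity with the two
    populations weighted equally; Hb the mean between-population pairwise
    diversity.  Undefined (None) when Hb = 0.
    """
    if h1.length != h2.length:
        raise ValueError("samples must share the alignment length")
    if h1.n < 2 or h2.n < 2:
        raise ValueError("need at least two sequences per population")
    m1, m2 = h1.matrix(), h2.matrix()
    hw = 0.5 * (_pairwise_diffs_per_site(m1) + _pairwise_diffs_per_site(m2))
    hb = _pairwise_diffs_per_site(m1, m2)
    if hb == 0:
        return None
    return 1.0 - hw / hb


# ---------------------------------------------------------------------------
# quantitative differentiation


def _anova_components(
    values: Mapping[str, float], populations: Mapping[str, str]
) -> tuple[float, float]:
    """Method-of-moments (sigma2_between, sigma2_within), untruncated."""
    groups: dict[str, list[float]] = {}
    for strain, value in values.items():
        pop = populations.get(strain)
        if pop is None:
            raise KeyError(f"strain {strain} has no population assignment")
        groups.setdefault(pop, []).append(float(value))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 populations, got {len(groups)}")
    sizes = [len(v) for v in groups.values()]
    if min(sizes) < 2:
        raise ValueError("need at least two strains per population")

    arrays = [np.asarray(v) for v in groups.values()]
    n_total = sum(sizes)
    k = len(arrays)
    grand = float(np.concatenate(arrays).mean())
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - sum(s**2 for s in sizes) / n_total) / (k - 1)
    return (ms_between - ms_within) / n0, ms_within


def qst(values: Mapping[str, float], populations: Mapping[str, str]) -> float | None:
    """Q_ST = s2_b / (s2_b + 2 s2_w) from one-way random-effects ANOVA.

    Variance components are method-of-moments estimates from strain values
    grouped by population; a negative between-population component is
    truncated at zero.  Undefined (None) when the total variance is zero.

    With two populations the between component has a single degree of
    freedom, so single-gene estimates are extremely noisy and their mean
    is biased downward; use :func:`qst_pooled` for a multi-gene summary.
    """
    sigma2_b, sigma2_w = _anova_components(values, populations)
    sigma2_b = max(0.0, sigma2_b)
    denom = sigma2_b + 2.0 * sigma2_w
    if denom == 0:
        return None
    return sigma2_b / denom


def qst_pooled(
    per_gene_values: Iterable[Mapping[str, float]], populations: Mapping[str, str]
) -> float | None:
    """Q_ST from variance components averaged over genes.

    Averaging the (unbiased, untruncated) per-gene components before
    forming the ratio removes the severe small-degrees-of-freedom bias of
    the per-gene estimator; the pooled between component is truncated at
    zero at the end.
    """
    sbs, sws = [], []
    for values in per_gene_values:
        sb, sw = _anova_components(values, populations)
        sbs.append(sb)
        sws.append(sw)
    if not sbs:
        raise ValueError("no genes supplied")
    sigma2_b = max(0.0, float(np.mean(sbs)))
    sigma2_w = float(np.mean(sws))
    denom = sigma2_b + 2.0 * sigma2_w
    if denom == 0:
        return None
    return sigma2_b / denom


# ---------------------------------------------------------------------------
# expression correlation and differential expression


def expression_correlation(
    pairs: Iterable[tuple[str, str]],
    matrix: pd.DataFrame,
    min_points: int = 20,
    r_threshold: float = 0.6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation per gene pair over shared finite samples.

    A pair is flagged co-expressed when it has at least ``min_points``
    shared data points, the correlation is significant at ``alpha`` and
    |R| >= ``r_threshold``.
    """
    rows = []
    for g1, g2 in pairs:
        if g1 not in matrix.index or g2 not in matrix.index:
            raise KeyError(f"pair ({g1}, {g2}) not fully present in expression matrix")
        x = matrix.loc[g1].to_numpy(dtype=float)
        y = matrix.loc[g2].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < max(3, min_points):
            r = p = np.nan
            if n >= 3:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append(
                {"gene_a": g1, "gene_b": g2, "r": r, "p": p, "n_points": n,
                 "status": "insufficient", "coexpressed": False}
            )
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        flagged = bool(p <= alpha and abs(r) >= r_threshold)
        rows.append(
            {"gene_a": g1, "gene_b": g2, "r": float(r), "p": float(p), "n_points": n,
             "status": "ok", "coexpressed": flagged}
        )
    return pd.DataFrame(rows)


def rank_product_de(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-group rank-product differential expression.

    Values are taken as log-scale expression; the fold change of gene g in
    comparison (i, j) is a_gi - b_gj over all replicate pairs.  The rank
    product is the geometric mean of the gene's fold-change ranks; both
    orderings are scored and the better one kept, so changes in either
    direction are detected.  pfp (percentage of false prediction) is
    estimated against a permutation null in which every comparison's rank
    vector is a uniformly random permutation.
    """
    if n_perm < 10:
        raise ValueError("need n_perm >= 10")
    if not group_a.index.equals(group_b.index):
        raise ValueError("the two groups must share an identical gene index")
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need at least two replicates per group")

    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    n_genes = a.shape[0]
    rng = np.random.default_rng(seed)

    def rank_products(av: np.ndarray, bv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(RP_up, RP_down): geometric-mean fold-change ranks per direction."""
        log_up = np.zeros(n_genes)
        log_dn = np.zeros(n_genes)
        n_comp = av.shape[1] * bv.shape[1]
        for i in range(av.shape[1]):
            for j in range(bv.shape[1]):
                fold = av[:, i] - bv[:, j]
                log_up += np.log(stats.rankdata(-fold, method="average"))
                log_dn += np.log(stats.rankdata(fold, method="average"))
        return np.exp(log_up / n_comp), np.exp(log_dn / n_comp)

    obs_up, obs_dn = rank_products(a, b)

    # null rank products from gene-label permutations within each replicate
    # array; this breaks gene effects while preserving the correlation
    # between comparisons that share a replicate
    exceed_up = np.zeros(n_genes)
    exceed_dn = np.zeros(n_genes)
    for _ in range(n_perm):
        a_perm = np.column_stack([a[rng.permutation(n_genes), j] for j in range(a.shape[1])])
        b_perm = np.column_stack([b[rng.permutation(n_genes), j] for j in range(b.shape[1])])
        null_up, null_dn = rank_products(a_perm, b_perm)
        exceed_up += np.searchsorted(np.sort(null_up), obs_up, side="right")
        exceed_dn += np.searchsorted(np.sort(null_dn), obs_dn, side="right")

    def pfp(observed: np.ndarray, exceed: np.ndarray) -> np.ndarray:
        expected_fp = exceed / n_perm
        order_rank = stats.rankdata(observed, method="average")
        return expected_fp / order_rank

    pfp_up = pfp(obs_up, exceed_up)
    pfp_dn = pfp(obs_dn, exceed_dn)
    best_down = pfp_dn < pfp_up
    return pd.DataFrame(
        {
            "gene": group_a.index,
            "rp": np.where(best_down, obs_dn, obs_up),
            "direction": np.where(best_down, "down", "up"),
            "pfp_up": pfp_up,
            "pfp_down": pfp_dn,
            "pfp": np.minimum(pfp_up, pfp_dn),
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# FASTA plumbing


def read_haplotype_fasta(path: str | Path, gene_id: str | None = None) -> list[HaplotypeSample]:
    """Read haplotype alignments from FASTA, splitting on the ``pop=`` header token."""
    from Bio import SeqIO

    path = Path(path)
    gene = gene_id or path.stem
    by_pop: dict[str, list[str]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pop = "default"
        for token in record.description.split():
            if token.startswith("pop="):
                pop = token[4:]
        by_pop.setdefault(pop, []).append(str(record.seq))
    return [HaplotypeSample(gene, pop, seqs) for pop, seqs in sorted(by_pop.items())]
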