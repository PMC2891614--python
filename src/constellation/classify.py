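"""Assignment of genes to constellation groups.

Every gene is placed in exactly one group by evaluating pairwise spatial
relations with its chromosomal neighbours and keeping the highest-priority
relation found:

* ``5PP`` - the 1 kb non-coding 5' regions of the two genes overlap;
* ``EE``  - exons overlap exons (cis-NAT geometry on opposite strands);
* ``5PI_EI`` - a 5' region or exon of one gene overlaps an intron of the
  other without any exon-exon contact;
* ``COS`` / ``CSS`` - the gene spans do not overlap but lie within the
  transcriptional-territory distance (default 20 kb) of one another, on
  opposite (COS) or the same (CSS) strand;
* ``SG``  - solitary: none of the above within the territory distance.

Priority ruling is 5PP > EE > 5PI_EI > COS > CSS > SG.  A pair in which the
exons of one gene overlap both the 5' region and the exons of the other on
the opposite strand cannot be placed consistently; both members are labelled
CONFLICT and excluded from group counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import GeneModel, Interval, derive_five_prime_region

log = logging.getLogger(__name__)

__all__ = [
    "RELATIONS",
    "GROUPS",
    "DEFAULT_PRIORITY",
    "ClassificationConfig",
    "PartnerEvidence",
    "ConstellationCall",
    "pairwise_relations",
    "classify_genome",
    "sweep_territory_distance",
    "calls_to_frame",
]

#: Relation labels, in default priority order (highest first).
DEFAULT_PRIORITY: tuple[str, ...] = ("5PP", "EE", "5PI_EI", "COS", "CSS")
RELATIONS = frozenset(DEFAULT_PRIORITY)
#: All group labels a gene can end up with.
GROUPS: tuple[str, ...] = ("SG",) + DEFAULT_PRIORITY


@dataclass(frozen=True)
class ClassificationConfig:
    """Geometry thresholds and the priority-ruling order."""

    promoter_len: int = 1000
    territory_dist: int = 20000
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        if self.promoter_len < 0 or self.territory_dist < 0:
            raise ValueError("promoter_len and territory_dist must be >= 0")
        if sorted(self.priority) != sorted(DEFAULT_PRIORITY):
            raise ValueError(f"priority must be a permutation of {DEFAULT_PRIORITY}")

    def rank(self, relation: str) -> int:
        return self.priority.index(relation)


@dataclass(frozen=True)
class PartnerEvidence:
    partner_id: str
    relation: str
    #: shared bases for overlap relations; span gap in bases for COS/CSS
    bases: int


@dataclass
class ConstellationCall:
    gene_id: str
    chrom: str
    strand: str
    span: Interval
    group: str
    partners: list[PartnerEvidence] = field(default_factory=list)


def _five_prime(gene: GeneModel, config: ClassificationConfig, chrom_len: int | None) -> Interval | None:
    if config.promoter_len == 0:
        return None
    return derive_five_prime_region(gene, config.promoter_len, chrom_len)


def _features_overlap(features: Sequence[Interval], others: Sequence[Interval]) -> int:
    """Total shared bases between two sets of disjoint intervals."""
    return sum(f.overlap_length(o) for f in features for o in others)


def _evaluate_pair(
    a: GeneModel,
    b: GeneModel,
    config: ClassificationConfig,
    chrom_len: int | None = None,
) -> tuple[dict[str, int], bool]:
    """Relations between two genes plus a conflict flag.

    Returns a mapping relation -> evidence bases (overlap length, or gap
    size for COS/CSS) and whether the pair triggers the exclusion rule.
    """
    if a.chrom != b.chrom:
        return {}, False

    relations: dict[str, int] = {}
    fp_a = _five_prime(a, config, chrom_len)
    fp_b = _five_prime(b, config, chrom_len)

    if fp_a is not None and fp_b is not None:
        shared = fp_a.overlap_length(fp_b)
        if shared > 0:
            relations["5PP"] = shared

    ee = _features_overlap(a.exons, b.exons)
    if ee > 0:
        relations["EE"] = ee
    else:
        # 5' region or exon of one gene inside an intron of the other,
        # permitted only in the absence of exon-exon contact.
        intruding = 0
        if b.introns:
            feats_a = list(a.exons) + ([fp_a] if fp_a is not None else [])
            intruding += _features_overlap(feats_a, b.introns)
        if a.introns:
            feats_b = list(b.exons) + ([fp_b] if fp_b is not None else [])
            intruding += _features_overlap(feats_b, a.introns)
        if intruding > 0:
            relations["5PI_EI"] = intruding

    conflict = False
    if a.strand != b.strand and ee > 0:
        # exons of one gene covering both the partner's 5' region and exons
        a_hits_fp = fp_b is not None and _features_overlap(a.exons, [fp_b]) > 0
        b_hits_fp = fp_a is not None and _features_overlap(b.exons, [fp_a]) > 0
        conflict = a_hits_fp or b_hits_fp

    # territory relations are subordinate: only pairs with no overlap
    # relation can be chromatin co-clustering partners
    if not relations:
        if a.span.overlaps(b.span):
            # interleaved spans with no overlap relation count as gap 0
            relations["COS" if a.strand != b.strand else "CSS"] = 0
        else:
            gap = a.span.gap_to(b.span)
            if 0 < gap <= config.territory_dist:
                relations["COS" if a.strand != b.strand else "CSS"] = gap

    return relations, conflict


def pairwise_relations(
    a: GeneModel,
    b: GeneModel,
    config: ClassificationConfig | None = None,
    chrom_len: int | None = None,
) -> set[str]:
    """The set of relation labels holding between two genes."""
    if a.gene_id == b.gene_id:
        raise ValueError("pairwise_relations requires two distinct genes")
    config = config or ClassificationConfig()
    relations, _ = _evaluate_pair(a, b, config, chrom_len)
    return set(relations)


def classify_genome(
    genes: Iterable[GeneModel],
    config: ClassificationConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ConstellationCall]:
    """Classify every gene into its constellation group.

    Neighbours are scanned with a sorted sweep per chromosome; two genes can
    only relate when their spans lie within max(territory distance,
    2 x promoter length) of one another.  Output is ordered by
    (chrom, span start, gene id).
    """
    config = config or ClassificationConfig()
    ordered = sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id))
    ids = [g.gene_id for g in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids must be unique")

    calls = {
        g.gene_id: ConstellationCall(g.gene_id, g.chrom, g.strand, g.span, "SG")
        for g in ordered
    }
    conflicted: set[str] = set()
    window = max(config.territory_dist, 2 * config.promoter_len)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in ordered:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom.items():
        chrom_len = chrom_lengths.get(chrom) if chrom_lengths else None
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1 :]:
                if b.span.start > a.span.end + window:
                    break
                relations, conflict = _evaluate_pair(a, b, config, chrom_len)
                if conflict:
                    conflicted.update((a.gene_id, b.gene_id))
                for rel, bases in relations.items():
                    calls[a.gene_id].partners.append(PartnerEvidence(b.gene_id, rel, bases))
                    calls[b.gene_id].partners.append(PartnerEvidence(a.gene_id, rel, bases))

    for call in calls.values():
        if call.gene_id in conflicted:
            call.group = "CONFLICT"
        elif call.partners:
            best = min(call.partners, key=lambda p: config.rank(p.relation))
            call.group = best.relation
    if conflicted:
        log.info("excluded %d genes under the conflict rule", len(conflicted))
    return [calls[g.gene_id] for g in ordered]


def sweep_territory_distance(
    genes: Iterable[GeneModel],
    config: ClassificationConfig | None = None,
    distances: Sequence[int] = (2000, 20000, 100000, 200000),
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Re-classify the genome at each territory distance.

    Only the territory distance varies; overlap-group counts are therefore
    constant across rows, SG counts are non-increasing and COS+CSS counts
    non-decreasing with distance.
    """
    if not distances:
        raise ValueError("distances must be nonempty")
    config = config or ClassificationConfig()
    genes = list(genes)
    rows = []
    for dist in distances:
        if dist < 0:
            raise ValueError("distances must be >= 0")
        cfg = ClassificationConfig(config.promoter_len, dist, config.priority)
        calls = classify_genome(genes, cfg, chrom_lengths)
        counts = {group: 0 for group in GROUPS}
        n_conflict = 0
        for call in calls:
            if call.group == "CONFLICT":
                n_conflict += 1
            else:
                counts[call.group] += 1
        total = sum(counts.values())
        row: dict[str, float] = {"distance": dist}
        row.update({f"n_{g}": counts[g] for g in GROUPS})
        row["n_CONFLICT"] = n_conflict
        for g in GROUPS:
            row[f"frac_{g}"] = counts[g] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_frame(calls: Iterable[ConstellationCall]) -> pd.DataFrame:
    """Tabular view of calls (one row per gene) for TSV output."""
    rows = []
    for c in calls:
        partners = ",".join(sorted({p.partner_id for p in c.partners}))
        evidence = ";".join(
            f"{p.partner_id}:{p.relation}:{p.bases}" for p in c.partners
        )
        rows.append(
            {
                "gene_id": c.gene_id,
                "chrom": c.chrom,
                "start": c.span.start,
                "end": c.span.end,
                "strand": c.strand,
                "group": c.group,
                "partners": partners,
                "evidence": evidence,
            }
        )
    return pd.DataFrame(rows)
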