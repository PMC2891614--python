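"""Genome-annotation input/output and gene-model reduction.

Annotations arrive as transcript-level records (GFF3, GTF or BED12).  All
coordinates are normalised to 0-based half-open intervals internally; the
readers own the dialect arithmetic (GFF/GTF are 1-based inclusive, BED is
already 0-based half-open).  Each gene is reduced to a single representative
gene model: the transcript with the longest genomic span, ties broken by the
longest summed exon length and then by transcript identifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "GeneModel",
    "TranscriptModel",
    "GenomeAnnotation",
    "AnnotationError",
    "read_annotation",
    "collapse_to_gene_models",
    "derive_five_prime_region",
    "write_gff3",
    "read_chrom_sizes",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"interval end must exceed start: ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """True iff the intervals share at least one base."""
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "Interval") -> int:
        """Nearest-edge distance; 0 for overlapping or abutting intervals."""
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def _check_exons(span: Interval, exons: Sequence[Interval], label: str) -> tuple[Interval, ...]:
    exons = tuple(sorted(exons))
    if not exons:
        raise AnnotationError(f"{label}: no exons")
    for prev, nxt in zip(exons, exons[1:]):
        if nxt.start < prev.end:
            raise AnnotationError(f"{label}: overlapping exons {prev} and {nxt}")
    if exons[0].start != span.start or exons[-1].end != span.end:
        raise AnnotationError(
            f"{label}: exon union ({exons[0].start}, {exons[-1].end}) does not "
            f"terminate at span bounds ({span.start}, {span.end})"
        )
    return exons


@dataclass(frozen=True)
class GeneModel:
    """One gene's representative transcript on a chromosome."""

    gene_id: str
    chrom: str
    strand: str
    span: Interval
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", _check_exons(self.span, self.exons, self.gene_id))

    @property
    def tss(self) -> int:
        """Transcription start site: span.start on +, span.end on -."""
        return self.span.start if self.strand == "+" else self.span.end

    @cached_property
    def introns(self) -> tuple[Interval, ...]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(Interval(prev.end, nxt.start))
        return tuple(out)

    @property
    def exon_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    span: Interval
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", _check_exons(self.span, self.exons, self.transcript_id))

    def to_gene_model(self) -> GeneModel:
        return GeneModel(self.gene_id, self.chrom, self.strand, self.span, self.exons)


@dataclass
class GenomeAnnotation:
    """Transcript-level annotation plus optional chromosome lengths."""

    transcripts: list[TranscriptModel] = field(default_factory=list)
    chrom_lengths: dict[str, int] | None = None

    @cached_property
    def genes(self) -> list[GeneModel]:
        return collapse_to_gene_models(self)


def derive_five_prime_region(
    gene: GeneModel, length: int = 1000, chrom_length: int | None = None
) -> Interval | None:
    """The non-coding 5' region upstream of the transcription start site.

    On the + strand this is [tss - length, tss), on the - strand
    [tss, tss + length); truncated at the chromosome bounds.  Returns None
    for a zero-length region at a chromosome edge.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gene.strand == "+":
        start, end = max(0, gene.tss - length), gene.tss
    else:
        start = gene.tss
        end = gene.tss + length
        if chrom_length is not None:
            end = min(chrom_length, end)
    if end <= start:
        return None
    return Interval(start, end)


def collapse_to_gene_models(annotation: GenomeAnnotation) -> list[GeneModel]:
    """One gene model per gene: the maximum-length transcript.

    Ties on span length are broken by the largest summed exon length, then
    by the lexicographically smallest transcript id.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in annotation.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    models = []
    for gene_id, ts in by_gene.items():
        best = min(
            ts,
            key=lambda t: (-t.span.length, -sum(e.length for e in t.exons), t.transcript_id),
        )
        models.append(best.to_gene_model())
    models.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    if annotation.chrom_lengths:
        for g in models:
            limit = annotation.chrom_lengths.get(g.chrom)
            if limit is not None and g.span.end > limit:
                raise AnnotationError(
                    f"{g.gene_id}: span end {g.span.end} exceeds {g.chrom} length {limit}"
                )
    return models


# ---------------------------------------------------------------------------
# readers


def read_annotation(path: str | Path, format: str | None = None) -> GenomeAnnotation:
    """Read a GFF3, GTF or BED12 annotation into transcript models.

    Coordinates are normalised to 0-based half-open.  Records without a
    usable strand are excluded with a warning.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"gff": "gff3", "gff3": "gff3", "gtf": "gtf", "bed": "bed12", "bed12": "bed12"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    format = format.lower()
    if format == "gff3":
        transcripts = _read_gff3(path)
    elif format == "gtf":
        transcripts = _read_gtf(path)
    elif format == "bed12":
        transcripts = _read_bed12(path)
    else:
        raise ValueError(f"unsupported annotation format {format!r}")
    return GenomeAnnotation(transcripts=transcripts)


def _stranded(records: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    kept = []
    for t in records:
        if t.strand not in ("+", "-"):
            warnings.warn(
                f"transcript {t.transcript_id} (gene {t.gene_id}) has no usable strand; excluded",
                stacklevel=3,
            )
            continue
        kept.append(t)
    return kept


def _read_gff3(path: Path) -> list[TranscriptModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps line info itself
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc
    out = []
    for t in db.features_of_type(("mRNA", "transcript")):
        parents = t.attributes.get("Parent") or t.attributes.get("gene_id") or [t.id]
        exons = [Interval(e.start - 1, e.end) for e in db.children(t, featuretype="exon")]
        if not exons:
            raise AnnotationError(f"transcript {t.id} has no exons")
        span = Interval(min(e.start for e in exons), max(e.end for e in exons))
        out.append(
            TranscriptModel(
                transcript_id=t.id,
                gene_id=parents[0],
                chrom=t.seqid,
                strand=t.strand if t.strand in ("+", "-") else ".",
                span=span,
                exons=tuple(exons),
            )
        )
    return _stranded(out)


def _read_gtf(path: Path) -> list[TranscriptModel]:
    """Group GTF exon lines by transcript_id; transcript lines are optional."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc
    groups: dict[str, dict] = {}
    for e in db.features_of_type("exon"):
        tid = e.attributes.get("transcript_id", [None])[0]
        gid = e.attributes.get("gene_id", [tid])[0]
        if tid is None:
            raise AnnotationError(f"GTF exon at {e.seqid}:{e.start} lacks transcript_id")
        rec = groups.setdefault(tid, {"gene": gid, "chrom": e.seqid, "strand": e.strand, "exons": []})
        rec["exons"].append(Interval(e.start - 1, e.end))
    out = []
    for tid, rec in groups.items():
        exons = sorted(rec["exons"])
        span = Interval(exons[0].start, exons[-1].end)
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene"],
                chrom=rec["chrom"],
                strand=rec["strand"] if rec["strand"] in ("+", "-") else ".",
                span=span,
                exons=tuple(exons),
            )
        )
    return _stranded(out)


def _read_bed12(path: Path) -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 record has {len(fields)} fields")
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = tuple(Interval(start + o, start + o + s) for o, s in zip(offsets, sizes))
            span = Interval(exons[0].start, exons[-1].end)
            out.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    span=span,
                    exons=exons,
                )
            )
    return _stranded(out)


# ---------------------------------------------------------------------------
# writers


def write_gff3(
    source: GenomeAnnotation | Iterable[GeneModel] | Iterable[TranscriptModel],
    path: str | Path,
) -> None:
    """Write gene/mRNA/exon features in GFF3 (1-based inclusive coordinates)."""
    if isinstance(source, GenomeAnnotation):
        records: list[TranscriptModel] = list(source.transcripts)
    else:
        records = [
            t if isinstance(t, TranscriptModel) else TranscriptModel(
                transcript_id=f"{t.gene_id}.t1",
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                span=t.span,
                exons=t.exons,
            )
            for t in source
        ]
    records.sort(key=lambda t: (t.chrom, t.span.start, t.gene_id, t.transcript_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seen_genes: set[str] = set()
        for t in records:
            if t.gene_id not in seen_genes:
                seen_genes.add(t.gene_id)
                fh.write(
                    f"{t.chrom}\tconstellation\tgene\t{t.span.start + 1}\t{t.span.end}\t.\t"
                    f"{t.strand}\t.\tID={t.gene_id}\n"
                )
            fh.write(
                f"{t.chrom}\tconstellation\tmRNA\t{t.span.start + 1}\t{t.span.end}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for i, e in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\tconstellation\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.e{i};Parent={t.transcript_id}\n"
                )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return sizes
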