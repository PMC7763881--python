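"""Genomic coordinate primitives.

All coordinates in this package are 1-based and inclusive on both ends
(the GTF convention); BED input/output is converted at the boundary by
:mod:`allolnc.gtfio`. "Length" of a transcript always means spliced
(exonic) length, never genomic span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a named sequence.

    ``start`` and ``end`` are 1-based and both inclusive, so a single
    base is ``start == end`` and ``length == end - start + 1``.
    Strand ``"."`` means unstranded (used e.g. for TE intervals).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on {self.seq_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same seq)."""
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of overlapping bases between two intervals, strand-blind.

    Returns 0 for intervals on different sequences and for adjacent
    intervals (inclusive coordinates: [100,199] and [200,300] share no base).
    """
    if a.seq_id != b.seq_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


@dataclass
class TranscriptModel:
    """An exon-chain transcript model.

    Exons are sorted ascending, non-overlapping, and all on one
    sequence and strand. ``cds`` optionally lists the coding intervals
    (subsets of exons) for protein-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        seq_ids = {e.seq_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seq_ids) > 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple sequences")
        if len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed strands")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start <= prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Spliced (exonic) length in bp."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            out.append(
                GenomicInterval(self.seq_id, prev.end + 1, nxt.start - 1, self.strand)
            )
        return tuple(out)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Intron coordinates as a hashable chain (for exact matching)."""
        return tuple((i.start, i.end) for i in self.introns)


class IntervalIndex:
    """Overlap index over payload-carrying intervals, one tree per sequence.

    Query results are guaranteed to equal a linear scan over all inserted
    intervals (this is property-tested).
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, iv: GenomicInterval, payload: object) -> None:
        # intervaltree is half-open; shift the inclusive end by one
        self._trees.setdefault(iv.seq_id, IntervalTree()).addi(
            iv.start, iv.end + 1, payload
        )

    def query(self, iv: GenomicInterval) -> list[object]:
        tree = self._trees.get(iv.seq_id)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end + 1)]


class AnnotationSet:
    """A set of transcript models grouped by gene, with an overlap index."""

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t)
        self._index: IntervalIndex | None = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    @property
    def index(self) -> IntervalIndex:
        """Interval index over transcript spans (built lazily)."""
        if self._index is None:
            idx = IntervalIndex()
            for t in self:
                idx.add(t.span, t.transcript_id)
            self._index = idx
        return self._index

    def overlapping(self, iv: GenomicInterval) -> list[TranscriptModel]:
        """All transcripts whose span overlaps *iv* by >= 1 bp."""
        return [self.transcripts[tid] for tid in self.index.query(iv)]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        models = self.genes[gene_id]
        return GenomicInterval(
            models[0].seq_id,
            min(t.span.start for t in models),
            max(t.span.end for t in models),
            models[0].strand,
        )
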