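"""Class-code assignment of assembled transcripts against a reference.

Only the three Cuffcompare relations the identification cascade keeps are
modelled precisely:

* ``u`` — intergenic: no overlap with any reference transcript span;
* ``i`` — entirely within one intron of a reference transcript (any strand);
* ``x`` — exon-exon overlap with a reference transcript on the opposite strand;

plus ``known_match`` for an exact intron-chain match (single-exon
transcripts match a single-exon reference on the same exon) and a
catch-all ``other_overlap`` for everything else. Precedence with multiple
overlapping references: known_match > x > i > other_overlap.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from .intervals import AnnotationSet, GenomicInterval, TranscriptModel, overlap_bp

NOVEL_CODES = ("u", "i", "x")


class ClassCode(str, Enum):
    known_match = "known_match"
    u = "u"
    i = "i"
    x = "x"
    other_overlap = "other_overlap"


def _exon_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += overlap_bp(ea, eb)
    return total


def _same_exon_chain(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.strand != b.strand or a.seq_id != b.seq_id:
        return False
    if a.n_exons != b.n_exons:
        return False
    if a.n_exons == 1:
        return (a.span.start, a.span.end) == (b.span.start, b.span.end)
    # multi-exon transcripts match on the intron chain (Cuffcompare "=")
    return a.intron_chain == b.intron_chain


def assign_class_code(t: TranscriptModel, ref: AnnotationSet) -> ClassCode:
    """Classify transcript *t* relative to the reference annotation."""
    hits = ref.overlapping(t.span)
    if not hits:
        return ClassCode.u
    best = ClassCode.other_overlap
    rank = {ClassCode.known_match: 3, ClassCode.x: 2, ClassCode.i: 1, ClassCode.other_overlap: 0}
    for r in hits:
        if _same_exon_chain(t, r):
            return ClassCode.known_match
        code = ClassCode.other_overlap
        if _exon_overlap_bp(t, r) > 0:
            if t.strand != r.strand and "." not in (t.strand, r.strand):
                code = ClassCode.x
        else:
            if any(intron.contains(t.span) for intron in r.introns):
                code = ClassCode.i
        if rank[code] > rank[best]:
            best = code
    return best


def extract_novel(
    transcripts: list[TranscriptModel],
    ref: AnnotationSet,
    min_length: int = 200,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Select novel long transcripts: class code u/i/x and spliced length
    >= ``min_length`` (200 bp by default, boundary inclusive).

    Returns the surviving transcripts plus a per-transcript audit table
    with columns ``class_code`` and ``removal_step`` (one of
    ``class_code_filter``, ``length_filter``, or ``retained``).
    """
    rows = []
    kept = []
    for t in transcripts:
        code = assign_class_code(t, ref)
        if code.value not in NOVEL_CODES:
            step = "class_code_filter"
        elif t.length < min_length:
            step = "length_filter"
        else:
            step = "retained"
            kept.append(t)
        rows.append({"transcript_id": t.transcript_id, "class_code": code.value, "removal_step": step})
    audit = pd.DataFrame(rows).set_index("transcript_id")
    return kept, audit
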