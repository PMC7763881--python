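"""Readers and writers for GTF, BED, FASTA and the count-matrix TSV pair.

GTF is parsed as a tab table with an attribute column; only ``exon`` and
``CDS`` rows are consumed, grouped into :class:`~allolnc.intervals.TranscriptModel`
objects. BED is 0-based half-open on disk and converted to the package's
1-based inclusive convention on read (and back on write).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import AnnotationSet, GenomicInterval, TranscriptModel

GROUPS = ("CC", "HH", "F1", "S14")

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _parse_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read a GTF file into an :class:`AnnotationSet`.

    Requires ``transcript_id`` and ``gene_id`` attributes on every exon
    row; raises :class:`FormatError` naming the offending line otherwise.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab fields")
            seq_id, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_attributes(attr)
            if "transcript_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing transcript_id attribute")
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            tid = attrs["transcript_id"]
            gene_of[tid] = attrs["gene_id"]
            iv = GenomicInterval(seq_id, int(start), int(end), strand)
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, ivs in exons.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of[tid],
                exons=tuple(ivs),
                cds=tuple(sorted(cds.get(tid, []), key=lambda c: c.start)),
            )
        )
    return AnnotationSet(models)


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "allolnc") -> None:
    with open(path, "w") as fh:
        for t in sorted(annotation, key=lambda t: (t.seq_id, t.span.start, t.transcript_id)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for feature, ivs in (("exon", t.exons), ("CDS", t.cds)):
                for iv in ivs:
                    fh.write(
                        "\t".join(
                            [
                                iv.seq_id,
                                source,
                                feature,
                                str(iv.start),
                                str(iv.end),
                                ".",
                                iv.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED (0-based half-open) file into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: BED start >= end")
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-"):
                strand = "."
            out.append(GenomicInterval(chrom, start + 1, end, strand))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start - 1}\t{iv.end}\t.\t0\t{iv.strand}\n")


def open_fasta(path: str | Path) -> Fasta:
    return Fasta(str(path), sequence_always_upper=True)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcript_sequence(fasta: Fasta, t: TranscriptModel) -> str:
    """Spliced, strand-aware transcript sequence (5'->3' on its own strand)."""
    parts = [str(fasta[t.seq_id][e.start - 1 : e.end]) for e in t.exons]
    seq = "".join(parts).upper()
    return revcomp(seq) if t.strand == "-" else seq


@dataclass
class CountMatrix:
    """Features x samples read counts with spliced lengths and a design.

    ``design`` maps sample name -> (group, replicate index); groups are the
    four study conditions CC, HH (parents), F1 (hybrid), S14 (allotetraploid).
    """

    counts: pd.DataFrame  # index = feature_id, columns = sample names
    lengths: pd.Series  # index = feature_id, bp
    design: pd.DataFrame  # index = sample, columns = [group, replicate]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = list(self.lengths.index[self.lengths.isna()][:5])
            raise ValueError(f"features without length: {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("non-positive feature length")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design entry: {sorted(missing)}")
        unknown = set(self.design["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in design: {sorted(unknown)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        sel = self.design[self.design["group"] == group]
        return list(sel.sort_values("replicate").index)

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[feature_ids].copy(),
            lengths=self.lengths.loc[feature_ids].copy(),
            design=self.design.copy(),
        )


def write_counts(cm: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.to_csv(counts_path, sep="\t", index_label="feature_id")
    cm.design.to_csv(design_path, sep="\t", index_label="sample")


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    tab = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    lengths = tab["length"]
    counts = tab.drop(columns=["length"])
    return CountMatrix(counts=counts, lengths=lengths, design=design)


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
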