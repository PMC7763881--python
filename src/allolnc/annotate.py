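"""Positional classification, TE flagging, subgenome and collinearity.

Identified lncRNA-genes are classified against the protein-coding
annotation (sense / antisense / intronic / intergenic, in that
precedence), flagged as TE-derived on >= 10 bp exonic overlap with a
transposable-element interval, assigned to a subgenome by chromosome
name prefix (H../C..), and paired between subgenomes by reciprocal-best
k-mer similarity chained into collinear blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    IntervalIndex,
    TranscriptModel,
    overlap_bp,
)

CATEGORIES = ("intergenic", "sense", "antisense", "intronic")


def classify_position(lnc: TranscriptModel, pcgs: AnnotationSet) -> str:
    """Positional category of a lncRNA relative to protein-coding genes.

    sense: >= 1 bp exonic overlap with a PCG exon on the same strand;
    antisense: exonic overlap on the opposite strand only;
    intronic: span fully inside one PCG intron with no exonic overlap;
    intergenic: otherwise. Among several qualifying PCGs the largest
    overlap defines the relation (ties to the lexicographically smaller
    gene_id), but category precedence sense > antisense > intronic wins
    regardless of overlap size.
    """
    hits = pcgs.overlapping(lnc.span)
    best = {"sense": (0, ""), "antisense": (0, "")}
    intronic = False
    for ref in hits:
        exonic = 0
        for le in lnc.exons:
            for re_ in ref.exons:
                exonic += overlap_bp(le, re_)
        if exonic > 0:
            key = "sense" if ref.strand == lnc.strand else "antisense"
            if exonic > best[key][0] or (
                exonic == best[key][0] and best[key][0] > 0 and ref.gene_id < best[key][1]
            ):
                best[key] = (exonic, ref.gene_id)
        elif any(intron.contains(lnc.span) for intron in ref.introns):
            intronic = True
    if best["sense"][0] > 0:
        return "sense"
    if best["antisense"][0] > 0:
        return "antisense"
    if intronic:
        return "intronic"
    return "intergenic"


def flag_te_derived(
    lnc: TranscriptModel, te_index: IntervalIndex, min_bp: int = 10
) -> tuple[int, bool]:
    """Maximum single-TE overlap with the lncRNA's exons; TE-derived at
    >= ``min_bp`` (study rule: 10 bp). TE strand is ignored."""
    best = 0
    for exon in lnc.exons:
        for te in te_index.query(exon):
            ov = sum(overlap_bp(exon2, te) for exon2 in lnc.exons)
            best = max(best, ov)
    return best, best >= min_bp


def build_te_index(te_intervals: list[GenomicInterval]) -> IntervalIndex:
    idx = IntervalIndex()
    for te in te_intervals:
        idx.add(te, te)
    return idx


def assign_subgenome(seq_id: str) -> str:
    """Subgenome by chromosome-name prefix: H.. -> subH, C.. -> subC,
    anything else (scaffolds) -> unplaced."""
    if seq_id.startswith("H"):
        return "subH"
    if seq_id.startswith("C"):
        return "subC"
    return "unplaced"


# ---------------------------------------------------------------------------
# Homoeologous pairing and collinear blocks


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_jaccard(a: str, b: str, k: int = 11) -> float:
    sa, sb = _kmer_set(a.upper(), k), _kmer_set(b.upper(), k)
    if not sa or not sb:
        return 0.0
    inter = len(sa & sb)
    return inter / (len(sa) + len(sb) - inter)


@dataclass
class CollinearBlock:
    block_id: int
    h_chrom: str
    c_chrom: str
    orientation: str  # "same" or "reversed"
    pairs: list[tuple[str, str]]  # (H feature, C feature) in H order


def find_homoeologous_pairs(
    sequences: dict[str, str],
    positions: dict[str, GenomicInterval],
    k: int = 11,
    min_sim: float = 0.2,
    min_anchors: int = 4,
    max_gap: int = 25,
) -> tuple[list[tuple[str, str]], list[CollinearBlock]]:
    """Two-stage homoeolog detection between subH and subC features.

    Stage 1: reciprocal best match by shared-k-mer Jaccard similarity,
    keeping one-to-one optimal matches with similarity >= ``min_sim``.
    Stage 2: anchors on each chromosome pair are sorted by H position and
    chained into runs whose C ranks are monotone (either orientation)
    with rank gaps <= ``max_gap``; blocks with >= ``min_anchors`` anchors
    are kept and only their member pairs are reported.
    """
    h_ids = [i for i in sequences if assign_subgenome(positions[i].seq_id) == "subH"]
    c_ids = [i for i in sequences if assign_subgenome(positions[i].seq_id) == "subC"]
    if not h_ids or not c_ids:
        return [], []
    h_kmers = {i: _kmer_set(sequences[i].upper(), k) for i in h_ids}
    c_kmers = {i: _kmer_set(sequences[i].upper(), k) for i in c_ids}

    def best_match(src_kmers, dst_kmers):
        out = {}
        for sid, sk in src_kmers.items():
            best_id, best_sim = None, 0.0
            for did, dk in dst_kmers.items():
                if not sk or not dk:
                    continue
                inter = len(sk & dk)
                if inter == 0:
                    continue
                sim = inter / (len(sk) + len(dk) - inter)
                if sim > best_sim or (sim == best_sim and (best_id is None or did < best_id)):
                    best_id, best_sim = did, sim
            if best_id is not None and best_sim >= min_sim:
                out[sid] = (best_id, best_sim)
        return out

    h2c = best_match(h_kmers, c_kmers)
    c2h = best_match(c_kmers, h_kmers)
    anchors = [
        (h, c) for h, (c, _s) in h2c.items() if c in c2h and c2h[c][0] == h
    ]

    # group anchors by (H chromosome, C chromosome)
    by_pair: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for h, c in anchors:
        key = (positions[h].seq_id, positions[c].seq_id)
        by_pair.setdefault(key, []).append((h, c))

    blocks: list[CollinearBlock] = []
    kept_pairs: list[tuple[str, str]] = []
    for (h_chrom, c_chrom), pair_list in sorted(by_pair.items()):
        pair_list.sort(key=lambda hc: positions[hc[0]].start)
        c_rank_order = sorted(pair_list, key=lambda hc: positions[hc[1]].start)
        c_rank = {hc: r for r, hc in enumerate(c_rank_order)}
        for direction in (+1, -1):
            run: list[tuple[str, str]] = []
            used = set()
            for hc in pair_list:
                if hc in used:
                    continue
                if not run:
                    run = [hc]
                    continue
                step = (c_rank[hc] - c_rank[run[-1]]) * direction
                if 0 < step <= max_gap:
                    run.append(hc)
                else:
                    if len(run) >= min_anchors:
                        blocks.append(
                            CollinearBlock(
                                len(blocks), h_chrom, c_chrom,
                                "same" if direction > 0 else "reversed", run,
                            )
                        )
                        used.update(run)
                    run = [hc]
            if len(run) >= min_anchors:
                blocks.append(
                    CollinearBlock(
                        len(blocks), h_chrom, c_chrom,
                        "same" if direction > 0 else "reversed", run,
                    )
                )
                used.update(run)
            if used:
                break  # one orientation per chromosome pair suffices
        # pairs inside kept blocks only
    seen: set[str] = set()
    for blk in blocks:
        for h, c in blk.pairs:
            if h not in seen and c not in seen:
                kept_pairs.append((h, c))
                seen.add(h)
                seen.add(c)
    return kept_pairs, blocks


# ---------------------------------------------------------------------------
# Record assembly and density table


@dataclass
class LncRNARecord:
    gene_id: str
    category: str
    te_overlap_bp: int
    te_derived: bool
    subgenome: str
    homoeolog_partner: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")
        if self.te_derived != (self.te_overlap_bp >= 10):
            raise ValueError("te_derived flag inconsistent with overlap")


def annotate_lncrna_genes(
    lnc_genes: dict[str, TranscriptModel],
    pcgs: AnnotationSet,
    te_intervals: list[GenomicInterval],
    sequences: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[CollinearBlock]]:
    """Build the per-gene record table. ``lnc_genes`` maps gene_id to a
    representative transcript; ``sequences`` (gene_id -> spliced
    sequence) enables homoeolog detection when provided."""
    te_index = build_te_index(te_intervals)
    records = {}
    for gid, rep in lnc_genes.items():
        ov, derived = flag_te_derived(rep, te_index)
        records[gid] = LncRNARecord(
            gene_id=gid,
            category=classify_position(rep, pcgs),
            te_overlap_bp=ov,
            te_derived=derived,
            subgenome=assign_subgenome(rep.seq_id),
        )
    blocks: list[CollinearBlock] = []
    if sequences:
        positions = {gid: rep.span for gid, rep in lnc_genes.items()}
        seqs = {gid: sequences[gid] for gid in lnc_genes if gid in sequences}
        pairs, blocks = find_homoeologous_pairs(seqs, positions)
        for h, c in pairs:
            records[h].homoeolog_partner = c
            records[c].homoeolog_partner = h
    table = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "category": r.category,
                "te_overlap_bp": r.te_overlap_bp,
                "te_derived": r.te_derived,
                "subgenome": r.subgenome,
                "homoeolog_partner": r.homoeolog_partner or "",
            }
            for r in records.values()
        ]
    ).set_index("gene_id")
    return table, blocks


def density_table(
    chrom_lengths: dict[str, int],
    lnc_genes: dict[str, TranscriptModel],
    pcgs: AnnotationSet,
    te_intervals: list[GenomicInterval],
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Per-100-kb feature density along each chromosome (circos-style):
    counts of lncRNA genes, PCG genes and TE intervals whose start falls
    in each bin."""
    rows = []
    pcg_starts: dict[str, list[int]] = {}
    for gid in pcgs.genes:
        span = pcgs.gene_span(gid)
        pcg_starts.setdefault(span.seq_id, []).append(span.start)
    lnc_starts: dict[str, list[int]] = {}
    for rep in lnc_genes.values():
        lnc_starts.setdefault(rep.seq_id, []).append(rep.span.start)
    te_starts: dict[str, list[int]] = {}
    for te in te_intervals:
        te_starts.setdefault(te.seq_id, []).append(te.start)
    for chrom, length in sorted(chrom_lengths.items()):
        edges = np.arange(0, length + bin_size, bin_size)
        for source, name in ((lnc_starts, "lncrna"), (pcg_starts, "pcg"), (te_starts, "te")):
            counts, _ = np.histogram(source.get(chrom, []), bins=edges)
            for b, n in enumerate(counts):
                rows.append({"chrom": chrom, "bin_start": int(edges[b]) + 1, "feature": name, "count": int(n)})
    tab = pd.DataFrame(rows)
    return tab.pivot_table(
        index=["chrom", "bin_start"], columns="feature", values="count", fill_value=0
    ).reset_index()
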