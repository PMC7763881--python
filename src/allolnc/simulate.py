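"""Synthetic two-subgenome genome, annotation and count generator.

Emulates the study design at desk scale: a 19-chromosome allotetraploid
genome (12 H-subgenome + 7 C-subgenome chromosomes), protein-coding
genes carrying real ATG..stop ORFs drawn from a codon-usage table,
planted noncoding transcripts of the four positional categories
(intergenic / sense / antisense / intronic), TE intervals enriched near
chromosome midpoints, homoeologous gene and lincRNA pairs at collinear
positions on paired chromosomes, and negative-binomial counts for the
four sample groups (CC, HH parents; F1 hybrid; S14 allotetraploid) with
planted parental differences, hybridization activation, additive /
non-additive inheritance and species-specific expression.

Every random artifact draws from its own stream spawned from the master
seed, so the same seed reproduces every file byte for byte.

Positional-category construction notes: "sense" lncRNAs are planted at
convergent gene pairs so that they overlap one gene's 3' UTR exon on the
same strand (making them positionally sense) and the other gene's 3' UTR
exon on the opposite strand (giving them class code "x" so they survive
novel-transcript extraction). All planted overlaps fall in UTR sequence,
never in CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gtfio import CountMatrix, revcomp
from .intervals import AnnotationSet, GenomicInterval, TranscriptModel, overlap_bp

BASES = np.frombuffer(b"ACGT", dtype="S1")
#: AT-rich intergenic background composition (plant-genome-like).
BACKGROUND_P = np.array([0.32, 0.18, 0.18, 0.32])

STOPS = {"TAA", "TAG", "TGA"}
#: Stylized codon-usage table: all 61 sense codons, weighted toward A/T
#: in the wobble position as in AT-rich plant genomes.
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]
CODON_WEIGHTS = np.array([1.25 if c[2] in "AT" else 0.75 for c in SENSE_CODONS])
CODON_WEIGHTS = CODON_WEIGHTS / CODON_WEIGHTS.sum()

GROUP_ORDER = ("CC", "HH", "F1", "S14")


class CapacityError(ValueError):
    """Requested features exceed genome capacity."""


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the package's study conditions."""

    seed: int = 0
    n_chrom_h: int = 12
    n_chrom_c: int = 7
    chrom_length: int = 500_000
    n_coding_genes: int = 1500
    #: planted lncRNA transcripts per positional category
    #: (intergenic, sense, antisense, intronic)
    n_lncrna: tuple[int, int, int, int] = (120, 100, 45, 15)
    n_te: int = 1200
    #: fraction of standalone genes on paired chromosomes with a collinear
    #: homoeolog copy on the partner chromosome
    homoeolog_fraction: float = 0.6
    #: collinear lincRNA homoeolog pairs, spread over the first paired
    #: chromosomes (>= min_anchors per chromosome pair)
    n_lnc_homoeolog_pairs: int = 20
    lnc_pairs_per_chrom: int = 5
    mutation_rate: float = 0.03
    #: probability a (non-paired) lincRNA locus carries a second isoform
    isoform_prob: float = 0.25
    # decoy novel transcripts exercising each cascade filter
    n_decoy_coding: int = 40
    n_decoy_monoexon: int = 20
    n_decoy_lowexpr: int = 20
    # expression model
    n_reps: int = 3
    dispersion: float = 0.02
    base_log_mean: float = float(np.log(40.0))
    base_log_sd: float = 1.8
    min_planted_mean: float = 8.0
    frac_parent_diff: float = 0.15
    parent_delta: tuple[float, float] = (2.5, 4.0)
    frac_species_specific: float = 0.03
    frac_nonadditive_f1: float = 0.22
    frac_nonadditive_s14: float = 0.021
    nonadd_delta: tuple[float, float] = (2.5, 4.0)
    #: probability a non-additive F1 feature is up- (not down-) regulated;
    #: hybridization predominantly activates lncRNAs
    f1_up_bias: float = 0.85
    s14_up_bias: float = 0.5
    library_size_range: tuple[float, float] = (0.85, 1.15)
    # cis-regulation + GO layer
    #: PCGs within this distance of a DE lncRNA inherit its expression
    #: pattern (cis-regulation emulation) and the marker GO term
    cis_window: int = 10_000
    n_go_terms: int = 30
    marker_term: str = "GO:0009999"

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in (
            "homoeolog_fraction",
            "frac_parent_diff",
            "frac_species_specific",
            "frac_nonadditive_f1",
            "frac_nonadditive_s14",
            "f1_up_bias",
            "s14_up_bias",
            "isoform_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        counts = (
            self.n_chrom_h, self.n_chrom_c, self.n_coding_genes, self.n_te,
            *self.n_lncrna, self.n_lnc_homoeolog_pairs,
            self.n_decoy_coding, self.n_decoy_monoexon, self.n_decoy_lowexpr,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be >= 0")
        n_hosts = 2 * self.n_lncrna[1] + self.n_lncrna[2] + self.n_lncrna[3]
        if self.n_coding_genes < n_hosts:
            raise ValueError(
                f"n_coding_genes={self.n_coding_genes} cannot host "
                f"{n_hosts} sense/antisense/intronic host genes"
            )


# ---------------------------------------------------------------------------
# Sequence helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n, p=BACKGROUND_P).tobytes().decode()


def _coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=CODON_WEIGHTS)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _longest_orf_len(seq: str) -> int:
    from .coding import find_longest_orf

    return find_longest_orf(seq)[0]


def _noncoding_seq(rng: np.random.Generator, n: int, max_orf: int = 297) -> str:
    """Background-composition sequence with no ORF of >= 100 codons."""
    for _ in range(200):
        seq = _random_seq(rng, n)
        if _longest_orf_len(seq) <= max_orf:
            return seq
    raise RuntimeError("could not draw an ORF-free sequence")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        arr[hit] = rng.choice(BASES, size=n_hit)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Locus builders. A locus is a self-contained stretch of sequence with
# local-coordinate transcripts; chromosomes are laid out locus by locus.


@dataclass
class _LocalTranscript:
    transcript_id: str
    gene_id: str
    exons: list[tuple[int, int]]  # local, 0-based inclusive
    strand: str
    kind: str  # coding_ref | lncrna | decoy_coding | decoy_monoexon | decoy_lowexpr
    category: str = ""  # for lncrna
    cds: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class _Locus:
    seq: str
    transcripts: list[_LocalTranscript]
    tag: str = ""  # shared loci carry a pairing tag


def _split_exons(
    rng: np.random.Generator,
    total: int,
    n_exons: int,
    first_min: int,
    last_min: int,
) -> list[int]:
    """Partition `total` nt into exon lengths with floor constraints."""
    floors = [first_min] + [30] * (n_exons - 2) + [last_min]
    if sum(floors) > total:
        return [total] if n_exons == 1 else [first_min, total - first_min]
    spare = total - sum(floors)
    cuts = np.sort(rng.integers(0, spare + 1, size=n_exons - 1))
    extra = np.diff(np.concatenate([[0], cuts, [spare]]))
    return [f + int(e) for f, e in zip(floors, extra)]


def _assemble(
    rng: np.random.Generator,
    transcript_seq: str,
    exon_lengths: list[int],
    intron_range: tuple[int, int] = (100, 400),
    forced_first_intron: int | None = None,
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """Interleave exon slices of `transcript_seq` with background introns.

    Returns (genomic local seq, exon coords, exon transcript-offset map).
    """
    parts = []
    exons = []
    offsets = []
    pos = 0
    t_off = 0
    for i, elen in enumerate(exon_lengths):
        if i > 0:
            ilen = (
                forced_first_intron
                if (i == 1 and forced_first_intron is not None)
                else int(rng.integers(*intron_range))
            )
            parts.append(_random_seq(rng, ilen))
            pos += ilen
        parts.append(transcript_seq[t_off : t_off + elen])
        exons.append((pos, pos + elen - 1))
        offsets.append((t_off, t_off + elen - 1))
        pos += elen
        t_off += elen
    return "".join(parts), exons, offsets


def _map_cds(
    cds_t: tuple[int, int],
    exons: list[tuple[int, int]],
    offsets: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate CDS range onto genomic exon pieces."""
    out = []
    for (gs, ge), (ts, te) in zip(exons, offsets):
        lo, hi = max(cds_t[0], ts), min(cds_t[1], te)
        if lo <= hi:
            out.append((gs + (lo - ts), gs + (hi - ts)))
    return out


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    strand: str = "+",
    forced_first_intron: int | None = None,
    n_exons: int | None = None,
) -> _Locus:
    utr5 = int(rng.integers(40, 81))
    utr3 = int(rng.integers(60, 121))
    n_codons = int(rng.integers(112, 252))
    cds = _coding_seq(rng, n_codons)
    tseq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    if n_exons is None:
        n_exons = int(rng.integers(2, 6))
    lengths = _split_exons(rng, len(tseq), n_exons, utr5 + 20, utr3 + 20)
    gseq, exons, offsets = _assemble(rng, tseq, lengths, forced_first_intron=forced_first_intron)
    cds_t = (utr5, utr5 + len(cds) - 1)
    cds_plus = _map_cds(cds_t, exons, offsets)
    if strand == "-":
        # mirror the layout so the transcript reads right-to-left
        n = len(gseq)
        gseq = revcomp(gseq)
        exons = sorted((n - 1 - e, n - 1 - s) for s, e in exons)
        cds_g = sorted((n - 1 - e, n - 1 - s) for s, e in cds_plus)
    else:
        cds_g = cds_plus
    t = _LocalTranscript(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        exons=exons,
        strand=strand,
        kind="coding_ref",
        cds=cds_g,
    )
    return _Locus(seq=gseq, transcripts=[t])


def _build_lincrna(
    rng: np.random.Generator, gene_id: str, n_isoforms: int = 1
) -> _Locus:
    tlen = int(rng.integers(300, 1200))
    n_exons = int(rng.integers(2, 5))
    strand = "+" if rng.random() < 0.5 else "-"
    tseq = _noncoding_seq(rng, tlen)
    lengths = _split_exons(rng, tlen, n_exons, 60, 60)
    gseq, exons, _ = _assemble(rng, tseq, lengths)
    if strand == "-":
        n = len(gseq)
        gseq = revcomp(gseq)
        exons = sorted((n - 1 - e, n - 1 - s) for s, e in exons)
    transcripts = [
        _LocalTranscript(f"{gene_id}.t1", gene_id, exons, strand, "lncrna", "intergenic")
    ]
    if n_isoforms > 1:
        # second isoform trims the outermost exon by 50 bp (same gene locus)
        iso = [list(e) for e in exons]
        if strand == "+":
            iso[0][0] += 50
        else:
            iso[-1][1] -= 50
        iso_t = [tuple(e) for e in iso]
        if sum(e - s + 1 for s, e in iso_t) >= 200:
            transcripts.append(
                _LocalTranscript(f"{gene_id}.t2", gene_id, iso_t, strand, "lncrna", "intergenic")
            )
    return _Locus(seq=gseq, transcripts=transcripts)


def _stamp(seq: str, start: int, piece: str) -> str:
    return seq[:start] + piece + seq[start + len(piece) :]


def _build_sense_unit(rng: np.random.Generator, uid: int, chrom_tag: str) -> _Locus:
    """Convergent gene pair with a sense lncRNA bridging their 3' UTRs."""
    g1 = _build_gene(rng, f"gene-{chrom_tag}-S{uid}a", strand="+")
    g2 = _build_gene(rng, f"gene-{chrom_tag}-S{uid}b", strand="-")
    gap = 400
    seq = g1.seq + _random_seq(rng, gap) + g2.seq
    off2 = len(g1.seq) + gap
    for t in g2.transcripts:
        t.exons = [(s + off2, e + off2) for s, e in t.exons]
        t.cds = [(s + off2, e + off2) for s, e in t.cds]
    g1_last_end = g1.transcripts[0].exons[-1][1]
    g2_first_start = g2.transcripts[0].exons[0][0]
    exon1 = (g1_last_end - 59, g1_last_end + 120)  # 60 bp same-strand overlap
    exon2 = (g2_first_start - 50, g2_first_start + 29)  # 30 bp opposite-strand
    lnc_len = (exon1[1] - exon1[0] + 1) + (exon2[1] - exon2[0] + 1)
    lnc_seq = _noncoding_seq(rng, lnc_len)
    seq = _stamp(seq, exon1[0], lnc_seq[: exon1[1] - exon1[0] + 1])
    seq = _stamp(seq, exon2[0], lnc_seq[exon1[1] - exon1[0] + 1 :])
    lnc = _LocalTranscript(
        f"novel-{chrom_tag}-SEN{uid}.t1",
        f"novel-{chrom_tag}-SEN{uid}",
        [exon1, exon2],
        "+",
        "lncrna",
        "sense",
    )
    return _Locus(seq=seq, transcripts=[*g1.transcripts, *g2.transcripts, lnc])


def _build_antisense_unit(rng: np.random.Generator, uid: int, chrom_tag: str) -> _Locus:
    host = _build_gene(rng, f"gene-{chrom_tag}-A{uid}", strand="+")
    tail = 450
    seq = host.seq + _random_seq(rng, tail)
    e = host.transcripts[0].exons[-1][1]
    exon1 = (e - 59, e + 140)  # 60 bp overlap with host 3' UTR exon
    exon2 = (e + 291, e + 390)
    lnc_len = (exon1[1] - exon1[0] + 1) + (exon2[1] - exon2[0] + 1)
    lnc_seq = _noncoding_seq(rng, lnc_len)  # 5'->3' on the minus strand
    genomic = revcomp(lnc_seq)
    seq = _stamp(seq, exon1[0], genomic[: exon1[1] - exon1[0] + 1])
    seq = _stamp(seq, exon2[0], genomic[exon1[1] - exon1[0] + 1 :])
    lnc = _LocalTranscript(
        f"novel-{chrom_tag}-AS{uid}.t1",
        f"novel-{chrom_tag}-AS{uid}",
        [exon1, exon2],
        "-",
        "lncrna",
        "antisense",
    )
    return _Locus(seq=seq, transcripts=[*host.transcripts, lnc])


def _build_intronic_unit(rng: np.random.Generator, uid: int, chrom_tag: str) -> _Locus:
    host = _build_gene(
        rng, f"gene-{chrom_tag}-I{uid}", strand="+", forced_first_intron=600, n_exons=2
    )
    host_t = host.transcripts[0]
    intron_start = host_t.exons[0][1] + 1
    exon1 = (intron_start + 50, intron_start + 249)
    exon2 = (intron_start + 330, intron_start + 449)
    strand = "+" if rng.random() < 0.5 else "-"
    lnc_len = 320
    lnc_seq = _noncoding_seq(rng, lnc_len)
    genomic = lnc_seq if strand == "+" else revcomp(lnc_seq)
    seq = _stamp(host.seq, exon1[0], genomic[:200])
    seq = _stamp(seq, exon2[0], genomic[200:])
    lnc = _LocalTranscript(
        f"novel-{chrom_tag}-IN{uid}.t1",
        f"novel-{chrom_tag}-IN{uid}",
        [exon1, exon2],
        strand,
        "lncrna",
        "intronic",
    )
    return _Locus(seq=seq, transcripts=[host_t, lnc])


def _build_decoy(rng: np.random.Generator, uid: int, chrom_tag: str, kind: str) -> _Locus:
    if kind == "decoy_coding":
        n_codons = int(rng.integers(140, 240))
        tseq = _random_seq(rng, 30) + _coding_seq(rng, n_codons) + _random_seq(rng, 40)
        lengths = _split_exons(rng, len(tseq), 2, 60, 60)
        gseq, exons, _ = _assemble(rng, tseq, lengths)
        tid = f"novel-{chrom_tag}-DC{uid}"
    elif kind == "decoy_monoexon":
        tlen = int(rng.integers(300, 800))
        gseq = _noncoding_seq(rng, tlen)
        exons = [(0, tlen - 1)]
        tid = f"novel-{chrom_tag}-DM{uid}"
    else:  # decoy_lowexpr
        tlen = int(rng.integers(300, 900))
        tseq = _noncoding_seq(rng, tlen)
        lengths = _split_exons(rng, tlen, 2, 60, 60)
        gseq, exons, _ = _assemble(rng, tseq, lengths)
        tid = f"novel-{chrom_tag}-DL{uid}"
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        # mirror so the designed transcript reads 5'->3' on the minus strand
        n = len(gseq)
        gseq = revcomp(gseq)
        exons = sorted((n - 1 - e, n - 1 - s) for s, e in exons)
    t = _LocalTranscript(f"{tid}.t1", tid, exons, strand, kind)
    return _Locus(seq=gseq, transcripts=[t])


def _mutate_locus(rng: np.random.Generator, locus: _Locus, rate: float, new_ids: dict[str, str]) -> _Locus:
    """Homoeolog copy: mutate the sequence, repair CDS stops, keep lncRNAs
    ORF-free; transcript/gene ids are remapped via `new_ids`."""
    for _ in range(10):
        seq = _mutate(rng, locus.seq, rate)
        # repair coding transcripts: no internal stop, intact start/stop
        for t in locus.transcripts:
            if not t.cds:
                continue
            spliced = "".join(seq[s : e + 1] for s, e in t.cds)
            orig = "".join(locus.seq[s : e + 1] for s, e in t.cds)
            if t.strand == "-":
                spliced, orig = revcomp(spliced), revcomp(orig)
            fixed = list(spliced)
            for i in range(0, len(fixed) - 3, 3):
                if "".join(fixed[i : i + 3]) in STOPS or i == 0:
                    fixed[i : i + 3] = orig[i : i + 3]
            fixed[-3:] = orig[-3:]
            repaired = "".join(fixed)
            if t.strand == "-":
                repaired = revcomp(repaired)
            pos = 0
            for s, e in t.cds:
                seq = _stamp(seq, s, repaired[pos : pos + e - s + 1])
                pos += e - s + 1
        ok = True
        for t in locus.transcripts:
            if t.kind != "lncrna":
                continue
            spliced = "".join(seq[s : e + 1] for s, e in t.exons)
            if t.strand == "-":
                spliced = revcomp(spliced)
            if _longest_orf_len(spliced) > 297:
                ok = False
                break
        if ok:
            break
    else:
        seq = locus.seq  # fall back to an identical copy
    new_transcripts = []
    for t in locus.transcripts:
        new_gene = new_ids[t.gene_id]
        new_transcripts.append(
            _LocalTranscript(
                transcript_id=t.transcript_id.replace(t.gene_id, new_gene),
                gene_id=new_gene,
                exons=list(t.exons),
                strand=t.strand,
                kind=t.kind,
                category=t.category,
                cds=list(t.cds),
            )
        )
    return _Locus(seq=seq, transcripts=new_transcripts, tag=locus.tag)


# ---------------------------------------------------------------------------
# Genome assembly


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: dict[str, str]
    reference: AnnotationSet
    assembled: AnnotationSet
    te_intervals: list[GenomicInterval]
    truth: pd.DataFrame  # per transcript
    counts: CountMatrix | None = None
    gene2term: dict[str, list[str]] = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


def _chrom_names(cfg: SimulationConfig) -> list[str]:
    return [f"H{i + 1:02d}" for i in range(cfg.n_chrom_h)] + [
        f"C{i + 1:02d}" for i in range(cfg.n_chrom_c)
    ]


def simulate_genome_and_annotation(cfg: SimulationConfig) -> SimulatedData:
    """Build genome FASTA, reference + assembled annotations, TE BED and
    the per-transcript truth table (without counts)."""
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_seq, rng_te, rng_counts, rng_go = (
        np.random.default_rng(s) for s in master.spawn(5)
    )
    del rng_counts, rng_go  # reserved for the other artifact streams

    chroms = _chrom_names(cfg)
    n_pairs = min(cfg.n_chrom_h, cfg.n_chrom_c)
    partner = {}
    for i in range(n_pairs):
        partner[f"H{i + 1:02d}"] = f"C{i + 1:02d}"

    # ---- allocate loci to chromosomes -----------------------------------
    n_hosts = 2 * cfg.n_lncrna[1] + cfg.n_lncrna[2] + cfg.n_lncrna[3]
    n_standalone = cfg.n_coding_genes - n_hosts

    pending: dict[str, list[_Locus]] = {c: [] for c in chroms}
    homoeolog_of: dict[str, str] = {}

    def round_robin(n):
        return [chroms[i % len(chroms)] for i in range(n)]

    # standalone genes
    gene_serial = {c: 0 for c in chroms}
    for chrom in round_robin(n_standalone):
        gene_serial[chrom] += 1
        gid = f"gene-{chrom}-{gene_serial[chrom]:04d}"
        pending[chrom].append(_build_gene(rng_seq, gid, strand="+" if rng_seq.random() < 0.5 else "-"))

    # lincRNA loci: collinear-paired ones first, then singles
    if 2 * cfg.n_lnc_homoeolog_pairs > cfg.n_lncrna[0]:
        raise ValueError(
            "2 * n_lnc_homoeolog_pairs exceeds the intergenic lncRNA budget"
        )
    n_pair_chroms = (
        (cfg.n_lnc_homoeolog_pairs + cfg.lnc_pairs_per_chrom - 1) // cfg.lnc_pairs_per_chrom
        if cfg.n_lnc_homoeolog_pairs
        else 0
    )
    if n_pair_chroms > n_pairs:
        raise CapacityError("not enough paired chromosomes for lncRNA homoeolog pairs")
    paired_budget = cfg.n_lnc_homoeolog_pairs
    linc_serial = 0
    linc_transcripts = 0
    for i in range(n_pair_chroms):
        h_chrom = f"H{i + 1:02d}"
        take = min(cfg.lnc_pairs_per_chrom, paired_budget)
        paired_budget -= take
        for _ in range(take):
            linc_serial += 1
            gid = f"novel-{h_chrom}-L{linc_serial:04d}"
            locus = _build_lincrna(rng_seq, gid, n_isoforms=1)
            locus.tag = f"lncpair-{linc_serial}"
            pending[h_chrom].append(locus)
            linc_transcripts += 1
    # each paired lincRNA will get a C copy: account for those transcripts
    linc_transcripts *= 2
    singles_chroms = iter(round_robin(max(0, cfg.n_lncrna[0])))
    while linc_transcripts < cfg.n_lncrna[0]:
        chrom = next(singles_chroms)
        linc_serial += 1
        gid = f"novel-{chrom}-L{linc_serial:04d}"
        want_iso = (
            rng_seq.random() < cfg.isoform_prob
            and cfg.n_lncrna[0] - linc_transcripts >= 2
        )
        locus = _build_lincrna(rng_seq, gid, n_isoforms=2 if want_iso else 1)
        linc_transcripts += len(locus.transcripts)
        pending[chrom].append(locus)

    # positional units and decoys
    for i, chrom in enumerate(round_robin(cfg.n_lncrna[1])):
        pending[chrom].append(_build_sense_unit(rng_seq, i + 1, chrom))
    for i, chrom in enumerate(round_robin(cfg.n_lncrna[2])):
        pending[chrom].append(_build_antisense_unit(rng_seq, i + 1, chrom))
    for i, chrom in enumerate(round_robin(cfg.n_lncrna[3])):
        pending[chrom].append(_build_intronic_unit(rng_seq, i + 1, chrom))
    for kind, n in (
        ("decoy_coding", cfg.n_decoy_coding),
        ("decoy_monoexon", cfg.n_decoy_monoexon),
        ("decoy_lowexpr", cfg.n_decoy_lowexpr),
    ):
        for i, chrom in enumerate(round_robin(n)):
            pending[chrom].append(_build_decoy(rng_seq, i + 1, chrom, kind))

    # ---- fix each chromosome's locus order (H order defines collinearity)
    def _shuffle(loci: list[_Locus]) -> list[_Locus]:
        idx = rng_layout.permutation(len(loci))
        return [loci[i] for i in idx]

    for chrom in chroms:
        pending[chrom] = _shuffle(pending[chrom])

    # ---- homoeolog copies on paired chromosomes -------------------------
    for h_chrom, c_chrom in partner.items():
        h_genes = [
            loc
            for loc in pending[h_chrom]
            if len(loc.transcripts) == 1 and loc.transcripts[0].kind == "coding_ref"
        ]
        n_shared_genes = int(round(cfg.homoeolog_fraction * len(h_genes)))
        for j, loc in enumerate(h_genes[:n_shared_genes]):
            loc.tag = f"genepair-{h_chrom}-{j}"
        # shared loci (tagged genes + paired lincRNAs) in H layout order
        h_shared = [loc for loc in pending[h_chrom] if loc.tag]
        c_copies = []
        for loc in h_shared:
            new_ids = {
                t.gene_id: t.gene_id.replace(h_chrom, c_chrom) + "h"
                for t in loc.transcripts
            }
            copy = _mutate_locus(rng_seq, loc, cfg.mutation_rate, new_ids)
            c_copies.append(copy)
            for t in loc.transcripts:
                homoeolog_of[t.gene_id] = new_ids[t.gene_id]
                homoeolog_of[new_ids[t.gene_id]] = t.gene_id
        # insert copies into the C chromosome preserving their H order
        existing = pending[c_chrom]
        merged: list[_Locus] = []
        slots = np.sort(rng_layout.integers(0, len(existing) + 1, size=len(c_copies)))
        ei = 0
        for k, copy in enumerate(c_copies):
            while ei < slots[k] and ei < len(existing):
                merged.append(existing[ei])
                ei += 1
            merged.append(copy)
        merged.extend(existing[ei:])
        pending[c_chrom] = merged

    # ---- lay out chromosomes -------------------------------------------
    genome: dict[str, str] = {}
    ref_models: list[TranscriptModel] = []
    novel_models: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    for chrom in chroms:
        order = pending[chrom]
        segments: list[str] = []
        cursor = 0
        for loc in order:
            gap = int(rng_layout.integers(300, 1500))
            segments.append(_random_seq(rng_layout, gap))
            cursor += gap
            for t in loc.transcripts:
                exons = tuple(
                    GenomicInterval(chrom, cursor + s + 1, cursor + e + 1, t.strand)
                    for s, e in t.exons
                )
                cds = tuple(
                    GenomicInterval(chrom, cursor + s + 1, cursor + e + 1, t.strand)
                    for s, e in t.cds
                )
                model = TranscriptModel(t.transcript_id, t.gene_id, exons, cds)
                if t.kind == "coding_ref":
                    ref_models.append(model)
                else:
                    novel_models.append(model)
                truth_rows.append(
                    {
                        "transcript_id": t.transcript_id,
                        "gene_id": t.gene_id,
                        "kind": t.kind,
                        "is_lncrna": t.kind == "lncrna",
                        "category": t.category,
                        "chrom": chrom,
                        "subgenome": "subH" if chrom.startswith("H") else "subC",
                        "homoeolog_partner": homoeolog_of.get(t.gene_id, ""),
                    }
                )
            segments.append(loc.seq)
            cursor += len(loc.seq)
            if cursor > cfg.chrom_length:
                raise CapacityError(
                    f"{chrom}: features need {cursor} bp, chromosome is {cfg.chrom_length}"
                )
        segments.append(_random_seq(rng_layout, cfg.chrom_length - cursor))
        genome[chrom] = "".join(segments)

    reference = AnnotationSet(ref_models)
    assembled = AnnotationSet(ref_models + novel_models)

    # ---- TE intervals (midpoint-enriched) -------------------------------
    te_intervals: list[GenomicInterval] = []
    te_chroms = rng_te.choice(len(chroms), size=cfg.n_te)
    for idx in te_chroms:
        chrom = chroms[int(idx)]
        length = int(rng_te.integers(100, 1000))
        center = rng_te.triangular(0, cfg.chrom_length / 2, cfg.chrom_length)
        start = int(np.clip(center - length / 2, 1, cfg.chrom_length - length))
        te_intervals.append(GenomicInterval(chrom, start, start + length - 1, "."))
    te_intervals.sort(key=lambda iv: (iv.seq_id, iv.start))

    truth = pd.DataFrame(truth_rows).set_index("transcript_id")

    # independent brute-force TE-overlap truth over lncRNA exons
    te_by_chrom: dict[str, list[GenomicInterval]] = {}
    for te in te_intervals:
        te_by_chrom.setdefault(te.seq_id, []).append(te)
    derived = {}
    for model in novel_models:
        if truth.loc[model.transcript_id, "kind"] != "lncrna":
            continue
        best = 0
        for te in te_by_chrom.get(model.seq_id, []):
            ov = sum(overlap_bp(e, te) for e in model.exons)
            best = max(best, ov)
        derived[model.transcript_id] = best >= 10
    truth["te_derived"] = truth.index.map(lambda t: derived.get(t, False))

    return SimulatedData(
        config=cfg,
        genome=genome,
        reference=reference,
        assembled=assembled,
        te_intervals=te_intervals,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Expression truth and count simulation


def plant_expression(cfg: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Add true per-transcript group means (mu_cc, mu_hh, mu_f1, mu_s14)
    and the planted inheritance classes to the truth table.

    Parental difference, species-specific silencing, and non-additive
    deviation from the mid-parent value in F1 / S14 are planted in
    disjoint randomly chosen feature sets; F1 deviations are biased
    upward (hybridization activation)."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[3])
    truth = truth.copy()
    n = len(truth)
    base = np.exp(rng.normal(cfg.base_log_mean, cfg.base_log_sd, n))
    visible = truth["kind"].isin(["lncrna", "decoy_coding", "decoy_monoexon"]).values
    base = np.where(visible, np.maximum(base, cfg.min_planted_mean), base)
    lowexpr = (truth["kind"] == "decoy_lowexpr").values
    base[lowexpr] = 0.01

    eligible = ~lowexpr
    pdiff = (rng.random(n) < cfg.frac_parent_diff) & eligible
    delta = rng.uniform(*cfg.parent_delta, n) * rng.choice([-1.0, 1.0], n)
    mu_cc = np.where(pdiff, base * 2 ** (delta / 2), base)
    mu_hh = np.where(pdiff, base * 2 ** (-delta / 2), base)

    ss = (rng.random(n) < cfg.frac_species_specific) & eligible & ~pdiff
    ss_cc_only = rng.random(n) < 0.5
    species = np.full(n, "none", dtype=object)
    species[ss & ss_cc_only] = "CC_only"
    species[ss & ~ss_cc_only] = "HH_only"
    mu_hh = np.where(ss & ss_cc_only, 0.0, mu_hh)
    mu_cc = np.where(ss & ss_cc_only, 2 * base, mu_cc)
    mu_cc = np.where(ss & ~ss_cc_only, 0.0, mu_cc)
    mu_hh = np.where(ss & ~ss_cc_only, 2 * base, mu_hh)

    mpv = (mu_cc + mu_hh) / 2.0

    def _progeny(frac: float, up_bias: float) -> tuple[np.ndarray, np.ndarray]:
        nonadd = (rng.random(n) < frac) & eligible
        sign = np.where(rng.random(n) < up_bias, 1.0, -1.0)
        shift = rng.uniform(*cfg.nonadd_delta, n) * sign
        mu = np.where(nonadd, mpv * 2**shift, mpv)
        cls = np.full(n, "additive", dtype=object)
        cls[nonadd & (sign > 0)] = "nonadditive_up"
        cls[nonadd & (sign < 0)] = "nonadditive_down"
        return mu, cls

    mu_f1, add_f1 = _progeny(cfg.frac_nonadditive_f1, cfg.f1_up_bias)
    mu_s14, add_s14 = _progeny(cfg.frac_nonadditive_s14, cfg.s14_up_bias)

    truth["mu_cc"] = mu_cc
    truth["mu_hh"] = mu_hh
    truth["mu_f1"] = mu_f1
    truth["mu_s14"] = mu_s14
    truth["species_specific"] = species
    truth["additivity_f1"] = add_f1
    truth["additivity_s14"] = add_s14
    return truth


def simulate_counts(
    cfg: SimulationConfig, truth: pd.DataFrame, lengths: pd.Series
) -> CountMatrix:
    """Draw NB counts for 4 groups x ``n_reps`` replicates from the true
    group means. NB(mean = library_size * mu, dispersion alpha); zero
    means yield exact zeros."""
    cfg.validate()
    if "mu_cc" not in truth.columns:
        truth = plant_expression(cfg, truth)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4])
    samples = [f"{g}_{r + 1}" for g in GROUP_ORDER for r in range(cfg.n_reps)]
    lib = rng.uniform(*cfg.library_size_range, len(samples))
    mu_cols = {"CC": "mu_cc", "HH": "mu_hh", "F1": "mu_f1", "S14": "mu_s14"}
    r_param = 1.0 / cfg.dispersion
    cols = {}
    for s_idx, sample in enumerate(samples):
        group = sample.rsplit("_", 1)[0]
        mu = truth[mu_cols[group]].values * lib[s_idx]
        counts = np.zeros(len(mu), dtype=int)
        nz = mu > 0
        p = r_param / (r_param + mu[nz])
        counts[nz] = rng.negative_binomial(r_param, p)
        cols[sample] = counts
    counts_df = pd.DataFrame(cols, index=truth.index)
    design = pd.DataFrame(
        {
            "group": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(counts=counts_df, lengths=lengths.reindex(truth.index), design=design)


def _annotation_lengths(annotation: AnnotationSet) -> pd.Series:
    return pd.Series({t.transcript_id: t.length for t in annotation})


def _de_adjacent_pcgs(cfg: SimulationConfig, data: SimulatedData) -> dict[str, str]:
    """PCG gene -> DE lncRNA gene, for PCGs within ``cis_window`` of a
    lncRNA gene whose planted expression makes it differentially
    expressed in the allotetraploid (parental difference,
    species-specific, or S14-non-additive)."""
    truth = data.truth
    if "mu_cc" not in truth.columns:
        return {}
    de_mask = (
        (truth["species_specific"] != "none")
        | (truth["additivity_s14"] != "additive")
        | (
            truth["mu_cc"].gt(0)
            & truth["mu_hh"].gt(0)
            & (np.abs(np.log2((truth["mu_s14"] + 0.5) / (truth["mu_cc"] + 0.5))) > 2)
        )
    ) & truth["is_lncrna"]
    de_genes = set(truth.loc[de_mask, "gene_id"])
    spans = {}
    for t in data.assembled:
        if t.gene_id in de_genes:
            spans.setdefault(t.gene_id, t.span)
    out: dict[str, str] = {}
    for gid in sorted(data.reference.genes):
        g_span = data.reference.gene_span(gid)
        for lnc_gid, l_span in sorted(spans.items()):
            if g_span.seq_id != l_span.seq_id:
                continue
            gap = max(l_span.start - g_span.end, g_span.start - l_span.end, 0)
            if gap <= cfg.cis_window:
                out[gid] = lnc_gid
                break
    return out


def plant_cis_structure(cfg: SimulationConfig, data: SimulatedData) -> None:
    """Impose each DE lncRNA's expression pattern on its adjacent PCGs
    (cis-regulation emulation): the PCG keeps its own expression scale
    but inherits the lncRNA gene's relative group profile, so the pair
    is strongly correlated across samples."""
    truth = data.truth
    mu_cols = ["mu_cc", "mu_hh", "mu_f1", "mu_s14"]
    gene_mu = truth.groupby("gene_id")[mu_cols].sum()
    for pcg_gid, lnc_gid in _de_adjacent_pcgs(cfg, data).items():
        lnc_mu = gene_mu.loc[lnc_gid].values
        if lnc_mu.mean() <= 0:
            continue
        pattern = lnc_mu / lnc_mu.mean()
        rows = truth.index[truth["gene_id"] == pcg_gid]
        for tid in rows:
            base = float(truth.loc[tid, mu_cols].mean())
            truth.loc[tid, mu_cols] = base * pattern


def assign_go_terms(cfg: SimulationConfig, data: SimulatedData) -> dict[str, list[str]]:
    """Random GO terms for every protein-coding gene, plus the marker
    term stamped on the DE-lncRNA-adjacent PCGs (the same set that
    inherits cis-regulated expression)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[5])
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    gene2term: dict[str, list[str]] = {}
    for gid in sorted(data.reference.genes):
        k = int(rng.integers(1, 4))
        picked = rng.choice(len(terms), size=k, replace=False)
        gene2term[gid] = sorted(terms[i] for i in picked)
    for gid in _de_adjacent_pcgs(cfg, data):
        gene2term[gid] = sorted(set(gene2term[gid]) | {cfg.marker_term})
    return gene2term


def simulate(cfg: SimulationConfig | None = None) -> SimulatedData:
    """Full synthetic data set: genome, annotations, TEs, truth with
    planted expression, counts, and GO terms."""
    cfg = cfg or SimulationConfig()
    data = simulate_genome_and_annotation(cfg)
    data.truth = plant_expression(cfg, data.truth)
    plant_cis_structure(cfg, data)
    lengths = _annotation_lengths(data.assembled)
    data.counts = simulate_counts(cfg, data.truth, lengths)
    data.gene2term = assign_go_terms(cfg, data)
    return data


def write_all(data: SimulatedData, outdir) -> dict[str, str]:
    """Write every artifact as plain text; returns the path map."""
    from pathlib import Path

    from .gtfio import write_bed, write_counts, write_fasta, write_gtf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "reference": out / "reference.gtf",
        "assembled": out / "assembled.gtf",
        "te": out / "te.bed",
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
        "gene2term": out / "gene2term.tsv",
    }
    write_fasta(data.genome, paths["genome"])
    write_gtf(data.reference, paths["reference"])
    write_gtf(data.assembled, paths["assembled"])
    write_bed(data.te_intervals, paths["te"])
    if data.counts is not None:
        write_counts(data.counts, paths["counts"], paths["design"])
    data.truth.to_csv(paths["truth"], sep="\t")
    with open(paths["gene2term"], "w") as fh:
        for gid, ts in sorted(data.gene2term.items()):
            for term in ts:
                fh.write(f"{gid}\t{term}\n")
    return {k: str(v) for k, v in paths.items()}
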