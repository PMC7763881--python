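"""The four-step lncRNA identification cascade.

Assembled transcripts are compared against the reference annotation,
novel long transcripts (class code u/i/x, spliced length >= 200 nt) are
scored for coding potential, and survivors are filtered for exon number
(>= 2) and expression (max per-group mean TPM > 0.3). Every casualty is
recorded in an audit table naming the step that removed it. Surviving
transcripts are collapsed to lncRNA-genes by gene_id, summing counts.

The internal coding-potential model is trained on the data at hand:
reference mRNAs (CDS-bearing transcripts) as the coding class, random
length-matched intergenic fragments as the noncoding background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coding
from .compare import extract_novel
from .expression import compute_tpm
from .gtfio import CountMatrix, revcomp, transcript_sequence
from .intervals import AnnotationSet, GenomicInterval, TranscriptModel

TPM_THRESHOLD = 0.3
MIN_EXONS = 2
MIN_LENGTH = 200


class ReconciliationError(ValueError):
    """Annotation and count matrix disagree about the feature universe."""


@dataclass
class LncRNATranscript:
    model: TranscriptModel
    class_code: str
    scores: coding.CodingScores
    group_tpm: dict[str, float]

    @property
    def transcript_id(self) -> str:
        return self.model.transcript_id


@dataclass
class LncRNAGene:
    gene_id: str
    members: list[str]
    representative: TranscriptModel  # longest member


def sample_intergenic_fragments(
    genome: dict[str, str] | object,
    reference: AnnotationSet,
    lengths: list[int],
    rng: np.random.Generator,
    max_tries: int = 50,
) -> list[str]:
    """Length-matched fragments drawn away from annotated transcripts,
    used as the noncoding training background."""
    chroms = sorted(
        genome.keys() if isinstance(genome, dict) else [k for k in genome.keys()]
    )
    sizes = {c: len(genome[c]) for c in chroms}
    out = []
    for want in lengths:
        frag = None
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            if sizes[chrom] <= want + 2:
                continue
            start = int(rng.integers(1, sizes[chrom] - want))
            iv = GenomicInterval(chrom, start, start + want - 1)
            if reference.overlapping(iv):
                continue
            frag = str(genome[chrom][start - 1 : start + want - 1]).upper()
            break
        if frag is not None:
            out.append(frag)
    return out


def train_coding_model(
    genome,
    reference: AnnotationSet,
    seed: int = 0,
    n_train: int = 300,
) -> tuple[coding.HexamerTable, coding.LogisticModel]:
    """Fit the hexamer table and logistic scorer from the reference
    annotation (mRNAs vs intergenic background)."""
    rng = np.random.default_rng(seed)
    mrnas = [t for t in reference if t.cds]
    if len(mrnas) > n_train:
        keep = rng.choice(len(mrnas), size=n_train, replace=False)
        mrnas = [mrnas[i] for i in sorted(keep)]
    pos_seqs = [transcript_sequence(genome, t) for t in mrnas]
    neg_seqs = sample_intergenic_fragments(
        genome, reference, [len(s) for s in pos_seqs], rng
    )
    table = coding.train_hexamer_table(pos_seqs, neg_seqs)

    def featurize(seq: str) -> list[float]:
        orf_len, _f, _s = coding.find_longest_orf(seq)
        fick = coding.fickett_score(seq) if len(seq) >= 200 else 0.0
        return [orf_len, orf_len / len(seq), fick, coding.hexamer_bias(seq, table)]

    feats = np.array([featurize(s) for s in pos_seqs + neg_seqs])
    labels = np.array([1] * len(pos_seqs) + [0] * len(neg_seqs))
    model = coding.train_logistic(feats, labels)
    return table, model


def identify_lncrnas(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    counts: CountMatrix,
    genome,
    seed: int = 0,
    thresholds: dict[str, float] | None = None,
    external_scores: dict[str, dict[str, float]] | None = None,
    min_length: int = MIN_LENGTH,
    min_exons: int = MIN_EXONS,
    tpm_threshold: float = TPM_THRESHOLD,
) -> tuple[list[LncRNATranscript], pd.DataFrame]:
    """Run the cascade; returns survivors and the full audit table.

    ``external_scores`` maps tool name -> {transcript_id -> score} for
    score tables produced by outside predictors; the internal coding
    probability always plays the CPAT role.
    """
    missing = [t.transcript_id for t in assembled if t.transcript_id not in counts.counts.index]
    if missing:
        raise ReconciliationError(
            f"{len(missing)} transcripts absent from counts, e.g. {missing[:5]}"
        )

    novel, audit = extract_novel(list(assembled), reference, min_length=min_length)
    audit["removal_step"] = audit["removal_step"].astype(object)

    table, model = train_coding_model(genome, reference, seed=seed)
    tpm = compute_tpm(counts)
    group_means = tpm.group_means()

    survivors: list[LncRNATranscript] = []
    for t in novel:
        seq = transcript_sequence(genome, t)
        scores = coding.score_transcript(t.transcript_id, seq, table, model)
        if external_scores:
            for tool, tab in external_scores.items():
                if t.transcript_id in tab:
                    scores.external[tool] = tab[t.transcript_id]
        if not coding.consensus_noncoding(scores, thresholds):
            audit.loc[t.transcript_id, "removal_step"] = "coding_filter"
            continue
        if t.n_exons < min_exons:
            audit.loc[t.transcript_id, "removal_step"] = "exon_filter"
            continue
        gm = group_means.loc[t.transcript_id]
        if not gm.max() > tpm_threshold:
            audit.loc[t.transcript_id, "removal_step"] = "tpm_filter"
            continue
        survivors.append(
            LncRNATranscript(
                model=t,
                class_code=audit.loc[t.transcript_id, "class_code"],
                scores=scores,
                group_tpm=gm.to_dict(),
            )
        )
    return survivors, audit


def collapse_to_genes(
    lncrnas: list[LncRNATranscript], counts: CountMatrix | None = None
) -> tuple[list[LncRNAGene], CountMatrix | None]:
    """Group surviving transcripts by gene_id; gene-level counts are the
    per-sample sums over member transcripts. The longest member is the
    representative transcript (interval/classification proxy)."""
    by_gene: dict[str, list[LncRNATranscript]] = {}
    for lnc in lncrnas:
        by_gene.setdefault(lnc.model.gene_id, []).append(lnc)
    genes = []
    for gid in sorted(by_gene):
        members = by_gene[gid]
        rep = max(members, key=lambda l: (l.model.length, l.transcript_id)).model
        genes.append(
            LncRNAGene(gene_id=gid, members=[m.transcript_id for m in members], representative=rep)
        )
    gene_counts = None
    if counts is not None and genes:
        rows = {}
        lengths = {}
        for g in genes:
            rows[g.gene_id] = counts.counts.loc[g.members].sum(axis=0)
            lengths[g.gene_id] = g.representative.length
        gene_counts = CountMatrix(
            counts=pd.DataFrame(rows).T[counts.samples],
            lengths=pd.Series(lengths),
            design=counts.design.copy(),
        )
    return genes, gene_counts


def collapse_gene_level_counts(
    annotation: AnnotationSet, counts: CountMatrix, feature_ids: list[str] | None = None
) -> CountMatrix:
    """Gene-level count matrix for any annotation subset: per-sample sums
    over each gene's transcripts; gene length is the longest transcript's
    spliced length (the study compares PCGs by their longest mRNA)."""
    ids = set(feature_ids) if feature_ids is not None else None
    rows = {}
    lengths = {}
    for gid, models in annotation.genes.items():
        members = [
            t.transcript_id
            for t in models
            if ids is None or t.transcript_id in ids
        ]
        members = [m for m in members if m in counts.counts.index]
        if not members:
            continue
        rows[gid] = counts.counts.loc[members].sum(axis=0)
        lengths[gid] = max(t.length for t in models if t.transcript_id in members)
    return CountMatrix(
        counts=pd.DataFrame(rows).T[counts.samples],
        lengths=pd.Series(lengths),
        design=counts.design.copy(),
    )
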