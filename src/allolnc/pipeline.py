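"""End-to-end pipeline orchestration and summary arithmetic.

Runs identification -> annotation -> expression -> differential
expression -> trend profiling -> target prediction on one input set,
writes every intermediate table as TSV, and assembles a summary report
whose percentages and ratios are recomputed from the underlying tables
with the same rounding the study's printed numbers use.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import diffexpr, trends
from . import targets as targets_mod
from .expression import compute_tpm, mid_parent, replicate_correlation
from .gtfio import (
    CountMatrix,
    read_bed,
    read_counts,
    read_gtf,
    open_fasta,
    transcript_sequence,
    write_gtf,
)
from .identify import (
    collapse_gene_level_counts,
    collapse_to_genes,
    identify_lncrnas,
)
from .intervals import AnnotationSet


def percentage(numerator: float, denominator: float, digits: int = 1) -> float:
    """100 * numerator / denominator, rounded to ``digits`` decimals with
    banker's rounding (matches the study's printed percentages)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_EVEN))


def ratio(a: float, b: float, digits: int = 2) -> float:
    """a / b rounded to ``digits`` decimals (banker's rounding)."""
    if b == 0:
        raise ZeroDivisionError("ratio with zero divisor")
    q = Decimal(a) / Decimal(b)
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_EVEN))


_KNOWN_KEYS = {
    "genome",
    "reference",
    "assembled",
    "te",
    "counts",
    "design",
    "gene2term",
    "outdir",
    "seed",
    "min_length",
    "min_exons",
    "tpm_threshold",
    "window",
    "n_perm",
    "alpha",
    "lfc_min",
}


@dataclass
class PipelineConfig:
    """Input paths and the tunable thresholds, with study defaults."""

    genome: str
    reference: str
    assembled: str
    te: str
    counts: str
    design: str
    gene2term: str | None = None
    outdir: str = "results"
    seed: int = 0
    min_length: int = 200
    min_exons: int = 2
    tpm_threshold: float = 0.3
    window: int = 100_000
    n_perm: int = 1000
    alpha: float = 1e-4
    lfc_min: float = 2.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """key=value config file; unknown keys are rejected."""
        values: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in _KNOWN_KEYS:
                    raise ValueError(f"unknown config key: {key}")
                values[key] = value.strip()
        casts = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, raw in values.items():
            typ = casts[key]
            if typ in ("int", int):
                kwargs[key] = int(raw)
            elif typ in ("float", float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class SummaryReport:
    """All stage-level counts; every percentage in here is recomputed
    from the numerator/denominator columns also stored here."""

    audit_counts: dict = field(default_factory=dict)
    n_lncrna_transcripts: int = 0
    n_lncrna_genes: int = 0
    category_counts: dict = field(default_factory=dict)
    subgenome_counts: dict = field(default_factory=dict)
    te_derived_count: int = 0
    n_collinear_pairs: int = 0
    n_collinear_blocks: int = 0
    replicate_correlation: dict = field(default_factory=dict)
    de_counts: dict = field(default_factory=dict)
    additivity: dict = field(default_factory=dict)
    trend_summary: dict = field(default_factory=dict)
    target_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute the full pipeline from files on disk (see
    :func:`run_on_inputs` for the in-memory variant)."""
    genome = open_fasta(config.genome)
    reference = read_gtf(config.reference)
    assembled = read_gtf(config.assembled)
    te = read_bed(config.te)
    counts = read_counts(config.counts, config.design)
    gene2term = (
        targets_mod.read_term_map(config.gene2term) if config.gene2term else None
    )
    return run_on_inputs(
        genome, reference, assembled, te, counts, gene2term, config
    )


def run_on_inputs(
    genome,
    reference: AnnotationSet,
    assembled: AnnotationSet,
    te_intervals,
    counts: CountMatrix,
    gene2term: dict[str, list[str]] | None,
    config: PipelineConfig,
) -> SummaryReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = SummaryReport()

    # ---- identification -------------------------------------------------
    survivors, audit = identify_lncrnas(
        assembled,
        reference,
        counts,
        genome,
        seed=config.seed,
        min_length=config.min_length,
        min_exons=config.min_exons,
        tpm_threshold=config.tpm_threshold,
    )
    audit.to_csv(outdir / "audit.tsv", sep="\t")
    report.audit_counts = audit["removal_step"].value_counts().to_dict()
    genes, lnc_gene_counts = collapse_to_genes(survivors, counts)
    report.n_lncrna_transcripts = len(survivors)
    report.n_lncrna_genes = len(genes)
    lnc_annotation = AnnotationSet([s.model for s in survivors])
    write_gtf(lnc_annotation, outdir / "lncrna.gtf")
    pd.DataFrame(
        [{"gene_id": g.gene_id, "members": ",".join(g.members)} for g in genes]
    ).to_csv(outdir / "gene_map.tsv", sep="\t", index=False)
    if not genes:
        report.write(outdir / "report.json")
        return report

    # ---- annotation -----------------------------------------------------
    lnc_reps = {g.gene_id: g.representative for g in genes}
    sequences = {
        gid: transcript_sequence(genome, rep) for gid, rep in lnc_reps.items()
    }
    records, blocks = annotate_mod.annotate_lncrna_genes(
        lnc_reps, reference, te_intervals, sequences
    )
    records.to_csv(outdir / "lncrna_records.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "h_chrom": b.h_chrom,
                "c_chrom": b.c_chrom,
                "orientation": b.orientation,
                "n_anchors": len(b.pairs),
                "pairs": ";".join(f"{h}|{c}" for h, c in b.pairs),
            }
            for b in blocks
        ]
    ).to_csv(outdir / "collinear_blocks.tsv", sep="\t", index=False)
    chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
    annotate_mod.density_table(chrom_lengths, lnc_reps, reference, te_intervals).to_csv(
        outdir / "density_100kb.tsv", sep="\t", index=False
    )
    report.category_counts = records["category"].value_counts().to_dict()
    report.subgenome_counts = records["subgenome"].value_counts().to_dict()
    report.te_derived_count = int(records["te_derived"].sum())
    report.n_collinear_pairs = int((records["homoeolog_partner"] != "").sum() // 2)
    report.n_collinear_blocks = len(blocks)

    # ---- expression ------------------------------------------------------
    tpm_all = compute_tpm(counts)
    report.replicate_correlation = {
        k: round(v, 4) for k, v in replicate_correlation(tpm_all).items()
    }
    gene_counts_all = collapse_gene_level_counts(assembled, counts)
    gene_tpm = compute_tpm(gene_counts_all)
    gene_tpm.tpm.to_csv(outdir / "gene_tpm.tsv", sep="\t", index_label="gene_id")
    lnc_gene_ids = [g.gene_id for g in genes]
    lnc_counts = lnc_gene_counts.counts
    mpv_counts = mid_parent(lnc_counts, counts.design, as_counts=True)
    mpv_counts.values.to_csv(outdir / "mpv_counts.tsv", sep="\t", index_label="gene_id")

    # ---- differential expression ----------------------------------------
    design = counts.design
    lnc_tpm = gene_tpm.tpm.loc[lnc_gene_ids]
    mpv_tpm = mid_parent(lnc_tpm, design, as_counts=False).values

    def block(group: str) -> pd.DataFrame:
        samples = [s for s in design.index if design.loc[s, "group"] == group]
        return lnc_counts[samples]

    def tpm_block(group: str) -> pd.DataFrame:
        samples = [s for s in design.index if design.loc[s, "group"] == group]
        return lnc_tpm[samples]

    de_tables: dict[tuple[str, str], diffexpr.DETable] = {}
    for a, b in diffexpr.STUDY_CONTRASTS:
        ca = mpv_counts.values if a == "MPV" else block(a)
        cb = mpv_counts.values if b == "MPV" else block(b)
        ta = mpv_tpm if a == "MPV" else tpm_block(a)
        tb = mpv_tpm if b == "MPV" else tpm_block(b)
        det = diffexpr.nb_test(
            ca, cb, (a, b), alpha=config.alpha, lfc_min=config.lfc_min,
            tpm_a=ta, tpm_b=tb,
        )
        det.table.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t")
        de_tables[(a, b)] = det
        calls = det.table["call"]
        report.de_counts[f"{a}_vs_{b}"] = {
            "up": int((calls == "up_in_A").sum()),
            "down": int((calls == "down_in_A").sum()),
            "total": int((calls != "ns").sum()),
            "species_specific": int((det.table["species_specific"] != "none").sum()),
        }

    n_genes = len(lnc_gene_ids)
    for progeny in ("S14", "F1"):
        add = diffexpr.classify_additivity(de_tables[(progeny, "MPV")])
        add.to_csv(outdir / f"additivity_{progeny}.tsv", sep="\t")
        counts_by_class = add.value_counts().to_dict()
        n_nonadd = int(
            counts_by_class.get("nonadditive_up", 0)
            + counts_by_class.get("nonadditive_down", 0)
        )
        report.additivity[progeny] = {
            **{k: int(v) for k, v in counts_by_class.items()},
            "n_nonadditive": n_nonadd,
            "pct_nonadditive": percentage(n_nonadd, n_genes),
        }

    # ---- trend profiles --------------------------------------------------
    series = pd.DataFrame(
        {
            "MPV": np.log2(mpv_tpm.mean(axis=1) + 1.0),
            "F1": np.log2(tpm_block("F1").mean(axis=1) + 1.0),
            "S14": np.log2(tpm_block("S14").mean(axis=1) + 1.0),
        }
    )
    profiles = trends.enumerate_profiles(T=3, c=2)
    assignment = trends.assign_genes(series, profiles)
    assignment.to_csv(outdir / "trend_assignment.tsv", sep="\t")
    sig = trends.profile_significance(
        series, profiles, n_perm=config.n_perm, seed=config.seed
    )
    sig_ids = list(sig.index[sig["significant"]])
    clusters = trends.cluster_profiles(profiles, sig_ids)
    sig["cluster_id"] = sig.index.map(lambda i: clusters.get(i, -1))
    sig.to_csv(outdir / "trend_profiles.tsv", sep="\t")
    biggest = int(sig["n_assigned"].idxmax())
    report.trend_summary = {
        "n_profiles": len(profiles),
        "n_significant": int(sig["significant"].sum()),
        "n_clusters": int(len(set(clusters.values))) if len(clusters) else 0,
        "largest_profile": {"profile_id": biggest, "n": int(sig.loc[biggest, "n_assigned"])},
    }

    # ---- cis targets and enrichment --------------------------------------
    de_union: set[str] = set()
    for key in (("S14", "CC"), ("S14", "HH"), ("S14", "MPV")):
        de_union |= set(de_tables[key].de_features)
    target_table = pd.DataFrame(
        columns=["lncrna_gene", "pcg", "distance", "relation", "pearson_r", "r_pvalue", "passes"]
    )
    enrichment = None
    if de_union:
        spans = {gid: lnc_reps[gid].span for gid in sorted(de_union)}
        pairs = targets_mod.find_cis_targets(spans, reference, window=config.window)
        log_expr = np.log2(gene_tpm.tpm + 1.0)
        target_table = targets_mod.correlate_pairs(pairs, log_expr)
        if gene2term is not None and target_table["passes"].any():
            ptgs = sorted(set(target_table.loc[target_table["passes"], "pcg"]))
            enrichment = targets_mod.hypergeom_enrich(
                ptgs, sorted(reference.genes), gene2term
            )
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    target_table.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    report.target_summary = {
        "n_de_lncrna_genes": len(de_union),
        "n_candidate_pairs": int(len(target_table)),
        "n_ptgs": int(target_table.loc[target_table["passes"], "pcg"].nunique())
        if len(target_table)
        else 0,
        "top_term": (enrichment["term_id"].iloc[0] if enrichment is not None and len(enrichment) else ""),
    }

    report.write(outdir / "report.json")
    return report
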