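"""Cis-target prediction for DE lncRNAs and hypergeometric GO enrichment.

Potential target genes (PTGs) are protein-coding genes whose span lies
within, or overlaps, a 100-kb window around the lncRNA-gene span; each
pair is then screened by Pearson correlation of log2(TPM+1) across all
12 replicate samples (two-sided t test, n-2 df, passing at p < 0.05).
GO enrichment of the targets against the full PCG background uses the
upper-tail hypergeometric test with BH correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .intervals import AnnotationSet, GenomicInterval

WINDOW_DEFAULT = 100_000


def find_cis_targets(
    lnc_spans: dict[str, GenomicInterval],
    pcgs: AnnotationSet,
    window: int = WINDOW_DEFAULT,
) -> pd.DataFrame:
    """All (lncRNA-gene, PCG) pairs within ``window`` bp, span to span.

    ``distance`` is the gap between the spans (0 when they overlap),
    signed by the PCG's position on the + axis relative to the lncRNA
    (negative = upstream/left). Windows at chromosome edges simply
    truncate; no error.
    """
    gene_spans = {gid: pcgs.gene_span(gid) for gid in pcgs.genes}
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for gid, span in gene_spans.items():
        by_chrom.setdefault(span.seq_id, []).append((gid, span))
    rows = []
    for lnc_id, lspan in sorted(lnc_spans.items()):
        for gid, gspan in by_chrom.get(lspan.seq_id, []):
            if gspan.start > lspan.end:
                dist = gspan.start - lspan.end - 1
                relation = "downstream"
            elif gspan.end < lspan.start:
                dist = -(lspan.start - gspan.end - 1)
                relation = "upstream"
            else:
                dist = 0
                relation = "overlapping"
            if abs(dist) <= window:
                rows.append(
                    {
                        "lncrna_gene": lnc_id,
                        "pcg": gid,
                        "distance": dist,
                        "relation": relation,
                    }
                )
    return pd.DataFrame(rows, columns=["lncrna_gene", "pcg", "distance", "relation"])


def correlate_pairs(
    pairs: pd.DataFrame, log_expression: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r (and two-sided t-test p) of each pair's expression over
    all replicate samples; ``passes`` marks p < alpha. Zero-variance
    series leave r undefined (NaN) and never pass."""
    out = pairs.copy()
    rs, ps = [], []
    for _, row in pairs.iterrows():
        a = log_expression.loc[row["lncrna_gene"]].values
        b = log_expression.loc[row["pcg"]].values
        if np.std(a) == 0 or np.std(b) == 0:
            rs.append(np.nan)
            ps.append(np.nan)
            continue
        r, p = stats.pearsonr(a, b)
        rs.append(float(r))
        ps.append(float(p))
    out["pearson_r"] = rs
    out["r_pvalue"] = ps
    out["passes"] = pd.Series(ps, index=out.index).lt(alpha).fillna(False)
    return out


def hypergeom_enrich(
    target_genes: list[str],
    background_genes: list[str],
    term_map: dict[str, list[str]],
    top: int = 10,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms among targets.

    p = P(X >= k) with N background genes, K of them carrying the term,
    and n targets; BH across terms; the result is sorted by p with the
    top-``top`` rows flagged when p < 0.05.
    """
    targets = set(target_genes)
    background = set(background_genes)
    if not targets:
        raise ValueError("empty target set")
    if not targets <= background:
        raise ValueError("targets must be a subset of the background")
    n, N = len(targets), len(background)
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in background:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    tab = pd.DataFrame(rows)
    tab["padj"] = bh_adjust(tab["p"].values)
    tab = tab.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    tab["top_flag"] = False
    tab.loc[: top - 1, "top_flag"] = tab["p"].iloc[: top] < 0.05
    return tab


def read_term_map(path) -> dict[str, list[str]]:
    """Two-column gene -> term TSV into a gene -> terms map."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    out: dict[str, list[str]] = {}
    for gene, term in zip(tab["gene"], tab["term"]):
        out.setdefault(str(gene), []).append(str(term))
    return out
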