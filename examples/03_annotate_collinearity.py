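"""Positional classes, TE overlap, subgenome, and homoeologous collinearity.

Each identified lncRNA-gene is classified against the coding annotation
(sense/antisense/intronic/intergenic), flagged TE-derived at >= 10 bp
exonic TE overlap, assigned a subgenome from its chromosome prefix, and
paired across subgenomes by reciprocal-best k-mer similarity chained
into collinear blocks (>= 4 anchors per block).
"""

from allolnc.annotate import annotate_lncrna_genes
from allolnc.gtfio import transcript_sequence
from allolnc.identify import collapse_to_genes, identify_lncrnas
from allolnc.simulate import SimulationConfig, simulate

cfg = SimulationConfig(
    seed=11, chrom_length=120_000, n_coding_genes=150,
    n_lncrna=(16, 10, 6, 4), n_te=150,
    n_lnc_homoeolog_pairs=6, lnc_pairs_per_chrom=6,
)
data = simulate(cfg)
survivors, _ = identify_lncrnas(
    data.assembled, data.reference, data.counts, data.genome, seed=cfg.seed
)
genes, _ = collapse_to_genes(survivors)
reps = {g.gene_id: g.representative for g in genes}
seqs = {gid: transcript_sequence(data.genome, rep) for gid, rep in reps.items()}

records, blocks = annotate_lncrna_genes(reps, data.reference, data.te_intervals, seqs)

print("positional categories:", records["category"].value_counts().to_dict())
print("subgenomes:           ", records["subgenome"].value_counts().to_dict())
te_pct = 100 * records["te_derived"].mean()
print(f"TE-derived (>=10 bp):  {records['te_derived'].sum()} ({te_pct:.1f}%)")
print(f"collinear blocks:      {len(blocks)}")
for b in blocks:
    print(f"  block {b.block_id}: {b.h_chrom} ~ {b.c_chrom}, "
          f"{len(b.pairs)} anchor pairs ({b.orientation} orientation)")
# The category counts partition the identified set -- the same identity
# the study reports for its 983 + 827 + 345 + 51 = 2206 lncRNAs.
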