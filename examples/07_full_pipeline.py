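"""The whole workflow in one call, from files on disk.

Writes a synthetic input set, then runs identification -> annotation ->
expression -> differential expression -> trends -> targets through the
same path the `allolnc run-all` CLI uses, and prints the stage summary.
"""

import json

from allolnc.pipeline import PipelineConfig, run_pipeline
from allolnc.simulate import SimulationConfig, simulate, write_all

cfg = SimulationConfig(
    seed=11, chrom_length=120_000, n_coding_genes=150,
    n_lncrna=(16, 10, 6, 4), n_te=150,
    n_lnc_homoeolog_pairs=6, lnc_pairs_per_chrom=6,
)
paths = write_all(simulate(cfg), "scratch/example_full/inputs")

report = run_pipeline(
    PipelineConfig(
        genome=paths["genome"],
        reference=paths["reference"],
        assembled=paths["assembled"],
        te=paths["te"],
        counts=paths["counts"],
        design=paths["design"],
        gene2term=paths["gene2term"],
        outdir="scratch/example_full/results",
        seed=11,
        n_perm=200,
    )
)
print(json.dumps(report.to_dict(), indent=2, default=str))
# Every table behind these numbers is in scratch/example_full/results/.
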