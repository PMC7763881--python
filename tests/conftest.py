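"""Shared fixtures: a small simulation for unit tests and the
default-condition simulation + full pipeline run used by the
acceptance-level checks (both session-scoped; everything is generated
programmatically, nothing is read from disk)."""

import time

import pytest

from allolnc.pipeline import PipelineConfig, run_on_inputs
from allolnc.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        seed=3,
        chrom_length=120_000,
        n_coding_genes=150,
        n_lncrna=(16, 10, 6, 4),
        n_te=150,
        n_lnc_homoeolog_pairs=6,
        lnc_pairs_per_chrom=6,
        n_decoy_coding=6,
        n_decoy_monoexon=4,
        n_decoy_lowexpr=4,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def default_data():
    """The study-condition synthetic data set (~2k features, 12 samples)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_data, tmp_path_factory):
    """Full pipeline on the default data; returns (report, outdir, seconds)."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    config = PipelineConfig(
        genome="", reference="", assembled="", te="", counts="", design="",
        outdir=str(outdir), seed=1, n_perm=1000,
    )
    t0 = time.perf_counter()
    report = run_on_inputs(
        default_data.genome,
        default_data.reference,
        default_data.assembled,
        default_data.te_intervals,
        default_data.counts,
        default_data.gene2term,
        config,
    )
    elapsed = time.perf_counter() - t0
    return report, outdir, elapsed
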