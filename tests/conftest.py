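"""Shared synthetic-data fixtures.

The session-scoped fixtures generate one small genome run reused by many
tests; per-test variations build their own configs.
"""

import os

import numpy as np
import pytest
from pyfaidx import Fasta

from retroprom import intervals_io as io, motif as mo
from retroprom.fixtures import (
    FixtureConfig,
    RepeatSpec,
    make_genome,
    simulate_chip_alignments,
    simulate_rna_alignments,
    simulate_tracks,
)


def small_config(seed: int = 11, **overrides) -> FixtureConfig:
    defaults = dict(
        genome_length=400_000,
        n_genes=5,
        reads_per_sample=5_000,
        rng_seed=seed,
    )
    defaults.update(overrides)
    return FixtureConfig(**defaults)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One complete generated dataset: genome, peaks, ChIP+RNA SAMs, tracks."""
    outdir = str(tmp_path_factory.mktemp("small_run"))
    cfg = small_config()
    genome_path, truth = make_genome(cfg, outdir)
    chip_t, chip_c = simulate_chip_alignments(genome_path, truth, cfg, outdir)
    rna = simulate_rna_alignments(genome_path, truth, cfg, outdir)
    simulate_tracks(genome_path, truth, cfg, outdir)
    return {
        "dir": outdir,
        "config": cfg,
        "truth": truth,
        "genome_path": genome_path,
        "chip": (chip_t, chip_c),
        "rna": rna,
    }


@pytest.fixture(scope="session")
def small_sites(small_run):
    """Refined, context-annotated binding sites for the small run."""
    genome = Fasta(small_run["genome_path"])
    repeats = io.read_repeat_table(os.path.join(small_run["dir"], "repeats.tsv"))
    peaks = io.read_bed(os.path.join(small_run["dir"], "peaks.bed"))
    pwm = mo.read_pwm(os.path.join(small_run["dir"], "pwm.tsv"))
    peak_ids = list(small_run["truth"].peaks["peak_id"])
    sites = [mo.best_window(pwm, iv, genome, peak_id=pid) for pid, iv in zip(peak_ids, peaks)]
    return mo.assign_repeat_context(sites, repeats), repeats, peaks, pwm, genome


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
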