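"""Statistical and structural properties of the synthetic-data generator."""

import filecmp
import os

import numpy as np
import pysam
import pytest
from scipy import stats

from retroprom.fixtures import (
    FeatureOverflowError,
    FixtureConfig,
    RepeatSpec,
    TruthTable,
    default_pwm,
    make_genome,
    simulate_chip_alignments,
    simulate_count_matrix,
    simulate_rna_alignments,
    simulate_tracks,
)
from tests.conftest import small_config


def one_type_config(**over):
    spec = RepeatSpec("REP1", "FAM1", "LTR", "ACGT" * 75, over.pop("n_copies", 50),
                      over.pop("divergence", 0.1))
    base = dict(
        genome_length=300_000,
        repeat_catalog=(spec,),
        motif_types=("REP1",),
        n_genes=0,
        chimera_fraction=0.0,
        satellite_n_monomers=0,
        rng_seed=5,
    )
    base.update(over)
    return FixtureConfig(**base)


class TestMakeGenome:
    def test_zero_copies_empty_annotation(self, tmp_path):
        cfg = one_type_config(n_copies=0, motif_plant_fraction=0.0)
        gp, truth = make_genome(cfg, str(tmp_path))
        assert len(truth.repeats) == 0
        assert os.path.getsize(gp) > cfg.genome_length  # background still emitted

    def test_zero_divergence_exact_copies(self, tmp_path):
        from pyfaidx import Fasta

        cfg = one_type_config(divergence=0.0, n_copies=10, motif_plant_fraction=0.0)
        gp, truth = make_genome(cfg, str(tmp_path))
        assert (truth.repeats["milliDiv"] == 0).all()
        fa = Fasta(gp)
        row = truth.repeats.iloc[0]
        assert str(fa[row["chrom"]][row["start"]: row["end"]]) == "ACGT" * 75

    def test_realized_divergence_binomial_oracle(self, tmp_path):
        cfg = one_type_config(divergence=0.10, n_copies=200, motif_plant_fraction=0.0,
                              genome_length=700_000, spacing_min=100)
        _, truth = make_genome(cfg, str(tmp_path))
        md = truth.repeats["milliDiv"].to_numpy()
        se = 1000 * np.sqrt(0.1 * 0.9 / 300) / np.sqrt(200)
        assert abs(md.mean() - 100) < 3 * se

    def test_overflow_reports_feature_class(self, tmp_path):
        cfg = one_type_config(genome_length=10_000, n_copies=100)
        with pytest.raises(FeatureOverflowError, match="repeat|chimera|gene|satellite"):
            make_genome(cfg, str(tmp_path))

    def test_planted_motifs_score_above_threshold(self, tmp_path):
        from pyfaidx import Fasta
        from retroprom.motif import revcomp, score_window

        cfg = one_type_config(motif_plant_fraction=1.0, n_copies=20)
        gp, truth = make_genome(cfg, str(tmp_path))
        fa = Fasta(gp)
        pwm = default_pwm()
        for _, m in truth.motifs.iterrows():
            seq = str(fa["chrSim"][m["start"]: m["end"]])
            if m["strand"] == "-":
                seq = revcomp(seq)
            assert score_window(pwm, seq) >= 9.75

    def test_truth_coordinates_inside_genome(self, small_run):
        truth, cfg = small_run["truth"], small_run["config"]
        for df, cols in ((truth.repeats, ("start", "end")), (truth.motifs, ("start", "end")),
                         (truth.peaks, ("start", "end"))):
            if len(df):
                assert (df[cols[0]] >= 0).all()
                assert (df[cols[1]] <= cfg.genome_length).all()

    def test_truth_round_trip(self, small_run, tmp_path):
        import pandas as pd

        truth = small_run["truth"]
        truth.write(str(tmp_path))
        back = TruthTable.read(str(tmp_path))
        for name in TruthTable._FILES:
            a, b = getattr(truth, name), getattr(back, name)
            pd.testing.assert_frame_equal(
                a.reset_index(drop=True), b.reset_index(drop=True),
                check_dtype=False, check_names=False,
            )

    def test_repeats_do_not_overlap(self, small_run):
        df = small_run["truth"].repeats.sort_values("start")
        assert (df["start"].to_numpy()[1:] >= df["end"].to_numpy()[:-1]).all()


class TestChipSimulation:
    def test_null_signal_indistinguishable_from_control(self, tmp_path):
        cfg = one_type_config(chip_signal_fraction=0.0, reads_per_sample=10_000,
                              motif_plant_fraction=1.0)
        gp, truth = make_genome(cfg, str(tmp_path))
        t, c = simulate_chip_alignments(gp, truth, cfg, str(tmp_path))
        starts = {}
        for label, path in (("t", t), ("c", c)):
            with pysam.AlignmentFile(path, check_sq=False) as fh:
                starts[label] = np.array([r.reference_start for r in fh])
        ks = stats.ks_2samp(starts["t"], starts["c"])
        assert ks.pvalue > 0.01

    def test_pure_signal_concentrates_on_single_motif(self, tmp_path):
        cfg = one_type_config(chip_signal_fraction=1.0, n_copies=1, motif_plant_fraction=1.0,
                              genome_length=100_000, reads_per_sample=2_000)
        gp, truth = make_genome(cfg, str(tmp_path))
        t, _ = simulate_chip_alignments(gp, truth, cfg, str(tmp_path))
        m = truth.motifs.iloc[0]
        with pysam.AlignmentFile(t, check_sq=False) as fh:
            for rec in fh:
                assert m["start"] - 100 <= rec.reference_start <= m["end"] + 100

    def test_mixture_proportion_oracle(self, tmp_path):
        """Treatment read fraction on the bound type matches s + (1-s)*p."""
        from intervaltree import IntervalTree

        cfg = one_type_config(chip_signal_fraction=0.5, motif_plant_fraction=1.0,
                              n_copies=30, genome_length=900_000, reads_per_sample=20_000)
        gp, truth = make_genome(cfg, str(tmp_path))
        t, _ = simulate_chip_alignments(gp, truth, cfg, str(tmp_path))
        tree = IntervalTree()
        for _, r in truth.repeats.iterrows():
            tree.addi(r["start"], r["end"])
        n_on = 0
        with pysam.AlignmentFile(t, check_sq=False) as fh:
            for rec in fh:
                if tree.overlap(rec.reference_start, rec.reference_start + cfg.chip_read_length):
                    n_on += 1
        L = cfg.chip_read_length
        p_bg = sum(min(e, cfg.genome_length - L) - max(0, s - L + 1)
                   for s, e in zip(truth.repeats["start"], truth.repeats["end"])) / (cfg.genome_length - L + 1)
        expected = 0.5 * 1.0 + 0.5 * p_bg
        se = np.sqrt(expected * (1 - expected) / cfg.reads_per_sample)
        assert abs(n_on / cfg.reads_per_sample - expected) < 3 * se

    def test_error_when_no_motifs(self, tmp_path):
        cfg = one_type_config(motif_plant_fraction=0.0, chip_signal_fraction=0.5)
        gp, truth = make_genome(cfg, str(tmp_path))
        with pytest.raises(ValueError, match="no bound motifs"):
            simulate_chip_alignments(gp, truth, cfg, str(tmp_path))


class TestRnaSimulation:
    def test_no_chimeras_no_linking_reads(self, small_run, tmp_path):
        cfg = small_config(seed=31, chimera_fraction=0.0, n_genes=3,
                           rna_background_fraction=0.0, satellite_n_monomers=0)
        gp, truth = make_genome(cfg, str(tmp_path))
        paths = simulate_rna_alignments(gp, truth, cfg, str(tmp_path))
        for path in paths.values():
            with pysam.AlignmentFile(path, check_sq=False) as fh:
                assert all("N" not in (r.cigarstring or "") for r in fh)

    def test_linking_reads_present_in_both_treated(self, small_run):
        truth = small_run["truth"]
        assert len(truth.chimeric_pairs) > 0
        for sample in ("treated_1", "treated_2"):
            with pysam.AlignmentFile(small_run["rna"][sample], check_sq=False) as fh:
                spliced = [r for r in fh if "N" in (r.cigarstring or "")]
            assert spliced

    def test_nb_moment_oracle(self, rng):
        """Across-region variance matches mean + dispersion*mean^2."""
        m = simulate_count_matrix(rng, 500, 20.0, 1.0, 0.1)
        target = 20 + 0.1 * 400  # 60
        observed = m.to_numpy().var(axis=0, ddof=1).mean()
        assert abs(observed - target) / target < 0.15

    def test_sam_blocks_reconstruct_read_length(self, small_run):
        for path in list(small_run["rna"].values()) + list(small_run["chip"]):
            with pysam.AlignmentFile(path, check_sq=False) as fh:
                for rec in fh:
                    block_sum = sum(e - s for s, e in rec.get_blocks())
                    assert block_sum == len(rec.query_sequence)


class TestTracks:
    def test_sigma_zero_two_valued(self, tmp_path):
        cfg = one_type_config(motif_plant_fraction=1.0, n_copies=5,
                              track_sigma=0.0, snp_rho_in=0.0, snp_rho_out=0.0)
        gp, truth = make_genome(cfg, str(tmp_path))
        bg, _ = simulate_tracks(gp, truth, cfg, str(tmp_path))
        values = {float(line.split("\t")[3]) for line in open(bg)}
        assert values == {cfg.track_mu_motif, cfg.track_mu_flank}

    def test_null_parameters_flat_profile(self, tmp_path):
        cfg = one_type_config(motif_plant_fraction=1.0, n_copies=40,
                              track_mu_motif=0.5, track_mu_flank=0.5,
                              snp_rho_in=0.01, snp_rho_out=0.01, genome_length=400_000)
        gp, truth = make_genome(cfg, str(tmp_path))
        bg, snp = simulate_tracks(gp, truth, cfg, str(tmp_path))
        from retroprom.intervals_io import BedGraph, GenomicInterval, read_bed
        from retroprom.conservation import score_profile
        from retroprom.motif import BindingSite

        sites = [
            BindingSite(m["peak_id"], GenomicInterval("chrSim", m["start"], m["end"], m["strand"]),
                        m["strand"], 10.0)
            for _, m in truth.motifs.iterrows()
        ]
        prof = score_profile(sites, BedGraph.read(bg))
        inm = (prof.positions >= 0) & (prof.positions < 17)
        assert abs(np.nanmean(prof.values[inm]) - np.nanmean(prof.values[~inm])) < 3 * 0.5 / np.sqrt(40 * 17)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        dirs = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            out.mkdir()
            cfg = small_config(seed=99, genome_length=200_000, n_genes=2,
                               reads_per_sample=500)
            gp, truth = make_genome(cfg, str(out))
            simulate_chip_alignments(gp, truth, cfg, str(out))
            simulate_rna_alignments(gp, truth, cfg, str(out))
            simulate_tracks(gp, truth, cfg, str(out))
            dirs.append(out)
        names = [n for n in os.listdir(dirs[0]) if not n.endswith(".fai")]
        match, mismatch, errors = filecmp.cmpfiles(dirs[0], dirs[1], names, shallow=False)
        assert mismatch == [] and errors == []


class TestConfigValidation:
    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError):
            RepeatSpec("X", "F", "LTR", "ACGT", 1, 0.6)
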