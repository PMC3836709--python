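"""Region counting, normalization, NB testing, age comparison, ORF scan."""

import numpy as np
import pandas as pd
import pytest

from retroprom.intervals_io import AlignmentRecord, GenomicInterval, RepeatInstance
from retroprom.motif import BindingSite
from retroprom.activation import (
    InternalRegion,
    activation_percentage,
    compare_repeat_age,
    count_region_reads,
    find_orfs,
    flanked_by_bound_ltr,
    results_table,
    size_factors,
    summarize_activation,
)
from retroprom.activation import test_regions as run_region_test
from retroprom.fixtures import simulate_count_matrix


def read(start, end, chrom="chr1", sample="s1", blocks=None):
    blocks = blocks or ((start, end),)
    return AlignmentRecord("r", chrom, tuple(blocks), 60, sample)


class TestCountRegionReads:
    REGION = GenomicInterval("chr1", 10_000, 10_300)

    def test_no_reads_zero_matrix(self):
        m = count_region_reads({"s1": [], "s2": []}, [self.REGION])
        assert (m.to_numpy() == 0).all()

    def test_flank_boundary(self):
        inside = read(10_000 - 999 - 50, 10_000 - 999)   # ends 999 bp left of start
        outside = read(10_000 - 1050, 10_000 - 1001)     # ends just past the 1 kb window
        m = count_region_reads({"s1": [inside, outside]}, [self.REGION], flank=1000)
        assert m.iloc[0, 0] == 1

    def test_intron_spanning_read_not_counted(self):
        rec = read(8000, 13_000, blocks=((8000, 8050), (12_900, 13_000)))
        m = count_region_reads({"s1": [rec]}, [self.REGION], flank=0)
        assert m.iloc[0, 0] == 0

    def test_read_counts_once_per_region(self):
        rec = read(10_000, 10_300, blocks=((10_000, 10_050), (10_250, 10_300)))
        m = count_region_reads({"s1": [rec]}, [self.REGION], flank=0)
        assert m.iloc[0, 0] == 1

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            count_region_reads({"s1": []}, [self.REGION], flank=-1)

    def test_fixture_counts_recovered_exactly(self, tmp_path):
        """Planted per-region counts come back exactly when regions are isolated."""
        import os
        from retroprom import intervals_io as io
        from retroprom.fixtures import FixtureConfig, make_genome, simulate_rna_alignments
        from tests.conftest import small_config

        cfg = small_config(
            seed=23, genome_length=600_000, spacing_min=2300,
            chimera_fraction=0.0, n_genes=0, satellite_n_monomers=0,
            rna_background_fraction=0.0, reads_per_sample=1000,
        )
        out = str(tmp_path)
        gp, truth = make_genome(cfg, out)
        simulate_rna_alignments(gp, truth, cfg, out)
        samples = ["treated_1", "treated_2", "control_1", "control_2"]
        al = {s: io.read_alignments(os.path.join(out, f"rna_{s}.sam"), sample_id=s) for s in samples}
        peaks = [
            GenomicInterval("chrSim", int(s), int(e))
            for s, e in zip(truth.peaks["start"], truth.peaks["end"])
        ]
        m = count_region_reads(al, peaks, flank=1000)
        m.index = list(truth.peaks["peak_id"])
        planted = pd.read_csv(os.path.join(out, "rna_true_counts.tsv"), sep="\t", index_col=0)
        pd.testing.assert_frame_equal(
            m.sort_index(), planted.sort_index(), check_dtype=False, check_names=False
        )


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        m = np.tile(np.array([[10], [20], [30]]), (1, 2))
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_doubled_sample_factor_ratio_two(self):
        a = np.array([10, 20, 30, 40])
        m = np.column_stack([a, 2 * a])
        f = size_factors(m)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self, rng):
        """Pure-python recomputation of the log-scale median of ratios."""
        import math

        m = rng.negative_binomial(10, 0.3, size=(200, 4)) + 1
        f = size_factors(m)
        for j in range(4):
            log_ratios = []
            for i in range(200):
                gm = math.exp(sum(math.log(x) for x in m[i]) / 4)
                log_ratios.append(math.log(m[i, j] / gm))
            v = sorted(log_ratios)
            mid = len(v) // 2
            med = v[mid] if len(v) % 2 else (v[mid - 1] + v[mid]) / 2
            assert abs(f[j] - math.exp(med)) < 1e-12

    def test_all_zero_region_matrix_rejected(self):
        with pytest.raises(ValueError):
            size_factors(np.array([[0, 1], [1, 0]]))


TREATED = ["treated_1", "treated_2"]
CONTROL = ["control_1", "control_2"]


class TestTestRegions:
    def test_identical_counts_no_calls(self):
        m = pd.DataFrame(
            {s: [50, 100, 200] for s in TREATED + CONTROL},
            index=["a", "b", "c"],
        )
        res = run_region_test(m, TREATED, CONTROL)
        assert all(r.call == "ns" for r in res)
        assert all(r.fold_change == pytest.approx(1.0) for r in res)

    def test_low_total_region_excluded(self):
        m = pd.DataFrame(
            {"treated_1": [0, 50], "treated_2": [0, 50], "control_1": [0, 50], "control_2": [9, 50]},
            index=["low", "high"],
        )
        res = run_region_test(m, TREATED, CONTROL, min_total=10)
        assert [r.region_id for r in res] == ["high"]

    def test_single_sample_group_rejected(self):
        m = pd.DataFrame({"treated_1": [10], "control_1": [10], "control_2": [10]})
        with pytest.raises(ValueError):
            run_region_test(m, ["treated_1"], CONTROL)

    def test_bh_monotonicity(self, rng):
        m = simulate_count_matrix(rng, 500, 50.0, 1.0, 0.1)
        res = run_region_test(m, TREATED, CONTROL)
        df = results_table(res).sort_values("p_value")
        assert (df["padj"].to_numpy() >= df["p_value"].to_numpy() - 1e-15).all()
        assert (np.diff(np.maximum.accumulate(df["padj"].to_numpy())) >= -1e-15).all()
        assert df["padj"].min() >= df["p_value"].min() - 1e-15

    def test_within_group_label_permutation_invariant(self, rng):
        m = simulate_count_matrix(rng, 200, 30.0, 1.0, 0.1)
        res1 = run_region_test(m, TREATED, CONTROL)
        res2 = run_region_test(m, TREATED[::-1], CONTROL[::-1])
        p1 = np.array([r.p_value for r in res1])
        p2 = np.array([r.p_value for r in res2])
        fc1 = np.array([r.fold_change for r in res1])
        fc2 = np.array([r.fold_change for r in res2])
        assert np.allclose(p1, p2, rtol=1e-10)
        assert np.allclose(fc1, fc2, rtol=1e-10)

    def test_poisson_limit(self, rng):
        """With dispersion -> 0 and large counts the NB test approaches a Poisson Wald test."""
        from scipy import stats

        m = simulate_count_matrix(rng, 200, 500.0, 1.0, 0.0)
        res = run_region_test(m, TREATED, CONTROL)
        k = m.to_numpy(float)
        sf = size_factors(k)
        q = k / sf
        mu_t, mu_c, mu0 = q[:, :2].mean(1), q[:, 2:].mean(1), q.mean(1)
        v = (np.sum(mu0[:, None] / sf[None, :2], axis=1) / 4
             + np.sum(mu0[:, None] / sf[None, 2:], axis=1) / 4)
        z_pois = np.abs(mu_t - mu_c) / np.sqrt(v)
        z_nb = stats.norm.isf(np.array([r.p_value for r in res]) / 2)
        # the residual dispersion floor only inflates the variance, never deflates
        assert np.all(z_nb <= z_pois + 1e-9)
        ok = z_pois > 0.5
        assert np.all(z_nb[ok] >= 0.7 * z_pois[ok])


class TestSummaries:
    @pytest.mark.parametrize(
        "n_act,n_total,expected",
        [(738, 63_795, 1.2), (43, 3_214, 1.3), (65, 6_594, 1.0),
         (16, 742, 2.2), (42, 778, 5.4), (0, 100, 0.0)],
    )
    def test_percentage_rounding(self, n_act, n_total, expected):
        assert activation_percentage(n_act, n_total) == expected

    def test_summarize_by_context(self):
        from retroprom.activation import RegionTestResult

        rep = RepeatInstance(GenomicInterval("chr1", 0, 300, "+"), "THE1B", "ERVL-MaLR", "LTR", 100)
        sites = [
            BindingSite("p1", GenomicInterval("chr1", 10, 27, "+"), "+", 10.0, rep),
            BindingSite("p2", GenomicInterval("chr1", 1000, 1017, "+"), "+", 10.0, "unique"),
        ]
        res = [RegionTestResult("p1", (0,), 10, 1, 10, 1e-4, 1e-3, "activated")]
        df = summarize_activation(res, sites).set_index("context")
        assert df.loc["THE1B", "n_activated"] == 1
        assert df.loc["THE1B", "pct_activated"] == 100.0
        assert df.loc["unique", "n_activated"] == 0
        assert df.loc["all", "n_bound"] == 2


def ltr_site(start, cls="LTR", kind_name="THE1B"):
    rep = RepeatInstance(GenomicInterval("chr1", start - 50, start + 300, "+"),
                         kind_name, "ERVL-MaLR", cls, 100)
    return BindingSite("p", GenomicInterval("chr1", start, start + 17, "+"), "+", 10.0, rep)


def internal(start, end, milli_div=100):
    return RepeatInstance(GenomicInterval("chr1", start, end, "+"),
                          "THE1B-int", "ERVL-MaLR", "LTR", milli_div)


class TestLtrFlanking:
    def test_boundary_distance(self):
        region = internal(100_000, 101_000)
        near = ltr_site(100_000 - 4_999 - 17)   # gap exactly 4999 < 5000
        out = flanked_by_bound_ltr([region], [near], max_dist=5000)
        assert out[0].flanked_by_bound_ltr

    def test_non_ltr_context_does_not_flag(self):
        region = internal(100_000, 101_000)
        site = BindingSite("p", GenomicInterval("chr1", 99_900, 99_917, "+"), "+", 10.0, "unique")
        out = flanked_by_bound_ltr([region], [site])
        assert not out[0].flanked_by_bound_ltr

    def test_too_far_not_flagged(self):
        region = internal(100_000, 101_000)
        far = ltr_site(100_000 - 6_000)
        out = flanked_by_bound_ltr([region], [far], max_dist=5000)
        assert not out[0].flanked_by_bound_ltr


class TestRepeatAge:
    def region_id(self, r):
        iv = r.repeat.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    def make_regions(self, rng, n, milli_div_mean, start0):
        out = []
        for i in range(n):
            start = start0 + i * 2000
            md = max(0, int(rng.normal(milli_div_mean, 10)))
            out.append(InternalRegion(internal(start, start + 800, md), True))
        return out

    def test_short_regions_excluded(self):
        short = InternalRegion(internal(0, 499), True)
        with pytest.raises(ValueError):
            compare_repeat_age([short], set())

    def test_identical_distributions_nonsignificant(self, rng):
        regions = self.make_regions(rng, 100, 150, 0)
        act = {self.region_id(r) for r in regions[:50]}
        a, b, p = compare_repeat_age(regions, act)
        assert p > 0.05

    def test_planted_age_separation(self, rng):
        young = self.make_regions(rng, 50, 50, 0)
        old = self.make_regions(rng, 500, 200, 1_000_000)
        act = {self.region_id(r) for r in young}
        a, b, p = compare_repeat_age(young + old, act)
        assert np.median(a) < np.median(b)
        assert p < 0.01


class TestFindOrfs:
    def test_no_atg_empty(self):
        assert find_orfs("CCCCCCTAACCC", 1) == []

    def test_constructed_orf_length(self):
        seq = "ATG" + "GCT" * 300 + "TAA"
        orfs = find_orfs(seq, 300)
        assert len(orfs) == 1
        assert orfs[0].length_aa == 301
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (0, len(seq), "+")

    def test_unterminated_orf_not_reported(self):
        assert find_orfs("ATG" + "GCT" * 50, 10) == []

    def test_n_codons_never_start_or_stop(self):
        assert find_orfs("ATN" + "GCT" * 20 + "TAA", 5) == []
        # N in the stop position: TAN is not a stop, so the ORF never terminates
        assert find_orfs("ATG" + "GCT" * 20 + "TAN", 5) == []

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGXXXTAA", 1)

    def brute(self, seq, min_aa):
        """Independent six-frame enumeration: split each frame at stops,
        open at the first ATG of each stop-terminated segment."""
        from retroprom.motif import revcomp

        stops = {"TAA", "TAG", "TGA"}
        found = set()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for frame in range(3):
                codons = [s[i: i + 3] for i in range(frame, n - 2, 3)]
                seg_start = 0
                for ci, codon in enumerate(codons):
                    if codon in stops:
                        seg = codons[seg_start:ci]
                        for k, c in enumerate(seg):
                            if c == "ATG":
                                aa = len(seg) - k
                                if aa >= min_aa:
                                    a = frame + 3 * (seg_start + k)
                                    b = frame + 3 * (ci + 1)
                                    if strand == "-":
                                        a, b = n - b, n - a
                                    found.add((frame, strand, a, b, aa))
                                break
                        seg_start = ci + 1
        return found

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            got = {(o.frame, o.strand, o.start, o.end, o.length_aa) for o in find_orfs(seq, 20)}
            assert got == self.brute(seq, 20)
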