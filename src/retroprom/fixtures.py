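"""Synthetic genome, annotation, alignment and track generator.

The generator emulates the statistical structure the pipeline assumes:

* a background genome of configurable GC content carrying planted repeat
  instances drawn from consensus sequences with per-site divergence;
* a subset of instances of designated repeat types carrying one planted
  PWM-consensus motif (these are the "bound" sites; a peak interval is
  emitted around each);
* ChIP reads concentrated near bound motifs over a uniform background,
  with an all-uniform control library (real ChIP libraries are 50-90%
  background, so the default signal fraction is 0.3);
* RNA libraries (two treated, two control) with negative-binomial
  per-region counts, spliced reads linking repeat promoters to gene
  exon 2 for the planted chimeric pairs, satellite-array reads, and
  uniform background;
* a conservation track elevated at motifs and SNPs depleted in motifs.

Everything is deterministic under the configured seed, and every planted
feature is recorded in a TruthTable for parameter-recovery tests.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals_io import GeneModel, GenomicInterval, RepeatInstance, write_bed, write_gtf, write_repeat_table
from .motif import PWM, revcomp, write_pwm

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatSpec:
    name: str
    family: str
    rep_class: str
    consensus: str
    n_copies: int
    divergence: float

    def __post_init__(self):
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError(f"divergence for {self.name} must be in [0, 0.5]")


def default_pwm(width: int = 17) -> PWM:
    """Surrogate AT-rich motif PWM whose consensus scores well above 9.75.

    Weights are deterministic: the consensus base at position i scores
    1 + 0.02*i, alternatives score around -1, so a window needs roughly
    14/17 consensus matches to clear the canonical 9.75 threshold.
    """
    consensus = "TAATCCAATCAAATTGA"[:width]
    if len(consensus) < width:
        consensus = (consensus * math.ceil(width / len(consensus)))[:width]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = np.zeros((width, 4))
    for i, base in enumerate(consensus):
        for b in range(4):
            w[i, b] = -0.9 - 0.05 * ((i + b) % 3)
        w[i, idx[base]] = 1.0 + 0.02 * i
    return PWM(name="surrogate_motif", weights=w, score_threshold=9.75)


def _default_catalog() -> tuple:
    rng = np.random.default_rng(20260921)
    def cons(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    return (
        RepeatSpec("THE1X", "ERVL-MaLR", "LTR", cons(350), 60, 0.08),
        RepeatSpec("THE1X-int", "ERVL-MaLR", "LTR", cons(400), 20, 0.10),
        RepeatSpec("MLT9A", "ERVL", "LTR", cons(300), 40, 0.12),
        RepeatSpec("L1XX", "L1", "LINE", cons(500), 40, 0.20),
        RepeatSpec("AluYZ", "Alu", "SINE", cons(280), 60, 0.15),
    )


@dataclass
class FixtureConfig:
    genome_length: int = 1_000_000
    chrom: str = "chrSim"
    gc_fraction: float = 0.5
    repeat_catalog: tuple = field(default_factory=_default_catalog)
    motif_types: tuple = ("THE1X", "MLT9A")   # types eligible for motif planting
    motif_plant_fraction: float = 0.5
    n_genes: int = 20
    chimera_fraction: float = 0.3             # of motif-bearing repeats, paired with a gene
    chimera_distance: tuple = (1000, 50000)   # repeat end to gene start, bp
    peak_halfwidth: int = 150                 # peak = motif +/- this
    spacing_min: int = 300                    # minimum gap between planted blocks

    chip_signal_fraction: float = 0.3         # ChIP libraries are 50-90% background
    chip_read_length: int = 40
    reads_per_sample: int = 50_000
    read_length: int = 100                    # RNA reads

    region_mean: float = 50.0                 # NB mean reads/region/sample (control)
    activation_fold: float = 8.0
    activated_fraction: float = 0.1           # of bound regions
    nb_dispersion: float = 0.1
    linking_mean: float = 10.0                # spliced linking reads/pair/treated sample
    rna_background_fraction: float = 0.1      # of reads_per_sample, uniform genomic

    satellite_monomer_len: int = 170
    satellite_n_monomers: int = 50
    satellite_fraction_treated: float = 6.7e-3
    satellite_fraction_control: float = 8.0e-6

    track_mu_motif: float = 1.0
    track_mu_flank: float = 0.0
    track_sigma: float = 0.5
    track_flank: int = 50                     # emitted neighborhood half-width
    snp_rho_in: float = 0.002                 # SNP density inside motifs
    snp_rho_out: float = 0.02                 # ... in flanks

    rng_seed: int = 0

    def __post_init__(self):
        for spec in self.repeat_catalog:
            if not (0.0 <= spec.divergence <= 0.5):
                raise ValueError("divergence rates must lie in [0, 0.5]")


class FeatureOverflowError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Truth table

@dataclass
class TruthTable:
    repeats: pd.DataFrame          # repeat_id, coords, type/family/class, milliDiv, has_motif
    motifs: pd.DataFrame           # motif_id, repeat_id, peak_id, start, end, strand
    peaks: pd.DataFrame            # peak_id, start, end, activated, fold_change
    chimeric_pairs: pd.DataFrame   # peak_id, repeat_id, gene_id
    genes: pd.DataFrame            # gene_id, exon coords
    enrichment: pd.DataFrame       # rep_type, n_instances, total_bp, n_bound_motifs, true_peak_enrichment
    satellite: pd.DataFrame        # array coords and planted expression fractions

    _FILES = ("repeats", "motifs", "peaks", "chimeric_pairs", "genes", "enrichment", "satellite")

    def write(self, outdir) -> None:
        for name in self._FILES:
            getattr(self, name).to_csv(os.path.join(outdir, f"truth_{name}.tsv"), sep="\t", index=False)

    @classmethod
    def read(cls, outdir) -> "TruthTable":
        frames = {
            name: pd.read_csv(os.path.join(outdir, f"truth_{name}.tsv"), sep="\t")
            for name in cls._FILES
        }
        return cls(**frames)


# ---------------------------------------------------------------------------
# Genome assembly

def _random_bases(rng, n, gc_fraction):
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return rng.choice(_BASES, size=n, p=[p_at, p_gc, p_gc, p_at])


def _mutate(rng, consensus: str, divergence: float) -> tuple[str, int]:
    """Substitute each site independently with the given probability.

    Returns (sequence, number of realized substitutions)."""
    arr = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    n_sub = int(hit.sum())
    if n_sub:
        # pick one of the three non-identical bases per hit site
        for i in np.flatnonzero(hit):
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), n_sub


@dataclass
class _Block:
    kind: str
    length: int
    payload: dict


def make_genome(config: FixtureConfig, outdir):
    """Generate genome FASTA, repeat annotation, gene GTF, peaks BED and truth.

    Returns (genome_path, truth). Also writes the surrogate PWM.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    pwm = default_pwm()
    motif_seq = pwm.consensus()
    width = pwm.width

    # --- build feature blocks -------------------------------------------
    repeat_payloads = []
    for spec in config.repeat_catalog:
        for copy in range(spec.n_copies):
            seq, n_sub = _mutate(rng, spec.consensus, spec.divergence)
            milli_div = round(1000 * n_sub / len(spec.consensus))
            repeat_payloads.append({
                "spec": spec, "seq": seq, "milli_div": milli_div,
                "motif_offset": None, "motif_strand": None,
            })
    eligible = [p for p in repeat_payloads if p["spec"].name in config.motif_types]
    n_motif = int(round(config.motif_plant_fraction * len(eligible)))
    for p_idx in rng.permutation(len(eligible))[:n_motif]:
        p = eligible[p_idx]
        seq = p["seq"]
        if len(seq) < width:
            continue
        off = (len(seq) - width) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        planted = motif_seq if strand == "+" else revcomp(motif_seq)
        p["seq"] = seq[:off] + planted + seq[off + width:]
        p["motif_offset"], p["motif_strand"] = off, strand

    motif_bearing = [p for p in repeat_payloads if p["motif_offset"] is not None]
    n_pairs = min(int(round(config.chimera_fraction * len(motif_bearing))), config.n_genes)
    paired = [motif_bearing[i] for i in rng.permutation(len(motif_bearing))[:n_pairs]]
    for p in paired:
        p["chimeric"] = True

    exon1_len, intron_len, exon2_len = 200, 800, 300
    gene_span = exon1_len + intron_len + exon2_len

    blocks: list[_Block] = []
    for p in repeat_payloads:
        if p.get("chimeric"):
            d = int(rng.integers(config.chimera_distance[0], config.chimera_distance[1] + 1))
            blocks.append(_Block("chimera", len(p["seq"]) + d + gene_span, {"repeat": p, "distance": d}))
        else:
            blocks.append(_Block("repeat", len(p["seq"]), {"repeat": p}))
    for _ in range(config.n_genes - n_pairs):
        blocks.append(_Block("gene", gene_span, {}))
    sat_len = config.satellite_monomer_len * config.satellite_n_monomers
    monomer = "".join("ACGT"[i] for i in rng.integers(0, 4, config.satellite_monomer_len))
    if config.satellite_n_monomers > 0:
        blocks.append(_Block("satellite", sat_len, {"monomer": monomer}))

    total_feature = sum(b.length for b in blocks)
    n_gaps = len(blocks) + 1
    slack = config.genome_length - total_feature - n_gaps * config.spacing_min
    if slack < 0:
        biggest = max(blocks, key=lambda b: b.length)
        raise FeatureOverflowError(
            f"genome_length {config.genome_length} cannot accommodate planted features "
            f"(need >= {total_feature + n_gaps * config.spacing_min} bp; "
            f"largest feature class: {biggest.kind})"
        )
    order = rng.permutation(len(blocks))
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps)) if slack > 0 else np.zeros(n_gaps, dtype=int)
    gaps = extra + config.spacing_min

    # --- lay out --------------------------------------------------------
    genome = _random_bases(rng, config.genome_length, config.gc_fraction)
    chrom = config.chrom
    cursor = int(gaps[0])
    repeat_rows, motif_rows, peak_rows, pair_rows, gene_rows, sat_rows = [], [], [], [], [], []
    genes: list[GeneModel] = []
    repeats: list[RepeatInstance] = []
    rep_counter = gene_counter = motif_counter = 0

    def place_seq(seq: str, at: int):
        genome[at: at + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)

    def place_repeat(p, at: int):
        nonlocal rep_counter, motif_counter
        spec, seq = p["spec"], p["seq"]
        place_seq(seq, at)
        iv = GenomicInterval(chrom, at, at + len(seq), "+")
        inst = RepeatInstance(iv, spec.name, spec.family, spec.rep_class, p["milli_div"])
        repeats.append(inst)
        rep_id = f"rep_{rep_counter:05d}"
        rep_counter += 1
        has_motif = p["motif_offset"] is not None
        repeat_rows.append((rep_id, chrom, at, at + len(seq), "+", spec.name, spec.family,
                            spec.rep_class, p["milli_div"], int(has_motif)))
        peak_id = None
        if has_motif:
            m_start = at + p["motif_offset"]
            peak_id = f"peak_{motif_counter:05d}"
            motif_rows.append((f"motif_{motif_counter:05d}", rep_id, peak_id,
                               m_start, m_start + width, p["motif_strand"]))
            peak_rows.append([peak_id, max(0, m_start - config.peak_halfwidth),
                              min(config.genome_length, m_start + width + config.peak_halfwidth)])
            motif_counter += 1
        return rep_id, peak_id

    def place_gene(at: int) -> str:
        nonlocal gene_counter
        gid = f"gene_{gene_counter:04d}"
        gene_counter += 1
        e1 = GenomicInterval(chrom, at, at + exon1_len, "+")
        e2 = GenomicInterval(chrom, at + exon1_len + intron_len, at + gene_span, "+")
        genes.append(GeneModel(gid, chrom, "+", (e1, e2)))
        gene_rows.append((gid, chrom, e1.start, e1.end, e2.start, e2.end, "+"))
        return gid

    for bi, gap_after in zip(order, gaps[1:]):
        b = blocks[bi]
        if b.kind in ("repeat", "chimera"):
            rep_id, peak_id = place_repeat(b.payload["repeat"], cursor)
            if b.kind == "chimera":
                rep_len = len(b.payload["repeat"]["seq"])
                gid = place_gene(cursor + rep_len + b.payload["distance"])
                pair_rows.append((peak_id, rep_id, gid))
        elif b.kind == "gene":
            place_gene(cursor)
        elif b.kind == "satellite":
            arr_seq = b.payload["monomer"] * config.satellite_n_monomers
            place_seq(arr_seq, cursor)
            sat_rows.append((chrom, cursor, cursor + len(arr_seq), b.payload["monomer"],
                             config.satellite_n_monomers,
                             config.satellite_fraction_treated, config.satellite_fraction_control))
        cursor += b.length + int(gap_after)

    # --- activation truth ------------------------------------------------
    peaks_df = pd.DataFrame(peak_rows, columns=["peak_id", "start", "end"])
    n_act = int(round(config.activated_fraction * len(peaks_df)))
    activated = np.zeros(len(peaks_df), dtype=int)
    chim_peaks = {r[0] for r in pair_rows}
    # chimeric peaks are activated by construction; fill the rest randomly
    for i, pid in enumerate(peaks_df["peak_id"]):
        if pid in chim_peaks:
            activated[i] = 1
    remaining = np.flatnonzero(activated == 0)
    need = max(0, n_act - int(activated.sum()))
    if need and remaining.size:
        sel = rng.permutation(remaining.size)[:need]
        activated[remaining[sel]] = 1
    peaks_df["activated"] = activated
    peaks_df["fold_change"] = np.where(activated == 1, config.activation_fold, 1.0)

    # --- enrichment truth -------------------------------------------------
    rep_df = pd.DataFrame(repeat_rows, columns=["repeat_id", "chrom", "start", "end", "strand",
                                                "rep_type", "rep_family", "rep_class", "milliDiv",
                                                "has_motif"])
    enr_rows = []
    total_motifs = int(rep_df["has_motif"].sum())
    for rep_type, grp in rep_df.groupby("rep_type"):
        bp = int((grp["end"] - grp["start"]).sum())
        n_bound = int(grp["has_motif"].sum())
        w = n_bound / total_motifs if total_motifs else 0.0
        p_bp = bp / config.genome_length
        enr_rows.append((rep_type, len(grp), bp, n_bound, w / p_bp if p_bp > 0 else 0.0))
    enr_df = pd.DataFrame(enr_rows, columns=["rep_type", "n_instances", "total_bp",
                                             "n_bound_motifs", "true_peak_enrichment"])

    truth = TruthTable(
        repeats=rep_df,
        motifs=pd.DataFrame(motif_rows, columns=["motif_id", "repeat_id", "peak_id",
                                                 "start", "end", "strand"]),
        peaks=peaks_df,
        chimeric_pairs=pd.DataFrame(pair_rows, columns=["peak_id", "repeat_id", "gene_id"]),
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "exon1_start", "exon1_end",
                                               "exon2_start", "exon2_end", "strand"]),
        enrichment=enr_df,
        satellite=pd.DataFrame(sat_rows, columns=["chrom", "start", "end", "monomer",
                                                  "n_monomers", "frac_treated", "frac_control"]),
    )

    # --- write -----------------------------------------------------------
    genome_path = os.path.join(outdir, "genome.fa")
    with open(genome_path, "w") as fh:
        fh.write(f">{chrom}\n")
        raw = genome.tobytes().decode()
        for i in range(0, len(raw), 80):
            fh.write(raw[i: i + 80] + "\n")
    write_repeat_table(repeats, os.path.join(outdir, "repeats.tsv"))
    write_gtf(genes, os.path.join(outdir, "genes.gtf"))
    peak_ivs = [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(peaks_df["start"], peaks_df["end"])]
    write_bed(peak_ivs, os.path.join(outdir, "peaks.bed"), names=list(peaks_df["peak_id"]))
    write_pwm(pwm, os.path.join(outdir, "pwm.tsv"))
    truth.write(outdir)
    return genome_path, truth


# ---------------------------------------------------------------------------
# Alignment emission

def _write_sam(path, chrom, chrom_len, records, extra_refs=()):
    """records: iterable of (name, chrom, pos0, cigar, seq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len}\n")
        for name, length in extra_refs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for name, rchrom, pos0, cigar, seq in records:
            fh.write(f"{name}\t0\t{rchrom}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n")


def _genome_str(genome_path):
    from pyfaidx import Fasta

    fa = Fasta(genome_path)
    chrom = list(fa.keys())[0]
    return chrom, str(fa[chrom][:])


def simulate_chip_alignments(genome_path, truth: TruthTable, config: FixtureConfig, outdir,
                             emit_fasta: bool = False):
    """Emit treatment and control ChIP SAM files.

    Treatment: a chip_signal_fraction of reads start uniformly within
    +/-100 bp of a uniformly chosen bound motif; the rest (and the whole
    control library) are uniform over the genome.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    chrom, seq = _genome_str(genome_path)
    G, L = len(seq), config.chip_read_length
    motifs = truth.motifs
    if config.chip_signal_fraction > 0 and len(motifs) == 0:
        raise ValueError("chip_signal_fraction > 0 but no bound motifs planted")

    def uniform_starts(n):
        return rng.integers(0, G - L + 1, size=n)

    def signal_starts(n):
        idx = rng.integers(0, len(motifs), size=n)
        starts = np.empty(n, dtype=np.int64)
        m_start = motifs["start"].to_numpy()
        m_end = motifs["end"].to_numpy()
        for i, mi in enumerate(idx):
            lo = max(0, m_start[mi] - 100)
            hi = min(G - L, m_end[mi] + 100 - L)
            starts[i] = rng.integers(lo, max(lo + 1, hi + 1))
        return starts

    paths = {}
    for label, signal_frac in (("chip_treatment", config.chip_signal_fraction), ("chip_control", 0.0)):
        n = config.reads_per_sample
        is_signal = rng.random(n) < signal_frac
        starts = np.where(is_signal, 0, uniform_starts(n))
        n_sig = int(is_signal.sum())
        if n_sig:
            starts[is_signal] = signal_starts(n_sig)
        recs = [
            (f"{label}_{i:07d}", chrom, int(s), f"{L}M", seq[s: s + L])
            for i, s in enumerate(starts)
        ]
        path = os.path.join(outdir, f"{label}.sam")
        _write_sam(path, chrom, G, recs)
        if emit_fasta:
            with open(os.path.join(outdir, f"{label}.fa"), "w") as fh:
                for name, _, _, _, rseq in recs:
                    fh.write(f">{name}\n{rseq}\n")
        paths[label] = path
    return paths["chip_treatment"], paths["chip_control"]


def _nb_draw(rng, mean, dispersion):
    """One NB draw with the mean/dispersion parameterization Var = mu + a*mu^2."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_rna_alignments(genome_path, truth: TruthTable, config: FixtureConfig, outdir,
                            emit_fasta: bool = False) -> dict[str, str]:
    """Emit four RNA-seq SAMs: treated_1/2 and control_1/2.

    Per bound region, reads ~ NB(region_mean * fold, dispersion) placed
    unspliced within the peak; for each true chimeric pair the treated
    samples carry spliced reads (block in the repeat, N-gap >= 20, block
    in gene exon 2); a configured fraction of reads comes from the
    satellite array; the rest is uniform background.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    chrom, seq = _genome_str(genome_path)
    G, L = len(seq), config.read_length
    if config.chimera_fraction > 0 and len(truth.chimeric_pairs) == 0 and len(truth.peaks):
        raise ValueError("chimera_fraction > 0 but no chimeric pairs planted")

    half = L // 2
    pair_info = truth.chimeric_pairs.merge(
        truth.motifs[["peak_id", "start", "end", "repeat_id"]], on="peak_id", how="left",
        suffixes=("", "_motif"),
    ).merge(truth.genes[["gene_id", "exon2_start", "exon2_end"]], on="gene_id", how="left")

    paths = {}
    region_counts: dict[str, list[int]] = {}
    for sample, treated in (("treated_1", True), ("treated_2", True),
                            ("control_1", False), ("control_2", False)):
        recs = []
        ridx = 0

        def emit(pos, cigar, rseq):
            nonlocal ridx
            recs.append((f"{sample}_{ridx:07d}", chrom, int(pos), cigar, rseq))
            ridx += 1

        # per-region expression reads
        for _, pk in truth.peaks.iterrows():
            mean = config.region_mean * (pk["fold_change"] if treated else 1.0)
            n = int(_nb_draw(rng, mean, config.nb_dispersion))
            region_counts.setdefault(pk["peak_id"], []).append(n)
            lo, hi = int(pk["start"]), int(pk["end"]) - L
            if hi <= lo:
                lo, hi = int(pk["start"]), int(pk["start"]) + 1
            for s in rng.integers(lo, hi + 1, size=n):
                emit(s, f"{L}M", seq[s: s + L])

        # chimeric linking reads (treated only)
        if treated:
            for _, pr in pair_info.iterrows():
                n = int(rng.poisson(config.linking_mean))
                b1_start = int(pr["start"]) - half // 2   # block 1 covers the motif region
                b2_start = int(pr["exon2_start"])
                gap = b2_start - (b1_start + half)
                if gap < 20:
                    continue
                cigar = f"{half}M{gap}N{L - half}M"
                rseq = seq[b1_start: b1_start + half] + seq[b2_start: b2_start + L - half]
                for _ in range(n):
                    emit(b1_start, cigar, rseq)

        # satellite reads
        if len(truth.satellite):
            sat = truth.satellite.iloc[0]
            frac = sat["frac_treated"] if treated else sat["frac_control"]
            n = int(rng.binomial(config.reads_per_sample, frac))
            lo, hi = int(sat["start"]), int(sat["end"]) - L
            for s in rng.integers(lo, hi + 1, size=n):
                emit(s, f"{L}M", seq[s: s + L])

        # background: transcriptome-derived when gene models exist (polyA
        # RNA-seq background comes from expressed transcripts, not uniformly
        # from the genome), else uniform genomic
        n_bg = int(config.rna_background_fraction * config.reads_per_sample)
        if n_bg > 0:
            exon_rows = []
            for _, g in truth.genes.iterrows():
                for a, b in ((g["exon1_start"], g["exon1_end"]), (g["exon2_start"], g["exon2_end"])):
                    if b - a >= L:
                        exon_rows.append((int(a), int(b)))
            if exon_rows:
                lens = np.array([b - a - L + 1 for a, b in exon_rows], dtype=float)
                probs = lens / lens.sum()
                choice = rng.choice(len(exon_rows), size=n_bg, p=probs)
                for ci in choice:
                    a, b = exon_rows[ci]
                    s = int(rng.integers(a, b - L + 1))
                    emit(s, f"{L}M", seq[s: s + L])
            else:
                for s in rng.integers(0, G - L + 1, size=n_bg):
                    emit(s, f"{L}M", seq[s: s + L])

        path = os.path.join(outdir, f"rna_{sample}.sam")
        _write_sam(path, chrom, G, recs)
        if emit_fasta:
            with open(os.path.join(outdir, f"rna_{sample}.fa"), "w") as fh:
                for name, _, _, _, rseq in recs:
                    fh.write(f">{name}\n{rseq}\n")
        paths[sample] = path
    # realized per-region expression counts, for exact-recovery tests
    cnt_df = pd.DataFrame.from_dict(
        region_counts, orient="index",
        columns=["treated_1", "treated_2", "control_1", "control_2"],
    )
    cnt_df.index.name = "peak_id"
    cnt_df.to_csv(os.path.join(outdir, "rna_true_counts.tsv"), sep="\t")
    return paths


def simulate_tracks(genome_path, truth: TruthTable, config: FixtureConfig, outdir):
    """Emit a conservation bedGraph and a SNP BED around every planted motif.

    Per-base conservation ~ N(mu_motif, sigma) inside motifs and
    N(mu_flank, sigma) in the emitted flanks; SNP incidence is Bernoulli
    with density rho_in inside motifs and rho_out in flanks.
    """
    rng = np.random.default_rng(config.rng_seed + 3)
    chrom, seq = _genome_str(genome_path)
    flank = config.track_flank
    bg_path = os.path.join(outdir, "conservation.bedGraph")
    snp_path = os.path.join(outdir, "snps.bed")
    with open(bg_path, "w") as bg, open(snp_path, "w") as sb:
        snp_i = 0
        for _, m in truth.motifs.iterrows():
            lo = max(0, int(m["start"]) - flank)
            hi = min(len(seq), int(m["end"]) + flank)
            for pos in range(lo, hi):
                inside = int(m["start"]) <= pos < int(m["end"])
                mu = config.track_mu_motif if inside else config.track_mu_flank
                val = mu if config.track_sigma == 0 else rng.normal(mu, config.track_sigma)
                bg.write(f"{chrom}\t{pos}\t{pos + 1}\t{val:.4f}\n")
                rho = config.snp_rho_in if inside else config.snp_rho_out
                if rng.random() < rho:
                    sb.write(f"{chrom}\t{pos}\t{pos + 1}\tsnp_{snp_i}\t0\t+\n")
                    snp_i += 1
    return bg_path, snp_path


def simulate_count_matrix(rng, n_regions: int, means, fold, dispersion: float,
                          n_treated: int = 2, n_control: int = 2) -> pd.DataFrame:
    """NB count matrix with known per-region fold changes (no genome involved).

    `means` may be scalar or per-region; `fold` likewise (applied to the
    treated group). Used for statistical-calibration studies of the
    region test at scales where read-level simulation is unnecessary.
    """
    means = np.broadcast_to(np.asarray(means, dtype=float), (n_regions,)).copy()
    fold = np.broadcast_to(np.asarray(fold, dtype=float), (n_regions,)).copy()

    def draw(mu):
        if dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu))

    data = {}
    for j in range(n_treated):
        data[f"treated_{j + 1}"] = draw(means * fold)
    for j in range(n_control):
        data[f"control_{j + 1}"] = draw(means)
    return pd.DataFrame(data, index=[f"region_{i:05d}" for i in range(n_regions)])
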