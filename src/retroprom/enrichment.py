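"""Repeat-enrichment estimators for ChIP-seq (and RNA-seq) data.

Two complementary estimators:

* peak-based — the proportion of refined binding sites whose best motif
  window falls in each repeat type, divided by the proportion of the
  sequenced (non-N) genome occupied by that type. Uses uniquely-mapped
  data upstream, so it is blind to recently duplicated repeats. An
  AT-matched random-window background is also provided, controlling for
  base-composition bias of AT-rich motifs.

* read-based — reads are aggregated over *all* genomic copies of each
  repeat type by mapping against a pseudo-chromosome reference in which
  every instance of a type (plus half-read-length flanks) is concatenated
  with read-length-exceeding N spacers. Per-type read proportions in a
  test sample are compared with a control sample with 0.5 pseudocounts.
  The estimate is dampened by background reads and is deliberately
  conservative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals_io import AlignmentRecord, GenomicInterval, repeat_tree

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    rep_type: str
    n_instances_genome: int
    n_observed: int  # peaks (peak-based) or test-sample reads (read-based)
    n_control: int | None
    observed_proportion: float
    expected_proportion: float
    enrichment_ratio: float


def enrichment_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.rep_type, r.n_instances_genome, r.n_observed, r.n_control,
             r.observed_proportion, r.expected_proportion, r.enrichment_ratio)
            for r in records
        ],
        columns=["rep_type", "n_instances_genome", "n_observed", "n_control",
                 "observed_proportion", "expected_proportion", "enrichment_ratio"],
    )


# ---------------------------------------------------------------------------
# Peak-based estimator

def sequenced_genome_size(genome) -> int:
    """Number of non-N bases across all chromosomes of a genome mapping."""
    total = 0
    for chrom in genome.keys():
        seq = str(genome[chrom][:]).upper()
        total += len(seq) - seq.count("N")
    return total


def repeat_bp_by_type(repeats) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in repeats:
        out[r.rep_type] = out.get(r.rep_type, 0) + r.length
    return out


def peak_enrichment(sites, repeats, genome, by: str = "rep_type") -> list[EnrichmentRecord]:
    """Observed/expected repeat-type proportions among refined binding sites.

    observed = fraction of sites whose repeat context is the type;
    expected = fraction of sequenced (non-N) genome bp in the type.
    Types with no sites report ratio 0. `by` may be "rep_type" or
    "rep_family" (family rows aggregate member instances).
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    seq_bp = sequenced_genome_size(genome)
    if seq_bp == 0:
        raise ValueError("zero sequenced (non-N) bases in genome")

    def key(rep):
        return rep.rep_type if by == "rep_type" else rep.rep_family

    bp: dict[str, int] = {}
    n_inst: dict[str, int] = {}
    for r in repeats:
        bp[key(r)] = bp.get(key(r), 0) + r.length
        n_inst[key(r)] = n_inst.get(key(r), 0) + 1

    n_sites: dict[str, int] = {}
    for s in sites:
        ctx = s.repeat_context
        if ctx is None:
            raise ValueError("sites must have repeat contexts assigned")
        if ctx != "unique":
            k = key(ctx)
            n_sites[k] = n_sites.get(k, 0) + 1

    records = []
    for k in sorted(bp):
        obs = n_sites.get(k, 0) / len(sites)
        exp = bp[k] / seq_bp
        records.append(
            EnrichmentRecord(
                rep_type=k,
                n_instances_genome=n_inst[k],
                n_observed=n_sites.get(k, 0),
                n_control=None,
                observed_proportion=obs,
                expected_proportion=exp,
                enrichment_ratio=obs / exp if exp > 0 else 0.0,
            )
        )
    return records


def sample_at_matched(
    genome,
    n_sites: int,
    width: int = 17,
    gc_min: int = 4,
    gc_max: int = 6,
    replicates: int = 10,
    seed: int = 0,
    repeats=None,
    max_attrition_rounds: int = 200,
) -> dict[str, float]:
    """Base-composition-matched random-window background.

    Draws `n_sites` random width-bp windows per replicate, keeping only
    windows free of N with a G+C count in [gc_min, gc_max], and returns the
    mean (over replicates) fraction of windows overlapping each repeat
    type. Deterministic under `seed`.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys())
    seqs = {c: str(genome[c][:]).upper() for c in chroms}
    lengths = np.array([len(seqs[c]) - width + 1 for c in chroms], dtype=float)
    if np.all(lengths <= 0):
        raise ValueError("genome shorter than window width")
    probs = lengths.clip(min=0) / lengths.clip(min=0).sum()
    trees = repeat_tree(repeats) if repeats is not None else {}

    fractions: dict[str, list[float]] = {}
    all_types = sorted({r.rep_type for r in repeats}) if repeats is not None else []
    for _ in range(replicates):
        kept: list[tuple[str, int]] = []
        rounds = 0
        while len(kept) < n_sites:
            rounds += 1
            if rounds > max_attrition_rounds:
                rate = 1.0 - len(kept) / max(1, rounds * n_sites)
                raise ValueError(
                    f"could not collect {n_sites} qualifying windows "
                    f"(attrition rate {rate:.3f} after {rounds} rounds)"
                )
            draw = n_sites - len(kept)
            ci = rng.choice(len(chroms), size=draw, p=probs)
            for c_idx in ci:
                chrom = chroms[c_idx]
                pos = int(rng.integers(0, len(seqs[chrom]) - width + 1))
                win = seqs[chrom][pos: pos + width]
                if "N" in win:
                    continue
                gc = win.count("G") + win.count("C")
                if gc_min <= gc <= gc_max:
                    kept.append((chrom, pos))
        kept = kept[:n_sites]
        counts = dict.fromkeys(all_types, 0)
        for chrom, pos in kept:
            if chrom in trees:
                # a window counts once per repeat type it overlaps
                hit_types = {node.data.rep_type for node in trees[chrom].overlap(pos, pos + width)}
                for t in hit_types:
                    counts[t] = counts.get(t, 0) + 1
        for t in all_types:
            fractions.setdefault(t, []).append(counts.get(t, 0) / n_sites)
    return {t: float(np.mean(v)) for t, v in fractions.items()}


# ---------------------------------------------------------------------------
# Pseudo-chromosome repeat reference

@dataclass
class RepeatReference:
    """One pseudo-chromosome per repeat type.

    Each pseudo-chromosome concatenates every genomic instance of the type
    with `flank` bases of real flanking sequence on each side, separated
    by all-N spacers longer than a read so no read can span two instances.
    """

    read_length: int
    sequences: dict[str, str] = field(default_factory=dict)
    offsets: dict[str, list[tuple[GenomicInterval, int]]] = field(default_factory=dict)

    @property
    def flank(self) -> int:
        return math.ceil(self.read_length / 2)

    @property
    def spacer_len(self) -> int:
        return self.read_length + 1

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i: i + 80] + "\n")


def build_repeat_reference(genome, repeats, read_length: int) -> RepeatReference:
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    ref = RepeatReference(read_length=read_length)
    flank, spacer = ref.flank, "N" * (read_length + 1)
    by_type: dict[str, list] = {}
    for r in repeats:
        by_type.setdefault(r.rep_type, []).append(r)
    chrom_len_cache: dict[str, int] = {}
    for rep_type, instances in sorted(by_type.items()):
        if not instances:
            log.info("repeat type %s has no instances; omitted from reference", rep_type)
            continue
        pieces, offs, cursor = [], [], 0
        for inst in sorted(instances, key=lambda r: (r.interval.chrom, r.interval.start)):
            iv = inst.interval
            if iv.chrom not in chrom_len_cache:
                chrom_len_cache[iv.chrom] = len(genome[iv.chrom])
            left = max(0, iv.start - flank)          # flank truncated at chromosome start
            right = min(chrom_len_cache[iv.chrom], iv.end + flank)
            seq = str(genome[iv.chrom][left:right]).upper()
            if pieces:
                pieces.append(spacer)
                cursor += len(spacer)
            offs.append((iv, cursor + (iv.start - left)))  # offset of the instance proper
            pieces.append(seq)
            cursor += len(seq)
        ref.sequences[rep_type] = "".join(pieces)
        ref.offsets[rep_type] = offs
    return ref


def liftover_to_reference(alignments, reference: RepeatReference) -> list[AlignmentRecord]:
    """Place genomic alignments onto the pseudo-chromosome reference by coordinates.

    A read lands on a pseudo-chromosome iff it lies entirely within one
    instance plus its flanks; this reproduces what an error-free aligner
    would do, hermetically. Reads matching no instance are dropped
    (they would be unmapped).
    """
    flank = reference.flank
    raw: dict[str, list[tuple[int, int, str, int]]] = {}
    for rep_type, offs in reference.offsets.items():
        for iv, off in offs:
            raw.setdefault(iv.chrom, []).append((iv.start - flank, iv.end + flank, rep_type, off - iv.start))
    index = {}
    for chrom, rows in raw.items():
        rows.sort()
        index[chrom] = (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            [r[2] for r in rows],
            np.array([r[3] for r in rows]),
        )
    out = []
    for rec in alignments:
        entry = index.get(rec.chrom)
        if entry is None:
            continue
        los, his, types, shifts = entry
        i = int(np.searchsorted(los, rec.start, side="right")) - 1
        # windows of distinct instances may abut; check the two nearest
        for j in (i, i - 1):
            if 0 <= j and rec.start >= los[j] and rec.end <= his[j]:
                shift = int(shifts[j])
                blocks = tuple((s + shift, e + shift) for s, e in rec.blocks)
                out.append(
                    AlignmentRecord(rec.read_id, types[j], blocks, rec.mapq, rec.sample_id, rec.strand)
                )
                break
    return out


def count_reads_per_reptype(alignments, reference: RepeatReference) -> tuple[dict[str, int], int]:
    """Per-pseudo-chromosome mapped-read counts (idxstats-equivalent).

    Returns (counts keyed by repeat type, number of mapped reads seen).
    Unmapped reads never appear in `alignments`; callers supply the sample
    total separately so totals can include unmapped reads.
    """
    counts = dict.fromkeys(reference.sequences, 0)
    n_mapped = 0
    for rec in alignments:
        if rec.chrom not in counts:
            raise ValueError(f"reference name {rec.chrom!r} not in RepeatReference")
        counts[rec.chrom] += 1
        n_mapped += 1
    return counts, n_mapped


# ---------------------------------------------------------------------------
# Read-based estimator

def read_enrichment(counts_test: dict, total_test: int, counts_ctrl: dict, total_ctrl: int) -> list[EnrichmentRecord]:
    """Pseudocounted proportion ratio per repeat type.

    ratio = ((c_test + 0.5)/total_test) / ((c_ctrl + 0.5)/total_ctrl).
    Totals are whole-sample read totals (mapped + unmapped), not per-type
    sums; the 0.5 pseudocount applies to per-type counts only. The same
    estimator serves ChIP-seq (vs input) and RNA-seq (treated vs control).
    """
    if total_test <= 0 or total_ctrl <= 0:
        raise ValueError("totals must be positive")
    records = []
    for rep_type in sorted(set(counts_test) | set(counts_ctrl)):
        c_t, c_c = counts_test.get(rep_type, 0), counts_ctrl.get(rep_type, 0)
        if c_t < 0 or c_c < 0:
            raise ValueError("negative read count")
        obs = (c_t + 0.5) / total_test
        exp = (c_c + 0.5) / total_ctrl
        records.append(
            EnrichmentRecord(
                rep_type=rep_type,
                n_instances_genome=0,
                n_observed=c_t,
                n_control=c_c,
                observed_proportion=obs,
                expected_proportion=exp,
                enrichment_ratio=obs / exp,
            )
        )
    return records


def filter_contaminant_reads(reads: list[str], contaminants: list[str]) -> list[str]:
    """Drop read sequences occurring as exact substrings of any contaminant."""
    return [r for r in reads if not any(r in c for c in contaminants)]
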