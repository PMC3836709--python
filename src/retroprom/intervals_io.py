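"""Genomic intervals, annotation tables and alignment ingestion.

All coordinates are 0-based half-open internally. GTF (1-based inclusive)
is converted at the parsing boundary. Repeat annotations use the UCSC
RepeatMasker table dialect: chrom, start, end, strand, repName, repClass,
repFamily, milliDiv.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

RMSK_COLUMNS = ["chrom", "start", "end", "strand", "repName", "repClass", "repFamily", "milliDiv"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: [0,10) and [10,20) do not overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap between two same-chromosome intervals; 0 if they overlap or abut."""
    if a.chrom != b.chrom:
        raise ValueError("distance undefined across chromosomes")
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated repeat copy.

    segment_kind distinguishes promoter-bearing LTRs from the ORF-bearing
    internal regions between them (rmsk names the latter with an "-int"
    suffix); everything else is "other".
    """

    interval: GenomicInterval
    rep_type: str
    rep_family: str
    rep_class: str
    milli_div: int
    segment_kind: str = field(init=False)

    def __post_init__(self):
        if self.milli_div < 0:
            raise ValueError("milliDiv must be >= 0")
        object.__setattr__(self, "segment_kind", classify_segment(self.rep_type, self.rep_class))

    @property
    def divergence(self) -> float:
        """Per-site divergence from consensus (milliDiv / 1000), a proxy for age."""
        return self.milli_div / 1000.0

    @property
    def length(self) -> int:
        return len(self.interval)


def classify_segment(rep_type: str, rep_class: str) -> str:
    if rep_type.endswith("-int"):
        return "internal"
    if rep_class == "LTR":
        return "LTR"
    return "other"


def read_repeat_table(path) -> list[RepeatInstance]:
    """Read an rmsk-dialect TSV into RepeatInstance records (0-based half-open)."""
    out: list[RepeatInstance] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # optional header
                continue
            if len(fields) < 8:
                raise ValueError(f"{path}: malformed rmsk row at line {lineno}: {line!r}")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[3])
                rec = RepeatInstance(iv, fields[4], fields[6], fields[5], int(fields[7]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed rmsk row at line {lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_repeat_table(repeats, path) -> None:
    rows = [
        (r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand,
         r.rep_type, r.rep_class, r.rep_family, r.milli_div)
        for r in repeats
    ]
    pd.DataFrame(rows, columns=RMSK_COLUMNS).to_csv(path, sep="\t", index=False)


def repeat_tree(repeats) -> dict[str, IntervalTree]:
    """chrom -> IntervalTree of RepeatInstance, for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(r.interval.start, r.interval.end, r)
    return trees


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                strand = f[5] if len(f) > 5 else "."
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed BED row at line {lineno}: {exc}") from exc
    return out


def write_bed(intervals, path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '+'}\n")


# ---------------------------------------------------------------------------
# GTF gene models

@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]  # sorted by start, 0-based half-open

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)


def read_gtf_genes(path) -> list[GeneModel]:
    """Parse gene models (exon features grouped by gene_id) from a GTF file."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    genes = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        grp = grp.sort_values("Start")
        chrom = grp["Chromosome"].iloc[0]
        strand = grp["Strand"].iloc[0]
        exons = tuple(
            GenomicInterval(chrom, int(s), int(e), strand)
            for s, e in zip(grp["Start"], grp["End"])
        )
        genes.append(GeneModel(str(gene_id), str(chrom), str(strand), exons))
    return genes


def write_gtf(genes, path, source="retroprom") -> None:
    """Write gene models as GTF (converting to 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            span = g.span
            fh.write(f"{g.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t{g.strand}\t.\t{attrs}\n")
            fh.write(f"{g.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for ex in g.exons:
                fh.write(f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# bedGraph

class BedGraph:
    """Per-chromosome step function read from a bedGraph file.

    Positions not covered by any record have no value (NaN on lookup).
    """

    def __init__(self, intervals_by_chrom):
        import numpy as np

        self._data = {}
        for chrom, rows in intervals_by_chrom.items():
            rows = sorted(rows)
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            self._data[chrom] = (starts, ends, vals)

    @classmethod
    def read(cls, path) -> "BedGraph":
        by_chrom: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        return cls(by_chrom)

    def values(self, chrom: str, start: int, end: int):
        """Per-base values over [start, end); NaN where the track is silent."""
        import numpy as np

        out = np.full(end - start, np.nan)
        if chrom not in self._data:
            return out
        starts, ends, vals = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a, b = max(starts[i], start), min(ends[i], end)
            if a < b:
                out[a - start: b - start] = vals[i]
        return out


# ---------------------------------------------------------------------------
# SAM alignments

@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped read reduced to its reference-aligned blocks.

    Consecutive blocks are separated by N-skips (introns); a block-aware
    overlap test therefore ignores intervals an intron merely spans.
    """

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    mapq: int
    sample_id: str = ""
    strand: str = "+"

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def gaps(self) -> list[int]:
        return [self.blocks[i + 1][0] - self.blocks[i][1] for i in range(len(self.blocks) - 1)]


def _merge_abutting(blocks):
    # pysam get_blocks() splits on N but also on D/I; merge abutting pieces
    merged = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return tuple(merged)


def read_alignments(path, sample_id: str = "", mapq_min: int | None = None) -> list[AlignmentRecord]:
    """Read mapped records from SAM/BAM.

    mapq_min, when given, keeps only reads with MAPQ > mapq_min (the
    uniquely-mapped convention); pass None to keep multi-mappers for the
    read-aggregation enrichment path.
    """
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if mapq_min is not None and rec.mapping_quality <= mapq_min:
                continue
            blocks = _merge_abutting(rec.get_blocks())
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    blocks=blocks,
                    mapq=rec.mapping_quality,
                    sample_id=sample_id,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out


def block_overlaps(rec: AlignmentRecord, iv: GenomicInterval) -> bool:
    """True iff at least one aligned block overlaps iv (split-read aware)."""
    if rec.chrom != iv.chrom:
        return False
    return any(s < iv.end and iv.start < e for s, e in rec.blocks)


def peak_overlap_fraction(query_peaks, subject_peaks) -> float:
    """Fraction of query peaks overlapping >=1 subject peak (whole-peak regions)."""
    query_peaks = list(query_peaks)
    if not query_peaks:
        raise ValueError("empty query set")
    trees: dict[str, IntervalTree] = {}
    for iv in subject_peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    n_hit = sum(
        1 for q in query_peaks
        if q.chrom in trees and trees[q.chrom].overlap(q.start, q.end)
    )
    return n_hit / len(query_peaks)
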