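"""Detection of repeat-borne alternative promoters via spliced linking reads.

A bound region (ChIP-seq peak) is linked to an annotated transcript unit
(gene or lncRNA) by a spliced RNA-seq read that (a) has an aligned block
overlapping the peak, (b) contains an intron gap of at least 20 bp, and
(c) has an aligned block overlapping an exon of the unit. Pairs where the
peak overlaps the unit itself are discarded, pairs must be supported by
at least one read in each treated sample, and the pooled pseudocounted
activation ratio must reach 2.

Note a documented blind spot: chimeras whose reads reach the gene only
through intervening novel exons — no single read joining repeat and gene
directly — are not detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals_io import overlaps
from intervaltree import IntervalTree


@dataclass
class PairLink:
    peak_id: str
    unit_id: str
    counts: dict[str, int]  # per-sample linking-read counts
    activation_ratio: float | None = None


def _tree_of(intervals_with_ids):
    trees: dict[str, IntervalTree] = {}
    for obj_id, iv in intervals_with_ids:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, obj_id)
    return trees


def filter_linking_reads(alignments, peaks: dict, units, min_intron: int = 20, genic_span: bool = False):
    """Keep reads that could evidence a peak-to-unit splice.

    peaks: peak_id -> GenomicInterval (full peak region, not refined site).
    units: GeneModel list. By default a read must overlap an *exon* of a
    unit (the read must splice into the transcript structure);
    genic_span=True relaxes this to the whole gene span.

    Returns a list of (record, peak_ids, unit_ids) for retained reads.
    """
    peak_trees = _tree_of(peaks.items())
    unit_trees = _tree_of(
        (g.gene_id, iv)
        for g in units
        for iv in ((g.span,) if genic_span else g.exons)
    )
    out = []
    for rec in alignments:
        if not any(g >= min_intron for g in rec.gaps()):
            continue
        ptree = peak_trees.get(rec.chrom)
        utree = unit_trees.get(rec.chrom)
        if ptree is None or utree is None:
            continue
        hit_peaks: set[str] = set()
        hit_units: set[str] = set()
        for s, e in rec.blocks:
            for node in ptree.overlap(s, e):
                hit_peaks.add(node.data)
            for node in utree.overlap(s, e):
                hit_units.add(node.data)
        if hit_peaks and hit_units:
            out.append((rec, sorted(hit_peaks), sorted(hit_units)))
    return out


def build_pairs(candidates, peaks: dict, units, sample_ids, treated: list[str]) -> list[PairLink]:
    """Tabulate per-sample linking-read counts for each (peak, unit) pair.

    Pairs whose peak overlaps the unit span are removed, as are pairs not
    supported by >=1 read in every treated sample. A read linking one peak
    to two overlapping units counts toward both pairs.
    """
    unit_span = {g.gene_id: g.span for g in units}
    table: dict[tuple[str, str], dict[str, int]] = {}
    for rec, peak_ids, unit_ids in candidates:
        for pid in peak_ids:
            for uid in unit_ids:
                counts = table.setdefault((pid, uid), dict.fromkeys(sample_ids, 0))
                counts[rec.sample_id] = counts.get(rec.sample_id, 0) + 1
    pairs = []
    for (pid, uid), counts in sorted(table.items()):
        if overlaps(peaks[pid], unit_span[uid]):
            continue
        if any(counts.get(s, 0) < 1 for s in treated):
            continue
        pairs.append(PairLink(peak_id=pid, unit_id=uid, counts=counts))
    return pairs


def activation_ratio(pair: PairLink, totals: dict[str, int], treated: list[str], control: list[str]) -> float:
    """Pooled pseudocounted linking-read proportion, treated over control.

    ratio = ((sum treated counts + 0.5) / sum treated totals)
          / ((sum control counts + 0.5) / sum control totals).
    """
    t_total = sum(totals[s] for s in treated)
    c_total = sum(totals[s] for s in control)
    if t_total <= 0 or c_total <= 0:
        raise ValueError("sample totals must be positive")
    t = sum(pair.counts.get(s, 0) for s in treated) + 0.5
    c = sum(pair.counts.get(s, 0) for s in control) + 0.5
    return (t / t_total) / (c / c_total)


def score_pairs(pairs, totals, treated, control, min_ratio: float = 2.0) -> list[PairLink]:
    """Attach activation ratios and drop pairs below the ratio threshold."""
    kept = []
    for p in pairs:
        p.activation_ratio = activation_ratio(p, totals, treated, control)
        if p.activation_ratio >= min_ratio:
            kept.append(p)
    return kept


def summarize_promoters(pairs, sites) -> pd.DataFrame:
    """Classify surviving pairs by the refined site's repeat context.

    Returns counts of repeat-origin vs unique-origin novel promoters, with
    a per-repeat-family breakdown of the repeat-origin ones.
    """
    ctx_by_peak = {s.peak_id: s.repeat_context for s in sites}
    rows = []
    for p in pairs:
        ctx = ctx_by_peak.get(p.peak_id, "unique")
        if ctx in (None, "unique"):
            rows.append((p.peak_id, p.unit_id, "unique", "", p.activation_ratio))
        else:
            rows.append((p.peak_id, p.unit_id, ctx.rep_type, ctx.rep_family, p.activation_ratio))
    return pd.DataFrame(rows, columns=["peak_id", "unit_id", "origin", "rep_family", "activation_ratio"])


def pairs_table(pairs, sample_ids) -> pd.DataFrame:
    rows = [
        [p.peak_id, p.unit_id] + [p.counts.get(s, 0) for s in sample_ids] + [p.activation_ratio]
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["peak_id", "unit_id"] + list(sample_ids) + ["activation_ratio"])
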