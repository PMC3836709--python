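"""Motif-anchored evolutionary-conservation and SNP profiles.

For every refined binding site, per-base conservation scores (or SNP
incidences) are collected over the motif window plus `flank` bases on
each side, oriented so position 0 is always the motif's 5' end in motif
orientation: minus-strand sites have their position vector reversed
before averaging. Functional motifs show elevated conservation and
depleted common variation relative to their flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals_io import BedGraph


@dataclass
class PositionProfile:
    positions: np.ndarray   # -flank .. width-1+flank
    values: np.ndarray      # per-position mean score, or SNP count
    n_sites: np.ndarray     # sites contributing at each position
    stratum: str
    overall_mean: float | None = None  # grand mean over all covered (site, position) cells


def _common_width(sites):
    widths = {len(s.interval) for s in sites}
    if len(widths) != 1:
        raise ValueError("all sites must share one motif width")
    return widths.pop()


def score_profile(sites, track: BedGraph, flank: int = 20, stratum: str = "all") -> PositionProfile:
    """Mean per-position conservation score across sites (strand-oriented).

    Positions without track data are excluded from that position's mean
    (n_sites is decremented accordingly).
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    width = _common_width(sites)
    n_pos = width + 2 * flank
    total = np.zeros(n_pos)
    n = np.zeros(n_pos, dtype=int)
    for s in sites:
        vals = track.values(s.interval.chrom, s.interval.start - flank, s.interval.end + flank)
        if s.strand == "-":
            vals = vals[::-1]
        ok = np.isfinite(vals)
        total[ok] += vals[ok]
        n[ok] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    overall = float(total.sum() / n.sum()) if n.sum() else float("nan")
    positions = np.arange(-flank, width + flank)
    return PositionProfile(positions, means, n, stratum, overall)


def snp_profile(sites, snps, flank: int = 20, stratum: str = "all") -> PositionProfile:
    """Per-position SNP counts across sites (strand-oriented).

    snps are single-base intervals; a SNP falling in the neighborhoods of
    two sites counts once per site.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    width = _common_width(sites)
    n_pos = width + 2 * flank
    counts = np.zeros(n_pos, dtype=int)
    by_chrom: dict[str, np.ndarray] = {}
    for snp in snps:
        if len(snp) != 1:
            raise ValueError("SNPs must be single-base intervals")
        by_chrom.setdefault(snp.chrom, []).append(snp.start)
    by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}
    for s in sites:
        pos = by_chrom.get(s.interval.chrom)
        if pos is None:
            continue
        lo, hi = s.interval.start - flank, s.interval.end + flank
        for p in pos[np.searchsorted(pos, lo): np.searchsorted(pos, hi)]:
            offset = int(p - lo)
            if s.strand == "-":
                offset = n_pos - 1 - offset
            counts[offset] += 1
    positions = np.arange(-flank, width + flank)
    n_sites = np.full(n_pos, len(sites), dtype=int)
    return PositionProfile(positions, counts.astype(float), n_sites, stratum)
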