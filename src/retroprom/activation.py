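"""Differential activation of binding-site-proximal regions.

The test is a simplified DESeq-style negative-binomial comparison of two
treated vs two control RNA-seq libraries:

* library size factors by the median-of-ratios method;
* per-region dispersion by method of moments from within-group variance,
  shrunk toward a fitted mean-dispersion trend alpha(mu) = a0 + a1/mu
  (df-weighted moderation; with two samples per group the per-region
  estimate carries little weight);
* a Wald z-test on the difference of normalized group means, with the
  null variance evaluated at the pooled mean;
* Benjamini-Hochberg correction over the tested regions only.

Regions are called activated at fold change >= 2 and adjusted p <= 0.1
(repressed at fold change <= 0.5), after excluding regions with fewer
than 10 raw reads summed over all samples. This reproduces the decision
thresholds of the analysis, not any particular DESeq release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals_io import GenomicInterval, interval_distance

PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# Counting

def count_region_reads(alignments_by_sample: dict, regions, flank: int = 1000) -> pd.DataFrame:
    """Split-read-aware count matrix (regions x samples).

    A read counts for a region iff at least one aligned block overlaps the
    region extended by `flank` on each side; each read counts at most once
    per region. Intron gaps spanning a region do not count.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    from intervaltree import IntervalTree

    regions = list(regions)
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(regions):
        start = max(0, iv.start - flank)
        trees.setdefault(iv.chrom, IntervalTree()).addi(start, iv.end + flank, idx)

    samples = list(alignments_by_sample)
    mat = np.zeros((len(regions), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        for rec in alignments_by_sample[sample]:
            tree = trees.get(rec.chrom)
            if tree is None:
                continue
            hit: set[int] = set()
            for s, e in rec.blocks:
                for node in tree.overlap(s, e):
                    hit.add(node.data)
            for idx in hit:
                mat[idx, j] += 1
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    return pd.DataFrame(mat, index=index, columns=samples)


# ---------------------------------------------------------------------------
# Normalization and testing

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors.

    factor_j = median over regions (with all-positive counts) of
    count_ij / geometric_mean_i(counts).
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError("no region has nonzero counts in all samples")
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    return np.exp(np.median(log_counts - log_geomean, axis=0))


@dataclass
class RegionTestResult:
    region_id: str
    counts: tuple
    mean_treated: float
    mean_control: float
    fold_change: float
    p_value: float
    padj: float
    call: str


def _fit_dispersion_trend(means: np.ndarray, disps: np.ndarray) -> tuple[float, float]:
    """Nonnegative least-squares fit of alpha = a0 + a1/mu.

    Fitted over all finite method-of-moments estimates (negatives
    included, clipped only through the nonnegativity of the fit itself, so
    pure-shot-noise data pulls the trend to zero rather than biasing it up).
    """
    from scipy.optimize import nnls

    ok = np.isfinite(disps) & (means > 0)
    if ok.sum() < 2:
        return 0.0, 0.0
    x = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, _ = nnls(x, disps[ok])
    return float(coef[0]), float(coef[1])


def test_regions(
    counts: pd.DataFrame,
    treated: list[str],
    control: list[str],
    min_total: int = 10,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.1,
) -> list[RegionTestResult]:
    """NB differential test of treated vs control region counts.

    Regions whose raw counts sum below `min_total` are excluded before
    testing (and before BH correction). Fold change is computed on
    normalized group means with a 0.5 pseudocount on each mean.
    """
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >=2 samples per group to estimate dispersion")
    samples = treated + control
    raw = counts[samples].to_numpy(dtype=float)
    keep = raw.sum(axis=1) >= min_total
    kept_ids = counts.index[keep]
    k = raw[keep]
    if k.shape[0] == 0:
        return []

    sf = size_factors(k)
    q = k / sf  # normalized counts
    n_t, n_c = len(treated), len(control)
    q_t, q_c = q[:, :n_t], q[:, n_t:]
    mu_t, mu_c = q_t.mean(axis=1), q_c.mean(axis=1)

    # Method-of-moments dispersion from within-group variability, pooled.
    # Var(K/s) = mu/s + alpha*mu^2 under NB, so subtract the Poisson part.
    inv_s_t = (1.0 / sf[:n_t]).mean()
    inv_s_c = (1.0 / sf[n_t:]).mean()
    var_t = q_t.var(axis=1, ddof=1)
    var_c = q_c.var(axis=1, ddof=1)
    mu0 = q.mean(axis=1)
    pooled_var = ((n_t - 1) * var_t + (n_c - 1) * var_c) / (n_t + n_c - 2)
    pooled_shot = (n_t * mu_t * inv_s_t + n_c * mu_c * inv_s_c) / (n_t + n_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mu0 > 0, (pooled_var - pooled_shot) / np.square(mu0), 0.0)
    a0, a1 = _fit_dispersion_trend(mu0, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(mu0 > 0, a0 + a1 / mu0, 0.0)
    # moderate the noisy 2-df per-region estimate toward the trend
    # (df-weighted shrinkage with a prior worth ~10 df, limma-style)
    resid_df = float(n_t + n_c - 2)
    prior_df = 10.0
    alpha = (prior_df * alpha_trend + resid_df * np.maximum(alpha_mom, 0.0)) / (prior_df + resid_df)
    alpha = np.maximum(alpha, 1e-8)

    # Wald test on the difference of normalized group means; null variance
    # at the pooled mean keeps the test calibrated when counts are small.
    def group_var(mu, s):
        # Var(mean_j K_j/s_j) with K_j ~ NB(mu*s_j, alpha)
        return np.sum(mu[:, None] / s[None, :] + alpha[:, None] * mu[:, None] ** 2, axis=1) / s.size ** 2

    v = group_var(mu0, sf[:n_t]) + group_var(mu0, sf[n_t:])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, (mu_t - mu_c) / np.sqrt(v), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]

    fc = (mu_t + PSEUDOCOUNT) / (mu_c + PSEUDOCOUNT)
    results = []
    for i, rid in enumerate(kept_ids):
        if fc[i] >= fc_threshold and padj[i] <= fdr_threshold:
            call = "activated"
        elif fc[i] <= 1.0 / fc_threshold and padj[i] <= fdr_threshold:
            call = "repressed"
        else:
            call = "ns"
        results.append(
            RegionTestResult(
                region_id=str(rid),
                counts=tuple(int(x) for x in k[i]),
                mean_treated=float(mu_t[i]),
                mean_control=float(mu_c[i]),
                fold_change=float(fc[i]),
                p_value=float(p[i]),
                padj=float(padj[i]),
                call=call,
            )
        )
    return results


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.region_id, r.mean_treated, r.mean_control, r.fold_change, r.p_value, r.padj, r.call)
            for r in results
        ],
        columns=["region_id", "mean_treated", "mean_control", "fold_change", "p_value", "padj", "call"],
    )


# ---------------------------------------------------------------------------
# Summaries

def activation_percentage(n_activated: int, n_total: int) -> float:
    """Percentage of bound regions showing activation, to one decimal."""
    if n_total == 0:
        return 0.0
    return round(100.0 * n_activated / n_total, 1)


def summarize_activation(results, sites) -> pd.DataFrame:
    """Per-repeat-context activation counts and percentages.

    `results` are RegionTestResults whose region_id equals the site's
    peak_id; sites carry repeat contexts. Also emits "unique" and "all"
    rows. Untested regions (below the count filter) count as not activated.
    """
    by_peak = {r.region_id: r for r in results}
    rows: dict[str, list[int]] = {}
    total_act = 0
    for s in sites:
        ctx = s.repeat_context
        label = "unique" if ctx == "unique" or ctx is None else ctx.rep_type
        res = by_peak.get(s.peak_id)
        act = 1 if (res is not None and res.call == "activated") else 0
        total_act += act
        bucket = rows.setdefault(label, [0, 0])
        bucket[0] += 1
        bucket[1] += act
    out = [
        (label, n, n_act, activation_percentage(n_act, n))
        for label, (n, n_act) in sorted(rows.items())
    ]
    n_sites = sum(r[1] for r in out)
    out.append(("all", n_sites, total_act, activation_percentage(total_act, n_sites)))
    return pd.DataFrame(out, columns=["context", "n_bound", "n_activated", "pct_activated"])


# ---------------------------------------------------------------------------
# Internal regions: LTR flanking and repeat age

@dataclass
class InternalRegion:
    repeat: object  # RepeatInstance with segment_kind == "internal"
    flanked_by_bound_ltr: bool = False

    @property
    def length(self) -> int:
        return self.repeat.length

    @property
    def divergence(self) -> float:
        return self.repeat.divergence


def flanked_by_bound_ltr(internal_repeats, sites, max_dist: int = 5000) -> list[InternalRegion]:
    """Flag internal regions with a bound site whose motif lies in an LTR within max_dist."""
    ltr_sites = [
        s for s in sites
        if s.repeat_context not in (None, "unique") and s.repeat_context.rep_class == "LTR"
        and s.repeat_context.segment_kind == "LTR"
    ]
    out = []
    for rep in internal_repeats:
        flag = any(
            s.interval.chrom == rep.interval.chrom
            and interval_distance(s.interval, rep.interval) <= max_dist
            for s in ltr_sites
        )
        out.append(InternalRegion(repeat=rep, flanked_by_bound_ltr=flag))
    return out


def compare_repeat_age(internal_regions, activated_ids: set, min_len: int = 500):
    """Divergence (age-proxy) distributions of activated vs non-activated internals.

    Restricted to regions flanked by a bound LTR and spanning >= min_len bp
    (ages from shorter fragments are unreliable). Returns
    (activated divergences, other divergences, two-sided rank-sum p).
    """
    kept = [r for r in internal_regions if r.flanked_by_bound_ltr and r.length >= min_len]
    act, non = [], []
    for r in kept:
        rid = f"{r.repeat.interval.chrom}:{r.repeat.interval.start}-{r.repeat.interval.end}"
        (act if rid in activated_ids else non).append(r.divergence)
    if not act or not non:
        raise ValueError("a group is empty after filtering; cannot compare ages")
    stat = stats.mannwhitneyu(act, non, alternative="two-sided")
    return np.array(act), np.array(non), float(stat.pvalue)


# ---------------------------------------------------------------------------
# ORF scanning

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    frame: int      # 0..2 within the scanned strand
    strand: str     # "+" or "-"
    start: int      # 0-based on the given sequence's forward coordinates
    end: int        # half-open; includes the stop codon
    length_aa: int  # codons from ATG through the last sense codon (stop excluded)


def find_orfs(seq: str, min_aa: int) -> list[Orf]:
    """Six-frame ORF scan: ATG .. in-frame stop with >= min_aa codons.

    ORFs running off the sequence end without a stop are not reported.
    Codons containing N match neither ATG nor a stop. Characters outside
    ACGTN are rejected.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-DNA characters")
    from .motif import revcomp

    n = len(seq)
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start_codon = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos: pos + 3]
                if start_codon is None:
                    if codon == "ATG":
                        start_codon = pos
                elif codon in _STOPS:
                    aa = (pos - start_codon) // 3
                    if aa >= min_aa:
                        if strand == "+":
                            a, b = start_codon, pos + 3
                        else:  # map back to forward coordinates
                            a, b = n - (pos + 3), n - start_codon
                        out.append(Orf(frame, strand, a, b, aa))
                    start_codon = None
    return out
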