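# Methods

This note documents the models, estimators and numerical choices behind
`retroprom`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
is converted at the parsing boundary, and the repeat table follows the
UCSC RepeatMasker dialect (chrom, start, end, strand, repName, repClass,
repFamily, milliDiv), also 0-based half-open. `segment_kind` is derived
from the annotation: names ending `-int` are internal (ORF-bearing)
segments, remaining LTR-class records are LTRs, everything else "other".
A MAPQ > 15 filter is available at alignment ingestion for
uniquely-mapped analyses; the read-aggregation enrichment path reads
without it, since keeping multi-mappers is that estimator's point.
Unknown strands are treated as "+" for sequence extraction.

## PWM scanning and peak refinement

A motif window's score is the sum of per-position base weights. The PWM
is an input file (positions × A,C,G,T weights plus a score threshold,
default 9.75, carried as file metadata since the weight scale is defined
by the matrix itself). Each peak is refined to the single best window
over both strands; ties go to the forward strand, then the smaller
start. Windows containing N score with per-position minimum weights
rather than being skipped, so assembly-gap edges can never produce
spurious maxima. Motif counting counts window starts whose better strand
reaches the threshold (a palindromic hit counts once per start). Repeat
context is the repeat overlapping the refined window by the most bases
(ties to the smaller start), else "unique".

The shipped surrogate PWM assigns the consensus base at position i a
weight of 1 + 0.02·i and alternatives about −1, so its 17-mer consensus
scores 19.72 and a window needs roughly 14/17 consensus matches to clear
9.75 — keeping the canonical threshold meaningful against divergent
repeat copies.

## Enrichment estimators

*Peak-based*: observed fraction of refined sites per repeat type divided
by the type's fraction of non-N genome bp. Types with no sites report
ratio 0. Family-level tables aggregate member types. The AT-matched
background samples 17-bp windows uniformly, rejects windows containing N
or with G+C outside [4, 6], collects the target number per replicate
(an attrition bound raises an error on degenerate genomes, e.g. all-A),
and averages overlap fractions over 10 replicates.

*Read-based*: a pseudo-chromosome per repeat type concatenates every
instance with ⌈read_length/2⌉ flanks (truncated at chromosome ends) and
all-N spacers of read_length + 1, so no read can span instances.
Counting is idxstats-like per pseudo-chromosome. Enrichment is the
pseudocounted proportion ratio ((c_t+0.5)/N_t)/((c_c+0.5)/N_c); totals
are whole-sample read totals (mapped + unmapped), so proportions are
comparable across types, and the pseudocount applies to per-type counts
only. Hermetic placement of error-free synthetic reads onto the
pseudo-chromosomes is done by coordinate liftover (a read lands iff it
lies entirely within one instance ± flank), which reproduces what an
aligner would do without needing one; real data would be mapped
externally and read in as SAM/BAM. Reads matching supplied contaminant
sequences (vector, adapters) can be removed by exact substring match
before counting.

The read-based estimate is dampened: with signal fraction s, motif share
w_t and mappable genomic fraction p_t, the expected ratio is
(s·w_t + (1−s)·p_t)/p_t rather than w_t/p_t. The recovery study checks
the observed ratio against this closed form within 3 SE (delta method on
the log ratio), which also documents why the estimator is conservative.

## Differential activation

Counting is split-read aware: a read counts for a region iff at least
one aligned block overlaps the region ± 1 kb (an intron spanning the
window does not count), at most once per region. Regions with fewer
than 10 raw reads summed over the four libraries are excluded before
testing and before multiplicity correction.

The test is a simplified DESeq-style NB comparison for two treated vs
two control libraries:

* size factors by median of ratios on the log scale,
  s_j = exp(median_i log(k_ij / geomean_i));
* per-region dispersion by method of moments from pooled within-group
  variance of normalized counts, Var(K/s) = μ/s + α μ²;
* a mean-dispersion trend α(μ) = a₀ + a₁/μ fitted by non-negative least
  squares over the raw (sign-preserving) moment estimates — the
  non-negativity lives in the fit, not in pre-clipping, so pure shot
  noise pulls the trend to zero instead of biasing it upward;
* moderation: α = (10·α_trend + 2·α_region⁺)/12, i.e. df-weighted
  shrinkage with a prior worth 10 df (with only 2 residual df the
  per-region estimate deserves little weight), floored at 1e−8;
* a Wald z-test on the difference of normalized group means with the
  null variance evaluated at the pooled mean — evaluating at the pooled
  mean rather than per-group means keeps the null calibrated when
  counts are small;
* BH correction over tested regions; activation at fold ≥ 2 and
  adjusted p ≤ 0.1, repression symmetrically; fold change on normalized
  group means with a 0.5 pseudocount each.

Simulation at the study conditions (NB mean 50, dispersion 0.1, 2 vs 2)
puts the type-I error at ≈1.0× nominal (α = 0.05) and power at planted
8-fold activation above 0.99; both are recomputed by the test suite and
the acceptance script rather than quoted. Exact reproduction of any
DESeq release is a non-goal; the thresholds and filters, not the
dispersion machinery, are what this stage exists to apply.

Internal-region analyses reuse the same test with flank 0. The repeat
age comparison keeps internal regions flanked by a bound LTR-context
site within 5 kb and spanning ≥500 bp (ages from shorter fragments are
unreliable), splits them by activation, and compares milliDiv/1000
divergence with a two-sided rank-sum test. The ORF scanner reports, per
frame and strand, ORFs opened at the first ATG after the previous
in-frame stop and closed at the next stop, with length in codons
excluding the stop; unterminated ORFs are not reported and codons
containing N never match ATG or a stop.

## Chimeric promoters

Linking reads must satisfy all three filters (peak block, intron gap
≥ 20 bp, exon block). "Overlaps annotated genes" is interpreted as exon
overlap, because a linking read must splice into the transcript
structure; a `genic_span` option relaxes to the whole gene span. The
activation ratio pools counts within groups (one 0.5 pseudocount per
pooled sum) — per-sample pseudocounts would make the two-sample
proportion depend on an arbitrary averaging order. A read linking one
peak to two overlapping units counts toward both pairs. A documented
false negative: chimeras routed through intervening novel exons, where
no single read joins repeat and gene, are not detected; the test suite
asserts this blind spot rather than hiding it.

## Profiles

Profiles span motif width + 2×20 positions. Minus-strand sites are
reversed before aggregation so position 0 is always the motif's 5′ end
in motif orientation (flipping is the right default for a
strand-specific motif; an unflipped variant is a one-line change in the
caller). Conservation values are means with per-position n decremented
where the track is silent; SNP profiles are counts, a SNP counting once
per site neighborhood containing it. The SNP input is taken as already
frequency-filtered.

## Satellite quantification

The alignment reference is one monomer (canonically 170 bp) plus bases
1–98 again, so reads crossing a monomer junction in a tandem array still
match; tallies fold the duplicated tail back modulo the monomer length.
Abundance is reads-per-million; sample comparisons are made on rpm.
A minimal converter from tabular BLAST output to SAM (ungapped hits) is
provided for workflows that align satellite reads with blastn.

## The generator, and what passing tests do not show

`fixtures.make_genome` lays out non-overlapping feature blocks (repeat
instances, gene cassettes, one tandem satellite array) in random order
with at least `spacing_min` background between blocks, over an i.i.d.
background of configurable GC content. Repeat instances are consensus
copies with independent per-site substitutions; the recorded milliDiv is
the realized substitution fraction × 1000. A configurable fraction of
designated-type instances receives one planted motif (PWM consensus,
random strand) at its center; those instances are the true bound set and
each gets a peak interval (motif ± 150 bp). A fraction of bound repeats
is paired with a gene (two exons, 200 + 300 bp, 800 bp intron) placed
1–50 kb downstream by default.

ChIP treatment libraries draw a fraction `chip_signal_fraction`
(default 0.3, matching libraries that are 50–90 % background) of read
starts uniformly within ±100 bp of a uniformly chosen bound motif and
the rest uniformly over the genome; controls are all-uniform. RNA
libraries superimpose: NB(region_mean × fold, dispersion) unspliced
reads per bound region (fold 8 for the activated fraction), Poisson
spliced linking reads per chimeric pair in treated samples only (block
in the repeat, N gap, block in exon 2), a satellite component at the
planted treated/control fractions (defaults 6.7e−3 and 8e−6), and a
background drawn from gene exons when gene models exist (polyA RNA-seq
background is transcriptome-derived, not genome-uniform) or uniformly
otherwise. Conservation tracks are N(μ_motif, σ) inside motifs and
N(μ_flank, σ) in flanks; SNPs are Bernoulli at density ρ_in inside
motifs and ρ_out outside.

Not emulated: sequencing errors and quality strings, paired ends,
fragment-length effects on peak shape, non-uniform mappability,
alignment ambiguity between related repeat copies (reads are placed by
construction), and transcript-level structure beyond two exons. Recovery
on these fixtures therefore demonstrates the correctness of the
estimators and filters under their own model assumptions — not
robustness to mapping artifacts, which in real data motivate exactly the
dual peak-based/read-based design.

Desk-scale caveat: the satellite array occupies ~1 % of the synthetic
genome versus ~0.1 % of a real one, and the background model determines
the control-sample satellite floor; with the transcriptome background
the control lands near the planted ~8 rpm, giving treated-vs-control
folds in the hundreds at these library sizes (the fold's sampling error
is dominated by the handful of control reads).

## Study problem sizes

Enrichment recovery: 1 Mb genome, five repeat types, 2,000 bound motifs
held by two short LTR-like types planted at 5× concentration, 10⁵ reads
per ChIP sample. Chimera recovery: 10 seeds × 50 genes with one planted
chimera each (500 pairs total). Calibration: 5 × 10⁴ null regions and
10 × (100 activated + 900 null). Profiles: 1,000 sites. These sizes
resolve each effect at 3-SE precision while keeping a full run of the
suite plus the reproduction script in the tens of seconds.
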