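# retroprom

Repeat-aware analysis of transcription-factor ChIP-seq and RNA-seq, built
around the question of whether a TF's binding sites in transposable
elements — LTR retrotransposons (MaLR/ERV families), satellites — are
functional: bound above chance, evolutionarily conserved, transcriptionally
activated, and co-opted as alternative promoters for nearby genes. The
package targets the analysis style used for DUX4, a germline homeodomain
factor whose somatic de-repression causes FSHD and whose binding sites are
dominated by MaLR-family LTRs, but every stage is generic over a genome,
a RepeatMasker-style annotation, a PWM and read alignments.

## What it computes

**Repeat enrichment, two estimators.** Peak-based: each ChIP peak is
refined to its single best-scoring PWM window over both strands, assigned
a repeat context, and per-type enrichment is

  E_peak(t) = (fraction of peaks whose best motif lies in repeat type t) /
              (fraction of non-N genome bp annotated as t),

with an AT-matched random-window background (17-mers, 4–6 G/C, 10
replicates) to control for base-composition bias. Read-based (for repeats
too young to map uniquely): reads are aggregated over *all* instances of a
type by mapping to pseudo-chromosomes — every instance plus half-read-length
flanks, concatenated with super-read-length N spacers — and

  E_read(t) = ((c_chip + 0.5)/N_chip) / ((c_ctrl + 0.5)/N_ctrl),

a deliberately conservative ("dampened") measure because ChIP libraries are
50–90 % background.

**Differential activation.** RNA-seq reads are counted within 1 kb of each
bound region (split-read aware), regions with <10 reads total are dropped,
and a DESeq-style negative-binomial test (median-of-ratios size factors,
trend-moderated method-of-moments dispersion, Wald test, Benjamini–Hochberg)
calls activation at fold change ≥2 and FDR ≤0.1.

**Chimeric promoters.** A bound region is linked to an annotated gene or
lncRNA by spliced reads that (a) have an aligned block in the peak, (b)
contain an intron gap ≥20 bp, and (c) have a block in an exon of the unit;
pairs overlapping their gene are dropped, support is required in both
treated samples, and the pooled pseudocounted activation ratio must be ≥2.

**Conservation and SNP profiles.** Per-position means of conservation
scores (and SNP counts) over every refined motif ±20 bp flanks, oriented to
motif strand, with a repeat-only stratum.

**Satellite quantification.** Reads matching a tandem satellite are scored
as reads-per-million; matching reads are re-aligned to a consensus monomer
(full copy + bases 1–98, so junction-spanning reads map) and per-position
variant tallies reveal how many monomer variants are transcribed.

**Synthetic data.** `retroprom.fixtures` generates genomes with planted
repeat instances (configurable per-site divergence; milliDiv recorded),
planted motifs, ChIP libraries with a configurable signal fraction over
background, NB-distributed per-region RNA counts, spliced chimeric linking
reads, satellite arrays, conservation/SNP tracks — all deterministic under
a seed, with truth tables for recovery tests.

## Worked example

```
python analysis/01_simulate.py --seed 0      # ~0.9 Mb genome into scratch/simdata
python analysis/02_refine_and_enrich.py
python analysis/03_activation.py
python analysis/04_chimera.py
python analysis/05_conservation.py
python analysis/06_satellite.py
```

With seed 0 the chain prints (abridged):

```
per-type enrichment (peak-based vs read-based):
 rep_type  enrichment_ratio_peak  enrichment_ratio_read
    MLT9A                  28.50                   9.18
    THE1X                  26.57                   8.62
    AluYZ                   0.00                   0.60
...
12 of 50 bound regions called activated (24.0%); 12 were planted
12 peak-gene pairs pass all filters (12 repeat-origin, 0 unique-origin)
planted pairs recovered: 12/12; false pairs: 0
motif positions: mean score 1.014, mean SNP count 0.18
flank positions: mean score -0.004, mean SNP count 1.23
pooled treated 19426.4 rpm vs control 0.00 rpm
```

Reading: the two motif-bearing LTR types are strongly enriched by both
estimators, with the read-based estimate dampened by background as
expected; every planted activated region and every planted chimeric
peak–gene pair is recovered with no false pairs; motifs show elevated
conservation and depleted SNPs relative to flanks; satellite transcription
is confined to the treated samples. Tables land in `results/`.

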