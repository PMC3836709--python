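#!/usr/bin/env python
"""Generate the demonstration dataset every later analysis step consumes.

Emits a ~0.9 Mb genome with planted repeat instances (five types, two of
them motif-bearing), ChIP-seq treatment/control libraries, four RNA-seq
libraries (two treated, two control) with chimeric linking reads and a
satellite component, conservation/SNP tracks, and the truth tables.

Output: scratch/simdata/ (regenerated deterministically from the seed).
"""

import argparse
import os
import sys

from retroprom.fixtures import (
    make_genome,
    simulate_chip_alignments,
    simulate_rna_alignments,
    simulate_tracks,
)
from retroprom.workflows import demo_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/simdata")
    args = ap.parse_args()

    cfg = demo_config(args.seed)
    os.makedirs(args.out, exist_ok=True)
    genome_path, truth = make_genome(cfg, args.out)
    simulate_chip_alignments(genome_path, truth, cfg, args.out)
    simulate_rna_alignments(genome_path, truth, cfg, args.out)
    simulate_tracks(genome_path, truth, cfg, args.out)

    print(f"genome: {genome_path} ({cfg.genome_length:,} bp)")
    print(f"repeat instances: {len(truth.repeats)}  bound motifs: {len(truth.motifs)}")
    print(f"genes: {len(truth.genes)}  planted chimeric pairs: {len(truth.chimeric_pairs)}")
    print(f"satellite array: {int(truth.satellite.iloc[0]['end'] - truth.satellite.iloc[0]['start']):,} bp")
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    sys.exit(main())
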