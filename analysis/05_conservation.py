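#!/usr/bin/env python
"""Profile evolutionary conservation and SNP density across bound motifs.

For each refined site, collects per-base conservation scores and SNP
incidences over the motif plus 20 bp flanks, oriented to the motif
strand, in two strata (all sites / repeat-context sites only).

Reads scratch/simdata/; writes results/conservation_profile.tsv and
results/snp_profile.tsv.
"""

import argparse
import os

import numpy as np
import pandas as pd

from retroprom import conservation as co, intervals_io as io
from retroprom.fixtures import TruthTable
from retroprom.workflows import refine_sites


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="scratch/simdata")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    truth = TruthTable.read(args.data)
    sites, _, _, pwm, _ = refine_sites(args.data, truth)
    track = io.BedGraph.read(os.path.join(args.data, "conservation.bedGraph"))
    snps = io.read_bed(os.path.join(args.data, "snps.bed"))

    rows = []
    strata = {"all": sites, "repeat_only": [s for s in sites if s.repeat_context != "unique"]}
    for name, subset in strata.items():
        prof = co.score_profile(subset, track, stratum=name)
        sprof = co.snp_profile(subset, snps, stratum=name)
        for p, v, n, sv in zip(prof.positions, prof.values, prof.n_sites, sprof.values):
            rows.append((name, int(p), float(v), int(n), int(sv)))
    df = pd.DataFrame(rows, columns=["stratum", "position", "mean_score", "n_sites", "snp_count"])
    df[df["stratum"] == "all"][["position", "mean_score", "n_sites"]].to_csv(
        os.path.join(args.out, "conservation_profile.tsv"), sep="\t", index=False)
    df[["stratum", "position", "snp_count"]].to_csv(
        os.path.join(args.out, "snp_profile.tsv"), sep="\t", index=False)

    inm = (df["stratum"] == "all") & (df["position"] >= 0) & (df["position"] < pwm.width)
    outm = (df["stratum"] == "all") & ~((df["position"] >= 0) & (df["position"] < pwm.width))
    print(f"motif positions: mean score {df.loc[inm, 'mean_score'].mean():.3f}, "
          f"mean SNP count {df.loc[inm, 'snp_count'].mean():.2f}")
    print(f"flank positions: mean score {df.loc[outm, 'mean_score'].mean():.3f}, "
          f"mean SNP count {df.loc[outm, 'snp_count'].mean():.2f}")


if __name__ == "__main__":
    main()
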