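"""Tandem satellite (HSATII-style) quantification.

Satellites occur in long head-to-tail arrays, so reads can begin near the
end of one monomer and run into the next. The alignment reference is
therefore one full monomer copy (170 bp for the canonical consensus)
concatenated with a partial second copy (bases 1-98), and per-position
tallies fold the duplicated tail back onto the monomer start. Abundance
is compared across samples as reads per million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PARTIAL_COPY_LEN = 98
COLUMNS = ["A", "C", "G", "T", "del", "ins"]


@dataclass(frozen=True)
class SatelliteReference:
    monomer: str
    name: str = "satellite"

    def __post_init__(self):
        object.__setattr__(self, "monomer", self.monomer.upper())

    @property
    def partial_len(self) -> int:
        return min(PARTIAL_COPY_LEN, len(self.monomer))

    @property
    def sequence(self) -> str:
        return self.monomer + self.monomer[: self.partial_len]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            seq = self.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")


def build_satellite_reference(monomer: str, name: str = "satellite") -> SatelliteReference:
    return SatelliteReference(monomer=monomer, name=name)


def satellite_rpm(n_matching_reads: int, total_reads: int) -> float:
    """Reads per million: 1e6 * matching / total."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return 1e6 * n_matching_reads / total_reads


def variant_tally(sam_path, reference: SatelliteReference) -> pd.DataFrame:
    """Per-monomer-position counts of A/C/G/T, deletions and insertions.

    Alignments are against the extended (monomer + partial copy)
    reference; positions in the duplicated tail are folded back modulo the
    monomer length, so the tally has exactly monomer length rows.
    """
    import pysam

    mono_len = len(reference.monomer)
    ext_len = len(reference.sequence)
    tally = np.zeros((mono_len, len(COLUMNS)), dtype=int)
    base_col = {b: i for i, b in enumerate("ACGT")}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.reference_end is not None and rec.reference_end > ext_len:
                raise ValueError(
                    f"alignment {rec.query_name} extends beyond reference ({rec.reference_end} > {ext_len})"
                )
            seq = rec.query_sequence or ""
            prev_ref = None
            for qpos, rpos in rec.get_aligned_pairs():
                if rpos is None:  # insertion relative to reference
                    if prev_ref is not None:
                        tally[prev_ref % mono_len, 5] += 1
                    continue
                fold = rpos % mono_len
                if qpos is None:  # deletion
                    tally[fold, 4] += 1
                else:
                    base = seq[qpos].upper()
                    if base in base_col:
                        tally[fold, base_col[base]] += 1
                prev_ref = rpos
    return pd.DataFrame(tally, columns=COLUMNS)


def project_tandem_reads(alignments, array_start: int, reference: SatelliteReference,
                         genome_seq: str, sam_path) -> int:
    """Re-express reads from a tandem array as alignments to the consensus.

    Each contiguous read lying inside the array is placed at its offset
    modulo the monomer length on the extended reference (so reads crossing
    a monomer junction map onto the duplicated tail). Returns the number
    of reads written.
    """
    mono = len(reference.monomer)
    n = 0
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference.name}\tLN:{len(reference.sequence)}\n")
        for rec in alignments:
            if len(rec.blocks) != 1:
                continue
            s, e = rec.blocks[0]
            pos = (s - array_start) % mono
            if pos + (e - s) > len(reference.sequence):
                continue
            seq = genome_seq[s:e]
            fh.write(f"{rec.read_id}\t0\t{reference.name}\t{pos + 1}\t60\t{e - s}M\t*\t0\t0\t{seq}\t{'I' * (e - s)}\n")
            n += 1
    return n


def blast_tabular_to_sam(blast_path, reference: SatelliteReference, sam_path, read_seqs: dict) -> None:
    """Convert blastn -outfmt 6 hits to SAM against the extended reference.

    Supports ungapped hits only (one aligned block); one SAM record per
    hit, forward hits only on the query.
    """
    ext_len = len(reference.sequence)
    with open(sam_path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        out.write(f"@SQ\tSN:{reference.name}\tLN:{ext_len}\n")
        with open(blast_path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) < 12:
                    continue
                qid, sstart, send = f[0], int(f[8]), int(f[9])
                qstart, qend = int(f[6]), int(f[7])
                if sstart > send:  # reverse hits unsupported in this minimal converter
                    continue
                seq = read_seqs[qid][qstart - 1: qend]
                cigar_parts = []
                if qstart > 1:
                    cigar_parts.append(f"{qstart - 1}S")
                cigar_parts.append(f"{qend - qstart + 1}M")
                full = read_seqs[qid]
                if qend < len(full):
                    cigar_parts.append(f"{len(full) - qend}S")
                out.write(
                    f"{qid}\t0\t{reference.name}\t{sstart}\t60\t{''.join(cigar_parts)}\t*\t0\t0\t{full}\t*\n"
                )
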