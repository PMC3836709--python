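"""Position weight matrix scanning and ChIP-seq peak refinement.

A peak is refined to the single best-scoring window of PWM width found on
either strand, under the simplifying assumption that each peak holds one
binding site. The score of a window is the sum of per-position base
weights; windows containing N take the per-position minimum weight at
those positions so assembly-gap edges never produce spurious maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .intervals_io import GenomicInterval, overlap_len, repeat_tree

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    name: str
    weights: np.ndarray  # shape (width, 4), column order A,C,G,T
    score_threshold: float = 9.75

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1 or not np.all(np.isfinite(w)):
            raise ValueError("PWM weights must be a finite (width, 4) matrix")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return replace(self, weights=self.weights[::-1, ::-1])


def read_pwm(path) -> PWM:
    """Read a PWM TSV: '# name=' / '# threshold=' headers, then pos A C G T rows."""
    name, threshold, rows = "pwm", 9.75, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("name="):
                    name = body.split("=", 1)[1]
                elif body.startswith("threshold="):
                    threshold = float(body.split("=", 1)[1])
                continue
            f = line.split("\t")
            if f[0] in ("pos", "position"):
                continue
            rows.append([float(x) for x in f[1:5]])
    return PWM(name=name, weights=np.array(rows), score_threshold=threshold)


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={pwm.name}\n# threshold={pwm.score_threshold}\n")
        fh.write("pos\tA\tC\tG\tT\n")
        for i, row in enumerate(pwm.weights):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


@dataclass(frozen=True)
class BindingSite:
    """A peak refined to its best-scoring motif window."""

    peak_id: str
    interval: GenomicInterval
    strand: str
    score: float
    repeat_context: object = None  # RepeatInstance or "unique" once assigned


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3, N (or any other IUPAC code) to 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _scan(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Scores of every width-sized window of an encoded sequence (one strand)."""
    w = pwm.width
    n = encoded.size - w + 1
    if n <= 0:
        return np.empty(0)
    # per-position lookup with N -> column minimum
    lut = np.hstack([pwm.weights, pwm.weights.min(axis=1, keepdims=True)])  # (width, 5)
    scores = np.zeros(n)
    for j in range(w):
        scores += lut[j, encoded[j: j + n]]
    return scores


def scan_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse) window scores indexed by window start on the given strand.

    reverse[i] is the score of the reverse complement of seq[i:i+width].
    """
    enc = _encode(seq)
    fwd = _scan(pwm, enc)
    rev = _scan(pwm.reverse_complement(), enc)
    return fwd, rev


def score_window(pwm: PWM, seq: str) -> float:
    """Score one window of exactly PWM width (single strand)."""
    if len(seq) != pwm.width:
        raise ValueError(f"window length {len(seq)} != PWM width {pwm.width}")
    return float(_scan(pwm, _encode(seq))[0])


def best_window(pwm: PWM, region: GenomicInterval, genome, peak_id: str = "") -> BindingSite:
    """Best-scoring window over both strands of a region.

    Ties are broken in favour of the forward strand, then the smaller start.
    `genome` is any mapping chrom -> sequence (e.g. a pyfaidx.Fasta).
    """
    if len(region) < pwm.width:
        raise ValueError(f"region {region} shorter than PWM width {pwm.width}")
    seq = str(genome[region.chrom][region.start: region.end])
    fwd, rev = scan_scores(pwm, seq)
    i_f, i_r = int(fwd.argmax()), int(rev.argmax())  # argmax takes smallest start on ties
    if fwd[i_f] >= rev[i_r]:  # forward strand wins score ties
        strand, i, score = "+", i_f, float(fwd[i_f])
    else:
        strand, i, score = "-", i_r, float(rev[i_r])
    iv = GenomicInterval(region.chrom, region.start + i, region.start + i + pwm.width, strand)
    return BindingSite(peak_id=peak_id, interval=iv, strand=strand, score=score)


def count_motifs(pwm: PWM, seq: str, threshold: float | None = None) -> int:
    """Number of window starts whose best-strand score reaches the threshold.

    A window and its reverse complement both passing at the same start count
    once (the better strand only); overlapping starts each count.
    """
    threshold = pwm.score_threshold if threshold is None else threshold
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if len(seq) < pwm.width:
        return 0
    fwd, rev = scan_scores(pwm, seq)
    return int((np.maximum(fwd, rev) >= threshold).sum())


def count_motifs_region(pwm: PWM, region: GenomicInterval, genome, threshold=None) -> int:
    return count_motifs(pwm, str(genome[region.chrom][region.start: region.end]), threshold)


def assign_repeat_context(sites, repeats) -> list[BindingSite]:
    """Attach to each site the repeat its refined window overlaps.

    The repeat with the largest overlap wins; ties go to the smaller start;
    sites whose window touches no repeat are labelled "unique".
    """
    trees = repeat_tree(repeats)
    out = []
    for s in sites:
        hits = []
        if s.interval.chrom in trees:
            for node in trees[s.interval.chrom].overlap(s.interval.start, s.interval.end):
                rep = node.data
                hits.append((overlap_len(rep.interval, s.interval), -rep.interval.start, rep))
        if hits:
            hits.sort(key=lambda t: (t[0], t[1]), reverse=True)
            context = hits[0][2]
        else:
            context = "unique"
        out.append(replace(s, repeat_context=context))
    return out
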