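"""PWM log-odds scanning and per-anchor CTCF site assignment.

An anchor (loop anchor or TAD boundary window) is assigned at most one
CTCF site: the highest-scoring motif hit inside the anchor that is
supported by a CTCF ChIP peak (>=1 bp overlap).  The ChIP gate supplies
specificity, so the scan threshold can stay permissive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .core import GenomicInterval, PeakSet, overlap_bp

__all__ = ["Pwm", "MotifHit", "log_odds_score", "scan_region",
           "assign_anchor_ctcf", "load_default_ctcf_pwm"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix over {A,C,G,T}.

    ``probs`` has shape (width, 4); each row sums to 1.  ``background``
    is the base composition used in the log-odds denominator and
    ``pseudocount`` regularizes zero probabilities:

        score(b, i) = log2( (p_i(b) + pc * bg(b)) / ((1 + pc) * bg(b)) )

    'N' in a scanned window contributes 0 bits.
    """

    name: str
    probs: tuple[tuple[float, ...], ...]
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        for i, row in enumerate(self.probs):
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"PWM position {i} probabilities sum to {sum(row)}")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @property
    def width(self) -> int:
        return len(self.probs)

    def score_table(self) -> np.ndarray:
        """(width, 4) array of per-base log-odds bits."""
        p = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        with np.errstate(divide="ignore"):   # zero prob + zero pseudocount -> -inf
            return np.log2((p + self.pseudocount * bg) / ((1.0 + self.pseudocount) * bg))

    def max_score(self) -> float:
        return float(self.score_table().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_BASES[int(i)] for i in np.asarray(self.probs).argmax(axis=1))

    @staticmethod
    def from_counts(name: str, counts: Sequence[Sequence[float]],
                    background=(0.25, 0.25, 0.25, 0.25),
                    pseudocount: float = 0.0) -> "Pwm":
        """Counts per base per position (rows = positions, cols = ACGT)."""
        arr = np.asarray(counts, dtype=float)
        probs = arr / arr.sum(axis=1, keepdims=True)
        return Pwm(name=name, probs=tuple(map(tuple, probs)),
                   background=tuple(background), pseudocount=pseudocount)

    @staticmethod
    def from_jaspar(path_or_text, pseudocount: float = 0.001) -> "Pwm":
        """Parse a JASPAR-format matrix: a '>' header then four rows
        ``A [ 1 2 3 ... ]`` etc. (rows are per-base, columns positions)."""
        if hasattr(path_or_text, "read"):
            text = path_or_text.read()
        else:
            text = str(path_or_text)
            if "\n" not in text and not text.lstrip().startswith(">"):
                with open(text) as fh:
                    text = fh.read()
        name = "pwm"
        rows: dict[str, list[float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else "pwm"
                continue
            base = line[0].upper()
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
        if set(rows) != set(_BASES):
            raise ValueError(f"JASPAR matrix must have A,C,G,T rows, got {sorted(rows)}")
        counts = np.array([rows[b] for b in _BASES], dtype=float).T  # (width, 4)
        return Pwm.from_counts(name, counts, pseudocount=pseudocount)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float
    anchor_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("motif hit score must be finite")


def log_odds_score(sequence_window: str, pwm: Pwm, strand: str = "+") -> float:
    """Log-odds bits of a window against the PWM; '-' scores the
    reverse complement.  Window length must equal the PWM width."""
    if len(sequence_window) != pwm.width:
        raise ValueError(f"window length {len(sequence_window)} != PWM width {pwm.width}")
    seq = sequence_window.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    table = pwm.score_table()
    total = 0.0
    for i, base in enumerate(seq):
        idx = _BASE_INDEX.get(base)
        if idx is not None:          # 'N' (or any ambiguity code) adds 0 bits
            total += table[i, idx]
    return float(total)


def scan_region(region: GenomicInterval, genome_sequence: Union[str, dict],
                pwm: Pwm, min_score: Optional[float] = None) -> list[MotifHit]:
    """All motif hits in ``region`` on both strands with score >= min_score.

    ``genome_sequence`` is either the chromosome string or a dict of
    chromosome -> sequence.  Default ``min_score`` is 60% of the PWM's
    maximum attainable bits.  Hits are sorted by score descending then
    genome position ascending (a deterministic total order).
    """
    if isinstance(genome_sequence, dict):
        try:
            chrom_seq = genome_sequence[region.chrom]
        except KeyError:
            raise KeyError(f"no sequence for chromosome {region.chrom!r}") from None
    else:
        chrom_seq = genome_sequence
    if region.end > len(chrom_seq):
        raise ValueError(f"region {region} beyond sequence length {len(chrom_seq)}")
    if min_score is None:
        min_score = 0.6 * pwm.max_score()

    w = pwm.width
    sub = chrom_seq[region.start:region.end].upper()
    if len(sub) < w:
        return []
    table = pwm.score_table()
    codes = np.full(len(sub), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(sub.encode(), dtype=np.uint8) == ord(base)] = idx
    n_pos = len(sub) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)[:n_pos]
    valid = windows >= 0
    # plus strand: position i of window scored by table row i
    fwd = np.where(valid, table[np.arange(w), np.clip(windows, 0, 3)], 0.0).sum(axis=1)
    # minus strand: reverse complement == complement base at mirrored row
    # score of revcomp(window) = sum_j table[j, comp[window[w-1-j]]]
    #                          = sum_i table[w-1-i, comp[window[i]]]
    comp = np.array([3, 2, 1, 0], dtype=np.int8)
    rev = np.where(valid, table[::-1][np.arange(w), comp[np.clip(windows, 0, 3)]], 0.0).sum(axis=1)

    hits: list[MotifHit] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for i in np.nonzero(scores >= min_score)[0]:
            hits.append(MotifHit(
                interval=GenomicInterval(region.chrom, region.start + int(i),
                                         region.start + int(i) + w, strand),
                strand=strand, score=float(scores[i])))
    hits.sort(key=lambda h: (-h.score, h.interval.start, h.strand))
    return hits


def assign_anchor_ctcf(anchor_interval: GenomicInterval, motif_hits: Sequence[MotifHit],
                       chip_peaks: PeakSet) -> Optional[MotifHit]:
    """The anchor's CTCF site: highest-scoring hit inside the anchor that
    overlaps a ChIP peak by >=1 bp; ties broken by smaller start.  None
    when no hit is peak-supported (a valid outcome)."""
    best: Optional[MotifHit] = None
    for hit in motif_hits:
        if not hit.interval.overlaps(anchor_interval):
            continue
        if not any(overlap_bp(hit.interval, p.interval) >= 1 for p in chip_peaks):
            continue
        if best is None or (hit.score, -hit.interval.start) > (best.score, -best.interval.start):
            best = hit
    return best


def load_default_ctcf_pwm(pseudocount: float = 0.001) -> Pwm:
    """The bundled 19-column CTCF-like matrix.

    This is a synthetic stand-in (see ``data/ctcf19_synthetic.jaspar``)
    built around a CTCF-like consensus, not a database matrix; replace it
    with any JASPAR-format file via :meth:`Pwm.from_jaspar` for real data.
    """
    text = resources.files("teanchor").joinpath("data/ctcf19_synthetic.jaspar").read_text()
    return Pwm.from_jaspar(text, pseudocount=pseudocount)
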