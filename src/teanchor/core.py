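"""Domain types shared by every stage of the pipeline.

All coordinates are 0-based, half-open ([start, end)), on a named
chromosome of a :class:`GenomeAssembly`.  The single convention is
enforced at the parser boundary (see :mod:`teanchor.io`): RepeatMasker
``.out`` rows (1-based inclusive) and UCSC chain blocks are converted on
read, never downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "Loop",
    "TadBoundary",
    "RepeatFeature",
    "Peak",
    "PeakSet",
    "ChromStateSegment",
    "ChainBlock",
    "ChainAlignment",
    "overlap_bp",
    "midpoint",
]

# RepeatMasker class labels counted as transposable elements (as opposed
# to simple/low-complexity repeats).  "?" suffixed variants are uncertain
# calls that RepeatMasker still assigns to the class.
DEFAULT_TE_CLASSES = frozenset(
    {"SINE", "SINE?", "LINE", "LINE?", "LTR", "LTR?", "DNA", "DNA?", "RC", "Retroposon"}
)


@dataclass(frozen=True)
class GenomeAssembly:
    """A named assembly: chromosome name -> length in bp."""

    name: str
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r} in assembly {self.name!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval; strand is '+', '-' or '.' (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> float:
        return (self.start + self.end) / 2

    def validate(self, assembly: GenomeAssembly) -> "GenomicInterval":
        if self.end > assembly.size(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {assembly.size(self.chrom)} in {assembly.name}"
            )
        return self

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if disjoint or trans)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def midpoint(iv: GenomicInterval) -> float:
    return iv.mid


def edge_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap between interval edges; 0 when overlapping, None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


@dataclass(frozen=True)
class Loop:
    """An ordered pair of loop-anchor intervals on one chromosome.

    ``anchor1`` precedes ``anchor2`` in genome order; callers may pass
    them in either order via :meth:`make`.
    """

    id: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int = 0

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(f"loop {self.id}: anchors on different chromosomes")
        if self.anchor1.start > self.anchor2.start:
            raise ValueError(f"loop {self.id}: anchor1 must precede anchor2")
        if self.span <= 0:
            raise ValueError(f"loop {self.id}: non-positive span")

    @staticmethod
    def make(anchor_a: GenomicInterval, anchor_b: GenomicInterval,
             id: Optional[str] = None, resolution: int = 0) -> "Loop":
        """Build a loop, swapping anchors into genome order if needed."""
        a1, a2 = sorted((anchor_a, anchor_b), key=lambda iv: (iv.start, iv.end))
        if id is None:
            id = f"{a1.chrom}:{a1.start}-{a1.end}_{a2.start}-{a2.end}"
        return Loop(id=id, anchor1=a1, anchor2=a2, resolution=resolution)

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def span(self) -> int:
        return self.anchor2.end - self.anchor1.start


@dataclass(frozen=True)
class TadBoundary:
    """A published TAD border point with its standardized +/-5 kb window."""

    id: str
    chrom: str
    point: int
    window: GenomicInterval

    def __post_init__(self) -> None:
        if not (self.window.start <= self.point < self.window.end):
            raise ValueError(f"boundary {self.id}: point outside window")


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker annotation with its three-level taxonomy."""

    interval: GenomicInterval
    subfamily: str
    family: str
    class_name: str

    def __post_init__(self) -> None:
        if not (self.subfamily and self.family and self.class_name):
            raise ValueError("repeat taxonomy fields must be non-empty")

    def is_te(self, te_classes: frozenset = DEFAULT_TE_CLASSES) -> bool:
        return self.class_name in te_classes


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float = 0.0
    name: str = "."


@dataclass
class PeakSet:
    """A labelled collection of ChIP/ATAC peaks (CTCF, p300, ATAC...)."""

    peaks: list[Peak]
    label: str = "CTCF"

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass(frozen=True)
class ChromStateSegment:
    interval: GenomicInterval
    state: str


@dataclass(frozen=True)
class ChainBlock:
    """One aligned block: ``size`` aligned bases followed by a gap of
    ``source_gap`` bases on the source and ``target_gap`` on the target.
    The last block of a chain has zero gaps."""

    size: int
    source_gap: int = 0
    target_gap: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("chain block size must be positive")
        if self.source_gap < 0 or self.target_gap < 0:
            raise ValueError("chain gaps must be non-negative")


@dataclass(frozen=True)
class ChainAlignment:
    """A UCSC chain: block-wise alignment from a source assembly interval
    to a target assembly interval.

    Coordinates follow the chain-file convention: ``source_start/end`` are
    on the + strand; ``target_start/end`` are on ``target_strand`` (for
    '-' they count from the chromosome's reverse-complement origin).
    """

    chain_id: str
    score: float
    source_chrom: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        s_span = sum(b.size + b.source_gap for b in self.blocks)
        t_span = sum(b.size + b.target_gap for b in self.blocks)
        if s_span != self.source_end - self.source_start:
            raise ValueError(
                f"chain {self.chain_id}: source span {self.source_end - self.source_start} "
                f"!= blocks+gaps {s_span}"
            )
        if t_span != self.target_end - self.target_start:
            raise ValueError(
                f"chain {self.chain_id}: target span {self.target_end - self.target_start} "
                f"!= blocks+gaps {t_span}"
            )
        if self.blocks and (self.blocks[-1].source_gap or self.blocks[-1].target_gap):
            raise ValueError(f"chain {self.chain_id}: final block must have zero gaps")

    def invert(self) -> "ChainAlignment":
        """Swap source and target roles (plus-strand chains only)."""
        if self.source_strand != "+" or self.target_strand != "+":
            raise NotImplementedError("inversion implemented for +/+ chains only")
        return ChainAlignment(
            chain_id=self.chain_id,
            score=self.score,
            source_chrom=self.target_chrom,
            source_size=self.target_size,
            source_strand="+",
            source_start=self.target_start,
            source_end=self.target_end,
            target_chrom=self.source_chrom,
            target_size=self.source_size,
            target_strand="+",
            target_start=self.source_start,
            target_end=self.source_end,
            blocks=tuple(
                ChainBlock(b.size, b.target_gap, b.source_gap) for b in self.blocks
            ),
        )
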