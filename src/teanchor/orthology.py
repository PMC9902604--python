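"""Chain-based interval lifting and loop/TAD-boundary conservation calls.

Lifting follows UCSC liftOver semantics: an interval is walked through
the best-scoring overlapping chain's aligned blocks; it maps when at
least ``min_match`` (default 0.1) of its bases fall inside blocks, and
an interval whose bases map through more than one chain is a *split*
(treated as unmapped).  A source loop is conserved when both lifted
anchors fall within min(half loop span, 50 kb) of a target loop's
anchor pair; a lifted TAD-boundary CTCF motif is conserved when it falls
within 50 kb of a target boundary motif.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import ChainAlignment, GenomicInterval, Loop
from .attribution import StructureClassification

logger = logging.getLogger(__name__)

DEFAULT_MIN_MATCH = 0.1
CONSERVATION_CAP_BP = 50_000

__all__ = ["LiftResult", "OrthologyLabel", "ChainIndex", "lift_interval",
           "loop_is_conserved", "tad_boundary_is_conserved", "cross_tabulate",
           "CrossTabulation"]


@dataclass(frozen=True)
class LiftResult:
    source: GenomicInterval
    target: Optional[GenomicInterval]
    mapped_fraction: float
    status: str      # mapped | unmapped_low_match | unmapped_no_chain | split

    @property
    def is_mapped(self) -> bool:
        return self.status == "mapped"


class ChainIndex:
    """Chains grouped by source chromosome, best score first."""

    def __init__(self, chains: Iterable[ChainAlignment]):
        self._by_chrom: dict[str, list[ChainAlignment]] = defaultdict(list)
        for ch in chains:
            self._by_chrom[ch.source_chrom].append(ch)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda c: -c.score)

    def overlapping(self, interval: GenomicInterval) -> list[ChainAlignment]:
        return [ch for ch in self._by_chrom.get(interval.chrom, ())
                if ch.source_start < interval.end and interval.start < ch.source_end]


def _walk_chain(interval: GenomicInterval, chain: ChainAlignment
                ) -> tuple[int, Optional[GenomicInterval]]:
    """Mapped base count and the [min,max) hull of their target images."""
    s_pos = chain.source_start
    t_pos = chain.target_start          # in target-strand coordinates
    mapped = 0
    lo = hi = None
    for block in chain.blocks:
        ov_start = max(interval.start, s_pos)
        ov_end = min(interval.end, s_pos + block.size)
        if ov_start < ov_end:
            mapped += ov_end - ov_start
            img_lo = t_pos + (ov_start - s_pos)
            img_hi = t_pos + (ov_end - s_pos)
            lo = img_lo if lo is None else min(lo, img_lo)
            hi = img_hi if hi is None else max(hi, img_hi)
        s_pos += block.size + block.source_gap
        t_pos += block.size + block.target_gap
    if mapped == 0:
        return 0, None
    if chain.target_strand == "-":
        # convert reverse-strand coordinates to forward-strand
        start, end = chain.target_size - hi, chain.target_size - lo
        strand = "-"
    else:
        start, end = lo, hi
        strand = "+"
    return mapped, GenomicInterval(chain.target_chrom, start, end, strand)


def lift_interval(interval: GenomicInterval, chains, min_match: float = DEFAULT_MIN_MATCH
                  ) -> LiftResult:
    """Map an interval through a chain set (a :class:`ChainIndex` or an
    iterable of chains)."""
    if not isinstance(chains, ChainIndex):
        chains = ChainIndex(chains)
    candidates = []
    for chain in chains.overlapping(interval):
        mapped, target = _walk_chain(interval, chain)
        if mapped > 0:
            candidates.append((chain, mapped, target))
    if not candidates:
        return LiftResult(interval, None, 0.0, "unmapped_no_chain")
    if len(candidates) > 1:
        logger.info("interval %s maps through %d chains; treated as split",
                    interval, len(candidates))
        return LiftResult(interval, None, 0.0, "split")
    _, mapped, target = candidates[0]
    fraction = mapped / interval.length
    if fraction >= min_match:
        return LiftResult(interval, target, fraction, "mapped")
    return LiftResult(interval, None, fraction, "unmapped_low_match")


@dataclass(frozen=True)
class OrthologyLabel:
    structure_id: str
    label: str                        # conserved | lineage_specific | unliftable
    matched_target_id: Optional[str] = None
    distance_bp: Optional[float] = None


def loop_is_conserved(source_loop: Loop, lifted_anchors: tuple[LiftResult, LiftResult],
                      target_loops: Sequence[Loop],
                      cap_bp: int = CONSERVATION_CAP_BP) -> OrthologyLabel:
    """Conservation call for one loop.

    Threshold t = min(source loop span / 2, ``cap_bp``); conserved iff
    some target loop has both anchor-midpoint distances <= t (pairing
    preserved, both loops genome-ordered).  The nearest qualifying
    target (by max of the two distances) is recorded.
    """
    lift1, lift2 = lifted_anchors
    if not (lift1.is_mapped and lift2.is_mapped):
        return OrthologyLabel(source_loop.id, "unliftable")
    t = min(source_loop.span / 2, cap_bp)
    m1, m2 = lift1.target.mid, lift2.target.mid
    if m1 > m2:          # minus-strand lifts can reverse anchor order
        m1, m2 = m2, m1
    best: Optional[tuple[float, Loop]] = None
    for tgt in target_loops:
        if tgt.chrom != lift1.target.chrom:
            continue
        d1 = abs(m1 - tgt.anchor1.mid)
        d2 = abs(m2 - tgt.anchor2.mid)
        if d1 <= t and d2 <= t:
            d = max(d1, d2)
            if best is None or d < best[0]:
                best = (d, tgt)
    if best is None:
        return OrthologyLabel(source_loop.id, "lineage_specific")
    return OrthologyLabel(source_loop.id, "conserved",
                          matched_target_id=best[1].id, distance_bp=best[0])


def tad_boundary_is_conserved(boundary_id: str, lifted_motif: LiftResult,
                              target_motifs: Sequence[GenomicInterval],
                              cap_bp: int = CONSERVATION_CAP_BP) -> OrthologyLabel:
    """Conserved iff the lifted boundary-CTCF motif midpoint lies within
    ``cap_bp`` (50 kb) of any target boundary-CTCF motif midpoint."""
    if not lifted_motif.is_mapped:
        return OrthologyLabel(boundary_id, "unliftable")
    mid = lifted_motif.target.mid
    best: Optional[tuple[float, int]] = None
    for i, tgt in enumerate(target_motifs):
        if tgt.chrom != lifted_motif.target.chrom:
            continue
        d = abs(mid - tgt.mid)
        if d <= cap_bp and (best is None or d < best[0]):
            best = (d, i)
    if best is None:
        return OrthologyLabel(boundary_id, "lineage_specific")
    return OrthologyLabel(boundary_id, "conserved",
                          matched_target_id=str(target_motifs[best[1]]),
                          distance_bp=best[0])


@dataclass
class CrossTabulation:
    """TE-origin x orthology contingency table with a per-subfamily
    breakdown of the TE-derived structures."""

    table: pd.DataFrame              # rows TE_derived/non_TE x cols conserved/lineage_specific
    percents: pd.DataFrame           # column-wise percents
    subfamily_breakdown: pd.DataFrame  # subfamily x orthology counts (TE-derived only)
    n_unliftable: int


def cross_tabulate(classifications: Mapping[str, StructureClassification],
                   orthology: Mapping[str, OrthologyLabel]) -> CrossTabulation:
    """Join origin and orthology labels on structure id and tabulate.

    Excluded structures and unliftable structures drop out of the table;
    an id present on one side only raises with the orphan list.
    """
    orphans = sorted(set(classifications) ^ set(orthology))
    if orphans:
        raise ValueError(f"structure ids missing from one side of the join: {orphans}")
    counts = {(o, c): 0 for o in ("TE_derived", "non_TE") for c in ("conserved", "lineage_specific")}
    sub_counts: dict[tuple[str, str], int] = defaultdict(int)
    n_unliftable = 0
    for sid, cls in classifications.items():
        orth = orthology[sid]
        if orth.label == "unliftable":
            n_unliftable += 1
            continue
        if cls.label == "excluded":
            continue
        te = cls.label == "RE_derived" and any(s.is_te_derived() for s in cls.re_sites())
        origin = "TE_derived" if te else "non_TE"
        counts[(origin, orth.label)] += 1
        if te:
            for site in cls.re_sites():
                if site.is_te_derived():
                    sub_counts[(site.repeat.subfamily, orth.label)] += 1
    table = pd.DataFrame(
        {c: [counts[("TE_derived", c)], counts[("non_TE", c)]]
         for c in ("conserved", "lineage_specific")},
        index=["TE_derived", "non_TE"])
    col_sums = table.sum(axis=0)
    percents = table.div(col_sums.where(col_sums > 0, 1), axis=1) * 100.0
    subfams = sorted({k[0] for k in sub_counts})
    breakdown = pd.DataFrame(
        {c: [sub_counts.get((s, c), 0) for s in subfams]
         for c in ("conserved", "lineage_specific")},
        index=subfams)
    return CrossTabulation(table=table, percents=percents,
                           subfamily_breakdown=breakdown, n_unliftable=n_unliftable)
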