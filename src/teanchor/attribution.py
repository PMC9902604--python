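"""Repeat-origin classification of CTCF sites, loops, and TAD boundaries.

A CTCF motif is *RE-derived* when it overlaps a repetitive element by at
least 10 bp.  A loop (or TAD) is RE-derived when at least one of its
anchor (boundary) CTCF sites is RE-derived, non-RE-derived when both
sides carry a CTCF site and neither is RE-derived, and excluded
otherwise; excluded structures never enter denominators.  Summaries
count unique CTCF sites (de-duplicated on motif coordinates), not
structures.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    DEFAULT_TE_CLASSES,
    GenomeAssembly,
    GenomicInterval,
    RepeatFeature,
    TadBoundary,
    overlap_bp,
)
from .motifs import MotifHit

logger = logging.getLogger(__name__)

RE_OVERLAP_MIN_BP = 10          # required motif-repeat overlap
TAD_BOUNDARY_FLANK_BP = 5_000   # border standardized to +/-5 kb

__all__ = [
    "CtcfSite", "StructureClassification", "TaxonomySummary", "RepeatIndex",
    "classify_ctcf_origin", "standardize_tad_boundary", "classify_structure",
    "summarize_taxonomy", "re_fraction", "pooled_re_fraction", "shuffle_null",
    "ShuffleNullResult",
]


class RepeatIndex:
    """Interval index over repeat annotations, per chromosome."""

    def __init__(self, repeats: Iterable[RepeatFeature]):
        self._trees: dict[str, IntervalTree] = {}
        self.repeats = list(repeats)
        for rep in self.repeats:
            iv = rep.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rep)

    def query(self, interval: GenomicInterval) -> list[RepeatFeature]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]


@dataclass(frozen=True)
class CtcfSite:
    """A motif-resolution CTCF site with its repeat-origin call."""

    motif: MotifHit
    origin: str                      # "RE_derived" | "non_RE"
    repeat: Optional[RepeatFeature]
    overlap_bp: int

    def __post_init__(self) -> None:
        re_derived = self.repeat is not None and self.overlap_bp >= RE_OVERLAP_MIN_BP
        if (self.origin == "RE_derived") != re_derived:
            raise ValueError("origin label inconsistent with repeat/overlap evidence")

    @property
    def is_re_derived(self) -> bool:
        return self.origin == "RE_derived"

    def is_te_derived(self, te_classes: frozenset = DEFAULT_TE_CLASSES) -> bool:
        return self.is_re_derived and self.repeat.is_te(te_classes)

    @property
    def key(self) -> tuple:
        """De-duplication key: the motif's genomic coordinates."""
        iv = self.motif.interval
        return (iv.chrom, iv.start, iv.end, iv.strand)


def classify_ctcf_origin(motif_hit: MotifHit, repeats: RepeatIndex,
                         min_overlap: int = RE_OVERLAP_MIN_BP) -> CtcfSite:
    """RE-derived iff the maximal single-repeat overlap is >= ``min_overlap``
    (default 10 bp); the maximal-overlap repeat is attached, ties broken
    by smaller repeat start."""
    best_rep: Optional[RepeatFeature] = None
    best_ov = 0
    for rep in repeats.query(motif_hit.interval):
        ov = overlap_bp(motif_hit.interval, rep.interval)
        if ov > best_ov or (ov == best_ov and ov > 0 and best_rep is not None
                            and rep.interval.start < best_rep.interval.start):
            best_rep, best_ov = rep, ov
    if best_rep is not None and best_ov >= min_overlap:
        return CtcfSite(motif=motif_hit, origin="RE_derived", repeat=best_rep,
                        overlap_bp=best_ov)
    return CtcfSite(motif=motif_hit, origin="non_RE", repeat=None, overlap_bp=best_ov)


def standardize_tad_boundary(border_point: int, chrom: str, assembly: GenomeAssembly,
                             id: Optional[str] = None,
                             flank: int = TAD_BOUNDARY_FLANK_BP) -> TadBoundary:
    """Published border point -> +/-5 kb analysis window, clipped at
    chromosome edges."""
    size = assembly.size(chrom)
    if not (0 <= border_point < size):
        raise ValueError(f"border point {border_point} outside {chrom} (length {size})")
    window = GenomicInterval(chrom, max(0, border_point - flank),
                             min(size, border_point + flank))
    return TadBoundary(id=id or f"{chrom}:{border_point}", chrom=chrom,
                       point=border_point, window=window)


@dataclass(frozen=True)
class StructureClassification:
    structure_id: str
    structure_kind: str              # "loop" | "tad"
    label: str                       # "RE_derived" | "non_RE_derived" | "excluded"
    sites: tuple[Optional[CtcfSite], Optional[CtcfSite]]
    te_only: bool

    @property
    def contributing_repeats(self) -> list[RepeatFeature]:
        return [s.repeat for s in self.sites if s is not None and s.is_re_derived]

    def re_sites(self) -> list[CtcfSite]:
        return [s for s in self.sites if s is not None and s.is_re_derived]


def classify_structure(structure_id: str, structure_kind: str,
                       sites: Sequence[Optional[CtcfSite]],
                       te_classes: frozenset = DEFAULT_TE_CLASSES
                       ) -> StructureClassification:
    """Label a loop/TAD from its 0-2 per-side CTCF sites.

    RE-derived: >=1 RE-derived site.  Non-RE-derived: both sides carry a
    CTCF site, none RE-derived.  Excluded: anything else (these drop out
    of all denominators).
    """
    sites = tuple(sites)
    if len(sites) != 2:
        raise ValueError("a structure has exactly two sides (use None for a missing site)")
    re_sites = [s for s in sites if s is not None and s.is_re_derived]
    if re_sites:
        label = "RE_derived"
        te_only = all(s.repeat.is_te(te_classes) for s in re_sites)
    elif all(s is not None for s in sites):
        label = "non_RE_derived"
        te_only = False
    else:
        label = "excluded"
        te_only = False
    return StructureClassification(structure_id=structure_id, structure_kind=structure_kind,
                                   label=label, sites=sites, te_only=te_only)


@dataclass(frozen=True)
class TaxonomySummary:
    level: str                       # "class" | "family" | "subfamily"
    rows: tuple[tuple[str, int, float], ...]   # (name, count, percent)
    denominator: int

    def as_dict(self) -> dict[str, tuple[int, float]]:
        return {name: (count, pct) for name, count, pct in self.rows}


_TAXON_ACCESSOR = {
    "class": lambda rep: rep.class_name,
    "family": lambda rep: rep.family,
    "subfamily": lambda rep: rep.subfamily,
}


def summarize_taxonomy(classifications: Iterable[StructureClassification],
                       level: str, te_only: bool = False,
                       te_classes: frozenset = DEFAULT_TE_CLASSES) -> TaxonomySummary:
    """Per-taxon counts/percents of unique RE-derived (or, with
    ``te_only``, TE-derived) CTCF sites across the given structures."""
    if level not in _TAXON_ACCESSOR:
        raise ValueError(f"level must be class/family/subfamily, got {level!r}")
    accessor = _TAXON_ACCESSOR[level]
    unique: dict[tuple, CtcfSite] = {}
    for cls in classifications:
        for site in cls.re_sites():
            if te_only and not site.is_te_derived(te_classes):
                continue
            unique.setdefault(site.key, site)
    tally = Counter(accessor(site.repeat) for site in unique.values())
    denom = sum(tally.values())
    if denom == 0:
        logger.warning("taxonomy summary at level %r has an empty denominator", level)
        rows = tuple()
    else:
        rows = tuple(sorted(((name, count, 100.0 * count / denom)
                             for name, count in tally.items()),
                            key=lambda r: (-r[1], r[0])))
    return TaxonomySummary(level=level, rows=rows, denominator=denom)


def re_fraction(sites: Iterable[CtcfSite], te_only: bool = False,
                te_classes: frozenset = DEFAULT_TE_CLASSES
                ) -> tuple[float, int, int]:
    """(percent, numerator, denominator) of unique CTCF sites that are
    RE-derived (or TE-derived with ``te_only``)."""
    unique: dict[tuple, CtcfSite] = {}
    for site in sites:
        unique.setdefault(site.key, site)
    denom = len(unique)
    if denom == 0:
        logger.warning("re_fraction: zero CTCF sites; fraction undefined")
        return float("nan"), 0, 0
    num = sum(1 for s in unique.values()
              if (s.is_te_derived(te_classes) if te_only else s.is_re_derived))
    return 100.0 * num / denom, num, denom


def pooled_re_fraction(samples: Sequence[Iterable[CtcfSite]], te_only: bool = False
                       ) -> tuple[float, int, int]:
    """Pool same-cell-type/species/assay samples: sum of unique RE-derived
    sites over sum of unique sites (not a mean of per-sample percents)."""
    num = den = 0
    for sample in samples:
        _, n, d = re_fraction(sample, te_only=te_only)
        num += n
        den += d
    if den == 0:
        return float("nan"), 0, 0
    return 100.0 * num / den, num, den


@dataclass(frozen=True)
class ShuffleNullResult:
    observed: float                  # observed RE-derived fraction (0-1)
    null: np.ndarray                 # one fraction per shuffle
    p_value: float                   # empirical two-sided

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())


def shuffle_null(ctcf_sites: Sequence[CtcfSite], repeats: RepeatIndex,
                 assembly: GenomeAssembly, n_shuffles: int = 1000,
                 seed: int = 0, min_overlap: int = RE_OVERLAP_MIN_BP
                 ) -> ShuffleNullResult:
    """Random-expectation null for the RE-derived fraction.

    Each shuffle re-places every motif uniformly on its own chromosome
    (length- and chromosome-preserving) and re-applies the >=10 bp rule.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    sites = list(ctcf_sites)
    if not sites:
        raise ValueError("no CTCF sites supplied")
    for s in sites:
        if s.motif.interval.length > assembly.size(s.motif.interval.chrom):
            raise ValueError(f"motif longer than chromosome {s.motif.interval.chrom}")
    observed = sum(1 for s in sites if s.is_re_derived) / len(sites)

    rng = np.random.default_rng(seed)
    chroms = [s.motif.interval.chrom for s in sites]
    lengths = np.array([s.motif.interval.length for s in sites])
    maxima = np.array([assembly.size(c) for c in chroms]) - lengths
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        starts = rng.integers(0, maxima + 1)
        n_re = 0
        for chrom, start, length in zip(chroms, starts, lengths):
            iv = GenomicInterval(chrom, int(start), int(start) + int(length))
            best = max((overlap_bp(iv, rep.interval) for rep in repeats.query(iv)),
                       default=0)
            if best >= min_overlap:
                n_re += 1
        null[k] = n_re / len(sites)
    p_hi = (1 + np.sum(null >= observed)) / (n_shuffles + 1)
    p_lo = (1 + np.sum(null <= observed)) / (n_shuffles + 1)
    return ShuffleNullResult(observed=observed, null=null,
                             p_value=float(min(1.0, 2 * min(p_hi, p_lo))))
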