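"""ChromHMM-based functional attribution of loops and CRISPR candidate
selection.

A loop is an *enhancer-promoter* loop when a ChromHMM promoter state
(TssA, TssAFlnk) lies within 10 kb of one anchor and an enhancer state
(Enh, EnhG; plus EnhA1/EnhA2 in the human vocabulary) lies within 10 kb
of the opposite anchor; a polycomb state (ReprPC, ReprPCWk) at the
opposite anchor instead makes it a *repressive* loop.  Distances are
measured from anchor interval edges (overlap = 0).  When both an
enhancer and a repressor qualify, enhancer-promoter wins and the
conflict is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import ChromStateSegment, GenomicInterval, Loop, PeakSet, overlap_bp
from .core import edge_distance
from .attribution import CtcfSite, StructureClassification
from .orthology import OrthologyLabel

logger = logging.getLogger(__name__)

FUNCTION_WINDOW_BP = 10_000
CTCF_EXCLUSION_WINDOW_BP = 15_000

PROMOTER_STATES = frozenset({"TssA", "TssAFlnk"})
ENHANCER_STATES = frozenset({"Enh", "EnhG", "EnhA1", "EnhA2"})
REPRESSOR_STATES = frozenset({"ReprPC", "ReprPCWk"})
KNOWN_STATES = PROMOTER_STATES | ENHANCER_STATES | REPRESSOR_STATES | {
    "Tx", "TxWk", "TxFlnk", "ZNF/Rpts", "Het", "TssBiv", "BivFlnk",
    "EnhBiv", "Quies", "unmarked"}

DEFAULT_STRENGTH_MAP = {
    "EnhA1": "strong", "EnhA2": "strong", "Enh": "weak", "EnhG": "weak",
    "TssA": "active", "TssAFlnk": "weak",
}

__all__ = ["LoopFunction", "attribute_loop_function", "subclassify_ep",
           "select_crispr_candidates", "CandidateReport", "GeneHancerPair",
           "PROMOTER_STATES", "ENHANCER_STATES", "REPRESSOR_STATES"]


@dataclass(frozen=True)
class LoopFunction:
    loop_id: str
    label: str                       # enhancer_promoter | repressive | unannotated
    ep_subclass: str = "none"        # strong_enh_active_prom | ... | none
    promoter_anchor: Optional[int] = None   # 1 or 2
    conflict_flag: bool = False      # enhancer and repressor both qualified

    def __post_init__(self) -> None:
        if self.ep_subclass != "none" and self.label != "enhancer_promoter":
            raise ValueError("ep_subclass set on a non-E-P loop")


_warned_states: set[str] = set()


def _states_near(anchor: GenomicInterval, segments: Sequence[ChromStateSegment],
                 window: int) -> set[str]:
    found: set[str] = set()
    for seg in segments:
        state = seg.state
        if state not in KNOWN_STATES:
            if state not in _warned_states:
                logger.warning("ignoring unknown ChromHMM state %r", state)
                _warned_states.add(state)
            continue
        d = edge_distance(anchor, seg.interval)
        if d is not None and d <= window:
            found.add(state)
    return found


def attribute_loop_function(loop: Loop, chromhmm_track: Sequence[ChromStateSegment],
                            window: int = FUNCTION_WINDOW_BP,
                            enhancer_states: frozenset = ENHANCER_STATES
                            ) -> LoopFunction:
    """Functional label for one loop from a ChromHMM segmentation.

    Symmetric in the anchors: the promoter may sit at either end.  The
    orientation with the promoter at anchor1 is evaluated first; this
    only affects ``promoter_anchor`` bookkeeping, never the label.
    """
    near1 = _states_near(loop.anchor1, chromhmm_track, window)
    near2 = _states_near(loop.anchor2, chromhmm_track, window)
    for promoter_anchor, prom_states, opp_states in ((1, near1, near2), (2, near2, near1)):
        if not (prom_states & PROMOTER_STATES):
            continue
        has_enh = bool(opp_states & enhancer_states)
        has_rep = bool(opp_states & REPRESSOR_STATES)
        if has_enh:
            if has_rep:
                logger.info("loop %s: enhancer and repressor both qualify; "
                            "labelled enhancer_promoter", loop.id)
            return LoopFunction(loop.id, "enhancer_promoter",
                                promoter_anchor=promoter_anchor, conflict_flag=has_rep)
        if has_rep:
            return LoopFunction(loop.id, "repressive", promoter_anchor=promoter_anchor)
    return LoopFunction(loop.id, "unannotated")


def subclassify_ep(loop: Loop, loop_function: LoopFunction,
                   chromhmm_track: Sequence[ChromStateSegment],
                   strength_map: Mapping[str, str] = DEFAULT_STRENGTH_MAP,
                   window: int = FUNCTION_WINDOW_BP) -> str:
    """Strong/weak enhancer x active/weak promoter subclass of an E-P loop.

    The strongest qualifying state on each side wins (any strong
    enhancer beats weak ones; TssA beats TssAFlnk with the default map).
    Non-E-P loops return "none".
    """
    if loop_function.label != "enhancer_promoter":
        return "none"
    prom_anchor = loop.anchor1 if loop_function.promoter_anchor == 1 else loop.anchor2
    enh_anchor = loop.anchor2 if loop_function.promoter_anchor == 1 else loop.anchor1
    prom_states = _states_near(prom_anchor, chromhmm_track, window) & PROMOTER_STATES
    enh_states = _states_near(enh_anchor, chromhmm_track, window) & ENHANCER_STATES
    enh = "strong" if any(strength_map.get(s) == "strong" for s in enh_states) else "weak"
    prom = "active" if any(strength_map.get(s) == "active" for s in prom_states) else "weak"
    return f"{enh}_enh_{prom}_prom"


@dataclass(frozen=True)
class GeneHancerPair:
    enhancer: GenomicInterval
    promoter: GenomicInterval


FILTER_NAMES = ("re_derived_specific", "functional", "ctcf_exclusion", "p300_overlap")


@dataclass
class CandidateReport:
    """Per-loop audit of the candidate-selection filters.

    ``passed`` lists filters the loop cleared; ``rejected_at`` is the
    first filter that fired, or None for retained candidates.
    """

    loop_id: str
    candidate_anchor: Optional[int]
    passed: list[str] = field(default_factory=list)
    rejected_at: Optional[str] = None
    genehancer_supported: bool = False
    motif_score: float = float("nan")
    rank: Optional[int] = None


def _candidate_site(cls: StructureClassification) -> tuple[Optional[int], Optional[CtcfSite]]:
    """The anchor index (1/2) and site of the RE-derived anchor CTCF;
    when both anchors qualify, the higher motif score wins."""
    best = None
    for idx, site in enumerate(cls.sites, start=1):
        if site is not None and site.is_re_derived:
            if best is None or site.motif.score > best[1].motif.score:
                best = (idx, site)
    return best if best is not None else (None, None)


def select_crispr_candidates(loops: Sequence[Loop],
                             classifications: Mapping[str, StructureClassification],
                             orthology: Mapping[str, OrthologyLabel],
                             functions: Mapping[str, LoopFunction],
                             ctcf_peaks: PeakSet,
                             p300_peaks: PeakSet,
                             genehancer_pairs: Sequence[GeneHancerPair] = (),
                             exclusion_window: int = CTCF_EXCLUSION_WINDOW_BP
                             ) -> tuple[list[CandidateReport], list[CandidateReport]]:
    """Apply the CRISPR candidate filters in order and rank survivors.

    Filters: (1) >=1 RE-derived anchor CTCF and lineage-specific;
    (2) promoter within 10 kb of one anchor and enhancer/repressor
    within 10 kb of the other (i.e. functionally annotated);
    (3) at most one active CTCF peak within 15 kb of the candidate
    anchor; (4) the candidate motif must not overlap a p300 peak.
    Survivors are ranked GeneHancer-supported first, then by motif PWM
    score descending.  Returns (ranked candidates, all reports).
    """
    reports: list[CandidateReport] = []
    for loop in loops:
        cls = classifications.get(loop.id)
        orth = orthology.get(loop.id)
        fn = functions.get(loop.id)
        if cls is None or orth is None or fn is None:
            raise ValueError(f"loop {loop.id} missing from a classification input")
        anchor_idx, site = _candidate_site(cls)
        rep = CandidateReport(loop_id=loop.id, candidate_anchor=anchor_idx)
        reports.append(rep)

        if site is None or orth.label != "lineage_specific":
            rep.rejected_at = "re_derived_specific"
            continue
        rep.passed.append("re_derived_specific")
        rep.motif_score = site.motif.score

        if fn.label == "unannotated":
            rep.rejected_at = "functional"
            continue
        rep.passed.append("functional")

        candidate_anchor = loop.anchor1 if anchor_idx == 1 else loop.anchor2
        n_near = sum(1 for p in ctcf_peaks
                     if (d := edge_distance(candidate_anchor, p.interval)) is not None
                     and d <= exclusion_window)
        if n_near > 1:
            rep.rejected_at = "ctcf_exclusion"
            continue
        rep.passed.append("ctcf_exclusion")

        if any(overlap_bp(site.motif.interval, p.interval) >= 1 for p in p300_peaks):
            rep.rejected_at = "p300_overlap"
            continue
        rep.passed.append("p300_overlap")

        rep.genehancer_supported = any(
            (loop.anchor1.overlaps(gh.enhancer) and loop.anchor2.overlaps(gh.promoter))
            or (loop.anchor2.overlaps(gh.enhancer) and loop.anchor1.overlaps(gh.promoter))
            for gh in genehancer_pairs)

    retained = [r for r in reports if r.rejected_at is None]
    retained.sort(key=lambda r: (not r.genehancer_supported, -r.motif_score, r.loop_id))
    for i, r in enumerate(retained, 1):
        r.rank = i
    return retained, reports


def candidate_table(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    """One row per loop with per-filter booleans, for the TSV report."""
    rows = []
    for r in reports:
        row = {"loop_id": r.loop_id, "candidate_anchor": r.candidate_anchor,
               "rejected_at": r.rejected_at or "", "rank": r.rank,
               "genehancer_supported": r.genehancer_supported,
               "motif_score": r.motif_score}
        for name in FILTER_NAMES:
            row[f"pass_{name}"] = name in r.passed
        rows.append(row)
    return pd.DataFrame(rows)
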