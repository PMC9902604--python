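"""Two-species synthetic dataset with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
two genomes related by a block-wise chain (species B derives from A by
seeded insertions/deletions), TE annotations at class/family/subfamily
resolution with a subset carrying an exact-consensus CTCF motif, loop
and TAD-boundary calls anchored at those motifs, ChromHMM-like state
tracks, ChIP peak files, and Poisson contact maps with distance decay,
domain blocks and a focal loop peak.

Layout guarantees make every planted label exactly recoverable:

* loops live on a fixed grid of ``slot_width`` (default 100 kb) slots,
  so no two loops can accidentally satisfy the 50 kb conservation cap;
* every anchor/boundary motif is an exact consensus with a ChIP peak,
  so the scan + peak gate recovers each site with position and strand
  exact;
* RE-derived sites sit fully inside a planted TE (overlap = motif
  width >= 10 bp); non-RE motifs are kept >= 25 bp clear of any repeat;
* lineage-specific (species A only) loop-anchor TEs sit in blocks
  deleted from B; conserved structures are re-planted in B at
  chain-lifted coordinates.

Background sequence is i.i.d. uniform so downstream logic is isolated
from scanner sensitivity.  Same config (including seed) => byte-
identical emitted files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ChainAlignment,
    ChainBlock,
    ChromStateSegment,
    GenomeAssembly,
    GenomicInterval,
    Loop,
    Peak,
    PeakSet,
    RepeatFeature,
)
from .contacts import ContactMatrix
from .loop_function import GeneHancerPair
from .motifs import Pwm, load_default_ctcf_pwm, reverse_complement
from . import io as tio

__all__ = ["SimConfig", "SyntheticDataset", "ContactTruth", "generate_dataset",
           "generate_genome_pair", "simulate_contact_pair", "write_dataset"]

# class -> family -> subfamilies used for planted TE identities
TE_TAXONOMY = {
    "SINE": {"Alu": ["AluY", "AluSx"], "MIR": ["MIRb", "MIR3"],
             "B2": ["B2_Mm2", "B2_Mm1t"]},
    "LINE": {"L1": ["L1MC1", "L1MB7"], "L2": ["L2a", "L2b"]},
    "LTR": {"ERVL-MaLR": ["MLT1H1", "MLT1K"], "ERV1": ["MER52C"]},
    "DNA": {"hAT-Charlie": ["MER20", "MER5A"], "hAT-Tip100": ["MER91B"]},
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    The planted fractions are the quantities the pipeline must recover:
    30% of anchor CTCF sites RE-derived, 50% of structures lineage-
    specific, 40% of loops enhancer-promoter (plus 10% repressive).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 3_000_000
    bin_size: int = 5_000
    slot_width: int = 100_000            # one loop per slot
    anchor_width: int = 10_000
    n_te_copies: int = 200               # per species, incl. anchor/boundary TEs
    te_class_mix: tuple = (("SINE", 0.4), ("LINE", 0.3), ("LTR", 0.2), ("DNA", 0.1))
    motif_carry_prob: float = 0.3        # background TEs carrying a (non-anchor) motif
    n_loops: int = 60
    n_tads: int = 12                     # total standardized boundaries
    re_derived_fraction: float = 0.3     # of anchor/boundary CTCF sites
    lineage_specific_fraction: float = 0.5
    ep_fraction: float = 0.4
    repressive_fraction: float = 0.1
    indel_size: int = 8_000              # neutral insertions in gap zones
    anchor_deletion_pad: int = 100       # padding around deleted A-specific TEs
    # contact model
    contact_region_length: int = 600_000
    contact_scale: float = 100.0
    contact_alpha: float = 1.0
    contact_d0: int = 50_000
    tad_factor: float = 3.0
    loop_factor: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.re_derived_fraction <= 1
                and 0 <= self.lineage_specific_fraction <= 1
                and 0 <= self.ep_fraction + self.repressive_fraction <= 1
                and 0 <= self.motif_carry_prob <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.chrom_length % self.bin_size:
            raise ValueError("bin size must divide chromosome length")
        if self.chrom_length % self.slot_width:
            raise ValueError("slot width must divide chromosome length")
        if self.n_loops % self.n_chromosomes:
            raise ValueError("n_loops must be divisible by n_chromosomes")
        if self.n_tads % self.n_chromosomes:
            raise ValueError("n_tads must be divisible by n_chromosomes")
        slots = self.chrom_length // self.slot_width * self.n_chromosomes
        if self.n_loops > slots:
            raise ValueError(f"{self.n_loops} loops need {self.n_loops} slots, "
                             f"only {slots} available; lower density")


@dataclass
class ContactTruth:
    region: GenomicInterval
    tad_a: GenomicInterval               # domain upstream of the ablated boundary
    tad_b: GenomicInterval               # downstream domain
    loop: Loop                           # the planted corner loop
    roi: GenomicInterval                 # region of interest for long-range stats


@dataclass
class SyntheticDataset:
    config: SimConfig
    pwm: Pwm
    assembly_a: GenomeAssembly
    assembly_b: GenomeAssembly
    sequences_a: dict[str, str]
    sequences_b: dict[str, str]
    chains_ab: list[ChainAlignment]      # lift A -> B
    chains_ba: list[ChainAlignment]
    repeats_a: list[RepeatFeature]
    repeats_b: list[RepeatFeature]
    loops_a: list[Loop]
    loops_b: list[Loop]
    boundaries_a: pd.DataFrame           # boundary_id, chrom, point, re_derived, conserved
    boundary_motifs_b: list[GenomicInterval]
    chromhmm_a: list[ChromStateSegment]
    ctcf_peaks_a: PeakSet
    ctcf_peaks_b: PeakSet
    p300_peaks_a: PeakSet
    genehancer_pairs: list[GeneHancerPair]
    loop_truth: pd.DataFrame             # per-loop planted labels
    site_truth: pd.DataFrame             # per-anchor planted CTCF sites
    background_motifs: list[tuple[str, int, str]]  # inactive in-TE motifs (chrom, start, strand)
    contact_truth: ContactTruth

    @property
    def candidate_loop_id(self) -> str:
        return self.loop_truth.loc[self.loop_truth.is_candidate, "loop_id"].iloc[0]


# ---------------------------------------------------------------------------
# planning helpers

@dataclass
class _AnchorPlan:
    loop_idx: int
    side: int                            # 1 or 2
    interval: GenomicInterval
    motif_start: int
    strand: str
    re_derived: bool = False
    te: Optional[RepeatFeature] = None


def _pick_taxon(rng: np.random.Generator, mix) -> tuple[str, str, str]:
    classes, weights = zip(*mix)
    cls = str(rng.choice(classes, p=np.array(weights) / sum(weights)))
    fams = sorted(TE_TAXONOMY[cls])
    fam = str(rng.choice(fams))
    sub = str(rng.choice(TE_TAXONOMY[cls][fam]))
    return cls, fam, sub


def _exact_subset(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Boolean mask with exactly k of n True, seeded."""
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


# ---------------------------------------------------------------------------
# generation

def generate_dataset(config: SimConfig = SimConfig()) -> SyntheticDataset:
    """Build the full two-species dataset with ground truth attached."""
    rng = np.random.default_rng(config.seed)
    pwm = load_default_ctcf_pwm()
    consensus = pwm.consensus()
    w = pwm.width
    cfg = config

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    slots_per_chrom = cfg.chrom_length // cfg.slot_width
    loops_per_chrom = cfg.n_loops // cfg.n_chromosomes
    tads_per_chrom = cfg.n_tads // cfg.n_chromosomes

    # --- per-loop layout -------------------------------------------------
    spans = rng.choice([50_000, 60_000, 70_000], size=cfg.n_loops)
    anchors: list[_AnchorPlan] = []
    loop_meta = []
    for li in range(cfg.n_loops):
        ci, slot = divmod(li, loops_per_chrom)
        # spread loops over the first `loops_per_chrom` slots of each chromosome
        s = slot * cfg.slot_width
        chrom = chroms[ci]
        span = int(spans[li])
        a1 = GenomicInterval(chrom, s + 10_000, s + 10_000 + cfg.anchor_width)
        a2 = GenomicInterval(chrom, s + 10_000 + span, s + 10_000 + span + cfg.anchor_width)
        m1 = s + 15_000 - w // 2
        m2 = s + 15_000 + span - w // 2
        for side, iv, m in ((1, a1, m1), (2, a2, m2)):
            anchors.append(_AnchorPlan(li, side, iv, m,
                                       strand="+" if rng.random() < 0.5 else "-"))
        loop_meta.append({"chrom": chrom, "slot": slot, "span": span,
                          "anchor1": a1, "anchor2": a2})

    # --- label assignment (exact planted counts) -------------------------
    n_specific = round(cfg.lineage_specific_fraction * cfg.n_loops)
    specific = _exact_subset(rng, cfg.n_loops, n_specific)
    n_re_anchors = round(cfg.re_derived_fraction * len(anchors))
    re_mask = _exact_subset(rng, len(anchors), n_re_anchors)
    for plan, is_re in zip(anchors, re_mask):
        plan.re_derived = bool(is_re)
    n_ep = round(cfg.ep_fraction * cfg.n_loops)
    n_rep = round(cfg.repressive_fraction * cfg.n_loops)
    func_perm = rng.permutation(cfg.n_loops)
    function = np.array(["unannotated"] * cfg.n_loops, dtype=object)
    function[func_perm[:n_ep]] = "enhancer_promoter"
    function[func_perm[n_ep:n_ep + n_rep]] = "repressive"

    by_loop: dict[int, dict[int, _AnchorPlan]] = {}
    for plan in anchors:
        by_loop.setdefault(plan.loop_idx, {})[plan.side] = plan

    # --- engineer exactly one pass-all CRISPR candidate ------------------
    # slot 1 of chr1 sits far from TAD boundaries (multiples of 5 slots)
    cand = 1

    def _swap_label(arr, want_value, idx):
        if arr[idx] != want_value:
            donors = [i for i in range(len(arr)) if arr[i] == want_value and i != cand]
            donor = donors[0]
            arr[donor], arr[idx] = arr[idx], arr[donor]

    _swap_label(specific, True, cand)
    _swap_label(function, "enhancer_promoter", cand)
    ca = by_loop[cand]
    if not ca[1].re_derived:
        if ca[2].re_derived:
            ca[1].re_derived, ca[2].re_derived = True, False
        else:
            donors = [p for p in anchors if p.re_derived and p.loop_idx != cand]
            donors[0].re_derived = False
            ca[1].re_derived = True

    # --- TAD boundaries ---------------------------------------------------
    boundary_rows = []
    # boundaries sit on slot edges, clear of both chromosome ends
    boundary_stride = max(1, slots_per_chrom // (tads_per_chrom + 1)) * cfg.slot_width
    n_boundaries = cfg.n_tads
    b_re = _exact_subset(rng, n_boundaries, round(cfg.re_derived_fraction * n_boundaries))
    b_cons = _exact_subset(rng, n_boundaries,
                           n_boundaries - round(cfg.lineage_specific_fraction * n_boundaries))
    bi = 0
    for ci, chrom in enumerate(chroms):
        for k in range(1, tads_per_chrom + 1):
            point = k * boundary_stride
            if point >= cfg.chrom_length:
                point = cfg.chrom_length - cfg.slot_width // 2
            boundary_rows.append({
                "boundary_id": f"tadb_{chrom}_{point}", "chrom": chrom, "point": point,
                "motif_start": point - w // 2,
                "strand": "+" if rng.random() < 0.5 else "-",
                "re_derived": bool(b_re[bi]), "conserved": bool(b_cons[bi])})
            bi += 1
    boundaries = pd.DataFrame(boundary_rows)

    # --- TE placement -----------------------------------------------------
    te_records: list[dict] = []            # species-A repeats
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _forbid(chrom, start, end, pad=25):
        forbidden[chrom].append((start - pad, end + pad))

    def _clear(chrom, start, end) -> bool:
        return all(e <= start or s >= end for s, e in forbidden[chrom])

    # anchor / boundary motifs are always forbidden zones for other repeats
    for plan in anchors:
        _forbid(plan.interval.chrom, plan.motif_start, plan.motif_start + w)
    for row in boundary_rows:
        _forbid(row["chrom"], row["motif_start"], row["motif_start"] + w)

    def _plant_te(chrom, motif_start, deleted_in_b) -> dict:
        te_len = int(rng.integers(300, 801))
        offset = int(rng.integers(50, min(201, te_len - w - 10)))
        te_start = motif_start - offset
        cls, fam, sub = _pick_taxon(rng, cfg.te_class_mix)
        rec = {"chrom": chrom, "start": te_start, "end": te_start + te_len,
               "strand": "+" if rng.random() < 0.5 else "-",
               "class": cls, "family": fam, "subfamily": sub,
               "deleted_in_b": deleted_in_b, "b_specific": False}
        _forbid(chrom, te_start, te_start + te_len, pad=5)
        return rec

    for plan in anchors:
        if plan.re_derived:
            deleted = bool(specific[plan.loop_idx]) and plan.side == _first_re_side(by_loop[plan.loop_idx])
            plan.te = _plant_te(plan.interval.chrom, plan.motif_start, deleted)
            te_records.append(plan.te)
    for idx, row in boundaries.iterrows():
        if row.re_derived:
            te_records.append(_plant_te(row.chrom, row.motif_start, False))

    # background TEs, a motif_carry_prob fraction carrying an (inactive) motif
    n_background = max(0, cfg.n_te_copies - len(te_records))
    attempts = 0
    placed = 0
    background_motifs: list[tuple[str, int, str]] = []
    while placed < n_background:
        attempts += 1
        if attempts > 50 * cfg.n_te_copies:
            raise RuntimeError("TE placement failed after max rejections; lower density")
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        te_len = int(rng.integers(200, 801))
        start = int(rng.integers(0, cfg.chrom_length - te_len))
        if not _clear(chrom, start - 25, start + te_len + 25):
            continue
        cls, fam, sub = _pick_taxon(rng, cfg.te_class_mix)
        rec = {"chrom": chrom, "start": start, "end": start + te_len,
               "strand": "+" if rng.random() < 0.5 else "-",
               "class": cls, "family": fam, "subfamily": sub,
               "deleted_in_b": False, "b_specific": False}
        _forbid(chrom, start, start + te_len, pad=5)
        te_records.append(rec)
        if rng.random() < cfg.motif_carry_prob and te_len > w + 60:
            m = start + int(rng.integers(30, te_len - w - 30))
            background_motifs.append((chrom, m, "+" if rng.random() < 0.5 else "-"))
        placed += 1

    # --- indel events (chain geometry) -----------------------------------
    # deletions remove each A-specific anchor TE; two neutral insertions
    # per chromosome sit in loop-free gap zones
    events: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    pad = cfg.anchor_deletion_pad
    for rec in te_records:
        if rec["deleted_in_b"]:
            events[rec["chrom"]].append((rec["start"] - pad, rec["end"] - rec["start"] + 2 * pad, "del"))
    # two neutral insertions per chromosome, inside the loop-free tail of
    # a slot ([slot_width-9kb, slot_width-1kb) is never touched by a loop)
    boundary_slots = {row["point"] // cfg.slot_width for row in boundary_rows}
    for chrom in chroms:
        for frac in (0.25, 0.75):
            slot = int(slots_per_chrom * frac)
            while slot in boundary_slots or (slot + 1) in boundary_slots:
                slot += 1
            pos = slot * cfg.slot_width + cfg.slot_width - cfg.indel_size - 1_000
            events[chrom].append((pos, cfg.indel_size, "ins"))
    for chrom in chroms:
        events[chrom].sort()

    # --- sequences --------------------------------------------------------
    sequences_a: dict[str, str] = {}
    for chrom in chroms:
        arr = _BASES[rng.integers(0, 4, size=cfg.chrom_length)]
        sequences_a[chrom] = arr.tobytes().decode()

    def _plant_motif(seqs, chrom, start, strand):
        site = consensus if strand == "+" else reverse_complement(consensus)
        s = seqs[chrom]
        seqs[chrom] = s[:start] + site + s[start + w:]

    for plan in anchors:
        _plant_motif(sequences_a, plan.interval.chrom, plan.motif_start, plan.strand)
    for row in boundary_rows:
        _plant_motif(sequences_a, row["chrom"], row["motif_start"], row["strand"])
    for chrom, m, strand in background_motifs:
        _plant_motif(sequences_a, chrom, m, strand)

    # species B sequence + chains
    sequences_b: dict[str, str] = {}
    chains_ab: list[ChainAlignment] = []
    for ci, chrom in enumerate(chroms):
        seq_b, chain = _apply_events(sequences_a[chrom], events[chrom], chrom, rng,
                                     chain_id=str(ci + 1))
        sequences_b[chrom] = seq_b
        chains_ab.append(chain)
    chains_ba = [c.invert() for c in chains_ab]
    assembly_a = GenomeAssembly("simA", {c: len(s) for c, s in sequences_a.items()})
    assembly_b = GenomeAssembly("simB", {c: len(s) for c, s in sequences_b.items()})

    def _b_pos(chrom: str, x: int) -> int:
        off = 0
        for p, size, kind in events[chrom]:
            if kind == "del":
                if p <= x < p + size:
                    raise ValueError(f"position {chrom}:{x} deleted in B")
                if x >= p + size:
                    off -= size
            elif x >= p:
                off += size
        return x + off

    # --- repeats ----------------------------------------------------------
    repeats_a = [RepeatFeature(GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
                               subfamily=r["subfamily"], family=r["family"],
                               class_name=r["class"]) for r in te_records]
    repeats_b = []
    for r in te_records:
        if r["deleted_in_b"]:
            continue
        repeats_b.append(RepeatFeature(
            GenomicInterval(r["chrom"], _b_pos(r["chrom"], r["start"]),
                            _b_pos(r["chrom"], r["end"] - 1) + 1, r["strand"]),
            subfamily=r["subfamily"], family=r["family"], class_name=r["class"]))
    # B-specific TEs inside B-only insertion blocks
    for chrom in chroms:
        for p, size, kind in events[chrom]:
            if kind != "ins":
                continue
            b_start = _b_pos(chrom, p) + int(rng.integers(100, size // 2))
            te_len = int(rng.integers(300, 801))
            cls, fam, sub = _pick_taxon(rng, cfg.te_class_mix)
            repeats_b.append(RepeatFeature(
                GenomicInterval(chrom, b_start, b_start + te_len, "+"),
                subfamily=sub, family=fam, class_name=cls))

    # --- loops, peaks, states --------------------------------------------
    loops_a: list[Loop] = []
    loops_b: list[Loop] = []
    ctcf_peaks_a: list[Peak] = []
    ctcf_peaks_b: list[Peak] = []
    p300_peaks: list[Peak] = []
    segments: list[ChromStateSegment] = []
    genehancer: list[GeneHancerPair] = []
    site_rows = []
    loop_rows = []

    ep_states = []
    for li in range(cfg.n_loops):
        meta = loop_meta[li]
        loop_id = f"loop_{meta['chrom']}_{li}"
        loop = Loop(loop_id, meta["anchor1"], meta["anchor2"], resolution=cfg.anchor_width)
        loops_a.append(loop)
        if not specific[li]:
            b1 = GenomicInterval(meta["chrom"], _b_pos(meta["chrom"], meta["anchor1"].start),
                                 _b_pos(meta["chrom"], meta["anchor1"].end - 1) + 1)
            b2 = GenomicInterval(meta["chrom"], _b_pos(meta["chrom"], meta["anchor2"].start),
                                 _b_pos(meta["chrom"], meta["anchor2"].end - 1) + 1)
            loops_b.append(Loop(f"{loop_id}_B", b1, b2, resolution=cfg.anchor_width))

        for side in (1, 2):
            plan = by_loop[li][side]
            m0 = plan.motif_start
            ctcf_peaks_a.append(Peak(GenomicInterval(meta["chrom"], m0 - 50, m0 + w + 50),
                                     score=10.0, name=f"{loop_id}_a{side}"))
            if not specific[li]:
                bm = _b_pos(meta["chrom"], m0)
                ctcf_peaks_b.append(Peak(GenomicInterval(meta["chrom"], bm - 50, bm + w + 50),
                                         score=10.0, name=f"{loop_id}_a{side}_B"))
            site_rows.append({
                "loop_id": loop_id, "anchor": side, "chrom": meta["chrom"],
                "motif_start": m0, "motif_end": m0 + w, "strand": plan.strand,
                "re_derived": plan.re_derived,
                "subfamily": plan.te["subfamily"] if plan.te else "",
                "family": plan.te["family"] if plan.te else "",
                "class": plan.te["class"] if plan.te else ""})

        subclass = "none"
        if function[li] == "enhancer_promoter":
            prom_state = str(rng.choice(["TssA", "TssAFlnk"]))
            enh_state = str(rng.choice(["Enh", "EnhA1"]))
            if li == cand:
                prom_state, enh_state = "TssA", "EnhA1"   # strong candidate story
            a1, a2 = meta["anchor1"], meta["anchor2"]
            segments.append(ChromStateSegment(
                GenomicInterval(a1.chrom, a1.start - 4_500, a1.start - 3_000), prom_state))
            enh_lo = int(a2.mid) - 750
            segments.append(ChromStateSegment(
                GenomicInterval(a2.chrom, enh_lo, enh_lo + 1_500), enh_state))
            p300_peaks.append(Peak(GenomicInterval(a2.chrom, int(a2.mid) - 150,
                                                   int(a2.mid) + 150), score=5.0))
            subclass = (("strong" if enh_state == "EnhA1" else "weak") + "_enh_" +
                        ("active" if prom_state == "TssA" else "weak") + "_prom")
            genehancer.append(GeneHancerPair(enhancer=a2, promoter=a1))
        elif function[li] == "repressive":
            a1, a2 = meta["anchor1"], meta["anchor2"]
            segments.append(ChromStateSegment(
                GenomicInterval(a1.chrom, a1.start - 4_500, a1.start - 3_000), "TssA"))
            rep_lo = int(a2.mid) - 750
            segments.append(ChromStateSegment(
                GenomicInterval(a2.chrom, rep_lo, rep_lo + 1_500), "ReprPC"))
        ep_states.append(subclass)

        loop_rows.append({
            "loop_id": loop_id, "chrom": meta["chrom"], "span": meta["span"],
            "conserved": not bool(specific[li]),
            "re_derived": by_loop[li][1].re_derived or by_loop[li][2].re_derived,
            "function": function[li], "ep_subclass": subclass,
            "is_candidate": li == cand})

    # boundary motifs get peaks too; conserved boundaries re-appear in B
    boundary_motifs_b: list[GenomicInterval] = []
    for row in boundary_rows:
        m0 = row["motif_start"]
        ctcf_peaks_a.append(Peak(GenomicInterval(row["chrom"], m0 - 50, m0 + w + 50),
                                 score=10.0, name=row["boundary_id"]))
        if row["conserved"]:
            bm = _b_pos(row["chrom"], m0)
            ctcf_peaks_b.append(Peak(GenomicInterval(row["chrom"], bm - 50, bm + w + 50),
                                     score=10.0, name=row["boundary_id"] + "_B"))
            boundary_motifs_b.append(GenomicInterval(row["chrom"], bm, bm + w))

    # decoy CTCF peaks force every non-engineered pass-through loop out at
    # the 15 kb exclusion filter, so the candidate list has length one
    for li in range(cfg.n_loops):
        if li == cand or not specific[li] or function[li] == "unannotated":
            continue
        side = _first_re_side(by_loop[li])
        if side is None:
            continue
        anchor = loop_meta[li]["anchor1"] if side == 1 else loop_meta[li]["anchor2"]
        ctcf_peaks_a.append(Peak(
            GenomicInterval(anchor.chrom, anchor.start - 1_200, anchor.start - 1_000),
            score=8.0, name=f"decoy_{li}"))

    loop_truth = pd.DataFrame(loop_rows)
    site_truth = pd.DataFrame(site_rows)
    contact_truth = _contact_truth(cfg, chroms[0])

    ds = SyntheticDataset(
        config=cfg, pwm=pwm,
        assembly_a=assembly_a, assembly_b=assembly_b,
        sequences_a=sequences_a, sequences_b=sequences_b,
        chains_ab=chains_ab, chains_ba=chains_ba,
        repeats_a=repeats_a, repeats_b=repeats_b,
        loops_a=loops_a, loops_b=loops_b,
        boundaries_a=boundaries, boundary_motifs_b=boundary_motifs_b,
        chromhmm_a=segments,
        ctcf_peaks_a=PeakSet(ctcf_peaks_a, "CTCF"),
        ctcf_peaks_b=PeakSet(ctcf_peaks_b, "CTCF"),
        p300_peaks_a=PeakSet(p300_peaks, "p300"),
        genehancer_pairs=genehancer,
        loop_truth=loop_truth, site_truth=site_truth,
        background_motifs=background_motifs,
        contact_truth=contact_truth)
    _validate(ds)
    return ds


def _first_re_side(sides: dict[int, _AnchorPlan]) -> Optional[int]:
    for side in (1, 2):
        if sides[side].re_derived:
            return side
    return None


def _apply_events(seq_a: str, events, chrom: str, rng: np.random.Generator,
                  chain_id: str) -> tuple[str, ChainAlignment]:
    """Derive the species-B chromosome and the exact A->B chain."""
    pieces = []
    blocks: list[ChainBlock] = []
    cursor = 0
    pending: Optional[tuple[int, int, int]] = None  # (size, sgap, tgap) awaiting flush
    for p, size, kind in events:
        block_len = p - cursor
        if kind == "del":
            pieces.append(seq_a[cursor:p])
            blocks.append(ChainBlock(block_len, size, 0))
            cursor = p + size
        else:
            pieces.append(seq_a[cursor:p])
            ins = _BASES[rng.integers(0, 4, size=size)].tobytes().decode()
            pieces.append(ins)
            blocks.append(ChainBlock(block_len, 0, size))
            cursor = p
    pieces.append(seq_a[cursor:])
    blocks.append(ChainBlock(len(seq_a) - cursor))
    seq_b = "".join(pieces)
    chain = ChainAlignment(
        chain_id=chain_id, score=1_000_000.0,
        source_chrom=chrom, source_size=len(seq_a), source_strand="+",
        source_start=0, source_end=len(seq_a),
        target_chrom=chrom, target_size=len(seq_b), target_strand="+",
        target_start=0, target_end=len(seq_b),
        blocks=tuple(blocks))
    return seq_b, chain


def _contact_truth(cfg: SimConfig, chrom: str) -> ContactTruth:
    region = GenomicInterval(chrom, 0, cfg.contact_region_length)
    tad_a = GenomicInterval(chrom, 100_000, 350_000)
    tad_b = GenomicInterval(chrom, 350_000, 550_000)
    # the loop pixel sits far enough inside the domain that its donut
    # annulus shares the pixel's domain context
    loop = Loop("contact_loop", GenomicInterval(chrom, 125_000, 135_000),
                GenomicInterval(chrom, 315_000, 325_000))
    roi = GenomicInterval(chrom, 100_000, 550_000)
    return ContactTruth(region=region, tad_a=tad_a, tad_b=tad_b, loop=loop, roi=roi)


def simulate_contact_pair(config: SimConfig = SimConfig(), seed: Optional[int] = None
                          ) -> tuple[ContactMatrix, ContactMatrix, ContactTruth]:
    """Poisson WT and KO contact maps over the validation region.

    mean(i,j) = scale * (1 + d_ij/d0)^(-alpha) * tad_factor(i,j)
    * loop_factor(i,j).  The WT map carries two domain blocks and a
    focal peak at the corner loop pixel; in the KO map the boundary
    between the two domains is ablated (the domains merge) and the loop
    factor is reset to 1 — the planted analogue of deleting the
    boundary-anchoring TE.
    """
    cfg = config
    truth = _contact_truth(cfg, "chr1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.contact_region_length // cfg.bin_size
    mids = (np.arange(n) + 0.5) * cfg.bin_size
    d = np.abs(mids[:, None] - mids[None, :])
    base = cfg.contact_scale * (1.0 + d / cfg.contact_d0) ** (-cfg.contact_alpha)

    def _tad_mask(domains):
        mask = np.ones((n, n))
        for dom in domains:
            inside = (mids >= dom.start) & (mids < dom.end)
            mask[np.ix_(inside, inside)] = cfg.tad_factor
        return mask

    pi = int(truth.loop.anchor1.mid // cfg.bin_size)
    pj = int(truth.loop.anchor2.mid // cfg.bin_size)
    loop_mask = np.ones((n, n))
    loop_mask[pi - 1:pi + 2, pj - 1:pj + 2] = cfg.loop_factor
    loop_mask[pj - 1:pj + 2, pi - 1:pi + 2] = cfg.loop_factor

    mean_wt = base * _tad_mask([truth.tad_a, truth.tad_b]) * loop_mask
    merged = GenomicInterval(truth.tad_a.chrom, truth.tad_a.start, truth.tad_b.end)
    mean_ko = base * _tad_mask([merged])

    def _draw(mean):
        upper = rng.poisson(np.triu(mean))
        counts = upper + np.triu(upper, 1).T
        return ContactMatrix(region=truth.region, bin_size=cfg.bin_size,
                             counts=counts.astype(float))

    return _draw(mean_wt), _draw(mean_ko), truth


# ---------------------------------------------------------------------------
# convenience wrappers for the individual generation stages

def generate_genome_pair(config: SimConfig = SimConfig()):
    """(assembly_a, assembly_b, sequences_a, sequences_b, chains_ab)."""
    ds = generate_dataset(config)
    return ds.assembly_a, ds.assembly_b, ds.sequences_a, ds.sequences_b, ds.chains_ab


# ---------------------------------------------------------------------------
# validation and output

def _validate(ds: SyntheticDataset) -> None:
    """Ground-truth/emitted consistency: every planted anchor motif is
    the exact consensus at its recorded position and, when RE-derived,
    fully inside its repeat."""
    consensus = ds.pwm.consensus()
    w = ds.pwm.width
    for row in ds.site_truth.itertuples():
        seq = ds.sequences_a[row.chrom][row.motif_start:row.motif_end]
        expected = consensus if row.strand == "+" else reverse_complement(consensus)
        if seq != expected:
            raise AssertionError(f"planted motif mismatch at {row.chrom}:{row.motif_start}")
    from .attribution import RepeatIndex
    idx = RepeatIndex(ds.repeats_a)
    for row in ds.site_truth.itertuples():
        iv = GenomicInterval(row.chrom, row.motif_start, row.motif_end)
        best = max((min(iv.end, r.interval.end) - max(iv.start, r.interval.start)
                    for r in idx.query(iv)), default=0)
        if row.re_derived and best < w:
            raise AssertionError(f"RE-derived site {row.chrom}:{row.motif_start} "
                                 f"not fully inside a repeat (overlap {best})")
        if not row.re_derived and best >= 10:
            raise AssertionError(f"non-RE site {row.chrom}:{row.motif_start} "
                                 f"overlaps a repeat by {best} bp")


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Emit the dataset in the exact formats the readers consume, plus
    ground-truth TSVs and a manifest echoing the config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name) -> Path:
        paths[name] = out / name
        return paths[name]

    tio.write_fasta(ds.sequences_a, _p("speciesA.fa"))
    tio.write_fasta(ds.sequences_b, _p("speciesB.fa"))
    tio.write_chrom_sizes(ds.assembly_a, _p("speciesA.chrom.sizes"))
    tio.write_chrom_sizes(ds.assembly_b, _p("speciesB.chrom.sizes"))
    tio.write_bedpe_loops(ds.loops_a, _p("loops_A.bedpe"))
    tio.write_bedpe_loops(ds.loops_b, _p("loops_B.bedpe"))
    tio.write_chain(ds.chains_ab, _p("A_to_B.chain"))
    tio.write_chain(ds.chains_ba, _p("B_to_A.chain"))
    tio.write_repeatmasker_out(ds.repeats_a, _p("speciesA.rmsk.out"))
    tio.write_repeatmasker_out(ds.repeats_b, _p("speciesB.rmsk.out"))
    tio.write_chromhmm_bed(ds.chromhmm_a, _p("chromhmm_A.bed"))
    tio.write_narrowpeak(ds.ctcf_peaks_a, _p("ctcf_A.narrowPeak"))
    tio.write_narrowpeak(ds.ctcf_peaks_b, _p("ctcf_B.narrowPeak"))
    tio.write_narrowpeak(ds.p300_peaks_a, _p("p300_A.narrowPeak"))
    with open(_p("tad_boundaries_A.bed"), "w") as fh:
        for row in ds.boundaries_a.itertuples():
            fh.write(f"{row.chrom}\t{row.point}\t{row.point + 1}\t{row.boundary_id}\n")
    with open(_p("genehancer_pairs.tsv"), "w") as fh:
        fh.write("enh_chrom\tenh_start\tenh_end\tprom_chrom\tprom_start\tprom_end\n")
        for gh in ds.genehancer_pairs:
            fh.write(f"{gh.enhancer.chrom}\t{gh.enhancer.start}\t{gh.enhancer.end}\t"
                     f"{gh.promoter.chrom}\t{gh.promoter.start}\t{gh.promoter.end}\n")
    ds.loop_truth.to_csv(_p("truth_loops.tsv"), sep="\t", index=False)
    ds.site_truth.to_csv(_p("truth_sites.tsv"), sep="\t", index=False)
    ds.boundaries_a.to_csv(_p("truth_boundaries.tsv"), sep="\t", index=False)
    with open(_p("manifest.yaml"), "w") as fh:
        yaml.safe_dump({"config": dataclasses.asdict(ds.config),
                        "candidate_loop_id": ds.candidate_loop_id}, fh,
                       sort_keys=True)
    return paths
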