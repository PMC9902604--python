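"""Chain lifting and conservation calls: block-walk oracle agreement,
round-trip identity, the min(half-loop, 50 kb) rule, and cross-tables."""

import numpy as np
import pytest

from teanchor.core import ChainAlignment, ChainBlock, GenomicInterval, Loop
from teanchor.orthology import (
    ChainIndex,
    LiftResult,
    OrthologyLabel,
    cross_tabulate,
    lift_interval,
    loop_is_conserved,
    tad_boundary_is_conserved,
)
from teanchor.attribution import RepeatIndex, classify_ctcf_origin, classify_structure

from conftest import make_hit


def identity_chain(length=1_000_000, chrom="chr1"):
    return ChainAlignment("1", 1e6, chrom, length, "+", 0, length,
                          chrom, length, "+", 0, length, (ChainBlock(length),))


def two_block_chain():
    """Blocks [0,500) -> [0,500) and [600,1100) -> [500,1000): a 100 bp
    source gap."""
    return ChainAlignment("2", 1000.0, "chr1", 2000, "+", 0, 1100,
                          "chr1", 2000, "+", 0, 1000,
                          (ChainBlock(500, 100, 0), ChainBlock(500)))


def brute_force_lift(interval, chain):
    """Per-base walk, independent of the block arithmetic in the library."""
    mapped = []
    s, t = chain.source_start, chain.target_start
    for block in chain.blocks:
        for k in range(block.size):
            if interval.start <= s + k < interval.end:
                mapped.append(t + k)
        s += block.size + block.source_gap
        t += block.size + block.target_gap
    if not mapped:
        return 0, None
    if chain.target_strand == "-":
        mapped = [chain.target_size - 1 - m for m in mapped]
    return len(mapped), (min(mapped), max(mapped) + 1)


class TestLiftInterval:
    def test_identity(self):
        iv = GenomicInterval("chr1", 10_000, 11_000)
        res = lift_interval(iv, [identity_chain()])
        assert res.status == "mapped" and res.mapped_fraction == 1.0
        assert (res.target.start, res.target.end) == (iv.start, iv.end)

    def test_half_mapped_interval(self):
        # [100, 1100): 400 bases in block 1 + 500 in block 2 -> wait: use oracle
        iv = GenomicInterval("chr1", 0, 1000)
        chain = two_block_chain()
        res = lift_interval(iv, [chain])
        n, hull = brute_force_lift(iv, chain)
        assert res.status == "mapped"
        assert res.mapped_fraction == pytest.approx(n / 1000)
        assert (res.target.start, res.target.end) == hull

    def test_low_match_rate_unmapped(self):
        # 1,000 bp interval with only 50 mapped bases: 0.05 < 0.1
        chain = ChainAlignment("3", 10.0, "chr1", 10_000, "+", 0, 50,
                               "chr1", 10_000, "+", 0, 50, (ChainBlock(50),))
        res = lift_interval(GenomicInterval("chr1", 0, 1000), [chain])
        assert res.status == "unmapped_low_match"
        assert res.mapped_fraction == pytest.approx(0.05)

    @pytest.mark.parametrize("mapped_bases,status", [(100, "mapped"),
                                                     (99, "unmapped_low_match")])
    def test_min_match_boundary(self, mapped_bases, status):
        chain = ChainAlignment("4", 10.0, "chr1", 10_000, "+", 0, mapped_bases,
                               "chr1", 10_000, "+", 0, mapped_bases,
                               (ChainBlock(mapped_bases),))
        res = lift_interval(GenomicInterval("chr1", 0, 1000), [chain], min_match=0.1)
        assert res.status == status

    def test_no_chain(self):
        res = lift_interval(GenomicInterval("chr2", 0, 100), [identity_chain()])
        assert res.status == "unmapped_no_chain"

    def test_split_across_two_chains(self):
        c1 = ChainAlignment("a", 10.0, "chr1", 10_000, "+", 0, 400,
                            "chr1", 10_000, "+", 0, 400, (ChainBlock(400),))
        c2 = ChainAlignment("b", 9.0, "chr1", 10_000, "+", 600, 1000,
                            "chr2", 10_000, "+", 0, 400, (ChainBlock(400),))
        res = lift_interval(GenomicInterval("chr1", 0, 1000), [c1, c2])
        assert res.status == "split" and res.target is None

    def test_minus_strand_target(self):
        # target on '-': forward coordinates flip around target_size
        chain = ChainAlignment("m", 10.0, "chr1", 1000, "+", 100, 300,
                               "chrB", 1000, "-", 0, 200, (ChainBlock(200),))
        iv = GenomicInterval("chr1", 100, 150)
        res = lift_interval(iv, [chain])
        n, hull = brute_force_lift(iv, chain)
        assert res.status == "mapped"
        assert (res.target.start, res.target.end) == hull
        assert res.target.strand == "-"

    def test_matches_block_walk_oracle_on_random_chains(self, rng):
        """1,000 random interval/chain pairs vs the per-base oracle."""
        for _ in range(1000):
            n_blocks = int(rng.integers(1, 5))
            blocks = []
            for b in range(n_blocks):
                size = int(rng.integers(10, 200))
                if b == n_blocks - 1:
                    blocks.append(ChainBlock(size))
                else:
                    blocks.append(ChainBlock(size, int(rng.integers(0, 100)),
                                             int(rng.integers(0, 100))))
            s_span = sum(b.size + b.source_gap for b in blocks)
            t_span = sum(b.size + b.target_gap for b in blocks)
            s0 = int(rng.integers(0, 500))
            t0 = int(rng.integers(0, 500))
            strand = "-" if rng.random() < 0.3 else "+"
            chain = ChainAlignment("r", 10.0, "chr1", 5000, "+", s0, s0 + s_span,
                                   "chrB", 5000, strand, t0, t0 + t_span, tuple(blocks))
            lo = int(rng.integers(0, 4000))
            iv = GenomicInterval("chr1", lo, lo + int(rng.integers(1, 800)))
            res = lift_interval(iv, [chain], min_match=0.0)
            n, hull = brute_force_lift(iv, chain)
            if n == 0:
                assert res.status == "unmapped_no_chain"
            else:
                assert res.mapped_fraction == pytest.approx(n / iv.length)
                assert (res.target.start, res.target.end) == hull

    def test_round_trip_through_inverse(self, dataset):
        """Fully-mapped intervals lift to B and back to their source."""
        fwd = ChainIndex(dataset.chains_ab)
        back = ChainIndex(dataset.chains_ba)
        for loop in dataset.loops_a[:10]:
            res = lift_interval(loop.anchor2, fwd)   # anchor2 never hosts a deletion
            assert res.status == "mapped"
            if res.mapped_fraction == 1.0:
                home = lift_interval(res.target, back)
                assert (home.target.start, home.target.end) == (loop.anchor2.start,
                                                                loop.anchor2.end)


def mapped(iv):
    return LiftResult(iv, iv, 1.0, "mapped")


def shifted(iv, offset):
    return LiftResult(iv, iv.shifted(offset), 1.0, "mapped")


class TestLoopConservation:
    def _loop(self, start1, span, width=10_000, id="L"):
        return Loop(id, GenomicInterval("chr1", start1, start1 + width),
                    GenomicInterval("chr1", start1 + span, start1 + span + width))

    def test_60kb_loop_half_span_threshold(self):
        # span 70k => anchor1.start..anchor2.end = 80k; use span so that
        # loop.span/2 = 30k < 50k, lifted anchors 10k/25k away qualify
        src = self._loop(100_000, 50_000)          # span = 60 kb
        assert src.span == 60_000
        tgt = self._loop(100_000 + 10_000, 50_000 + 15_000, id="T")  # d1=10k, d2=25k
        label = loop_is_conserved(src, (mapped(src.anchor1), mapped(src.anchor2)), [tgt])
        assert label.label == "conserved" and label.matched_target_id == "T"

    def test_50kb_cap_on_large_loops(self):
        src = self._loop(100_000, 190_000)         # span = 200 kb => t = 50 kb
        tgt = self._loop(100_000 + 60_000, 190_000, id="T")   # both anchors 60 kb off
        label = loop_is_conserved(src, (mapped(src.anchor1), mapped(src.anchor2)), [tgt])
        assert label.label == "lineage_specific"

    @pytest.mark.parametrize("offset,expected", [
        (50_000, "conserved"), (50_001, "lineage_specific"),   # 200 kb loop, cap 50 kb
    ])
    def test_cap_boundary(self, offset, expected):
        src = self._loop(100_000, 190_000)
        tgt = self._loop(100_000 + offset, 190_000, id="T")
        label = loop_is_conserved(src, (mapped(src.anchor1), mapped(src.anchor2)), [tgt])
        assert label.label == expected

    @pytest.mark.parametrize("offset,expected", [
        (30_000, "conserved"), (30_001, "lineage_specific"),   # 60 kb loop, t = 30 kb
    ])
    def test_half_span_boundary(self, offset, expected):
        src = self._loop(100_000, 50_000)
        tgt = self._loop(100_000 + offset, 50_000, id="T")
        label = loop_is_conserved(src, (mapped(src.anchor1), mapped(src.anchor2)), [tgt])
        assert label.label == expected

    def test_identity_self_comparison_reflexive(self):
        loops = [self._loop(s, 60_000, id=f"L{s}") for s in (0, 200_000, 400_000)]
        for lp in loops:
            label = loop_is_conserved(lp, (mapped(lp.anchor1), mapped(lp.anchor2)), loops)
            assert label.label == "conserved"
            assert label.matched_target_id == lp.id and label.distance_bp == 0

    def test_unliftable_anchor(self):
        src = self._loop(100_000, 60_000)
        lifts = (LiftResult(src.anchor1, None, 0.0, "unmapped_no_chain"),
                 mapped(src.anchor2))
        assert loop_is_conserved(src, lifts, []).label == "unliftable"

    def test_conserved_set_monotone_in_cap(self, rng):
        """Growing the threshold never flips conserved to specific."""
        src_loops = [self._loop(int(s), int(sp), id=f"s{k}")
                     for k, (s, sp) in enumerate(zip(rng.integers(0, 500_000, 30),
                                                     rng.integers(30_000, 200_000, 30)))]
        tgt_loops = [self._loop(int(s), int(sp), id=f"t{k}")
                     for k, (s, sp) in enumerate(zip(rng.integers(0, 500_000, 30),
                                                     rng.integers(30_000, 200_000, 30)))]
        previous: set[str] = set()
        for cap in (10_000, 30_000, 50_000, 100_000):
            conserved = {lp.id for lp in src_loops
                         if loop_is_conserved(lp, (mapped(lp.anchor1), mapped(lp.anchor2)),
                                              tgt_loops, cap_bp=cap).label == "conserved"}
            assert previous <= conserved
            previous = conserved


class TestTadBoundaryConservation:
    MOTIF = GenomicInterval("chr1", 500_000, 500_019)

    @pytest.mark.parametrize("distance,expected", [
        (49_999, "conserved"), (50_000, "conserved"), (50_001, "lineage_specific")])
    def test_50kb_rule_boundary(self, distance, expected):
        target = GenomicInterval("chr1", 500_000 + distance, 500_019 + distance)
        label = tad_boundary_is_conserved("b", mapped(self.MOTIF), [target])
        assert label.label == expected

    def test_unliftable_excluded(self):
        lift = LiftResult(self.MOTIF, None, 0.05, "unmapped_low_match")
        assert tad_boundary_is_conserved("b", lift, [self.MOTIF]).label == "unliftable"

    def test_identity_self_comparison(self):
        assert tad_boundary_is_conserved("b", mapped(self.MOTIF),
                                         [self.MOTIF]).label == "conserved"


class TestCrossTabulate:
    @staticmethod
    def _cls(sid, te):
        from teanchor.core import RepeatFeature
        if te:
            rep = RepeatFeature(GenomicInterval("chr1", 990, 1300), "B2_Mm2", "B2", "SINE")
            site = classify_ctcf_origin(make_hit(start=1000), RepeatIndex([rep]))
            return classify_structure(sid, "loop", (site, None))
        site = classify_ctcf_origin(make_hit(start=1000), RepeatIndex([]))
        return classify_structure(sid, "loop", (site, site))   # non-RE-derived

    def test_hand_tally(self):
        # 10 loops, 4 lineage-specific of which 1 TE-derived
        cls = {f"l{i}": self._cls(f"l{i}", te=(i == 0)) for i in range(10)}
        orth = {f"l{i}": OrthologyLabel(f"l{i}", "lineage_specific" if i < 4 else "conserved")
                for i in range(10)}
        tab = cross_tabulate(cls, orth)
        assert tab.table.loc["TE_derived", "lineage_specific"] == 1
        assert tab.table.loc["non_TE", "lineage_specific"] == 3
        assert tab.percents.loc["TE_derived", "lineage_specific"] == pytest.approx(25.0)

    def test_percents_sum_to_100_per_column(self, pipeline_result):
        tab = cross_tabulate(pipeline_result.loop_classifications,
                             pipeline_result.loop_orthology)
        for col in tab.percents:
            if tab.table[col].sum() > 0:
                assert tab.percents[col].sum() == pytest.approx(100.0)

    def test_all_conserved_zero_specific_column(self):
        cls = {f"l{i}": self._cls(f"l{i}", te=True) for i in range(4)}
        orth = {f"l{i}": OrthologyLabel(f"l{i}", "conserved") for i in range(4)}
        tab = cross_tabulate(cls, orth)
        assert tab.table["lineage_specific"].sum() == 0

    def test_orphan_ids_rejected(self):
        cls = {"a": self._cls("a", te=True)}
        orth = {"b": OrthologyLabel("b", "conserved")}
        with pytest.raises(ValueError, match="a"):
            cross_tabulate(cls, orth)

    def test_synthetic_specific_te_fraction(self, pipeline_result):
        """The TE share of lineage-specific loops matches planted truth."""
        truth = pipeline_result.dataset.loop_truth
        tab = cross_tabulate(pipeline_result.loop_classifications,
                             pipeline_result.loop_orthology)
        expected = int((~truth.conserved & truth.re_derived).sum())
        assert tab.table.loc["TE_derived", "lineage_specific"] == expected
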