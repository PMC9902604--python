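"""Repeat-origin rules: the 10 bp overlap threshold, boundary
standardization, structure labels, taxonomy summaries, and the
placement-shuffle null."""

import numpy as np
import pytest

from teanchor.attribution import (
    RepeatIndex,
    classify_ctcf_origin,
    classify_structure,
    pooled_re_fraction,
    re_fraction,
    shuffle_null,
    standardize_tad_boundary,
    summarize_taxonomy,
)
from teanchor.core import GenomeAssembly, GenomicInterval, RepeatFeature, overlap_bp

from conftest import make_hit


def repeat(chrom="chr1", start=0, end=100, sub="L1MC1", fam="L1", cls="LINE"):
    return RepeatFeature(GenomicInterval(chrom, start, end), sub, fam, cls)


def site_for(start, repeats, chrom="chr1"):
    return classify_ctcf_origin(make_hit(chrom=chrom, start=start), RepeatIndex(repeats))


class TestTenBpRule:
    def test_overlap_14_is_re_derived(self):
        # 19 bp motif [1000,1019) vs repeat [1005,1200): overlap 14
        site = site_for(1000, [repeat(start=1005, end=1200)])
        assert site.origin == "RE_derived" and site.overlap_bp == 14

    @pytest.mark.parametrize("overlap,expected", [(9, "non_RE"), (10, "RE_derived"),
                                                  (11, "RE_derived")])
    def test_threshold_boundary(self, overlap, expected):
        # motif [1000,1019); repeat ends at 1000+overlap
        site = site_for(1000, [repeat(start=500, end=1000 + overlap)])
        assert site.origin == expected
        assert site.overlap_bp == overlap

    def test_maximal_overlap_repeat_attributed(self):
        l1 = repeat(start=1005, end=1200, sub="L1MC1", fam="L1", cls="LINE")
        alu = repeat(start=900, end=1005, sub="AluY", fam="Alu", cls="SINE")
        site = site_for(1000, [alu, l1])
        assert site.repeat == l1 and site.overlap_bp == 14

    def test_agrees_with_quadratic_oracle(self, rng):
        """1,000 random motif/repeat configurations vs a brute-force
        max-overlap oracle."""
        for _ in range(1000):
            m_start = int(rng.integers(0, 2000))
            hit = make_hit(start=m_start)
            reps = []
            for r in range(int(rng.integers(0, 6))):
                s = int(rng.integers(0, 2000))
                reps.append(repeat(start=s, end=s + int(rng.integers(5, 400)),
                                   sub=f"r{r}", fam="f", cls="LINE"))
            site = classify_ctcf_origin(hit, RepeatIndex(reps))
            best = max((overlap_bp(hit.interval, r.interval) for r in reps), default=0)
            assert site.overlap_bp == best
            assert (site.origin == "RE_derived") == (best >= 10)


class TestBoundaryStandardization:
    ASSEMBLY = GenomeAssembly("t", {"chr1": 200_000})

    def test_plus_minus_5kb(self):
        b = standardize_tad_boundary(100_000, "chr1", self.ASSEMBLY)
        assert (b.window.start, b.window.end) == (95_000, 105_000)

    def test_left_clip(self):
        b = standardize_tad_boundary(2_000, "chr1", self.ASSEMBLY)
        assert (b.window.start, b.window.end) == (0, 7_000)

    def test_right_clip(self):
        b = standardize_tad_boundary(199_000, "chr1", self.ASSEMBLY)
        assert (b.window.start, b.window.end) == (194_000, 200_000)

    def test_point_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            standardize_tad_boundary(300_000, "chr1", self.ASSEMBLY)


class TestStructureLabels:
    RE_SITE = site_for(1000, [repeat(start=990, end=1200)])
    NON_RE = site_for(5000, [])

    def test_one_re_anchor_suffices(self):
        cls = classify_structure("l1", "loop", (self.RE_SITE, None))
        assert cls.label == "RE_derived"

    def test_two_non_re_anchors(self):
        cls = classify_structure("l2", "loop", (self.NON_RE, self.NON_RE))
        assert cls.label == "non_RE_derived"

    def test_single_non_re_anchor_excluded(self):
        cls = classify_structure("l3", "loop", (self.NON_RE, None))
        assert cls.label == "excluded"

    def test_te_only_flag_tracks_repeat_class(self):
        simple = classify_ctcf_origin(
            make_hit(start=1000),
            RepeatIndex([repeat(start=990, end=1200, sub="(TA)n",
                                fam="Simple_repeat", cls="Simple_repeat")]))
        assert classify_structure("l", "loop", (simple, None)).te_only is False
        assert classify_structure("l", "loop", (self.RE_SITE, None)).te_only is True

    def test_denominator_accounting(self, pipeline_result):
        """RE + non-RE + excluded == total structures."""
        labels = [c.label for c in pipeline_result.loop_classifications.values()]
        total = len(pipeline_result.dataset.loops_a)
        assert (labels.count("RE_derived") + labels.count("non_RE_derived")
                + labels.count("excluded")) == total


class TestTaxonomySummary:
    @staticmethod
    def _cls(sites):
        return [classify_structure(f"s{i}", "loop", (s, None)) for i, s in enumerate(sites)]

    def test_hand_count(self):
        sites = [site_for(1000 * k, [repeat(start=1000 * k - 10, end=1000 * k + 200,
                                            sub="AluY", fam="Alu", cls="SINE")])
                 for k in range(1, 4)]
        sites.append(site_for(9000, [repeat(start=8990, end=9200, sub="MLT1H1",
                                            fam="ERVL-MaLR", cls="LTR")]))
        summ = summarize_taxonomy(self._cls(sites), "class")
        assert summ.as_dict() == {"SINE": (3, 75.0), "LTR": (1, 25.0)}

    def test_single_site_is_100_percent(self):
        summ = summarize_taxonomy(self._cls([site_for(1000, [repeat(start=990, end=1200)])]),
                                  "subfamily")
        assert summ.as_dict() == {"L1MC1": (1, 100.0)}

    def test_family_reaggregates_to_class(self, pipeline_result):
        classes = summarize_taxonomy(pipeline_result.loop_classifications.values(), "class")
        families = summarize_taxonomy(pipeline_result.loop_classifications.values(), "family")
        fam_to_class = {fam: cls for cls, fams in
                        __import__("teanchor.simulate", fromlist=["TE_TAXONOMY"]).TE_TAXONOMY.items()
                        for fam in fams}
        reagg = {}
        for fam, count, _ in families.rows:
            reagg[fam_to_class[fam]] = reagg.get(fam_to_class[fam], 0) + count
        assert reagg == {name: count for name, count, _ in classes.rows}

    def test_percents_sum_to_100(self, pipeline_result):
        for level in ("class", "family", "subfamily"):
            summ = summarize_taxonomy(pipeline_result.loop_classifications.values(), level)
            assert sum(pct for _, _, pct in summ.rows) == pytest.approx(100.0, abs=1e-6)


class TestReFraction:
    def test_simple_arithmetic(self):
        re_sites = [site_for(1000 * k, [repeat(start=1000 * k - 10, end=1000 * k + 300)])
                    for k in range(1, 4)]
        non = [site_for(100_000 + 1000 * k, []) for k in range(17)]
        pct, num, den = re_fraction(re_sites + non)
        assert (pct, num, den) == (15.0, 3, 20)

    def test_duplicate_motifs_counted_once(self):
        s = site_for(1000, [repeat(start=990, end=1300)])
        pct, num, den = re_fraction([s, s, site_for(50_000, [])])
        assert (num, den) == (1, 2)

    def test_pooling_is_sum_over_sum(self):
        sample1 = ([site_for(1000, [repeat(start=990, end=1300)])]
                   + [site_for(10_000 + 500 * k, []) for k in range(9)])
        sample2 = ([site_for(1000 * k, [repeat(start=1000 * k - 10, end=1000 * k + 300)])
                    for k in range(1, 4)]
                   + [site_for(200_000 + 500 * k, []) for k in range(7)])
        pct, num, den = pooled_re_fraction([sample1, sample2])
        assert (pct, num, den) == (20.0, 4, 20)   # 4/20, not mean(10%, 30%) = 20% anyway
        # distinguish from mean-of-percents with asymmetric sizes
        pct2, _, _ = pooled_re_fraction([sample1, sample2[:4]])
        assert pct2 == pytest.approx(100.0 * 4 / 14)

    def test_planted_fraction_recovered(self, pipeline_result):
        anchors = [s for c in pipeline_result.loop_classifications.values()
                   for s in c.sites if s is not None]
        pct, num, den = re_fraction(anchors)
        truth = pipeline_result.dataset.site_truth
        assert num == int(truth.re_derived.sum())
        assert den == len(truth)
        assert pct == pytest.approx(100.0 * truth.re_derived.mean())


class TestShuffleNull:
    ASSEMBLY = GenomeAssembly("t", {"chr1": 1_000_000})

    def _sites(self, n, repeats):
        idx = RepeatIndex(repeats)
        return [classify_ctcf_origin(make_hit(start=1000 + 777 * k), idx)
                for k in range(n)]

    def test_full_coverage_always_re(self):
        reps = [repeat(start=0, end=1_000_000)]
        res = shuffle_null(self._sites(20, reps), RepeatIndex(reps), self.ASSEMBLY,
                           n_shuffles=100, seed=1)
        assert np.all(res.null == 1.0)

    def test_seed_reproducibility(self):
        reps = [repeat(start=s, end=s + 500) for s in range(0, 1_000_000, 2_000)]
        idx = RepeatIndex(reps)
        a = shuffle_null(self._sites(10, reps), idx, self.ASSEMBLY, 200, seed=3)
        b = shuffle_null(self._sites(10, reps), idx, self.ASSEMBLY, 200, seed=3)
        assert np.array_equal(a.null, b.null)

    def test_tiled_repeats_match_enumeration(self):
        """Repeats tile 50% of a 1 Mb chromosome in 500 bp blocks; the
        null mean must match the exact placement probability computed by
        enumerating all motif offsets within one 1 kb period."""
        reps = [repeat(start=s, end=s + 500) for s in range(0, 1_000_000, 1_000)]
        idx = RepeatIndex(reps)
        width = 19
        hits = 0
        for u in range(1000):
            iv = GenomicInterval("chr1", 5_000 + u, 5_000 + u + width)
            best = max((overlap_bp(iv, r.interval) for r in idx.query(iv)), default=0)
            hits += best >= 10
        p_exact = hits / 1000
        res = shuffle_null(self._sites(50, reps), idx, self.ASSEMBLY,
                           n_shuffles=1000, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 50 / 1000)
        assert abs(res.null_mean - p_exact) < 3 * se + 1e-3

    def test_motif_longer_than_chromosome_rejected(self):
        tiny = GenomeAssembly("t", {"chr1": 10})
        reps = [repeat(start=0, end=10)]
        with pytest.raises(ValueError):
            shuffle_null(self._sites(1, reps), RepeatIndex(reps), tiny, 100, seed=0)
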