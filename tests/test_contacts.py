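"""Contact-matrix numerics: balancing, O/E, long-range fractions,
virtual 4C, focal enrichment, and text dialect round-trips."""

import numpy as np
import pytest

from teanchor.core import GenomicInterval, Loop
from teanchor.contacts import (
    ContactMatrix,
    KrConvergenceError,
    expected_by_distance,
    focal_enrichment,
    kr_balance,
    long_range_fraction,
    oe_transform,
    read_coo_text,
    read_dense_tsv,
    virtual_4c,
    write_coo_text,
    write_dense_tsv,
)


def matrix(counts, bin_size=10_000, chrom="chr1"):
    counts = np.asarray(counts, dtype=float)
    region = GenomicInterval(chrom, 0, counts.shape[0] * bin_size)
    return ContactMatrix(region=region, bin_size=bin_size, counts=counts)


def random_symmetric(rng, n, density=1.0):
    a = rng.random((n, n)) + 0.1
    return (a + a.T) / 2


class TestKrBalance:
    def test_2x2_closed_form(self):
        # For [[a,b],[b,c]], equal row sums need d1/d2 = sqrt(c/a)
        m = matrix([[2.0, 1.0], [1.0, 3.0]])
        balanced, d = kr_balance(m, tol=1e-12)
        assert d[0] / d[1] == pytest.approx(np.sqrt(3.0 / 2.0), abs=1e-8)
        rows = balanced.counts.sum(axis=1)
        assert rows[0] == pytest.approx(rows[1], abs=1e-8)

    def test_already_balanced_gives_constant_scaling(self):
        m = matrix([[1.0, 2.0], [2.0, 1.0]])      # row sums already equal
        _, d = kr_balance(m, tol=1e-12)
        assert d[0] == pytest.approx(d[1], rel=1e-9)

    def test_zero_row_masked(self):
        m = matrix([[2.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 2.0]])
        balanced, d = kr_balance(m)
        assert d[1] == 0.0
        assert np.all(balanced.counts[1] == 0)
        rows = balanced.counts[[0, 2]].sum(axis=1)
        assert rows[0] == pytest.approx(rows[1], rel=1e-6)

    def test_row_sum_cv_below_tolerance(self, rng):
        m = matrix(random_symmetric(rng, 200))
        balanced, _ = kr_balance(m, tol=1e-8)
        rows = balanced.counts.sum(axis=1)
        assert rows.std() / rows.mean() < 1e-6

    def test_output_symmetric_and_mass_scale_preserved(self, rng):
        m = matrix(random_symmetric(rng, 50))
        balanced, _ = kr_balance(m, tol=1e-10)
        assert np.allclose(balanced.counts, balanced.counts.T)
        assert balanced.counts.sum(axis=1).mean() == pytest.approx(
            m.counts.sum(axis=1).mean(), rel=1e-6)

    def test_nonconvergence_reports_residual(self):
        m = matrix([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(KrConvergenceError) as err:
            kr_balance(m, tol=0.0, max_iter=3)
        assert err.value.residual >= 0


class TestExpectedAndOE:
    def test_constant_matrix_oe_is_one(self):
        m = matrix(np.full((6, 6), 3.5))
        assert np.allclose(oe_transform(m).counts, 1.0)

    def test_expected_matches_diagonal_mean_oracle(self, rng):
        m = matrix(random_symmetric(rng, 15))
        exp = expected_by_distance(m)
        for d in range(15):
            vals = [m.counts[i, i + d] for i in range(15 - d)]
            assert exp[d] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_oe_idempotent(self, rng):
        m = matrix(random_symmetric(rng, 12))
        once = oe_transform(m)
        twice = oe_transform(once)
        assert np.allclose(once.counts, twice.counts, atol=1e-12)

    def test_zero_diagonal_stays_zero(self):
        counts = np.ones((4, 4))
        counts[range(4), range(4)] = 0.0
        oe = oe_transform(matrix(counts))
        assert np.all(oe.counts.diagonal() == 0)


class TestLongRangeFraction:
    def test_matches_pair_enumeration_oracle(self, rng):
        raw = rng.integers(0, 20, size=(8, 8)) * 1.0
        m = matrix(np.triu(raw) + np.triu(raw, 1).T, bin_size=10_000)
        roi = GenomicInterval("chr1", 0, 80_000)
        pa = GenomicInterval("chr1", 0, 40_000)
        pb = GenomicInterval("chr1", 40_000, 80_000)
        rep = long_range_fraction(m, roi, pa, pb, min_distance=30_000)
        denom = intra = inter = 0.0
        for i in range(8):
            for j in range(i, 8):
                if (j - i) * 10_000 <= 30_000:
                    continue
                denom += m.counts[i, j]
                if i < 4 and j < 4:
                    intra += m.counts[i, j]
                if (i < 4) != (j < 4):
                    inter += m.counts[i, j]
        assert rep.intra_a_pct == pytest.approx(100 * intra / denom)
        assert rep.inter_ab_pct == pytest.approx(100 * inter / denom)

    def test_no_long_range_mass_flagged(self):
        counts = np.zeros((8, 8))
        counts[0, 1] = counts[1, 0] = 5.0       # 10 kb apart only
        rep = long_range_fraction(matrix(counts), GenomicInterval("chr1", 0, 80_000),
                                  GenomicInterval("chr1", 0, 40_000),
                                  GenomicInterval("chr1", 40_000, 80_000))
        assert not rep.defined and np.isnan(rep.intra_a_pct)

    def test_invariant_to_global_rescaling(self, rng):
        m = matrix(random_symmetric(rng, 12), bin_size=10_000)
        roi = GenomicInterval("chr1", 0, 120_000)
        pa = GenomicInterval("chr1", 0, 60_000)
        pb = GenomicInterval("chr1", 60_000, 120_000)
        a = long_range_fraction(m, roi, pa, pb)
        scaled = matrix(m.counts * 7.3, bin_size=10_000)
        b = long_range_fraction(scaled, roi, pa, pb)
        assert a.intra_a_pct == pytest.approx(b.intra_a_pct)
        assert a.inter_ab_pct == pytest.approx(b.inter_ab_pct)


class TestVirtual4c:
    def test_single_bin_anchor_equals_row(self, rng):
        m = matrix(random_symmetric(rng, 10))
        profile = virtual_4c(m, GenomicInterval("chr1", 30_000, 40_000))
        assert np.array_equal(profile, m.counts[3])

    def test_two_bin_anchor_is_row_mean(self, rng):
        m = matrix(random_symmetric(rng, 10))
        profile = virtual_4c(m, GenomicInterval("chr1", 30_000, 50_000))
        assert np.allclose(profile, m.counts[3:5].mean(axis=0))

    def test_smoothing_preserves_interior_mass(self, rng):
        m = matrix(random_symmetric(rng, 40))
        raw = virtual_4c(m, GenomicInterval("chr1", 200_000, 210_000))
        smooth = virtual_4c(m, GenomicInterval("chr1", 200_000, 210_000), smooth_bins=2)
        # away from the edges the moving average redistributes but keeps mass
        assert smooth[5:-5].sum() == pytest.approx(raw[5:-5].sum(), rel=0.05)
        assert smooth.sum() <= raw.sum() + 1e-9

    def test_anchor_outside_region_rejected(self, rng):
        m = matrix(random_symmetric(rng, 10))
        with pytest.raises(ValueError):
            virtual_4c(m, GenomicInterval("chr1", 95_000, 105_000))


class TestFocalEnrichment:
    def test_uniform_matrix_ratio_one(self):
        m = matrix(np.full((30, 30), 5.0))
        loop = Loop("l", GenomicInterval("chr1", 95_000, 105_000),
                    GenomicInterval("chr1", 195_000, 205_000))
        assert focal_enrichment(m, loop) == pytest.approx(1.0)

    def test_edge_pixel_rejected(self):
        m = matrix(np.full((30, 30), 5.0))
        loop = Loop("l", GenomicInterval("chr1", 5_000, 15_000),
                    GenomicInterval("chr1", 195_000, 205_000))
        with pytest.raises(ValueError):
            focal_enrichment(m, loop)


class TestTextDialects:
    def test_dense_round_trip(self, tmp_path, rng):
        m = matrix(np.round(random_symmetric(rng, 12), 6))
        p = tmp_path / "m.tsv"
        write_dense_tsv(m, p)
        back = read_dense_tsv(p)
        assert back.region == m.region and back.bin_size == m.bin_size
        assert np.allclose(back.counts, m.counts)

    def test_coo_round_trip(self, tmp_path, rng):
        counts = np.round(random_symmetric(rng, 9), 4)
        counts[counts < 0.3] = 0.0
        m = matrix((counts + counts.T) / 2)
        p = tmp_path / "m.coo"
        write_coo_text(m, p)
        back = read_coo_text(p)
        assert np.allclose(back.counts, m.counts)
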