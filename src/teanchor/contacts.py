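"""Binned contact-matrix computations used for validation.

Covers Knight-Ruiz-style diagonal balancing, expected-by-distance and
observed/expected transforms, long-range (>30 kb) intra/inter-domain
interaction percentages, virtual 4C profiles, and a simplified focal
enrichment score for loop pixels (full HiCCUPS-style calling is out of
scope; loop lists are inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import GenomicInterval, Loop

DEFAULT_MIN_LONG_RANGE_BP = 30_000

__all__ = ["ContactMatrix", "InteractionFractionReport", "kr_balance",
           "expected_by_distance", "oe_transform", "long_range_fraction",
           "virtual_4c", "focal_enrichment", "read_dense_tsv", "write_dense_tsv",
           "read_coo_text", "write_coo_text"]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts over one genomic region."""

    region: GenomicInterval
    bin_size: int
    counts: np.ndarray
    normalization: str = "raw"       # raw | KR | OE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n}) "
                             f"for region {self.region} at {self.bin_size} bp bins")
        if not np.allclose(self.counts, self.counts.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("contact counts must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return -(-self.region.length // self.bin_size)

    def bin_of(self, position: float) -> int:
        """Bin index of a genomic position inside the region."""
        if not (self.region.start <= position < self.region.end):
            raise ValueError(f"position {position} outside region {self.region}")
        return int((position - self.region.start) // self.bin_size)

    def bin_midpoints(self) -> np.ndarray:
        return self.region.start + (np.arange(self.n_bins) + 0.5) * self.bin_size


# ---------------------------------------------------------------------------
# text dialects (juicer dump emits COO text)

def write_dense_tsv(matrix: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# region={matrix.region}\tbin_size={matrix.bin_size}\t"
                 f"normalization={matrix.normalization}\n")
        np.savetxt(fh, matrix.counts, delimiter="\t", fmt="%.10g")


def read_dense_tsv(path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(part.split("=", 1) for part in header.lstrip("# ").split("\t"))
        chrom, span = meta["region"].split(":")
        start, end = map(int, span.split("-"))
        counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ContactMatrix(region=GenomicInterval(chrom, start, end),
                         bin_size=int(meta["bin_size"]), counts=counts,
                         normalization=meta.get("normalization", "raw"))


def write_coo_text(matrix: ContactMatrix, path) -> None:
    """3-column upper-triangle COO: bin1_start <TAB> bin2_start <TAB> count."""
    with open(path, "w") as fh:
        fh.write(f"# region={matrix.region}\tbin_size={matrix.bin_size}\t"
                 f"normalization={matrix.normalization}\n")
        n = matrix.n_bins
        for i in range(n):
            for j in range(i, n):
                c = matrix.counts[i, j]
                if c != 0:
                    fh.write(f"{matrix.region.start + i * matrix.bin_size}\t"
                             f"{matrix.region.start + j * matrix.bin_size}\t{c:.10g}\n")


def read_coo_text(path, region: Optional[GenomicInterval] = None,
                  bin_size: Optional[int] = None) -> ContactMatrix:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta = dict(part.split("=", 1) for part in line.lstrip("# ").split("\t"))
                continue
            b1, b2, c = line.split("\t")
            rows.append((int(b1), int(b2), float(c)))
    if region is None:
        chrom, span = meta["region"].split(":")
        start, end = map(int, span.split("-"))
        region = GenomicInterval(chrom, start, end)
    if bin_size is None:
        bin_size = int(meta["bin_size"])
    n = -(-region.length // bin_size)
    counts = np.zeros((n, n))
    for b1, b2, c in rows:
        i = (b1 - region.start) // bin_size
        j = (b2 - region.start) // bin_size
        counts[i, j] = c
        counts[j, i] = c
    return ContactMatrix(region=region, bin_size=bin_size, counts=counts,
                         normalization=meta.get("normalization", "raw"))


# ---------------------------------------------------------------------------
# balancing and O/E

class KrConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(f"balancing did not converge within {max_iter} iterations "
                         f"(residual {residual:.3e})")
        self.residual = residual


def kr_balance(matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 10_000
               ) -> tuple[ContactMatrix, np.ndarray]:
    """Diagonal balancing B = D A D with equal unmasked row sums.

    All-zero rows are masked (their scaling is 0 and they stay zero);
    unmasked row sums converge to the mean raw unmasked row sum, so the
    total contact mass scale is preserved.  Deterministic fixed-point
    iteration; raises :class:`KrConvergenceError` carrying the residual
    when the tolerance is not reached.
    """
    A = matrix.counts
    mask = A.sum(axis=1) > 0
    scaling = np.zeros(A.shape[0])
    if not mask.any():
        return replace(matrix, counts=A.copy(), normalization="KR"), scaling
    sub = A[np.ix_(mask, mask)]
    target = sub.sum(axis=1).mean()
    d = np.ones(sub.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        row = d * (sub @ d)          # current row sums of D A D
        residual = float(np.abs(row / target - 1.0).max())
        if residual < tol:
            break
        d = d / np.sqrt(row / target)
    else:
        raise KrConvergenceError(residual, max_iter)
    balanced = np.zeros_like(A)
    balanced[np.ix_(mask, mask)] = sub * np.outer(d, d)
    balanced = (balanced + balanced.T) / 2   # kill last-ulp asymmetry
    scaling[mask] = d
    return replace(matrix, counts=balanced, normalization="KR"), scaling


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """expected[d] = mean count over all bin pairs at bin-distance d."""
    A = matrix.counts
    n = A.shape[0]
    return np.array([A.diagonal(d).mean() for d in range(n)])


def oe_transform(matrix: ContactMatrix) -> ContactMatrix:
    """Observed/expected matrix; 0/0 -> 0."""
    A = matrix.counts
    n = A.shape[0]
    expected = expected_by_distance(matrix)
    i, j = np.indices(A.shape)
    e = expected[np.abs(i - j)]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(e > 0, A / np.where(e > 0, e, 1.0), 0.0)
    return replace(matrix, counts=oe, normalization="OE")


# ---------------------------------------------------------------------------
# long-range interaction fractions

@dataclass
class InteractionFractionReport:
    region_of_interest: GenomicInterval
    partition_a: GenomicInterval
    partition_b: GenomicInterval
    intra_a_pct: float
    inter_ab_pct: float
    min_distance: int
    denominator_mass: float
    defined: bool
    notes: tuple[str, ...] = ()


def _bins_in(matrix: ContactMatrix, interval: GenomicInterval) -> np.ndarray:
    """Boolean bin mask: a bin belongs to an interval iff its midpoint
    lies inside it."""
    mids = matrix.bin_midpoints()
    return (mids >= interval.start) & (mids < interval.end)


def long_range_fraction(matrix: ContactMatrix, region_of_interest: GenomicInterval,
                        partition_a: GenomicInterval, partition_b: GenomicInterval,
                        min_distance: int = DEFAULT_MIN_LONG_RANGE_BP,
                        notes: tuple[str, ...] = ()) -> InteractionFractionReport:
    """Percentages of long-range contact mass inside partition A and
    between partitions A and B.

    Denominator: total mass over upper-triangle bin pairs with genomic
    distance > ``min_distance`` and both bins inside the region of
    interest.  Invariant to global rescaling of the matrix.
    """
    n = matrix.n_bins
    in_roi = _bins_in(matrix, region_of_interest)
    in_a = _bins_in(matrix, partition_a)
    in_b = _bins_in(matrix, partition_b)
    i, j = np.triu_indices(n)
    dist = (j - i) * matrix.bin_size
    long_pairs = (dist > min_distance) & in_roi[i] & in_roi[j]
    mass = matrix.counts[i, j]
    denom = mass[long_pairs].sum()
    if denom <= 0:
        return InteractionFractionReport(
            region_of_interest, partition_a, partition_b,
            intra_a_pct=float("nan"), inter_ab_pct=float("nan"),
            min_distance=min_distance, denominator_mass=0.0, defined=False,
            notes=notes + ("no long-range contact mass in region of interest",))
    intra_a = mass[long_pairs & in_a[i] & in_a[j]].sum()
    inter_ab = mass[long_pairs & ((in_a[i] & in_b[j]) | (in_b[i] & in_a[j]))].sum()
    return InteractionFractionReport(
        region_of_interest, partition_a, partition_b,
        intra_a_pct=100.0 * intra_a / denom, inter_ab_pct=100.0 * inter_ab / denom,
        min_distance=min_distance, denominator_mass=float(denom), defined=True,
        notes=notes)


# ---------------------------------------------------------------------------
# virtual 4C and focal enrichment

def virtual_4c(matrix: ContactMatrix, anchor_interval: GenomicInterval,
               smooth_bins: int = 0) -> np.ndarray:
    """Per-bin contact profile anchored at the anchor's bin(s): the mean
    of the anchor bins' rows, optionally smoothed with a centered moving
    average of width 2*smooth_bins+1 (mass-preserving in the interior)."""
    if not (matrix.region.start <= anchor_interval.start
            and anchor_interval.end <= matrix.region.end):
        raise ValueError(f"anchor {anchor_interval} outside matrix region {matrix.region}")
    lo = matrix.bin_of(anchor_interval.start)
    hi = matrix.bin_of(anchor_interval.end - 1)
    profile = matrix.counts[lo:hi + 1].mean(axis=0)
    if smooth_bins > 0:
        w = 2 * smooth_bins + 1
        profile = np.convolve(profile, np.ones(w) / w, mode="same")
    return profile


def focal_enrichment(matrix: ContactMatrix, loop: Loop, peak_radius_bins: int = 1,
                     donut_radius_bins: int = 5) -> float:
    """Observed/expected-local ratio at the loop pixel.

    Computed on O/E values: mean over the (2r+1)^2 peak neighbourhood
    divided by the mean over the surrounding square annulus.  Raises
    when the pixel sits within ``donut_radius_bins`` of the matrix edge.
    """
    oe = matrix if matrix.normalization == "OE" else oe_transform(matrix)
    i = matrix.bin_of(loop.anchor1.mid)
    j = matrix.bin_of(loop.anchor2.mid)
    n = matrix.n_bins
    r, R = peak_radius_bins, donut_radius_bins
    if R <= r:
        raise ValueError("donut radius must exceed peak radius")
    if i - R < 0 or j - R < 0 or i + R >= n or j + R >= n:
        raise ValueError(f"loop pixel ({i},{j}) within {R} bins of the matrix edge")
    peak = oe.counts[i - r:i + r + 1, j - r:j + r + 1]
    donut = oe.counts[i - R:i + R + 1, j - R:j + R + 1]
    donut_sum = donut.sum() - peak.sum()
    donut_n = donut.size - peak.size
    donut_mean = donut_sum / donut_n
    if donut_mean <= 0:
        return float("inf") if peak.mean() > 0 else float("nan")
    return float(peak.mean() / donut_mean)
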