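# Methods

This note documents the models, rules and numerical choices behind
`teanchor`, what the synthetic data generator does and does not
emulate, and the design decisions taken where the procedure was
genuinely open.

## Coordinate model

All intervals are 0-based, half-open, on named chromosomes of an
assembly. Conversions happen only at parser boundaries: RepeatMasker
`.out` query coordinates (1-based inclusive) are shifted on read, and
UCSC chain target coordinates on the '-' strand are flipped around the
chromosome length when a lifted interval is materialized. Chromosome
names are matched exactly — no "chr" prefix munging — because silent
renaming corrupts cross-species joins; callers needing aliases rename
explicitly before loading.

## Anchor CTCF assignment

Each loop anchor or boundary window receives at most one CTCF site: the
PWM hit (both strands, log-odds bits against a uniform background,
`score = Σ_i log2((p_i(b)+pc·bg(b))/((1+pc)·bg(b)))`, N scoring 0) with
the highest score among hits overlapping a CTCF ChIP peak by ≥ 1 bp,
ties broken toward the smaller start. The scan threshold defaults to
60% of the matrix's maximum attainable bits — deliberately permissive,
because the ChIP gate supplies the specificity. The bundled
19-position matrix (`data/ctcf19_synthetic.jaspar`) is a synthetic
CTCF-like matrix built around a fixed consensus, not a database entry;
any JASPAR-format matrix can replace it (`Pwm.from_jaspar`). The PWM
pseudocount defaults to 0.001 and only matters for zero-count columns.

## Repeat origin

A site is RE-derived iff its maximal single-repeat overlap is ≥ 10 bp.
When two repeats both clear 10 bp the larger overlap wins (smaller
start on ties) — a deterministic maximal-evidence rule. "RE" includes
simple and low-complexity repeats; TE-restricted summaries use a
configurable class set (SINE/LINE/LTR/DNA plus their "?" variants, RC,
Retroposon). Structure labels: RE-derived with ≥ 1 RE-derived side;
non-RE-derived when both sides carry sites and none is RE-derived;
excluded otherwise, and excluded structures never enter denominators.
Summaries count unique sites de-duplicated on motif coordinates, so a
site shared by several loops counts once; pooling across same-condition
samples is sum-of-numerators over sum-of-denominators, never a mean of
percents. TAD borders are standardized to ±5 kb windows (clipped at
chromosome edges) before site assignment.

The random-expectation null re-places each motif-length interval
uniformly on its own chromosome and re-applies the ≥ 10 bp rule,
preserving per-chromosome repeat density; the p-value is the empirical
two-sided tail with the +1 correction. The null's construction is a
design choice (the placement scheme is not externally specified);
chromosome-preserving placement was chosen because repeat content
varies strongly between chromosomes.

## Orthology

Lifting walks the best-scoring chain overlapping the interval;
`mapped_fraction` is the fraction of source bases inside aligned
blocks, and the target is the [min, max) hull of their images
(strand-aware). An interval with mapped bases in more than one chain is
a *split* and treated as unmapped, matching liftOver's default
behaviour. The minimum match rate defaults to 0.1.

Loop conservation uses threshold t = min(½·span, 50 kb), applied
per anchor (both lifted anchor midpoints must fall within t of the
target pair's anchor midpoints, pairing preserved after genome-ordering
both loops). Midpoints were chosen as the reference points because they
are robust to differing anchor resolutions; per-anchor application of
the cap is an interpretation — the alternative (a joint cap on the
pair) is strictly looser. The nearest qualifying target by
max(anchor distance) is recorded. Boundary conservation lifts every
ChIP-supported CTCF motif in the 40 kb boundary region and calls the
boundary conserved when any lifted motif lands within 50 kb of a target
boundary motif. Unliftable structures are excluded from conservation
denominators.

## Function and candidate selection

Function attribution is symmetric in the anchors; distances are
measured from anchor interval edges (overlap = 0), the conservative
reading given that anchors are pixels rather than points. When both an
enhancer and a repressor qualify opposite a promoter, the loop is
labelled enhancer-promoter and flagged — the two outcomes are reported
as disjoint without a stated precedence, so the conflict is kept
auditable rather than silently resolved. E-P strength subclasses use a
configurable map (EnhA1/EnhA2 strong, Enh/EnhG weak; TssA active,
TssAFlnk weak); the strongest qualifying state on each side wins.
Reports expose both the combined functional count (E-P + repressive)
and the split, since downstream uses differ on which they need.

Candidate filters run in a fixed order (lineage-specific RE-derived
anchor; functional annotation; ≤ 1 active CTCF peak within 15 kb of the
candidate anchor; no p300 overlap on the candidate motif), each
rejection recording the filter that fired, so audit counts telescope.
"Active CTCF site" means a peak in the supplied CTCF peak file.
GeneHancer-style enhancer-promoter pairs only affect ranking
(supported-first, then motif score); their absence never excludes.

## Contact matrices

Balancing is a symmetric diagonal fixed-point iteration
(d ← d / √(rowsum(DAD)/target)) — the same B = DAD objective as
Knight–Ruiz, chosen for determinism and simplicity at these matrix
sizes. All-zero rows are masked and stay zero; converged unmasked row
sums equal the mean raw unmasked row sum, preserving the overall mass
scale; tolerance 1e-6 on the max relative row-sum deviation,
non-convergence raises with the residual. Expected-by-distance is the
per-diagonal mean within the matrix region; O/E divides by it with
0/0 → 0 (idempotent by construction).

Long-range interaction percentages count upper-triangle bin pairs with
genomic distance > 30 kb and both bin midpoints inside the region of
interest; the intra percentage takes pairs inside partition A, the
inter percentage pairs straddling A and B. Midpoint bin membership is
unambiguous for partitions not aligned to bin edges; distance between
bins is |i−j|·bin size. Percentages are computed on raw counts by
default (normalization is a caller choice) and are invariant to global
rescaling. Virtual 4C is the mean of the anchor bins' rows, optionally
smoothed by a centered moving average (mass-preserving away from
edges). Focal enrichment is the mean O/E over the (2r+1)² pixel
neighbourhood divided by the surrounding square annulus (r = 1, R = 5
by default); it is a simplified validation score, not a loop caller.
One stated ambiguity is surfaced in report headers: the long-range
region of interest is taken from the explicit coordinates rather than
the looser "domain start to chromosome end" phrasing.

## Synthetic data

The generator's defaults are the study conditions the tests assert:
2 chromosomes × 3 Mb per species, 5 kb bins, 200 TEs per species,
60 loops on a 100 kb slot grid, 12 TAD boundaries, 30% of anchor CTCF
sites RE-derived, 50% of structures lineage-specific, 40%
enhancer-promoter and 10% repressive loops, and a contact model
mean(i,j) = 100·(1+d/50 kb)^(−1) with domain factor 3 and loop-pixel
factor 4 under Poisson noise. Three megabases per chromosome (rather
than a smaller genome) is what guarantees the slot grid keeps distinct
loops more than 50 kb apart, so the conservation cap can never match a
loop to a neighbour's twin and planted fractions are recovered exactly;
the whole pipeline still runs in about two seconds.

Species B derives from A by seeded block insertions and deletions; the
chain file describes the correspondence exactly, and conserved
structures are re-planted at chain-lifted coordinates, so conservation
recovery is exact by construction. Lineage-specific loop-anchor TEs sit
in blocks deleted from B (the anchor still lifts at ≥ 0.88 of its
bases, well above the 0.1 threshold, so such loops are called
lineage-specific rather than unliftable). Background sequence is i.i.d.
uniform and planted motifs are exact consensus, isolating downstream
label logic from scanner sensitivity. One loop is engineered to pass
all candidate filters; every other filter-passing loop receives a decoy
CTCF peak inside its 15 kb exclusion window, so the expected candidate
list has length one.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: TE sequence decay and subfamily
phylogeny (motifs in real TEs are degenerate, so real scan recall is
< 1), GC/mappability structure, polymer-physics contact features
(stripes, compartments), peak-calling noise in ChIP inputs, split or
partially syntenic chains beyond simple indels, and any relationship
between the planted fractions and the fractions reported for real
genomes. Recovery tests validate the *logic* of the rules, not their
field performance.

## Determinism and degenerate inputs

Every stochastic step takes a seed; the same config yields a
byte-identical emitted file tree. Empty denominators (no CTCF sites, no
long-range mass) return NaN with a flag or warning rather than raising.
Readers fail with file/line context on malformed rows and name unknown
chromosomes. Chain parsing verifies declared spans against the block
walk. Inversion of minus-strand chains is not implemented (the
generator emits only +/+ chains); minus-strand *lifting* is implemented
and oracle-tested.

## Problem sizes

Default test and acceptance runs use the 2 × 3 Mb dataset
(60 loops / 120 anchors / 12 boundaries), 120-bin contact matrices, 100
WT/KO map pairs for the direction test, and 1,000 randomized instances
per brute-force oracle comparison — sizes chosen so the full suite
completes in well under a minute while keeping every estimate's Monte
Carlo error far below the asserted margins.
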