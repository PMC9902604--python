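# teanchor

Transposable elements (TEs) carry sequences that resemble CTCF binding
motifs, and when a TE insertion deposits a functional CTCF site it can
anchor a new chromatin loop or insulate a new TAD boundary. `teanchor`
is a Python library for quantifying that process: it classifies the
CTCF sites under loop anchors and TAD boundaries by repeat origin,
labels the structures as conserved or lineage-specific across species,
attributes regulatory function (enhancer–promoter vs polycomb-
repressive) to loops from ChromHMM segmentations, ranks candidate
TE-derived anchors for deletion experiments, and measures what removing
an anchor does to a binned Hi-C contact map. It is aimed at
comparative/regulatory genomicists working with loop calls (BEDPE), TAD
calls, RepeatMasker annotations, narrowPeak ChIP files, UCSC chains and
text-format contact matrices.

A first-class synthetic-data module generates a complete two-species
dataset — genomes related by an exact block-wise chain, planted TEs and
CTCF motifs, loops, boundaries, ChromHMM tracks, ChIP peaks, and
Poisson contact maps — with full ground truth, so every stage is
testable offline.

## The rules at the core

* **Repeat origin.** Each anchor is assigned at most one CTCF site: the
  highest-scoring PWM hit overlapping a CTCF ChIP peak. A site is
  *RE-derived* iff its motif overlaps a repetitive element by ≥ 10 bp.
  A loop is RE-derived with ≥ 1 RE-derived anchor site, non-RE-derived
  when both anchors carry CTCF sites and none is RE-derived, excluded
  otherwise. TAD borders are standardized to ±5 kb windows.
* **Orthology.** Anchors are lifted through UCSC chains with a minimum
  match rate of 0.1 (fraction of source bases mapped). A loop is
  *conserved* when both lifted anchors fall within
  t = min(½·loop span, 50 kb) of a target loop's anchor pair; a lifted
  boundary CTCF motif is conserved within 50 kb of a target boundary
  motif.
* **Function.** A loop is *enhancer–promoter* when a promoter state
  (TssA/TssAFlnk) lies within 10 kb of one anchor and an enhancer state
  (Enh/EnhG, plus EnhA1/EnhA2 in the human vocabulary) within 10 kb of
  the other; ReprPC/ReprPCWk instead makes it *repressive*.
* **Candidate selection.** Deletion candidates need a lineage-specific
  RE-derived anchor, a functional annotation, at most one active CTCF
  peak within 15 kb of the candidate anchor, and no p300 overlap on the
  motif; GeneHancer-supported pairs rank first.
* **Contact maps.** Knight–Ruiz-style diagonal balancing
  (B = DAD, equal row sums), observed/expected by distance, long-range
  (> 30 kb) intra/inter-domain interaction percentages, virtual 4C
  profiles, and a local observed/expected focal-enrichment score at a
  loop pixel.

## Worked example

```python
from teanchor import SimConfig
from teanchor.pipeline import run_synthetic

result = run_synthetic(SimConfig(seed=1))
for key, value in result.summary.items():
    print(key, value)
```

prints (seed 1):

```
loop_anchor_re_pct 30.0
loop_anchor_sites 120
tad_boundary_re_pct 33.333333333333336
loop_conserved_pct 50.0
tad_boundary_conserved_pct 50.0
ep_loop_pct 40.0
repressive_loop_pct 10.0
functional_loop_pct 50.0
n_candidates 1
wt_intra_pct 49.08531935176359
wt_inter_pct 19.46711153479504
ko_intra_pct 35.12991306983344
ko_inter_pct 42.12737818066596
wt_focal_enrichment 3.8004588514535596
ko_focal_enrichment 0.9746292379352879
```

Reading: of 120 anchor CTCF sites the pipeline calls exactly the
planted 30% RE-derived; 50% of loops are conserved against the second
genome; 40% are enhancer–promoter loops; exactly one loop survives all
candidate filters. On the simulated maps, ablating the TE-derived
boundary collapses the focal loop peak (3.8 → 0.97) and drains
intra-domain long-range contacts (49% → 35%) into inter-domain leakage
(19% → 42%).

The `examples/` directory has one short narrative script per
capability (dataset generation, repeat attribution, orthology, function
and candidate selection, contact-map validation); each prints the
numbers it computes and what they mean. A thin CLI mirrors the stages:
`teanchor simulate|attribute|orthology|run-all`.

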