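"""Generate the two-species synthetic dataset and inspect its ground truth.

Builds two 2x3 Mb genomes related by a block-wise chain, plants 200 TEs,
120 anchor CTCF motifs (30% inside TEs), 60 loops (50% lineage-specific,
40% enhancer-promoter) and 12 TAD boundaries, and writes every file in
the formats the pipeline reads.
"""

from teanchor import SimConfig
from teanchor.simulate import generate_dataset, write_dataset

ds = generate_dataset(SimConfig(seed=1))
paths = write_dataset(ds, "scratch/example_dataset")

truth = ds.loop_truth
print(f"species A: {ds.assembly_a.chrom_sizes}")
print(f"species B: {ds.assembly_b.chrom_sizes}")
print(f"loops planted: {len(ds.loops_a)}  "
      f"(conserved {int(truth.conserved.sum())}, "
      f"lineage-specific {int((~truth.conserved).sum())})")
print(f"anchor CTCF sites: {len(ds.site_truth)}  "
      f"RE-derived {int(ds.site_truth.re_derived.sum())}")
print(f"TEs planted: {len(ds.repeats_a)} (A), {len(ds.repeats_b)} (B)")
print(f"engineered CRISPR candidate: {ds.candidate_loop_id}")
print(f"files written: {sorted(p.name for p in paths.values())}")
# The B genome differs from A by seeded insertions/deletions; the chain
# file records the correspondence exactly, so conserved structures lift
# onto their planted B twins with zero coordinate error.
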