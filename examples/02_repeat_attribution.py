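"""Classify loop-anchor CTCF sites by repeat origin.

Scans each anchor for the best ChIP-supported CTCF motif, applies the
10 bp motif-repeat overlap rule, and summarizes the TE taxonomy of the
RE-derived sites — the per-sample quantities behind statements like
"x% of loop anchor CTCF sites are derived from REs".
"""

from teanchor import SimConfig
from teanchor.attribution import RepeatIndex, re_fraction, shuffle_null, summarize_taxonomy
from teanchor.pipeline import attribute_loops
from teanchor.simulate import generate_dataset

ds = generate_dataset(SimConfig(seed=1))
repeats = RepeatIndex(ds.repeats_a)
cls = attribute_loops(ds.loops_a, ds.sequences_a, ds.pwm, ds.ctcf_peaks_a, repeats)

sites = [s for c in cls.values() for s in c.sites if s is not None]
pct, num, den = re_fraction(sites)
print(f"RE-derived anchor CTCF sites: {num}/{den} = {pct:.1f}%")

for level in ("class", "family", "subfamily"):
    summ = summarize_taxonomy(cls.values(), level, te_only=True)
    top = ", ".join(f"{name} {p:.0f}%" for name, _, p in summ.rows[:4])
    print(f"TE {level:<9} contribution: {top}")

null = shuffle_null(sites, repeats, ds.assembly_a, n_shuffles=500, seed=1)
print(f"random expectation: observed {null.observed:.3f} vs null mean "
      f"{null.null_mean:.3f} (two-sided p = {null.p_value:.3g})")
# The observed fraction is far above the null because motifs were planted
# inside TEs by construction; on real genomes the observed fraction
# typically sits *below* random expectation.
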