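"""Detect a preferred relative orientation of a co-occurring motif pair.

Plants a pair in 100 promoters with 85% of co-occurrences in the
tandem-plus arrangement and tests each of the four orientation classes
against the uniform 1/4 expectation with an exact binomial tail
(Bonferroni x 4).
"""

import numpy as np

import crepair as cp
from crepair import fixtures as fx
from crepair.motif_scan import scan_promoters
from crepair.orientation import count_orientations, orientation_bias_test

rng = np.random.default_rng(5)
pwmA = fx.consensus_pwm("TFA", fx.DEFAULT_WORD_A)
pwmB = fx.consensus_pwm("TFB", fx.DEFAULT_WORD_B)

promoters = fx.simulate_promoters(100, rng=rng)
promoters, truth = fx.plant_pair_sites(
    promoters, pwmA, pwmB, [p.gene_id for p in promoters],
    orientation_probs=(0.85, 0.05, 0.05, 0.05), rng=rng,
)

table = cp.build_slot_table(scan_promoters([pwmA, pwmB], promoters))
counts = count_orientations(table, "TFA", "TFB", max_gap=25)
res = orientation_bias_test(counts)

print(f"co-occurrences classified: {counts.n}")
for cls, c in counts.counts.items():
    print(f"  {cls:<13} {c:>4}   corrected p = {res['p_corrected'][cls]:.3g}")
print(f"preferred orientation: {res['preferred']} "
      f"(significant: {res['significant']})")
print()
print("One strand arrangement dominates far beyond the n/4 expected under")
print("random orientation - the kind of physical constraint that suggests")
print("a geometry-dependent interaction between the two factors.")
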