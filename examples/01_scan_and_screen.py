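"""Scan synthetic promoters for a planted motif pair and screen for
short-spacing co-occurrence bias.

Builds 300 promoters, plants consensus words for two TFs at gaps of
0-25 bp in 60 of them, predicts sites at the 25-fold relative-affinity
cutoff, and runs the Poisson co-occurrence test against the analytic
spacing null.
"""

import numpy as np

import crepair as cp
from crepair import fixtures as fx
from crepair.motif_scan import scan_promoters

rng = np.random.default_rng(42)
pwmA = fx.consensus_pwm("TFA", fx.DEFAULT_WORD_A)
pwmB = fx.consensus_pwm("TFB", fx.DEFAULT_WORD_B)

promoters = fx.simulate_promoters(300, rng=rng)
targets = [p.gene_id for p in promoters[:60]]
promoters, truth = fx.plant_pair_sites(promoters, pwmA, pwmB, targets, rng=rng)

sites = scan_promoters([pwmA, pwmB], promoters)
table = cp.build_slot_table(sites)
result = cp.screen_pairs([table]).iloc[0]

print(f"predicted sites: {len(sites)} in {len(promoters)} promoters")
print(f"pair {result['tf1']} x {result['tf2']}:")
print(f"  co-occurrences with gap <= 25 bp : {result['observed_le25']}")
print(f"  expected under the spacing null  : {result['lambda_le25']:.2f}")
print(f"  Poisson p (Bonferroni-corrected) : {result['p_bonferroni']:.3g}")
print(f"  significant at alpha = 0.01      : {result['significant']}")
print()
print("The observed short-gap count dwarfs the null expectation because")
print("60 promoters carry the pair at planted gaps; the corrected p-value")
print("is the screen's evidence for a functional CRE combination.")
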