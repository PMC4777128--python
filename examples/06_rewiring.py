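"""Cross-species rewiring of a motif pair's target genes.

Partitions orthologous targets into species-1-only (A), shared (B) and
species-2-only (C) sets, then asks whether A tracks B's expression in
species 1 and C tracks B in species 2 more closely than random
re-assignments of the pooled A+C genes (1000 permutations).
"""

from crepair import fixtures as fx
from crepair import rewiring as rw

part, expr_sp1, expr_sp2, orthologs = fx.simulate_rewiring_scenario(rng=11)
print(f"target partition: |A|={len(part.set_A)} |B|={len(part.set_B)} "
      f"|C|={len(part.set_C)}")

res = rw.rewiring_permutation_test(part, expr_sp1, expr_sp2, orthologs,
                                   n_sims=1000, seed=11)
print(f"mean PCC A vs B (species 1): {res['mean_pcc_A_vs_B']:.3f}")
print(f"mean PCC C vs B (species 2): {res['mean_pcc_C_vs_B']:.3f}")
print(f"permutation p: {res['p_rewire']:.4g} "
      f"({res['n_sims']} re-deals of A+C)")
print()
print("Random re-deals almost never match the species-specific coherence")
print("of the real A and C sets, so the gain/loss of this motif pair")
print("between the species predicts a genuine change in co-regulation.")
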