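import numpy as np
import pytest

from crepair import fixtures as fx
from crepair.motif_scan import BindingSite


@pytest.fixture(scope="session")
def pwm_pair():
    """Two sharp, non-palindromic 8 bp motifs used throughout."""
    return (
        fx.consensus_pwm("TFA", fx.DEFAULT_WORD_A),
        fx.consensus_pwm("TFB", fx.DEFAULT_WORD_B),
    )


@pytest.fixture(scope="session")
def planted_genome(pwm_pair):
    """300 promoters, 60 with an A-B block planted at gaps 0..25."""
    pwmA, pwmB = pwm_pair
    rng = np.random.default_rng(42)
    promoters = fx.simulate_promoters(300, rng=rng)
    targets = [p.gene_id for p in promoters[:60]]
    promoters, truth = fx.plant_pair_sites(promoters, pwmA, pwmB, targets, rng=rng)
    return promoters, truth


def uniform_sites(n_promoters, mean_sites_per_tf, seed, width=8,
                  tfs=("TFA", "TFB"), species="sp1", promoter_len=600):
    """Sites with uniform random positions: the geometry S(d) models."""
    rng = np.random.default_rng(seed)
    sites = []
    for k in range(n_promoters):
        for tf in tfs:
            for _ in range(rng.poisson(mean_sites_per_tf)):
                start = int(rng.integers(0, promoter_len - width + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                sites.append(
                    BindingSite(f"g{k:05d}", species, tf, start, width,
                                strand, 1.0)
                )
    return sites
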