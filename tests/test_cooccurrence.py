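import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crepair import cooccurrence as co
from crepair.motif_scan import BindingSite

from conftest import uniform_sites


def site(gene, tf, start, width=8, strand="+"):
    return BindingSite(gene, "sp1", tf, start, width, strand, 1.0)


class TestSpacingDistribution:
    def test_edge_to_edge_gap(self):
        sd = co.pair_spacing_distribution(
            [site("g1", "A", 10), site("g1", "B", 30)], "A", "B"
        )
        assert sd.N == 1 and sd.counts[12] == 1

    def test_overlapping_pair_discarded(self):
        sd = co.pair_spacing_distribution(
            [site("g1", "A", 10), site("g1", "B", 15)], "A", "B"
        )
        assert sd.N == 0

    def test_all_pairs_counted(self):
        sd = co.pair_spacing_distribution(
            [site("g1", "A", 0), site("g1", "A", 100), site("g1", "B", 300)],
            "A", "B",
        )
        assert sd.N == 2

    def test_cross_promoter_pairs_not_counted(self):
        sd = co.pair_spacing_distribution(
            [site("g1", "A", 10), site("g2", "B", 30)], "A", "B"
        )
        assert sd.N == 0

    def test_homotypic_rejected(self):
        with pytest.raises(ValueError, match="homotypic"):
            co.pair_spacing_distribution([site("g1", "A", 10)], "A", "A")

    def test_B_is_promoter_minus_widths(self):
        sd = co.pair_spacing_distribution(
            [site("g1", "A", 10), site("g1", "B", 30)], "A", "B"
        )
        assert sd.B == 600 - 16


class TestExpectedProfile:
    def test_zero_at_maximum_gap(self):
        assert co.expected_spacing_profile(50, 100, 100) == 0.0

    def test_printed_formula_value(self):
        assert co.expected_spacing_profile(1000, 500, 0) == pytest.approx(4.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            co.expected_spacing_profile(10, 100, 101)
        with pytest.raises(ValueError):
            co.expected_spacing_profile(10, 100, -1)
        with pytest.raises(ValueError):
            co.expected_spacing_profile(10, 0, 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 10_000), st.integers(1, 600))
    def test_conservation_identity(self, N, B):
        """sum_d S(d) over 0..B equals N(B+1)/B for any N, B."""
        total = co.expected_spacing_profile(N, B, np.arange(B + 1)).sum()
        assert math.isclose(total, N * (B + 1) / B, rel_tol=1e-12)

    def test_conservation_example(self):
        total = co.expected_spacing_profile(100, 100, np.arange(101)).sum()
        assert total == pytest.approx(101.0)


class TestShuffles:
    @pytest.fixture()
    def table(self):
        return co.build_slot_table(uniform_sites(30, 2.0, seed=1))

    def test_genome_shuffle_preserves_marginals(self, table):
        labels = co.genome_label_shuffle(table, 11)
        assert np.array_equal(np.bincount(labels), np.bincount(table.labels))
        # slot geometry untouched by construction: labels vector only

    def test_same_seed_same_permutation(self, table):
        a = co.genome_label_shuffle(table, 7)
        b = co.genome_label_shuffle(table, 7)
        assert np.array_equal(a, b)

    def test_single_label_shuffle_is_identity(self):
        table = co.build_slot_table(
            uniform_sites(10, 2.0, seed=2, tfs=("A",))
        )
        labels = co.genome_label_shuffle(table, 3)
        assert np.array_equal(labels, table.labels)

    def test_promoter_shuffle_preserves_within_promoter_multisets(self, table):
        labels = co.promoter_label_shuffle(table, 5)
        for g in range(len(table.promoter_ids)):
            mask = table.slot_promoter == g
            assert sorted(labels[mask]) == sorted(table.labels[mask])

    def test_single_shuffle_profile_matches_direct_computation(self, table):
        mean, sd = co.null_profile(table, "TFA", "TFB", n_shuffles=1, seed=9)
        labels = co.genome_label_shuffle(table, np.random.default_rng(9))
        a, b = table.tf_index("TFA"), table.tf_index("TFB")
        B = 600 - 16
        direct = co._pair_counts_from_table(table, labels, a, b, B)
        assert np.allclose(mean, direct[: mean.size])
        assert np.all(sd == 0)

    def test_absent_motif_gives_empty_profile(self):
        table = co.build_slot_table(uniform_sites(10, 2.0, seed=2, tfs=("TFA",)))
        mean, sd = co.null_profile(table, "TFA", "ZZZ", n_shuffles=3, seed=0)
        assert mean.sum() == 0


class TestPoissonTest:
    def test_zero_observed_gives_p_one(self):
        r = co.pair_cooccurrence_test(0, 3.0, n_tests=10)
        assert r.p_poisson == 1.0

    def test_tail_matches_direct_pmf_summation(self):
        # independent oracle: sum the Poisson pmf tail by hand
        lam, obs = 2.0, 10
        tail = sum(
            math.exp(-lam) * lam**k / math.factorial(k) for k in range(obs, 60)
        )
        r = co.pair_cooccurrence_test(obs, lam, n_tests=1)
        assert r.p_poisson == pytest.approx(tail, rel=1e-9)
        assert r.p_poisson == pytest.approx(4.6e-5, rel=0.02)

    def test_bonferroni_over_hypothesis_space(self):
        r = co.pair_cooccurrence_test(30, 2.0, n_tests=19110, alpha=0.01)
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p_poisson * 19110))
        r2 = co.pair_cooccurrence_test(10, 2.0, n_tests=19110, alpha=0.01)
        assert r2.p_bonferroni == pytest.approx(4.6e-5 * 19110, rel=0.02)

    def test_negative_observed_rejected(self):
        with pytest.raises(ValueError):
            co.pair_cooccurrence_test(-1, 2.0, n_tests=1)

    def test_p_decreases_with_observed(self):
        ps = [
            co.pair_cooccurrence_test(k, 5.0, n_tests=1).p_poisson
            for k in range(0, 30)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestShapeTest:
    def test_identical_distributions_give_p_one(self):
        obs = np.array([10.0, 20, 30, 40])
        stat, p, df = co.spacing_shape_test(obs, obs.copy())
        assert stat == 0 and p == 1.0

    def test_hand_computed_two_bin_statistic(self):
        stat, p, df = co.spacing_shape_test([30.0, 70.0], [50.0, 50.0])
        assert stat == pytest.approx(16.0)
        assert df == 1
        assert p == pytest.approx(6.33e-5, rel=0.01)

    def test_light_bins_pooled_until_expected_five(self):
        obs = np.array([1.0, 1, 1, 1, 1, 20])
        exp = np.array([1.0, 1, 1, 1, 1, 20])
        stat, p, df = co.spacing_shape_test(obs, exp)
        assert df == 1  # bins: first five pooled (exp 5), last bin 20

    def test_untestable_when_single_bin(self):
        stat, p, df = co.spacing_shape_test([1.0, 1.0], [1.0, 1.0])
        assert df == 0 and math.isnan(p)

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="totals differ"):
            co.spacing_shape_test([10.0, 10.0], [100.0, 100.0])


class TestPromoterNull:
    def test_two_slot_promoter_is_degenerate(self):
        sites = [site("g1", "A", 10), site("g1", "B", 40)]
        table = co.build_slot_table(sites)
        exp = co.promoter_level_null(table, "A", "B", n_sims=20, seed=0)
        obs = co.pair_spacing_distribution(sites, "A", "B")
        assert np.allclose(exp[: obs.counts.size], obs.counts)

    def test_total_N_invariant_without_overlaps(self):
        # non-overlapping slots: starts on a 20 bp grid, width 8
        rng = np.random.default_rng(8)
        sites = []
        for k in range(25):
            starts = rng.choice(np.arange(0, 592, 20), size=4, replace=False)
            for j, s in enumerate(sorted(starts)):
                sites.append(site(f"g{k}", "TFA" if j % 2 else "TFB", int(s)))
        table = co.build_slot_table(sites)
        obs = co.pair_spacing_distribution(table, "TFA", "TFB")
        for s in (1, 2, 3):
            labels = co.promoter_label_shuffle(table, s)
            c = co._pair_counts_from_table(
                table, labels, table.tf_index("TFA"), table.tf_index("TFB"),
                obs.B,
            )
            # equal motif widths: overlap pattern is label-independent
            assert c.sum() == obs.N

    def test_single_site_promoter_contributes_nothing(self):
        sites = [site("g1", "A", 10)]
        table = co.build_slot_table(sites)
        exp = co.promoter_level_null(table, "A", "B", n_sims=5, seed=0)
        assert exp.sum() == 0


def exhaustive_genome_null(table, tfA, tfB, B):
    """Mean pair profile over ALL distinct genome-wide label permutations."""
    a, b = table.tf_index(tfA), table.tf_index(tfB)
    perms = set(itertools.permutations(table.labels.tolist()))
    acc = np.zeros(B + 1)
    for perm in perms:
        acc += co._pair_counts_from_table(
            table, np.array(perm), a, b, B
        )[: B + 1]
    return acc / len(perms)


class TestEnumerationOracles:
    def test_genome_null_matches_exhaustive_enumeration(self):
        sites = [
            site("g1", "TFA", 5), site("g1", "TFB", 40), site("g1", "TFA", 200),
            site("g2", "TFB", 10), site("g2", "TFA", 100),
            site("g3", "TFB", 30), site("g3", "TFA", 380), site("g3", "TFB", 500),
        ]
        table = co.build_slot_table(sites)
        B = 600 - 16
        oracle = exhaustive_genome_null(table, "TFA", "TFB", B)
        mean, sd = co.null_profile(table, "TFA", "TFB", n_shuffles=4000, seed=13)
        sem = sd / math.sqrt(4000)
        diff = np.abs(mean[: B + 1] - oracle)
        assert np.all(diff <= 4 * sem + 0.02)

    def test_promoter_null_matches_per_promoter_enumeration(self):
        sites = [
            site("g1", "TFA", 5), site("g1", "TFB", 40), site("g1", "TFA", 200),
            site("g2", "TFB", 10), site("g2", "TFA", 100), site("g2", "TFB", 300),
            site("g3", "TFB", 30), site("g3", "TFA", 380),
        ]
        table = co.build_slot_table(sites)
        B = 600 - 16
        a, b = table.tf_index("TFA"), table.tf_index("TFB")
        # independent per-promoter enumeration: promoters don't interact,
        # so enumerate each promoter's arrangements on its own sub-table
        oracle = np.zeros(B + 1)
        for gene in table.promoter_ids:
            sub = [s for s in sites if s.gene_id == gene]
            subtab = co.build_slot_table(sub)
            if "TFA" not in subtab.tf_names or "TFB" not in subtab.tf_names:
                continue
            sa, sb = subtab.tf_index("TFA"), subtab.tf_index("TFB")
            perms = set(itertools.permutations(subtab.labels.tolist()))
            part = np.zeros(B + 1)
            for perm in perms:
                part += co._pair_counts_from_table(
                    subtab, np.array(perm), sa, sb, B
                )[: B + 1]
            oracle += part / len(perms)
        mean = co.promoter_level_null(table, "TFA", "TFB", n_sims=4000, seed=21)
        assert np.abs(mean[: B + 1] - oracle).max() < 0.05


class TestScreen:
    def test_hypothesis_space_count(self):
        assert co.n_heterotypic_pairs(196) == 19110
        names = [f"TF{i:03d}" for i in range(196)]
        assert len(co.iter_heterotypic_pairs(names)) == 19110

    def test_planted_pair_detected(self, pwm_pair, planted_genome):
        from crepair.motif_scan import scan_promoters

        promoters, truth = planted_genome
        sites = scan_promoters(pwm_pair, promoters)
        table = co.build_slot_table(sites)
        df = co.screen_pairs([table])
        row = df.iloc[0]
        assert row["significant"]
        assert row["observed_le25"] >= len(truth)

    def test_multi_species_counts_pool(self):
        t1 = co.build_slot_table(uniform_sites(20, 2.0, seed=1, species="sp1"))
        t2 = co.build_slot_table(uniform_sites(20, 2.0, seed=2, species="sp2"))
        df12 = co.screen_pairs([t1, t2])
        df1 = co.screen_pairs([t1])
        df2 = co.screen_pairs([t2])
        assert (
            df12["N_total"][0] == df1["N_total"][0] + df2["N_total"][0]
        )
        assert df12["lambda_le25"][0] == pytest.approx(
            df1["lambda_le25"][0] + df2["lambda_le25"][0]
        )
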