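"""Synthetic repertoire generator: determinism, clone-size law, pairing."""

import numpy as np
import pytest

from tcrfocus import (
    PairedSimConfig,
    clonotype_key,
    renyi_entropy,
    simulate_paired,
    simulate_repertoire,
)
from tcrfocus.errors import ConfigurationError


class TestSimulateRepertoire:
    def test_bit_identical_for_fixed_seed(self):
        a = simulate_repertoire(100, 1000, seed=42)
        b = simulate_repertoire(100, 1000, seed=42)
        assert a.clones == b.clones

    def test_count_floor_gives_exact_richness(self):
        rep = simulate_repertoire(500, 5000, seed=1)
        assert rep.richness == 500
        assert rep.total_reads == 5000
        assert all(c.count >= 1 for c in rep.clones)

    def test_infeasible_reads_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_repertoire(100, 50, seed=0)

    def test_zipf_exponent_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            simulate_repertoire(10, 100, zipf_exponent=1.0, seed=0)

    def test_steep_exponent_gives_dominant_top_clone(self):
        rep = simulate_repertoire(100, 10000, zipf_exponent=4.0, seed=2)
        assert rep.frequencies.max() > 0.85
        assert renyi_entropy(rep.frequencies, np.inf) < 0.2

    def test_rank_one_frequency_matches_normalized_weight(self):
        """Law of large numbers: realized top-clone frequency ~ its weight."""
        n, s = 500, 1.5
        weights = np.arange(1, n + 1, dtype=float) ** -s
        expected = weights[0] / weights.sum()
        realized = np.array(
            [
                simulate_repertoire(n, 50_000, zipf_exponent=s, seed=seed)
                .frequencies.max()
                for seed in range(200)
            ]
        )
        # +1 floor shifts the mean by < n/total; allow that plus 3 SE
        tolerance = n / 50_000 + 3 * realized.std(ddof=1) / np.sqrt(realized.size)
        assert abs(realized.mean() - expected) < tolerance

    def test_unique_cdr3s_and_lognormal_law(self):
        rep = simulate_repertoire(300, 3000, size_law="lognormal", seed=3)
        cdr3s = [c.cdr3_aa for c in rep.clones]
        assert len(set(cdr3s)) == 300
        assert all(8 <= len(s) <= 20 for s in cdr3s)

    def test_nt_junctions_translate_back_to_cdr3(self):
        from Bio.Seq import Seq

        rep = simulate_repertoire(30, 300, seed=4)
        for clone in rep.clones:
            assert str(Seq(clone.cdr3_nt).translate()) == clone.cdr3_aa


class TestSimulatePaired:
    def test_no_bottleneck_shares_all_keys(self):
        config = PairedSimConfig(
            n_clones_bl=300, total_reads_bl=3000, total_reads_post=1500,
            bottleneck=1.0, persistence_rho=1.0, expansion_boost=1.0,
            n_novel_post=0, seed=7,
        )
        bl, post, truth = simulate_paired(config)
        assert set(post.keys()) == set(bl.keys())
        assert truth.realized_persistent_expanded_fraction == 1.0

    def test_bottleneck_reduces_richness(self):
        for seed in range(5):
            config = PairedSimConfig(
                n_clones_bl=500, total_reads_bl=5000, total_reads_post=2500,
                bottleneck=0.3, n_novel_post=50, seed=seed,
            )
            bl, post, _ = simulate_paired(config)
            assert post.richness < bl.richness

    def test_truth_record_consistent_with_repertoires(self):
        config = PairedSimConfig(
            n_clones_bl=400, total_reads_bl=4000, total_reads_post=2000,
            n_novel_post=100, seed=11,
        )
        bl, post, truth = simulate_paired(config)
        post_keys = set(post.keys(truth.key_mode))
        bl_keys = set(bl.keys(truth.key_mode))
        assert truth.surviving_keys <= bl_keys
        assert truth.surviving_keys <= post_keys
        assert truth.novel_keys <= post_keys
        assert not (truth.novel_keys & bl_keys)
        assert truth.surviving_keys | truth.novel_keys == post_keys
        assert truth.post_expanded_keys <= post_keys

    def test_all_randomness_flows_from_config_seed(self):
        config = PairedSimConfig(
            n_clones_bl=200, total_reads_bl=2000, total_reads_post=1000,
            n_novel_post=50, seed=13,
        )
        bl1, post1, t1 = simulate_paired(config)
        bl2, post2, t2 = simulate_paired(config)
        assert bl1.clones == bl2.clones
        assert post1.clones == post2.clones
        assert t1.surviving_keys == t2.surviving_keys

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            PairedSimConfig(bottleneck=1.5)
        with pytest.raises(ConfigurationError):
            PairedSimConfig(persistence_rho=-0.1)

    def test_motif_families_survive_into_post(self):
        config = PairedSimConfig(
            n_clones_bl=600, total_reads_bl=9000, total_reads_post=4000,
            n_motif_families=3, family_size=6, n_novel_post=50, seed=17,
        )
        bl, post, truth = simulate_paired(config)
        assert len(truth.family_of) == 18
        post_cdr3s = {c.cdr3_aa for c in post.clones}
        # expanded family members persist with high probability; at least some survive
        assert post_cdr3s & set(truth.family_of)
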