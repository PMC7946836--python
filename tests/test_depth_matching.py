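"""Iterative subsampling: hypergeometric draws, pairing rule, summaries."""

import numpy as np
import pytest

from tcrfocus import (
    SubsampleSpec,
    iterate_subsamples,
    match_pair,
    simulate_repertoire,
    subsample,
    summarize_iterates,
)
from tcrfocus.errors import DepthError, PairingError


class TestSubsample:
    def test_full_depth_is_identity(self, two_clone_rep):
        sub = subsample(two_clone_rep, two_clone_rep.total_reads, seed=5)
        assert [c.count for c in sub.clones] == [c.count for c in two_clone_rep.clones]
        assert sub.keys() == two_clone_rep.keys()

    def test_depth_above_total_raises(self, two_clone_rep):
        with pytest.raises(DepthError):
            subsample(two_clone_rep, two_clone_rep.total_reads + 1, seed=0)

    def test_total_reads_equal_depth_and_zero_draws_dropped(self, two_clone_rep):
        sub = subsample(two_clone_rep, 10, seed=1)
        assert sub.total_reads == 10
        assert all(c.count >= 1 for c in sub.clones)

    def test_deterministic_for_fixed_seed(self, skewed_rep):
        a = subsample(skewed_rep, 300, seed=17)
        b = subsample(skewed_rep, 300, seed=17)
        assert [c.count for c in a.clones] == [c.count for c in b.clones]
        assert a.keys() == b.keys()

    def test_richness_never_increases(self, skewed_rep):
        for seed in range(50):
            assert subsample(skewed_rep, 200, seed=seed).richness <= skewed_rep.richness

    def test_rare_clone_retention_matches_hypergeometric(self):
        """1-read clone vs 999-read clone at depth 1: retention ~ 1/1000."""
        from tcrfocus import Clone, Repertoire

        rep = Repertoire(
            sample_id="r",
            clones=(Clone(cdr3_aa="CAAAA", count=1), Clone(cdr3_aa="CCCCC", count=999)),
        )
        hits = sum(
            any(c.cdr3_aa == "CAAAA" for c in subsample(rep, 1, seed=s).clones)
            for s in range(10_000)
        )
        # binomial(10000, 0.001): mean 10, sd ~3.16; 95% band ~ [4, 16]
        assert 2 <= hits <= 22

    def test_expected_count_matches_depth_times_frequency(self, two_clone_rep):
        depth = 50
        counts = np.array(
            [
                next(c.count for c in subsample(two_clone_rep, depth, seed=s).clones
                     if c.cdr3_aa == "CASSLG")
                for s in range(4000)
            ]
        )
        expected = depth * 30 / 100
        n, K, N = depth, 30, 100
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        assert abs(counts.mean() - expected) < 3 * np.sqrt(var / counts.size)


class TestMatchPair:
    def test_equal_depths_pass_through(self, two_clone_rep):
        other = two_clone_rep.with_clones(two_clone_rep.clones)
        pairs = match_pair(two_clone_rep, other, n_iterations=5, seed=0)
        assert len(pairs) == 5
        for a, b in pairs:
            assert a is two_clone_rep and b is other

    def test_deeper_member_is_subsampled(self):
        deep = simulate_repertoire(200, 5000, sample_id="BL", timepoint="BL", seed=1)
        shallow = simulate_repertoire(150, 1200, sample_id="post", timepoint="postASCT", seed=2)
        for a, b in match_pair(deep, shallow, n_iterations=3, seed=0):
            assert a.total_reads == 1200
            assert b is shallow
        # direction flips when the post sample is deeper
        for a, b in match_pair(shallow, deep, n_iterations=3, seed=0):
            assert a is shallow
            assert b.total_reads == 1200

    def test_chain_mismatch_raises(self):
        alpha = simulate_repertoire(10, 50, chain="alpha", seed=1)
        beta = simulate_repertoire(10, 50, chain="beta", seed=2)
        with pytest.raises(PairingError, match="chain"):
            match_pair(alpha, beta)

    def test_fixed_seed_reproduces_iterate_sequence(self):
        deep = simulate_repertoire(100, 2000, sample_id="d", seed=4)
        shallow = simulate_repertoire(80, 900, sample_id="s", seed=5)
        run1 = match_pair(deep, shallow, n_iterations=10, seed=99)
        run2 = match_pair(deep, shallow, n_iterations=10, seed=99)
        for (a1, _), (a2, _) in zip(run1, run2):
            assert [c.count for c in a1.clones] == [c.count for c in a2.clones]


class TestSummarize:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2, 2, 2], (2.0, 2.0, 2.0, 2.0)),
            ([1, 2, 9], (4.0, 2.0, 1.0, 9.0)),
        ],
    )
    def test_summary_values(self, values, expected):
        assert summarize_iterates(values) == expected

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            summarize_iterates([])

    def test_iterate_richness_summary_reproducible(self):
        rep = simulate_repertoire(300, 6000, sample_id="x", seed=8)
        spec = SubsampleSpec(depth=1000, n_iterations=20, seed=3)
        s1 = summarize_iterates([r.richness for r in iterate_subsamples(rep, spec)])
        s2 = summarize_iterates([r.richness for r in iterate_subsamples(rep, spec)])
        assert s1 == s2
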