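"""Triplet spectrum kernel, similarity networks and threshold calibration."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcrfocus import (
    build_network,
    calibrate_control,
    kernel_similarity,
    simulate_repertoire,
    top_expanded_cdr3s,
    triplet_counts,
)
from tcrfocus.errors import SimilarityError

from conftest import random_cdr3

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=20)


def brute_force_triplets(s):
    """Independent oracle: scan every length-3 substring."""
    out = {}
    for i in range(len(s)):
        sub = s[i : i + 3]
        if len(sub) == 3:
            out[sub] = out.get(sub, 0) + 1
    return out


def brute_force_similarity(s, t):
    cs, ct = brute_force_triplets(s), brute_force_triplets(t)
    cross = sum(cs[u] * ct.get(u, 0) for u in cs)
    ss = sum(v * v for v in cs.values())
    tt = sum(v * v for v in ct.values())
    return cross / math.sqrt(ss * tt) if cross else 0.0


class TestTripletCounts:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("CASS", {"CAS": 1, "ASS": 1}),
            ("AAAA", {"AAA": 2}),
            ("CA", {}),
        ],
    )
    def test_enumeration(self, s, expected):
        assert triplet_counts(s) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(SimilarityError):
            triplet_counts("CASX1")

    def test_matches_brute_force_on_random_strings(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = random_cdr3(rng, 15, 15)
            assert triplet_counts(s) == brute_force_triplets(s)


class TestKernelSimilarity:
    def test_worked_case(self):
        # CASS vs CASSF: shared CAS, ASS; K=2, K_ss=2, K_tt=3
        assert kernel_similarity("CASS", "CASSF") == pytest.approx(2 / math.sqrt(6))

    def test_no_shared_triplet_is_zero(self):
        assert kernel_similarity("CASSL", "WGYQP") == 0.0

    def test_too_short_raises(self):
        with pytest.raises(SimilarityError):
            kernel_similarity("CA", "CASS")

    @given(peptides)
    def test_self_similarity_is_exactly_one(self, s):
        assert kernel_similarity(s, s) == 1.0

    @given(peptides, peptides)
    def test_symmetric_and_bounded(self, s, t):
        sim = kernel_similarity(s, t)
        assert sim == kernel_similarity(t, s)
        assert 0.0 <= sim <= 1.0 + 1e-12


class TestTopExpanded:
    def test_returns_all_when_fewer_than_n(self, skewed_rep):
        top = top_expanded_cdr3s(skewed_rep, n=50)
        assert len(top) == 1  # only the 100-read clone exceeds 1/1000

    def test_tie_break_is_lexicographic(self):
        from tcrfocus import Clone, Repertoire

        rep = Repertoire(
            sample_id="t",
            clones=(
                Clone(cdr3_aa="CWSSA", count=10),
                Clone(cdr3_aa="CASSA", count=10),
                Clone(cdr3_aa="CMSSA", count=10),
            ),
        )
        assert top_expanded_cdr3s(rep, n=2) == ["CASSA", "CMSSA"]

    def test_nonproductive_and_short_excluded(self):
        from tcrfocus import Clone, Repertoire

        rep = Repertoire(
            sample_id="t",
            clones=(
                Clone(cdr3_aa="CAS*SL", count=50),
                Clone(cdr3_aa="CA", count=50),
                Clone(cdr3_aa="CASSL", count=50),
            ),
        )
        assert top_expanded_cdr3s(rep, n=10) == ["CASSL"]

    def test_exactly_top_n_most_frequent_returned(self):
        rep = simulate_repertoire(2000, 40000, seed=31)
        freqs = {c.cdr3_aa: c.count / rep.total_reads for c in rep.clones}
        top = top_expanded_cdr3s(rep, n=50)
        assert len(top) == 50
        ranked = sorted(
            (c for c, f in freqs.items() if f > 1e-3), key=lambda c: (-freqs[c], c)
        )
        assert top == ranked[:50]


class TestNetwork:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            build_network(["CASSL", "CASSL"])

    def test_pair_above_threshold_forms_single_cluster(self):
        net = build_network(["CASS", "CASSF", "WGYQPW"], 0.80)
        assert net.n_clusters == 1
        assert net.clusters[0] == ("CASS", "CASSF")
        assert net.clustered_fraction == pytest.approx(2 / 3)

    def test_dissimilar_strings_give_no_clusters(self):
        rng = np.random.default_rng(3)
        cdr3s = sorted({random_cdr3(rng) for _ in range(80)})[:50]
        assert build_network(cdr3s, 0.80).n_clusters == 0

    def test_matches_brute_force_component_search(self):
        rng = np.random.default_rng(8)
        # mix of random strings and near-duplicates to force some edges
        base = sorted({random_cdr3(rng, 12, 14) for _ in range(40)})[:25]
        variants = [s[:-1] + ("A" if s[-1] != "A" else "C") for s in base[:10]]
        cdr3s = sorted(set(base + variants))
        net = build_network(cdr3s, 0.80)
        # independent oracle: similarity matrix + BFS
        n = len(cdr3s)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                if brute_force_similarity(cdr3s[i], cdr3s[j]) >= 0.80:
                    adj[i, j] = adj[j, i] = True
        seen, components = set(), []
        for start in range(n):
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(np.flatnonzero(adj[k]))
            seen |= comp
            if len(comp) >= 2:
                components.append(frozenset(cdr3s[k] for k in comp))
        assert {frozenset(c) for c in net.clusters} == set(components)

    def test_raising_threshold_never_increases_clustering(self):
        rng = np.random.default_rng(12)
        base = sorted({random_cdr3(rng, 12, 14) for _ in range(30)})[:20]
        cdr3s = sorted(set(base + [s[:-1] + "A" for s in base if s[-1] != "A"]))
        prev_edges, prev_frac = math.inf, math.inf
        for threshold in (0.5, 0.7, 0.8, 0.9, 1.0):
            net = build_network(cdr3s, threshold)
            assert net.graph.number_of_edges() <= prev_edges
            assert net.clustered_fraction <= prev_frac + 1e-12
            prev_edges = net.graph.number_of_edges()
            prev_frac = net.clustered_fraction


class TestCalibration:
    def test_empty_control_is_zero(self):
        assert calibrate_control([], 0.8) == 0.0

    def test_threshold_floor_connects_everything_sharing_structure(self):
        # at a tiny positive threshold any shared triplet makes an edge
        frac = calibrate_control(["CASSA", "CASSC", "WGYQP"], 1e-9)
        assert frac == pytest.approx(2 / 3)

    def test_planted_families_recovered_with_high_purity(self):
        rep, truth = simulate_repertoire(
            1000, 20000, n_motif_families=4, family_size=8, seed=19, return_truth=True
        )
        top = top_expanded_cdr3s(rep, 50)
        net = build_network(top, 0.80)
        assert net.n_clusters >= 4
        for members in net.clusters:
            labels = Counter(truth.family_of.get(m) for m in members)
            purity = labels.most_common(1)[0][1] / len(members)
            assert purity >= 0.9
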