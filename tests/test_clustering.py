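"""Similarity graph, partitioning and size-filter tests, including the
all-vs-all brute-force oracle comparison."""

import math
import random

import numpy as np
import pytest

from cenrepeat.align import best_overlap, exhaustive_overlap, kmer_positions
from cenrepeat.clustering import (Read, build_similarity_graph, cluster_graph,
                                  cluster_reads, filter_clusters, qc_filter)
from cenrepeat.qc import low_complexity_fraction, passes_complexity_filter
from cenrepeat.simulate import _random_seq, encode, mutate, revcomp

import oracles


def _mk_reads(seqs, prefix="r"):
    return [Read(f"{prefix}{i:03d}", s) for i, s in enumerate(seqs)]


class TestOverlapCriterion:
    def test_identical_reads_full_identity(self, rng):
        s = _random_seq(300, rng)
        g = build_similarity_graph(_mk_reads([s, s])).graph
        assert g.number_of_edges() == 1
        _, _, d = next(iter(g.edges(data=True)))
        assert d["identity"] == 1.0 and d["overlap_fraction"] == 1.0

    def test_reverse_complement_pair_connects(self, rng):
        s = _random_seq(300, rng)
        g = build_similarity_graph(_mk_reads([s, revcomp(s)])).graph
        assert g.number_of_edges() == 1

    def test_half_shared_block_below_overlap_cutoff(self, rng):
        block = _random_seq(150, rng)
        a = block + _random_seq(150, rng)
        b = _random_seq(150, rng) + block
        # 150/300 = 0.50 < 0.55: no edge, by implementation and by brute force
        g = build_similarity_graph(_mk_reads([a, b]), 0.9, 0.55).graph
        assert g.number_of_edges() == 0
        assert oracles.brute_force_overlap(a, b, 0.9, 0.55) is None
        # the same block passes a 0.45 cutoff
        g2 = build_similarity_graph(_mk_reads([a, b]), 0.9, 0.45).graph
        assert g2.number_of_edges() == 1
        assert oracles.brute_force_overlap(a, b, 0.9, 0.45) is not None

    def test_seeded_matches_exhaustive_on_diverged_pairs(self, rng):
        template = _random_seq(400, rng)
        for div in (0.0, 0.02, 0.05):
            a = mutate(template[:300], div, rng)
            b = mutate(template[80:380], div, rng)
            hit = best_overlap(a, encode(a), kmer_positions(a, 17), b, 0.9, 0.55)
            ex = exhaustive_overlap(a, b, 0.9, 0.55)
            assert (hit is None) == (ex is None)
            if hit is not None:
                assert hit.identity == pytest.approx(ex.identity, abs=0.02)

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            build_similarity_graph([])
        with pytest.raises(ValueError):
            cluster_reads([])


class TestClusterGraph:
    def test_rank_and_ids(self, rng):
        t1 = _random_seq(300, rng)
        t2 = _random_seq(300, rng)
        reads = _mk_reads([t1] * 10, "a") + _mk_reads([t2] * 5, "b")
        clusters = cluster_graph(build_similarity_graph(reads))
        assert [c.cluster_id for c in clusters] == ["CL1", "CL2"]
        assert clusters[0].size == 10 and clusters[1].size == 5

    def test_edgeless_graph_zero_clusters(self, rng):
        reads = _mk_reads([_random_seq(300, rng) for _ in range(8)])
        clusters = cluster_graph(build_similarity_graph(reads))
        assert clusters == []

    def test_two_planted_families_two_pure_clusters(self, small_pooled):
        reads = [r for r in small_pooled if r.true_family_id != "none"]
        clusters = cluster_reads(reads, total_reads=len(reads))
        top = [c for c in clusters if c.size >= 10]
        fams = {c.majority_family for c in top}
        assert "sat187" in fams and "line1" in fams
        for c in top:
            purity = sum(1 for r in c.reads
                         if r.true_family_id == c.majority_family) / c.size
            assert purity >= 0.95

    def test_proportions_sum_to_one_with_singletons(self, small_pooled):
        reads = small_pooled[:1200]
        clusters = cluster_reads(reads, total_reads=len(reads))
        clustered = sum(c.size for c in clusters)
        singletons = len(reads) - clustered
        total = sum(c.proportion for c in clusters) + singletons / len(reads)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_input_order_permutation_invariance(self, small_pooled):
        reads = [r for r in small_pooled if r.true_family_id != "none"][:150]
        base = cluster_reads(reads, total_reads=len(reads))
        shuffled = reads[:]
        random.Random(5).shuffle(shuffled)
        perm = cluster_reads(shuffled, total_reads=len(shuffled))
        assert [set(c.member_reads) for c in base] == [set(c.member_reads) for c in perm]

    def test_components_match_brute_force_oracle(self, small_pooled):
        reads = sorted((r for r in small_pooled if r.true_family_id != "none"),
                       key=lambda r: r.read_id)[:120]
        ours = cluster_reads(reads, total_reads=len(reads))
        got = sorted((frozenset(c.member_reads) for c in ours),
                     key=lambda c: (-len(c), min(c)))
        expected = oracles.brute_force_components(reads, 0.90, 0.55)
        assert got == expected

    def test_no_edge_crosses_clusters(self, small_pooled):
        reads = [r for r in small_pooled if r.true_family_id != "none"][:150]
        sim = build_similarity_graph(reads)
        clusters = cluster_graph(sim)
        owner = {}
        for c in clusters:
            for m in c.member_reads:
                owner[m] = c.cluster_id
        for a, b in sim.graph.edges:
            assert owner.get(a) == owner.get(b)


class TestFilterClusters:
    def _fake(self, sizes):
        return [Read("", "")] and [
            __import__("cenrepeat.clustering", fromlist=["ReadCluster"]).ReadCluster(
                f"CL{i+1}", [f"r{i}_{j}" for j in range(s)], 0, s, 0.0)
            for i, s in enumerate(sizes)]

    def test_cutoff_is_ceiling(self):
        clusters = self._fake([3, 2, 1])
        retained, dropped = filter_clusters(clusters, 10_000, 0.0001)
        assert len(retained) == 3  # ceil(1.0) = 1: everything stays
        assert math.ceil(0.0001 * 2_000_000) == 200  # the paper-scale cutoff

    def test_cutoff_200_retains_only_larger(self):
        clusters = self._fake([300, 150])
        retained, dropped = filter_clusters(clusters, 2_000_000, 0.0001)
        assert [c.size for c in retained] == [300]
        assert len(dropped) == 1 and "cutoff 200" in dropped[0][1]

    def test_bad_proportion(self):
        with pytest.raises(ValueError):
            filter_clusters([], 100, 0.0)


class TestLowComplexityFilter:
    def test_simple_repeat_flagged(self, rng):
        noisy_at = mutate("AT" * 150, 0.03, rng)
        assert low_complexity_fraction(noisy_at) > 0.9
        assert not passes_complexity_filter(noisy_at)

    def test_random_read_passes(self, rng):
        assert passes_complexity_filter(_random_seq(300, rng))

    def test_half_simple_read_borderline(self, rng):
        seq = _random_seq(140, rng) + "AT" * 80
        frac = low_complexity_fraction(seq)
        assert 0.4 <= frac <= 0.75

    def test_qc_filter_keeps_tagged_reads(self, rng):
        reads = [Read("a", _random_seq(300, rng)), Read("b", "AT" * 150)]
        kept = qc_filter(reads)
        assert [r.read_id for r in kept] == ["a"]
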