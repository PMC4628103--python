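"""Topology, consensus, monomer, AT content, ORF, junction and connection tests."""

import math

import edlib
import networkx as nx
import numpy as np
import pytest

from cenrepeat.characterize import (assemble_consensus, classify_topology,
                                    compute_at_content, connection_analysis,
                                    consensus_closure, detect_junctions,
                                    estimate_monomer_length, find_orfs)
from cenrepeat.clustering import Read, ReadCluster, cluster_reads
from cenrepeat.simulate import (RepeatFamilySpec, _random_seq,
                                generate_dispersed_family,
                                generate_tandem_array, mutate, revcomp)

import oracles


class TestTopology:
    def test_path_graph_is_line(self):
        assert classify_topology(nx.path_graph(100)).label == "line"

    def test_cycle_graph_is_ring(self):
        assert classify_topology(nx.cycle_graph(100)).label == "ring"

    def test_hub_and_spokes_is_star(self):
        assert classify_topology(nx.star_graph(99)).label == "star"

    def test_small_graph_is_other(self):
        assert classify_topology(nx.path_graph(10)).label == "other"

    def test_disconnected_rejected(self):
        g = nx.Graph()
        g.add_edges_from([(1, 2), (3, 4)])
        with pytest.raises(ValueError):
            classify_topology(g)

    def test_consensus_closure_overrides_graph_fallback(self):
        # a cycle declared non-closed by its consensus is not a ring
        rep = classify_topology(nx.cycle_graph(100), closure=False)
        assert rep.label != "ring"


class TestMonomer:
    def test_exact_short_period(self):
        assert estimate_monomer_length("ACGT" * 100) == 4

    def test_planted_187_recovered_from_diverged_array(self):
        _, arr = generate_tandem_array(187, 40, 0.583, 0.02, seed=5)
        assert estimate_monomer_length(arr) == 187

    def test_random_sequence_has_no_period(self, rng):
        seq = _random_seq(2000, rng)
        assert estimate_monomer_length(seq) is None
        # exhaustive lag oracle: no lag reaches the 0.8 score
        assert all(oracles.best_lag_score(seq, lag) < 0.8
                   for lag in range(2, len(seq) // 3))

    def test_phase_invariance(self):
        _, arr = generate_tandem_array(187, 30, 0.583, 0.02, seed=6)
        base = estimate_monomer_length(arr)
        for shift in (13, 94, 186):
            assert estimate_monomer_length(arr[shift:] + arr[:shift]) == base

    def test_strand_invariance(self):
        _, arr = generate_tandem_array(120, 30, 0.5, 0.02, seed=7)
        assert estimate_monomer_length(arr) == estimate_monomer_length(revcomp(arr))

    def test_score_matches_direct_loop(self, rng):
        _, arr = generate_tandem_array(50, 12, 0.5, 0.05, seed=8)
        lag = estimate_monomer_length(arr)
        assert lag == 50
        assert oracles.best_lag_score(arr, 50) >= 0.8


class TestATContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 1.0), ("GCGC", 0.0), ("ACGT", 0.5), ("AANN", 1.0),
    ])
    def test_examples(self, seq, expected):
        assert compute_at_content(seq) == pytest.approx(expected)

    def test_strand_invariance(self, rng):
        s = _random_seq(501, rng, 0.6)
        assert compute_at_content(s) == pytest.approx(compute_at_content(revcomp(s)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_at_content("")
        with pytest.raises(ValueError):
            compute_at_content("NNN")


class TestORFs:
    def test_429_nt_orf_is_143_aa(self, rng):
        codons = []
        while len(codons) < 142:
            c = _random_seq(3, rng)
            if c not in ("TAA", "TAG", "TGA") and c != "ATG":
                codons.append(c)
        orf = "ATG" + "".join(codons)
        assert len(orf) == 429
        seq = "C" * 10 + orf + "TAA" + "C" * 10
        hits = [o for o in find_orfs(seq, min_aa=100)]
        assert len(hits) == 1
        assert hits[0].aa_length == 143
        assert hits[0].end - hits[0].start == 429

    def test_minimal_orf(self):
        hits = find_orfs("ATGTAA", min_aa=1)
        assert any(o.aa_length == 1 and o.strand == "+" for o in hits)

    def test_no_start_codon_no_orfs(self):
        assert find_orfs("CCCCCCCCTAACCCCCC", min_aa=1) == []

    def test_agreement_with_codon_walk_oracle(self, rng):
        for _ in range(100):
            seq = _random_seq(1000, rng)
            ours = sorted((o.strand, o.frame, o.start, o.end, o.aa_length)
                          for o in find_orfs(seq, min_aa=20))
            assert ours == oracles.six_frame_orfs(seq, 20)


def _reads_from(template, n, rng, err=0.0, read_len=300, prefix="t"):
    out = []
    for i in range(n):
        s = int(rng.integers(0, len(template) - read_len + 1))
        seq = template[s:s + read_len]
        if err:
            seq = mutate(seq, err, rng)
        out.append(Read(f"{prefix}{i:04d}", seq))
    return out


class TestAssembly:
    def test_identical_reads_single_contig(self, rng):
        s = _random_seq(300, rng)
        contigs = assemble_consensus([Read(f"r{i}", s) for i in range(10)])
        assert len(contigs) == 1
        assert contigs[0].sequence == s

    def test_tiled_error_free_reads_contain_template(self, rng):
        template = _random_seq(1000, rng)
        reads = [Read(f"r{i:02d}", template[s:s + 300])
                 for i, s in enumerate(range(0, 701, 50))]
        contigs = assemble_consensus(reads)
        assert template in contigs[0].sequence

    def test_noisy_reads_high_identity_consensus(self, rng):
        template = _random_seq(1000, rng)
        reads = _reads_from(template, 100, rng, err=0.005)  # ~30x
        contigs = assemble_consensus(reads)
        longest = contigs[0].sequence
        d = edlib.align(longest, template, mode="HW", task="distance")["editDistance"]
        assert 1 - d / len(longest) >= 0.995

    def test_no_overlaps_each_read_own_contig(self, rng):
        reads = [Read(f"r{i}", _random_seq(300, rng)) for i in range(5)]
        contigs = assemble_consensus(reads)
        assert len(contigs) == 5

    def test_mixed_strand_reads_assemble(self, rng):
        template = _random_seq(800, rng)
        reads = []
        for i, s in enumerate(range(0, 501, 50)):
            seq = template[s:s + 300]
            reads.append(Read(f"r{i:02d}", seq if i % 2 == 0 else revcomp(seq)))
        contigs = assemble_consensus(reads)
        longest = contigs[0].sequence
        hit = min(
            edlib.align(longest, template, mode="HW", task="distance")["editDistance"],
            edlib.align(revcomp(longest), template, mode="HW", task="distance")["editDistance"])
        assert len(longest) >= 600 and hit <= 2

    def test_periodic_consensus_closure(self, rng):
        _, arr = generate_tandem_array(187, 10, 0.583, 0.0, seed=9)
        reads = _reads_from(arr, 60, rng)
        contigs = assemble_consensus(reads)
        assert consensus_closure(contigs[0])


class TestJunctions:
    def test_homogeneous_tandem_reads_no_junctions(self, rng):
        _, arr = generate_tandem_array(187, 30, 0.583, 0.01, seed=10)
        reads = _reads_from(arr, 80, rng, err=0.001)
        contigs = assemble_consensus(reads)
        assert detect_junctions(reads, contigs[:2]) == []

    def test_clip_threshold_one_never_fires(self, rng):
        spec = RepeatFamilySpec("T", "ltr", 1200, 6, divergence=0.02, ltr_length_bp=150)
        copies = generate_dispersed_family(spec, 6, 0.02, seed=11)
        reads = []
        for ci, cp in enumerate(copies):
            flanked = _random_seq(400, rng) + cp + _random_seq(400, rng)
            reads += _reads_from(flanked, 40, rng, prefix=f"c{ci}_")
        element_reads = [r for r in reads]
        contigs = assemble_consensus(element_reads, max_reads=150, seed=1)
        assert detect_junctions(element_reads, contigs[:2], clip_threshold=1.0) == []

    def test_ltr_boundary_junction_recovered(self, rng):
        spec = RepeatFamilySpec("T", "ltr", 1200, 6, divergence=0.02, ltr_length_bp=150)
        copies = generate_dispersed_family(spec, 6, 0.02, seed=12)
        # reads from each copy embedded in its own genomic flanks
        reads = []
        for ci, cp in enumerate(copies):
            flanked = _random_seq(400, rng) + cp + _random_seq(400, rng)
            reads += _reads_from(flanked, 60, rng, err=0.001, prefix=f"c{ci}_")
        # keep reads overlapping the element to mimic cluster membership
        clusters = cluster_reads(reads, total_reads=len(reads))
        cl = clusters[0]
        contigs = assemble_consensus(cl.reads, max_reads=200, seed=1)
        junctions = detect_junctions(cl.reads, contigs[:1], clip_threshold=0.3)
        assert junctions, "no junction found at the element boundary"
        # the junction should sit within +-25 nt of an element end on the contig
        contig = contigs[0].sequence
        spots = []
        for copy in copies:
            for probe in (copy[:60], copy[-60:]):
                for q in (probe, revcomp(probe)):
                    res = edlib.align(q, contig, mode="HW", task="locations", k=8)
                    if res["editDistance"] != -1 and res["locations"]:
                        loc = res["locations"][0]
                        spots.extend([loc[0], loc[1] + 1])
        assert any(min(abs(j.position - s) for s in spots) <= 25 for j in junctions)


class TestConnections:
    def _clusters_and_contigs(self, rng):
        t1 = _random_seq(2000, rng)
        t2 = _random_seq(2000, rng)
        reads1 = _reads_from(t1, 80, rng, prefix="a")
        reads2 = _reads_from(t2, 80, rng, prefix="b")
        cl1 = ReadCluster("CL1", [r.read_id for r in reads1], 0, 80, 0.5, reads=reads1)
        cl2 = ReadCluster("CL2", [r.read_id for r in reads2], 0, 80, 0.5, reads=reads2)
        contigs = {"CL1": assemble_consensus(reads1), "CL2": assemble_consensus(reads2)}
        return [cl1, cl2], contigs

    def test_unrelated_clusters_no_split_groups(self, rng):
        clusters, contigs = self._clusters_and_contigs(rng)
        table = connection_analysis(clusters, contigs)
        assert table.split_groups == []

    def test_infinite_threshold_empty_groups(self, rng):
        clusters, contigs = self._clusters_and_contigs(rng)
        table = connection_analysis(clusters, contigs, link_threshold=math.inf)
        assert table.split_groups == []

    def test_mate_links_counted_symmetrically(self, rng):
        reads1 = [Read(f"p{i:03d}/1", _random_seq(300, rng)) for i in range(10)]
        reads2 = [Read(f"p{i:03d}/2", _random_seq(300, rng)) for i in range(10)]
        cl1 = ReadCluster("CL1", [r.read_id for r in reads1], 0, 10, 0.5, reads=reads1)
        cl2 = ReadCluster("CL2", [r.read_id for r in reads2], 0, 10, 0.5, reads=reads2)
        table = connection_analysis([cl1, cl2], {}, link_threshold=5)
        assert table.rows == [("CL1", "CL2", 10, 0)]
        assert table.split_groups == [{"CL1", "CL2"}]

    def test_fewer_than_two_clusters_rejected(self, rng):
        clusters, contigs = self._clusters_and_contigs(rng)
        with pytest.raises(ValueError):
            connection_analysis(clusters[:1], contigs)
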