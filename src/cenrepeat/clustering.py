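"""Similarity-graph construction and repeat clustering of pooled reads.

The clustering criterion: two reads are joined when their best dovetail
overlap (either strand) covers at least `min_overlap_fraction` of the shorter
read at `min_identity` or better.  Clusters are the connected components of
that graph, ranked by size.

Two routes compute the partition:

* :func:`build_similarity_graph` materializes the full edge set (optionally
  by exhaustive all-pairs, all-offset scanning) — exact, quadratic, used for
  moderate read counts, topology subgraphs and oracle comparisons.
* :func:`cluster_reads` computes the same connected components incrementally
  with a union-find, a sampled k-mer candidate index with bucket caps, and a
  per-component alignment cap — the bounded-work strategy of greedy sequence
  clusterers.  Caps can only cause missed edges between already-distant pairs;
  on homogeneous repeat families the components match the exact route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .align import best_overlap, exhaustive_overlap, kmer_positions
from .qc import passes_complexity_filter
from .simulate import FractionLibrary, encode


@dataclass
class Read:
    read_id: str
    seq: str
    fraction: str = "input"      # 'input' or 'chip'
    true_family_id: str = "none"


@dataclass
class SimilarityGraph:
    """Read-similarity graph plus the thresholds that defined its edges."""

    graph: nx.Graph
    min_identity: float
    min_overlap_fraction: float

    def __post_init__(self) -> None:
        assert all(not self.graph.has_edge(n, n) for n in self.graph), "self-edges forbidden"


@dataclass
class ReadCluster:
    cluster_id: str
    member_reads: list[str]
    n_input: int
    n_chip: int
    proportion: float
    subgraph: nx.Graph | None = None
    majority_family: str = "none"
    reads: list[Read] = field(default_factory=list, repr=False)

    @property
    def size(self) -> int:
        return len(self.member_reads)


def pool_fractions(input_lib: FractionLibrary, chip_lib: FractionLibrary) -> list[Read]:
    """Pool both fractions into single-read records tagged with their fraction."""
    reads = []
    for lib in (input_lib, chip_lib):
        for rid, seq, fam, frac in lib.iter_single_reads():
            reads.append(Read(rid, seq, frac, fam))
    return reads


def qc_filter(reads: Sequence[Read], max_masked_fraction: float = 0.5) -> list[Read]:
    """Drop reads dominated by low-complexity sequence."""
    return [r for r in reads if passes_complexity_filter(r.seq, max_masked_fraction)]


def subsample_reads(reads: Sequence[Read], max_reads: int, seed: int = 0) -> list[Read]:
    if len(reads) <= max_reads:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=max_reads, replace=False))
    return [reads[i] for i in idx]


# ---------------------------------------------------------------------------
# Exact graph construction
# ---------------------------------------------------------------------------

def build_similarity_graph(
    reads: Sequence[Read],
    min_identity: float = 0.90,
    min_overlap_fraction: float = 0.55,
    k: int = 17,
    exhaustive: bool = False,
    query_stride: int = 4,
) -> SimilarityGraph:
    """All qualifying edges among `reads`.

    With `exhaustive=False` candidate pairs come from a shared-k-mer inverted
    index over both strands; the prefilter can only miss pairs whose identity
    is below 1 - 1/k.  With `exhaustive=True` every pair is scanned at every
    dovetail offset (quadratic; small inputs only).
    """
    if not reads:
        raise ValueError("read set is empty")
    if not (0 < min_identity <= 1 and 0 < min_overlap_fraction <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    g = nx.Graph()
    for r in reads:
        g.add_node(r.read_id, fraction=r.fraction, true_family_id=r.true_family_id)

    if exhaustive:
        pairs: Iterable[tuple[int, int]] = (
            (i, j) for i in range(len(reads)) for j in range(i + 1, len(reads)))
        for i, j in pairs:
            hit = exhaustive_overlap(reads[i].seq, reads[j].seq,
                                     min_identity, min_overlap_fraction)
            if hit is not None:
                g.add_edge(reads[i].read_id, reads[j].read_id,
                           identity=hit.identity, overlap_fraction=hit.overlap_fraction)
        return SimilarityGraph(g, min_identity, min_overlap_fraction)

    from collections import defaultdict
    index: dict[str, list[int]] = defaultdict(list)
    canon = []
    for i, r in enumerate(reads):
        canon.append((r.seq, encode(r.seq), kmer_positions(r.seq, k)))
    # candidate pairs: any two reads sharing a k-mer on either strand; strand
    # handled inside best_overlap, so index forward k-mers of all reads and
    # query with both strands of the later read
    from .simulate import revcomp
    cand: set[tuple[int, int]] = set()
    for i, r in enumerate(reads):
        seen: set[int] = set()
        for s in (r.seq, revcomp(r.seq)):
            for p in range(0, len(s) - k + 1, query_stride):
                for j in index.get(s[p:p + k], ()):
                    if j != i:
                        seen.add(j)
        for j in seen:
            cand.add((min(i, j), max(i, j)))
        for p in range(len(r.seq) - k + 1):
            index[r.seq[p:p + k]].append(i)
    for i, j in cand:
        a_seq, a_arr, a_kmers = canon[i]
        hit = best_overlap(a_seq, a_arr, a_kmers, reads[j].seq,
                           min_identity, min_overlap_fraction, k=k)
        if hit is not None:
            g.add_edge(reads[i].read_id, reads[j].read_id,
                       identity=hit.identity, overlap_fraction=hit.overlap_fraction)
    return SimilarityGraph(g, min_identity, min_overlap_fraction)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _rank_components(components: list[list[str]]) -> list[list[str]]:
    """Largest first; ties broken by the lexicographically smallest member."""
    return sorted(components, key=lambda c: (-len(c), min(c)))


def _make_clusters(components: list[list[str]], reads_by_id: dict[str, Read],
                   total_reads: int) -> list[ReadCluster]:
    clusters = []
    for rank, comp in enumerate(_rank_components(components), start=1):
        members = sorted(comp)
        rs = [reads_by_id[m] for m in members]
        n_input = sum(1 for r in rs if r.fraction == "input")
        fams = {}
        for r in rs:
            fams[r.true_family_id] = fams.get(r.true_family_id, 0) + 1
        majority = max(sorted(fams), key=lambda f: fams[f]) if fams else "none"
        clusters.append(ReadCluster(
            cluster_id=f"CL{rank}",
            member_reads=members,
            n_input=n_input,
            n_chip=len(members) - n_input,
            proportion=len(members) / total_reads,
            majority_family=majority,
            reads=rs,
        ))
    return clusters


def cluster_graph(sim: SimilarityGraph, total_reads: int | None = None) -> list[ReadCluster]:
    """Connected components of the similarity graph as ranked clusters.

    Singleton nodes are not clusters.  `total_reads` defaults to the node
    count and is the denominator of each cluster's proportion.
    """
    g = sim.graph
    total = total_reads if total_reads is not None else g.number_of_nodes()
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    reads_by_id = {n: Read(n, "", g.nodes[n].get("fraction", "input"),
                           g.nodes[n].get("true_family_id", "none")) for n in g}
    clusters = _make_clusters(comps, reads_by_id, total)
    for cl in clusters:
        cl.subgraph = g.subgraph(cl.member_reads).copy()
    return clusters


def cluster_reads(
    reads: Sequence[Read],
    min_identity: float = 0.90,
    min_overlap_fraction: float = 0.55,
    k: int = 17,
    kmer_sample_rate: int = 6,
    bucket_cap: int = 32,
    per_component_cap: int = 3,
    exact_below: int = 400,
    total_reads: int | None = None,
) -> list[ReadCluster]:
    """Partition reads into similarity clusters with bounded work.

    Reads are processed in sorted-id order (so the result is invariant to the
    input ordering); each read queries an inverted index holding a
    hash-selected ~1/`kmer_sample_rate` subset of the k-mers of previously
    processed reads (hash selection is position-independent, so overlapping
    reads sample the same k-mers regardless of their relative offset) and is
    aligned against at most `per_component_cap` of the best-supported
    candidates of each currently distinct component, merging components
    through a union-find.
    """
    if not reads:
        raise ValueError("read set is empty")
    if len(reads) <= exact_below:
        # small inputs: no candidate caps, so components equal those of the
        # full k-mer-prefiltered similarity graph
        bucket_cap = per_component_cap = len(reads)
    order = sorted(range(len(reads)), key=lambda i: reads[i].read_id)
    from collections import Counter, defaultdict
    from zlib import crc32
    from .simulate import revcomp

    def sampled(seq: str) -> list[str]:
        out = []
        for p in range(len(seq) - k + 1):
            km = seq[p:p + k]
            if crc32(km.encode()) % kmer_sample_rate == 0:
                out.append(km)
        return out

    parent = list(range(len(reads)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    index: dict[str, list[int]] = defaultdict(list)
    cache: dict[int, tuple] = {}

    def canon(i: int):
        c = cache.get(i)
        if c is None:
            s = reads[i].seq
            c = (s, encode(s), kmer_positions(s, k))
            cache[i] = c
        return c

    for i in order:
        seq = reads[i].seq
        votes: Counter[int] = Counter()
        for s in (seq, revcomp(seq)):
            for km in sampled(s):
                for j in index.get(km, ()):
                    votes[j] += 1
        # group candidates by current component, best-supported first
        by_root: dict[int, list[int]] = defaultdict(list)
        for j, _ in votes.most_common():
            by_root[find(j)].append(j)
        for root, members in by_root.items():
            if find(i) == root:
                continue
            for j in members[:per_component_cap]:
                a_seq, a_arr, a_kmers = canon(j)
                hit = best_overlap(a_seq, a_arr, a_kmers, seq,
                                   min_identity, min_overlap_fraction, k=k)
                if hit is not None:
                    union(i, j)
                    break
        for km in sampled(seq):
            bucket = index[km]
            if len(bucket) < bucket_cap:
                bucket.append(i)

    comps: dict[int, list[str]] = defaultdict(list)
    for i in range(len(reads)):
        comps[find(i)].append(reads[i].read_id)
    components = [c for c in comps.values() if len(c) >= 2]
    reads_by_id = {r.read_id: r for r in reads}
    total = total_reads if total_reads is not None else len(reads)
    return _make_clusters(components, reads_by_id, total)


def filter_clusters(
    clusters: Sequence[ReadCluster],
    total_reads: int,
    min_proportion: float = 0.0001,
) -> tuple[list[ReadCluster], list[tuple[ReadCluster, str]]]:
    """Retain clusters holding at least ceil(min_proportion * total_reads) reads.

    Returns (retained, filtered) where each filtered entry carries the reason.
    """
    if not 0 < min_proportion < 1:
        raise ValueError("min_proportion must be in (0, 1)")
    cutoff = math.ceil(min_proportion * total_reads)
    retained, dropped = [], []
    for cl in clusters:
        if cl.size >= cutoff:
            retained.append(cl)
        else:
            dropped.append((cl, f"size {cl.size} < cutoff {cutoff}"))
    return retained, dropped
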