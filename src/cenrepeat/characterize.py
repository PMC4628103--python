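"""Characterization of retained read clusters.

Graph topology (star / ring / line) separates tandem satellites from
dispersed retroelements; a greedy overlap-layout consensus provides contigs
on which monomer periodicity, AT content, open reading frames and insertion
junctions are measured; and mate-pair plus contig-end connections between
clusters flag long-monomer satellites that the clustering split.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .align import kmer_positions
from .clustering import Read, ReadCluster
from .simulate import encode, decode, revcomp


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    cluster_id: str
    label: str  # line | star | ring | other
    n_nodes: int
    density: float
    normalized_diameter: float
    max_degree_fraction: float
    closure: bool
    elongation: float = 0.0


def _graph_metrics(g: nx.Graph) -> tuple[int, float, float, float, float]:
    n = g.number_of_nodes()
    density = nx.density(g)
    diam = nx.diameter(g)
    norm_diam = diam / n
    max_deg = max(d for _, d in g.degree)
    max_deg_frac = max_deg / (n - 1) if n > 1 else 0.0
    mean_deg = 2 * g.number_of_edges() / n
    # 1.0 for a path-of-overlaps graph at any coverage, ~0.5 for rings and
    # complete graphs: diameter relative to the minimum possible for a graph
    # with this degree
    elongation = diam * mean_deg / (2 * n)
    return n, density, norm_diam, max_deg_frac, elongation


def _robustly_connected(g: nx.Graph, n_samples: int = 10, seed: int = 0) -> bool:
    """Connected after removal of any single sampled node."""
    nodes = sorted(g.nodes)
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(nodes), size=min(n_samples, len(nodes)), replace=False)
    for i in picks:
        h = g.copy()
        h.remove_node(nodes[i])
        if h.number_of_nodes() and not nx.is_connected(h):
            return False
    return True


def classify_topology(
    subgraph: nx.Graph,
    closure: Optional[bool] = None,
    cluster_id: str = "",
    min_nodes: int = 20,
    star_adjacency: float = 0.5,
    star_max_norm_diam: float = 0.1,
    line_min_norm_diam: float = 0.3,
    line_min_elongation: float = 0.7,
    seed: int = 0,
) -> TopologyReport:
    """Label a cluster graph as star, ring, line or other.

    Rules, in order: star when one node is adjacent to at least half of the
    others and the graph is compact; ring when the consensus closes on itself
    and the graph survives single-node removal; line when the graph is
    elongated (large normalized diameter, or diameter near the maximum
    possible for its degree — the coverage-independent form) and not closed.
    `closure` comes from the consensus end-overlap test; when unavailable a
    graph-only fallback (2-connectedness of a non-elongated graph) is used.
    """
    if subgraph.number_of_nodes() == 0:
        raise ValueError("empty subgraph")
    if not nx.is_connected(subgraph):
        raise ValueError("cluster subgraphs must be connected components")
    n, density, norm_diam, max_deg_frac, elongation = _graph_metrics(subgraph)
    if n < min_nodes:
        return TopologyReport(cluster_id, "other", n, density, norm_diam,
                              max_deg_frac, bool(closure), elongation)
    closed = closure
    if closed is None:
        closed = (elongation < line_min_elongation
                  and min(d for _, d in subgraph.degree) >= 2
                  and _robustly_connected(subgraph, seed=seed))
    label = "other"
    if max_deg_frac >= star_adjacency and norm_diam <= star_max_norm_diam:
        label = "star"
    elif closed and _robustly_connected(subgraph, seed=seed):
        label = "ring"
    elif (norm_diam >= line_min_norm_diam or elongation >= line_min_elongation) and not closed:
        label = "line"
    return TopologyReport(cluster_id, label, n, density, norm_diam,
                          max_deg_frac, bool(closed), elongation)


# ---------------------------------------------------------------------------
# Consensus assembly (greedy overlap-layout-consensus)
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    sequence: str
    coverage: np.ndarray                      # per-position read depth
    layout: list[tuple[str, int, str]] = field(default_factory=list)  # (read_id, offset, strand)

    def __len__(self) -> int:
        return len(self.sequence)


def _orient_reads(reads: Sequence[Read], k: int = 17) -> list[tuple[str, str, str]]:
    """Assign each read the strand that best matches the already-oriented set.

    Returns (read_id, oriented_seq, strand) tuples.  Greedy and k-mer based;
    adequate for reads drawn from one repeat family.
    """
    seen: set[str] = set()
    out: list[tuple[str, str, str]] = []
    for r in reads:
        fwd = r.seq
        rev = revcomp(fwd)
        if not seen:
            choice, strand = fwd, "+"
        else:
            nf = sum(1 for p in range(0, len(fwd) - k + 1, 4) if fwd[p:p + k] in seen)
            nr = sum(1 for p in range(0, len(rev) - k + 1, 4) if rev[p:p + k] in seen)
            choice, strand = (fwd, "+") if nf >= nr else (rev, "-")
        for p in range(len(choice) - k + 1):
            seen.add(choice[p:p + k])
        out.append((r.read_id, choice, strand))
    return out


def _polish_contig(contig: Contig, reads: Sequence[tuple[str, str]], k: int = 17) -> Contig:
    """Re-vote consensus columns using all reads mapped back to the contig.

    Greedy chains leave some columns at low coverage; mapping every read back
    restores the full depth so the majority vote can correct isolated errors.
    """
    ckmers = kmer_positions(contig.sequence, k)
    L = len(contig)
    votes = np.zeros((4, L), dtype=np.int32)
    lut = np.full(256, -1, dtype=np.int64)
    for bi, b in enumerate(b"ACGT"):
        lut[b] = bi
    n_mapped = 0
    for _, seq in reads:
        m = _map_read(contig.sequence, ckmers, seq, k=k)
        if m is None:
            continue
        off, a, b, rs, _ = m
        lo = max(0, off + a)
        hi = min(L, off + b)
        if hi <= lo:
            continue
        arr = lut[encode(rs[a + (lo - off - a):a + (hi - off - a)])]
        cols = np.arange(lo, hi)
        good = arr >= 0
        np.add.at(votes, (arr[good], cols[good]), 1)
        n_mapped += 1
    if n_mapped < 3:
        return contig
    covered = votes.sum(axis=0) > 0
    cons_idx = votes.argmax(axis=0)
    new = np.frombuffer(b"ACGT", dtype=np.uint8)[cons_idx]
    old = encode(contig.sequence)
    new = np.where(covered, new, old)
    return Contig(decode(new), votes.sum(axis=0), contig.layout)


def assemble_consensus(
    cluster_reads: Sequence[Read],
    min_overlap: int = 40,
    max_reads: int = 400,
    seed: int = 0,
    polish: bool = True,
) -> list[Contig]:
    """Greedy overlap-layout consensus of a cluster's reads.

    Longest exact suffix/prefix overlaps (>= min_overlap, either strand via a
    prior orientation pass) are merged first, forming read chains; each chain
    becomes a contig by per-column majority vote.  Reads without any
    qualifying overlap become single-read contigs.  Contigs are returned
    longest first.
    """
    if len(cluster_reads) < 1:
        raise ValueError("no reads to assemble")
    reads = sorted(cluster_reads, key=lambda r: r.read_id)
    if len(reads) > max_reads:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(reads), size=max_reads, replace=False))
        reads = [reads[i] for i in idx]

    oriented = _orient_reads(reads)
    n = len(oriented)
    seqs = [s for _, s, _ in oriented]

    # index of read prefixes for suffix->prefix overlap lookup
    prefix_index: dict[str, list[int]] = defaultdict(list)
    for j, s in enumerate(seqs):
        prefix_index[s[:min_overlap]].append(j)

    overlaps: list[tuple[int, int, int]] = []  # (overlap_len, i, j): suffix of i == prefix of j
    for i, s in enumerate(seqs):
        found: set[int] = set()
        for p in range(0, len(s) - min_overlap + 1):
            for j in prefix_index.get(s[p:p + min_overlap], ()):
                if j == i or j in found:
                    continue
                olap = len(s) - p
                if s[p:] == seqs[j][:olap]:
                    overlaps.append((olap, i, j))
                    found.add(j)
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    succ: dict[int, tuple[int, int]] = {}
    has_pred: set[int] = set()
    for olap, i, j in overlaps:
        if i in succ or j in has_pred:
            continue
        if find(i) == find(j):
            continue  # would close a cycle; ends are left for the closure test
        succ[i] = (j, len(seqs[i]) - olap)
        has_pred.add(j)
        parent[find(j)] = find(i)

    contigs: list[Contig] = []
    starts = [i for i in range(n) if i not in has_pred]
    for start in starts:
        chain = [(start, 0)]
        cur, off = start, 0
        while cur in succ:
            nxt, adv = succ[cur]
            off += adv
            chain.append((nxt, off))
            cur = nxt
        length = max(off + len(seqs[i]) for i, off in chain)
        votes = np.zeros((5, length), dtype=np.int32)
        lut = np.full(256, 4, dtype=np.int64)
        for bi, b in enumerate(b"ACGT"):
            lut[b] = bi
        for i, off in chain:
            arr = lut[encode(seqs[i])]
            np.add.at(votes, (arr, np.arange(off, off + arr.size)), 1)
        cons_idx = votes[:4].argmax(axis=0)
        coverage = votes[:4].sum(axis=0)
        cons = decode(np.frombuffer(b"ACGT", dtype=np.uint8)[cons_idx])
        layout = [(oriented[i][0], off, oriented[i][2]) for i, off in chain]
        contigs.append(Contig(cons, coverage, layout))
    contigs.sort(key=lambda c: -len(c))
    if polish:
        read_seqs = [(rid, s) for rid, s, _ in oriented]
        contigs = [
            _polish_contig(c, read_seqs) if i < 5 and len(c.layout) >= 3 and len(c) >= 300
            else c
            for i, c in enumerate(contigs)
        ]
    return contigs


def consensus_closure(contig: Contig, min_overlap: int = 40, search_span: int = 600) -> bool:
    """True when the contig end re-enters its start: the terminal `min_overlap`
    exact word occurs again near the contig start (circular or tandem layout)."""
    s = contig.sequence
    if len(s) < 2 * min_overlap + 1:
        return False
    tail = s[-min_overlap:]
    hit = s.find(tail, 0, min(len(s) - min_overlap, search_span))
    return hit >= 0


# ---------------------------------------------------------------------------
# Sequence measurements
# ---------------------------------------------------------------------------

def compute_at_content(sequence: str) -> float:
    """(A+T) / (length - N).  Raises on an empty effective length."""
    if not sequence:
        raise ValueError("empty sequence")
    arr = encode(sequence.upper())
    n_n = int((arr == ord("N")).sum())
    eff = arr.size - n_n
    if eff == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    at = int((arr == ord("A")).sum() + (arr == ord("T")).sum())
    return at / eff


def estimate_monomer_length(
    sequence: str,
    min_lag: int = 2,
    min_score: float = 0.8,
) -> Optional[int]:
    """Dominant tandem period of `sequence`, or None if it is not tandem.

    For each lag L in [min_lag, len/3], the score is the mean per-base match
    fraction between the sequence and itself shifted by L; the smallest L
    whose score reaches `min_score` and is a local maximum is returned.
    """
    arr = encode(sequence.upper())
    n = arr.size
    max_lag = n // 3
    if max_lag < min_lag:
        return None
    lags = np.arange(min_lag - 1, max_lag + 2)  # guard lags for local-max test
    scores = np.full(lags.size, -1.0)
    for idx, lag in enumerate(lags):
        if lag < 1 or lag >= n:
            continue
        scores[idx] = float((arr[:-lag] == arr[lag:]).mean())
    for idx in range(1, lags.size - 1):
        lag = lags[idx]
        if lag < min_lag or lag > max_lag:
            continue
        s = scores[idx]
        if s >= min_score and s >= scores[idx - 1] and s >= scores[idx + 1]:
            return int(lag)
    return None


@dataclass
class ORF:
    frame: int        # 0..2 within the scanned strand
    strand: str       # '+' or '-'
    start: int        # nucleotide span on that strand, stop codon excluded
    end: int          # half-open
    aa_length: int


def find_orfs(sequence: str, min_aa: int = 1) -> list[ORF]:
    """ATG-initiated open reading frames on all six frames.

    An ORF runs from ATG to the last sense codon and must be immediately
    followed by a stop codon; the reported span excludes the stop, so
    aa_length = (end - start) / 3.  Coordinates of '-' strand ORFs refer to
    the reverse complement of the input.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    stops = {"TAA", "TAG", "TGA"}
    out: list[ORF] = []
    for strand, seq in (("+", sequence.upper()), ("-", revcomp(sequence.upper()))):
        for frame in range(3):
            pos = frame
            starts_open: list[int] = []
            while pos + 3 <= len(seq):
                codon = seq[pos:pos + 3]
                if codon == "ATG":
                    starts_open.append(pos)
                if codon in stops:
                    for s0 in starts_open:
                        aa = (pos - s0) // 3
                        if aa >= min_aa:
                            out.append(ORF(frame, strand, s0, pos, aa))
                    starts_open = []
                pos += 3
    return out


# ---------------------------------------------------------------------------
# Junction detection
# ---------------------------------------------------------------------------

@dataclass
class Junction:
    contig_index: int
    position: int
    clipped_fraction: float
    n_distinct_tails: int


def _map_read(contig_seq: str, contig_kmers: dict[str, list[int]],
              read: str, k: int = 17, min_block: int = 15,
              min_block_identity: float = 0.66) -> Optional[tuple[int, int, int, str, str]]:
    """Locate a read on a contig and trim poorly matching ends.

    Returns (offset, aligned_start, aligned_end, oriented_read, strand) in read
    coordinates, where [aligned_start, aligned_end) is the well-matching core.
    """
    carr = encode(contig_seq)
    best = None
    for strand, rs in (("+", read), ("-", revcomp(read))):
        votes: Counter[int] = Counter()
        for p in range(0, len(rs) - k + 1, 3):
            for cpos in contig_kmers.get(rs[p:p + k], ()):
                votes[cpos - p] += 1
        if not votes:
            continue
        off = votes.most_common(1)[0][0]
        rarr = encode(rs)
        lo = max(0, -off)
        hi = min(len(rs), len(contig_seq) - off)
        if hi - lo < k:
            continue
        matches = rarr[lo:hi] == carr[off + lo: off + hi]
        score = int(matches.sum())
        if best is None or score > best[0]:
            best = (score, off, lo, hi, matches, rs, strand)
    if best is None:
        return None
    _, off, lo, hi, matches, rs, strand = best
    # trim ends while the local window identity is poor
    a, b = 0, matches.size
    while b - a >= min_block and matches[a:a + min_block].mean() < min_block_identity:
        a += 1
    while b - a >= min_block and matches[b - min_block:b].mean() < min_block_identity:
        b -= 1
    if b - a < min_block:
        return None
    return off, lo + a, lo + b, rs, strand


def detect_junctions(
    cluster_reads: Sequence[Read],
    contigs: Sequence[Contig],
    clip_threshold: float = 0.3,
    min_tail: int = 20,
    k: int = 17,
    merge_window: int = 5,
) -> list[Junction]:
    """Sites where reads stop aligning and continue into heterologous sequence.

    For every contig position, the clipped fraction is the share of reads
    spanning that position whose alignment terminates there with an unaligned
    tail of at least `min_tail` nt that does not match the contig.  Positions
    with clipped fraction >= clip_threshold supported by >= 2 distinct tail
    sequences are junctions; nearby positions are merged.
    """
    if not 0 < clip_threshold <= 1.0:
        raise ValueError("clip_threshold must be in (0, 1]")
    junctions: list[Junction] = []
    for ci, contig in enumerate(contigs):
        if len(contig) < 2 * min_tail:
            continue
        ckmers = kmer_positions(contig.sequence, k)
        L = len(contig)
        spanning = np.zeros(L + 1, dtype=np.int64)
        clips: dict[int, list[str]] = defaultdict(list)
        for r in cluster_reads:
            m = _map_read(contig.sequence, ckmers, r.seq, k=k)
            if m is None:
                continue
            off, a, b, rs, _ = m
            span_lo = max(0, off)
            span_hi = min(L, off + len(rs))
            if span_hi <= span_lo:
                continue
            spanning[span_lo:span_hi] += 1
            # left clip: unaligned head inside the contig
            if a >= min_tail and off + a > 0:
                clips[off + a].append(rs[:a][-min_tail:])
            # right clip: unaligned tail inside the contig
            if len(rs) - b >= min_tail and off + b < L:
                clips[off + b].append(rs[b:][:min_tail])
        candidates = []
        for pos in clips:
            # clip coordinates jitter a few bases with trimming, so pool
            # support across a small window around each candidate site
            pooled: list[str] = []
            for q in range(pos - merge_window, pos + merge_window + 1):
                pooled.extend(clips.get(q, ()))
            depth = spanning[min(pos, L - 1)]
            if depth == 0:
                continue
            frac = min(1.0, len(pooled) / depth)
            n_distinct = len(set(pooled))
            if frac >= clip_threshold and n_distinct >= 2:
                candidates.append((pos, frac, n_distinct))
        candidates.sort()
        merged: list[list] = []
        for pos, frac, nd in candidates:
            if merged and pos - merged[-1][0] <= merge_window:
                if frac > merged[-1][1]:
                    merged[-1] = [pos, frac, nd]
            else:
                merged.append([pos, frac, nd])
        junctions.extend(Junction(ci, p, f, nd) for p, f, nd in merged)
    return junctions


# ---------------------------------------------------------------------------
# Inter-cluster connections
# ---------------------------------------------------------------------------

@dataclass
class ConnectionTable:
    rows: list[tuple[str, str, int, int]]  # (cluster_a, cluster_b, mate_links, end_hits)
    split_groups: list[set[str]]


def _end_similarity(end_a: str, end_b: str, min_identity: float = 0.8,
                    min_len: int = 50) -> bool:
    """True when some >= min_len stretch of end_a matches end_b (either
    strand) at >= min_identity, assessed by sliding min_len windows of end_a
    through end_b with a banded edit-distance search."""
    import edlib
    max_dist = int(min_len * (1.0 - min_identity))
    step = max(1, min_len // 2)
    windows = [end_a[p:p + min_len] for p in range(0, len(end_a) - min_len + 1, step)]
    if not windows:
        return False
    for seq_b in (end_b, revcomp(end_b)):
        for w in windows:
            res = edlib.align(w, seq_b, mode="HW", task="distance", k=max_dist)
            if res["editDistance"] != -1:
                return True
    return False


def connection_analysis(
    clusters: Sequence[ReadCluster],
    contigs_by_cluster: dict[str, Sequence[Contig]],
    link_threshold: int = 5,
    end_length: int = 100,
    min_end_identity: float = 0.8,
    min_end_len: int = 50,
    join_on: str = "any",
) -> ConnectionTable:
    """Count mate links and contig-end similarity hits between clusters, and
    join clusters whose evidence reaches the threshold into split groups.

    Mate links: read pairs whose two mates were assigned to different
    clusters (mate ids share a pair stem, '/1' vs '/2').  End hits: pairs of
    contig terminal segments from different clusters that align at >=
    `min_end_identity` over >= `min_end_len` nt.

    `join_on` selects the evidence that merges clusters into split groups:
    "end_hits" (default) joins on frequent terminal-sequence similarity — the
    specific signature of a satellite whose monomer exceeds the read length —
    while "any" also joins on mate links alone.  Mate links by themselves
    mostly flag coverage-gap fragments of a single locus, so they are always
    reported but only join clusters in "any" mode.
    """
    if join_on not in ("end_hits", "any"):
        raise ValueError("join_on must be 'end_hits' or 'any'")
    if len(clusters) < 2:
        raise ValueError("connection analysis needs at least two clusters")
    cluster_of: dict[str, str] = {}
    for cl in clusters:
        for rid in cl.member_reads:
            cluster_of[rid] = cl.cluster_id

    mate_links: Counter[tuple[str, str]] = Counter()
    for rid, cid in cluster_of.items():
        if rid.endswith("/1"):
            mate = rid[:-2] + "/2"
            mcid = cluster_of.get(mate)
            if mcid is not None and mcid != cid:
                key = tuple(sorted((cid, mcid)))
                mate_links[key] += 1

    ids = [cl.cluster_id for cl in clusters]
    # terminal segments of assembled contigs (single- and two-read contigs are
    # not trustworthy ends)
    all_ends: list[tuple[str, str]] = []  # (cluster_id, segment)
    for cl in clusters:
        for contig in contigs_by_cluster.get(cl.cluster_id, []):
            if len(contig.layout) < 3:
                continue
            if len(contig) >= 2 * end_length:
                all_ends.append((cl.cluster_id, contig.sequence[:end_length]))
                all_ends.append((cl.cluster_id, contig.sequence[-end_length:]))
            elif len(contig) >= min_end_len:
                all_ends.append((cl.cluster_id, contig.sequence))

    # k-mer prefilter: only end pairs sharing an exact word can reach 80%
    # identity over 50 nt in practice
    kk = 13
    bucket: dict[str, list[int]] = defaultdict(list)
    for idx, (_, seg) in enumerate(all_ends):
        seen_local: set[str] = set()
        for s in (seg, revcomp(seg)):
            for p in range(0, len(s) - kk + 1, 2):
                seen_local.add(s[p:p + kk])
        for km in seen_local:
            bucket[km].append(idx)
    cand_pairs: set[tuple[int, int]] = set()
    for members in bucket.values():
        if len(members) < 2:
            continue
        for x, y in itertools.combinations(members, 2):
            if all_ends[x][0] != all_ends[y][0]:
                cand_pairs.add((x, y))

    end_hits: Counter[tuple[str, str]] = Counter()
    for x, y in cand_pairs:
        (ca, sa), (cb, sb) = all_ends[x], all_ends[y]
        if _end_similarity(sa, sb, min_end_identity, min_end_len):
            end_hits[tuple(sorted((ca, cb)))] += 1

    keys = sorted(set(mate_links) | set(end_hits))
    rows = [(a, b, mate_links.get((a, b), 0), end_hits.get((a, b), 0)) for a, b in keys]

    parent = {cid: cid for cid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, ml, eh in rows:
        if not math.isfinite(link_threshold):
            continue
        evidence = eh if join_on == "end_hits" else max(eh, ml)
        if evidence >= link_threshold:
            parent[find(b)] = find(a)
    groups: dict[str, set[str]] = defaultdict(set)
    for cid in ids:
        groups[find(cid)].add(cid)
    split_groups = [g for g in groups.values() if len(g) >= 2]
    return ConnectionTable(rows, split_groups)


# ---------------------------------------------------------------------------
# Per-cluster report
# ---------------------------------------------------------------------------

@dataclass
class ConsensusReport:
    cluster_id: str
    contigs: list[Contig]
    monomer_length_bp: Optional[int]
    at_fraction: float
    orfs: list[ORF]
    junctions: list[Junction]
    closure: bool


def characterize_cluster(
    cluster: ReadCluster,
    min_overlap: int = 40,
    max_assembly_reads: int = 400,
    min_orf_aa: int = 50,
    clip_threshold: float = 0.3,
    max_map_reads: int = 400,
    seed: int = 0,
) -> ConsensusReport:
    """Assemble a cluster and measure its consensus features on the longest contig."""
    contigs = assemble_consensus(cluster.reads, min_overlap=min_overlap,
                                 max_reads=max_assembly_reads, seed=seed)
    longest = contigs[0]
    closure = consensus_closure(longest, min_overlap)
    monomer = estimate_monomer_length(longest.sequence)
    at = compute_at_content(longest.sequence)
    orfs = find_orfs(longest.sequence, min_aa=min_orf_aa)
    map_reads = cluster.reads
    if len(map_reads) > max_map_reads:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(map_reads), size=max_map_reads, replace=False))
        map_reads = [map_reads[i] for i in idx]
    junctions = detect_junctions(map_reads, contigs[:3], clip_threshold=clip_threshold)
    return ConsensusReport(cluster.cluster_id, contigs, monomer, at, orfs, junctions, closure)
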