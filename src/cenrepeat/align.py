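"""Pairwise read-overlap detection.

Reads are compared by the best dovetail overlap between them (either strand):
shared k-mers vote for candidate diagonal offsets, each candidate window is
scored by per-base identity, and windows falling just short of the identity
threshold are re-scored with a banded edit-distance alignment (edlib) so that
occasional indels in external data do not cost true edges.  With the
substitution-only simulator the ungapped score is already exact.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

from .simulate import encode, revcomp


@dataclass(frozen=True)
class OverlapHit:
    identity: float
    overlap_fraction: float
    offset: int          # start of b relative to start of a (a coordinates)
    strand: str          # '+' if b matched forward, '-' if reverse complement


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    d: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        d[seq[i:i + k]].append(i)
    return d


def _window_identity(a: np.ndarray, b: np.ndarray, offset: int) -> tuple[float, int]:
    """Ungapped identity of the overlap when b starts at `offset` in a's frame."""
    if offset >= 0:
        wa = a[offset:]
        wb = b[: wa.size]
        wa = wa[: wb.size]
    else:
        wb = b[-offset:]
        wa = a[: wb.size]
        wb = wb[: wa.size]
    n = wa.size
    if n == 0:
        return 0.0, 0
    return float((wa == wb).mean()), n


def _edlib_identity(a_sub: str, b_sub: str) -> float:
    if not a_sub or not b_sub:
        return 0.0
    res = edlib.align(a_sub, b_sub, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a_sub), len(b_sub))


def candidate_offsets(a_kmers: dict[str, list[int]], b_seq: str, k: int,
                      max_offsets: int = 4, stride: int = 1) -> list[int]:
    """Diagonal offsets (a_pos - b_pos) supported by shared k-mers, most-voted first."""
    votes: Counter[int] = Counter()
    for j in range(0, len(b_seq) - k + 1, stride):
        for i in a_kmers.get(b_seq[j:j + k], ()):
            votes[i - j] += 1
    return [off for off, _ in votes.most_common(max_offsets)]


def best_overlap(
    a_seq: str,
    a_arr: np.ndarray,
    a_kmers: dict[str, list[int]],
    b_seq: str,
    min_identity: float,
    min_overlap_fraction: float,
    k: int = 17,
    refine_margin: float = 0.04,
    seed_stride: int = 3,
) -> OverlapHit | None:
    """Best qualifying dovetail overlap of b (either strand) against a.

    Returns None when no strand/offset reaches both thresholds.
    """
    shorter = min(len(a_seq), len(b_seq))
    min_olap = min_overlap_fraction * shorter
    best: OverlapHit | None = None
    for strand, bs in (("+", b_seq), ("-", revcomp(b_seq))):
        b_arr = encode(bs)
        for off in candidate_offsets(a_kmers, bs, k, stride=seed_stride):
            ident, olap = _window_identity(a_arr, b_arr, off)
            if olap < min_olap:
                continue
            if ident < min_identity and ident >= min_identity - refine_margin:
                # allow indels to rescue a borderline window
                if off >= 0:
                    ident = max(ident, _edlib_identity(a_seq[off:off + olap], bs[:olap]))
                else:
                    ident = max(ident, _edlib_identity(a_seq[:olap], bs[-off:-off + olap]))
            if ident >= min_identity:
                frac = olap / shorter
                if best is None or (ident, frac) > (best.identity, best.overlap_fraction):
                    best = OverlapHit(ident, frac, off, strand)
    return best


def exhaustive_overlap(
    a_seq: str,
    b_seq: str,
    min_identity: float,
    min_overlap_fraction: float,
) -> OverlapHit | None:
    """Scan every dovetail offset on both strands (no k-mer seeding).

    Quadratic in read length; intended for small inputs and as the exact
    reference for the seeded search.
    """
    a_arr = encode(a_seq)
    shorter = min(len(a_seq), len(b_seq))
    min_olap = int(np.ceil(min_overlap_fraction * shorter))
    best: OverlapHit | None = None
    for strand, bs in (("+", b_seq), ("-", revcomp(b_seq))):
        b_arr = encode(bs)
        for off in range(-(len(bs) - min_olap), len(a_seq) - min_olap + 1):
            ident, olap = _window_identity(a_arr, b_arr, off)
            if olap < min_olap:
                continue
            if ident >= min_identity:
                frac = olap / shorter
                if best is None or (ident, frac) > (best.identity, best.overlap_fraction):
                    best = OverlapHit(ident, frac, off, strand)
    return best
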