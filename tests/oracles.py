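"""Independent reference implementations used only to check the package.

These deliberately use different algorithms/styles than the implementation:
exhaustive scans, closed-form statistics, and codon walks written from the
textbook definitions.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_overlap(a: str, b: str, min_identity: float,
                        min_overlap_fraction: float):
    """Best dovetail overlap by scanning every offset on both strands.

    Returns (identity, overlap_fraction) or None.  Pure-python reference.
    """
    shorter = min(len(a), len(b))
    min_olap = math.ceil(min_overlap_fraction * shorter)
    best = None
    for bs in (b, rc(b)):
        for off in range(-(len(bs) - min_olap), len(a) - min_olap + 1):
            if off >= 0:
                wa = a[off:off + len(bs)]
                wb = bs[:len(wa)]
            else:
                wb = bs[-off:]
                wa = a[:len(wb)]
                wb = wb[:len(wa)]
            n = min(len(wa), len(wb))
            if n < min_olap:
                continue
            matches = sum(1 for x, y in zip(wa, wb) if x == y)
            ident = matches / n
            if ident >= min_identity:
                cand = (ident, n / shorter)
                if best is None or cand > best:
                    best = cand
    return best


def brute_force_components(reads, min_identity, min_overlap_fraction):
    """Connected components from all-vs-all brute-force overlap."""
    n = len(reads)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if brute_force_overlap(reads[i].seq, reads[j].seq,
                                   min_identity, min_overlap_fraction):
                parent[find(j)] = find(i)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(reads[i].read_id)
    return sorted((frozenset(c) for c in comps.values() if len(c) >= 2),
                  key=lambda c: (-len(c), min(c)))


def six_frame_orfs(seq: str, min_aa: int):
    """Codon-walk ORF scan written independently of the implementation."""
    stops = ("TAA", "TAG", "TGA")
    found = []
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            open_starts = []
            for ci, codon in enumerate(codons):
                if codon == "ATG":
                    open_starts.append(ci)
                elif codon in stops:
                    for s0 in open_starts:
                        aa = ci - s0
                        if aa >= min_aa:
                            found.append((strand, frame, frame + 3 * s0,
                                          frame + 3 * ci, aa))
                    open_starts = []
    return sorted(found)


def students_t(a, b):
    """Two-sample equal-variance t statistic and two-tailed p, by the
    textbook formula and the t CDF from scipy.special."""
    from scipy.special import stdtr
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * (1 - stdtr(df, abs(t)))
    return t, p


def pearson_r(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def best_lag_score(seq: str, lag: int) -> float:
    """Mean per-base self-match fraction at one lag (direct loop)."""
    n = len(seq) - lag
    return sum(1 for i in range(n) if seq[i] == seq[i + lag]) / n
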