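"""Read quality control: low-complexity masking.

Satellite spacers, telomeric arrays and other simple sequence produce
promiscuous similarity hits that fuse unrelated clusters, so repeat-discovery
pipelines routinely drop reads dominated by low-complexity sequence before
clustering.  Masking here is DUST-like: trinucleotide Shannon entropy in
sliding windows.
"""

from __future__ import annotations

import math
from collections import Counter


def window_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the trinucleotide composition of `seq`."""
    n = len(seq) - 2
    if n <= 0:
        return 0.0
    counts = Counter(seq[i:i + 3] for i in range(n))
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def low_complexity_fraction(seq: str, window: int = 50, step: int = 25,
                            min_entropy: float = 3.5) -> float:
    """Fraction of the read covered by windows with trinucleotide entropy
    below `min_entropy`."""
    if len(seq) < window:
        return 1.0 if window_entropy(seq) < min_entropy else 0.0
    masked = [False] * len(seq)
    for start in range(0, len(seq) - window + 1, step):
        if window_entropy(seq[start:start + window]) < min_entropy:
            for i in range(start, start + window):
                masked[i] = True
    # make sure the trailing window is evaluated
    if (len(seq) - window) % step != 0:
        start = len(seq) - window
        if window_entropy(seq[start:]) < min_entropy:
            for i in range(start, len(seq)):
                masked[i] = True
    return sum(masked) / len(seq)


def passes_complexity_filter(seq: str, max_masked_fraction: float = 0.5, **kwargs) -> bool:
    return low_complexity_fraction(seq, **kwargs) <= max_masked_fraction
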