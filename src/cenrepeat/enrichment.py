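"""Per-cluster ChIP enrichment ratio (ER) and the selection rule.

ER for a cluster is the ratio of ChIP reads to input reads among its members.
The default is the raw count ratio; an optional normalized mode divides each
count by its library size first, for use when the two libraries differ badly
in depth.  Clusters with ER strictly greater than the threshold (default 2.0)
are called enriched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .clustering import ReadCluster


@dataclass
class EnrichmentRecord:
    cluster_id: str
    n_chip: int
    n_input: int
    er: float
    normalized: bool = False
    library_chip: int | None = None
    library_input: int | None = None
    undetermined: bool = False
    pseudocount: float = 0.5


def compute_er(
    n_chip: int,
    n_input: int,
    pseudocount: float = 0.5,
    normalize: bool = False,
    library_sizes: tuple[int, int] | None = None,
    cluster_id: str = "",
) -> EnrichmentRecord:
    """ER = chip reads / input reads for one cluster.

    The pseudocount is applied to both counts only when either count is zero,
    so typical records are untouched.  `library_sizes` is (chip, input) and is
    required in normalized mode.
    """
    if n_chip < 0 or n_input < 0:
        raise ValueError("counts must be non-negative")
    if n_chip == 0 and n_input == 0:
        return EnrichmentRecord(cluster_id, 0, 0, float("nan"),
                                normalized=normalize, undetermined=True,
                                pseudocount=pseudocount)
    c, i = float(n_chip), float(n_input)
    if n_chip == 0 or n_input == 0:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive when a count is zero")
        c += pseudocount
        i += pseudocount
    if normalize:
        if library_sizes is None:
            raise ValueError("normalized mode requires library_sizes=(chip, input)")
        lc, li = library_sizes
        er = (c / lc) / (i / li)
        return EnrichmentRecord(cluster_id, n_chip, n_input, er, True, lc, li,
                                pseudocount=pseudocount)
    return EnrichmentRecord(cluster_id, n_chip, n_input, c / i,
                            pseudocount=pseudocount)


def score_clusters(
    clusters: Sequence[ReadCluster],
    pseudocount: float = 0.5,
    normalize: bool = False,
    library_sizes: tuple[int, int] | None = None,
) -> list[EnrichmentRecord]:
    return [
        compute_er(cl.n_chip, cl.n_input, pseudocount, normalize, library_sizes,
                   cluster_id=cl.cluster_id)
        for cl in clusters
    ]


def select_enriched(
    records: Sequence[EnrichmentRecord],
    threshold: float = 2.0,
) -> tuple[list[EnrichmentRecord], pd.DataFrame]:
    """Records with ER strictly above the threshold, plus the full sorted table."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ranked = sorted((r for r in records if not r.undetermined),
                    key=lambda r: (-r.er, r.cluster_id))
    selected = [r for r in ranked if r.er > threshold]
    rows = [{
        "cluster_id": r.cluster_id, "n_input": r.n_input, "n_chip": r.n_chip,
        "ER": r.er, "selected": r.er > threshold,
    } for r in ranked]
    rows += [{
        "cluster_id": r.cluster_id, "n_input": r.n_input, "n_chip": r.n_chip,
        "ER": float("nan"), "selected": False,
    } for r in records if r.undetermined]
    return selected, pd.DataFrame(rows, columns=["cluster_id", "n_input", "n_chip", "ER", "selected"])
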