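"""Canned recovery experiments on the default study conditions.

These functions re-run the discovery pipeline on the planted fixture and
report what it recovers (satellite monomer length, consensus AT content,
cluster enrichment ratios, topology labels, split groups, qPCR relative
enrichment).  They are the backing for the package's reproducibility script
and the statistical acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .characterize import (assemble_consensus, characterize_cluster,
                           classify_topology, compute_at_content,
                           connection_analysis, estimate_monomer_length)
from .clustering import (Read, build_similarity_graph, cluster_reads,
                         filter_clusters, pool_fractions, qc_filter,
                         subsample_reads)
from .enrichment import score_clusters
from .qpcr import compute_re
from .simulate import (RepeatFamilySpec, assemble_genome, default_fixture_specs,
                       simulate_fractions, simulate_qpcr)


def default_tandem_spec() -> RepeatFamilySpec:
    return next(s for s in default_fixture_specs() if s.family_class == "tandem")


@dataclass
class TandemRecovery:
    monomer_length_bp: int | None
    at_fraction: float
    n_cluster_reads: int
    contig_length: int


def tandem_recovery(seed: int, coverage: float = 30.0,
                    unit_divergence: float = 0.02) -> TandemRecovery:
    """Monomer-length and AT-content recovery for the planted satellite.

    The satellite family (unit length and composition from the default
    fixture spec, 200 copies, 2% per-unit divergence) is planted in a short
    background chromosome, sequenced as 2x300 bp pairs at the requested
    coverage, clustered, and assembled; the period and AT fraction are
    measured on the longest consensus contig.
    """
    spec = default_tandem_spec()
    spec = RepeatFamilySpec(spec.family_id, "tandem", spec.unit_length_bp,
                            spec.copy_number, spec.at_fraction, unit_divergence,
                            enrichment_factor=1.0)
    chrom = spec.total_length_bp + 9000  # two flanks + gaps
    fixture = assemble_genome([spec], chrom, seed=seed)
    lib, _ = simulate_fractions(fixture, coverage, 0.01, seed=seed + 1)
    reads = qc_filter([Read(rid, s, frac, fam)
                       for rid, s, fam, frac in lib.iter_single_reads()])
    clusters = cluster_reads(reads, total_reads=len(reads))
    cl = next(c for c in clusters if c.majority_family == spec.family_id)
    contigs = assemble_consensus(cl.reads, max_reads=300, seed=seed + 2)
    longest = contigs[0]
    return TandemRecovery(
        estimate_monomer_length(longest.sequence),
        compute_at_content(longest.sequence),
        cl.size,
        len(longest),
    )


@dataclass
class DiscoveryRun:
    seed: int
    er_by_cluster: dict[str, float]
    family_by_cluster: dict[str, str]
    size_by_cluster: dict[str, int]
    topology_by_cluster: dict[str, str] = field(default_factory=dict)
    split_group_families: list[list[str]] = field(default_factory=list)

    def er_of_family(self, family_id: str) -> float | None:
        """ER of the largest cluster whose majority truth label is the family."""
        best = None
        for cid, fam in self.family_by_cluster.items():
            if fam == family_id and cid in self.er_by_cluster:
                if best is None or self.size_by_cluster[cid] > self.size_by_cluster[best]:
                    best = cid
        return None if best is None else self.er_by_cluster[best]


def discovery_run(seed: int, coverage: float = 1.6, with_topology: bool = False,
                  with_connections: bool = False, topology_max_nodes: int = 120,
                  min_topology_reads: int = 50) -> DiscoveryRun:
    """One full clustering + ER pass over the default fixture.

    Optionally also classifies cluster topologies (clusters holding at least
    `min_topology_reads` reads) and runs the inter-cluster connection
    analysis.
    """
    fixture = assemble_genome(default_fixture_specs(), 300_000, seed=seed)
    inp, chip = simulate_fractions(fixture, coverage, coverage, seed=seed + 100)
    pooled = qc_filter(pool_fractions(inp, chip))
    pooled = subsample_reads(pooled, 24_000, seed=seed + 200)
    clusters = cluster_reads(pooled, total_reads=len(pooled))
    retained, _ = filter_clusters(clusters, len(pooled))
    records = score_clusters(retained)

    run = DiscoveryRun(
        seed=seed,
        er_by_cluster={r.cluster_id: r.er for r in records if not r.undetermined},
        family_by_cluster={c.cluster_id: c.majority_family for c in retained},
        size_by_cluster={c.cluster_id: c.size for c in retained},
    )

    focus = [c for c in retained if c.size >= min_topology_reads]
    if with_topology:
        for cl in focus:
            rep = characterize_cluster(cl, max_assembly_reads=150, seed=seed + 300)
            sub = subsample_reads(cl.reads, topology_max_nodes, seed=seed + 400)
            sg = build_similarity_graph(sub)
            comp = max(nx.connected_components(sg.graph), key=len)
            top = classify_topology(sg.graph.subgraph(comp).copy(),
                                    closure=rep.closure, cluster_id=cl.cluster_id,
                                    seed=seed + 500)
            run.topology_by_cluster[cl.cluster_id] = top.label

    if with_connections:
        conn_clusters = [c for c in retained if c.size >= 20]
        contigs_by = {c.cluster_id: assemble_consensus(c.reads, max_reads=150,
                                                       seed=seed + 300)
                      for c in conn_clusters}
        table = connection_analysis(conn_clusters, contigs_by)
        fam = run.family_by_cluster
        run.split_group_families = [sorted(fam[c] for c in g)
                                    for g in table.split_groups]
    return run


def er_recovery(n_seeds: int = 10, base_seed: int = 1) -> list[float]:
    """Raw ER of the satellite-majority cluster over independent fixtures."""
    ers = []
    for s in range(n_seeds):
        run = discovery_run(base_seed + s)
        er = run.er_of_family("sat187")
        if er is not None:
            ers.append(er)
    return ers


def re_recovery(true_ratio: float = 370.0, n_seeds: int = 10,
                base_seed: int = 1, ct_noise_sd: float = 0.15,
                n_replicates: int = 4) -> list[float]:
    """Mean qPCR RE recovered from simulated plates with a known truth ratio."""
    res = []
    for s in range(n_seeds):
        plate = simulate_qpcr(true_ratio, 1.0, efficiency=1.0,
                              ct_noise_sd=ct_noise_sd,
                              n_replicates=n_replicates, seed=base_seed + s)
        res.append(compute_re(plate, "target").re)
    return res


def null_er_fractions(n_seeds: int = 20, base_seed: int = 1,
                      min_cluster_size: int = 200,
                      threshold: float = 2.0) -> tuple[int, int]:
    """Null calibration: with no enrichment anywhere, how many large clusters
    exceed the ER threshold?  Returns (n_exceeding, n_evaluated)."""
    spec = RepeatFamilySpec("sat", "tandem", 187, 100, at_fraction=0.583,
                            divergence=0.02, enrichment_factor=1.0)
    exceeding = evaluated = 0
    for s in range(n_seeds):
        fixture = assemble_genome([spec], 50_000, seed=base_seed + s)
        inp, chip = simulate_fractions(fixture, 1.8, 1.8, seed=base_seed + s + 1000)
        pooled = qc_filter(pool_fractions(inp, chip))
        clusters = cluster_reads(pooled, total_reads=len(pooled))
        records = score_clusters([c for c in clusters if c.size >= min_cluster_size])
        for r in records:
            if r.undetermined:
                continue
            evaluated += 1
            if r.er > threshold:
                exceeding += 1
    return exceeding, evaluated
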