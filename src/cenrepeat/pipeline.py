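"""One-command orchestration: fixture -> reads -> clusters -> ER -> characterization -> qPCR.

Each stage consumes and produces only declared file formats, so stages are
independently testable; `run_all` chains them and writes a manifest with the
config snapshot, every derived seed and the digest of every output file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import (ConnectionTable, ConsensusReport, TopologyReport,
                           assemble_consensus, characterize_cluster,
                           classify_topology, connection_analysis)
from .clustering import (Read, ReadCluster, build_similarity_graph, cluster_reads,
                         filter_clusters, pool_fractions, qc_filter, subsample_reads)
from .config import RunConfig
from .enrichment import EnrichmentRecord, score_clusters, select_enriched
from .io import (sha256_of, write_bed, write_ct_table, write_fasta,
                 write_fastq_pair, write_json, write_truth_table)
from .qpcr import correlate_er_re, validate_targets
from .simulate import (GenomeFixture, assemble_genome, combine_plates,
                       simulate_fractions, simulate_qpcr)

logger = logging.getLogger("cenrepeat")

NEG_CONTROL_ID = "neg_control"


def stage_seed(master_seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed * 1_000_003 + stage * 7919 + 17) % (2**31)


@dataclass
class RunResult:
    outdir: Path
    fixture: GenomeFixture
    pooled_reads: list[Read]
    clusters: list[ReadCluster]
    retained: list[ReadCluster]
    er_records: list[EnrichmentRecord]
    selected: list[EnrichmentRecord]
    er_table: pd.DataFrame
    topologies: dict[str, TopologyReport] = field(default_factory=dict)
    reports: dict[str, ConsensusReport] = field(default_factory=dict)
    connections: ConnectionTable | None = None
    qpcr_results: pd.DataFrame | None = None
    concordance_r: float | None = None
    manifest: dict = field(default_factory=dict)


def simulate_stage(cfg: RunConfig, seed: int, outdir: Path | None = None):
    fixture = assemble_genome(
        [f.to_spec() for f in cfg.fixture.families],
        cfg.fixture.chrom_length,
        seed=stage_seed(seed, 1),
        chrom_name=cfg.fixture.chrom_name,
        min_gap=cfg.fixture.min_gap,
    )
    input_lib, chip_lib = simulate_fractions(
        fixture,
        cfg.reads.coverage_input,
        cfg.reads.coverage_chip,
        read_length_bp=cfg.reads.read_length_bp,
        insert_mean=cfg.reads.insert_mean_bp,
        insert_sd=cfg.reads.insert_sd_bp,
        seed=stage_seed(seed, 2),
        error_rate=cfg.reads.error_rate,
    )
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(fixture.sequences, outdir / "genome.fasta")
        if fixture.consensi:
            write_fasta(fixture.consensi, outdir / "family_consensus.fasta")
        write_bed(fixture, outdir / "features.bed")
        write_fastq_pair(input_lib, outdir / "input_R1.fastq", outdir / "input_R2.fastq")
        write_fastq_pair(chip_lib, outdir / "chip_R1.fastq", outdir / "chip_R2.fastq")
        write_truth_table([input_lib, chip_lib], outdir / "read_truth.tsv")
    return fixture, input_lib, chip_lib


def cluster_stage(cfg: RunConfig, pooled: list[Read], seed: int,
                  outdir: Path | None = None):
    kept = qc_filter(pooled, cfg.clustering.max_masked_fraction)
    logger.info("QC: %d of %d reads pass the low-complexity filter", len(kept), len(pooled))
    kept = subsample_reads(kept, cfg.clustering.max_reads, seed=stage_seed(seed, 3))
    clusters = cluster_reads(
        kept,
        min_identity=cfg.clustering.min_identity,
        min_overlap_fraction=cfg.clustering.min_overlap_fraction,
        k=cfg.clustering.kmer_size,
        total_reads=len(kept),
    )
    retained, dropped = filter_clusters(clusters, len(kept),
                                        cfg.clustering.min_cluster_proportion)
    logger.info("clustering: %d clusters, %d retained", len(clusters), len(retained))
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [{"cluster_id": c.cluster_id, "size": c.size, "n_input": c.n_input,
                 "n_chip": c.n_chip, "proportion": c.proportion,
                 "retained": c in retained} for c in clusters]
        pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    return kept, clusters, retained


def enrich_stage(cfg: RunConfig, retained: list[ReadCluster],
                 library_sizes: tuple[int, int] | None,
                 outdir: Path | None = None):
    records = score_clusters(retained, pseudocount=cfg.enrichment.pseudocount,
                             normalize=cfg.enrichment.normalize,
                             library_sizes=library_sizes)
    selected, table = select_enriched(records, cfg.enrichment.threshold)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        write_json({"threshold": cfg.enrichment.threshold,
                    "normalize": cfg.enrichment.normalize,
                    "pseudocount": cfg.enrichment.pseudocount,
                    "n_selected": len(selected)}, outdir / "enrichment_summary.json")
    return records, selected, table


def characterize_stage(cfg: RunConfig, retained: list[ReadCluster],
                       selected: list[EnrichmentRecord], seed: int,
                       outdir: Path | None = None):
    ch = cfg.characterization
    by_id = {c.cluster_id: c for c in retained}
    focus_ids = [r.cluster_id for r in selected[:ch.max_characterized]]

    topologies: dict[str, TopologyReport] = {}
    reports: dict[str, ConsensusReport] = {}
    for cid in focus_ids:
        cl = by_id[cid]
        if cl.size < ch.min_topology_reads:
            continue
        rep = characterize_cluster(
            cl,
            min_overlap=ch.assembly_min_overlap,
            max_assembly_reads=ch.max_assembly_reads,
            min_orf_aa=ch.min_orf_aa,
            clip_threshold=ch.clip_threshold,
            seed=stage_seed(seed, 4),
        )
        reports[cid] = rep
        sub = subsample_reads(cl.reads, ch.topology_max_nodes,
                              seed=stage_seed(seed, 5))
        sg = build_similarity_graph(sub, cfg.clustering.min_identity,
                                    cfg.clustering.min_overlap_fraction,
                                    k=cfg.clustering.kmer_size)
        import networkx as nx
        comp = max(nx.connected_components(sg.graph), key=len)
        topologies[cid] = classify_topology(
            sg.graph.subgraph(comp).copy(), closure=rep.closure, cluster_id=cid,
            seed=stage_seed(seed, 6))

    conn_clusters = [c for c in retained if c.size >= ch.min_topology_reads]
    connections = None
    if len(conn_clusters) >= 2:
        contigs_by = {}
        for c in conn_clusters:
            if c.cluster_id in reports:
                contigs_by[c.cluster_id] = reports[c.cluster_id].contigs
            else:
                contigs_by[c.cluster_id] = assemble_consensus(
                    c.reads, min_overlap=ch.assembly_min_overlap,
                    max_reads=ch.max_assembly_reads, seed=stage_seed(seed, 4))
        connections = connection_analysis(conn_clusters, contigs_by,
                                          link_threshold=ch.link_threshold,
                                          join_on=ch.join_on)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for cid in focus_ids:
            if cid not in reports:
                continue
            rep, top = reports[cid], topologies[cid]
            rows.append({
                "cluster_id": cid, "label": top.label,
                "monomer_bp": rep.monomer_length_bp if rep.monomer_length_bp else "NA",
                "at_fraction": round(rep.at_fraction, 4),
                "n_orfs": len(rep.orfs), "n_junctions": len(rep.junctions),
                "closure": rep.closure, "n_contigs": len(rep.contigs),
            })
        pd.DataFrame(rows).to_csv(outdir / "characterization.tsv", sep="\t", index=False)
        consensi = {f"{cid}_contig{i}": ctg.sequence
                    for cid, rep in reports.items()
                    for i, ctg in enumerate(rep.contigs[:3])}
        if consensi:
            write_fasta(consensi, outdir / "cluster_consensus.fasta")
        if connections is not None:
            pd.DataFrame(connections.rows,
                         columns=["cluster_a", "cluster_b", "n_mate_links",
                                  "n_end_similarity_hits"]).to_csv(
                outdir / "connections.tsv", sep="\t", index=False)
            write_json({"split_groups": [sorted(g) for g in connections.split_groups]},
                       outdir / "split_groups.json")
        for cid in focus_ids:
            cl = by_id.get(cid)
            if cid in topologies and cl is not None:
                sub = subsample_reads(cl.reads, ch.topology_max_nodes,
                                      seed=stage_seed(seed, 5))
                sg = build_similarity_graph(sub, cfg.clustering.min_identity,
                                            cfg.clustering.min_overlap_fraction,
                                            k=cfg.clustering.kmer_size)
                with open(outdir / f"edges_{cid}.tsv", "w") as fh:
                    fh.write("read_a\tread_b\tidentity\toverlap_fraction\n")
                    for a, b, d in sorted(sg.graph.edges(data=True)):
                        fh.write(f"{a}\t{b}\t{d['identity']:.4f}\t{d['overlap_fraction']:.4f}\n")
    return topologies, reports, connections


def qpcr_stage(cfg: RunConfig, fixture: GenomeFixture, retained: list[ReadCluster],
               selected: list[EnrichmentRecord], seed: int,
               outdir: Path | None = None):
    """Simulate validation plates for the top enriched clusters and test them.

    The true antibody/mock abundance ratio of each target is the planted
    enrichment factor of the cluster's majority family (fixture truth); the
    negative control is an unenriched single-copy target with true ratio 1.
    """
    q = cfg.qpcr
    by_id = {c.cluster_id: c for c in retained}
    targets = [r.cluster_id for r in selected[:q.n_targets]]
    if not targets:
        return None, None, None
    plates = []
    for i, cid in enumerate(targets):
        fam = by_id[cid].majority_family
        spec = fixture.spec_by_id(fam)
        ratio = spec.enrichment_factor if spec else 1.0
        plates.append(simulate_qpcr(ratio, 1.0, q.efficiency, q.ct_noise_sd,
                                    q.n_replicates, seed=stage_seed(seed, 7 + i),
                                    target_id=cid))
    plates.append(simulate_qpcr(1.0, 1.0, q.efficiency, q.ct_noise_sd,
                                q.n_replicates, seed=stage_seed(seed, 7 + len(targets)),
                                target_id=NEG_CONTROL_ID))
    plate = combine_plates(plates)
    results = validate_targets(plate, targets, NEG_CONTROL_ID, q.efficiency)
    er_by_id = {r.cluster_id: r.er for r in selected}
    re_by_id = {r.target_id: r.re for r in results}
    conc = correlate_er_re({t: er_by_id[t] for t in targets}, re_by_id)

    rows = [{"target_id": r.target_id, "RE": r.re, "t": r.t_statistic,
             "p": r.p_value, "significant": (r.p_value is not None and r.p_value < 0.01)}
            for r in results]
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_ct_table(plate, outdir / "qpcr_ct.tsv")
        df.to_csv(outdir / "qpcr_results.tsv", sep="\t", index=False)
        write_json({"r": conc.r, "undefined": conc.undefined,
                    "pairs": [{"target_id": t, "er": e, "re": re}
                              for t, e, re in conc.pairs]},
                   outdir / "concordance.json")
    return df, conc, plate


def run_all(cfg: RunConfig, seed: int, outdir: str | Path) -> RunResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fixture, input_lib, chip_lib = simulate_stage(cfg, seed, outdir)
    pooled = pool_fractions(input_lib, chip_lib)
    kept, clusters, retained = cluster_stage(cfg, pooled, seed, outdir)
    lib_sizes = (sum(1 for r in kept if r.fraction == "chip"),
                 sum(1 for r in kept if r.fraction == "input"))
    records, selected, table = enrich_stage(cfg, retained, lib_sizes, outdir)
    topologies, reports, connections = characterize_stage(cfg, retained, selected,
                                                          seed, outdir)
    qpcr_df, conc, _plate = qpcr_stage(cfg, fixture, retained, selected, seed, outdir)

    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {f"stage_{i}": stage_seed(seed, i) for i in range(1, 8)},
        "config": cfg.model_dump(),
        "library_pairs": {"input": len(input_lib), "chip": len(chip_lib)},
        "pooled_reads": len(pooled),
        "reads_after_qc_and_cap": len(kept),
        "n_clusters": len(clusters),
        "n_retained": len(retained),
        "n_selected": len(selected),
        "concordance_r": None if conc is None or conc.undefined else conc.r,
        "files": {},
    }
    for p in sorted(outdir.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = sha256_of(p)
    write_json(manifest, outdir / "manifest.json")

    return RunResult(outdir, fixture, pooled, clusters, retained, records, selected,
                     table, topologies, reports, connections, qpcr_df,
                     None if conc is None or conc.undefined else conc.r, manifest)
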