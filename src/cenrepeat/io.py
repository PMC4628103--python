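"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; BED6, cluster/ER/characterization tables
and Ct tables are plain TSV via pandas.  All writers are deterministic given
their inputs, so run manifests can carry file digests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clustering import Read
from .simulate import FractionLibrary, GenomeFixture, QPCRPlate


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(fixture: GenomeFixture, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fixture.features:
            name = f.name or f.family_id
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name", "score", "strand"])


def write_fastq_pair(lib: FractionLibrary, path1: str | Path, path2: str | Path) -> None:
    """Two FASTQ files (Phred+33), one per mate."""
    recs1, recs2 = [], []
    for pr in lib.reads:
        r1 = SeqRecord(Seq(pr.seq1), id=f"{pr.read_id}/1", description="")
        r1.letter_annotations["phred_quality"] = [ord(c) - 33 for c in pr.qual1]
        r2 = SeqRecord(Seq(pr.seq2), id=f"{pr.read_id}/2", description="")
        r2.letter_annotations["phred_quality"] = [ord(c) - 33 for c in pr.qual2]
        recs1.append(r1)
        recs2.append(r2)
    SeqIO.write(recs1, str(path1), "fastq")
    SeqIO.write(recs2, str(path2), "fastq")


def read_fastq_pair(path1: str | Path, path2: str | Path, fraction: str,
                    truth: dict[str, str] | None = None) -> list[Read]:
    """Load both mates of one fraction as single tagged reads.

    `truth` optionally maps pair ids to true family ids (fixture runs only).
    """
    reads = []
    for path in (path1, path2):
        for rec in SeqIO.parse(str(path), "fastq"):
            stem = rec.id.rsplit("/", 1)[0]
            fam = truth.get(stem, "none") if truth else "none"
            reads.append(Read(rec.id, str(rec.seq), fraction, fam))
    return reads


def write_truth_table(libs: Sequence[FractionLibrary], path: str | Path) -> None:
    rows = [{"read_id": pr.read_id, "fraction": lib.fraction,
             "true_family_id": pr.true_family_id}
            for lib in libs for pr in lib.reads]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.read_id, df.true_family_id))


def write_ct_table(plate: QPCRPlate, path: str | Path) -> None:
    plate.table.to_csv(path, sep="\t", index=False,
                       columns=["target_id", "fraction", "replicate", "ct"])


def read_ct_table(path: str | Path, efficiency: float, n_replicates: int) -> QPCRPlate:
    return QPCRPlate(pd.read_csv(path, sep="\t"), efficiency, n_replicates)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
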