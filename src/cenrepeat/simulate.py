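"""Synthetic genomes, ChIP/input read libraries and qPCR plates with known truth.

The generator emulates the repeat landscape the downstream analysis is built
for: a chromosome-specific AT-rich satellite with a short monomer, a dispersed
LINE-like family whose copies are only ~60% similar to each other (so each
insertion seeds its own read cluster), an LTR element with detectable
insertion junctions, a long-monomer rDNA-like satellite whose conserved genes
are separated by low-complexity spacers (the configuration that makes
similarity clustering split it into connected daughter clusters), and
single-copy background.  ChIP enrichment is modeled as a per-family sampling
weight on fragment midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

FamilyClass = Literal["tandem", "line_like", "ltr", "rdna_like", "background"]

STOP_CODONS = {"TAA", "TAG", "TGA"}


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return _COMP[encode(seq)][::-1].tobytes().decode()


def _random_seq(n: int, rng: np.random.Generator, at_fraction: float = 0.5) -> str:
    """Random sequence with expected AT fraction (uniform within AT and GC)."""
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return decode(rng.choice(np.frombuffer(b"ATGC", dtype=np.uint8),
                             size=n, p=[p_at, p_at, p_gc, p_gc]))


def _exact_composition_seq(n: int, at_fraction: float, rng: np.random.Generator) -> str:
    """Random sequence whose A+T count is round(at_fraction * n) exactly."""
    n_at = int(round(at_fraction * n))
    n_gc = n - n_at
    arr = np.concatenate([
        np.full((n_at + 1) // 2, ord("A"), dtype=np.uint8),
        np.full(n_at // 2, ord("T"), dtype=np.uint8),
        np.full((n_gc + 1) // 2, ord("G"), dtype=np.uint8),
        np.full(n_gc // 2, ord("C"), dtype=np.uint8),
    ])
    rng.shuffle(arr)
    return decode(arr)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently at `rate`, always to a different base."""
    if rate <= 0:
        return seq
    arr = encode(seq)
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        # offset 1..3 within the base alphabet guarantees a change
        lut = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        shifted = (lut[arr[idx]] + rng.integers(1, 4, size=idx.size)) % 4
        arr[idx] = BASES[shifted]
    return decode(arr)


def pairwise_mutation_rate(target_divergence: float) -> float:
    """Per-copy substitution rate so two copies show the target pairwise divergence.

    Each copy is mutated independently from a master at rate p; two copies then
    match per site with probability (1-p)^2 + p^2/3, which is solved for the
    requested expected pairwise divergence.
    """
    d = float(target_divergence)
    if d <= 0:
        return 0.0
    # (4/3) p^2 - 2 p + d = 0, smaller root
    disc = 4.0 - (16.0 / 3.0) * d
    if disc < 0:
        raise ValueError("pairwise divergence too large to realize with substitutions")
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RepeatFamilySpec:
    """Parameterization of one planted repeat family.

    enrichment_factor is the relative ChIP sampling weight of fragments whose
    midpoint falls in a copy of this family (1.0 = unenriched background).
    """

    family_id: str
    family_class: FamilyClass
    unit_length_bp: int
    copy_number: int
    at_fraction: float = 0.5
    divergence: float = 0.0
    enrichment_factor: float = 1.0
    orf_length_nt: int = 0
    ltr_length_bp: int = 150
    spacer_length_bp: int = 400  # rdna_like only: low-complexity spacer per half-monomer

    def __post_init__(self) -> None:
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError(f"at_fraction must be in [0,1], got {self.at_fraction}")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"divergence must be in [0,1], got {self.divergence}")
        if self.unit_length_bp < 1:
            raise ValueError("unit_length_bp must be positive")
        if self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be positive")
        if self.orf_length_nt and self.orf_length_nt % 3 != 0:
            raise ValueError("orf_length_nt must be a multiple of 3")

    @property
    def arrangement(self) -> str:
        return "array" if self.family_class in ("tandem", "rdna_like") else "dispersed"

    @property
    def total_length_bp(self) -> int:
        return self.unit_length_bp * self.copy_number


@dataclass
class Feature:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    family_id: str
    strand: str = "+"
    name: str = ""


@dataclass
class GenomeFixture:
    """A synthetic genome with its planted-repeat annotation and provenance."""

    sequences: dict[str, str]
    features: list[Feature]
    specs: list[RepeatFamilySpec]
    seed: int
    consensi: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def family_of_position(self, chrom: str, pos: int) -> str:
        for f in self.features:
            if f.chrom == chrom and f.start <= pos < f.end:
                return f.family_id
        return "none"

    def spec_by_id(self, family_id: str) -> Optional[RepeatFamilySpec]:
        for s in self.specs:
            if s.family_id == family_id:
                return s
        return None


@dataclass
class PairedRead:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    true_family_id: str = "none"


@dataclass
class FractionLibrary:
    """All read pairs of one sequencing fraction (input or chip)."""

    fraction: Literal["input", "chip"]
    reads: list[PairedRead]
    read_length_bp: int
    insert_mean_bp: float
    insert_sd_bp: float
    seed: int

    def __len__(self) -> int:
        return len(self.reads)

    def iter_single_reads(self):
        """Yield (read_id, seq, true_family, fraction) for each mate."""
        for pr in self.reads:
            yield (f"{pr.read_id}/1", pr.seq1, pr.true_family_id, self.fraction)
            yield (f"{pr.read_id}/2", pr.seq2, pr.true_family_id, self.fraction)


@dataclass
class QPCRPlate:
    """Long-format Ct table: one row per (target, fraction, replicate) well."""

    table: pd.DataFrame  # columns: target_id, fraction, replicate, ct
    efficiency: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        counts = self.table.groupby(["target_id", "fraction"]).size()
        if not (counts == self.n_replicates).all():
            raise ValueError("every (target, fraction) must have exactly n_replicates wells")


# ---------------------------------------------------------------------------
# Sequence-family generators
# ---------------------------------------------------------------------------

def generate_tandem_array(
    unit_length_bp: int,
    copy_number: int,
    at_fraction: float = 0.5,
    divergence: float = 0.0,
    seed: int | None = None,
    consensus: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Build a head-to-tail satellite array.

    Returns (consensus, array_sequence) where the array is `copy_number`
    copies of the consensus, each independently mutated at `divergence`.
    The consensus base composition matches at_fraction exactly (by count).
    """
    if unit_length_bp < 2:
        raise ValueError("unit_length_bp must be >= 2")
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must be in [0,1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if consensus is None:
        consensus = _exact_composition_seq(unit_length_bp, at_fraction, rng)
    elif len(consensus) != unit_length_bp:
        raise ValueError("consensus length must equal unit_length_bp")
    copies = [mutate(consensus, divergence, rng) for _ in range(copy_number)]
    return consensus, "".join(copies)


def _orf_sequence(orf_length_nt: int, rng: np.random.Generator) -> str:
    """ATG-initiated reading frame of exactly orf_length_nt (stop excluded),
    immediately followed by TAA."""
    n_codons = orf_length_nt // 3 - 1  # codons after the start codon
    codons = ["ATG"]
    while len(codons) < n_codons + 1:
        c = _random_seq(3, rng)
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons) + "TAA"


def build_line_master(spec: RepeatFamilySpec, rng: np.random.Generator) -> str:
    """Master LINE-like element: random body with an embedded intact ORF."""
    if spec.orf_length_nt <= 0:
        raise ValueError("line_like spec requires orf_length_nt > 0")
    orf = _orf_sequence(spec.orf_length_nt, rng)
    flank = spec.unit_length_bp - len(orf)
    if flank < 0:
        raise ValueError("unit_length_bp too short for the requested ORF")
    left = flank // 3
    right = flank - left
    return _random_seq(left, rng, spec.at_fraction) + orf + _random_seq(right, rng, spec.at_fraction)


def build_ltr_master(spec: RepeatFamilySpec, rng: np.random.Generator) -> tuple[str, str]:
    """Master LTR element: (ltr, body); full element is ltr + body + ltr."""
    body_len = spec.unit_length_bp - 2 * spec.ltr_length_bp
    if body_len < 1:
        raise ValueError("unit_length_bp must exceed twice ltr_length_bp")
    return _random_seq(spec.ltr_length_bp, rng, spec.at_fraction), _random_seq(body_len, rng, spec.at_fraction)


def generate_dispersed_family(
    spec: RepeatFamilySpec,
    n_subcopies: int,
    inter_copy_divergence: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Variants of a master element with the requested mean pairwise divergence.

    For ltr specs every copy carries two identical terminal repeats (the copy's
    own LTR, mutated once and used at both ends, as in a young insertion).
    """
    if spec.family_class not in ("line_like", "ltr"):
        raise ValueError("dispersed generation applies to line_like/ltr specs")
    rng = rng if rng is not None else np.random.default_rng(seed)
    p = pairwise_mutation_rate(inter_copy_divergence)
    if spec.family_class == "line_like":
        master = build_line_master(spec, rng)
        return [mutate(master, p, rng) for _ in range(n_subcopies)]
    ltr, body = build_ltr_master(spec, rng)
    copies = []
    for _ in range(n_subcopies):
        my_ltr = mutate(ltr, p, rng)
        my_body = mutate(body, p, rng)
        copies.append(my_ltr + my_body + my_ltr)
    return copies


def build_rdna_monomer(spec: RepeatFamilySpec, rng: np.random.Generator) -> str:
    """Long monomer with rDNA architecture: two conserved blocks, each followed
    by a low-complexity (AT)n intergenic spacer."""
    s = spec.spacer_length_bp
    block_len = (spec.unit_length_bp - 2 * s) // 2
    rem = spec.unit_length_bp - 2 * s - 2 * block_len
    block_a = _random_seq(block_len + rem, rng, spec.at_fraction)
    block_b = _random_seq(block_len, rng, spec.at_fraction)
    spacer = mutate("AT" * (s // 2) + "A" * (s % 2), 0.02, rng)
    spacer2 = mutate("AT" * (s // 2) + "A" * (s % 2), 0.02, rng)
    return block_a + spacer + block_b + spacer2


def _rdna_copy(monomer: str, spec: RepeatFamilySpec, rng: np.random.Generator) -> str:
    """One monomer copy: conserved blocks mutate at `divergence`; the spacers
    (fast-evolving in real rDNA) mutate ten times faster, capped at 0.3."""
    s = spec.spacer_length_bp
    # segment boundaries as laid out by build_rdna_monomer
    ba = len(monomer) - 2 * s - (len(monomer) - 2 * s) // 2
    bb = (len(monomer) - 2 * s) // 2
    # spacers evolve faster than the genes but stay simple sequence
    spacer_rate = min(0.1, spec.divergence * 2)
    i = 0
    parts = []
    for seg_len, rate in ((ba, spec.divergence), (s, spacer_rate), (bb, spec.divergence), (s, spacer_rate)):
        parts.append(mutate(monomer[i:i + seg_len], rate, rng))
        i += seg_len
    return "".join(parts)


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def default_fixture_specs() -> list[RepeatFamilySpec]:
    """The study conditions: one spec per emulated repeat family."""
    return [
        RepeatFamilySpec("sat187", "tandem", 187, 200, at_fraction=0.583,
                         divergence=0.02, enrichment_factor=52.0),
        RepeatFamilySpec("line1", "line_like", 2100, 20, at_fraction=0.5,
                         divergence=0.40, enrichment_factor=15.0, orf_length_nt=429),
        RepeatFamilySpec("ltr1", "ltr", 1200, 8, at_fraction=0.5,
                         divergence=0.03, enrichment_factor=2.5, ltr_length_bp=150),
        RepeatFamilySpec("rdna", "rdna_like", 5000, 8, at_fraction=0.5,
                         divergence=0.002, enrichment_factor=1.0, spacer_length_bp=400),
    ]


def assemble_genome(
    specs: Sequence[RepeatFamilySpec],
    chrom_length: int,
    spacing_model: str = "uniform",
    seed: int = 0,
    chrom_name: str = "chr1",
    min_gap: int = 3000,
) -> GenomeFixture:
    """Plant every family into a random background chromosome.

    Array families (tandem, rdna_like) are placed as one contiguous block with
    a single BED feature; dispersed families get one feature per copy, on a
    random strand.  Background is uniform 25% per base.
    """
    if spacing_model != "uniform":
        raise ValueError("only the uniform spacing model is implemented")
    rng = np.random.default_rng(seed)
    consensi: dict[str, str] = {}

    blocks: list[tuple[str, str, str]] = []  # (family_id, sequence, strand)
    for spec in specs:
        if spec.copy_number == 0 or spec.family_class == "background":
            continue
        if spec.family_class == "tandem":
            cons, arr = generate_tandem_array(
                spec.unit_length_bp, spec.copy_number, spec.at_fraction,
                spec.divergence, rng=rng)
            consensi[spec.family_id] = cons
            blocks.append((spec.family_id, arr, "+"))
        elif spec.family_class == "rdna_like":
            monomer = build_rdna_monomer(spec, rng)
            consensi[spec.family_id] = monomer
            arr = "".join(_rdna_copy(monomer, spec, rng) for _ in range(spec.copy_number))
            blocks.append((spec.family_id, arr, "+"))
        else:
            copies = generate_dispersed_family(spec, spec.copy_number, spec.divergence, rng=rng)
            if spec.family_class == "line_like":
                consensi[spec.family_id] = build_line_master(spec, np.random.default_rng(seed + 1))
            for cp in copies:
                strand = "+" if rng.random() < 0.5 else "-"
                blocks.append((spec.family_id, cp if strand == "+" else revcomp(cp), strand))

    planted = sum(len(b[1]) for b in blocks)
    n_gaps = len(blocks) + 1
    free = chrom_length - planted - n_gaps * min_gap
    if free < 0:
        raise ValueError(
            f"planted repeats ({planted} bp + gaps) exceed chrom_length {chrom_length}")

    order = rng.permutation(len(blocks))
    # random gap sizes: min_gap plus a random split of the free background
    cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1)) if n_gaps > 1 else np.array([], dtype=int)
    gap_sizes = np.diff(np.concatenate([[0], cuts, [free]])) + min_gap

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    copy_counter: dict[str, int] = {}
    for i, bi in enumerate(order):
        g = int(gap_sizes[i])
        parts.append(_random_seq(g, rng))
        pos += g
        fam, seqblk, strand = blocks[bi]
        k = copy_counter.get(fam, 0)
        copy_counter[fam] = k + 1
        features.append(Feature(chrom_name, pos, pos + len(seqblk), fam, strand,
                                name=f"{fam}.{k}"))
        parts.append(seqblk)
        pos += len(seqblk)
    parts.append(_random_seq(int(gap_sizes[-1]), rng))
    genome = "".join(parts)
    assert len(genome) == chrom_length

    features.sort(key=lambda f: f.start)
    return GenomeFixture({chrom_name: genome}, features, list(specs), seed, consensi)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_sequencing_error(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0:
        return seqs
    return [mutate(s, rate, rng) for s in seqs]


def simulate_fractions(
    fixture: GenomeFixture,
    coverage_input: float,
    coverage_chip: float,
    read_length_bp: int = 300,
    insert_mean: float = 700.0,
    insert_sd: float = 120.0,
    seed: int = 0,
    error_rate: float = 0.001,
) -> tuple[FractionLibrary, FractionLibrary]:
    """Draw paired-end libraries for the input and ChIP fractions.

    Input fragments fall uniformly on the genome.  ChIP fragments are drawn
    with weight equal to the enrichment factor of the family at the fragment
    midpoint (1.0 on background), and the ChIP library size scales with the
    genome-average weight, so at equal nominal coverage the expected per-family
    chip/input read ratio equals the planted enrichment factor exactly.
    """
    if coverage_input <= 0 or coverage_chip <= 0:
        raise ValueError("coverages must be positive")
    if read_length_bp > insert_mean:
        raise ValueError("read_length_bp must not exceed insert_mean")
    chrom = next(iter(fixture.sequences))
    genome = fixture.sequences[chrom]
    g = len(genome)
    garr = encode(genome)

    weight = np.ones(g, dtype=np.float64)
    fam_at = np.full(g, -1, dtype=np.int64)
    fam_ids = ["none"] + [s.family_id for s in fixture.specs]
    fam_index = {fid: i for i, fid in enumerate(fam_ids)}
    for f in fixture.features:
        spec = fixture.spec_by_id(f.family_id)
        weight[f.start:f.end] = spec.enrichment_factor if spec else 1.0
        fam_at[f.start:f.end] = fam_index[f.family_id]
    mean_w = float(weight.mean())

    rng = np.random.default_rng(seed)
    n_input = int(round(coverage_input * g / (2 * read_length_bp)))
    n_chip = int(round(coverage_chip * g / (2 * read_length_bp) * mean_w))

    def draw(fraction: str, n_pairs: int, weighted: bool) -> FractionLibrary:
        if weighted:
            p = weight / weight.sum()
            mids = rng.choice(g, size=n_pairs, p=p)
        else:
            mids = rng.integers(0, g, size=n_pairs)
        lens = np.clip(np.round(rng.normal(insert_mean, insert_sd, size=n_pairs)),
                       read_length_bp, g).astype(np.int64)
        starts = np.clip(mids - lens // 2, 0, g - lens)
        ends = starts + lens
        flips = rng.random(n_pairs) < 0.5
        fam_codes = fam_at[mids]
        reads: list[PairedRead] = []
        s1 = [decode(garr[a:a + read_length_bp]) for a in starts]
        s2 = [decode(_COMP[garr[b - read_length_bp:b]][::-1]) for b in ends]
        s1 = _apply_sequencing_error(s1, error_rate, rng)
        s2 = _apply_sequencing_error(s2, error_rate, rng)
        qual = "I" * read_length_bp
        for i in range(n_pairs):
            fam = fam_ids[fam_codes[i]] if fam_codes[i] >= 0 else "none"
            a, b = (s2[i], s1[i]) if flips[i] else (s1[i], s2[i])
            reads.append(PairedRead(f"{fraction}_{i:06d}", a, qual, b, qual, fam))
        return FractionLibrary(fraction, reads, read_length_bp, insert_mean, insert_sd, seed)

    return draw("input", n_input, False), draw("chip", n_chip, True)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_amount_antibody: float,
    true_amount_mock: float,
    efficiency: float = 1.0,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 4,
    seed: int = 0,
    target_id: str = "target",
    threshold_constant: float = 1e12,
) -> QPCRPlate:
    """Ct values for one target under the exponential amplification model:
    ct = log_{1+E}(K / amount) + Normal(0, ct_noise_sd), same K for all wells."""
    if true_amount_antibody <= 0 or true_amount_mock <= 0:
        raise ValueError("amounts must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    base = math.log(1.0 + efficiency)
    rows = []
    for fraction, amount in (("antibody", true_amount_antibody), ("mock", true_amount_mock)):
        ct0 = math.log(threshold_constant / amount) / base
        for rep in range(1, n_replicates + 1):
            noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
            rows.append({"target_id": target_id, "fraction": fraction,
                         "replicate": rep, "ct": ct0 + noise})
    return QPCRPlate(pd.DataFrame(rows), efficiency, n_replicates)


def combine_plates(plates: Sequence[QPCRPlate]) -> QPCRPlate:
    if not plates:
        raise ValueError("no plates to combine")
    eff = plates[0].efficiency
    n = plates[0].n_replicates
    if any(p.efficiency != eff or p.n_replicates != n for p in plates):
        raise ValueError("plates differ in efficiency or replicate count")
    return QPCRPlate(pd.concat([p.table for p in plates], ignore_index=True), eff, n)
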