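"""Run configuration: schema, defaults and YAML loading.

Every tunable of the pipeline lives here so that a run manifest can snapshot
it.  Unknown keys are rejected; field constraints mirror the generator's and
analysis stages' preconditions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .simulate import RepeatFamilySpec


class FamilyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    family_id: str
    family_class: Literal["tandem", "line_like", "ltr", "rdna_like"]
    unit_length_bp: int = Field(gt=1)
    copy_number: int = Field(ge=0)
    at_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    divergence: float = Field(default=0.0, ge=0.0, le=1.0)
    enrichment_factor: float = Field(default=1.0, gt=0.0)
    orf_length_nt: int = Field(default=0, ge=0, multiple_of=3)
    ltr_length_bp: int = Field(default=150, gt=0)
    spacer_length_bp: int = Field(default=400, gt=0)

    def to_spec(self) -> RepeatFamilySpec:
        return RepeatFamilySpec(**self.model_dump())


def _default_families() -> list[FamilyConfig]:
    return [
        FamilyConfig(family_id="sat187", family_class="tandem", unit_length_bp=187,
                     copy_number=200, at_fraction=0.583, divergence=0.02,
                     enrichment_factor=52.0),
        FamilyConfig(family_id="line1", family_class="line_like", unit_length_bp=2100,
                     copy_number=20, divergence=0.40, enrichment_factor=15.0,
                     orf_length_nt=429),
        FamilyConfig(family_id="ltr1", family_class="ltr", unit_length_bp=1200,
                     copy_number=8, divergence=0.03, enrichment_factor=2.5,
                     ltr_length_bp=150),
        FamilyConfig(family_id="rdna", family_class="rdna_like", unit_length_bp=5000,
                     copy_number=8, divergence=0.002, enrichment_factor=1.0,
                     spacer_length_bp=400),
    ]


class FixtureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chrom_length: int = Field(default=300_000, gt=0)
    chrom_name: str = "chr1"
    min_gap: int = Field(default=3000, ge=0)
    families: list[FamilyConfig] = Field(default_factory=_default_families)


class ReadSimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    read_length_bp: int = Field(default=300, gt=0)
    insert_mean_bp: float = Field(default=700.0, gt=0)
    insert_sd_bp: float = Field(default=120.0, ge=0)
    coverage_input: float = Field(default=1.6, gt=0)
    coverage_chip: float = Field(default=1.6, gt=0)
    error_rate: float = Field(default=0.001, ge=0.0, le=0.1)


class ClusterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_identity: float = Field(default=0.90, gt=0.0, le=1.0)
    min_overlap_fraction: float = Field(default=0.55, gt=0.0, le=1.0)
    kmer_size: int = Field(default=17, ge=8)
    max_reads: int = Field(default=24_000, gt=0)
    min_cluster_proportion: float = Field(default=0.0001, gt=0.0, lt=1.0)
    max_masked_fraction: float = Field(default=0.5, gt=0.0, le=1.0)


class ERConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    threshold: float = Field(default=2.0, gt=0.0)
    pseudocount: float = Field(default=0.5, gt=0.0)
    normalize: bool = False


class CharacterizeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    topology_max_nodes: int = Field(default=200, ge=20)
    min_topology_reads: int = Field(default=20, ge=2)
    assembly_min_overlap: int = Field(default=40, ge=10)
    max_assembly_reads: int = Field(default=200, gt=0)
    min_orf_aa: int = Field(default=50, ge=1)
    clip_threshold: float = Field(default=0.3, gt=0.0, le=1.0)
    link_threshold: int = Field(default=5, ge=1)
    join_on: Literal["any", "end_hits"] = "any"
    max_characterized: int = Field(default=12, gt=0)


class QPCRConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    efficiency: float = Field(default=1.0, gt=0.0, le=1.0)
    ct_noise_sd: float = Field(default=0.15, ge=0.0)
    n_replicates: int = Field(default=4, ge=2)
    n_targets: int = Field(default=5, ge=1)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fixture: FixtureConfig = Field(default_factory=FixtureConfig)
    reads: ReadSimConfig = Field(default_factory=ReadSimConfig)
    clustering: ClusterConfig = Field(default_factory=ClusterConfig)
    enrichment: ERConfig = Field(default_factory=ERConfig)
    characterization: CharacterizeConfig = Field(default_factory=CharacterizeConfig)
    qpcr: QPCRConfig = Field(default_factory=QPCRConfig)


class ConfigError(ValueError):
    """Itemized configuration problems."""

    def __init__(self, messages: list[str]):
        self.messages = messages
        super().__init__("; ".join(messages))


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config file; an empty or missing file means
    all defaults.  Raises ConfigError with one message per violation, each
    naming the offending field path."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError([f"top level of {path} must be a mapping"])
            data = loaded
    if overrides:
        for dotted, value in overrides.items():
            node = data
            parts = dotted.split(".")
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError(msgs) from None
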