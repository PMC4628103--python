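"""Shared fixtures: scaled-down genomes and reusable pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from cenrepeat.clustering import pool_fractions, qc_filter
from cenrepeat.simulate import (RepeatFamilySpec, assemble_genome,
                                simulate_fractions)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def small_specs(tandem_factor: float = 8.0) -> list[RepeatFamilySpec]:
    """A two-family miniature of the default fixture for fast tests."""
    return [
        RepeatFamilySpec("sat187", "tandem", 187, 60, at_fraction=0.583,
                         divergence=0.02, enrichment_factor=tandem_factor),
        RepeatFamilySpec("line1", "line_like", 2100, 4, at_fraction=0.5,
                         divergence=0.40, enrichment_factor=3.0, orf_length_nt=429),
    ]


@pytest.fixture(scope="session")
def small_fixture():
    return assemble_genome(small_specs(), 60_000, seed=11)


@pytest.fixture(scope="session")
def small_pooled(small_fixture):
    inp, chip = simulate_fractions(small_fixture, 1.2, 1.2, seed=12)
    return qc_filter(pool_fractions(inp, chip))
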