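"""Shared fixtures: a small synthetic study reused across test modules.

Session-scoped so the genome/methylome/count sampling happens once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stemmeth as sm
from stemmeth.io_formats import CX_COLUMNS, MethylomeSample


def make_sample(rows, sample_id="s", stage="D7", fraction="stem"):
    """Build a MethylomeSample from (chrom, pos, strand, n_meth, n_unmeth,
    context, trinucleotide) tuples."""
    df = pd.DataFrame(rows, columns=CX_COLUMNS)
    return MethylomeSample(
        sample_id=sample_id, stage=stage, fraction=fraction, records=df
    )


@pytest.fixture(scope="session")
def genome():
    return sm.generate_genome(2, 100_000, 20, 20, seed=101)


@pytest.fixture(scope="session")
def base_methylome(genome):
    return sm.generate_methylome(genome, seed=102, label="nonstem")


@pytest.fixture(scope="session")
def planted(base_methylome):
    """(stem methylome, truth region set) with 12 planted CHG DMRs."""
    return sm.plant_dmrs(
        base_methylome, 12, (300, 800), 0.4, "CHG", seed=103, label="stem"
    )


@pytest.fixture(scope="session")
def sample_pair(base_methylome, planted):
    stem_meth, _ = planted
    a = sm.sample_counts(
        base_methylome, 20.0, 0.005, seed=104, sample_id="nonstem", fraction="nonstem"
    )
    b = sm.sample_counts(
        stem_meth, 20.0, 0.005, seed=105, sample_id="stem", fraction="stem"
    )
    return a, b
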