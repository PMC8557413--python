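"""Shared fixtures: small hand-built genomes and simulated genome pairs."""

from __future__ import annotations

import numpy as np
import pytest

from symsrna.io_formats import CdsFeature, GenomeRecord, SrnaTable
from symsrna.synthetic import SimulationConfig, simulate_genome_pair


def make_genome(sequence: str, features=(), genome_id: str = "g1") -> GenomeRecord:
    return GenomeRecord(genome_id, sequence, tuple(features))


def make_srna_table(rows) -> SrnaTable:
    """rows: iterables of (srna_id, genome, start, end, strand[, category])."""
    recs = []
    for r in rows:
        rec = {
            "srna_id": r[0], "genome": r[1], "start": r[2], "end": r[3],
            "strand": r[4], "category": r[5] if len(r) > 5 else "unset",
        }
        recs.append(rec)
    return SrnaTable.from_records(recs)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast-but-nontrivial simulation: 40 CDSs, 10 A-side asRNAs of which
    5 are conserved in the 9-asRNA B side."""
    return SimulationConfig(
        seed=42, n_cds=40, mean_cds_len=600, n_asrna=10, n_asrna_b=9, n_conserved=5
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return simulate_genome_pair(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
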