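"""Shared fixtures: one default synthetic bundle reused across test modules."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from centroscan.simulate import (
    SimulationParams,
    simulate_contacts,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def sim(default_params) -> SimpleNamespace:
    """Default synthetic bundle: genome, truth, tracks, reads, contacts."""
    genome, truth, genes, repeats, rna = simulate_genome(default_params)
    reads, table, depth = simulate_reads(genome, truth, default_params)
    contacts = simulate_contacts(genome, truth, default_params)
    return SimpleNamespace(
        params=default_params,
        genome=genome,
        truth=truth,
        genes=genes,
        repeats=repeats,
        rna=rna,
        reads=reads,
        table=table,
        depth=depth,
        contacts=contacts,
    )


@pytest.fixture(scope="session")
def clean_reads_sim() -> SimpleNamespace:
    """Error-free reads for tests needing exact sequence identity."""
    params = SimulationParams(seed=5, read_error_rate=0.0)
    genome, truth, genes, repeats, rna = simulate_genome(params)
    reads, table, depth = simulate_reads(genome, truth, params)
    return SimpleNamespace(
        params=params,
        genome=genome,
        truth=truth,
        reads=reads,
        table=table,
        depth=depth,
    )
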