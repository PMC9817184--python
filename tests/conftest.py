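"""Shared fixtures: seeded simulations reused across test modules.

The replicate fixtures run the full simulate -> census -> fit chain at the
default study scale (four candidate species, 20,000 reads of 100 bp at
0.5% error); they are session-scoped because each replicate takes a few
seconds of alignment time.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridcensus import (
    ParentageModel,
    SimulationConfig,
    build_database,
    census_reads,
    make_hybrid,
    mito_census,
    simulate_parent_genomes,
    simulate_reads,
)

F1_SEEDS = [1000 + i for i in range(20)]
BC1_SEEDS = [2000 + i for i in range(20)]


def run_replicate(seed: int, cross: str, backcross_parent: str | None = None, **kw):
    """One full simulate -> census -> fit replicate at default scale."""
    cfg = SimulationConfig(
        seed=seed, hybrid_cross=cross, backcross_parent=backcross_parent, **kw
    )
    genomes = simulate_parent_genomes(cfg)
    hybrid = make_hybrid(genomes, cfg)
    reads = simulate_reads(hybrid, cfg)
    nuclear = census_reads(reads, build_database(genomes))
    mito = mito_census(reads, build_database(genomes, mito=True))
    results = ParentageModel(nuclear, mito=mito).fit()
    return {
        "config": cfg,
        "genomes": genomes,
        "hybrid": hybrid,
        "reads": reads,
        "nuclear": nuclear,
        "mito": mito,
        "results": results,
    }


@pytest.fixture(scope="session")
def f1_replicates():
    return [run_replicate(s, "F1") for s in F1_SEEDS]


@pytest.fixture(scope="session")
def bc1_replicates():
    return [run_replicate(s, "BC1", backcross_parent="numida") for s in BC1_SEEDS]


@pytest.fixture(scope="session")
def small_genomes():
    """Two close parents + one decoy on a small genome (fast unit tests)."""
    cfg = SimulationConfig(
        seed=42,
        genome_length=10_000,
        n_chromosomes=4,
        mito_length=4_000,
        species=[("numida", 0.05), ("gallus", 0.05), ("phasianus", 0.2)],
        n_reads=500,
    )
    return cfg, simulate_parent_genomes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
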