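from __future__ import annotations

import random

import pytest

from orthopath import (
    GeneRecord,
    ModelEntry,
    PathwayModel,
    Proteome,
    SimulationConfig,
    simulate_study,
)
from orthopath.types import AMINO_ACIDS


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def make_proteome(organism_id: str, n_genes: int, seed: int, length=(80, 150)) -> Proteome:
    rng = random.Random(seed)
    return Proteome(
        organism_id,
        [
            GeneRecord(
                f"{organism_id}_g{i:02d}",
                organism_id,
                random_protein(rng, rng.randint(*length)),
            )
            for i in range(n_genes)
        ],
    )


def make_model(target_organism: str, initial_genes, recruited=()) -> PathwayModel:
    model = PathwayModel(target_organism)
    for g in initial_genes:
        model.add_entry(ModelEntry(g, "initial", sources=["template:t"]))
    for g, src in recruited:
        model.add_entry(ModelEntry(g, "recruited", sources=[src]))
    return model


@pytest.fixture(scope="session")
def small_study():
    """A complete synthetic study shared by read-only tests."""
    cfg = SimulationConfig(
        n_organisms=2,
        n_families=20,
        divergence=0.15,
        pathway_size=6,
        n_operons_for_pathway=2,
        padding_per_operon=1,
        edge_sensitivity=1.0,
        decoy_rate=0.0,
        seed=11,
    )
    return simulate_study(cfg)
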