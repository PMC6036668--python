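"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from htscan.formats import SeqRecord
from htscan.simulate import (
    SimConfig,
    evolve,
    generate_species_tree,
    make_master_te,
    plant_cross_class_events,
    taxonomy_from_tree,
)

warnings.filterwarnings("ignore", category=UserWarning, module="dendropy")


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate_substitutions(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly n substitutions, each to a different base."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[(("ACGT".index(out[p])) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def master():
    return make_master_te(3200, seed=11)


@pytest.fixture(scope="session")
def sim_vertical():
    """12-species vertical-only simulation (no HT), moderate divergence."""
    tree = generate_species_tree(12, seed=3, height=0.35)
    config = SimConfig(species_tree=tree, seed=7)
    return evolve(config), tree, taxonomy_from_tree(tree, n_phyla=2)


@pytest.fixture(scope="session")
def sim_with_ht():
    """12-species simulation with two recent cross-class transfers."""
    tree = generate_species_tree(12, seed=1, height=0.35)
    taxonomy = taxonomy_from_tree(tree, n_phyla=2)
    events = plant_cross_class_events(tree, taxonomy, time_fraction=0.9)
    config = SimConfig(species_tree=tree, seed=1, ht_events=events)
    return evolve(config), tree, taxonomy, events


def seq_records(copies: dict) -> list[SeqRecord]:
    return [SeqRecord(cid, rec.seq) for cid, rec in copies.items()]
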