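"""Shared fixtures: curated mixture table, small synthetic datasets, ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from odorspace.dataset import OdorantRecord, OdorDataset, load_mixture_components
from odorspace.pharmacophore import generate_conformers
from odorspace.synthetic import default_config, generate_dataset


@pytest.fixture(scope="session")
def table1():
    """The 7 mixture components with the footnoted rare notes pruned."""
    return load_mixture_components(prune_rare=True)


@pytest.fixture(scope="session")
def small_synthetic():
    """A scaled-down default synthetic dataset plus family truth labels."""
    ds, labels = generate_dataset(default_config(seed=11, scale=0.25))
    return ds, labels


@pytest.fixture(scope="session")
def ia_ensemble():
    return generate_conformers("CC(C)CCOC(C)=O", "IA", seed=7)


@pytest.fixture(scope="session")
def wl_ensemble():
    return generate_conformers("CCCCC1OC(=O)CC1C", "WL", seed=7)


def make_record(rid: str, notes: set[str], smiles: str = "CCO") -> OdorantRecord:
    return OdorantRecord(id=rid, name=rid, smiles=smiles, notes=frozenset(notes))


def make_dataset(note_sets: dict[str, set[str]], min_occurrence: int = 1) -> OdorDataset:
    recs = [make_record(rid, notes) for rid, notes in note_sets.items()]
    return OdorDataset(recs, min_note_occurrence=min_occurrence)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
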