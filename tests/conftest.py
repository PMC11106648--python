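"""Shared fixtures: synthetic chains, ensembles and on-disk fixture suites."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from glocon import (
    ChainRecord,
    MappingRow,
    MappingTable,
    Segment,
    generate_ensemble,
    two_state_spec,
)
from glocon.fixtures import generate_backbone


def make_chain(structure_id, start, end, accession="SYN00001", chain_id="A", rng=None):
    """Helical chain covering reference residues [start, end]."""
    n = end - start + 1
    base = generate_backbone(n, structure_id=structure_id,
                             chain_id=chain_id, accession=accession)
    residues = {start + i: pos for i, (_, pos) in enumerate(base.residues.items())}
    if rng is not None:
        residues = {k: v + rng.normal(0, 0.01, 3) for k, v in residues.items()}
    return ChainRecord(structure_id, chain_id, accession, residues)


def segment_of(chains, segment_id="SYN00001_1"):
    start = min(min(c.residues) for c in chains)
    end = max(max(c.residues) for c in chains)
    return Segment(segment_id, chains[0].accession, start, end, tuple(chains))


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_state_ensemble():
    """In-memory canonical two-state (open/closed hinge) ensemble, seed 0."""
    return generate_ensemble(two_state_spec(seed=0))


@pytest.fixture
def ensemble_dir(tmp_path):
    """Canonical two-state ensemble written as mmCIF files + mapping TSV."""
    out = tmp_path / "fixture_suite"
    ens = generate_ensemble(two_state_spec(seed=0), out_dir=out)
    return out, ens
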