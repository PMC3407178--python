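from pathlib import Path

import numpy as np
import pytest

from hide.fixtures import (
    FixtureSpec,
    build_monomer_homologue,
    build_protomer,
    build_swapped_dimer,
)
from hide.structure_io import read_structure

RCSB_DIR = Path(__file__).parent / "data" / "rcsb"


def load_rcsb(pdb_id: str):
    """Load a real PDB entry from tests/data/rcsb (not distributed; fetch
    with hide.structure_io.fetch_pdb on a machine with network access)."""
    path = RCSB_DIR / f"{pdb_id.lower()}.pdb"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} missing: this check needs the real wwPDB entry "
            f"{pdb_id.upper()}; download it via hide.structure_io.fetch_pdb"
            f"('{pdb_id}', '{RCSB_DIR}') and re-run."
        )
    return read_structure(path)


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def open_protomer(default_spec):
    return build_protomer(default_spec, conformer="open")


@pytest.fixture(scope="session")
def closed_monomer(default_spec):
    return build_monomer_homologue(default_spec)


@pytest.fixture(scope="session")
def swapped_dimer(default_spec):
    return build_swapped_dimer(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
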