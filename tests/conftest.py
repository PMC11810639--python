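"""Shared fixtures: tiny hand-written structures and session-scoped bundles."""

from __future__ import annotations

import numpy as np
import pytest

from megago.config import RunConfig
from megago.pipeline import load_bundle
from megago.synthetic import SyntheticSpec, make_dataset

#: minimal 3-residue PDB (GLY/ALA/LYS) with Cα-only records
THREE_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   2       4.500   0.000   0.000  1.00  0.00           C
ATOM      4  CB  ALA A   2       5.000   1.000   0.000  1.00  0.00           C
ATOM      5  CA  LYS A   3       8.000   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture(scope="session")
def bundle60(tmp_path_factory):
    """60-protein synthetic bundle with a 1:1:1 length mixture."""
    outdir = tmp_path_factory.mktemp("bundle60")
    spec = SyntheticSpec(n_proteins=60, seed=7)
    manifest = make_dataset(spec, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def graphs60(bundle60):
    outdir, _ = bundle60
    graphs, term_ids = load_bundle(outdir, f2_dim=16)
    return graphs, term_ids


@pytest.fixture
def quick_config():
    """A configuration small and short enough for unit-test training."""
    return RunConfig(seed=3, epochs=2, batch_size=8, patience=100)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
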