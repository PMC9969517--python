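import numpy as np
import pytest

from samredox.backends import MockCoulombEngine
from samredox.builder import build_sam, neutralize
from samredox.fixtures import make_snapshots, make_template, make_toy_ligand


@pytest.fixture(scope="session")
def toy_template():
    """Small 4x5 two-layer slab with placeholder thiols and 30 waters."""
    return make_template(n_sites_x=4, n_sites_y=5, n_waters=30, seed=11)


@pytest.fixture(scope="session")
def guanine_neutral():
    return make_toy_ligand("guanine_like", "neutral")


@pytest.fixture(scope="session")
def guanine_cation():
    return make_toy_ligand("guanine_like", "cation")


@pytest.fixture(scope="session")
def neutral_sam(toy_template, guanine_neutral):
    return build_sam(toy_template, guanine_neutral, coverage=0.70, seed=5)


@pytest.fixture(scope="session")
def cation_sam(toy_template, guanine_neutral, guanine_cation):
    system = build_sam(
        toy_template,
        guanine_neutral,
        guanine_cation,
        coverage=0.70,
        seed=5,
        cation_site="central",
    )
    return neutralize(system)


@pytest.fixture(scope="session")
def central_ligand(neutral_sam):
    """Ligand id of the ligand nearest the slab xy-centroid."""
    metal = neutral_sam.indices_by_role("metal")
    center = np.mean(neutral_sam.positions[metal][:, :2], axis=0)
    lids = neutral_sam.ligand_ids()
    d = [
        np.linalg.norm(
            neutral_sam.atoms[neutral_sam.anchor_index_of(l)].position[:2] - center
        )
        for l in lids
    ]
    return lids[int(np.argmin(d))]


@pytest.fixture(scope="session")
def neutral_snapshots(neutral_sam):
    return make_snapshots(neutral_sam, n=5, amplitude=0.05, seed=21)


@pytest.fixture(scope="session")
def cation_snapshots(cation_sam):
    return make_snapshots(cation_sam, n=5, amplitude=0.05, seed=22)


@pytest.fixture
def mock_engine():
    return MockCoulombEngine()
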