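import numpy as np
import pytest

from sstbind import synthetic_data as sd
from sstbind.energetics import ParamTable
from sstbind.structio import Complex, Structure


@pytest.fixture(scope="session")
def toy_receptor():
    structure, manifest = sd.make_toy_receptor(42)
    return structure, manifest


@pytest.fixture(scope="session")
def sst_peptide():
    structure, manifest = sd.make_sst_peptide(cyclic=True, seed_rng=42)
    return structure, manifest


@pytest.fixture(scope="session")
def sst_peptide_open():
    structure, _ = sd.make_sst_peptide(cyclic=False, seed_rng=42)
    return structure


@pytest.fixture(scope="session")
def intermediate_fixture():
    return sd.make_intermediate_fixture(42)


@pytest.fixture(scope="session")
def scenario():
    """Default association scenario (2000 frames, seed 42)."""
    return sd.make_scenario_trajectory(sd.ScenarioSpec(seed=42))


@pytest.fixture(scope="session")
def param_table():
    return ParamTable.default()


@pytest.fixture(scope="session")
def posed_complex(toy_receptor, sst_peptide):
    """Receptor + cyclic peptide posed at the near-intermediate distance."""
    receptor, _ = toy_receptor
    peptide, _ = sst_peptide
    posed = sd.pose_ligand(peptide, receptor, dsb_target=5.5)
    structure = Structure([a for a in receptor.atoms] + [a for a in posed.atoms])
    return Complex(structure, receptor_chains={"R"}, ligand_chains={"L"})


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-20, 20, size=3)
    return R, t
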