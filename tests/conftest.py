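import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from cocryst.chemio import (
    Atom,
    CrystalStructure,
    Molecule,
    SymmetryOp,
    UnitCell,
    assign_typing,
    from_rdkit,
    perceive_bonds,
)
from cocryst.energy import ForceFieldParams, LatticeModel
from cocryst.synthdata import make_ribbon_crystal


def embed_smiles(smiles: str, name: str, seed: int = 7) -> Molecule:
    m = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(m, params) == 0
    mol = from_rdkit(m, name=name)
    # re-perceive connectivity from geometry so the perception path is tested
    mol = perceive_bonds(mol.atoms, name=name)
    return mol


@pytest.fixture(scope="session")
def benzene() -> Molecule:
    th = np.arange(6) * np.pi / 3
    atoms = [Atom("C", [1.39 * np.cos(t), 1.39 * np.sin(t), 0.0]) for t in th]
    atoms += [Atom("H", [2.47 * np.cos(t), 2.47 * np.sin(t), 0.0]) for t in th]
    mol = perceive_bonds(atoms, name="benzene")
    assign_typing(mol)
    return mol


@pytest.fixture(scope="session")
def water() -> Molecule:
    atoms = [
        Atom("O", [0.0, 0.0, 0.0]),
        Atom("H", [0.9572, 0.0, 0.0]),
        Atom("H", [-0.2399, 0.9266, 0.0]),
    ]
    mol = perceive_bonds(atoms, name="water")
    assign_typing(mol)
    return mol


@pytest.fixture(scope="session")
def methane() -> Molecule:
    t = 1.09 / np.sqrt(3.0)
    atoms = [Atom("C", [0, 0, 0])] + [
        Atom("H", p)
        for p in ([t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t])
    ]
    mol = perceive_bonds(atoms, name="methane")
    assign_typing(mol)
    return mol


@pytest.fixture(scope="session")
def imidazole() -> Molecule:
    mol = embed_smiles("c1cnc[nH]1", "imidazole")
    assign_typing(mol)
    return mol


@pytest.fixture(scope="session")
def quercetin() -> Molecule:
    mol = embed_smiles("O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", "quercetin")
    assign_typing(mol)
    return mol


@pytest.fixture(scope="session")
def dreiding() -> ForceFieldParams:
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def ribbon() -> CrystalStructure:
    return make_ribbon_crystal()


@pytest.fixture(scope="session")
def ribbon_model(ribbon, dreiding) -> LatticeModel:
    return LatticeModel(ribbon, dreiding, cutoff=15.0)


@pytest.fixture()
def point_cubic() -> CrystalStructure:
    """One pointlike molecule in a 10 Å cube, neutral, pure LJ."""
    mol = Molecule([Atom("C", [5.0, 5.0, 5.0], ff_type="C_3")], name="pt")
    return CrystalStructure(
        UnitCell(10, 10, 10), [SymmetryOp.identity()], [mol], "P 1"
    )


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
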