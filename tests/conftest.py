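import numpy as np
import pytest
from hypothesis import settings

from ternscan import Atom, Structure

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    element: str,
    altloc: str = " ",
    occ: float = 1.0,
    record: str = "ATOM",
) -> str:
    """One fixed-width PDB coordinate record."""
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_residue_chain() -> Structure:
    """Toy 2-residue peptide-like chain: N, CA, C, O + one sidechain atom each."""
    atoms = []
    for res in (1, 2):
        base = np.array([res * 5.0, 0.0, 0.0])
        for name, element, offset in [
            ("N", "N", (0, 0, 0)),
            ("CA", "C", (1.5, 0, 0)),
            ("C", "C", (2.5, 1.0, 0)),
            ("O", "O", (2.5, 2.2, 0)),
            ("CB", "C", (1.5, -1.5, 0)),
        ]:
            atoms.append(
                Atom(
                    element=element,
                    name=name,
                    residue_index=res,
                    residue_name="ALA",
                    chain_id="A",
                    coords=base + np.array(offset, dtype=float),
                    is_backbone=name in ("N", "CA", "C", "O"),
                    is_heavy=True,
                    is_calpha=name == "CA",
                )
            )
    return Structure(atoms, label="toy-chain")


def random_structure(rng: np.random.Generator, n: int = 12, spread: float = 10.0) -> Structure:
    """Random heavy-atom cloud for geometric property tests."""
    coords = rng.uniform(-spread, spread, size=(n, 3))
    atoms = [
        Atom("C", f"X{i}", 1, "UNK", "A", coords[i], is_heavy=True)
        for i in range(n)
    ]
    return Structure(atoms)


def random_rigid_transform(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    from ternscan import RigidTransform

    return RigidTransform(
        Rotation.random(random_state=rng).as_matrix(),
        rng.uniform(-15, 15, size=3),
    )
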