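"""Synthetic inputs with planted ground truth.

Every pipeline stage can be exercised without any external structure or
instrument file: a toy diyne PROTAC with rigid six-atom ring warheads, toy
"protein" atom clouds with backbone/sidechain annotations, fully constructed
ternary scenes whose set of clash-free grid angles is known by design, and
simulated multi-cycle sensorgram datasets with recorded truth.

The planted scene works by geometry, not rejection sampling: a probe
backbone atom of partner B sweeps a 20 Å-radius circle as the grid angle
changes, and partner A carries a blocking backbone atom at exactly the
circle positions of every *non*-viable angle.  Adjacent 10° grid positions
on that circle are ~3.5 Å apart — farther than the 2.4 Å clash cutoff — so
each blocker vetoes exactly one angle.  The generator verifies the planted
truth with a brute-force distance census before returning; it never hands
out an unverified scene.

Generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .conformers import DiyneLigand, rotate_about_axis
from .spr import InjectionSeries, KineticParams, Sensorgram, simulate_sensorgram
from .structure import Atom, RigidTransform, Structure, apply_transform, concat, write_pdb
from .superpose import AtomMap

__all__ = [
    "PlantedScene",
    "make_toy_ligand",
    "make_toy_protein",
    "plant_ternary_scene",
    "make_sensorgram_dataset",
    "export_scene",
]

# canonical toy-ligand geometry (Å): a linear diyne on the z axis with a
# planar 6-atom ring at each end, ring centres offset from the axis so that
# rotation about the axis genuinely moves the mobile warhead
_BOND_LENGTHS = (1.21, 1.37, 1.21)  # alternating triple/single bonds
_RING_RADIUS = 1.4
_RING_OFFSET = np.array([1.4, 0.0, 3.3])


def _ring(center: np.ndarray) -> np.ndarray:
    angles = np.radians(60.0 * np.arange(6))
    ring = np.stack(
        [np.cos(angles) * _RING_RADIUS, np.sin(angles) * _RING_RADIUS, np.zeros(6)],
        axis=1,
    )
    return ring + center


def _canonical_ligand_coords() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fixed ring, linker carbons, mobile ring) in the canonical frame."""
    z = np.concatenate([[0.0], np.cumsum(_BOND_LENGTHS)])
    z -= z.mean()
    linker = np.stack([np.zeros(4), np.zeros(4), z], axis=1)
    fixed = _ring(_RING_OFFSET * np.array([1, 1, -1]))
    mobile = _ring(_RING_OFFSET)
    return fixed, linker, mobile


def _ligand_structure(coords_f: np.ndarray, coords_l: np.ndarray, coords_m: np.ndarray) -> Structure:
    atoms = []
    for k, xyz in enumerate(coords_f):
        atoms.append(Atom("C", f"F{k+1}", 1, "LIG", "L", xyz))
    for k, xyz in enumerate(coords_l):
        atoms.append(Atom("C", f"C{k+1}", 1, "LIG", "L", xyz))
    for k, xyz in enumerate(coords_m):
        atoms.append(Atom("C", f"M{k+1}", 1, "LIG", "L", xyz))
    return Structure(atoms, label="toy-diyne-PROTAC")


def _seed_transform(rng: np.random.Generator) -> RigidTransform:
    rotation = Rotation.random(random_state=rng).as_matrix()
    translation = rng.uniform(-20.0, 20.0, size=3)
    return RigidTransform(rotation, translation)


def make_toy_ligand(seed: int = 0) -> DiyneLigand:
    """Toy diyne PROTAC: 4 collinear sp carbons (bond lengths 1.21/1.37/
    1.21 Å) flanked by two rigid planar 6-atom ring warheads.

    The whole molecule is placed at a random rigid pose drawn from ``seed``;
    atom indices 0–5 are the fixed (POI) warhead, 6–9 the linker carbons and
    10–15 the mobile (E3) warhead.
    """
    fixed, linker, mobile = _canonical_ligand_coords()
    transform = _seed_transform(np.random.default_rng(seed))
    structure = apply_transform(
        _ligand_structure(fixed, linker, mobile), transform
    )
    return DiyneLigand.from_partition(
        structure,
        warhead_fixed=range(0, 6),
        warhead_mobile=range(10, 16),
        linker=range(6, 10),
    )


def make_toy_protein(
    n_residues: int,
    sidechain_atoms: int = 2,
    radius: float = 20.0,
    seed: int = 0,
) -> Structure:
    """Toy protein: a self-avoiding random walk of pseudo-residues.

    Each residue contributes backbone atoms N, CA, C, O plus
    ``sidechain_atoms`` pseudo-sidechain carbons (SC1, SC2, …).  Atoms are
    placed sequentially with steps of 2.8–3.5 Å inside a sphere of the given
    radius, keeping every pair at least 2.6 Å apart so the cloud has no
    internal clash at the 2.4 Å census cutoff.  Deterministic under seed.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    names = ["N", "CA", "C", "O"] + [f"SC{k+1}" for k in range(sidechain_atoms)]
    elements = ["N", "C", "C", "O"] + ["C"] * sidechain_atoms
    n_atoms = n_residues * len(names)
    rng = np.random.default_rng(seed)
    min_dist = 2.6
    for _attempt in range(30):
        coords = np.zeros((n_atoms, 3))
        coords[0] = rng.uniform(-radius / 4, radius / 4, size=3)
        ok = True
        for i in range(1, n_atoms):
            placed = False
            for _retry in range(300):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                candidate = coords[i - 1] + direction * rng.uniform(2.8, 3.5)
                if np.linalg.norm(candidate) > radius:
                    continue
                if np.min(np.linalg.norm(coords[:i] - candidate, axis=1)) < min_dist:
                    continue
                coords[i] = candidate
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not pack {n_atoms} atoms in a {radius} Å sphere after 30 walks"
        )
    atoms = []
    i = 0
    for res in range(1, n_residues + 1):
        for name, element in zip(names, elements):
            backbone = name in ("N", "CA", "C", "O")
            atoms.append(
                Atom(
                    element=element,
                    name=name,
                    residue_index=res,
                    residue_name="ALA",
                    chain_id="A",
                    coords=coords[i],
                    is_backbone=backbone,
                    is_heavy=True,
                    is_calpha=(name == "CA"),
                )
            )
            i += 1
    return Structure(atoms, label=f"toy-protein-{n_residues}res")


@dataclasses.dataclass
class PlantedScene:
    """A fully constructed screening scene with known viable angles."""

    ligand: DiyneLigand
    complex_A: Structure
    complex_B: Structure
    map_A: AtomMap
    map_B: AtomMap
    truth_viable_angles: frozenset[float]
    seed: int
    step_deg: float = 10.0


_PROBE_RADIUS = 20.0  # Å; 10° chord = 2·20·sin5° ≈ 3.49 Å > 2.4 Å cutoff
_PROBE_Z = 10.0
_BODY_Z = 60.0


def _rotz(angle_deg: float, points: np.ndarray) -> np.ndarray:
    return rotate_about_axis(points, np.zeros(3), np.array([0.0, 0.0, 1.0]), angle_deg)


def plant_ternary_scene(
    viable_angles: Iterable[float],
    seed: int = 0,
    step_deg: float = 10.0,
    n_residues: int = 6,
    sidechain_atoms: int = 2,
) -> PlantedScene:
    """Construct a screening scene whose viable angle set is exact by design.

    ``viable_angles`` must be a subset of the ``step_deg`` grid.  Partner A
    (target side) sits below the ligand, partner B (ligase side) above; a
    backbone probe atom of B traces a circle under the scan and backbone
    blockers in A occupy the circle positions of every non-viable angle.
    The whole scene is then moved by a seed-derived rigid transform.  The
    planted truth is re-checked by a brute-force heavy-atom distance census
    before the scene is returned.
    """
    n_steps = round(360.0 / step_deg)
    if abs(n_steps * step_deg - 360.0) > 1e-9:
        raise ValueError("step_deg must divide 360")
    grid = [i * step_deg for i in range(n_steps)]
    viable = frozenset(float(a) % 360.0 for a in viable_angles)
    if not viable <= set(grid):
        raise ValueError(f"viable angles must lie on the {step_deg}° grid")
    blocked = [a for a in grid if a not in viable]

    rng = np.random.default_rng(seed)
    fixed, linker, mobile = _canonical_ligand_coords()
    ligand_structure = _ligand_structure(fixed, linker, mobile)

    protein_A = make_toy_protein(
        n_residues, sidechain_atoms, seed=int(rng.integers(2**31))
    )
    protein_B = make_toy_protein(
        n_residues, sidechain_atoms, seed=int(rng.integers(2**31))
    )
    shift_A = RigidTransform.from_translation([0.0, 0.0, -_BODY_Z])
    shift_B = RigidTransform.from_translation([0.0, 0.0, _BODY_Z])
    probe_pos = np.array([_PROBE_RADIUS, 0.0, _PROBE_Z])

    def _bound_copy(coords: np.ndarray, prefix: str, resname: str, chain: str) -> Structure:
        return Structure(
            [
                Atom("C", f"{prefix}{k+1}", 1, resname, chain, xyz)
                for k, xyz in enumerate(coords)
            ]
        )

    blockers = Structure(
        [
            Atom(
                "C", "CA", k + 1, "GLY", "Z", _rotz(angle, probe_pos[None])[0],
                is_backbone=True, is_heavy=True, is_calpha=True,
            )
            for k, angle in enumerate(blocked)
        ]
    )
    probe = Structure(
        [
            Atom(
                "C", "CA", 1, "GLY", "P", probe_pos,
                is_backbone=True, is_heavy=True, is_calpha=True,
            )
        ]
    )
    complex_A = concat(
        [apply_transform(protein_A, shift_A), _bound_copy(fixed, "F", "LGA", "X"), blockers],
        label="partner-A",
    )
    complex_B = concat(
        [apply_transform(protein_B, shift_B), _bound_copy(mobile, "M", "LGB", "Y"), probe],
        label="partner-B",
    )
    n_prot = len(protein_A)
    map_A = AtomMap(tuple((n_prot + k, k) for k in range(6)))
    n_prot_b = len(protein_B)
    map_B = AtomMap(tuple((n_prot_b + k, 10 + k) for k in range(6)))

    # brute-force verification in the canonical frame: posing partner B onto
    # the conformer at angle theta is exactly a rotation of B by theta about z
    coords_a = complex_A.coords[complex_A.is_heavy]
    bb_a = complex_A.is_backbone[complex_A.is_heavy]
    coords_b0 = complex_B.coords[complex_B.is_heavy]
    bb_b = complex_B.is_backbone[complex_B.is_heavy]
    for angle in grid:
        dists = cdist(coords_a, _rotz(angle, coords_b0))
        clashing = dists < 2.4
        n_heavy = int(clashing.sum())
        n_backbone = int((clashing & np.outer(bb_a, bb_b)).sum())
        if angle in viable:
            if n_heavy != 0:
                raise RuntimeError(
                    f"scene verification failed: {n_heavy} clashes at viable "
                    f"angle {angle:g}°"
                )
        elif n_backbone == 0:
            raise RuntimeError(
                f"scene verification failed: no backbone clash planted at "
                f"blocked angle {angle:g}°"
            )

    scene_transform = _seed_transform(rng)
    ligand = DiyneLigand.from_partition(
        apply_transform(ligand_structure, scene_transform),
        warhead_fixed=range(0, 6),
        warhead_mobile=range(10, 16),
        linker=range(6, 10),
    )
    return PlantedScene(
        ligand=ligand,
        complex_A=apply_transform(complex_A, scene_transform),
        complex_B=apply_transform(complex_B, scene_transform),
        map_A=map_A,
        map_B=map_B,
        truth_viable_angles=viable,
        seed=seed,
        step_deg=float(step_deg),
    )


def make_sensorgram_dataset(
    truth: KineticParams,
    series: InjectionSeries,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[Sensorgram], dict]:
    """Simulate one sensorgram per series concentration, plus a truth record.

    Per-cycle noise seeds are derived from ``seed`` so the whole dataset is
    reproducible; the truth record carries the generating parameters for
    recovery tests.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(series.concentrations)
    )
    grams = [
        simulate_sensorgram(
            truth,
            conc,
            series.contact_time,
            series.dissociation_time,
            noise_sd=noise_sd,
            seed=int(child_seeds[i]),
        )
        for i, conc in enumerate(series.concentrations)
    ]
    record = {
        "k_on": truth.k_on,
        "k_off": truth.k_off,
        "Rmax": truth.Rmax,
        "K_D": truth.K_D,
        "noise_sd": noise_sd,
        "seed": seed,
        "concentrations_M": list(series.concentrations),
        "contact_time_s": series.contact_time,
        "dissociation_time_s": series.dissociation_time,
    }
    return grams, record


def export_scene(scene: PlantedScene, directory: str | Path) -> None:
    """Write a scene as PDB files, name-based map files and a truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pdb(scene.complex_A, directory / "complex_A.pdb")
    write_pdb(scene.complex_B, directory / "complex_B.pdb")
    write_pdb(scene.ligand.atoms, directory / "ligand.pdb")
    for map_name, atom_map, complex_structure in (
        ("map_A.txt", scene.map_A, scene.complex_A),
        ("map_B.txt", scene.map_B, scene.complex_B),
    ):
        lines = ["# complex_atom_name  protac_atom_name"]
        for src, dst in atom_map.pairs:
            lines.append(
                f"{complex_structure.names[src]}  {scene.ligand.atoms.names[dst]}"
            )
        (directory / map_name).write_text("\n".join(lines) + "\n")
    partition = {
        "warhead_fixed": scene.ligand.warhead_fixed.tolist(),
        "warhead_mobile": scene.ligand.warhead_mobile.tolist(),
        "linker": scene.ligand.linker.tolist(),
    }
    (directory / "ligand_partition.json").write_text(
        json.dumps(partition, indent=2) + "\n"
    )
    truth = {
        "viable_angles_deg": sorted(scene.truth_viable_angles),
        "step_deg": scene.step_deg,
        "seed": scene.seed,
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
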