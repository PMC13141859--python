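"""Structure data model, PDB I/O, atom selection and rigid transforms.

The in-memory model is columnar: a :class:`Structure` holds parallel numpy
arrays (one row per atom) rather than a list of atom objects, so geometric
stages can operate on ``(N, 3)`` coordinate blocks directly.  Individual
:class:`Atom` records are materialised on demand.

Coordinates are in Ångström throughout the package; no unit conversion
happens anywhere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "RigidTransform",
    "read_pdb",
    "read_multimodel_pdb",
    "write_pdb",
    "write_multimodel_pdb",
    "select",
    "apply_transform",
    "parse_selector",
    "concat",
    "STANDARD_RESIDUES",
    "BACKBONE_NAMES",
]

#: 3-letter codes treated as polymer residues (ATOM records, backbone flags).
STANDARD_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE SEC PYL""".split()
)

#: Backbone atom names of polymer residues.  OXT counts as backbone.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom record.

    Attributes
    ----------
    element : str
        Chemical element symbol (e.g. ``"C"``, ``"N"``).
    name : str
        Atom name (e.g. ``"CA"``).
    residue_index : int
        Residue sequence number.
    residue_name : str
        3-letter residue code.
    chain_id : str
        Chain identifier.
    coords : numpy.ndarray
        Cartesian position, Å, shape ``(3,)``.
    is_backbone, is_heavy, is_calpha : bool
        Classification flags.  ``is_calpha`` implies ``is_backbone`` and
        ``is_heavy`` is consistent with the element.
    """

    element: str
    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    is_backbone: bool = False
    is_heavy: bool = True
    is_calpha: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.is_calpha and not self.is_backbone:
            raise ValueError("a C-alpha atom must be flagged as backbone")
        heavy = self.element.upper() not in _HYDROGEN_ELEMENTS
        if self.is_heavy != heavy:
            raise ValueError(
                f"is_heavy={self.is_heavy} inconsistent with element {self.element!r}"
            )


class Structure:
    """Ordered collection of atoms with selection views.

    Selections preserve atom order and keep ``parent_indices`` pointing back
    into the structure they were taken from, so a view's atoms can always be
    located in the parent.
    """

    def __init__(
        self,
        atoms: Iterable[Atom] = (),
        *,
        label: str = "",
        source: str | None = None,
    ) -> None:
        atoms = list(atoms)
        n = len(atoms)
        self.label = label
        self.source = source
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.residue_indices = np.array(
            [a.residue_index for a in atoms], dtype=np.int64
        )
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.coords = (
            np.array([a.coords for a in atoms], dtype=float)
            if n
            else np.zeros((0, 3))
        )
        self.is_backbone = np.array([a.is_backbone for a in atoms], dtype=bool)
        self.is_heavy = np.array([a.is_heavy for a in atoms], dtype=bool)
        self.is_calpha = np.array([a.is_calpha for a in atoms], dtype=bool)
        self.parent_indices = np.arange(n, dtype=np.int64)

    @classmethod
    def from_arrays(
        cls,
        *,
        elements: np.ndarray,
        names: np.ndarray,
        residue_indices: np.ndarray,
        residue_names: np.ndarray,
        chain_ids: np.ndarray,
        coords: np.ndarray,
        is_backbone: np.ndarray,
        is_heavy: np.ndarray,
        is_calpha: np.ndarray,
        parent_indices: np.ndarray | None = None,
        label: str = "",
        source: str | None = None,
    ) -> "Structure":
        obj = cls.__new__(cls)
        obj.label = label
        obj.source = source
        obj.elements = np.asarray(elements, dtype=object)
        obj.names = np.asarray(names, dtype=object)
        obj.residue_indices = np.asarray(residue_indices, dtype=np.int64)
        obj.residue_names = np.asarray(residue_names, dtype=object)
        obj.chain_ids = np.asarray(chain_ids, dtype=object)
        obj.coords = np.array(coords, dtype=float)
        if obj.coords.ndim != 2 or obj.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(obj.coords)):
            raise ValueError("coordinates must be finite")
        obj.is_backbone = np.asarray(is_backbone, dtype=bool)
        obj.is_heavy = np.asarray(is_heavy, dtype=bool)
        obj.is_calpha = np.asarray(is_calpha, dtype=bool)
        n = len(obj.coords)
        obj.parent_indices = (
            np.arange(n, dtype=np.int64)
            if parent_indices is None
            else np.asarray(parent_indices, dtype=np.int64)
        )
        return obj

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, index: int) -> Atom:
        return Atom(
            element=str(self.elements[index]),
            name=str(self.names[index]),
            residue_index=int(self.residue_indices[index]),
            residue_name=str(self.residue_names[index]),
            chain_id=str(self.chain_ids[index]),
            coords=self.coords[index].copy(),
            is_backbone=bool(self.is_backbone[index]),
            is_heavy=bool(self.is_heavy[index]),
            is_calpha=bool(self.is_calpha[index]),
        )

    def __iter__(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield self[i]

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<Structure{lab}: {len(self)} atoms>"

    # -- derived views ------------------------------------------------------

    def take(self, indices: np.ndarray | Sequence[int], label: str | None = None) -> "Structure":
        """Sub-structure at the given row positions, order preserved."""
        idx = np.asarray(indices, dtype=np.int64)
        return Structure.from_arrays(
            elements=self.elements[idx],
            names=self.names[idx],
            residue_indices=self.residue_indices[idx],
            residue_names=self.residue_names[idx],
            chain_ids=self.chain_ids[idx],
            coords=self.coords[idx],
            is_backbone=self.is_backbone[idx],
            is_heavy=self.is_heavy[idx],
            is_calpha=self.is_calpha[idx],
            parent_indices=self.parent_indices[idx],
            label=self.label if label is None else label,
            source=self.source,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        if coords.shape != self.coords.shape:
            raise ValueError("replacement coordinates must match atom count")
        return Structure.from_arrays(
            elements=self.elements,
            names=self.names,
            residue_indices=self.residue_indices,
            residue_names=self.residue_names,
            chain_ids=self.chain_ids,
            coords=coords,
            is_backbone=self.is_backbone,
            is_heavy=self.is_heavy,
            is_calpha=self.is_calpha,
            parent_indices=self.parent_indices,
            label=self.label,
            source=self.source,
        )

    def same_roster(self, other: "Structure") -> bool:
        """True when both structures list the same atoms in the same order."""
        return (
            len(self) == len(other)
            and np.array_equal(self.names, other.names)
            and np.array_equal(self.elements, other.elements)
            and np.array_equal(self.residue_indices, other.residue_indices)
            and np.array_equal(self.chain_ids, other.chain_ids)
        )


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    _ORTHO_TOL = 1e-8

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-7):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (determinant +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(N, 3)`` array (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


# ---------------------------------------------------------------------------
# selection


Selector = Callable[[Structure], np.ndarray]


def parse_selector(expr: str) -> Selector:
    """Compile a simple selection expression into a mask function.

    The grammar is a disjunction (``or``) of conjunctions (``and``) of
    clauses; ``and`` binds tighter than ``or``.  Clauses:

    * ``all`` — every atom
    * ``backbone`` / ``sidechain`` / ``calpha`` / ``heavy``
    * ``protein`` — atoms of standard polymer residues
    * ``ligand`` — atoms of non-polymer residues
    * ``chain <id>[,<id>...]``
    * ``name <n1>[,<n2>...]``
    * ``resname <r1>[,<r2>...]``

    e.g. ``"chain A and backbone"`` or ``"backbone and heavy or ligand"``.
    """

    groups = [
        [c.strip() for c in part.split(" and ")]
        for part in expr.strip().split(" or ")
    ]

    def _conjunction(structure: Structure, clauses: list[str]) -> np.ndarray:
        m = np.ones(len(structure), dtype=bool)
        for clause in clauses:
            parts = clause.split(None, 1)
            if not parts:
                raise ValueError(f"empty clause in selector {expr!r}")
            key = parts[0].lower()
            if key == "all":
                continue
            if key == "backbone":
                m &= structure.is_backbone
            elif key == "sidechain":
                std = np.isin(
                    structure.residue_names.astype(str), list(STANDARD_RESIDUES)
                )
                m &= std & ~structure.is_backbone
            elif key == "calpha":
                m &= structure.is_calpha
            elif key == "heavy":
                m &= structure.is_heavy
            elif key == "protein":
                m &= np.isin(
                    structure.residue_names.astype(str), list(STANDARD_RESIDUES)
                )
            elif key == "ligand":
                m &= ~np.isin(
                    structure.residue_names.astype(str), list(STANDARD_RESIDUES)
                )
            elif key in ("chain", "name", "resname"):
                if len(parts) < 2:
                    raise ValueError(f"selector clause {clause!r} needs an argument")
                values = [v.strip() for v in parts[1].split(",") if v.strip()]
                col = {
                    "chain": structure.chain_ids,
                    "name": structure.names,
                    "resname": structure.residue_names,
                }[key]
                m &= np.isin(col.astype(str), values)
            else:
                raise ValueError(f"unknown selector clause {clause!r}")
        return m

    def mask(structure: Structure) -> np.ndarray:
        m = np.zeros(len(structure), dtype=bool)
        for clauses in groups:
            m |= _conjunction(structure, clauses)
        return m

    return mask


def select(structure: Structure, selector: Selector | str) -> Structure:
    """View containing exactly the atoms matching ``selector``.

    ``selector`` is either a selection-expression string (see
    :func:`parse_selector`) or a callable returning a boolean mask / per-atom
    predicate.  The original atom order is preserved and ``parent_indices``
    keep pointing into the parent structure.
    """
    if isinstance(selector, str):
        mask = parse_selector(selector)(structure)
    else:
        result = selector(structure)  # type: ignore[arg-type]
        mask = np.asarray(result, dtype=bool)
        if mask.shape != (len(structure),):
            raise ValueError("selector callable must return a per-atom boolean mask")
    return structure.take(np.flatnonzero(mask))


def apply_transform(structure: Structure, t: RigidTransform) -> Structure:
    """New structure with every coordinate mapped through ``t``."""
    return structure.with_coords(t.apply(structure.coords))


def concat(structures: Sequence[Structure], label: str = "") -> Structure:
    """Concatenate structures in order (parent indices are renumbered)."""
    if not structures:
        return Structure(label=label)
    return Structure.from_arrays(
        elements=np.concatenate([s.elements for s in structures]),
        names=np.concatenate([s.names for s in structures]),
        residue_indices=np.concatenate([s.residue_indices for s in structures]),
        residue_names=np.concatenate([s.residue_names for s in structures]),
        chain_ids=np.concatenate([s.chain_ids for s in structures]),
        coords=np.concatenate([s.coords for s in structures]),
        is_backbone=np.concatenate([s.is_backbone for s in structures]),
        is_heavy=np.concatenate([s.is_heavy for s in structures]),
        is_calpha=np.concatenate([s.is_calpha for s in structures]),
        label=label,
    )


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)


class PDBFormatError(ValueError):
    """Raised when a PDB file yields no usable atom records."""


def _classify(name: str, element: str, residue_name: str) -> tuple[bool, bool, bool]:
    """(is_backbone, is_heavy, is_calpha) from atom name/element/residue."""
    heavy = element.upper() not in _HYDROGEN_ELEMENTS
    polymer = residue_name in STANDARD_RESIDUES
    backbone = polymer and name in BACKBONE_NAMES
    calpha = polymer and name == "CA" and element.upper() == "C"
    return backbone, heavy, calpha


def _model_to_structure(
    model: gemmi.Model, *, keep_hydrogens: bool, label: str, source: str | None
) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            # altloc policy: per atom name keep highest occupancy,
            # ties -> altloc 'A', then first encountered
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                groups.setdefault(atom.name, []).append(atom)
            for name, group in groups.items():
                chosen = group[0]
                if len(group) > 1:
                    def rank(a: gemmi.Atom) -> tuple[float, int, int]:
                        return (
                            a.occ,
                            1 if a.altloc == "A" else 0,
                            -group.index(a),
                        )
                    chosen = max(group, key=rank)
                element = chosen.element.name
                if not keep_hydrogens and element.upper() in _HYDROGEN_ELEMENTS:
                    continue
                backbone, heavy, calpha = _classify(name, element, residue.name)
                atoms.append(
                    Atom(
                        element=element,
                        name=name,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        coords=np.array(
                            [chosen.pos.x, chosen.pos.y, chosen.pos.z]
                        ),
                        is_backbone=backbone,
                        is_heavy=heavy,
                        is_calpha=calpha,
                    )
                )
    return Structure(atoms, label=label, source=source)


def read_pdb(
    path: str | Path, *, keep_hydrogens: bool = False, label: str | None = None
) -> Structure:
    """Read the first model of a PDB file.

    Hydrogens are dropped unless ``keep_hydrogens``; for alternate locations
    the highest-occupancy conformer wins (ties: altloc ``A``, then first
    encountered).

    Raises
    ------
    OSError
        If the file cannot be read.
    PDBFormatError
        If no atom record survives parsing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models parsed")
    structure = _model_to_structure(
        st[0],
        keep_hydrogens=keep_hydrogens,
        label=label if label is not None else st.name or path.stem,
        source=str(path),
    )
    if len(structure) == 0:
        n_lines = sum(1 for _ in path.open())
        raise PDBFormatError(
            f"{path}: zero atoms parsed from {n_lines} lines"
        )
    return structure


def read_multimodel_pdb(
    path: str | Path, *, keep_hydrogens: bool = False
) -> list[Structure]:
    """Read every MODEL of a multi-model PDB file as a list of structures."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    frames = [
        _model_to_structure(
            model,
            keep_hydrogens=keep_hydrogens,
            label=f"{path.stem}#{i}",
            source=str(path),
        )
        for i, model in enumerate(st)
    ]
    if not frames or all(len(f) == 0 for f in frames):
        raise PDBFormatError(f"{path}: zero atoms parsed")
    return frames


def _structure_to_model(structure: Structure, num: int) -> gemmi.Model:
    model = gemmi.Model(num)
    chain: gemmi.Chain | None = None
    residue: gemmi.Residue | None = None
    prev_key: tuple | None = None
    for i in range(len(structure)):
        chain_id = str(structure.chain_ids[i])
        res_key = (chain_id, int(structure.residue_indices[i]), str(structure.residue_names[i]))
        if chain is None or chain.name != chain_id:
            chain = gemmi.Chain(chain_id)
            model.add_chain(chain)
            chain = model[len(model) - 1]
            prev_key = None
        if res_key != prev_key:
            residue = gemmi.Residue()
            residue.name = str(structure.residue_names[i])
            residue.seqid = gemmi.SeqId(int(structure.residue_indices[i]), " ")
            residue.het_flag = (
                "A" if str(structure.residue_names[i]) in STANDARD_RESIDUES else "H"
            )
            chain.add_residue(residue)
            residue = chain[len(chain) - 1]
            prev_key = res_key
        atom = gemmi.Atom()
        atom.name = str(structure.names[i])
        atom.element = gemmi.Element(str(structure.elements[i]))
        x, y, z = structure.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = 0.0
        residue.add_atom(atom)
    return model


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as fixed-width PDB ATOM/HETATM records.

    Round-tripping preserves element, name, residue, chain and coordinates to
    3 decimal places (the PDB fixed-width precision).  Structures with more
    than 99999 atoms use gemmi's serial-number convention.
    """
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.label or "ternscan"
    st.add_model(_structure_to_model(structure, 1))
    st.setup_entities()
    st.write_pdb(str(path))


def write_multimodel_pdb(
    frames: Sequence[Structure],
    path: str | Path,
    times_ns: Sequence[float] | None = None,
) -> None:
    """Write frames as a MODEL/ENDMDL multi-model PDB.

    Frame times, if given, go to a sidecar table ``<path>.times.tsv``
    (frame index, time in ns) so any MD engine's output stays readable.
    """
    if not frames:
        raise ValueError("no frames to write")
    st = gemmi.Structure()
    st.name = "trajectory"
    for i, frame in enumerate(frames):
        st.add_model(_structure_to_model(frame, i + 1))
    st.setup_entities()
    st.write_pdb(str(path))
    if times_ns is not None:
        if len(times_ns) != len(frames):
            raise ValueError("times_ns length must match frame count")
        sidecar = Path(str(path) + ".times.tsv")
        with sidecar.open("w") as fh:
            fh.write("frame\ttime_ns\n")
            for i, t in enumerate(times_ns):
                fh.write(f"{i}\t{t:g}\n")
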