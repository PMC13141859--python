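"""Least-squares rigid-body superposition (Kabsch) and RMSD.

Each protein–ligand complex is placed onto a PROTAC conformer by fitting its
bound ligand atoms onto the matching warhead atoms and moving the whole
complex with the fitted transform.  The atom correspondence is always an
explicit :class:`AtomMap` — substructure inference is deliberately out of
scope.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import RigidTransform, Structure, apply_transform

__all__ = ["AtomMap", "kabsch", "align_partner", "rmsd", "AlignedPartner"]


@dataclasses.dataclass(frozen=True)
class AtomMap:
    """Ordered correspondence (complex-ligand atom, PROTAC warhead atom).

    ``pairs[k] = (i, j)`` maps atom ``i`` of the source complex onto atom
    ``j`` of the PROTAC.  At least three non-collinear pairs are required for
    a well-defined rigid fit; indices must be unique on each side.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        left = [p[0] for p in pairs]
        right = [p[1] for p in pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("atom map indices must be unique on each side")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def source_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=np.int64)

    @property
    def target_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=np.int64)

    @classmethod
    def from_name_file(
        cls, path: str | Path, complex_structure: Structure, ligand: Structure
    ) -> "AtomMap":
        """Read a two-column map file of atom names.

        Each non-comment line is ``<complex atom name> <ligand atom name>``;
        names must be unique within the complex's non-polymer atoms and
        within the ligand.
        """
        pairs: list[tuple[int, int]] = []
        complex_names = [str(n) for n in complex_structure.names]
        ligand_names = [str(n) for n in ligand.names]
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{line_no}: expected two columns")
            src, dst = fields
            if complex_names.count(src) != 1:
                raise ValueError(
                    f"{path}:{line_no}: atom name {src!r} not unique in complex"
                )
            if ligand_names.count(dst) != 1:
                raise ValueError(
                    f"{path}:{line_no}: atom name {dst!r} not unique in ligand"
                )
            pairs.append((complex_names.index(src), ligand_names.index(dst)))
        return cls(pairs=tuple(pairs))


def _check_not_collinear(points: np.ndarray, context: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError(f"{context}: points are collinear (degenerate geometry)")


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Sequence[float] | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform minimising the (weighted) RMSD between the
    transformed mobile points and the reference, together with that minimal
    RMSD.  Reflections are never returned: the rotation is proper by
    construction.

    Raises
    ------
    ValueError
        Fewer than 3 points, mismatched lengths, or collinear geometry.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    if len(mob) < 3:
        raise ValueError("need at least 3 point pairs for a rigid fit")
    _check_not_collinear(mob, "kabsch mobile")
    _check_not_collinear(ref, "kabsch reference")
    if weights is None:
        w = np.ones(len(mob))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mob),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mob_centroid = (w[:, None] * mob).sum(axis=0) / wsum
    ref_centroid = (w[:, None] * ref).sum(axis=0) / wsum
    # scipy's align_vectors solves the constrained (proper-rotation) Wahba
    # problem; rssd is sqrt(sum_i w_i |ref_i - R mob_i|^2)
    rot, rssd = Rotation.align_vectors(
        ref - ref_centroid, mob - mob_centroid, weights=w
    )
    R = rot.as_matrix()
    transform = RigidTransform(R, ref_centroid - R @ mob_centroid)
    fitted_rmsd = float(rssd / np.sqrt(wsum))
    return transform, fitted_rmsd


def rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square deviation between two ordered point sets.

    No superposition is performed here; alignment is an explicit, separate
    step (:func:`kabsch`).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    if len(A) < 1:
        raise ValueError("need at least one point pair")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


@dataclasses.dataclass
class AlignedPartner:
    """A posed complex plus the fit metadata that produced it."""

    structure: Structure
    transform: RigidTransform
    mapped_rmsd: float


def align_partner(
    complex_structure: Structure,
    atom_map: AtomMap,
    conformer: Structure,
    weights: Sequence[float] | None = None,
) -> AlignedPartner:
    """Pose a protein–ligand complex onto a PROTAC conformer.

    The transform is fitted on the mapped ligand↔warhead atom pairs only and
    then applied to the entire complex (protein plus its bound ligand), so
    the complex's internal geometry is untouched.
    """
    if len(atom_map) < 3:
        raise ValueError(
            f"atom map has {len(atom_map)} pairs; need at least 3 for alignment"
        )
    src = atom_map.source_indices
    dst = atom_map.target_indices
    if src.max() >= len(complex_structure):
        raise ValueError("atom map source index out of range for the complex")
    if dst.max() >= len(conformer):
        raise ValueError("atom map target index out of range for the conformer")
    try:
        transform, fit_rmsd = kabsch(
            complex_structure.coords[src], conformer.coords[dst], weights=weights
        )
    except ValueError as exc:
        raise ValueError(
            f"alignment of {complex_structure.label or 'complex'} failed: {exc}"
        ) from exc
    posed = apply_transform(complex_structure, transform)
    return AlignedPartner(structure=posed, transform=transform, mapped_rmsd=fit_rmsd)
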