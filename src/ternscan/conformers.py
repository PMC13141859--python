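"""Dihedral conformer enumeration for diyne-linked PROTACs.

A rigid, linear diyne spacer (C≡C–C≡C) leaves the torsion about its own axis
as the only conformational degree of freedom between the two warheads.  The
scan therefore rotates one warhead about the linker axis on a regular angular
grid while the other warhead and the linker stay fixed — 10° steps give the
canonical 36-member conformer family.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Structure

__all__ = [
    "DiyneLigand",
    "ConformerSet",
    "rotate_about_axis",
    "enumerate_conformers",
    "fit_linker_axis",
]


def fit_linker_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through a set of points.

    Returns ``(axis_point, axis_dir, max_deviation_deg)`` where the axis
    point is the centroid, the direction is the dominant principal axis
    (unit norm), and the deviation is the largest angle between the axis and
    any centroid-to-point vector — a collinearity diagnostic in degrees.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least two 3-D points to fit an axis")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # orient consistently: from first to last point
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    norms = np.linalg.norm(centered, axis=1)
    nonzero = norms > 1e-12
    if not np.any(nonzero):
        return centroid, direction, 0.0
    cosines = np.abs(centered[nonzero] @ direction) / norms[nonzero]
    max_dev = float(np.degrees(np.arccos(np.clip(cosines.min(), -1.0, 1.0))))
    return centroid, direction, max_dev


@dataclasses.dataclass
class DiyneLigand:
    """A PROTAC partitioned into fixed warhead, diyne linker and mobile warhead.

    Parameters
    ----------
    atoms : Structure
        Full ligand.
    warhead_fixed : array of int
        Atom indices of the target-protein (POI) warhead; held fixed.
    warhead_mobile : array of int
        Atom indices of the E3-ligase warhead; rotated during the scan.
    linker : array of int
        Indices of the four sp carbons of the diyne.
    axis_point, axis_dir : 3-vectors
        Anchor point and unit direction of the rotation axis.
    collinearity_tol_deg : float
        Maximum allowed angular deviation of the linker carbons from the
        axis (default 5°); a genuinely bent "linker" has no well-defined
        single torsion and is rejected.
    """

    atoms: Structure
    warhead_fixed: np.ndarray
    warhead_mobile: np.ndarray
    linker: np.ndarray
    axis_point: np.ndarray
    axis_dir: np.ndarray
    collinearity_tol_deg: float = 5.0

    def __post_init__(self) -> None:
        self.warhead_fixed = np.asarray(self.warhead_fixed, dtype=np.int64)
        self.warhead_mobile = np.asarray(self.warhead_mobile, dtype=np.int64)
        self.linker = np.asarray(self.linker, dtype=np.int64)
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_dir = np.asarray(self.axis_dir, dtype=float)
        n = len(self.atoms)
        sets = [set(self.warhead_fixed), set(self.warhead_mobile), set(self.linker)]
        total = set().union(*sets)
        if sum(len(s) for s in sets) != len(total):
            raise ValueError("warhead and linker index sets must be disjoint")
        if total != set(range(n)):
            raise ValueError(
                "warhead_fixed, warhead_mobile and linker must cover all "
                f"{n} atoms exactly"
            )
        if abs(np.linalg.norm(self.axis_dir) - 1.0) > 1e-8:
            raise ValueError("axis_dir must be unit norm")
        _, _, dev = fit_linker_axis(self.atoms.coords[self.linker])
        if dev > self.collinearity_tol_deg:
            raise ValueError(
                f"linker carbons deviate {dev:.2f}° from collinearity "
                f"(tolerance {self.collinearity_tol_deg}°)"
            )

    @classmethod
    def from_partition(
        cls,
        atoms: Structure,
        warhead_fixed: Sequence[int],
        warhead_mobile: Sequence[int],
        linker: Sequence[int],
        collinearity_tol_deg: float = 5.0,
    ) -> "DiyneLigand":
        """Build a ligand, fitting the axis through the linker carbons."""
        linker = np.asarray(linker, dtype=np.int64)
        point, direction, _ = fit_linker_axis(atoms.coords[linker])
        return cls(
            atoms=atoms,
            warhead_fixed=np.asarray(warhead_fixed, dtype=np.int64),
            warhead_mobile=np.asarray(warhead_mobile, dtype=np.int64),
            linker=linker,
            axis_point=point,
            axis_dir=direction,
            collinearity_tol_deg=collinearity_tol_deg,
        )


@dataclasses.dataclass
class ConformerSet:
    """The dihedral-grid family of ligand conformers."""

    conformers: list[Structure]
    angles_deg: np.ndarray
    step_deg: float

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        n_expected = round(360.0 / self.step_deg)
        if abs(n_expected * self.step_deg - 360.0) > 1e-9:
            raise ValueError("step_deg must divide 360")
        if len(self.conformers) != n_expected or len(self.angles_deg) != n_expected:
            raise ValueError(
                f"expected {n_expected} conformers for a {self.step_deg}° grid"
            )
        diffs = np.diff(self.angles_deg)
        if self.angles_deg[0] != 0 or not np.allclose(diffs, self.step_deg):
            raise ValueError("angles must start at 0 with constant spacing")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(zip(self.angles_deg, self.conformers))


def rotate_about_axis(
    points: np.ndarray,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    angle_deg: float,
) -> np.ndarray:
    """Rodrigues rotation of points about an arbitrary axis.

    Points on the axis are fixed; distances to the axis are preserved.
    """
    axis_dir = np.asarray(axis_dir, dtype=float)
    norm = np.linalg.norm(axis_dir)
    if norm < 1e-12:
        raise ValueError("rotation axis has zero length")
    axis_dir = axis_dir / norm
    axis_point = np.asarray(axis_point, dtype=float)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis_dir)
    pts = np.asarray(points, dtype=float)
    return rot.apply(pts - axis_point) + axis_point


def enumerate_conformers(ligand: DiyneLigand, step_deg: float = 10.0) -> ConformerSet:
    """Systematic torsion scan about the diyne axis.

    Conformer ``i`` has the mobile warhead rotated by ``i * step_deg`` about
    the linker axis; the fixed warhead and the linker carbons are bitwise
    identical across all conformers.  The grid starts at the input geometry
    (angle 0).  ``step_deg`` must divide 360.
    """
    n_steps = round(360.0 / step_deg)
    if n_steps < 1 or abs(n_steps * step_deg - 360.0) > 1e-9:
        raise ValueError(f"step_deg={step_deg} does not divide 360")
    angles = np.arange(n_steps) * step_deg
    mobile = ligand.warhead_mobile
    base = ligand.atoms.coords
    conformers: list[Structure] = []
    for angle in angles:
        coords = base.copy()
        if angle != 0.0:
            coords[mobile] = rotate_about_axis(
                base[mobile], ligand.axis_point, ligand.axis_dir, float(angle)
            )
        conf = ligand.atoms.with_coords(coords)
        conf.label = f"{ligand.atoms.label or 'ligand'}@{angle:g}deg"
        conformers.append(conf)
    return ConformerSet(conformers=conformers, angles_deg=angles, step_deg=float(step_deg))
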