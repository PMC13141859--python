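"""Steric clash census between posed protein partners and the viability rule.

A clash is an unordered inter-structure heavy-atom pair closer than the
cutoff (default 2.4 Å, strict ``<``).  A posed conformer survives screening
only if it produces no backbone–backbone clash and at most 20 heavy-atom
clashing pairs in total — "at most 20" because rejection requires strictly
more than 20.

Two counting paths exist: a naive O(n·m) double loop and a KD-tree
accelerated path.  They must agree exactly; the tests hold them to that.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .conformers import ConformerSet
from .structure import Selector, Structure, parse_selector, select
from .superpose import AtomMap, align_partner

__all__ = [
    "ClashReport",
    "TernaryPose",
    "count_clashes",
    "is_viable",
    "screen_conformers",
    "DEFAULT_CLASH_CUTOFF",
    "DEFAULT_MAX_HEAVY_CLASHES",
]

logger = logging.getLogger(__name__)

DEFAULT_CLASH_CUTOFF = 2.4  # Å, heavy-atom distance below which a pair clashes
DEFAULT_MAX_HEAVY_CLASHES = 20  # rejection requires strictly more than this


@dataclasses.dataclass
class ClashReport:
    """Clash census between two structures.

    ``heavy_pairs`` counts all clashing heavy-atom pairs and is a superset
    of ``backbone_pairs`` (pairs where both atoms are backbone).
    """

    backbone_pairs: int
    heavy_pairs: int
    cutoff: float
    pair_list: list[tuple[int, int, float]] | None = None

    def __post_init__(self) -> None:
        if not (self.heavy_pairs >= self.backbone_pairs >= 0):
            raise ValueError(
                "invalid census: need heavy_pairs >= backbone_pairs >= 0"
            )
        if self.pair_list is not None:
            for i, j, d in self.pair_list:
                if d >= self.cutoff:
                    raise ValueError(
                        f"pair ({i},{j}) at {d:.3f} Å is not below the "
                        f"{self.cutoff} Å cutoff"
                    )


def count_clashes(
    A: Structure,
    B: Structure,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
    *,
    method: str = "grid",
    collect_pairs: bool = False,
) -> ClashReport:
    """Count inter-structure heavy-atom pairs with distance strictly < cutoff.

    ``method`` selects ``"grid"`` (KD-tree) or ``"naive"`` (full distance
    matrix); both return identical counts.  The backbone sub-count requires
    both atoms of a pair to be backbone atoms.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both structures must be non-empty")
    heavy_a = np.flatnonzero(A.is_heavy)
    heavy_b = np.flatnonzero(B.is_heavy)
    if len(heavy_a) == 0 or len(heavy_b) == 0:
        return ClashReport(0, 0, cutoff, [] if collect_pairs else None)
    coords_a = A.coords[heavy_a]
    coords_b = B.coords[heavy_b]
    bb_a = A.is_backbone[heavy_a]
    bb_b = B.is_backbone[heavy_b]

    if method == "naive":
        dists = cdist(coords_a, coords_b)
        ii, jj = np.nonzero(dists < cutoff)
        dd = dists[ii, jj]
    elif method == "grid":
        tree_a = cKDTree(coords_a)
        tree_b = cKDTree(coords_b)
        pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
        ii_list: list[int] = []
        jj_list: list[int] = []
        for i, neighbours in enumerate(pairs):
            ii_list.extend([i] * len(neighbours))
            jj_list.extend(neighbours)
        ii = np.array(ii_list, dtype=np.int64)
        jj = np.array(jj_list, dtype=np.int64)
        dd = (
            np.linalg.norm(coords_a[ii] - coords_b[jj], axis=1)
            if len(ii)
            else np.zeros(0)
        )
        keep = dd < cutoff  # KD-tree query includes the boundary; census is strict
        ii, jj, dd = ii[keep], jj[keep], dd[keep]
    else:
        raise ValueError(f"unknown clash-count method {method!r}")

    heavy_pairs = int(len(ii))
    backbone_pairs = int(np.count_nonzero(bb_a[ii] & bb_b[jj])) if heavy_pairs else 0
    pair_list = None
    if collect_pairs:
        pair_list = [
            (int(heavy_a[i]), int(heavy_b[j]), float(d))
            for i, j, d in zip(ii, jj, dd)
        ]
    return ClashReport(
        backbone_pairs=backbone_pairs,
        heavy_pairs=heavy_pairs,
        cutoff=cutoff,
        pair_list=pair_list,
    )


def is_viable(report: ClashReport, max_heavy: int = DEFAULT_MAX_HEAVY_CLASHES) -> bool:
    """Viability rule: no backbone clash and at most ``max_heavy`` heavy pairs.

    Exactly ``max_heavy`` clashes is still viable; rejection requires
    strictly more.
    """
    return report.backbone_pairs == 0 and report.heavy_pairs <= max_heavy


@dataclasses.dataclass
class TernaryPose:
    """One aligned target+ligase placement for a single grid angle."""

    conformer_angle: float
    pose_A: Structure
    pose_B: Structure
    ligand: Structure
    clash: ClashReport
    viable: bool
    mapped_rmsd_A: float = 0.0
    mapped_rmsd_B: float = 0.0


def screen_conformers(
    conformers: ConformerSet,
    complex_A: Structure,
    map_A: AtomMap,
    complex_B: Structure,
    map_B: AtomMap,
    *,
    clash_selection_A: Selector | str | None = None,
    clash_selection_B: Selector | str | None = None,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
    max_heavy: int = DEFAULT_MAX_HEAVY_CLASHES,
    include_ligand: bool = False,
    method: str = "grid",
) -> list[TernaryPose]:
    """Align both partners onto every conformer and apply the viability rule.

    For each grid angle the two complexes are posed by warhead superposition
    and the clash census runs between their selected atoms (default: every
    heavy atom of each posed complex; pass selectors to e.g. drop accessory
    chains).  With ``include_ligand`` the conformer's own atoms are added to
    each side's census against the opposite protein.

    Returns one :class:`TernaryPose` per conformer, in grid order.
    """
    sel_A = parse_selector(clash_selection_A) if isinstance(clash_selection_A, str) else clash_selection_A
    sel_B = parse_selector(clash_selection_B) if isinstance(clash_selection_B, str) else clash_selection_B
    poses: list[TernaryPose] = []
    for angle, conformer in conformers:
        try:
            aligned_A = align_partner(complex_A, map_A, conformer)
            aligned_B = align_partner(complex_B, map_B, conformer)
        except ValueError as exc:
            raise ValueError(f"screening aborted at angle {angle:g}°: {exc}") from exc
        census_A = select(aligned_A.structure, sel_A) if sel_A is not None else aligned_A.structure
        census_B = select(aligned_B.structure, sel_B) if sel_B is not None else aligned_B.structure
        report = count_clashes(census_A, census_B, cutoff=cutoff, method=method)
        backbone = report.backbone_pairs
        heavy = report.heavy_pairs
        if include_ligand:
            for partner in (census_A, census_B):
                lig_report = count_clashes(conformer, partner, cutoff=cutoff, method=method)
                heavy += lig_report.heavy_pairs
        combined = ClashReport(backbone_pairs=backbone, heavy_pairs=heavy, cutoff=cutoff)
        poses.append(
            TernaryPose(
                conformer_angle=float(angle),
                pose_A=aligned_A.structure,
                pose_B=aligned_B.structure,
                ligand=conformer,
                clash=combined,
                viable=is_viable(combined, max_heavy=max_heavy),
                mapped_rmsd_A=aligned_A.mapped_rmsd,
                mapped_rmsd_B=aligned_B.mapped_rmsd,
            )
        )
    n_viable = sum(p.viable for p in poses)
    logger.info(
        "screened %d conformers: %d viable (cutoff %.2f Å, max %d heavy clashes)",
        len(poses), n_viable, cutoff, max_heavy,
    )
    return poses
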