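"""Staged restrained-relaxation protocol, trajectory bookkeeping and
representative-frame selection.

Rigid-body docking leaves strained interfaces, so posed complexes are relaxed
under a schedule of positional harmonic restraints that are released in
stages: first everything heavy is restrained, then protein sidechains are
freed, then the protein backbone, and finally the ligand.  Production MD is
out of scope here — trajectories are consumed as multi-model PDB files
whatever engine produced them — but a toy soft-sphere restrained minimizer is
provided so the release semantics are exercisable end-to-end.

Frame bookkeeping follows the simulation design of 50 ns sampled every
0.5 ns with the first 10 ns discarded as equilibration, and the
representative snapshot is the medoid frame: the one with the lowest median
RMSD (over a chosen atom selection, after per-pair superposition on an
alignment selection) to all other frames.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import Selector, Structure, parse_selector
from .superpose import kabsch, rmsd

__all__ = [
    "RestraintStage",
    "RestraintSchedule",
    "Trajectory",
    "build_restraint_schedule",
    "equilibration_filter",
    "select_representative",
    "restrained_minimize",
    "SoftSphereParams",
    "DEFAULT_FORCE_CONSTANT",
]

logger = logging.getLogger(__name__)

DEFAULT_FORCE_CONSTANT = 10.0  # kcal mol^-1 Å^-2, harmonic positional restraint


@dataclasses.dataclass(frozen=True)
class RestraintStage:
    """One stage of the release schedule.

    ``restrained`` selects the atoms held by harmonic positional restraints
    of strength ``force_constant`` (kcal·mol⁻¹·Å⁻²) during this stage.
    """

    name: str
    restrained: str
    force_constant: float = DEFAULT_FORCE_CONSTANT
    action: str = "minimize"

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if self.action not in ("minimize", "simulate"):
            raise ValueError(f"unknown stage action {self.action!r}")

    def restrained_mask(self, structure: Structure) -> np.ndarray:
        if not self.restrained:
            return np.zeros(len(structure), dtype=bool)
        return parse_selector(self.restrained)(structure)


@dataclasses.dataclass(frozen=True)
class RestraintSchedule:
    """Ordered stages whose restrained sets only ever shrink."""

    stages: tuple[RestraintStage, ...]

    def validate_monotone(self, structure: Structure) -> None:
        """Check on a concrete roster that each stage releases, never re-restrains."""
        prev: np.ndarray | None = None
        for stage in self.stages:
            mask = stage.restrained_mask(structure)
            if prev is not None and np.any(mask & ~prev):
                raise ValueError(
                    f"stage {stage.name!r} re-restrains atoms released earlier"
                )
            prev = mask

    def describe(self) -> str:
        """Plain-text report usable as input documentation for any MD engine."""
        lines = ["restraint schedule (positional harmonic restraints)"]
        for i, s in enumerate(self.stages, 1):
            sel = s.restrained or "(none)"
            lines.append(
                f"  stage {i} [{s.name}]: action={s.action}, "
                f"k={s.force_constant:g} kcal/mol/A^2, restrained={sel}"
            )
        return "\n".join(lines)


def build_restraint_schedule(
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> RestraintSchedule:
    """The canonical 4-stage gradual-release minimisation schedule.

    1. restrain all protein and ligand heavy atoms;
    2. release the protein sidechains;
    3. release the protein backbone (ligand still held);
    4. release the ligand — nothing restrained.
    """
    return RestraintSchedule(
        stages=(
            RestraintStage("all-heavy", "heavy", force_constant),
            RestraintStage(
                "release-sidechains", "backbone and heavy or ligand and heavy", force_constant
            ),
            RestraintStage("release-backbone", "ligand and heavy", force_constant),
            RestraintStage("release-ligand", "", force_constant),
        )
    )


@dataclasses.dataclass
class Trajectory:
    """Time-stamped frames over a constant atom roster."""

    frames: list[Structure]
    times_ns: np.ndarray

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if len(self.frames) != len(self.times_ns):
            raise ValueError("frames and times must have equal length")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("frame times must be strictly increasing")
        for frame in self.frames[1:]:
            if not frame.same_roster(self.frames[0]):
                raise ValueError("all frames must share the same atom roster")

    def __len__(self) -> int:
        return len(self.frames)


def equilibration_filter(traj: Trajectory, discard_ns: float = 10.0) -> Trajectory:
    """Drop the leading equilibration period; keep frames with time > discard.

    Emits a warning (and returns an empty trajectory) when nothing survives;
    the caller decides whether that is fatal.
    """
    keep = traj.times_ns > discard_ns
    if not np.any(keep):
        warnings.warn(
            f"equilibration filter at {discard_ns:g} ns discarded every frame",
            stacklevel=2,
        )
    idx = np.flatnonzero(keep)
    return Trajectory(
        frames=[traj.frames[i] for i in idx], times_ns=traj.times_ns[idx]
    )


def select_representative(
    traj: Trajectory,
    align_selection: Selector | str,
    rmsd_selection: Selector | str,
) -> int:
    """Medoid frame index: lowest median RMSD to all other frames.

    For each candidate frame *i*, every other frame *j* is superposed onto
    *i* using the alignment selection (e.g. the ligase backbone) and the RMSD
    is evaluated over the RMSD selection (e.g. the target's Cα atoms); the
    median over *j* ≠ *i* scores the candidate.  Ties break to the lowest
    index; a single frame scores 0 and is returned.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    align_mask = (
        parse_selector(align_selection)(traj.frames[0])
        if isinstance(align_selection, str)
        else np.asarray(align_selection(traj.frames[0]), dtype=bool)
    )
    rmsd_mask = (
        parse_selector(rmsd_selection)(traj.frames[0])
        if isinstance(rmsd_selection, str)
        else np.asarray(rmsd_selection(traj.frames[0]), dtype=bool)
    )
    if not align_mask.any():
        raise ValueError("alignment selection matches no atoms")
    if not rmsd_mask.any():
        raise ValueError("RMSD selection matches no atoms")
    n = len(traj)
    if n == 1:
        return 0
    align_idx = np.flatnonzero(align_mask)
    rmsd_idx = np.flatnonzero(rmsd_mask)
    # pairwise superposed RMSD is symmetric: kabsch minimises the same
    # objective in either direction, so compute each unordered pair once
    pairwise = np.zeros((n, n))
    for i in range(n):
        ref_align = traj.frames[i].coords[align_idx]
        ref_rmsd = traj.frames[i].coords[rmsd_idx]
        for j in range(i + 1, n):
            transform, _ = kabsch(traj.frames[j].coords[align_idx], ref_align)
            moved = transform.apply(traj.frames[j].coords[rmsd_idx])
            pairwise[i, j] = pairwise[j, i] = rmsd(moved, ref_rmsd)
    medians = np.array(
        [np.median(np.delete(pairwise[i], i)) for i in range(n)]
    )
    return int(np.argmin(medians))  # argmin takes the first (lowest) index on ties


# ---------------------------------------------------------------------------
# toy restrained minimizer


@dataclasses.dataclass(frozen=True)
class SoftSphereParams:
    """Pairwise soft repulsion U(r) = epsilon * (sigma/r)^12.

    sigma defaults to 2.4 Å, echoing the clash cutoff, so minimisation
    pushes censused clashes apart; epsilon is in kcal/mol.
    """

    sigma: float = 2.4
    epsilon: float = 1.0
    cutoff: float = 6.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon < 0 or self.cutoff <= 0:
            raise ValueError("soft-sphere parameters must be positive")


def _energy_and_gradient(
    coords: np.ndarray,
    reference: np.ndarray,
    restrained: np.ndarray,
    k: float,
    potential: SoftSphereParams,
) -> tuple[float, np.ndarray]:
    n = len(coords)
    grad = np.zeros_like(coords)
    energy = 0.0
    if n > 1:
        dists = squareform(pdist(coords))
        ii, jj = np.triu_indices(n, k=1)
        d = dists[ii, jj]
        near = d < potential.cutoff
        ii, jj, d = ii[near], jj[near], d[near]
        d = np.maximum(d, 1e-6)  # soft clamp to keep overlapping atoms finite
        ratio = (potential.sigma / d) ** 12
        energy += potential.epsilon * ratio.sum()
        # dU/dr = -12 eps sigma^12 / r^13
        coeff = -12.0 * potential.epsilon * ratio / d
        diff = (coords[ii] - coords[jj]) / d[:, None]
        forces = coeff[:, None] * diff
        np.add.at(grad, ii, forces)
        np.add.at(grad, jj, -forces)
    if k > 0 and restrained.any():
        delta = coords[restrained] - reference[restrained]
        energy += k * np.sum(delta**2)
        grad[restrained] += 2.0 * k * delta
    return float(energy), grad


def restrained_minimize(
    structure: Structure,
    reference: Structure,
    stage: RestraintStage,
    potential: SoftSphereParams = SoftSphereParams(),
    max_steps: int = 500,
    tol: float = 1e-4,
) -> Structure:
    """Gradient descent on soft-sphere repulsion plus stage restraints.

    Energy is ``Σ_pairs ε(σ/r)¹² + Σ_restrained k·|x − x_ref|²`` with the
    restrained set taken from ``stage`` evaluated on the structure.  Uses
    backtracking line search, so the energy never increases between accepted
    iterates; stops when the gradient norm falls below ``tol`` or after
    ``max_steps``.  This is a deliberately minimal stand-in for a real MD
    engine's minimiser: it exercises the schedule's release semantics, not
    force-field physics.
    """
    if not structure.same_roster(reference):
        raise ValueError("structure and reference must share the same atom roster")
    restrained = stage.restrained_mask(structure)
    coords = structure.coords.copy()
    ref_coords = reference.coords
    k = stage.force_constant
    energy, grad = _energy_and_gradient(coords, ref_coords, restrained, k, potential)
    step = 1e-3
    for _ in range(max_steps):
        gnorm = np.linalg.norm(grad)
        if gnorm < tol:
            break
        # backtracking: shrink until the move lowers the energy
        accepted = False
        trial_step = step
        for _ in range(40):
            trial = coords - trial_step * grad
            e_trial, g_trial = _energy_and_gradient(
                trial, ref_coords, restrained, k, potential
            )
            if e_trial <= energy:
                coords, energy, grad = trial, e_trial, g_trial
                step = trial_step * 1.5
                accepted = True
                break
            trial_step *= 0.5
        if not accepted:
            break
    return structure.with_coords(coords)
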