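"""Per-frame measurements: virial stress, molecular strain, gap/overlap
profile, class-filtered interaction energies, broken-bond bookkeeping.

All functions are pure in (frame data, model): repeated evaluation on the
same inputs returns identical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forcefield as ff
from .model import COLLAGEN, MINERAL, FibrilModel
from .units import ACC_CONV, STRESS_GPA


def virial_stress(
    per_bead_virial: np.ndarray,
    velocities: np.ndarray,
    masses: np.ndarray,
    volume: float,
    include_kinetic: bool = True,
    subset: np.ndarray | None = None,
    component: int = 0,
) -> float:
    """Axial (or another diagonal) virial stress in GPa, tension positive.

    ``per_bead_virial`` is the (N, 6) array from the force evaluation.  The
    kinetic term is included by default (full virial).  ``subset`` restricts
    the per-bead sum (e.g. mineral-only internal stress) while keeping the
    same volume convention; the volume is always the constant-diameter
    cylinder volume supplied by the caller.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if subset is None:
        w = np.sum(per_bead_virial[:, component])
        kin = np.sum(masses * velocities[:, component] ** 2) if include_kinetic else 0.0
    else:
        w = np.sum(per_bead_virial[subset, component])
        kin = (
            np.sum(masses[subset] * velocities[subset, component] ** 2)
            if include_kinetic
            else 0.0
        )
    # configurational part is negative under tension; kinetic part (m v v)
    # acts as a positive pressure.  Tension-positive stress:
    return float(-(w + kin / ACC_CONV) / volume * STRESS_GPA)


def mineral_internal_stress(model: FibrilModel, result: ff.ForceResult) -> float:
    """Axial virial stress of the mineral beads alone, normalized by the
    total fibril volume (declared convention), GPa."""
    subset = np.flatnonzero(model.species == MINERAL)
    if not len(subset):
        return 0.0
    return virial_stress(
        result.virial,
        model.velocities,
        model.masses,
        model.cylinder_volume(),
        subset=subset,
    )


def molecule_contours(model: FibrilModel) -> np.ndarray:
    """Per-molecule contour length = sum of unbroken backbone bond lengths."""
    Lx = model.box.Lx
    out = np.zeros(model.n_molecules)
    ij = model.bond_ij
    backbone = model.bond_kind == 0
    d = model.positions[ij[:, 1]] - model.positions[ij[:, 0]]
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    r = np.linalg.norm(d, axis=1)
    r[model.bond_broken] = 0.0
    mol_of_bond = model.molecule_id[ij[:, 0]]
    for k in range(model.n_molecules):
        sel = backbone & (mol_of_bond == k)
        out[k] = np.sum(r[sel])
    return out


@dataclass
class MolecularStrain:
    per_molecule: np.ndarray
    mean: float
    n_excluded: int  # molecules with at least one broken bond


def molecular_strain(
    model: FibrilModel, ref_contours: np.ndarray
) -> MolecularStrain:
    """Per-molecule and mean contour strain vs. reference contours.

    Molecules containing broken bonds are excluded from the mean and counted
    separately.
    """
    cur = molecule_contours(model)
    strain = cur / ref_contours - 1.0
    ij = model.bond_ij
    mol_of_bond = model.molecule_id[ij[:, 0]]
    broken_mols = np.unique(
        mol_of_bond[(model.bond_kind == 0) & model.bond_broken]
    )
    ok = np.ones(model.n_molecules, bool)
    ok[broken_mols[broken_mols >= 0]] = False
    mean = float(np.mean(strain[ok])) if np.any(ok) else float("nan")
    return MolecularStrain(
        per_molecule=strain, mean=mean, n_excluded=int(np.sum(~ok))
    )


def per_bead_strain(model: FibrilModel) -> np.ndarray:
    """Bond-strain field mapped to beads (mean of adjacent unbroken bonds)."""
    Lx = model.box.Lx
    ij = model.bond_ij
    d = model.positions[ij[:, 1]] - model.positions[ij[:, 0]]
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    r = np.linalg.norm(d, axis=1)
    eps = r / model.bond_params[:, 0] - 1.0
    num = np.zeros(model.n_beads)
    den = np.zeros(model.n_beads)
    ok = (~model.bond_broken) & (model.bond_kind == 0)
    np.add.at(num, ij[ok, 0], eps[ok])
    np.add.at(num, ij[ok, 1], eps[ok])
    np.add.at(den, ij[ok, 0], 1.0)
    np.add.at(den, ij[ok, 1], 1.0)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


@dataclass
class GapOverlapProfile:
    n_gap_segments: int
    n_overlap_segments: int
    gap_length: float
    overlap_length: float
    degenerate: bool
    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def ratio(self) -> float:
        return self.gap_length / self.overlap_length if self.overlap_length else np.inf


def gap_overlap_profile(
    model: FibrilModel, bin_width: float = 14.0, threshold: float | None = None
) -> GapOverlapProfile:
    """Classify axial bins gap/overlap by molecule count per cross-section.

    The threshold defaults to the midpoint between the construction-time gap
    and overlap molecule counts.  A constant profile (no stagger) is flagged
    degenerate.
    """
    Lx = model.box.Lx
    nbins = int(Lx / bin_width)
    if nbins < 2:
        raise ValueError("bin width larger than the box")
    if model.gap_slabs.size:
        gap_w = np.min(
            np.where(
                model.gap_slabs[:, 1] >= model.gap_slabs[:, 0],
                model.gap_slabs[:, 1] - model.gap_slabs[:, 0],
                model.gap_slabs[:, 1] + Lx - model.gap_slabs[:, 0],
            )
        )
        if bin_width > gap_w:
            raise ValueError(
                f"bin width {bin_width} Å exceeds the gap length {gap_w:.1f} Å"
            )
    edges = np.linspace(0.0, Lx, nbins + 1)
    coll = model.species == COLLAGEN
    x = np.mod(model.positions[coll, 0], Lx)
    mol = model.molecule_id[coll]
    bin_of = np.minimum((x / (Lx / nbins)).astype(int), nbins - 1)
    # distinct molecules per bin
    counts = np.zeros(nbins, int)
    pairs = np.unique(np.stack([bin_of, mol], axis=1), axis=0)
    np.add.at(counts, pairs[:, 0], 1)
    if counts.min() == counts.max():
        return GapOverlapProfile(0, 0, 0.0, Lx, True, counts, edges)
    if threshold is None:
        if model.overlap_count > model.gap_count:
            threshold = (model.gap_count + model.overlap_count) / 2.0
        else:
            threshold = (counts.min() + counts.max()) / 2.0
    is_gap = counts < threshold
    # count circular runs
    changes = np.sum(is_gap != np.roll(is_gap, 1))
    n_gap = changes // 2
    n_overlap = changes // 2
    bw = Lx / nbins
    return GapOverlapProfile(
        n_gap_segments=int(n_gap),
        n_overlap_segments=int(n_overlap),
        gap_length=float(np.sum(is_gap) * bw),
        overlap_length=float(np.sum(~is_gap) * bw),
        degenerate=False,
        counts=counts,
        bin_edges=edges,
    )


def interaction_energy_sums(
    model: FibrilModel, nl: ff.NeighborList | None = None
) -> tuple[float, float]:
    """(collagen-mineral, mineral-mineral) pair-energy sums, kcal/mol."""
    res = ff.compute_forces(model, nl)
    return res.energy.E_inter, res.energy.E_HAP


@dataclass
class BrokenBondSeries:
    counts: np.ndarray
    molecule_failure_fraction: float


def count_broken_bonds(
    trajectory, model: FibrilModel | None = None
) -> BrokenBondSeries:
    """Broken-bond count per frame plus the final molecule-failure fraction
    (requires the model topology for the bond-to-molecule map)."""
    counts = []
    last_flags = None
    for fr in trajectory.frames:
        if fr.bond_broken is not None:
            counts.append(int(np.sum(fr.bond_broken)))
            last_flags = fr.bond_broken
        else:
            counts.append(int(fr.broken_bonds))
    frac = float("nan")
    if model is not None and last_flags is not None:
        ij = model.bond_ij
        mol_of_bond = model.molecule_id[ij[:, 0]]
        sel = (model.bond_kind == 0) & last_flags
        broken_mols = np.unique(mol_of_bond[sel])
        frac = len(broken_mols[broken_mols >= 0]) / max(1, model.n_molecules)
    return BrokenBondSeries(
        counts=np.asarray(counts), molecule_failure_fraction=frac
    )


def molecule_failure_fraction(model: FibrilModel) -> float:
    """Fraction of molecules with at least one broken backbone bond."""
    ij = model.bond_ij
    mol_of_bond = model.molecule_id[ij[:, 0]]
    sel = (model.bond_kind == 0) & model.bond_broken
    broken_mols = np.unique(mol_of_bond[sel])
    return len(broken_mols[broken_mols >= 0]) / max(1, model.n_molecules)
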