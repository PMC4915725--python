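"""Domain types of the mesoscale mineralized-fibril model.

Two representations coexist:

* light dataclasses (:class:`Bead`, :class:`Bond`, :class:`Angle`) that
  carry the published parameters and serve as the reference definition of
  each interaction term;
* a struct-of-arrays container (:class:`FibrilModel`) holding the whole
  particle system, which is what the builder produces and the force field
  and integrator consume.

All parameters default to the published mesoscale parameter set for
collagen and hydroxyapatite (HAP) beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# species codes
COLLAGEN = 0
MINERAL = 1

# --- published bond / angle / pair parameters -------------------------------

#: equilibrium bead distance, Å
R0 = 14.00
#: critical hyperelastic distance, Å
R1 = 18.20
#: bond breaking distance, Å
RBREAK = 21.00
#: small-deformation tensile stiffness, kcal/mol/Å²
KT0 = 17.13
#: large-deformation tensile stiffness, kcal/mol/Å²
KT1 = 97.66
#: bending stiffness, kcal/mol/rad²
KB_ANGLE = 14.98

#: collagen bead mass, amu (14-Å triple-helix segment)
MASS_COLLAGEN = 1324.0
#: hydroxyapatite bead mass, amu
MASS_MINERAL = 1548.0

SIGMA_COLL = 14.72
EPS_COLL = 6.87
#: collagen-collagen cutoff: 2.5 σ_coll (configurable; captures the adhesive well)
CUTOFF_COLL = 2.5 * SIGMA_COLL

SIGMA_HAP = 10.28
EPS_HAP = 106.7
CUTOFF_HAP = 13.85

SIGMA_INTER = 9.88
EPS_INTER = 137.1
CUTOFF_INTER = 20.00

BACKBONE = 0
CROSSLINK = 1


@dataclass(frozen=True)
class BeadSpecies:
    name: str
    mass: float


SPECIES = (
    BeadSpecies("collagen", MASS_COLLAGEN),
    BeadSpecies("mineral", MASS_MINERAL),
)


@dataclass
class Bead:
    """One mesoscale particle (a 14-Å tropocollagen segment or a HAP bead)."""

    id: int
    species: int  # COLLAGEN or MINERAL
    molecule_id: int  # -1 for mineral
    axial_index: int  # position along the molecule; -1 for mineral
    position: np.ndarray
    velocity: np.ndarray


@dataclass
class Bond:
    """Bilinear breakable spring between two beads.

    The restoring force is ``kT0·(r−r0)`` below the hyperelastic distance
    ``r1``, ``kT1·(r−r0)`` between ``r1`` and ``r_break``, and zero beyond
    ``r_break``; crossing ``r_break`` breaks the bond irreversibly.
    """

    i: int
    j: int
    r0: float = R0
    r1: float = R1
    r_break: float = RBREAK
    kT0: float = KT0
    kT1: float = KT1
    kind: int = BACKBONE
    broken: bool = False


@dataclass
class Angle:
    """Harmonic three-bead angle with equilibrium angle phi_i in degrees."""

    i: int
    j: int
    k: int
    phi_i: float = 180.0
    kB: float = KB_ANGLE


@dataclass
class PairTable:
    """Lennard-Jones parameters per species pair (2×2 symmetric tables)."""

    sigma: np.ndarray = field(
        default_factory=lambda: np.array(
            [[SIGMA_COLL, SIGMA_INTER], [SIGMA_INTER, SIGMA_HAP]]
        )
    )
    epsilon: np.ndarray = field(
        default_factory=lambda: np.array(
            [[EPS_COLL, EPS_INTER], [EPS_INTER, EPS_HAP]]
        )
    )
    cutoff: np.ndarray = field(
        default_factory=lambda: np.array(
            [[CUTOFF_COLL, CUTOFF_INTER], [CUTOFF_INTER, CUTOFF_HAP]]
        )
    )
    #: if True, subtract the pair energy at the cutoff (plain truncation by default)
    shift: bool = False

    def max_cutoff(self) -> float:
        return float(np.max(self.cutoff))


@dataclass
class SimulationBox:
    """Orthogonal box, periodic along the fibril (x) axis."""

    lengths: np.ndarray
    periodic: np.ndarray = field(
        default_factory=lambda: np.array([True, False, False])
    )
    #: reference axial length for strain bookkeeping, Å
    L_ref: float = 0.0

    @property
    def Lx(self) -> float:
        return float(self.lengths[0])

    @property
    def axial_strain(self) -> float:
        return self.Lx / self.L_ref - 1.0 if self.L_ref else 0.0


@dataclass
class EnergyBreakdown:
    """Energy bookkeeping: E_total = E_collagen + E_HAP + E_inter and
    E_collagen = E_bond + E_angle + E_nonbonded."""

    E_bond: float = 0.0
    E_angle: float = 0.0
    E_nonbonded: float = 0.0  # collagen-collagen pair energy
    E_HAP: float = 0.0  # mineral-mineral pair energy
    E_inter: float = 0.0  # collagen-mineral pair energy

    @property
    def E_collagen(self) -> float:
        return self.E_bond + self.E_angle + self.E_nonbonded

    @property
    def E_total(self) -> float:
        return self.E_collagen + self.E_HAP + self.E_inter


@dataclass
class EngineConfig:
    """Integrator / thermostat / barostat settings."""

    timestep: float = 10.0  # fs
    temperature: float = 300.0  # K
    damping: float = 1000.0  # Langevin damping time, fs
    equilibration_ns: float = 20.0
    pull_rate: float = 1.0  # m/s
    seed: int = 0
    barostat: str = "axial"  # or "off"
    #: Berendsen-style axial relaxation time, fs
    barostat_damping: float = 10000.0
    #: bulk-modulus scale used by the axial barostat, GPa
    barostat_modulus: float = 5.0
    #: neighbor-list skin, Å
    skin: float = 2.0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.pull_rate < 0:
            raise ValueError("pull rate must be non-negative")


@dataclass
class MoleculeInfo:
    """Registry entry for one tropocollagen molecule (contiguous bead range)."""

    start: int  # first bead index
    n_beads: int
    stagger_class: int
    x_start: float  # axial position of the N-terminal bead at construction
    x_end: float  # axial position of the C-terminal bead at construction

    @property
    def stop(self) -> int:
        return self.start + self.n_beads


@dataclass
class FibrilModel:
    """Struct-of-arrays particle system for one fibril.

    Collagen beads come first, contiguous per molecule; mineral beads follow.
    """

    positions: np.ndarray  # (N, 3) Å
    velocities: np.ndarray  # (N, 3) Å/fs
    species: np.ndarray  # (N,) int8
    molecule_id: np.ndarray  # (N,) int32; -1 for mineral
    axial_index: np.ndarray  # (N,) int32; -1 for mineral
    bond_ij: np.ndarray  # (M, 2) int32
    bond_params: np.ndarray  # (M, 5): r0, r1, r_break, kT0, kT1
    bond_kind: np.ndarray  # (M,) int8
    bond_broken: np.ndarray  # (M,) bool
    angle_ijk: np.ndarray  # (K, 3) int32
    angle_phi0: np.ndarray  # (K,) degrees
    angle_k: np.ndarray  # (K,) kcal/mol/rad²
    pair_table: PairTable
    box: SimulationBox
    molecules: list[MoleculeInfo] = field(default_factory=list)
    #: axial positions (Å) of molecule terminal planes at construction
    terminal_planes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    #: gap/overlap boundary positions at construction: (g0, g1) per gap slab
    gap_slabs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    D_period: float = 670.0
    periods: int = 5
    diameter: float = 200.0  # Å
    mineral_wt: float = 0.0  # achieved weight fraction, percent
    mass_collagen: float = MASS_COLLAGEN
    mass_mineral: float = MASS_MINERAL
    #: collagen-molecule count per cross-section in gap / overlap at construction
    gap_count: int = 0
    overlap_count: int = 0

    # -- convenience ---------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_collagen(self) -> int:
        return int(np.sum(self.species == COLLAGEN))

    @property
    def n_mineral(self) -> int:
        return int(np.sum(self.species == MINERAL))

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def masses(self) -> np.ndarray:
        return np.where(self.species == COLLAGEN, self.mass_collagen, self.mass_mineral)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def total_mass(self) -> float:
        return float(np.sum(self.masses))

    def cylinder_volume(self) -> float:
        """Fibril volume at the constant-diameter convention, Å³."""
        return float(np.pi * self.radius**2 * self.box.Lx)

    def copy(self) -> "FibrilModel":
        return FibrilModel(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            axial_index=self.axial_index.copy(),
            bond_ij=self.bond_ij.copy(),
            bond_params=self.bond_params.copy(),
            bond_kind=self.bond_kind.copy(),
            bond_broken=self.bond_broken.copy(),
            angle_ijk=self.angle_ijk.copy(),
            angle_phi0=self.angle_phi0.copy(),
            angle_k=self.angle_k.copy(),
            pair_table=replace(
                self.pair_table,
                sigma=self.pair_table.sigma.copy(),
                epsilon=self.pair_table.epsilon.copy(),
                cutoff=self.pair_table.cutoff.copy(),
            ),
            box=SimulationBox(
                self.box.lengths.copy(), self.box.periodic.copy(), self.box.L_ref
            ),
            molecules=[replace(m) for m in self.molecules],
            terminal_planes=self.terminal_planes.copy(),
            gap_slabs=self.gap_slabs.copy(),
            D_period=self.D_period,
            periods=self.periods,
            diameter=self.diameter,
            mineral_wt=self.mineral_wt,
            mass_collagen=self.mass_collagen,
            mass_mineral=self.mass_mineral,
            gap_count=self.gap_count,
            overlap_count=self.overlap_count,
        )

    def get_bead(self, i: int) -> Bead:
        return Bead(
            id=i,
            species=int(self.species[i]),
            molecule_id=int(self.molecule_id[i]),
            axial_index=int(self.axial_index[i]),
            position=self.positions[i].copy(),
            velocity=self.velocities[i].copy(),
        )

    def get_bond(self, m: int) -> Bond:
        p = self.bond_params[m]
        return Bond(
            i=int(self.bond_ij[m, 0]),
            j=int(self.bond_ij[m, 1]),
            r0=float(p[0]),
            r1=float(p[1]),
            r_break=float(p[2]),
            kT0=float(p[3]),
            kT1=float(p[4]),
            kind=int(self.bond_kind[m]),
            broken=bool(self.bond_broken[m]),
        )


# --- validation -------------------------------------------------------------


def validate_model(m: FibrilModel) -> list[str]:
    """Check all type invariants; return a list of violations (empty = valid)."""
    report: list[str] = []
    n = m.n_beads

    if m.bond_ij.size:
        if m.bond_ij.min() < 0 or m.bond_ij.max() >= n:
            report.append("bond indices: bead id out of range")
        p = m.bond_params
        if not np.all((p[:, 0] < p[:, 1]) & (p[:, 1] < p[:, 2])):
            report.append("bond ordering: need r0 < r1 < r_break for every bond")
        if not np.all(p[:, 3:5] > 0):
            report.append("bond stiffness: kT0 and kT1 must be positive")

    if m.angle_ijk.size:
        if m.angle_ijk.min() < 0 or m.angle_ijk.max() >= n:
            report.append("angle indices: bead id out of range")
        if np.any(m.angle_phi0 < 164.0) or np.any(m.angle_phi0 > 180.0):
            report.append("angle range: phi_i outside [164, 180] degrees")
        if not np.all(m.angle_k > 0):
            report.append("angle stiffness: kB must be positive")

    mineral = m.species == MINERAL
    if np.any(m.molecule_id[mineral] >= 0):
        report.append("mineral membership: mineral beads must have molecule_id = -1")
    coll = m.species == COLLAGEN
    if np.any(m.molecule_id[coll] < 0):
        report.append("collagen membership: collagen beads must belong to a molecule")

    for k, mol in enumerate(m.molecules):
        if mol.start < 0 or mol.stop > n:
            report.append(f"molecule {k}: bead range out of bounds")
            continue
        ids = m.molecule_id[mol.start : mol.stop]
        if not np.all(ids == k):
            report.append(f"molecule {k}: registry range does not match molecule_id")

    if m.mass_collagen <= 0 or m.mass_mineral <= 0:
        report.append("species masses must be positive")

    pt = m.pair_table
    if np.any(pt.sigma <= 0) or np.any(pt.epsilon <= 0) or np.any(pt.cutoff <= 0):
        report.append("pair table: sigma, epsilon, cutoffs must be positive")
    elif np.any(pt.cutoff < pt.sigma):
        report.append("pair table: cutoff must be >= sigma")

    if not m.box.periodic[0]:
        report.append("box: fibril (x) axis must be periodic")
    # lateral vacuum margin must exceed the largest cutoff
    if n and not np.all(m.box.periodic[1:]):
        rc = pt.max_cutoff()
        for ax in (1, 2):
            if not m.box.periodic[ax]:
                lo = m.positions[:, ax].min()
                hi = m.positions[:, ax].max()
                if (lo - 0.0) < rc or (m.box.lengths[ax] - hi) < rc:
                    report.append(
                        "box: lateral vacuum margin smaller than the largest cutoff"
                    )
                    break
    return report
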