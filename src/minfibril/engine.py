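"""Dynamics: velocity-Verlet integration, Langevin thermostat, axial
box relaxation, equilibration and strain-controlled tensile testing.

The integrator advances positions in Å and velocities in Å/fs with a
10-fs default time step.  The thermostat is a Langevin bath (local friction
plus fluctuation); the axial "NPT" relaxation is a Berendsen-style rescale
of the box length toward zero axial virial stress.  Tensile tests deform
the simulation box at a constant displacement rate with an affine remap of
all bead coordinates, exactly as a strain-controlled box deformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numba import njit

from . import forcefield as ff
from .forcefield import _force_only_kernel
from .model import COLLAGEN, EnergyBreakdown, EngineConfig, FibrilModel
from .units import ACC_CONV, KB, MPS_TO_APFS, STRESS_GPA

log = logging.getLogger(__name__)

#: error threshold on per-step box extension, Å
MAX_STEP_EXTENSION = 0.1

#: integrator chunk size (steps per kernel call; bounds noise-buffer memory)
CHUNK = 200


@njit(cache=True)
def _md_chunk_kernel(
    pos,
    vel,
    masses,
    species,
    mol_id,
    ax_idx,
    bond_ij,
    bond_params,
    bond_broken,
    angle_ijk,
    angle_phi0_rad,
    angle_k,
    pairs,
    excl,
    sigma,
    epsilon,
    cutoff,
    box,
    n_steps,
    dt,
    box_rate,
    fric_coef,  # (N,) friction force coefficient m/(tau*ACC); 0 = off
    noise,  # (n_steps+1, N, 3) random forces, kcal/mol/Å (zeros = off)
    use_noise,
    clamped,
    clamp_vel,
    ref_pos,
    ref_Lx,
    skin_half2,
    forces,
):
    """Velocity-Verlet chunk with Langevin coupling and affine box extension.

    Returns the number of steps completed; exits early when any bead has
    moved more than half the neighbor skin since the list was built.
    """
    n = pos.shape[0]
    Lx = box[0]
    _force_only_kernel(
        pos, species, mol_id, ax_idx, bond_ij, bond_params, bond_broken,
        angle_ijk, angle_phi0_rad, angle_k, pairs, excl, sigma, epsilon,
        cutoff, Lx, forces,
    )
    if use_noise:
        for i in range(n):
            for d in range(3):
                forces[i, d] += noise[0, i, d] - fric_coef[i] * vel[i, d]
    for s in range(n_steps):
        if box_rate != 0.0:
            Lold = box[0]
            Lnew = Lold + box_rate * dt
            mu = Lnew / Lold
            for i in range(n):
                pos[i, 0] *= mu
            box[0] = Lnew
            Lx = Lnew
        for i in range(n):
            if clamped[i]:
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                pos[i, 0] += dt * clamp_vel[i, 0]
                pos[i, 1] += dt * clamp_vel[i, 1]
                pos[i, 2] += dt * clamp_vel[i, 2]
            else:
                c = 0.5 * dt * ACC_CONV / masses[i]
                for d in range(3):
                    vel[i, d] += c * forces[i, d]
                    pos[i, d] += dt * vel[i, d]
        _force_only_kernel(
            pos, species, mol_id, ax_idx, bond_ij, bond_params, bond_broken,
            angle_ijk, angle_phi0_rad, angle_k, pairs, excl, sigma, epsilon,
            cutoff, Lx, forces,
        )
        if use_noise:
            for i in range(n):
                for d in range(3):
                    forces[i, d] += noise[s + 1, i, d] - fric_coef[i] * vel[i, d]
        maxdisp2 = 0.0
        for i in range(n):
            if clamped[i]:
                continue
            c = 0.5 * dt * ACC_CONV / masses[i]
            for d in range(3):
                vel[i, d] += c * forces[i, d]
            dx = pos[i, 0] - ref_pos[i, 0]
            dx -= Lx * round(dx / Lx)
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxdisp2:
                maxdisp2 = d2
        if maxdisp2 > skin_half2:
            return s + 1
    return n_steps


def kinetic_energy(model: FibrilModel) -> float:
    """Kinetic energy, kcal/mol."""
    v2 = np.sum(model.velocities**2, axis=1)
    return float(0.5 * np.sum(model.masses * v2) / ACC_CONV)


def kinetic_temperature(model: FibrilModel) -> float:
    """Instantaneous kinetic temperature, K."""
    n = model.n_beads
    if n == 0:
        return 0.0
    return 2.0 * kinetic_energy(model) / (3.0 * n * KB)


@dataclass
class TrajectoryFrame:
    """State snapshot at one sampling instant."""

    step: int
    time: float  # fs
    strain: float
    box_lengths: np.ndarray
    stress_axial: float  # GPa, tension positive
    temperature: float
    energy_total: float
    broken_bonds: int
    positions: Optional[np.ndarray] = None
    bond_broken: Optional[np.ndarray] = None
    virial: Optional[np.ndarray] = None  # (N, 6) per-bead
    velocities: Optional[np.ndarray] = None


@dataclass
class Trajectory:
    frames: list[TrajectoryFrame] = field(default_factory=list)

    @property
    def strain(self) -> np.ndarray:
        return np.array([f.strain for f in self.frames])

    @property
    def stress(self) -> np.ndarray:
        return np.array([f.stress_axial for f in self.frames])

    @property
    def broken(self) -> np.ndarray:
        return np.array([f.broken_bonds for f in self.frames])


@dataclass
class EquilibrationReport:
    converged: bool
    initial_length: float
    final_length: float
    contraction_percent: float
    mean_temperature: float
    rmsd_series: np.ndarray
    stress_series: np.ndarray


class EngineState:
    """Mutable simulation state: model, clock, RNG and cached force data."""

    def __init__(self, model: FibrilModel, config: EngineConfig | None = None):
        self.model = model
        self.config = config or EngineConfig()
        self.time = 0.0
        self.step_count = 0
        self.rng = np.random.default_rng(self.config.seed)
        self.equilibrated = False
        self._nl: ff.NeighborList | None = None
        # cached per-run constants
        self._phi0_rad = np.radians(model.angle_phi0)
        self._excl = ff.crosslink_exclusion_codes(model)
        self._masses = model.masses.astype(float)
        self._result: ff.ForceResult | None = None
        #: beads whose positions are prescribed (clamped), not integrated
        self.clamped = np.zeros(model.n_beads, bool)
        self.clamp_velocity = np.zeros((model.n_beads, 3))
        self._chunk_hint = 64

    # -- plumbing ------------------------------------------------------------

    def refresh_topology_cache(self) -> None:
        self._phi0_rad = np.radians(self.model.angle_phi0)
        self._excl = ff.crosslink_exclusion_codes(self.model)
        self._masses = self.model.masses.astype(float)
        self._nl = None

    def _ensure_neighbors(self) -> ff.NeighborList:
        m = self.model
        if self._nl is None or self._nl.needs_rebuild(m.positions, m.box.Lx):
            self._nl = ff.build_neighbor_list(
                m.positions,
                m.box.Lx,
                m.pair_table.max_cutoff(),
                self.config.skin,
                species=m.species,
                cutoff_table=m.pair_table.cutoff,
            )
        return self._nl

    def compute_forces(self) -> ff.ForceResult:
        nl = self._ensure_neighbors()
        m = self.model
        n = m.n_beads
        forces = np.zeros((n, 3))
        virial = np.zeros((n, 6))
        newly = np.zeros(len(m.bond_ij), bool)
        eb, ea, ec, eh, ei, ndeg, bad = ff._eval_kernel(
            m.positions,
            m.species,
            m.molecule_id,
            m.axial_index,
            m.bond_ij,
            m.bond_params,
            m.bond_broken,
            m.angle_ijk,
            self._phi0_rad,
            m.angle_k,
            nl.pairs,
            self._excl,
            m.pair_table.sigma,
            m.pair_table.epsilon,
            m.pair_table.cutoff,
            m.pair_table.shift,
            m.box.Lx,
            forces,
            virial,
            newly,
        )
        if bad >= 0:
            i, j = nl.pairs[bad]
            raise ValueError(
                f"overlapping beads below guard distance: pair ({i}, {j})"
            )
        res = ff.ForceResult(
            forces=forces,
            energy=EnergyBreakdown(eb, ea, ec, eh, ei),
            virial=virial,
            newly_broken=np.flatnonzero(newly),
            degenerate_angles=int(ndeg),
        )
        ff.apply_bond_breaking(res, m)
        self._result = res
        return res

    # -- observables helpers ------------------------------------------------

    def axial_stress(self, include_kinetic: bool = True) -> float:
        """Axial virial stress over the fibril volume, GPa, tension positive."""
        from .observables import virial_stress

        res = self._result or self.compute_forces()
        return virial_stress(
            res.virial,
            self.model.velocities,
            self._masses,
            self.model.cylinder_volume(),
            include_kinetic=include_kinetic,
        )

    # -- velocity initialisation --------------------------------------------

    def initialize_velocities(self, T: float | None = None, seed: int | None = None):
        """Maxwell-Boltzmann velocities at T with zero center-of-mass momentum."""
        T = self.config.temperature if T is None else T
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        m = self.model
        if T <= 0:
            m.velocities[:] = 0.0
            return self
        std = np.sqrt(KB * T * ACC_CONV / self._masses)
        m.velocities[:] = self.rng.standard_normal((m.n_beads, 3)) * std[:, None]
        p = np.sum(self._masses[:, None] * m.velocities, axis=0)
        m.velocities -= p / np.sum(self._masses)
        m.velocities[self.clamped] = 0.0
        return self

    # -- integration ---------------------------------------------------------

    def run(
        self,
        n_steps: int,
        thermostat: bool = True,
        box_rate: float = 0.0,
        callback: Optional[Callable[["EngineState"], None]] = None,
        callback_every: int = 0,
    ) -> "EngineState":
        """Advance ``n_steps`` velocity-Verlet steps.

        ``box_rate`` is an axial box-length rate in Å/fs; the box is extended
        and all coordinates affinely remapped each step.  The loop runs in a
        compiled kernel in chunks bounded by neighbor-list validity and the
        callback cadence; bond breaking is applied in place every step.
        """
        m = self.model
        cfg = self.config
        dt = cfg.timestep
        if abs(box_rate) * dt > MAX_STEP_EXTENSION:
            raise ValueError(
                f"per-step box extension {abs(box_rate) * dt:.3g} Å exceeds the "
                f"stability bound {MAX_STEP_EXTENSION} Å"
            )
        n = m.n_beads
        # Langevin coupling: friction always accompanies the thermostat; at
        # T = 0 the noise amplitude vanishes and the dynamics is overdamped
        # relaxation (used for quasi-static pulls)
        use_noise = thermostat and cfg.damping > 0
        if use_noise:
            fric = self._masses / (cfg.damping * ACC_CONV)
            amp = np.sqrt(
                2.0 * self._masses * KB * max(cfg.temperature, 0.0)
                / (cfg.damping * ACC_CONV * dt)
            )
        else:
            fric = np.zeros(n)
            amp = None
        forces = np.empty((n, 3))
        remaining = n_steps
        while remaining > 0:
            nl = self._ensure_neighbors()
            # adapt the chunk to the observed rebuild interval so that the
            # pre-generated noise buffer is not wasted on early exits
            chunk = min(remaining, CHUNK, max(16, int(1.5 * self._chunk_hint)))
            if callback is not None and callback_every:
                to_boundary = callback_every - (self.step_count % callback_every)
                chunk = min(chunk, to_boundary)
            if use_noise and cfg.temperature > 0:
                noise = (
                    self.rng.standard_normal((chunk + 1, n, 3)) * amp[None, :, None]
                )
            elif use_noise:
                noise = np.zeros((chunk + 1, n, 3))
            else:
                noise = np.zeros((1, 1, 3))
            done = _md_chunk_kernel(
                m.positions,
                m.velocities,
                self._masses,
                m.species,
                m.molecule_id,
                m.axial_index,
                m.bond_ij,
                m.bond_params,
                m.bond_broken,
                m.angle_ijk,
                self._phi0_rad,
                m.angle_k,
                nl.pairs,
                self._excl,
                m.pair_table.sigma,
                m.pair_table.epsilon,
                m.pair_table.cutoff,
                m.box.lengths,
                chunk,
                dt,
                box_rate,
                fric,
                noise,
                use_noise,
                self.clamped,
                self.clamp_velocity,
                nl.ref_positions,
                nl.ref_Lx,
                (0.5 * cfg.skin) ** 2,
                forces,
            )
            self._result = None
            prev = self.step_count
            self.step_count += done
            self.time += done * dt
            remaining -= done
            if done < chunk:
                self._nl = None  # displacement exceeded half the skin
                self._chunk_hint = max(16, done)
            else:
                self._chunk_hint = min(CHUNK, 2 * self._chunk_hint)
            if callback is not None and callback_every and (
                self.step_count % callback_every == 0
            ):
                callback(self)
            if prev // 10000 != self.step_count // 10000:
                log.info(
                    "step %d strain %.4f T %.1f K broken %d",
                    self.step_count,
                    m.box.axial_strain,
                    kinetic_temperature(m),
                    int(np.sum(m.bond_broken)),
                )
        return self

    def step(self, thermostat: bool = True) -> "EngineState":
        """Advance a single velocity-Verlet step."""
        return self.run(1, thermostat=thermostat)

    # -- preparation ---------------------------------------------------------

    def minimize(self, n_steps: int = 200, max_disp: float = 0.5) -> "EngineState":
        """Capped-displacement steepest descent to remove construction overlaps."""
        m = self.model
        for _ in range(n_steps):
            res = self.compute_forces()
            f = res.forces
            fmax = np.max(np.abs(f))
            if fmax < 1.0:
                break
            step = min(max_disp / fmax, 0.02)
            m.positions += step * f
        return self

    # -- high-level protocols ------------------------------------------------

    def equilibrate(
        self,
        duration_ns: float | None = None,
        barostat: str | None = None,
        sample_every: int = 500,
        rmsd_tol: float = 0.02,
    ) -> EquilibrationReport:
        """Thermostated relaxation with axial box-length relaxation.

        The box length is rescaled every ``sample_every`` steps toward zero
        axial virial stress (Berendsen-style).  Convergence is declared when
        the positional RMSD between consecutive sampling windows levels off
        (relative change below ``rmsd_tol``).
        """
        cfg = self.config
        duration_ns = cfg.equilibration_ns if duration_ns is None else duration_ns
        barostat = cfg.barostat if barostat is None else barostat
        n_total = int(round(duration_ns * 1.0e6 / cfg.timestep))
        m = self.model
        L_init = m.box.Lx
        if not np.any(m.velocities):
            self.initialize_velocities()
        self.minimize()
        ref = m.positions.copy()
        rmsds: list[float] = []
        stresses: list[float] = []
        temps: list[float] = []
        done = 0
        while done < n_total:
            chunk = min(sample_every, n_total - done)
            self.run(chunk, thermostat=True)
            done += chunk
            stress = self.axial_stress()
            stresses.append(stress)
            temps.append(kinetic_temperature(m))
            d = m.positions - ref
            d[:, 0] -= m.box.Lx * np.round(d[:, 0] / m.box.Lx)
            rmsds.append(float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
            ref = m.positions.copy()
            if barostat == "axial":
                # relax box length toward zero axial stress: tension (> 0)
                # shortens the box, compression lengthens it
                dt_eff = chunk * cfg.timestep
                mu = 1.0 - (dt_eff / cfg.barostat_damping) * (
                    stress / cfg.barostat_modulus
                )
                mu = float(np.clip(mu, 0.995, 1.005))
                m.positions[:, 0] *= mu
                m.box.lengths[0] *= mu
        L_fin = m.box.Lx
        tail = max(1, len(rmsds) // 4)
        converged = bool(
            len(rmsds) >= 8
            and np.std(rmsds[-tail:]) < rmsd_tol * max(np.mean(rmsds[-tail:]), 1e-12)
        )
        self.equilibrated = True
        return EquilibrationReport(
            converged=converged,
            initial_length=L_init,
            final_length=L_fin,
            contraction_percent=100.0 * (L_init - L_fin) / L_init,
            mean_temperature=float(np.mean(temps[-tail:])) if temps else 0.0,
            rmsd_series=np.asarray(rmsds),
            stress_series=np.asarray(stresses),
        )

    def run_tensile_test(
        self,
        rate: float | None = None,
        max_strain: float = 1.0,
        sample_every: int = 1000,
        store_positions_every: int = 0,
        include_kinetic: bool = True,
    ) -> Trajectory:
        """Strain-controlled tension: extend the box at ``rate`` (m/s) with
        affine remap; sample strain and block-averaged axial stress.

        Runs to ``max_strain`` (relative to the length at the start of the
        pull) or until every backbone bond is broken.
        """
        cfg = self.config
        rate = cfg.pull_rate if rate is None else rate
        box_rate = rate * MPS_TO_APFS  # Å/fs
        m = self.model
        L_start = m.box.Lx
        m.box.L_ref = L_start
        traj = Trajectory()
        backbone = m.bond_kind == 0
        n_backbone = int(np.sum(backbone))

        def snapshot(keep_positions: bool) -> TrajectoryFrame:
            res = self._result or self.compute_forces()
            return TrajectoryFrame(
                step=self.step_count,
                time=self.time,
                strain=m.box.Lx / L_start - 1.0,
                box_lengths=m.box.lengths.copy(),
                stress_axial=self.axial_stress(include_kinetic),
                temperature=kinetic_temperature(m),
                energy_total=res.energy.E_total,
                broken_bonds=int(np.sum(m.bond_broken)),
                positions=m.positions.copy() if keep_positions else None,
                bond_broken=m.bond_broken.copy(),
            )

        traj.frames.append(snapshot(store_positions_every > 0))
        if box_rate == 0.0:
            return traj
        n_total = int(
            np.ceil(max_strain * L_start / (box_rate * cfg.timestep) - 1e-9)
        )
        done = 0
        isample = 0
        while done < n_total:
            chunk = min(sample_every, n_total - done)
            # block-average the stress over the sampling window
            acc: list[float] = []

            def cb(state: "EngineState") -> None:
                acc.append(state.axial_stress(include_kinetic))

            sub = max(1, chunk // 5)
            self.run(
                chunk,
                thermostat=True,
                box_rate=box_rate,
                callback=cb,
                callback_every=sub,
            )
            done += chunk
            isample += 1
            fr = snapshot(
                store_positions_every > 0 and isample % store_positions_every == 0
            )
            if acc:
                fr.stress_axial = float(np.mean(acc))
            traj.frames.append(fr)
            if n_backbone and int(np.sum(m.bond_broken[backbone])) == n_backbone:
                log.info("total rupture at strain %.3f", fr.strain)
                break
        return traj

    def pull_molecule_ends(
        self,
        rate: float = 4.0,
        max_strain: float = 0.6,
        sample_every: int = 200,
        molecule: int = 0,
    ) -> "MoleculePullResult":
        """Steered tension on one molecule: clamp its terminal beads and move
        them apart symmetrically at ``rate`` m/s total separation rate.

        Records end-to-end strain and the mean tension of the interior bonds
        (time-averaged per sampling window), which is the quantity the
        single-molecule stress-strain analysis consumes.
        """
        m = self.model
        mol = m.molecules[molecule]
        i0, i1 = mol.start, mol.stop - 1
        self.clamped[:] = False
        self.clamped[[i0, i1]] = True
        v = rate * MPS_TO_APFS / 2.0
        self.clamp_velocity[i0] = (-v, 0.0, 0.0)
        self.clamp_velocity[i1] = (v, 0.0, 0.0)
        m.velocities[[i0, i1]] = 0.0

        bonds = np.flatnonzero(
            (m.bond_ij[:, 0] >= mol.start)
            & (m.bond_ij[:, 1] < mol.stop)
            & (m.bond_kind == 0)
        )
        interior = bonds[2:-2] if len(bonds) > 8 else bonds
        L0 = float(m.positions[i1, 0] - m.positions[i0, 0])
        dt = self.config.timestep
        n_total = int(np.ceil(max_strain * L0 / (rate * MPS_TO_APFS * dt) - 1e-9))
        strains: list[float] = []
        tensions: list[float] = []
        broken: list[int] = []
        done = 0
        while done < n_total:
            chunk = min(sample_every, n_total - done)
            acc: list[float] = []

            def cb(state: "EngineState") -> None:
                acc.append(_mean_bond_tension(state.model, interior))

            self.run(chunk, thermostat=True, callback=cb, callback_every=max(1, chunk // 4))
            done += chunk
            L = float(m.positions[i1, 0] - m.positions[i0, 0])
            strains.append(L / L0 - 1.0)
            tensions.append(float(np.mean(acc)) if acc else _mean_bond_tension(m, interior))
            broken.append(int(np.sum(m.bond_broken[bonds])))
        self.clamped[:] = False
        return MoleculePullResult(
            strain=np.asarray(strains),
            tension=np.asarray(tensions),
            broken=np.asarray(broken),
            L0=L0,
        )


@dataclass
class MoleculePullResult:
    """Steered single-molecule tension record."""

    strain: np.ndarray  # end-to-end engineering strain
    tension: np.ndarray  # mean interior bond tension, kcal/mol/Å
    broken: np.ndarray  # cumulative broken bonds in the molecule
    L0: float

    def stress_GPa(self, cross_section_A2: float) -> np.ndarray:
        """Convert tension to molecular stress with a cross-section in Å²."""
        return self.tension / cross_section_A2 * STRESS_GPA


def _mean_bond_tension(model: FibrilModel, bond_idx: np.ndarray) -> float:
    """Mean signed bond tension (positive = stretched), kcal/mol/Å."""
    ij = model.bond_ij[bond_idx]
    p = model.bond_params[bond_idx]
    d = model.positions[ij[:, 1]] - model.positions[ij[:, 0]]
    Lx = model.box.Lx
    d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
    r = np.linalg.norm(d, axis=1)
    f = np.where(r < p[:, 1], p[:, 3] * (r - p[:, 0]), p[:, 4] * (r - p[:, 0]))
    f[model.bond_broken[bond_idx] | (r >= p[:, 2])] = 0.0
    return float(np.mean(f))
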