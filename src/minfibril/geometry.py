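"""Construction of mineralized collagen fibril models.

The fibril is a quarter-staggered lattice of tropocollagen bead chains cut
to a cylinder, with hydroxyapatite bead crystals grown in the gap regions
near the molecular termini, and optional inter-molecular crosslinks.

Layout
------
Molecule axes run along x (the fibril axis, periodic).  The cross-section is
a quasi-hexagonal lattice of columns; each column holds one molecule per
periodic box.  Columns are assigned one of ``periods`` stagger classes and
the class-``s`` molecule starts at ``x = s * D``.  With the default
five-period box, one gap and one overlap region appear per D-period, five
of each per box.

Calibration
-----------
The lattice spacing (15.2 Å) and offset are calibrated so the default 20-nm
cylinder holds exactly 158 columns, and the default bead count (179 per
molecule, with one extra bead on the 23 molecules nearest the fibril axis)
reproduces the reference total of 28,305 collagen beads.  Each chain carries
a small planar zigzag crimp whose per-bead turn magnitudes cycle through a
frozen integer pattern; measuring and rounding the resulting interior
angles yields exactly 13 distinct equilibrium angles between 164° and 180°.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import model as M
from .model import (
    BACKBONE,
    COLLAGEN,
    CROSSLINK,
    MINERAL,
    FibrilModel,
    MoleculeInfo,
    PairTable,
    SimulationBox,
    validate_model,
)

log = logging.getLogger(__name__)

#: crimp turn-magnitude palette, degrees (13 distinct values incl. 0 and 16)
CRIMP_MAGS = (0, 1, 2, 3, 4, 5, 7, 9, 11, 13, 14, 15, 16)
#: up-down sweep through the palette; turn sign alternates per bead
CRIMP_PATTERN = CRIMP_MAGS + CRIMP_MAGS[-2:0:-1]

#: lateral vacuum margin beyond the cylinder surface, Å (> largest cutoff)
VACUUM_MARGIN = 45.0


@dataclass
class GeometrySpec:
    """Geometry of the collagen lattice.

    Defaults are calibrated to the reference fibril: 20-nm diameter, 670-Å
    D-period, five periods per box, 158 molecules, 28,305 collagen beads.
    """

    diameter_nm: float = 20.0
    d_period: float = 670.0  # Å
    periods: int = 5
    bead_spacing: float = 14.0  # Å
    lattice_spacing: float = 15.2  # Å, hex nearest-neighbor distance
    lattice_offset: tuple[float, float] = (7.6, 0.0)  # Å, (y, z) shift
    #: beads per molecule; None = auto from the column-coverage fraction
    molecule_beads: Optional[int] = 179
    #: exact collagen bead total; extra beads go to the innermost molecules
    total_collagen_beads: Optional[int] = 28305
    #: molecule axial span as a fraction of the box (used when
    #: molecule_beads is None); value implied by the calibrated default
    column_coverage: float = 0.7415
    crimp: bool = True

    @property
    def radius(self) -> float:
        return self.diameter_nm * 10.0 / 2.0

    @property
    def box_length(self) -> float:
        return self.periods * self.d_period


@dataclass
class MineralizationSpec:
    """Mineral placement settings."""

    #: target weight fraction, percent of total model mass, in [0, 45]
    target_wt: float = 0.0
    #: close-packed lattice spacing; None = LJ equilibrium distance 2^(1/6) σ_HAP
    lattice_spacing: Optional[float] = None
    #: minimum clearance between a mineral site and any collagen bead, Å.
    #: Moderate initial overlap energies are resolved by the engine's
    #: capped-displacement relaxation.
    collagen_clearance: float = 8.0
    keep_inside_cylinder: bool = True
    #: achieved-vs-target tolerance, percentage points (absolute)
    tolerance: float = 0.5


@dataclass
class CrosslinkSpec:
    """Crosslink placement settings (two trivalent crosslinks per molecule)."""

    per_molecule: int = 2
    search_radius: float = 18.0  # Å
    #: rupture-distance scale factor applied to the backbone parameter set
    r_break_scale: float = 1.0


# --------------------------------------------------------------------------
# collagen lattice
# --------------------------------------------------------------------------


def _hex_columns(spec: GeometrySpec) -> list[tuple[int, int, float, float]]:
    """Hex lattice sites (i, j, y, z) inside the fibril cylinder, centered."""
    a = spec.lattice_spacing
    R = spec.radius
    oy, oz = spec.lattice_offset
    nmax = int(R / a * 2) + 3
    cols = []
    for j in range(-nmax, nmax + 1):
        for i in range(-nmax, nmax + 1):
            y = (i + 0.5 * (j % 2)) * a + oy
            z = j * (np.sqrt(3.0) / 2.0 * a) + oz
            if y * y + z * z <= R * R:
                cols.append((i, j, y, z))
    cols.sort(key=lambda c: (c[1], c[0]))
    return cols


def _crimped_chain(
    n_beads: int, spacing: float, crimp: bool, phase: int = 0
) -> np.ndarray:
    """Local (x, y) coordinates of one chain; bond lengths exactly `spacing`.

    ``phase`` shifts the turn pattern cyclically, giving each molecule its
    own crimp phase (the phases are deterministic per molecule and break the
    crystallographic coherence of the crimp between neighboring chains).
    """
    if not crimp or n_beads < 3:
        x = np.arange(n_beads) * spacing
        return np.stack([x, np.zeros(n_beads)], axis=1)
    P = len(CRIMP_PATTERN)
    phi = 0.0
    dirs = [0.0]
    for k in range(1, n_beads - 1):
        phi += ((-1) ** k) * CRIMP_PATTERN[(k - 1 + phase) % P]
        dirs.append(phi)
    d = np.radians(np.asarray(dirs))
    dx = spacing * np.cos(d)
    dy = spacing * np.sin(d)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    # rigid rotation: align the end-to-end vector with the chain axis so a
    # phase-shifted pattern does not tilt the molecule
    tilt = np.arctan2(y[-1] - y[0], x[-1] - x[0])
    ct, st = np.cos(-tilt), np.sin(-tilt)
    x, y = ct * x - st * y, st * x + ct * y
    y -= y.mean()
    return np.stack([x, y], axis=1)


def chain_span(n_beads: int, spacing: float, crimp: bool = True) -> float:
    """Axial extent of one constructed chain, Å."""
    xy = _crimped_chain(n_beads, spacing, crimp)
    return float(xy[-1, 0] - xy[0, 0])


def _auto_molecule_beads(spec: GeometrySpec) -> int:
    """Largest bead count whose span fits the column-coverage fraction."""
    target = spec.column_coverage * spec.box_length
    n = max(3, int(target / spec.bead_spacing))
    while chain_span(n + 1, spec.bead_spacing, spec.crimp) <= target:
        n += 1
    while n > 3 and chain_span(n, spec.bead_spacing, spec.crimp) > target:
        n -= 1
    return n


def build_collagen_lattice(spec: GeometrySpec) -> FibrilModel:
    """Quarter-staggered collagen lattice cut to the fibril cylinder."""
    cols = _hex_columns(spec)
    n_mol = len(cols)
    if n_mol == 0:
        raise ValueError("no lattice columns fit inside the fibril cylinder")
    base = (
        spec.molecule_beads
        if spec.molecule_beads is not None
        else _auto_molecule_beads(spec)
    )
    extra = 0
    if spec.total_collagen_beads is not None:
        extra = spec.total_collagen_beads - base * n_mol
        if extra < 0 or extra > n_mol:
            raise ValueError(
                f"total_collagen_beads={spec.total_collagen_beads} not reachable "
                f"with {n_mol} molecules of base count {base}"
            )
    # innermost `extra` molecules carry one extra bead (seam-inclusion rule)
    r2 = [c[2] ** 2 + c[3] ** 2 for c in cols]
    radial_rank = np.argsort(np.argsort(r2, kind="stable"), kind="stable")

    Lx = spec.box_length
    Lyz = spec.diameter_nm * 10.0 + 2.0 * VACUUM_MARGIN
    center = Lyz / 2.0

    n_classes = spec.periods
    positions = []
    molecule_id = []
    axial_index = []
    molecules: list[MoleculeInfo] = []
    bonds = []
    start = 0
    max_span = 0.0
    P = len(CRIMP_PATTERN)
    for k, (i, j, y, z) in enumerate(cols):
        s = (i + 2 * j) % n_classes
        nb = base + (1 if radial_rank[k] < extra else 0)
        # per-molecule crimp phase and crimp-plane azimuth: the built-in
        # incoherence emulates the steric entanglement of real molecules
        # and removes the soft coherent accordion mode of a perfect lattice
        phase = (7 * k) % P
        azim = 2.0 * np.pi * ((5 * k) % 16) / 16.0
        xy = _crimped_chain(nb, spec.bead_spacing, spec.crimp, phase)
        span = xy[-1, 0] - xy[0, 0]
        max_span = max(max_span, span)
        x0 = s * spec.d_period
        px = np.mod(x0 + xy[:, 0], Lx)
        py = y + np.cos(azim) * xy[:, 1] + center
        pz = z + np.sin(azim) * xy[:, 1] + center
        positions.append(np.stack([px, py, pz], axis=1))
        molecule_id.append(np.full(nb, k, np.int32))
        axial_index.append(np.arange(nb, dtype=np.int32))
        molecules.append(
            MoleculeInfo(
                start=start,
                n_beads=nb,
                stagger_class=int(s),
                x_start=float(np.mod(x0, Lx)),
                x_end=float(np.mod(x0 + span, Lx)),
            )
        )
        for b in range(nb - 1):
            bonds.append((start + b, start + b + 1))
        start += nb
    if max_span >= Lx:
        raise ValueError(
            f"molecule span {max_span:.1f} Å does not fit in the periodic box "
            f"{Lx:.1f} Å; a molecule would interact with itself"
        )

    pos = np.concatenate(positions)
    n = len(pos)
    bond_ij = np.asarray(bonds, np.int32).reshape(-1, 2)
    bond_params = np.tile(
        np.array([M.R0, M.R1, M.RBREAK, M.KT0, M.KT1]), (len(bond_ij), 1)
    )
    mdl = FibrilModel(
        positions=pos,
        velocities=np.zeros((n, 3)),
        species=np.zeros(n, np.int8),
        molecule_id=np.concatenate(molecule_id),
        axial_index=np.concatenate(axial_index),
        bond_ij=bond_ij,
        bond_params=bond_params,
        bond_kind=np.zeros(len(bond_ij), np.int8),
        bond_broken=np.zeros(len(bond_ij), bool),
        angle_ijk=np.zeros((0, 3), np.int32),
        angle_phi0=np.zeros(0),
        angle_k=np.zeros(0),
        pair_table=PairTable(),
        box=SimulationBox(lengths=np.array([Lx, Lyz, Lyz]), L_ref=Lx),
        molecules=molecules,
        D_period=spec.d_period,
        periods=spec.periods,
        diameter=spec.diameter_nm * 10.0,
    )
    assign_angles(mdl)
    _register_slabs(mdl)
    return mdl


def assign_angles(mdl: FibrilModel) -> FibrilModel:
    """Assign one harmonic angle per interior collagen bead.

    The equilibrium angle is the angle measured on the constructed geometry,
    rounded to the nearest integer degree and clamped to [164, 180].
    """
    Lx = mdl.box.Lx
    triples = []
    phis = []
    for mol in mdl.molecules:
        idx = np.arange(mol.start, mol.stop)
        if len(idx) < 3:
            continue
        p = mdl.positions[idx]
        d = np.diff(p, axis=0)
        d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
        u = d / np.linalg.norm(d, axis=1, keepdims=True)
        c = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
        ang = 180.0 - np.degrees(np.arccos(c))
        phi = np.clip(np.round(ang), 164.0, 180.0)
        for t in range(len(idx) - 2):
            triples.append((idx[t], idx[t + 1], idx[t + 2]))
            phis.append(phi[t])
    mdl.angle_ijk = np.asarray(triples, np.int32).reshape(-1, 3)
    mdl.angle_phi0 = np.asarray(phis, float)
    mdl.angle_k = np.full(len(phis), M.KB_ANGLE)
    return mdl


def _register_slabs(mdl: FibrilModel) -> None:
    """Record terminal planes, gap slabs and construction molecule counts."""
    Lx = mdl.box.Lx
    planes = sorted(
        {round(m.x_start, 6) for m in mdl.molecules}
        | {round(m.x_end, 6) for m in mdl.molecules}
    )
    mdl.terminal_planes = np.asarray(planes)

    # molecule count per cross-section between consecutive planes
    bounds = planes + [planes[0] + Lx]
    counts = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = (a + b) / 2.0 % Lx
        c = sum(1 for m in mdl.molecules if _covers(m, mid, Lx))
        counts.append(c)
    counts = np.asarray(counts)
    if counts.size == 0 or counts.min() == counts.max():
        mdl.gap_slabs = np.zeros((0, 2))
        mdl.gap_count = mdl.overlap_count = int(counts[0]) if counts.size else 0
        return
    lo, hi = counts.min(), counts.max()
    thresh = (lo + hi) / 2.0
    is_gap = counts < thresh
    # merge contiguous gap intervals (with wrap-around)
    segs = []
    for (a, b), g in zip(zip(bounds[:-1], bounds[1:]), is_gap):
        if not g:
            continue
        if segs and abs(segs[-1][1] - a) < 1e-9:
            segs[-1][1] = b
        else:
            segs.append([a, b])
    if len(segs) > 1 and is_gap[0] and is_gap[-1]:
        # last interval wraps onto the first
        segs[-1][1] = segs[0][1] + Lx
        segs.pop(0)
    mdl.gap_slabs = np.asarray([[a % Lx, b if b <= Lx else b % Lx] for a, b in segs])
    mdl.gap_count = int(lo)
    mdl.overlap_count = int(hi)


def _covers(m: MoleculeInfo, x: float, Lx: float) -> bool:
    a, b = m.x_start, m.x_end
    if a <= b:
        return a <= x <= b
    return x >= a or x <= b


# --------------------------------------------------------------------------
# mineralization
# --------------------------------------------------------------------------


def mineral_bead_count(
    target_wt: float, n_collagen: int, m_coll: float, m_min: float
) -> int:
    """Mineral bead count from the weight-fraction identity (wt in percent)."""
    if target_wt <= 0:
        return 0
    w = target_wt / 100.0
    return int(round(w / (1.0 - w) * n_collagen * m_coll / m_min))


def _fcc_sites(Lx: float, R: float, center: float, a: float) -> np.ndarray:
    """FCC lattice points with nearest-neighbor distance `a` inside the
    cylinder of radius R, axis along x through (center, center)."""
    L = a * np.sqrt(2.0)  # conventional cubic cell edge
    basis = np.array(
        [[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]
    )
    nx = int(np.ceil(Lx / L))
    nr = int(np.ceil(2 * R / L)) + 1
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(-nr, nr + 1), np.arange(-nr, nr + 1), indexing="ij"
    )
    cells = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * L
    pts[:, 1] += center
    pts[:, 2] += center
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < Lx)
    pts = pts[keep]
    r2 = (pts[:, 1] - center) ** 2 + (pts[:, 2] - center) ** 2
    return pts[r2 <= R * R]


def mineralize(
    mdl: FibrilModel, mspec: MineralizationSpec
) -> FibrilModel:
    """Grow mineral crystals from the molecule terminal planes.

    Sites of a close-packed lattice inside the fibril cylinder are filled in
    order of axial distance to the nearest terminal plane, skipping sites
    too close to a collagen bead.  At low densities this yields two disjoint
    crystals per gap region; they merge as density grows.
    """
    if mdl.n_mineral:
        raise ValueError("model is already mineralized")
    w = mspec.target_wt
    if w < 0 or w > 45.0:
        raise ValueError("target mineral weight fraction must be in [0, 45] %")
    n_target = mineral_bead_count(
        w, mdl.n_collagen, mdl.mass_collagen, mdl.mass_mineral
    )
    if n_target == 0:
        mdl.mineral_wt = 0.0
        return mdl

    a = mspec.lattice_spacing or 2.0 ** (1.0 / 6.0) * M.SIGMA_HAP
    Lx = mdl.box.Lx
    center = mdl.box.lengths[1] / 2.0
    R = mdl.radius if mspec.keep_inside_cylinder else mdl.radius + 2 * a
    sites = _fcc_sites(Lx, R, center, a)

    # drop sites too close to collagen (x-periodic via tiling)
    coll = mdl.positions[mdl.species == COLLAGEN]
    tiled = np.concatenate(
        [coll + np.array([dx, 0, 0]) for dx in (-Lx, 0.0, Lx)]
    )
    tree = cKDTree(tiled)
    dmin, _ = tree.query(sites, k=1)
    sites = sites[dmin >= mspec.collagen_clearance]

    if len(sites) < n_target:
        max_wt = (
            100.0
            * len(sites)
            * mdl.mass_mineral
            / (len(sites) * mdl.mass_mineral + mdl.n_collagen * mdl.mass_collagen)
        )
        raise ValueError(
            f"target mineral density {w:.1f}% not reachable: only {len(sites)} "
            f"placement sites available (max ≈ {max_wt:.1f}%)"
        )

    # nucleation planes: the terminal planes bounding each gap slab (one
    # N-terminal and one C-terminal plane per gap); fall back to the raw
    # terminus list for degenerate geometries
    if mdl.gap_slabs.size:
        planes = np.unique(mdl.gap_slabs.ravel())
    else:
        planes = mdl.terminal_planes
    dx = np.abs(sites[:, 0][:, None] - planes[None, :])
    dx = np.minimum(dx, Lx - dx)
    dist = dx.min(axis=1)
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0], dist))
    chosen = sites[order[:n_target]]

    achieved = (
        100.0
        * n_target
        * mdl.mass_mineral
        / (n_target * mdl.mass_mineral + mdl.n_collagen * mdl.mass_collagen)
    )
    if abs(achieved - w) > mspec.tolerance:
        raise ValueError(
            f"achieved mineral density {achieved:.2f}% outside ±{mspec.tolerance}% "
            f"of target {w:.1f}%"
        )

    n0 = mdl.n_beads
    mdl.positions = np.concatenate([mdl.positions, chosen])
    mdl.velocities = np.concatenate([mdl.velocities, np.zeros_like(chosen)])
    mdl.species = np.concatenate([mdl.species, np.ones(n_target, np.int8)])
    mdl.molecule_id = np.concatenate(
        [mdl.molecule_id, np.full(n_target, -1, np.int32)]
    )
    mdl.axial_index = np.concatenate(
        [mdl.axial_index, np.full(n_target, -1, np.int32)]
    )
    mdl.mineral_wt = achieved
    log.info(
        "mineralized: %d mineral beads, achieved %.2f %% (target %.1f %%)",
        n_target,
        achieved,
        w,
    )
    return mdl


# --------------------------------------------------------------------------
# crosslinks
# --------------------------------------------------------------------------


def add_crosslinks(
    mdl: FibrilModel, cspec: CrosslinkSpec, seed: int = 0
) -> FibrilModel:
    """Bond molecule end beads to the nearest bead of a neighboring molecule.

    Deterministic given the model and spec (the seed is accepted for
    interface stability; partner choice is nearest-first with index
    tie-break).  Molecules with no partner in range are skipped with a
    warning.
    """
    Lx = mdl.box.Lx
    coll_idx = np.flatnonzero(mdl.species == COLLAGEN)
    pos = mdl.positions
    tiled = np.concatenate([pos[coll_idx] + np.array([dx, 0, 0]) for dx in (-Lx, 0.0, Lx)])
    tree = cKDTree(tiled)
    new_bonds = []
    params = np.array(
        [M.R0, M.R1, M.RBREAK * cspec.r_break_scale, M.KT0, M.KT1]
    )
    existing = {tuple(sorted(b)) for b in mdl.bond_ij.tolist()}
    for k, mol in enumerate(mdl.molecules):
        ends = [mol.start, mol.stop - 1][: max(0, cspec.per_molecule)]
        placed = 0
        for e in ends:
            if placed >= cspec.per_molecule:
                break
            cand = tree.query_ball_point(pos[e], cspec.search_radius)
            best = None
            best_d = np.inf
            for c in sorted(cand):
                j = int(coll_idx[c % len(coll_idx)])
                if mdl.molecule_id[j] == k:
                    continue
                key = tuple(sorted((e, j)))
                if key in existing:
                    continue
                d = tiled[c] - pos[e]
                dd = float(np.linalg.norm(d))
                if dd < best_d - 1e-12 or (
                    abs(dd - best_d) <= 1e-12 and (best is None or j < best)
                ):
                    best = j
                    best_d = dd
            if best is None:
                log.warning(
                    "crosslink skipped: no partner within %.1f Å of molecule %d end bead %d",
                    cspec.search_radius,
                    k,
                    e,
                )
                continue
            existing.add(tuple(sorted((e, best))))
            new_bonds.append((e, best))
            placed += 1
    if new_bonds:
        nb = np.asarray(new_bonds, np.int32)
        mdl.bond_ij = np.concatenate([mdl.bond_ij, nb])
        mdl.bond_params = np.concatenate(
            [mdl.bond_params, np.tile(params, (len(nb), 1))]
        )
        mdl.bond_kind = np.concatenate(
            [mdl.bond_kind, np.full(len(nb), CROSSLINK, np.int8)]
        )
        mdl.bond_broken = np.concatenate([mdl.bond_broken, np.zeros(len(nb), bool)])
    return mdl


# --------------------------------------------------------------------------
# top-level builders
# --------------------------------------------------------------------------


def build_fibril(
    g: GeometrySpec | None = None,
    m: MineralizationSpec | None = None,
    c: CrosslinkSpec | None = None,
    seed: int = 0,
) -> FibrilModel:
    """Build a validated fibril model: lattice, angles, mineral, crosslinks."""
    g = g or GeometrySpec()
    mdl = build_collagen_lattice(g)
    if m is not None:
        mineralize(mdl, m)
    if c is not None:
        add_crosslinks(mdl, c, seed)
    report = validate_model(mdl)
    if report:
        raise RuntimeError("built model fails validation: " + "; ".join(report))
    return mdl


def build_fixture(kind: str, **overrides) -> FibrilModel:
    """Deterministic test fixtures.

    ``single_molecule``
        one straight chain (default 215 beads) in a long periodic box;
    ``molecule_pair``
        two straight parallel chains at a given separation;
    ``mini_fibril``
        a reduced fibril (default 7-nm diameter, 2 periods) with optional
        mineral (``mineral_wt``) and crosslinks (``crosslinks=True``).
    """
    if kind == "single_molecule":
        n = int(overrides.pop("n_beads", 215))
        spacing = float(overrides.pop("bead_spacing", 14.0))
        crimp = bool(overrides.pop("crimp", False))
        span = chain_span(n, spacing, crimp)
        Lx = float(overrides.pop("box_length", span + 20 * spacing))
        xy = _crimped_chain(n, spacing, crimp)
        Lyz = 2 * VACUUM_MARGIN + 40.0
        pos = np.stack(
            [xy[:, 0] + spacing, xy[:, 1] + Lyz / 2, np.full(n, Lyz / 2)], axis=1
        )
        mdl = _chain_model(pos, Lx, Lyz)
        return mdl
    if kind == "molecule_pair":
        n = int(overrides.pop("n_beads", 30))
        spacing = float(overrides.pop("bead_spacing", 14.0))
        sep = float(overrides.pop("separation", 15.2))
        span = (n - 1) * spacing
        Lx = float(overrides.pop("box_length", span + 20 * spacing))
        Lyz = 2 * VACUUM_MARGIN + 60.0
        x = np.arange(n) * spacing + spacing
        pos = np.concatenate(
            [
                np.stack([x, np.full(n, Lyz / 2 - sep / 2), np.full(n, Lyz / 2)], 1),
                np.stack([x, np.full(n, Lyz / 2 + sep / 2), np.full(n, Lyz / 2)], 1),
            ]
        )
        mdl = _chain_model(pos, Lx, Lyz, n_chains=2)
        return mdl
    if kind == "mini_fibril":
        g = GeometrySpec(
            diameter_nm=float(overrides.pop("diameter_nm", 7.0)),
            periods=int(overrides.pop("periods", 2)),
            d_period=float(overrides.pop("d_period", 670.0)),
            molecule_beads=None,
            total_collagen_beads=None,
            crimp=bool(overrides.pop("crimp", True)),
        )
        wt = float(overrides.pop("mineral_wt", 0.0))
        mspec = MineralizationSpec(target_wt=wt) if wt > 0 else None
        cspec = CrosslinkSpec() if overrides.pop("crosslinks", False) else None
        seed = int(overrides.pop("seed", 0))
        if overrides:
            raise TypeError(f"unknown overrides: {sorted(overrides)}")
        return build_fibril(g, mspec, cspec, seed)
    raise ValueError(f"unknown fixture kind: {kind!r}")


def _chain_model(pos: np.ndarray, Lx: float, Lyz: float, n_chains: int = 1) -> FibrilModel:
    n = len(pos)
    per = n // n_chains
    bonds = []
    mol_id = np.zeros(n, np.int32)
    ax = np.zeros(n, np.int32)
    mols = []
    for c in range(n_chains):
        s = c * per
        mol_id[s : s + per] = c
        ax[s : s + per] = np.arange(per)
        for b in range(per - 1):
            bonds.append((s + b, s + b + 1))
        mols.append(
            MoleculeInfo(
                start=s,
                n_beads=per,
                stagger_class=0,
                x_start=float(pos[s, 0]),
                x_end=float(pos[s + per - 1, 0] % Lx),
            )
        )
    bond_ij = np.asarray(bonds, np.int32).reshape(-1, 2)
    mdl = FibrilModel(
        positions=pos.astype(float),
        velocities=np.zeros((n, 3)),
        species=np.zeros(n, np.int8),
        molecule_id=mol_id,
        axial_index=ax,
        bond_ij=bond_ij,
        bond_params=np.tile(
            np.array([M.R0, M.R1, M.RBREAK, M.KT0, M.KT1]), (len(bond_ij), 1)
        ),
        bond_kind=np.zeros(len(bond_ij), np.int8),
        bond_broken=np.zeros(len(bond_ij), bool),
        angle_ijk=np.zeros((0, 3), np.int32),
        angle_phi0=np.zeros(0),
        angle_k=np.zeros(0),
        pair_table=PairTable(),
        box=SimulationBox(lengths=np.array([Lx, Lyz, Lyz]), L_ref=Lx),
        molecules=mols,
        D_period=Lx,
        periods=1,
        diameter=20.0,
    )
    assign_angles(mdl)
    _register_slabs(mdl)
    return mdl
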