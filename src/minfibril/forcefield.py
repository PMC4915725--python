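"""Force field: bilinear breakable bonds, harmonic angles, truncated 12-6 pairs.

Scalar reference functions (:func:`bond_force`, :func:`bond_energy`,
:func:`angle_energy`, :func:`pair_energy`) define each term on plain Python
objects; the numba kernels evaluate the same expressions over the whole
particle system with a neighbor list, per-bead virial accumulation and
irreversible bond rupture.

Conventions
-----------
* Pair interactions are excluded between directly bonded beads (1-2) and
  angle-spanning beads (1-3); within a molecule that is any pair with
  axial-index difference <= 2.  Crosslink partners are excluded explicitly.
* Truncation is plain (unshifted) by default; ``PairTable.shift`` subtracts
  the cutoff energy instead.
* A bond evaluated at r >= r_break carries zero force and is flagged for
  permanent breaking; its stored energy stays at the rupture plateau
  Phi(r_break) so the total energy is continuous at the breaking step.
* The per-bead virial is accumulated in the convention where a stretched
  bond contributes a negative w_xx; tension-positive stress is -w/V
  (see :mod:`minfibril.observables`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import (
    COLLAGEN,
    Angle,
    Bond,
    EnergyBreakdown,
    FibrilModel,
    PairTable,
)

# guard distance below which overlapping beads are reported as an error, Å
MIN_GUARD = 1.0e-3


# --------------------------------------------------------------------------
# scalar reference implementations
# --------------------------------------------------------------------------


def bond_force(r: float, b: Bond) -> float:
    """Restoring force magnitude (kcal/mol/Å) of the bilinear bond at length r.

    Positive values pull the beads back together.  Crossing ``r_break``
    marks the bond broken (irreversibly); a broken bond carries no force.
    """
    if b.broken:
        return 0.0
    if r >= b.r_break:
        b.broken = True
        return 0.0
    if r < b.r1:
        return b.kT0 * (r - b.r0)
    return b.kT1 * (r - b.r0)


def bond_energy(r: float, b: Bond) -> float:
    """Stretching energy (kcal/mol): continuous piecewise integral of the force.

    Phi(r0) = 0; constant at the rupture plateau for r >= r_break (and for a
    broken bond at any length).
    """
    if b.broken or r >= b.r_break:
        return _bond_energy_scalar(
            b.r_break, b.r0, b.r1, b.r_break, b.kT0, b.kT1
        )
    return _bond_energy_scalar(r, b.r0, b.r1, b.r_break, b.kT0, b.kT1)


@njit(cache=True)
def _bond_energy_scalar(r, r0, r1, rbreak, kT0, kT1):
    if r < r1:
        return 0.5 * kT0 * (r - r0) ** 2
    # continuity constant at r1
    c1 = 0.5 * kT0 * (r1 - r0) ** 2 - 0.5 * kT1 * (r1 - r0) ** 2
    if r < rbreak:
        return 0.5 * kT1 * (r - r0) ** 2 + c1
    return 0.5 * kT1 * (rbreak - r0) ** 2 + c1


def angle_energy(
    phi_deg: float, a: Angle
) -> float:
    """Bending energy (kcal/mol) at an angle of ``phi_deg`` degrees.

    The deviation from the equilibrium angle is taken in radians.
    """
    dphi = math.radians(phi_deg - a.phi_i)
    return 0.5 * a.kB * dphi * dphi


def pair_energy(r: float, cls: tuple[int, int], t: PairTable) -> tuple[float, float]:
    """12-6 pair energy (kcal/mol) and radial force (kcal/mol/Å) for a
    species pair, truncated at the class cutoff.

    Returns ``(energy, force)`` where a positive force is repulsive.
    """
    if r <= MIN_GUARD:
        raise ValueError(f"pair distance {r} below guard distance")
    si, sj = cls
    sig = t.sigma[si, sj]
    eps = t.epsilon[si, sj]
    rc = t.cutoff[si, sj]
    if r >= rc:
        return 0.0, 0.0
    sr6 = (sig / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    if t.shift:
        src6 = (sig / rc) ** 6
        e -= 4.0 * eps * (src6 * src6 - src6)
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return e, f


# --------------------------------------------------------------------------
# neighbor list
# --------------------------------------------------------------------------


@dataclass
class NeighborList:
    """Candidate pairs within max cutoff + skin, with rebuild bookkeeping."""

    pairs: np.ndarray  # (P, 2) int32, i < j
    skin: float
    cutoff: float  # max class cutoff used for the build
    ref_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    ref_Lx: float = 0.0

    def needs_rebuild(self, positions: np.ndarray, Lx: float) -> bool:
        if len(self.ref_positions) != len(positions):
            return True
        # displacement since build; box rescaling shows up in the same metric
        d = positions - self.ref_positions
        dx = d[:, 0]
        dx -= Lx * np.round(dx / Lx)
        disp2 = dx * dx + d[:, 1] ** 2 + d[:, 2] ** 2
        return bool(np.max(disp2) > (0.5 * self.skin) ** 2)


@njit(cache=True)
def _count_fill_pairs(
    order, cell_start, cell_count, cell_of, ncx, ncy, ncz, pos, Lx, rc2, species,
    rc2_table, out, fill
):
    """Loop over cell neighborhoods; count pairs (fill=0) or fill them (1).

    ``rc2_table`` holds per-species-pair squared candidate cutoffs (cutoff +
    skin); a negative entry means "use the global rc2"."""
    npairs = 0
    ncells = ncx * ncy * ncz
    for c in range(ncells):
        cx = c % ncx
        cy = (c // ncx) % ncy
        cz = c // (ncx * ncy)
        for dz in range(-1, 2):
            z2 = cz + dz
            if z2 < 0 or z2 >= ncz:
                continue
            for dy in range(-1, 2):
                y2 = cy + dy
                if y2 < 0 or y2 >= ncy:
                    continue
                for dx in range(-1, 2):
                    x2 = cx + dx
                    # periodic along x
                    if x2 < 0:
                        x2 += ncx
                    elif x2 >= ncx:
                        x2 -= ncx
                    c2 = x2 + ncx * (y2 + ncy * z2)
                    if c2 < c:
                        continue
                    same = c2 == c
                    for a in range(cell_start[c], cell_start[c] + cell_count[c]):
                        i = order[a]
                        b0 = cell_start[c2]
                        if same:
                            b0 = a + 1
                        for b in range(b0, cell_start[c2] + cell_count[c2]):
                            j = order[b]
                            rc2_ij = rc2_table[species[i], species[j]]
                            if rc2_ij < 0.0:
                                rc2_ij = rc2
                            ddx = pos[i, 0] - pos[j, 0]
                            ddx -= Lx * round(ddx / Lx)
                            ddy = pos[i, 1] - pos[j, 1]
                            ddz = pos[i, 2] - pos[j, 2]
                            r2 = ddx * ddx + ddy * ddy + ddz * ddz
                            if r2 <= rc2_ij:
                                if fill == 1:
                                    if i < j:
                                        out[npairs, 0] = i
                                        out[npairs, 1] = j
                                    else:
                                        out[npairs, 0] = j
                                        out[npairs, 1] = i
                                npairs += 1
    return npairs


def build_neighbor_list(
    positions: np.ndarray,
    Lx: float,
    cutoff: float,
    skin: float = 2.0,
    species: np.ndarray | None = None,
    cutoff_table: np.ndarray | None = None,
) -> NeighborList:
    """Cell-list construction of candidate pairs within ``cutoff + skin``.

    When ``species`` and ``cutoff_table`` are given, each pair is kept at
    its own class cutoff + skin instead of the global one, which keeps the
    list compact in dense mineral regions.  Periodic along x only;
    deterministic pair order.
    """
    n = len(positions)
    rc = cutoff + skin
    if species is None or cutoff_table is None:
        species_arr = np.zeros(n, np.int8)
        rc2_table = np.full((2, 2), -1.0)
    else:
        species_arr = species
        rc2_table = (cutoff_table + skin) ** 2
    if n < 2:
        return NeighborList(
            np.zeros((0, 2), np.int32), skin, cutoff, positions.copy(), Lx
        )
    if not np.all(np.isfinite(positions)):
        raise RuntimeError("coordinates are not finite (simulation diverged)")
    # wrap x into [0, Lx)
    x = np.mod(positions[:, 0], Lx)
    y = positions[:, 1]
    z = positions[:, 2]
    if (y.max() - y.min()) + (z.max() - z.min()) > 100.0 * Lx + 1e5:
        raise RuntimeError(
            "lateral coordinate spread is unphysically large (simulation diverged)"
        )
    ncx = max(1, int(Lx / rc))
    y0, z0 = y.min(), z.min()
    ncy = max(1, int((y.max() - y0) / rc) + 1)
    ncz = max(1, int((z.max() - z0) / rc) + 1)
    cx = np.minimum((x / (Lx / ncx)).astype(np.int64), ncx - 1)
    cy = np.minimum(((y - y0) / rc).astype(np.int64), ncy - 1)
    cz = np.minimum(((z - z0) / rc).astype(np.int64), ncz - 1)
    cell_of = cx + ncx * (cy + ncy * cz)
    order = np.argsort(cell_of, kind="stable").astype(np.int64)
    ncells = ncx * ncy * ncz
    cell_count = np.bincount(cell_of, minlength=ncells).astype(np.int64)
    cell_start = np.concatenate([[0], np.cumsum(cell_count)[:-1]]).astype(np.int64)
    pos = positions.copy()
    pos[:, 0] = x
    dummy = np.zeros((1, 2), np.int32)
    count = _count_fill_pairs(
        order, cell_start, cell_count, cell_of, ncx, ncy, ncz, pos, Lx, rc * rc,
        species_arr, rc2_table, dummy, 0,
    )
    pairs = np.zeros((count, 2), np.int32)
    _count_fill_pairs(
        order, cell_start, cell_count, cell_of, ncx, ncy, ncz, pos, Lx, rc * rc,
        species_arr, rc2_table, pairs, 1,
    )
    # canonical deterministic order
    idx = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return NeighborList(pairs[idx], skin, cutoff, positions.copy(), Lx)


# --------------------------------------------------------------------------
# full-system evaluation
# --------------------------------------------------------------------------


@dataclass
class ForceResult:
    """Forces, energy breakdown, per-bead virials and newly broken bonds."""

    forces: np.ndarray  # (N, 3) kcal/mol/Å
    energy: EnergyBreakdown
    virial: np.ndarray  # (N, 6): xx, yy, zz, xy, xz, yz
    newly_broken: np.ndarray  # indices into the bond arrays
    degenerate_angles: int = 0


@njit(cache=True)
def _eval_kernel(
    pos,
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
    excl_codes,
    sigma,
    epsilon,
    cutoff,
    shift,
    Lx,
    forces,
    virial,
    newly_broken_mask,
):
    n = pos.shape[0]
    e_bond = 0.0
    e_angle = 0.0
    e_coll = 0.0
    e_hap = 0.0
    e_inter = 0.0
    n_degenerate = 0
    bad_pair = -1

    # bonds
    for m in range(bond_ij.shape[0]):
        i = bond_ij[m, 0]
        j = bond_ij[m, 1]
        r0 = bond_params[m, 0]
        r1 = bond_params[m, 1]
        rb = bond_params[m, 2]
        kT0 = bond_params[m, 3]
        kT1 = bond_params[m, 4]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * round(dx / Lx)
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if bond_broken[m] or r >= rb:
            if not bond_broken[m]:
                newly_broken_mask[m] = True
            e_bond += _bond_energy_scalar(rb, r0, r1, rb, kT0, kT1)
            continue
        e_bond += _bond_energy_scalar(r, r0, r1, rb, kT0, kT1)
        if r < r1:
            fmag = kT0 * (r - r0)
        else:
            fmag = kT1 * (r - r0)
        # force on i along -d/r * fmag (restoring when stretched)
        fx = -fmag * dx / r
        fy = -fmag * dy / r
        fz = -fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        # half virial to each bead: w = d (x) f
        wxx = 0.5 * dx * fx
        wyy = 0.5 * dy * fy
        wzz = 0.5 * dz * fz
        wxy = 0.5 * dx * fy
        wxz = 0.5 * dx * fz
        wyz = 0.5 * dy * fz
        virial[i, 0] += wxx
        virial[i, 1] += wyy
        virial[i, 2] += wzz
        virial[i, 3] += wxy
        virial[i, 4] += wxz
        virial[i, 5] += wyz
        virial[j, 0] += wxx
        virial[j, 1] += wyy
        virial[j, 2] += wzz
        virial[j, 3] += wxy
        virial[j, 4] += wxz
        virial[j, 5] += wyz

    # angles
    for m in range(angle_ijk.shape[0]):
        i = angle_ijk[m, 0]
        j = angle_ijk[m, 1]
        k = angle_ijk[m, 2]
        # vectors from the central bead j
        ax = pos[i, 0] - pos[j, 0]
        ax -= Lx * round(ax / Lx)
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        bx -= Lx * round(bx / Lx)
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ra2 = ax * ax + ay * ay + az * az
        rb2 = bx * bx + by * by + bz * bz
        ra = math.sqrt(ra2)
        rbn = math.sqrt(rb2)
        c = (ax * bx + ay * by + az * bz) / (ra * rbn)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = math.acos(c)
        dtheta = theta - angle_phi0_rad[m]
        e_angle += 0.5 * angle_k[m] * dtheta * dtheta
        s = math.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            # collinear triple: undefined gradient direction, zero force
            n_degenerate += 1
            continue
        coeff = angle_k[m] * dtheta / s
        # dtheta/dri etc. (standard harmonic angle gradient)
        fi_x = coeff * (bx / (ra * rbn) - c * ax / ra2)
        fi_y = coeff * (by / (ra * rbn) - c * ay / ra2)
        fi_z = coeff * (bz / (ra * rbn) - c * az / ra2)
        fk_x = coeff * (ax / (ra * rbn) - c * bx / rb2)
        fk_y = coeff * (ay / (ra * rbn) - c * by / rb2)
        fk_z = coeff * (az / (ra * rbn) - c * bz / rb2)
        forces[i, 0] += fi_x
        forces[i, 1] += fi_y
        forces[i, 2] += fi_z
        forces[k, 0] += fk_x
        forces[k, 1] += fk_y
        forces[k, 2] += fk_z
        forces[j, 0] -= fi_x + fk_x
        forces[j, 1] -= fi_y + fk_y
        forces[j, 2] -= fi_z + fk_z
        # virial relative to the central bead, split equally over the triple
        wxx = (ax * fi_x + bx * fk_x) / 3.0
        wyy = (ay * fi_y + by * fk_y) / 3.0
        wzz = (az * fi_z + bz * fk_z) / 3.0
        wxy = (ax * fi_y + bx * fk_y) / 3.0
        wxz = (ax * fi_z + bx * fk_z) / 3.0
        wyz = (ay * fi_z + by * fk_z) / 3.0
        for t in (i, j, k):
            virial[t, 0] += wxx
            virial[t, 1] += wyy
            virial[t, 2] += wzz
            virial[t, 3] += wxy
            virial[t, 4] += wxz
            virial[t, 5] += wyz

    # pairs
    n_excl = excl_codes.shape[0]
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        # bonded-topology exclusions: 1-2 and 1-3 within a molecule
        if mol_id[i] >= 0 and mol_id[i] == mol_id[j]:
            d = ax_idx[i] - ax_idx[j]
            if -2 <= d <= 2:
                continue
        if n_excl > 0:
            code = np.int64(i) * np.int64(n) + np.int64(j)
            lo = 0
            hi = n_excl
            found = False
            while lo < hi:
                mid = (lo + hi) // 2
                v = excl_codes[mid]
                if v == code:
                    found = True
                    break
                elif v < code:
                    lo = mid + 1
                else:
                    hi = mid
            if found:
                continue
        si = species[i]
        sj = species[j]
        rc = cutoff[si, sj]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * round(dx / Lx)
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        if r2 < MIN_GUARD * MIN_GUARD:
            bad_pair = p
            continue
        sig = sigma[si, sj]
        eps = epsilon[si, sj]
        sr6 = (sig * sig / r2) ** 3
        e = 4.0 * eps * (sr6 * sr6 - sr6)
        if shift:
            src6 = (sig / rc) ** 6
            e -= 4.0 * eps * (src6 * src6 - src6)
        if si == COLLAGEN and sj == COLLAGEN:
            e_coll += e
        elif si != sj:
            e_inter += e
        else:
            e_hap += e
        fr_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        fx = fr_over_r * dx
        fy = fr_over_r * dy
        fz = fr_over_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx = 0.5 * dx * fx
        wyy = 0.5 * dy * fy
        wzz = 0.5 * dz * fz
        wxy = 0.5 * dx * fy
        wxz = 0.5 * dx * fz
        wyz = 0.5 * dy * fz
        virial[i, 0] += wxx
        virial[i, 1] += wyy
        virial[i, 2] += wzz
        virial[i, 3] += wxy
        virial[i, 4] += wxz
        virial[i, 5] += wyz
        virial[j, 0] += wxx
        virial[j, 1] += wyy
        virial[j, 2] += wzz
        virial[j, 3] += wxy
        virial[j, 4] += wxz
        virial[j, 5] += wyz

    return e_bond, e_angle, e_coll, e_hap, e_inter, n_degenerate, bad_pair


@njit(cache=True)
def _force_only_kernel(
    pos,
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
    excl_codes,
    sigma,
    epsilon,
    cutoff,
    Lx,
    forces,
):
    """Lean force evaluation for the integrator: no virial, no energies.

    Bonds crossing r_break are flagged broken in place (irreversibly).
    """
    n = pos.shape[0]
    forces[:] = 0.0
    for m in range(bond_ij.shape[0]):
        if bond_broken[m]:
            continue
        i = bond_ij[m, 0]
        j = bond_ij[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * round(dx / Lx)
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= bond_params[m, 2]:
            bond_broken[m] = True
            continue
        if r < bond_params[m, 1]:
            fmag = bond_params[m, 3] * (r - bond_params[m, 0])
        else:
            fmag = bond_params[m, 4] * (r - bond_params[m, 0])
        fx = -fmag * dx / r
        fy = -fmag * dy / r
        fz = -fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    for m in range(angle_ijk.shape[0]):
        i = angle_ijk[m, 0]
        j = angle_ijk[m, 1]
        k = angle_ijk[m, 2]
        ax = pos[i, 0] - pos[j, 0]
        ax -= Lx * round(ax / Lx)
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        bx -= Lx * round(bx / Lx)
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ra2 = ax * ax + ay * ay + az * az
        rb2 = bx * bx + by * by + bz * bz
        ra = math.sqrt(ra2)
        rbn = math.sqrt(rb2)
        c = (ax * bx + ay * by + az * bz) / (ra * rbn)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s = math.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            continue
        dtheta = math.acos(c) - angle_phi0_rad[m]
        coeff = angle_k[m] * dtheta / s
        fi_x = coeff * (bx / (ra * rbn) - c * ax / ra2)
        fi_y = coeff * (by / (ra * rbn) - c * ay / ra2)
        fi_z = coeff * (bz / (ra * rbn) - c * az / ra2)
        fk_x = coeff * (ax / (ra * rbn) - c * bx / rb2)
        fk_y = coeff * (ay / (ra * rbn) - c * by / rb2)
        fk_z = coeff * (az / (ra * rbn) - c * bz / rb2)
        forces[i, 0] += fi_x
        forces[i, 1] += fi_y
        forces[i, 2] += fi_z
        forces[k, 0] += fk_x
        forces[k, 1] += fk_y
        forces[k, 2] += fk_z
        forces[j, 0] -= fi_x + fk_x
        forces[j, 1] -= fi_y + fk_y
        forces[j, 2] -= fi_z + fk_z
    n_excl = excl_codes.shape[0]
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if mol_id[i] >= 0 and mol_id[i] == mol_id[j]:
            d = ax_idx[i] - ax_idx[j]
            if -2 <= d <= 2:
                continue
        if n_excl > 0:
            code = np.int64(i) * np.int64(n) + np.int64(j)
            lo = 0
            hi = n_excl
            found = False
            while lo < hi:
                mid = (lo + hi) // 2
                v = excl_codes[mid]
                if v == code:
                    found = True
                    break
                elif v < code:
                    lo = mid + 1
                else:
                    hi = mid
            if found:
                continue
        si = species[i]
        sj = species[j]
        rc = cutoff[si, sj]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * round(dx / Lx)
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc or r2 < 1.0e-6:
            continue
        sig = sigma[si, sj]
        eps = epsilon[si, sj]
        sr6 = (sig * sig / r2) ** 3
        fr_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        forces[i, 0] += fr_over_r * dx
        forces[i, 1] += fr_over_r * dy
        forces[i, 2] += fr_over_r * dz
        forces[j, 0] -= fr_over_r * dx
        forces[j, 1] -= fr_over_r * dy
        forces[j, 2] -= fr_over_r * dz
    return 0


def crosslink_exclusion_codes(model: FibrilModel) -> np.ndarray:
    """Encoded (i*N+j) crosslink pairs excluded from pair interactions."""
    n = model.n_beads
    xl = model.bond_ij[model.bond_kind != 0]
    if not len(xl):
        return np.zeros(0, np.int64)
    i = np.minimum(xl[:, 0], xl[:, 1]).astype(np.int64)
    j = np.maximum(xl[:, 0], xl[:, 1]).astype(np.int64)
    return np.sort(i * n + j)


def compute_forces(
    model: FibrilModel, nl: NeighborList | None = None
) -> ForceResult:
    """Evaluate all bond, angle and pair terms.

    Returns forces, the energy breakdown, per-bead virial tensors and the
    list of bonds newly stretched past their breaking distance (flags are
    applied separately by :func:`apply_bond_breaking`).
    """
    if nl is None:
        nl = build_neighbor_list(
            model.positions, model.box.Lx, model.pair_table.max_cutoff(), skin=0.0
        )
    n = model.n_beads
    forces = np.zeros((n, 3))
    virial = np.zeros((n, 6))
    newly_broken_mask = np.zeros(len(model.bond_ij), bool)
    eb, ea, ec, eh, ei, ndeg, bad = _eval_kernel(
        model.positions,
        model.species.astype(np.int8),
        model.molecule_id.astype(np.int32),
        model.axial_index.astype(np.int32),
        model.bond_ij.astype(np.int32),
        model.bond_params,
        model.bond_broken,
        model.angle_ijk.astype(np.int32),
        np.radians(model.angle_phi0),
        model.angle_k,
        nl.pairs,
        crosslink_exclusion_codes(model),
        model.pair_table.sigma,
        model.pair_table.epsilon,
        model.pair_table.cutoff,
        model.pair_table.shift,
        model.box.Lx,
        forces,
        virial,
        newly_broken_mask,
    )
    if bad >= 0:
        i, j = nl.pairs[bad]
        raise ValueError(f"overlapping beads below guard distance: pair ({i}, {j})")
    energy = EnergyBreakdown(
        E_bond=eb, E_angle=ea, E_nonbonded=ec, E_HAP=eh, E_inter=ei
    )
    return ForceResult(
        forces=forces,
        energy=energy,
        virial=virial,
        newly_broken=np.flatnonzero(newly_broken_mask),
        degenerate_angles=int(ndeg),
    )


def apply_bond_breaking(result: ForceResult, model: FibrilModel) -> FibrilModel:
    """Flag the newly broken bonds permanently; flags never reset."""
    if len(result.newly_broken):
        model.bond_broken[result.newly_broken] = True
    return model
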