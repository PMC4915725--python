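"""Force-field checks against closed forms and a brute-force reference."""

import numpy as np
import pytest

from minfibril import forcefield as ff
from minfibril import model as M
from minfibril.geometry import build_fixture
from minfibril.model import Angle, Bond, FibrilModel, PairTable


# --------------------------------------------------------------------------
# brute-force O(N²) reference implementation (independent oracle)
# --------------------------------------------------------------------------


def brute_force_reference(m: FibrilModel):
    """All-pairs double-loop evaluation of the total energy and forces."""
    n = m.n_beads
    Lx = m.box.Lx

    def minimg(d):
        d = d.copy()
        d[0] -= Lx * np.round(d[0] / Lx)
        return d

    E = dict(bond=0.0, angle=0.0, coll=0.0, hap=0.0, inter=0.0)
    F = np.zeros((n, 3))
    for b in range(len(m.bond_ij)):
        i, j = m.bond_ij[b]
        r0, r1, rb, k0, k1 = m.bond_params[b]
        d = minimg(m.positions[i] - m.positions[j])
        r = np.linalg.norm(d)
        if m.bond_broken[b] or r >= rb:
            c1 = 0.5 * (k0 - k1) * (r1 - r0) ** 2
            E["bond"] += 0.5 * k1 * (rb - r0) ** 2 + c1
            continue
        if r < r1:
            E["bond"] += 0.5 * k0 * (r - r0) ** 2
            fmag = k0 * (r - r0)
        else:
            c1 = 0.5 * (k0 - k1) * (r1 - r0) ** 2
            E["bond"] += 0.5 * k1 * (r - r0) ** 2 + c1
            fmag = k1 * (r - r0)
        fvec = -fmag * d / r
        F[i] += fvec
        F[j] -= fvec
    for a in range(len(m.angle_ijk)):
        i, j, k = m.angle_ijk[a]
        va = minimg(m.positions[i] - m.positions[j])
        vb = minimg(m.positions[k] - m.positions[j])
        ra, rb_ = np.linalg.norm(va), np.linalg.norm(vb)
        c = np.clip(va @ vb / (ra * rb_), -1, 1)
        th = np.arccos(c)
        dth = th - np.radians(m.angle_phi0[a])
        E["angle"] += 0.5 * m.angle_k[a] * dth * dth
        s = np.sqrt(1 - c * c)
        if s < 1e-8:
            continue
        coeff = m.angle_k[a] * dth / s
        fi = coeff * (vb / (ra * rb_) - c * va / ra**2)
        fk = coeff * (va / (ra * rb_) - c * vb / rb_**2)
        F[i] += fi
        F[k] += fk
        F[j] -= fi + fk
    xl = {tuple(sorted(p)) for p in m.bond_ij[m.bond_kind != 0].tolist()}
    pt = m.pair_table
    for i in range(n):
        for j in range(i + 1, n):
            if (
                m.molecule_id[i] >= 0
                and m.molecule_id[i] == m.molecule_id[j]
                and abs(int(m.axial_index[i]) - int(m.axial_index[j])) <= 2
            ):
                continue
            if (i, j) in xl:
                continue
            si, sj = int(m.species[i]), int(m.species[j])
            d = minimg(m.positions[i] - m.positions[j])
            r = np.linalg.norm(d)
            rc = pt.cutoff[si, sj]
            if r >= rc:
                continue
            sr6 = (pt.sigma[si, sj] / r) ** 6
            e = 4 * pt.epsilon[si, sj] * (sr6**2 - sr6)
            if pt.shift:
                s6 = (pt.sigma[si, sj] / rc) ** 6
                e -= 4 * pt.epsilon[si, sj] * (s6**2 - s6)
            key = "coll" if (si == 0 and sj == 0) else ("hap" if si == sj else "inter")
            E[key] += e
            fmag = 24 * pt.epsilon[si, sj] * (2 * sr6**2 - sr6) / r
            F[i] += fmag * d / r
            F[j] -= fmag * d / r
    return E, F


# --------------------------------------------------------------------------
# scalar terms
# --------------------------------------------------------------------------


class TestBond:
    def test_force_piecewise_values(self):
        b = Bond(0, 1)
        assert ff.bond_force(14.0, b) == pytest.approx(0.0)
        assert ff.bond_force(16.0, b) == pytest.approx(17.13 * 2.0)
        # second branch applies kT1 to (r - r0), as the model defines
        assert ff.bond_force(19.0, b) == pytest.approx(97.66 * 5.0)

    def test_force_at_transition_matches_first_branch_limit(self):
        b = Bond(0, 1)
        assert ff.bond_force(18.20 - 1e-9, b) == pytest.approx(71.946, abs=1e-3)

    def test_breaking_is_permanent(self):
        b = Bond(0, 1)
        assert ff.bond_force(22.0, b) == 0.0
        assert b.broken
        assert ff.bond_force(14.0, b) == 0.0  # re-shortened but stays broken

    def test_energy_values_and_continuity(self):
        b = Bond(0, 1)
        assert ff.bond_energy(14.0, b) == 0.0
        assert ff.bond_energy(18.20, b) == pytest.approx(0.5 * 17.13 * 4.2**2, rel=1e-9)
        e_lo = ff.bond_energy(18.20 - 1e-8, b)
        e_hi = ff.bond_energy(18.20 + 1e-8, b)
        assert e_hi == pytest.approx(e_lo, abs=1e-3)
        # constant beyond r_break
        assert ff.bond_energy(25.0, Bond(0, 1)) == pytest.approx(
            ff.bond_energy(21.0, Bond(0, 1))
        )

    @pytest.mark.parametrize("r", [14.5, 16.0, 17.9, 18.5, 19.7, 20.6])
    def test_force_is_negative_energy_gradient(self, r):
        b = Bond(0, 1)
        h = 1e-6
        dnum = (ff.bond_energy(r + h, b) - ff.bond_energy(r - h, b)) / (2 * h)
        # restoring force = -dPhi/dr; bond_force returns the magnitude along
        # (r - r0), i.e. +dPhi/dr
        assert ff.bond_force(r, Bond(0, 1)) == pytest.approx(dnum, rel=1e-6)


class TestAngle:
    def test_energy_at_equilibrium_and_offset(self):
        a = Angle(0, 1, 2, phi_i=170.0)
        assert ff.angle_energy(170.0, a) == 0.0
        # 0.1 rad deviation
        off = np.degrees(0.1)
        assert ff.angle_energy(170.0 + off, a) == pytest.approx(
            0.5 * 14.98 * 0.01, rel=1e-9
        )

    def test_gradient_matches_central_differences(self, rng):
        """Analytic angle forces equal -dE/dx on random triples (1e-6 rel)."""
        for _ in range(10):
            pos = rng.normal(scale=5.0, size=(3, 3)) + np.array([50.0, 50.0, 50.0])
            m = _triple_model(pos, phi0=172.0)
            res = ff.compute_forces(m)
            h = 1e-4
            for bead in range(3):
                for d in range(3):
                    mp = m.copy()
                    mp.positions[bead, d] += h
                    mm = m.copy()
                    mm.positions[bead, d] -= h
                    ep = ff.compute_forces(mp).energy.E_total
                    em = ff.compute_forces(mm).energy.E_total
                    fnum = -(ep - em) / (2 * h)
                    assert res.forces[bead, d] == pytest.approx(
                        fnum, rel=1e-6, abs=1e-8
                    )


def _triple_model(pos, phi0):
    return FibrilModel(
        positions=np.asarray(pos, float),
        velocities=np.zeros((3, 3)),
        species=np.zeros(3, np.int8),
        molecule_id=np.zeros(3, np.int32),
        axial_index=np.arange(3, dtype=np.int32),
        bond_ij=np.zeros((0, 2), np.int32),
        bond_params=np.zeros((0, 5)),
        bond_kind=np.zeros(0, np.int8),
        bond_broken=np.zeros(0, bool),
        angle_ijk=np.array([[0, 1, 2]], np.int32),
        angle_phi0=np.array([phi0]),
        angle_k=np.array([M.KB_ANGLE]),
        pair_table=PairTable(),
        box=M.SimulationBox(lengths=np.array([1000.0, 1000.0, 1000.0])),
    )


class TestPair:
    def test_root_minimum_cutoff(self):
        t = PairTable()
        e, _ = ff.pair_energy(M.SIGMA_HAP, (1, 1), t)
        assert e == pytest.approx(0.0, abs=1e-9)
        rmin = 2 ** (1 / 6) * M.SIGMA_HAP
        e, f = ff.pair_energy(rmin, (1, 1), t)
        assert e == pytest.approx(-106.7, rel=1e-9)
        assert f == pytest.approx(0.0, abs=1e-9)
        e, f = ff.pair_energy(t.cutoff[1, 1] + 1e-9, (1, 1), t)
        assert e == 0.0 and f == 0.0

    def test_guard_distance(self):
        with pytest.raises(ValueError):
            ff.pair_energy(1e-6, (0, 0), PairTable())


# --------------------------------------------------------------------------
# full-system evaluation
# --------------------------------------------------------------------------


def _random_mixed_model(rng, n=50):
    """Random mixed collagen/mineral configuration with a short chain."""
    Lx = 150.0
    pos = rng.uniform([0, 40, 40], [Lx, 110, 110], size=(n, 3))
    species = np.zeros(n, np.int8)
    species[: n // 3] = 1  # minerals
    mol = np.full(n, -1, np.int32)
    ax = np.full(n, -1, np.int32)
    chain = np.arange(n // 3, n // 3 + 8)
    mol[chain] = 0
    ax[chain] = np.arange(8)
    for t, i in enumerate(chain):  # straight-ish chain
        pos[i] = [10.0 + 13.5 * t, 75.0 + rng.normal(0, 1), 75.0 + rng.normal(0, 1)]
    # spread the non-chain beads so no pair sits deep in the repulsive core
    # (keeps the energy scale moderate; finite differences stay meaningful)
    from scipy.spatial import cKDTree

    chain_set = set(chain.tolist())
    for _ in range(300):
        tree = cKDTree(np.mod(pos, [Lx, 1e9, 1e9]))
        pairs = tree.query_pairs(9.7)
        pairs = [
            (i, j) for i, j in pairs
            if not (i in chain_set and j in chain_set)
        ]
        if not pairs:
            break
        for i, j in pairs:
            d = pos[i] - pos[j]
            nrm = np.linalg.norm(d) or 1.0
            if i in chain_set:
                pos[j] -= 1.0 * d / nrm
            elif j in chain_set:
                pos[i] += 1.0 * d / nrm
            else:
                pos[i] += 0.6 * d / nrm
                pos[j] -= 0.6 * d / nrm
    bonds = np.stack([chain[:-1], chain[1:]], 1).astype(np.int32)
    angles = np.stack([chain[:-2], chain[1:-1], chain[2:]], 1).astype(np.int32)
    m = FibrilModel(
        positions=pos,
        velocities=np.zeros((n, 3)),
        species=species,
        molecule_id=mol,
        axial_index=ax,
        bond_ij=bonds,
        bond_params=np.tile(
            np.array([M.R0, M.R1, M.RBREAK, M.KT0, M.KT1]), (len(bonds), 1)
        ),
        bond_kind=np.zeros(len(bonds), np.int8),
        bond_broken=np.zeros(len(bonds), bool),
        angle_ijk=angles,
        angle_phi0=np.full(len(angles), 178.0),
        angle_k=np.full(len(angles), M.KB_ANGLE),
        pair_table=PairTable(),
        box=M.SimulationBox(lengths=np.array([Lx, 120.0, 120.0])),
    )
    return m


def test_matches_brute_force_reference(rng):
    """Neighbor-listed evaluation equals the O(N²) double loop (1e-10 rel)."""
    for _ in range(3):
        m = _random_mixed_model(rng)
        res = ff.compute_forces(m)
        E, F = brute_force_reference(m)
        assert res.energy.E_bond == pytest.approx(E["bond"], rel=1e-10, abs=1e-10)
        assert res.energy.E_angle == pytest.approx(E["angle"], rel=1e-10, abs=1e-10)
        assert res.energy.E_nonbonded == pytest.approx(E["coll"], rel=1e-10, abs=1e-10)
        assert res.energy.E_HAP == pytest.approx(E["hap"], rel=1e-10, abs=1e-10)
        assert res.energy.E_inter == pytest.approx(E["inter"], rel=1e-10, abs=1e-10)
        np.testing.assert_allclose(res.forces, F, rtol=1e-9, atol=1e-9)


def test_newtons_third_law_and_invariance(rng):
    m = _random_mixed_model(rng)
    res = ff.compute_forces(m)
    net = np.sum(res.forces, axis=0)
    scale = np.max(np.abs(res.forces)) or 1.0
    assert np.all(np.abs(net) / scale < 1e-8)
    # translation invariance (lateral, no wrap effects)
    m2 = m.copy()
    m2.positions[:, 1] += 3.7
    res2 = ff.compute_forces(m2)
    assert res2.energy.E_total == pytest.approx(res.energy.E_total, rel=1e-12)


def test_energy_additivity_every_call(rng):
    m = _random_mixed_model(rng)
    e = ff.compute_forces(m).energy
    assert e.E_total == pytest.approx(
        e.E_bond + e.E_angle + e.E_nonbonded + e.E_HAP + e.E_inter, rel=1e-12
    )


def test_virial_sum_equals_global_virial(rng):
    """Per-bead virial sums to the system virial computed from -dE/deps."""
    m = _random_mixed_model(rng)
    res = ff.compute_forces(m)
    w = np.sum(res.virial[:, 0])
    h = 1e-6
    Es = []
    for sgn in (+1, -1):
        m2 = m.copy()
        m2.positions[:, 0] *= 1 + sgn * h
        m2.box.lengths[0] *= 1 + sgn * h
        Es.append(ff.compute_forces(m2).energy.E_total)
    dEde = (Es[0] - Es[1]) / (2 * h)
    # stretched interactions accumulate negative w_xx; w_xx = -dE/deps
    assert w == pytest.approx(-dEde, rel=1e-4, abs=1e-6)


def test_single_and_dimer_trivial_cases():
    m = build_fixture("single_molecule", n_beads=2)
    res = ff.compute_forces(m)
    assert res.energy.E_total == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.forces, 0.0, atol=1e-12)


def test_bond_breaking_flags_applied_and_monotone():
    m = build_fixture("single_molecule", n_beads=3)
    m.positions[2, 0] = m.positions[1, 0] + 22.0  # beyond r_break
    res = ff.compute_forces(m)
    assert len(res.newly_broken) == 1
    ff.apply_bond_breaking(res, m)
    assert m.bond_broken[1]
    # re-shorten: stays broken, no new breaks
    m.positions[2, 0] = m.positions[1, 0] + 14.0
    res2 = ff.compute_forces(m)
    assert len(res2.newly_broken) == 0
    assert m.bond_broken[1]


class TestBondProperties:
    """Property tests of the bilinear bond law."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=10.0, max_value=25.0))
    def test_energy_is_antiderivative_of_force(self, r):
        """Numerical derivative of the energy equals the signed force
        everywhere off the breakpoints."""
        b = Bond(0, 1)
        if min(abs(r - b.r1), abs(r - b.r_break)) < 1e-3:
            return
        h = 1e-5
        dnum = (ff.bond_energy(r + h, b) - ff.bond_energy(r - h, b)) / (2 * h)
        expect = 0.0 if r >= b.r_break else ff.bond_force(r, Bond(0, 1))
        assert dnum == pytest.approx(expect, rel=1e-5, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1.0, max_value=60.0),
        st.sampled_from([(0, 0), (0, 1), (1, 1)]),
    )
    def test_pair_energy_zero_beyond_cutoff_negative_in_well(self, r, cls):
        t = PairTable()
        si, sj = cls
        e, f = ff.pair_energy(r, cls, t)
        if r >= t.cutoff[si, sj]:
            assert e == 0.0 and f == 0.0
        elif r > t.sigma[si, sj]:
            assert e < 0.0


def test_overlap_guard_error():
    m = build_fixture("single_molecule", n_beads=4)
    # put a bead of another molecule on top of bead 0
    m.positions[3] = m.positions[0] + [0.0, 1e-5, 0.0]
    m.molecule_id[3] = 1
    with pytest.raises(ValueError, match="guard"):
        ff.compute_forces(m)
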