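"""Observable checks: virial stress closed forms, molecular strain,
gap/overlap profiling, interaction sums, broken-bond bookkeeping."""

import numpy as np
import pytest

from minfibril import forcefield as ff
from minfibril import model as M
from minfibril.geometry import build_fixture
from minfibril.observables import (
    count_broken_bonds,
    gap_overlap_profile,
    interaction_energy_sums,
    mineral_internal_stress,
    molecular_strain,
    molecule_contours,
    molecule_failure_fraction,
    per_bead_strain,
    virial_stress,
)
from minfibril.units import STRESS_GPA


class TestVirialStress:
    def test_noninteracting_static_beads_zero(self):
        m = build_fixture("single_molecule", n_beads=2)
        m.positions[1, 0] = m.positions[0, 0] + 14.0  # bond at equilibrium
        res = ff.compute_forces(m)
        s = virial_stress(res.virial, m.velocities, m.masses, 1e6)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_two_bead_closed_form(self):
        """Stretched dimer along x: sigma = F * r / V (tension positive)."""
        m = build_fixture("single_molecule", n_beads=2)
        r = 16.0
        m.positions[1, 0] = m.positions[0, 0] + r
        res = ff.compute_forces(m)
        V = 2.0e5
        F = 17.13 * 2.0  # kcal/mol/Å
        expected = F * r / V * STRESS_GPA
        s = virial_stress(res.virial, m.velocities, m.masses, V,
                          include_kinetic=False)
        assert s == pytest.approx(expected, rel=1e-10)

    def test_zero_volume_error(self):
        with pytest.raises(ValueError):
            virial_stress(np.zeros((1, 6)), np.zeros((1, 3)), np.ones(1), 0.0)

    def test_subset_sums_to_total(self, mini_fibril_25):
        m = mini_fibril_25
        res = ff.compute_forces(m)
        V = m.cylinder_volume()
        tot = virial_stress(res.virial, m.velocities, m.masses, V)
        a = virial_stress(res.virial, m.velocities, m.masses, V,
                          subset=np.flatnonzero(m.species == 0))
        b = virial_stress(res.virial, m.velocities, m.masses, V,
                          subset=np.flatnonzero(m.species == 1))
        assert a + b == pytest.approx(tot, rel=1e-10)
        assert mineral_internal_stress(m, res) == pytest.approx(b, rel=1e-12)


class TestMolecularStrain:
    def test_zero_at_equilibrium(self):
        m = build_fixture("molecule_pair", n_beads=20)
        ref = molecule_contours(m)
        ms = molecular_strain(m, ref)
        assert ms.mean == pytest.approx(0.0, abs=1e-12)

    def test_uniform_stretch(self):
        m = build_fixture("molecule_pair", n_beads=20)
        ref = molecule_contours(m)
        m.positions[:, 0] *= 1.1
        m.box.lengths[0] *= 1.1
        ms = molecular_strain(m, ref)
        assert ms.per_molecule == pytest.approx([0.1, 0.1], rel=1e-9)

    def test_broken_molecule_excluded(self):
        m = build_fixture("molecule_pair", n_beads=20)
        ref = molecule_contours(m)
        m.bond_broken[0] = True  # first bond of molecule 0
        ms = molecular_strain(m, ref)
        assert ms.n_excluded == 1
        assert ms.mean == pytest.approx(0.0, abs=1e-12)  # only molecule 1

    def test_per_bead_strain_field(self):
        m = build_fixture("single_molecule", n_beads=10)
        m.positions[:, 0] *= 1.05
        m.box.lengths[0] *= 1.05
        eps = per_bead_strain(m)
        assert eps == pytest.approx(np.full(10, 0.05), rel=1e-9)


class TestGapOverlap:
    def test_fresh_default_fibril_has_five_of_each(self, default_fibril):
        prof = gap_overlap_profile(default_fibril)
        assert prof.n_gap_segments == 5
        assert prof.n_overlap_segments == 5
        assert not prof.degenerate
        assert prof.gap_length < prof.overlap_length

    def test_uniform_rod_degenerate(self):
        # chains spanning the whole periodic box: no stagger, no gaps
        m = build_fixture("molecule_pair", n_beads=20, box_length=20 * 14.0)
        prof = gap_overlap_profile(m, bin_width=14.0)
        assert prof.degenerate

    def test_bin_width_larger_than_gap_rejected(self, default_fibril):
        with pytest.raises(ValueError, match="bin width"):
            gap_overlap_profile(default_fibril, bin_width=300.0)

    def test_simulated_slippage_reduces_overlap(self, default_fibril):
        """Relaxed termini (molecules contracted toward their centers, as
        after slippage) shrink the overlap length."""
        m = default_fibril
        ref = gap_overlap_profile(m)
        m2 = m.copy()
        Lx = m2.box.Lx
        for mol in m2.molecules:
            x = m2.positions[mol.start:mol.stop, 0]
            xu = np.unwrap(x, period=Lx)  # continuous along the chain
            xc = xu.mean()
            m2.positions[mol.start:mol.stop, 0] = np.mod(
                xc + 0.85 * (xu - xc), Lx
            )
        prof = gap_overlap_profile(m2)
        assert prof.overlap_length < ref.overlap_length


class TestInteractionSums:
    def test_unmineralized_sums_zero(self):
        m = build_fixture("mini_fibril", diameter_nm=6.0)
        inter, hap = interaction_energy_sums(m)
        assert inter == 0.0 and hap == 0.0

    def test_two_mineral_beads_at_minimum(self):
        m = build_fixture("single_molecule", n_beads=2)
        m.species[:] = M.MINERAL
        m.molecule_id[:] = -1
        m.axial_index[:] = -1
        m.bond_ij = np.zeros((0, 2), np.int32)
        m.bond_params = np.zeros((0, 5))
        m.bond_kind = np.zeros(0, np.int8)
        m.bond_broken = np.zeros(0, bool)
        m.positions[1, 0] = m.positions[0, 0] + 2 ** (1 / 6) * M.SIGMA_HAP
        inter, hap = interaction_energy_sums(m)
        assert hap == pytest.approx(-106.7, rel=1e-9)
        assert inter == 0.0

    def test_matches_brute_force_class_sums(self, mini_fibril_25):
        from tests.test_forcefield import brute_force_reference

        m = build_fixture("mini_fibril", diameter_nm=6.0, periods=1,
                          mineral_wt=20.0)
        inter, hap = interaction_energy_sums(m)
        E, _ = brute_force_reference(m)
        assert inter == pytest.approx(E["inter"], rel=1e-10)
        assert hap == pytest.approx(E["hap"], rel=1e-10)


class TestBrokenBonds:
    def test_no_rupture_all_zero(self):
        from minfibril.engine import EngineState
        from minfibril.model import EngineConfig

        m = build_fixture("molecule_pair", n_beads=10)
        st = EngineState(m, EngineConfig(seed=3))
        st.initialize_velocities()
        traj = st.run_tensile_test(rate=50.0, max_strain=0.01, sample_every=20)
        series = count_broken_bonds(traj, m)
        assert np.all(series.counts == 0)
        assert series.molecule_failure_fraction == 0.0

    def test_monotone_and_failure_fraction(self):
        m = build_fixture("molecule_pair", n_beads=10)

        class Frame:
            def __init__(self, flags):
                self.bond_broken = flags
                self.broken_bonds = int(np.sum(flags))

        f1 = np.zeros(len(m.bond_ij), bool)
        f2 = f1.copy(); f2[0] = True
        f3 = f2.copy(); f3[3] = True

        class T:
            frames = [Frame(f1), Frame(f2), Frame(f3)]

        series = count_broken_bonds(T(), m)
        assert np.all(np.diff(series.counts) >= 0)
        assert series.molecule_failure_fraction == pytest.approx(0.5)

    def test_failure_fraction_helper(self):
        m = build_fixture("molecule_pair", n_beads=10)
        m.bond_broken[0] = True
        assert molecule_failure_fraction(m) == pytest.approx(0.5)
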