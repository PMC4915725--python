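"""Builder checks: reference counts, angles, mineralization, crosslinks."""

import numpy as np
import pytest

from minfibril import forcefield as ff
from minfibril import model as M
from minfibril.geometry import (
    CrosslinkSpec,
    GeometrySpec,
    MineralizationSpec,
    add_crosslinks,
    build_fibril,
    build_fixture,
    mineral_bead_count,
    mineralize,
)
from minfibril.model import validate_model


class TestDefaultBuild:
    def test_reference_molecule_and_bead_counts(self, default_fibril):
        """The 20-nm, five-period fibril holds 158 molecules / 28,305 beads."""
        assert default_fibril.n_molecules == 158
        assert default_fibril.n_collagen == 28305

    def test_thirteen_distinct_equilibrium_angles(self, default_fibril):
        phis = set(default_fibril.angle_phi0.tolist())
        assert len(phis) <= 13
        assert min(phis) >= 164.0 and max(phis) <= 180.0
        assert 164.0 in phis and 180.0 in phis

    def test_five_gap_overlap_periods(self, default_fibril):
        assert len(default_fibril.gap_slabs) == 5

    def test_gap_has_fewer_molecules_than_overlap(self, default_fibril):
        assert default_fibril.gap_count < default_fibril.overlap_count

    def test_validates(self, default_fibril):
        assert validate_model(default_fibril) == []

    def test_determinism(self):
        a = build_fibril()
        b = build_fibril()
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.bond_ij, b.bond_ij)
        np.testing.assert_array_equal(a.angle_phi0, b.angle_phi0)

    def test_seam_bond_lengths_periodic(self, default_fibril):
        """Minimum-image bond lengths at the seam equal the bead spacing."""
        m = default_fibril
        ij = m.bond_ij
        d = m.positions[ij[:, 1]] - m.positions[ij[:, 0]]
        d[:, 0] -= m.box.Lx * np.round(d[:, 0] / m.box.Lx)
        r = np.linalg.norm(d, axis=1)
        assert np.max(np.abs(r - 14.0)) < 1e-6


class TestAngleAssignment:
    def test_straight_chain_angles_are_180(self):
        m = build_fixture("single_molecule", n_beads=215)
        assert len(m.angle_ijk) == 213
        assert len(m.bond_ij) == 214
        assert np.all(m.angle_phi0 == 180.0)

    def test_rounding_rule(self):
        """A triple measured at 167.4 degrees is assigned phi_i = 167."""
        from minfibril.geometry import assign_angles

        m = build_fixture("single_molecule", n_beads=3)
        th = np.radians(180.0 - 167.4)
        m.positions[2] = m.positions[1] + 14.0 * np.array(
            [np.cos(th), np.sin(th), 0.0]
        )
        assign_angles(m)
        assert m.angle_phi0[0] == 167.0


class TestMineralization:
    def test_zero_target_zero_beads(self):
        m = build_fixture("mini_fibril", diameter_nm=6.0, mineral_wt=0.0)
        assert m.n_mineral == 0

    @pytest.mark.parametrize("wt", [5.0, 20.0, 33.0, 45.0])
    def test_weight_fraction_identity(self, wt):
        """Achieved wt% obeys the closed-form identity within ±0.5 points."""
        m = build_fixture("mini_fibril", diameter_nm=6.0, mineral_wt=wt)
        n_min, n_coll = m.n_mineral, m.n_collagen
        achieved = (
            100.0 * n_min * m.mass_mineral
            / (n_min * m.mass_mineral + n_coll * m.mass_collagen)
        )
        assert achieved == pytest.approx(m.mineral_wt, abs=1e-9)
        assert abs(achieved - wt) <= 0.5

    def test_counts_match_closed_form(self):
        assert mineral_bead_count(0.0, 1000, 1324.0, 1548.0) == 0
        n = mineral_bead_count(25.0, 28305, 1324.0, 1548.0)
        assert n == round(25 / 75 * 28305 * 1324.0 / 1548.0)

    def test_mineral_beads_inside_cylinder(self, mini_fibril_25):
        m = mini_fibril_25
        c = m.box.lengths[1] / 2
        p = m.positions[m.species == M.MINERAL]
        r = np.hypot(p[:, 1] - c, p[:, 2] - c)
        assert np.max(r) <= m.radius + 1e-9

    def test_mineral_in_gap_regions_near_termini(self, mini_fibril_25):
        """Mineral bead axial positions concentrate near terminal planes."""
        m = mini_fibril_25
        x = m.positions[m.species == M.MINERAL, 0]
        planes = m.terminal_planes
        d = np.abs(x[:, None] - planes[None, :])
        d = np.minimum(d, m.box.Lx - d).min(axis=1)
        # random placement over the box would average Lx / (2 * n_slabs)...;
        # growth from the planes must do much better
        assert np.mean(d) < 0.25 * m.box.Lx / 2

    def test_low_density_two_clusters_per_gap(self):
        """At 5% density each gap holds two disjoint crystals: mineral mass
        sits at both terminal planes with an empty band in the gap middle."""
        m = build_fibril(m=MineralizationSpec(target_wt=5.0))
        p = m.positions[m.species == M.MINERAL]
        Lx = m.box.Lx
        margin = 60.0
        for g0, g1 in m.gap_slabs:
            width = (g1 - g0) % Lx
            rel = (p[:, 0] - g0) % Lx  # axial position relative to the gap start
            at_start = np.sum((rel <= 20.0) | (rel >= Lx - margin))
            at_end = np.sum((rel >= width - 20.0) & (rel <= width + margin))
            assert at_start > 20 and at_end > 20  # one crystal per plane
            # the middle of the gap stays unmineralized (disjoint clusters)
            assert np.sum((rel > 0.35 * width) & (rel < 0.65 * width)) == 0

    def test_unreachable_density_raises_with_maximum(self):
        g = GeometrySpec(
            diameter_nm=6.0, periods=2, molecule_beads=None,
            total_collagen_beads=None,
        )
        m = build_fibril(g)
        with pytest.raises(ValueError, match="not reachable"):
            mineralize(m, MineralizationSpec(target_wt=45.0, collagen_clearance=14.0))


class TestCrosslinks:
    def test_isolated_molecule_gets_none(self, caplog):
        m = build_fixture("single_molecule", n_beads=30)
        add_crosslinks(m, CrosslinkSpec())
        assert np.sum(m.bond_kind == M.CROSSLINK) == 0

    def test_pair_crosslinks_are_intermolecular(self):
        m = build_fixture("molecule_pair", n_beads=30, separation=15.2)
        add_crosslinks(m, CrosslinkSpec())
        xl = m.bond_ij[m.bond_kind == M.CROSSLINK]
        assert 1 <= len(xl) <= 4
        for i, j in xl:
            assert m.molecule_id[i] != m.molecule_id[j]

    def test_count_bound_on_mini_fibril(self):
        m = build_fixture("mini_fibril", diameter_nm=6.0, crosslinks=True)
        n_xl = int(np.sum(m.bond_kind == M.CROSSLINK))
        assert 0 < n_xl <= 2 * m.n_molecules


class TestFixtures:
    def test_single_molecule_topology(self):
        m = build_fixture("single_molecule", n_beads=215)
        assert m.n_beads == 215 and len(m.bond_ij) == 214 and len(m.angle_ijk) == 213

    def test_molecule_pair_is_adhesive(self):
        """Two parallel chains at the LJ sigma separation attract (E < 0)."""
        m = build_fixture("molecule_pair", n_beads=30, separation=14.72 * 2 ** (1 / 6))
        res = ff.compute_forces(m)
        assert res.energy.E_nonbonded < 0

    def test_mini_fibril_validates_with_mineral(self):
        m = build_fixture("mini_fibril", diameter_nm=7.0, periods=2, mineral_wt=25.0)
        assert validate_model(m) == []
        assert abs(m.mineral_wt - 25.0) <= 0.5

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            build_fixture("nope")
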