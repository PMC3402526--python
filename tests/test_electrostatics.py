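"""Formal charges, Debye-Hückel constants, screened and FD-PB potentials."""

import math

import numpy as np
import pytest

from crossepi.electrostatics import (
    ChargeSet,
    ElectrostaticsError,
    assign_formal_charges,
    compare_patch_potentials,
    debye_parameters,
    fd_poisson_boltzmann,
    screened_potential,
    surface_evaluation_points,
)
from crossepi.sasa import relative_exposure, shrake_rupley
from crossepi.structio import assign_radii
from crossepi.synthetic import make_homolog_pair, make_ideal_helix, make_peptide

from conftest import single_atom_structure


def unit_charge(pos=(0.0, 0.0, 0.0), q=1.0):
    return ChargeSet(
        positions=np.array([pos], dtype=float),
        charges=np.array([q]),
        tags=[(("A", 1, ""), "NZ")],
    )


class TestFormalCharges:
    def test_poly_ala_only_termini_charged(self):
        st = make_ideal_helix("A" * 10)
        cs = assign_formal_charges(st)
        assert cs.net_charge == pytest.approx(0.0)
        # +1 on N-terminal N, -0.5/-0.5 on the C-terminal carboxylate
        assert sorted(cs.charges) == [-0.5, -0.5, 1.0]

    def test_counting_oracle_two_lys_one_asp(self):
        st = make_ideal_helix("AKAKDA")
        cs = assign_formal_charges(st)
        # termini cancel; 2 Lys - 1 Asp = +1
        assert cs.net_charge == pytest.approx(1.0)
        by_tag = {}
        for (rkey, aname), q in zip(cs.tags, cs.charges):
            by_tag.setdefault(aname, []).append(q)
        assert by_tag["NZ"] == [1.0, 1.0]
        assert sorted(by_tag["OD1"] + by_tag["OD2"]) == [-0.5, -0.5]

    def test_missing_tip_atom_falls_back_to_cb(self):
        st = make_ideal_helix("AKAA")
        res = st.residue("A", 2)
        res.atoms = [a for a in res.atoms if a.name != "NZ"]
        cs = assign_formal_charges(st)
        assert any("NZ -> CB" in f for f in cs.fallbacks)
        assert cs.net_charge == pytest.approx(1.0)


class TestDebyeParameters:
    def test_zero_ionic_strength_limit(self):
        kappa, debye_len, _ = debye_parameters(0.0)
        assert kappa == 0.0 and math.isinf(debye_len)

    def test_physiological_constants_hand_calculation(self):
        """Independent evaluation of the closed forms at I=0.15 M, T=298.15 K, ε=80."""
        from scipy import constants as c

        kT = c.k * 298.15
        lb = c.e**2 / (4 * math.pi * c.epsilon_0 * 80.0 * kT) * 1e10
        kappa = math.sqrt(2 * c.e**2 * c.N_A * 150.0 / (c.epsilon_0 * 80.0 * kT)) * 1e-10
        k, d, b = debye_parameters(0.15, 298.15, 80.0)
        assert b == pytest.approx(lb, rel=1e-12)
        assert k == pytest.approx(kappa, rel=1e-12)
        assert d == pytest.approx(1 / kappa, rel=1e-12)
        # magnitudes: ~7.0 Å Bjerrum, ~7.9 Å Debye at ε=80
        assert b == pytest.approx(7.0, abs=0.1)
        assert d == pytest.approx(7.9, abs=0.1)

    def test_negative_inputs_error(self):
        with pytest.raises(ElectrostaticsError):
            debye_parameters(-0.1)


class TestScreenedPotential:
    def test_zero_charges_identically_zero(self):
        cs = unit_charge(q=0.0)
        m = screened_potential(cs, np.array([[5.0, 0, 0], [0, 8.0, 0]]), kappa=0.0)
        np.testing.assert_allclose(m.values, 0.0)

    def test_unit_charge_at_bjerrum_length_gives_one_kt(self):
        _, _, lb = debye_parameters(0.0, 298.15, 80.0)
        m = screened_potential(unit_charge(), np.array([[lb, 0.0, 0.0]]), kappa=0.0)
        assert m.values[0] == pytest.approx(1.0, rel=1e-12)

    def test_term_by_term_summation_oracle(self):
        rng = np.random.default_rng(5)
        charges = ChargeSet(
            positions=rng.normal(size=(3, 3)) * 4,
            charges=np.array([1.0, -1.0, 0.5]),
            tags=[(("A", i, ""), "X") for i in range(3)],
        )
        pts = rng.normal(size=(5, 3)) * 12
        kappa, _, lb = debye_parameters(0.15)
        m = screened_potential(charges, pts, kappa=kappa)
        for p, v in zip(pts, m.values):
            expected = sum(
                q * lb * math.exp(-kappa * np.linalg.norm(p - c)) / np.linalg.norm(p - c)
                for q, c in zip(charges.charges, charges.positions)
            )
            assert v == pytest.approx(expected, abs=1e-10)

    def test_linearity_and_sign_symmetry(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(size=(4, 3)) * 5
        qa, qb = rng.normal(size=4), rng.normal(size=4)
        pts = rng.normal(size=(6, 3)) * 15
        tags = [(("A", i, ""), "X") for i in range(4)]

        def mk(q):
            return ChargeSet(positions=pos, charges=q, tags=tags)

        va = screened_potential(mk(qa), pts, kappa=0.1).values
        vb = screened_potential(mk(qb), pts, kappa=0.1).values
        vab = screened_potential(mk(qa + qb), pts, kappa=0.1).values
        np.testing.assert_allclose(vab, va + vb, atol=1e-12)
        vneg = screened_potential(mk(-qa), pts, kappa=0.1).values
        np.testing.assert_allclose(vneg, -va, atol=1e-12)

    def test_screening_monotone_in_kappa(self):
        pts = np.array([[6.0, 0, 0], [0, 10.0, 0], [3.0, 3.0, 3.0]])
        prev = None
        for kappa in (0.0, 0.05, 0.1, 0.3, 1.0):
            v = np.abs(screened_potential(unit_charge(), pts, kappa=kappa).values)
            if prev is not None:
                assert (v <= prev + 1e-12).all()
            prev = v

    def test_close_points_excluded_and_all_excluded_errors(self):
        m = screened_potential(
            unit_charge(), np.array([[0.2, 0, 0], [5.0, 0, 0]]), kappa=0.0
        )
        assert m.params["n_excluded_points"] == 1 and len(m.values) == 1
        with pytest.raises(ElectrostaticsError):
            screened_potential(unit_charge(), np.array([[0.1, 0, 0]]), kappa=0.0)


class TestSurfacePoints:
    def test_single_atom_points_on_offset_sphere(self):
        st = single_atom_structure(radius=1.6)
        table = shrake_rupley(st)
        pts, tags = surface_evaluation_points(st, table, offset=1.4)
        assert len(pts) == 1
        assert np.linalg.norm(pts[0]) == pytest.approx(3.0, abs=1e-9)

    def test_point_count_equals_exposed_atom_count(self, helix):
        table = shrake_rupley(helix)
        pts, tags = surface_evaluation_points(helix, table)
        n_exposed = sum(1 for a in table.atom_areas.values() if a > 0)
        assert len(pts) == n_exposed

    def test_buried_atom_emits_no_point(self):
        # central atom of a dense cluster is buried
        from conftest import cluster_structure

        centers = [[0.0, 0, 0]] + [
            [2.6 * x, 2.6 * y, 2.6 * z]
            for x, y, z in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
                            (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0), (1, 0, 1), (-1, 0, 1),
                            (0, 1, 1), (0, -1, 1), (1, 0, -1), (-1, 0, -1), (0, 1, -1), (0, -1, -1)]
        ]
        st = cluster_structure(centers, radius=1.9)
        table = shrake_rupley(st)
        pts, tags = surface_evaluation_points(st, table)
        assert (("A", 1, ""), "CA") not in tags


class TestFdPoissonBoltzmann:
    def eval_shell(self):
        dirs = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1] / np.sqrt(3), [-1, 1, 0] / np.sqrt(2)]
        )
        return np.vstack([d * r for r in (5.0, 8.0, 11.0, 15.0) for d in dirs])

    def test_zero_charges_zero_field(self):
        st = single_atom_structure(radius=1.65)
        cs = unit_charge(q=0.0)
        m = fd_poisson_boltzmann(st, cs, self.eval_shell(), grid_spacing=1.0, padding=6.0)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_coulomb_limit_uniform_dielectric_no_salt(self):
        st = single_atom_structure(radius=1.65)
        cs = unit_charge()
        m = fd_poisson_boltzmann(
            st, cs, self.eval_shell(), grid_spacing=1.0, padding=8.0,
            epsilon_in=80.0, epsilon_out=80.0, ionic_strength_M=0.0,
        )
        ref = screened_potential(cs, self.eval_shell(), kappa=0.0, epsilon_out=80.0)
        rel = np.abs(m.values - ref.values) / np.abs(ref.values)
        assert rel.max() < 0.05

    def test_debye_huckel_limit_with_salt(self):
        st = single_atom_structure(radius=1.65)
        cs = unit_charge()
        pts = self.eval_shell()
        sel = np.linalg.norm(pts, axis=1) >= 8.0 - 1e-9
        m = fd_poisson_boltzmann(
            st, cs, pts[sel], grid_spacing=1.0, padding=8.0,
            epsilon_in=80.0, epsilon_out=80.0, ionic_strength_M=0.15, ion_exclusion=0.0,
        )
        ref = screened_potential(cs, pts[sel], ionic_strength_M=0.15, epsilon_out=80.0)
        rel = np.abs(m.values - ref.values) / np.abs(ref.values)
        assert rel.max() < 0.07

    def test_grid_refinement_stable(self):
        st = single_atom_structure(radius=1.65)
        cs = unit_charge()
        pts = np.array([[6.0, 0, 0], [0, 9.0, 0], [0, 0, 12.0]])
        m1 = fd_poisson_boltzmann(st, cs, pts, grid_spacing=1.0, padding=6.0,
                                  epsilon_in=80.0, epsilon_out=80.0, ion_exclusion=0.0)
        m2 = fd_poisson_boltzmann(st, cs, pts, grid_spacing=0.5, padding=6.0,
                                  epsilon_in=80.0, epsilon_out=80.0, ion_exclusion=0.0)
        assert (np.abs(m1.values - m2.values) / np.abs(m2.values)).max() < 0.10

    def test_linearity_in_charges(self):
        st = single_atom_structure(radius=1.65)
        pts = np.array([[7.0, 0, 0], [0, 0, 10.0]])
        kwargs = dict(grid_spacing=1.0, padding=6.0, epsilon_in=4.0, epsilon_out=80.0)
        v1 = fd_poisson_boltzmann(st, unit_charge(q=1.0), pts, **kwargs).values
        v2 = fd_poisson_boltzmann(st, unit_charge(q=-0.5), pts, **kwargs).values
        v3 = fd_poisson_boltzmann(st, unit_charge(q=0.5), pts, **kwargs).values
        np.testing.assert_allclose(v1 + v2, v3, atol=1e-8)


class TestComparePatchPotentials:
    def make_map(self, structure, table):
        charges = assign_formal_charges(structure)
        pts, tags = surface_evaluation_points(structure, table)
        return screened_potential(charges, pts, tags, ionic_strength_M=0.15)

    def test_self_comparison_rms_zero(self, helix):
        table = shrake_rupley(helix)
        m = self.make_map(helix, table)
        pairing = [(i, i) for i in range(1, 13)]
        comp = compare_patch_potentials(m, m, pairing, {3, 4, 5})
        assert comp.rms_difference == 0.0 and comp.sign_flips == 0

    def test_planted_swap_is_largest_difference_in_patch(self):
        seq = "AEALQASNVAGTLDAV"
        a, b, pairing = make_homolog_pair(seq, {8: "K"}, jitter_sigma=0.0, seed=0)
        # swap Asn8 (a: N) -> Lys (b: K); patch = residues 6..10
        for st in (a, b):
            assign_radii(st)
        ta, tb = shrake_rupley(a), shrake_rupley(b)
        ma, mb = self.make_map(a, ta), self.make_map(b, tb)
        comp = compare_patch_potentials(ma, mb, pairing, set(range(6, 11)))
        assert comp.rms_difference > 0
        assert comp.largest_pair == (8, 8)

    def test_remote_swap_leaves_patch_quiet(self):
        # swap at residue 2; patch at residues 12..16, ≥ 12 Å away on the helix
        seq = "ANALQASNVAGTLDAV"
        a, b, pairing = make_homolog_pair(seq, {2: "K"}, jitter_sigma=0.0, seed=0)
        for st in (a, b):
            assign_radii(st)
        ta, tb = shrake_rupley(a), shrake_rupley(b)
        ma, mb = self.make_map(a, ta), self.make_map(b, tb)
        comp = compare_patch_potentials(ma, mb, pairing, set(range(12, 17)))
        assert comp.rms_difference < 0.1

    def test_parameter_mismatch_error(self, helix):
        table = shrake_rupley(helix)
        charges = assign_formal_charges(helix)
        pts, tags = surface_evaluation_points(helix, table)
        m1 = screened_potential(charges, pts, tags, ionic_strength_M=0.15)
        m2 = screened_potential(charges, pts, tags, ionic_strength_M=0.0)
        with pytest.raises(ElectrostaticsError, match="mismatch"):
            compare_patch_potentials(m1, m2, [(1, 1)], {1})
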