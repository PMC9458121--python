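"""Geometric kernels, per-term energies, and whole-system evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from energysplit import (
    CONSTANTS,
    FixtureSpec,
    angle_energy,
    bend_angle,
    bond_energy,
    brute_force_energy,
    coulomb_pair_energy,
    dihedral_angle,
    distance,
    improper_energy,
    lj_pair_energy,
    make_fixture,
    scale_factors,
    torsion_energy,
    total_energy,
)
from energysplit.energy import nonbonded_pair_arrays
from energysplit.errors import EvaluationError, MissingParameterError
from energysplit.params import (
    AngleParams,
    AtomTypeParams,
    BondParams,
    ImproperParams,
    TorsionParams,
    combine_lj,
)
from energysplit.topology import EXCLUDED_12, EXCLUDED_13, FULL, SCALED_14

from conftest import make_inert_pair

coords = st.floats(-50.0, 50.0, allow_nan=False)


class TestGeometry:
    def test_distance_trivial_cases(self):
        assert distance((0, 0, 0), (0, 0, 0)) == 0.0
        assert distance((0, 0, 0), (3, 4, 0)) == 5.0

    @settings(deadline=None, max_examples=100)
    @given(p=st.tuples(coords, coords, coords), q=st.tuples(coords, coords, coords))
    def test_distance_matches_componentwise_formula(self, p, q):
        expected = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        assert distance(p, q) == pytest.approx(expected, abs=1e-12)
        assert distance(q, p) == distance(p, q)

    def test_straight_angle(self):
        assert bend_angle((-1, 0, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(math.pi)

    def test_right_angle(self):
        assert bend_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(math.pi / 2)

    def test_near_collinear_cosine_is_clamped(self):
        # arms chosen so the raw cosine overshoots 1 by floating-point noise
        p = (0.1 + 0.2, 0.0, 0.0)
        q = (0.0, 0.0, 0.0)
        r = (-0.3, 0.0, 0.0)
        assert bend_angle(p, q, r) == pytest.approx(math.pi)
        assert bend_angle(p, q, (0.3, 0.0, 0.0)) == 0.0

    def test_zero_length_arm_names_atoms(self):
        with pytest.raises(EvaluationError, match="1, 2"):
            bend_angle((0, 0, 0), (0, 0, 0), (1, 0, 0), atoms=(1, 2, 3))

    def test_planar_cis_is_zero(self):
        # i and l on the same side of the j-k axis, all in one plane
        assert dihedral_angle((1, 1, 0), (0, 0, 0), (0, 2, 0), (1, 1.5, 0)) == pytest.approx(0.0)

    def test_planar_trans_is_pi(self):
        assert dihedral_angle((1, 1, 0), (0, 0, 0), (0, 2, 0), (-1, 1.5, 0)) == pytest.approx(
            math.pi
        )

    def test_staggered_matches_explicit_normal_construction(self):
        pts = [
            np.array([1.2, 0.3, -0.4]),
            np.array([0.0, 0.0, 0.0]),
            np.array([0.0, 1.5, 0.1]),
            np.array([-0.9, 1.9, 1.1]),
        ]
        n1 = np.cross(pts[1] - pts[0], pts[2] - pts[1])
        n2 = np.cross(pts[2] - pts[1], pts[3] - pts[2])
        expected = math.acos(
            np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        )
        assert abs(dihedral_angle(*pts)) == pytest.approx(expected, abs=1e-10)

    def test_collinear_axis_is_evaluation_error(self):
        with pytest.raises(EvaluationError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0), atoms=(0, 1, 2, 3))

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_dihedral_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 2.0
        try:
            phi = dihedral_angle(*pts)
        except EvaluationError:
            return
        rot = Rotation.random(random_state=int(seed)).as_matrix()
        shift = rng.normal(size=3) * 10
        moved = pts @ rot.T + shift
        assert dihedral_angle(*moved) == pytest.approx(phi, abs=1e-9)


BOND_CT_HC = BondParams(("CT", "HC"), 340.0, 1.09)
ANGLE_CNH = AngleParams(("C", "N", "H"), 50.0, 120.0001)
TORSION_PRINTED = TorsionParams(
    ("NJ", "CJ", "ND", "CK"), (0.0, 180.0, 0.0, 0.0), (0.0, 4.75, 0.0, 0.0), 1.0
)
IMPROPER_PRINTED = ImproperParams(("CJ", "NJ", "CD", "NH"), 1.1, 180.0, 2.0)


class TestTermEnergies:
    def test_bond_zero_at_equilibrium(self):
        assert bond_energy(BOND_CT_HC, 1.09) == 0.0

    def test_bond_stretched_tenth_angstrom(self):
        assert bond_energy(BOND_CT_HC, 1.19) == pytest.approx(3.40, rel=1e-12)

    def test_zero_force_constant_bond(self):
        assert bond_energy(BondParams(("A", "B"), 0.0, 1.0), 5.0) == 0.0

    def test_angle_zero_at_equilibrium(self):
        assert angle_energy(ANGLE_CNH, math.radians(120.0001)) == 0.0

    def test_angle_tenth_radian_displacement(self):
        th = math.radians(120.0001) + 0.1
        assert angle_energy(ANGLE_CNH, th) == pytest.approx(0.5, rel=1e-9)

    @pytest.mark.parametrize("theta", [0.3, 1.5, 3.0])
    def test_zero_force_constant_angle(self, theta):
        assert angle_energy(AngleParams(("A", "B", "C"), 0.0, 100.0), theta) == 0.0

    def test_torsion_printed_record_at_ninety_degrees(self):
        # kd2 * (1 + cos(2*90 - 180)) = 4.75 * 2 = 9.5
        assert torsion_energy(TORSION_PRINTED, math.pi / 2) == pytest.approx(9.5, rel=1e-12)

    def test_torsion_all_zero_magnitudes(self):
        rec = TorsionParams(("A", "B", "C", "D"), (0, 0, 0, 0), (0, 0, 0, 0), 1.0)
        assert torsion_energy(rec, 1.234) == 0.0

    @pytest.mark.parametrize("phi", [-2.0, 0.0, 0.7, 3.0])
    def test_torsion_is_two_pi_periodic(self, phi):
        assert torsion_energy(TORSION_PRINTED, phi) == pytest.approx(
            torsion_energy(TORSION_PRINTED, phi + 2 * math.pi), abs=1e-12
        )

    def test_torsion_n_paths_divides_series(self):
        rec = TorsionParams(
            ("A", "B", "C", "D"), (0.0, 180.0, 0.0, 0.0), (0.0, 4.75, 0.0, 0.0), 2.0
        )
        assert torsion_energy(rec, 0.5) == pytest.approx(
            torsion_energy(TORSION_PRINTED, 0.5) / 2.0, rel=1e-12
        )

    def test_improper_phase_aligned_is_zero(self):
        assert improper_energy(IMPROPER_PRINTED, math.pi) == pytest.approx(0.0, abs=1e-12)

    def test_improper_ninety_degree_displacement(self):
        # ki * (1 - cos(2*(90 - 180) deg)) = 1.1 * (1 - cos(-180 deg)) = 2.2
        assert improper_energy(IMPROPER_PRINTED, math.pi / 2) == pytest.approx(2.2, rel=1e-12)

    def test_improper_zero_magnitude(self):
        rec = ImproperParams(("A", "B", "C", "D"), 0.0, 180.0, 2.0)
        assert improper_energy(rec, 0.3) == 0.0

    @pytest.mark.parametrize(
        "rec,x0,kernel",
        [
            (BOND_CT_HC, 1.09, lambda r, x: bond_energy(r, x)),
            (ANGLE_CNH, math.radians(120.0001), lambda r, x: angle_energy(r, x)),
        ],
    )
    def test_quadratic_terms_even_about_equilibrium(self, rec, x0, kernel):
        for delta in (0.01, 0.1, 0.4):
            assert kernel(rec, x0 + delta) == pytest.approx(
                kernel(rec, x0 - delta), rel=1e-12
            )

    @pytest.mark.parametrize("phi", [-2.5, -0.3, 1.1, 3.0])
    def test_torsion_energy_even_in_phi_for_printed_phases(self, phi):
        # phases 0/180 make the cosine series even, so a reversed quadruple
        # (whose dihedral flips sign) has the same energy
        assert torsion_energy(TORSION_PRINTED, -phi) == pytest.approx(
            torsion_energy(TORSION_PRINTED, phi), abs=1e-12
        )


class TestNonbondedPairs:
    HP = AtomTypeParams("HP", 1.1, 0.0157)

    def test_lj_minimum_value_at_combined_diameter(self):
        co = combine_lj(self.HP, self.HP)
        assert lj_pair_energy(co, co.d_pair, 1.0) == pytest.approx(-0.0157, rel=1e-12)

    def test_lj_numerical_minimum_matches_well_depth(self):
        co = combine_lj(self.HP, self.HP)
        res = minimize_scalar(
            lambda r: lj_pair_energy(co, r, 1.0), bounds=(0.5, 10.0), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.fun == pytest.approx(-0.0157, abs=1e-9)
        assert res.x == pytest.approx(co.d_pair, abs=1e-6)

    def test_lj_scale_zero_kills_any_separation(self):
        co = combine_lj(self.HP, self.HP)
        assert lj_pair_energy(co, 0.3, 0.0) == 0.0

    def test_lj_vanishes_at_infinity_from_below(self):
        co = combine_lj(self.HP, self.HP)
        e = lj_pair_energy(co, 500.0, 1.0)
        assert -1e-10 < e < 0.0

    def test_lj_zero_separation_is_error(self):
        co = combine_lj(self.HP, self.HP)
        with pytest.raises(EvaluationError):
            lj_pair_energy(co, 0.0, 1.0)

    def test_coulomb_unit_charges_at_one_angstrom(self):
        e = coulomb_pair_energy(1.0, -1.0, 1.0, 1.0)
        assert e == -332.063712827427

    def test_coulomb_zero_charge(self):
        assert coulomb_pair_energy(0.0, 5.0, 2.0, 1.0) == 0.0

    def test_coulomb_14_scale_is_exact_division(self):
        full = coulomb_pair_energy(0.4, -0.3, 2.5, 1.0)
        scaled = coulomb_pair_energy(0.4, -0.3, 2.5, CONSTANTS.coulomb_14_scale)
        assert scaled == pytest.approx(full / 1.2, rel=1e-15)

    def test_coulomb_sign_structure(self):
        q = 0.37
        assert coulomb_pair_energy(q, q, 1.7, 1.0) == coulomb_pair_energy(-q, -q, 1.7, 1.0)
        assert coulomb_pair_energy(q, -q, 1.7, 1.0) == -coulomb_pair_energy(q, q, 1.7, 1.0)

    def test_scale_factor_table(self):
        assert scale_factors(EXCLUDED_12) == (0.0, 0.0)
        assert scale_factors(EXCLUDED_13) == (0.0, 0.0)
        assert scale_factors(SCALED_14) == (0.5, 1.0 / 1.2)
        assert scale_factors(FULL) == (1.0, 1.0)


class TestTotalEnergy:
    def test_inert_bonded_pair_at_equilibrium_is_zero(self):
        system = make_inert_pair(1.09)
        assert total_energy(system).total == 0.0

    def test_single_isolated_charged_atom_is_zero(self):
        from energysplit import Atom, ConnectivityGraph, ParameterSet, build_system
        from energysplit.params import AtomTypeParams as ATP

        params = ParameterSet()
        params.add_vdw(ATP("Q", 1.0, 0.1))
        system = build_system(
            [Atom(index=0, type_name="Q", charge=1.0)], ConnectivityGraph(1), params
        )
        system.set_positions(np.zeros((1, 3)))
        assert total_energy(system).total == 0.0

    def test_missing_bond_parameter_names_types(self):
        system = make_inert_pair(1.0)
        system.params.bond_table.clear()
        with pytest.raises(MissingParameterError, match="NUL-NUL"):
            total_energy(system)

    @pytest.mark.parametrize(
        "spec",
        [
            FixtureSpec("chain", 10),
            FixtureSpec("ring", 7),
            FixtureSpec("star", 6),
            FixtureSpec("two-molecule", 9),
            FixtureSpec("random", 40, seed=1),
            FixtureSpec("random", 80, seed=2),
        ],
        ids=lambda s: f"{s.recipe}{s.n_atoms}",
    )
    def test_matches_independent_oracle_per_class(self, spec):
        system = make_fixture(spec)
        totals = total_energy(system)
        oracle = brute_force_energy(system)
        for name, value in totals.as_dict().items():
            assert value == pytest.approx(oracle[name], abs=1e-9)
        assert totals.total == pytest.approx(oracle["total"], abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_rigid_motion(self, seed):
        system = make_fixture(FixtureSpec("random", 50, seed=seed))
        before = total_energy(system).total
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = np.array([7.0, -3.0, 11.0])
        system.set_positions(system.positions @ rot.T + shift)
        assert total_energy(system).total == pytest.approx(before, abs=1e-9)

    def test_worker_chunking_does_not_change_results(self):
        system = make_fixture(FixtureSpec("random", 60, seed=3))
        t1 = total_energy(system, workers=1)
        t4 = total_energy(system, workers=4)
        assert t4.vdw == pytest.approx(t1.vdw, abs=1e-10)
        assert t4.coulomb == pytest.approx(t1.coulomb, abs=1e-10)

    def test_pair_arrays_cover_every_pair_once(self):
        system = make_fixture(FixtureSpec("chain", 8))
        ii, jj, _, _ = nonbonded_pair_arrays(system)
        assert len(ii) == 8 * 7 // 2
        assert len({(int(i), int(j)) for i, j in zip(ii, jj)}) == len(ii)
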