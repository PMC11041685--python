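"""Rigid-body geometry, closure analysis, Debye scattering, Guinier fits."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fractasm.geometry import GeometryError, GeometryParams, ParameterError, build_sierpinski
from fractasm.structure import (
    BeadModel,
    FitError,
    ScatteringProfile,
    center_of_mass,
    closure_gap,
    closure_root,
    debye_profile,
    default_q_grid,
    dihedral_4point,
    dihedral_between_dimers,
    guinier_fit,
    mixture_rg,
    radius_of_gyration,
    rotation_between_conformations,
)


class TestCenterOfMass:
    def test_uniform(self):
        m = BeadModel(positions=[[0, 0, 0], [2, 0, 0]])
        assert np.allclose(center_of_mass(m), [1, 0, 0])

    def test_weighted(self):
        m = BeadModel(positions=[[0, 0, 0], [4, 0, 0]], masses=[1, 3])
        assert np.allclose(center_of_mass(m), [3, 0, 0])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(7, 3))
        t = np.array([1.5, -2.0, 0.3])
        a = center_of_mass(BeadModel(positions=pos))
        b = center_of_mass(BeadModel(positions=pos + t))
        assert np.allclose(b, a + t, atol=1e-12)

    def test_bad_masses(self):
        with pytest.raises(ParameterError):
            BeadModel(positions=[[0, 0, 0]], masses=[0.0])


class TestRadiusOfGyration:
    def test_single_bead(self):
        assert radius_of_gyration(BeadModel(positions=[[3, 1, 4]])) == 0.0

    def test_equilateral_triangle(self):
        s = 2.5
        pts = [[0, 0, 0], [s, 0, 0], [s / 2, s * math.sqrt(3) / 2, 0]]
        assert radius_of_gyration(BeadModel(positions=pts)) == pytest.approx(
            s / math.sqrt(3)
        )

    def test_doubles_per_level(self):
        rgs = [
            radius_of_gyration(BeadModel.from_assembly(build_sierpinski(k)))
            for k in (1, 2, 3)
        ]
        assert rgs[1] / rgs[0] == pytest.approx(2.0, abs=0.05)
        assert rgs[2] / rgs[1] == pytest.approx(2.0, abs=0.05)


class TestDihedral:
    def test_cis_coplanar_is_zero(self):
        ang = dihedral_4point([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        assert ang == pytest.approx(0.0, abs=1e-12)

    def test_trans_coplanar_is_180(self):
        ang = dihedral_4point([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
        assert ang == pytest.approx(180.0)

    @pytest.mark.parametrize("twist", [15.0, 60.0, 120.0])
    def test_constructed_twist_recovered(self, twist):
        # rotate the fourth point about the axis from the cis arrangement
        p0, p1, p2 = np.array([0.0, 1, 0]), np.zeros(3), np.array([1.0, 0, 0])
        p3_cis = np.array([1.0, 1, 0])
        rot = Rotation.from_rotvec(np.radians(twist) * np.array([1.0, 0, 0]))
        p3 = rot.apply(p3_cis - p2) + p2
        assert dihedral_4point(p0, p1, p2, p3) == pytest.approx(twist, abs=1e-9)

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3))
        base = dihedral_4point(*pts, signed=True)
        R = Rotation.random(random_state=7)
        t = np.array([2.0, -1.0, 5.0])
        moved = R.apply(pts) + t
        assert dihedral_4point(*moved, signed=True) == pytest.approx(base, abs=1e-9)

    def test_collinear_degenerate(self):
        with pytest.raises(GeometryError):
            dihedral_4point([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])

    def test_planar_assembly_interface_is_trans(self, level1):
        # head-to-head terminus swap: the planar coarse model reads 180 deg
        # on every fractal bond (C3 symmetry makes all three equal)
        angles = [dihedral_between_dimers(level1, a, b) for a, b in level1.fractal_bonds]
        assert np.allclose(angles, angles[0], atol=1e-9)
        assert angles[0] == pytest.approx(180.0, abs=1e-9)


class TestRotationBetweenConformations:
    def _hexamer_beads(self):
        return BeadModel.from_assembly(build_sierpinski(0))

    def test_identity(self):
        ref = self._hexamer_beads()
        axis, ang = rotation_between_conformations(ref, ref, [0, 1, 5], [2, 3, 4])
        assert ang == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [4.0, 4.2])
    def test_recovers_constructed_dimer_rotation(self, angle):
        # mirrors the free-hexamer vs in-fractal comparison: probe dimers
        # rotated by a few degrees about an internal axis
        ref = self._hexamer_beads()
        tgt = self._hexamer_beads()
        axis = np.array([0.2, -0.4, 0.89])
        axis /= np.linalg.norm(axis)
        probe = [2, 3, 4]
        ctr = tgt.positions[probe].mean(axis=0)
        R = Rotation.from_rotvec(np.radians(angle) * axis)
        tgt.positions[probe] = R.apply(tgt.positions[probe] - ctr) + ctr
        got_axis, got = rotation_between_conformations(ref, tgt, [0, 1, 5], probe)
        assert got == pytest.approx(angle, abs=1e-6)
        assert abs(np.dot(got_axis, axis)) == pytest.approx(1.0, abs=1e-6)

    def test_composition(self):
        ref = self._hexamer_beads()
        axis = np.array([0.0, 0.0, 1.0])
        probe = [2, 3, 4]

        def rotated(angle):
            t = self._hexamer_beads()
            ctr = t.positions[probe].mean(axis=0)
            R = Rotation.from_rotvec(np.radians(angle) * axis)
            t.positions[probe] = R.apply(t.positions[probe] - ctr) + ctr
            return t

        _, a3 = rotation_between_conformations(ref, rotated(3.0), [0, 1, 5], probe)
        _, a5 = rotation_between_conformations(ref, rotated(5.0), [0, 1, 5], probe)
        assert a5 == pytest.approx(a3 + 2.0, abs=1e-6)

    def test_degenerate_subset(self):
        ref = BeadModel(positions=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
        with pytest.raises(GeometryError):
            rotation_between_conformations(ref, ref, [0, 1, 2], [0, 1, 3])


class TestClosure:
    def test_gap_positive_at_level1_dihedral(self):
        gap = closure_gap(60.0)
        assert 5.0 < gap < 60.0  # of order 10 nm

    def test_gap_monotone_decreasing_toward_root(self):
        thetas = np.linspace(60.0, 1.0, 30)
        gaps = [closure_gap(t) for t in thetas]
        assert all(b < a for a, b in zip(gaps, gaps[1:]))

    def test_root_below_level1_angle(self):
        theta_star = closure_root()
        assert 0 < theta_star < 60.0
        assert closure_gap(theta_star) <= 0.1 + 1e-6

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            closure_gap(0.0)
        with pytest.raises(ParameterError):
            closure_gap(181.0)

    def test_gap_continuous(self):
        # small parameter steps give small gap steps
        g = [closure_gap(t) for t in (29.9, 30.0, 30.1)]
        assert abs(g[1] - g[0]) < 0.2 and abs(g[2] - g[1]) < 0.2


class TestDebye:
    def test_single_bead_flat(self):
        prof = debye_profile(BeadModel(positions=[[0, 0, 0]]), np.linspace(0.01, 2, 50))
        assert np.allclose(prof.intensity, 1.0)

    def test_two_bead_closed_form(self):
        d = 3.0
        q = np.linspace(0.05, 2, 100)
        prof = debye_profile(BeadModel(positions=[[0, 0, 0], [d, 0, 0]]), q)
        expected = 2 + 2 * np.sin(q * d) / (q * d)
        assert np.allclose(prof.intensity, expected, atol=1e-12)

    def test_forward_limit_is_n_squared(self, level1):
        m = BeadModel.from_assembly(level1)
        prof = debye_profile(m, np.array([0.0, 0.001]))
        assert prof.intensity[0] == pytest.approx(len(m) ** 2)

    def test_guinier_limit(self, level1):
        # I(q) ~ n^2 exp(-q^2 Rg^2 / 3) within 1% for q Rg <= 0.5
        m = BeadModel.from_assembly(level1)
        rg = radius_of_gyration(m)
        q = np.linspace(0.01, 0.5 / rg, 40)
        prof = debye_profile(m, q)
        guinier = len(m) ** 2 * np.exp(-(q ** 2) * rg ** 2 / 3)
        assert np.allclose(prof.intensity, guinier, rtol=0.01)


class TestGuinierFit:
    def test_exact_guinier_profile(self):
        q = np.linspace(0.01, 1.0, 200)
        prof = ScatteringProfile(q=q, intensity=5.0 * np.exp(-(q ** 2) * 16 / 3))
        rg, i0 = guinier_fit(prof)
        assert rg == pytest.approx(4.0, rel=1e-6)
        assert i0 == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_debye_consistency_all_levels(self, level):
        m = BeadModel.from_assembly(build_sierpinski(level))
        prof = debye_profile(m, default_q_grid())
        rg, _ = guinier_fit(prof)
        assert rg == pytest.approx(radius_of_gyration(m), rel=0.03)

    def test_noisy_profile_within_ten_percent(self, level1):
        from fractasm.synth import simulate_saxs

        m = BeadModel.from_assembly(level1)
        prof = simulate_saxs(m, default_q_grid(), noise_frac=0.02, seed=11)
        rg, _ = guinier_fit(prof)
        assert rg == pytest.approx(radius_of_gyration(m), rel=0.10)

    def test_rising_profile_rejected(self):
        q = np.linspace(0.01, 1.0, 50)
        with pytest.raises(FitError):
            guinier_fit(ScatteringProfile(q=q, intensity=np.exp(q ** 2)))


class TestMixtureRg:
    def test_single_species(self, level1):
        m = BeadModel.from_assembly(level1)
        rg = mixture_rg({18: 1e-9}, {18: m})
        assert rg == pytest.approx(radius_of_gyration(m))

    def test_equal_molar_closed_form(self):
        m6 = BeadModel.from_assembly(build_sierpinski(0))
        m54 = BeadModel.from_assembly(build_sierpinski(2))
        rg6, rg54 = radius_of_gyration(m6), radius_of_gyration(m54)
        got = mixture_rg({6: 1e-9, 54: 1e-9}, {6: m6, 54: m54})
        want = math.sqrt(
            (36 * rg6 ** 2 + 54 ** 2 * rg54 ** 2) / (36 + 54 ** 2)
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_missing_model_rejected(self):
        with pytest.raises(ParameterError):
            mixture_rg({6: 1e-9}, {})

    def test_apparent_rg_rises_with_concentration(self):
        from fractasm.equilibrium import Conditions, DEFAULT_LADDER, solve_equilibrium

        models = {
            n: BeadModel.from_assembly(build_sierpinski(k))
            for n, k in ((6, 0), (18, 1), (54, 2))
        }
        models[1] = BeadModel(positions=[[0, 0, 0]])
        models[2] = BeadModel(positions=[[0, 0, 0], [2.2, 0, 0]])
        rgs = []
        for c in np.geomspace(5e-9, 100e-6, 8):
            dist = solve_equilibrium(DEFAULT_LADDER, Conditions(total_subunit_conc=c))
            rgs.append(mixture_rg(dist, models))
        assert all(b >= a - 1e-9 for a, b in zip(rgs, rgs[1:]))
        assert rgs[-1] > rgs[0]
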