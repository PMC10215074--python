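"""Ligament mechanics, contact surrogate, and model serialization."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kneeplan.kinematics import Pose6
from kneeplan.knee_model import (ContactSurfacePair, KneeModel, LigamentBundle,
                                 TibialPatch, contact_force, ligament_energy,
                                 ligament_force, ligament_length,
                                 ligament_strain, total_potential_energy)


def make_bundle(**kw):
    defaults = dict(name="LCL", origin=[0.0, 1.0, 44.0],
                    insertion=[-8.0, -50.0, 41.0], stiffness=2000.0,
                    slack_length=50.0, toe_limit=0.03)
    defaults.update(kw)
    return LigamentBundle(**defaults)


def independent_transform(pose):
    """Oracle transform built from scipy's Euler machinery, not the package's.

    Intrinsic Z-X-Y sequence with angles (-fe, vv, -ei); translation
    assembled along the JCS triad from the rotated tibial y axis.
    """
    R = Rotation.from_euler("ZXY", [-pose.fe, pose.vv, -pose.ei],
                            degrees=True).as_matrix()
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R @ np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2)
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = pose.lm * e1 + pose.ap * e2 + pose.pd * e3
    return T


class TestLigamentLength:
    def test_coincident_points_zero_length(self):
        b = make_bundle(origin=[1.0, 2.0, 3.0], insertion=[1.0, 2.0, 3.0])
        assert ligament_length(b, Pose6()) == pytest.approx(0.0, abs=1e-12)

    def test_vertical_bundle_at_identity(self):
        b = make_bundle(origin=[0.0, 0.0, 0.0], insertion=[0.0, -100.0, 0.0],
                        slack_length=100.0)
        assert ligament_length(b, Pose6()) == pytest.approx(100.0, abs=1e-12)

    def test_matches_matrix_oracle_on_random_poses(self):
        rng = np.random.default_rng(5)
        b = make_bundle()
        for _ in range(50):
            pose = Pose6(fe=rng.uniform(0, 60), ei=rng.uniform(-15, 15),
                         vv=rng.uniform(-10, 10), ap=rng.uniform(-10, 10),
                         lm=rng.uniform(-10, 10), pd=rng.uniform(-10, 10))
            T = independent_transform(pose)
            p = T[:3, :3] @ b.insertion + T[:3, 3]
            expected = float(np.linalg.norm(p - b.origin))
            assert ligament_length(b, pose) == pytest.approx(expected, abs=1e-9)


class TestStrainAndForce:
    @pytest.mark.parametrize("length,L0,expected",
                             [(110.0, 100.0, 0.10), (100.0, 100.0, 0.0),
                              (95.0, 100.0, -0.05)])
    def test_strain_values(self, length, L0, expected):
        assert ligament_strain(length, L0) == pytest.approx(expected, abs=1e-15)

    def test_nonpositive_slack_length_rejected(self):
        with pytest.raises(ValueError):
            ligament_strain(100.0, 0.0)
        with pytest.raises(ValueError):
            make_bundle(slack_length=-1.0)

    def test_slack_ligament_carries_no_force(self):
        b = make_bundle()
        assert ligament_force(b, 0.0) == 0.0
        assert ligament_force(b, -0.10) == 0.0

    def test_toe_linear_branches_agree_at_junction(self):
        b = make_bundle(stiffness=2000.0, toe_limit=0.03)
        eps = 2.0 * b.toe_limit
        toe = b.stiffness * eps ** 2 / (4.0 * b.toe_limit)
        lin = b.stiffness * (eps - b.toe_limit)
        assert abs(toe - lin) < 1e-12
        assert ligament_force(b, eps) == pytest.approx(toe, abs=1e-12)

    def test_force_nondecreasing_on_dense_grid(self):
        b = make_bundle()
        grid = np.linspace(-0.05, 0.20, 2001)
        f = np.array([ligament_force(b, e) for e in grid])
        assert np.all(np.diff(f) >= 0.0)
        assert np.all(f >= 0.0)

    def test_energy_derivative_matches_force(self):
        # dE/dlength = f; energy is the integral of the force over length
        b = make_bundle(slack_length=50.0)
        for eps in (0.01, 0.04, 0.09):
            h = 1e-7
            dE = (ligament_energy(b, eps + h) - ligament_energy(b, eps - h)) / (2 * h)
            assert dE / b.slack_length == pytest.approx(
                ligament_force(b, eps), rel=1e-5)


def flat_pair(y0=-20.5, stiffness=300.0, slope=0.0):
    return ContactSurfacePair(
        sphere_centers=[[0.0, 0.0, -22.0], [0.0, 0.0, 22.0]],
        sphere_radius=21.0,
        patches=(TibialPatch(y0, slope, 0.0, 0.0, 0.0, -22.0),
                 TibialPatch(y0, slope, 0.0, 0.0, 0.0, 22.0)),
        stiffness=stiffness)


class TestContact:
    def test_separated_surfaces_zero_force(self):
        pair = flat_pair(y0=-25.0)
        for f, _ in contact_force(pair, Pose6()):
            np.testing.assert_allclose(f, 0.0)

    def test_sphere_on_plane_closed_form(self):
        pair = flat_pair(y0=-20.5)
        depth = -20.5 - (0.0 - 21.0)
        expected = pair.stiffness * depth ** pair.exponent
        for f, point in contact_force(pair, Pose6()):
            assert np.linalg.norm(f) == pytest.approx(expected, rel=1e-12)
            assert f[1] == pytest.approx(-expected)   # pushes the tibia distally
            assert point[1] == pytest.approx(-20.5)

    def test_symmetric_penetration_mirrors_mediolaterally(self):
        pair = ContactSurfacePair(
            sphere_centers=[[0.0, 0.0, -22.0], [0.0, 0.0, 22.0]],
            sphere_radius=21.0,
            patches=(TibialPatch(-20.8, 0.0, 0.004, 0.008, 0.0, -22.0),
                     TibialPatch(-20.8, 0.0, 0.004, 0.008, 0.0, 22.0)),
            stiffness=300.0)
        (f_med, p_med), (f_lat, p_lat) = contact_force(pair, Pose6(lm=0.0))
        np.testing.assert_allclose(f_med[[0, 1]], f_lat[[0, 1]], atol=1e-12)
        assert f_med[2] == pytest.approx(-f_lat[2], abs=1e-12)
        assert p_med[2] == pytest.approx(-p_lat[2], abs=1e-12)

    def test_force_continuous_at_first_contact(self):
        pair = flat_pair(y0=-21.0)   # exactly touching at pd = 0
        mags = []
        for pd in np.linspace(-0.02, 0.02, 41):
            total = sum(np.linalg.norm(f) for f, _ in
                        contact_force(pair, Pose6(pd=pd)))
            mags.append(total)
        jumps = np.abs(np.diff(mags))
        assert jumps.max() < 0.05    # K*d^2 ramps in smoothly from zero

    def test_outside_working_range_rejected(self):
        pair = flat_pair(y0=-10.0)   # 11 mm interpenetration
        with pytest.raises(ValueError):
            contact_force(pair, Pose6())

    def test_excessive_patch_curvature_rejected(self):
        with pytest.raises(ValueError):
            ContactSurfacePair(
                sphere_centers=[[0, 0, -22], [0, 0, 22]], sphere_radius=21.0,
                patches=(TibialPatch(-21.0, 0.0, 0.03, 0.0, 0.0, -22.0),
                         TibialPatch(-21.0, 0.0, 0.03, 0.0, 0.0, 22.0)),
                stiffness=300.0)


class TestKneeModel:
    def test_ligament_set_validation(self, knee):
        with pytest.raises(ValueError):
            # dropping a non-ACL ligament is not a valid resection state
            KneeModel(femur_frame=knee.femur_frame, tibia_frame=knee.tibia_frame,
                      ligaments=knee.ligaments[:6], contact=knee.contact,
                      mass_kg=knee.mass_kg, com_tibia=knee.com_tibia)

    def test_serialization_round_trip_bit_exact(self, knee, tmp_path):
        path = tmp_path / "knee.json"
        knee.save(path)
        loaded = type(knee).load(path)
        assert loaded.to_dict() == knee.to_dict()
        # strict float identity on a few deep fields
        for a, b in zip(knee.ligaments, loaded.ligaments):
            assert (a.origin == b.origin).all()
            assert a.slack_length == b.slack_length

    def test_total_potential_energy_finite(self, knee):
        E = total_potential_energy(knee, Pose6())
        assert math.isfinite(E)
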