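"""Corridor sampling, mean corridor HU, and the axial/sagittal measurements."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pediplan as pp
from pediplan.geometry import GeometryError, cylinder_samples

from conftest import uniform_volume


def simple_frame(side="left"):
    return pp.VertebralFrame(
        midline_plane=pp.Plane(np.zeros(3), np.array([1.0, 0.0, 0.0])),
        lower_endplate_plane=pp.Plane(np.array([0.0, 0.0, -15.0]),
                                      np.array([0.0, 0.0, 1.0])),
        axial_normal=np.array([0.0, 0.0, 1.0]),
        side=side)


def random_trajectory(rng, side="left"):
    sign = -1.0 if side == "left" else 1.0
    entry = np.array([sign * rng.uniform(8, 20), rng.uniform(-30, -20),
                      rng.uniform(-10, 10)])
    # anterior-dominant direction, mild convergence and tilt
    d = np.array([-sign * rng.uniform(0, 0.5), 1.0, rng.uniform(-0.5, 0.5)])
    return pp.Trajectory(entry=entry, direction=d / np.linalg.norm(d),
                         length=30.0, diameter=6.0)


class TestCylinderSamples:
    def test_weights_normalized(self):
        t = pp.Trajectory(entry=np.zeros(3), direction=[0, 1, 0],
                          length=30.0, diameter=6.0)
        _, w = cylinder_samples(t, step_axial=0.25, rings=3)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_single_ring_is_centerline(self):
        t = pp.Trajectory(entry=np.zeros(3), direction=[0, 1, 0],
                          length=10.0, diameter=6.0)
        pts, _ = cylinder_samples(t, step_axial=1.0, rings=1)
        assert np.allclose(pts[:, [0, 2]], 0.0)
        assert np.all((pts[:, 1] > 0) & (pts[:, 1] < 10))

    def test_linear_field_mean_is_centroid_value(self, rng):
        t = random_trajectory(rng)
        pts, w = cylinder_samples(t, step_axial=0.5, rings=4)
        g = np.array([0.3, -1.2, 2.1])
        vals = pts @ g + 5.0
        centroid = t.entry + (t.length / 2.0) * t.direction
        assert np.sum(w * vals) == pytest.approx(centroid @ g + 5.0, abs=1e-6)


class TestMeanCtValue:
    def test_uniform_volume(self):
        v = uniform_volume(1000.0, shape=(40, 40, 40), spacing=1.0)
        t = pp.Trajectory(entry=[20, 5, 20], direction=[0, 1, 0],
                          length=30.0, diameter=6.0)
        assert pp.mean_ct_value(t, v) == pytest.approx(1000.0)

    def test_half_space_split_at_axial_midpoint(self):
        v = uniform_volume(shape=(40, 60, 40), spacing=1.0)
        data = np.where(np.arange(60)[None, :, None] < 20, 1000.0, 2000.0)
        v = v.with_data(np.broadcast_to(data, v.shape).copy())
        t = pp.Trajectory(entry=[20, 5, 20], direction=[0, 1, 0],
                          length=29.0, diameter=6.0)  # midpoint at the 1000/2000 step
        assert pp.mean_ct_value(t, v) == pytest.approx(1500.0, rel=0.01)

    def test_refinement_oracle_on_phantom(self, default_phantom, left_frame):
        ct, lab, _ = default_phantom
        manual = pp.plan_manual(ct, lab, left_frame, "left")
        coarse = pp.mean_ct_value(manual.trajectory, ct)
        dense = pp.mean_ct_value(manual.trajectory, ct,
                                 step_axial=0.025, rings=10)
        assert coarse == pytest.approx(dense, rel=0.005)

    def test_corridor_exits_grid_raises(self):
        v = uniform_volume(shape=(20, 20, 20), spacing=1.0)
        t = pp.Trajectory(entry=[10, 5, 10], direction=[0, 1, 0],
                          length=30.0, diameter=6.0)
        with pytest.raises(pp.VolumeError):
            pp.mean_ct_value(t, v)

    def test_centerline_option(self):
        v = uniform_volume(shape=(40, 40, 40), spacing=1.0)
        xs = np.arange(40)[:, None, None]
        v = v.with_data(np.broadcast_to(100.0 * xs, v.shape).copy())
        t = pp.Trajectory(entry=[20, 5, 20], direction=[0, 1, 0],
                          length=30.0, diameter=6.0)
        assert pp.mean_ct_value(t, v, centerline_only=True) == pytest.approx(
            2000.0, abs=1e-6)


class TestMeasurement:
    def test_straight_anterior_screw(self):
        f = simple_frame()
        t = pp.Trajectory(entry=[-15, -28, 0], direction=[0, 1, 0],
                          length=30.0, diameter=6.0)
        m = pp.measure_trajectory(t, f)
        assert m.theta == pytest.approx(90.0)
        assert m.abduction == pytest.approx(0.0)
        assert m.theta_prime == pytest.approx(90.0)
        assert m.craniocaudal == pytest.approx(0.0)
        assert m.d == pytest.approx(15.0)
        assert m.d_prime == pytest.approx(15.0)

    def test_caudal_tilt_gives_theta_prime_above_90(self):
        f = simple_frame()
        g = np.deg2rad(19.19)
        t = pp.Trajectory(entry=[-15, -28, 0],
                          direction=[0, np.cos(g), -np.sin(g)],
                          length=30.0, diameter=6.0)
        m = pp.measure_trajectory(t, f)
        assert m.theta_prime == pytest.approx(109.19, abs=1e-9)
        assert m.craniocaudal == pytest.approx(19.19, abs=1e-9)

    def test_convergent_screw_abduction(self):
        f = simple_frame()
        a = np.deg2rad(12.0)
        t = pp.Trajectory(entry=[-15, -28, 0],
                          direction=[np.sin(a), np.cos(a), 0],
                          length=30.0, diameter=6.0)
        m = pp.measure_trajectory(t, f)
        assert m.abduction == pytest.approx(12.0, abs=1e-9)

    def test_vector_algebra_oracle(self, rng):
        f = simple_frame()
        for _ in range(50):
            t = random_trajectory(rng)
            m = pp.measure_trajectory(t, f)
            # independent oracle: explicit projections and arccos
            d_oracle = abs(t.entry[0])
            dir_ax = t.direction.copy()
            dir_ax[2] = 0.0
            m_hat = np.array([1.0, 0.0, 0.0])  # entry x < 0: toward midline
            th = np.degrees(np.arccos(dir_ax @ m_hat / np.linalg.norm(dir_ax)))
            dp_oracle = abs(t.entry[2] + 15.0)
            dir_sag = t.direction.copy()
            dir_sag[0] = 0.0
            e_hat = np.array([0.0, 0.0, 1.0])  # entry above the endplate
            thp = np.degrees(np.arccos(dir_sag @ e_hat / np.linalg.norm(dir_sag)))
            assert m.d == pytest.approx(d_oracle, abs=1e-9)
            assert m.theta == pytest.approx(th, abs=1e-9)
            assert m.d_prime == pytest.approx(dp_oracle, abs=1e-9)
            assert m.theta_prime == pytest.approx(thp, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        f = simple_frame()
        for _ in range(10):
            t = random_trajectory(rng)
            m0 = pp.measure_trajectory(t, f)
            R = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(scale=40.0, size=3)
            t2 = pp.Trajectory(entry=R @ t.entry + shift,
                               direction=R @ t.direction,
                               length=t.length, diameter=t.diameter)
            f2 = pp.VertebralFrame(
                midline_plane=pp.Plane(R @ f.midline_plane.point + shift,
                                       R @ f.midline_plane.normal),
                lower_endplate_plane=pp.Plane(
                    R @ f.lower_endplate_plane.point + shift,
                    R @ f.lower_endplate_plane.normal),
                axial_normal=R @ f.axial_normal, side=f.side)
            m1 = pp.measure_trajectory(t2, f2)
            for attr in ("d", "theta", "d_prime", "theta_prime"):
                assert getattr(m1, attr) == pytest.approx(
                    getattr(m0, attr), abs=1e-9)

    def test_degenerate_projection_raises(self):
        f = simple_frame()
        t = pp.Trajectory(entry=[-15, -28, 0], direction=[0, 0, 1],
                          length=30.0, diameter=6.0)
        with pytest.raises(GeometryError, match="degenerate"):
            pp.measure_trajectory(t, f)

    @given(theta=st.floats(10, 170), theta_prime=st.floats(10, 170))
    @settings(max_examples=50, deadline=None)
    def test_derived_angles_identities(self, theta, theta_prime):
        m = pp.TrajectoryMeasurement(d=10.0, theta=theta, d_prime=20.0,
                                     theta_prime=theta_prime)
        assert m.abduction == 90.0 - theta
        assert m.craniocaudal == theta_prime - 90.0


class TestReconstruction:
    def test_round_trip_fixed_point(self, rng):
        f = simple_frame()
        for _ in range(100):
            t = random_trajectory(rng)
            m = pp.measure_trajectory(t, f)
            t2 = pp.reconstruct_trajectory(m, t.entry, f, t.length, t.diameter)
            m2 = pp.measure_trajectory(t2, f)
            for attr in ("d", "theta", "d_prime", "theta_prime"):
                assert getattr(m2, attr) == pytest.approx(
                    getattr(m, attr), abs=1e-6)
            assert np.allclose(t2.direction, t.direction, atol=1e-9)

    def test_zero_angles_give_pure_anterior_direction(self):
        f = simple_frame()
        m = pp.TrajectoryMeasurement(d=15.0, theta=90.0, d_prime=15.0,
                                     theta_prime=90.0)
        t = pp.reconstruct_trajectory(m, np.array([-15.0, -28.0, 0.0]), f,
                                      30.0, 6.0)
        assert np.allclose(t.direction, [0.0, 1.0, 0.0], atol=1e-12)
        assert abs(t.direction @ f.midline_plane.normal) < 1e-12
        assert abs(t.direction @ f.lower_endplate_plane.normal) < 1e-12

    def test_inconsistent_distance_rejected(self):
        f = simple_frame()
        m = pp.TrajectoryMeasurement(d=99.0, theta=90.0, d_prime=15.0,
                                     theta_prime=90.0)
        with pytest.raises(GeometryError, match="inconsistent"):
            pp.reconstruct_trajectory(m, np.array([-15.0, -28.0, 0.0]), f,
                                      30.0, 6.0)


class TestPlacementError:
    def test_identity_is_zero(self):
        m = pp.TrajectoryMeasurement(d=20.0, theta=60.0, d_prime=21.0,
                                     theta_prime=100.0)
        e = pp.placement_error(m, m)
        assert e.displacement_error == 0.0 and e.angle_error == 0.0

    def test_printed_group_means_difference(self):
        planned = pp.TrajectoryMeasurement(d=20.44, theta=58.11,
                                           d_prime=21.11, theta_prime=101.21)
        actual = pp.TrajectoryMeasurement(d=20.54, theta=57.85,
                                          d_prime=21.16, theta_prime=100.96)
        e = pp.placement_error(planned, actual)
        assert e.displacement_error == pytest.approx(0.10, abs=1e-9)
        assert e.angle_error == pytest.approx(-0.26, abs=1e-9)

    def test_antisymmetry(self, rng):
        f = simple_frame()
        a = pp.measure_trajectory(random_trajectory(rng), f)
        b = pp.measure_trajectory(random_trajectory(rng), f)
        e1 = pp.placement_error(a, b)
        e2 = pp.placement_error(b, a)
        assert e1.displacement_error == -e2.displacement_error
        assert e1.angle_error == -e2.angle_error
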