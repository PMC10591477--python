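"""Hinge angle, interhelical angle and distance metrics against constructed
geometries and planted ground truth."""

import numpy as np
import pytest

from tndyn import geometry, synthetic
from tndyn.geometry import (
    GeometryError,
    HelixDefinition,
    HingeDefinition,
    centroid,
    hinge_angle,
    helix_axis,
    interhelical_angle,
    pair_distance,
)
from tndyn.structure_io import AtomRecord, Topology

from conftest import make_point_topology, make_trajectory, random_rigid_transform


def hinge_def(head="HD:1-1:CA", hinge="HG:1-1:CA", arm="AR:1-1:CA"):
    return HingeDefinition.create(head, hinge, arm)


class TestCentroid:
    def test_two_point_mean(self):
        top, X = make_point_topology({"A": [(0, 0, 0), (2, 0, 0)]})
        np.testing.assert_allclose(centroid(X, np.array([0, 1])), [1, 0, 0])

    def test_single_atom_identity(self):
        top, X = make_point_topology({"A": [(3.0, -1.0, 2.5)]})
        np.testing.assert_allclose(centroid(X, np.array([0])), [3.0, -1.0, 2.5])

    def test_brute_force_sum_oracle(self, small_system):
        traj, _ = small_system
        from tndyn.structure_io import resolve_selection

        idx = resolve_selection(traj.topology, "TnC:3-85:CA")
        X = traj.coordinates[0]
        brute = np.zeros(3)
        for i in idx:
            brute += X[i]
        brute /= len(idx)
        np.testing.assert_allclose(centroid(X, idx), brute, atol=1e-9)

    def test_empty_selection_errors(self):
        top, X = make_point_topology({"A": [(0, 0, 0)]})
        with pytest.raises(GeometryError):
            centroid(X, np.array([], dtype=int))


class TestHingeAngle:
    def test_right_angle(self):
        top, X = make_point_topology(
            {"HD": [(0, 1, 0)], "HG": [(0, 0, 0)], "AR": [(1, 0, 0)]}
        )
        assert hinge_angle(X, top, hinge_def()) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_is_180(self):
        top, X = make_point_topology(
            {"HD": [(-2, 0, 0)], "HG": [(0, 0, 0)], "AR": [(3, 0, 0)]}
        )
        assert hinge_angle(X, top, hinge_def()) == pytest.approx(180.0, abs=1e-9)

    def test_coincident_centroids_error(self):
        top, X = make_point_topology(
            {"HD": [(0, 0, 0)], "HG": [(0, 0, 0)], "AR": [(1, 0, 0)]}
        )
        with pytest.raises(GeometryError):
            hinge_angle(X, top, hinge_def())

    def test_planted_angle_exact(self):
        spec = synthetic.SyntheticSpec(
            n_runs=1,
            frames_per_run=3,
            seed=7,
            hinge_distribution=synthetic.GaussianAngles(121.6, 0.0),
        )
        traj, _ = synthetic.generate_trajectory(spec)
        series = geometry.hinge_series(traj)
        np.testing.assert_allclose(series.values, 121.6, atol=1e-6)

    def test_swap_head_arm_invariance(self, small_system):
        traj, _ = small_system
        d = geometry.hinge_from_manifest()
        swapped = HingeDefinition(d.arm_end, d.hinge, d.head)
        a = hinge_angle(traj.coordinates[0], traj.topology, d)
        b = hinge_angle(traj.coordinates[0], traj.topology, swapped)
        assert a == pytest.approx(b, abs=1e-9)


def ideal_helix_topology(n=36, transform=None):
    ca = synthetic._helix_ca(n)
    if transform is not None:
        ca = transform(ca)
    return make_point_topology({"HX": [tuple(p) for p in ca]})


class TestHelixAxis:
    def test_straight_helix_axis_is_z(self):
        # 18-residue endpoint windows span whole turns (18 x 100 deg), so the
        # radial terms cancel exactly and the estimate equals the true axis
        top, X = ideal_helix_topology(36)
        axis = helix_axis(X, top, HelixDefinition("HX", 1, 36, endpoint_window=18))
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-6)

    def test_reversed_residue_order_negates_axis(self):
        top, X = ideal_helix_topology(36)
        hd = HelixDefinition("HX", 1, 36, endpoint_window=18)
        fwd = helix_axis(X, top, hd)
        rev = helix_axis(X[::-1], top, hd)
        np.testing.assert_allclose(rev, -fwd, atol=1e-6)

    def test_full_window_clamped_with_warning(self):
        top, X = ideal_helix_topology(10)
        with pytest.warns(UserWarning, match="clamped"):
            helix_axis(X, top, HelixDefinition("HX", 1, 10, endpoint_window=10))

    def test_degenerate_axis_errors(self):
        top, X = make_point_topology({"HX": [(0, 0, 0)] * 6})
        with pytest.raises(GeometryError):
            helix_axis(X, top, HelixDefinition("HX", 1, 6, endpoint_window=3))


class TestInterhelicalAngle:
    @pytest.mark.parametrize(
        "raw_angle,expected",
        [(0.0, 180.0), (180.0, 0.0), (80.0, 100.0)],
    )
    def test_constructed_crossing(self, raw_angle, expected):
        n = 36
        ca_a = synthetic._helix_ca(n)
        R = synthetic._rotation(np.array([0.0, 1.0, 0.0]), np.radians(raw_angle))
        ca_b = (R @ synthetic._helix_ca(n).T).T + np.array([15.0, 0, 0])
        top, X = make_point_topology(
            {"HA": [tuple(p) for p in ca_a], "HB": [tuple(p) for p in ca_b]}
        )
        ha = HelixDefinition("HA", 1, n, endpoint_window=18)
        hb = HelixDefinition("HB", 1, n, endpoint_window=18)
        got = interhelical_angle(X, top, ha, hb)
        # independent brute-force: dot product of window-averaged axes
        def axis(ca):
            return (ca[-18:].mean(0) - ca[:18].mean(0))

        va, vb = axis(ca_a), axis(ca_b)
        brute = 180.0 - np.degrees(
            np.arccos(np.dot(va, vb) / np.linalg.norm(va) / np.linalg.norm(vb))
        )
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(brute, abs=1e-9)

    def test_symmetric_in_arguments(self, small_system):
        traj, _ = small_system
        ha, hb = geometry.helices_from_manifest()
        X = traj.coordinates[0]
        with pytest.warns(UserWarning):
            ab = interhelical_angle(X, traj.topology, ha, hb)
            ba = interhelical_angle(X, traj.topology, hb, ha)
        assert ab == pytest.approx(ba, abs=1e-9)


class TestPairDistance:
    def test_three_four_five(self):
        top, X = make_point_topology({"A": [(0, 0, 0)], "B": [(3, 4, 0)]})
        assert pair_distance(X, top, "A:1-1:CA", "B:1-1:CA") == pytest.approx(5.0)

    def test_identical_selections_zero(self):
        top, X = make_point_topology({"A": [(1, 2, 3), (4, 5, 6)]})
        assert pair_distance(X, top, "A:1-2:CA", "A:1-2:CA") == 0.0

    def test_planted_domain_separation(self, small_system):
        traj, truth = small_system
        series = geometry.distance_series(traj)
        np.testing.assert_allclose(series.values, truth.domain_separation, atol=1e-6)


class TestMetricSeries:
    def test_static_trajectory_constant(self, small_system):
        traj, _ = small_system
        static = make_trajectory(
            traj.topology, np.repeat(traj.coordinates[:1], 5, axis=0)
        )
        series = geometry.hinge_series(static)
        assert len(series.values) == 5
        assert np.ptp(series.values) == 0.0

    def test_recovers_planted_series_elementwise(self, small_system):
        traj, truth = small_system
        series = geometry.hinge_series(traj)
        np.testing.assert_allclose(series.values, truth.hinge_angles, atol=1e-6)

    @pytest.mark.parametrize("metric", ["hinge", "ab_helix", "distance"])
    def test_rigid_body_invariance(self, small_system, metric):
        """Internal metrics are invariant under a global rotation+translation
        applied to every frame, to 1e-9."""
        traj, _ = small_system
        sub = make_trajectory(traj.topology, traj.coordinates[:10].copy())
        rng = np.random.default_rng(11)
        moved = sub.coordinates.copy()
        for i in range(len(moved)):
            Q, t = random_rigid_transform(rng)
            moved[i] = moved[i] @ Q.T + t
        moved_traj = make_trajectory(traj.topology, moved)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = geometry.metric_series(sub, metric).values
            b = geometry.metric_series(moved_traj, metric).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_gaussian_plant_recovered_statistically(self):
        mu, sigma, n = 110.0, 6.0, 1000
        spec = synthetic.SyntheticSpec(
            n_runs=1,
            frames_per_run=n,
            seed=5,
            hinge_distribution=synthetic.GaussianAngles(mu, sigma),
            planted_contacts=(),
        )
        traj, _ = synthetic.generate_trajectory(spec)
        vals = geometry.hinge_series(traj).values
        assert abs(vals.mean() - mu) < 3 * sigma / np.sqrt(n)
        assert abs(vals.std(ddof=1) - sigma) / sigma < 0.10
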