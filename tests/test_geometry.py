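import math

import numpy as np
import pytest

from turcmap.geometry import (
    Axis,
    DegenerateGeometryError,
    InvalidRotationError,
    Polyline,
    RigidTransform,
    fit_axis_tls,
    kabsch_superpose,
    point_to_polyline,
    quat_angle,
    quat_canonicalize,
    quat_from_matrix,
    quat_mean,
    quat_multiply,
    quat_to_matrix,
    random_rotation,
    relative_orientation,
    rotate_vector,
)

SQ2 = math.sqrt(0.5)
Q_ID = np.array([1.0, 0, 0, 0])
Q_90Z = np.array([SQ2, 0, 0, SQ2])


def axis_angle_quat(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    h = math.radians(deg) / 2
    return quat_canonicalize([math.cos(h), *(math.sin(h) * axis)])


class TestQuaternions:
    @pytest.mark.parametrize(
        "q, expected",
        [
            ((2, 0, 0, 0), Q_ID),
            ((-SQ2, 0, 0, -SQ2), Q_90Z),
            ((0, 1, 0, 0), (0, 1, 0, 0)),
            ((0, -1, 0, 0), (0, 1, 0, 0)),  # w=0 tie broken on first vector component
        ],
    )
    def test_canonicalize(self, q, expected):
        np.testing.assert_allclose(quat_canonicalize(q), expected, atol=1e-12)

    def test_canonicalize_rejects_zero(self):
        with pytest.raises(InvalidRotationError):
            quat_canonicalize((0, 0, 0, 0))

    def test_w_zero_convention_matches_matrix_round_trip(self):
        # a 180-degree rotation has w=0; the canonical form must encode the
        # same rotation as the matrix round trip
        q = quat_canonicalize((0, -1, 0, 0))
        np.testing.assert_allclose(
            quat_to_matrix(q), quat_to_matrix(quat_from_matrix(quat_to_matrix((0, 1, 0, 0)))),
            atol=1e-12,
        )

    @pytest.mark.parametrize(
        "qa, qb, expected",
        [
            (Q_ID, Q_ID, Q_ID),
            (Q_ID, Q_90Z, Q_90Z),
            # derived by composing rotation matrices: Rz(90)^-1 Rz(180) = Rz(90)
            (Q_90Z, axis_angle_quat([0, 0, 1], 180), Q_90Z),
        ],
    )
    def test_relative_orientation(self, qa, qb, expected):
        np.testing.assert_allclose(relative_orientation(qa, qb), expected, atol=1e-9)

    def test_relative_orientation_composes_back(self, rng):
        for _ in range(20):
            qa, qb = random_rotation(rng), random_rotation(rng)
            rel = relative_orientation(qa, qb)
            recomposed = quat_canonicalize(quat_multiply(qa, rel))
            assert quat_angle(recomposed, qb) < 1e-5

    @pytest.mark.parametrize(
        "q, v, expected",
        [
            (Q_ID, (1, 2, 3), (1, 2, 3)),
            (Q_90Z, (1, 0, 0), (0, 1, 0)),
            # 120 degrees about (1,1,1)/sqrt(3) permutes the axes cyclically
            (axis_angle_quat([1, 1, 1], 120), (1, 0, 0), (0, 1, 0)),
        ],
    )
    def test_rotate_vector(self, q, v, expected):
        np.testing.assert_allclose(rotate_vector(q, v), expected, atol=1e-12)

    def test_rotate_vector_is_isometry(self, rng):
        for _ in range(20):
            q = random_rotation(rng)
            u, v = rng.normal(size=3), rng.normal(size=3)
            ru, rv = rotate_vector(q, u), rotate_vector(q, v)
            assert np.linalg.norm(ru) == pytest.approx(np.linalg.norm(u), abs=1e-9)
            assert np.dot(ru, rv) == pytest.approx(np.dot(u, v), abs=1e-9)

    def test_quat_angle(self, rng):
        q = random_rotation(rng)
        assert quat_angle(q, q) == 0.0
        assert quat_angle(q, -q) == 0.0  # double cover
        assert quat_angle(Q_ID, Q_90Z) == pytest.approx(90.0, abs=1e-9)

    def test_quat_angle_antipode_invariant(self, rng):
        q, r = random_rotation(rng), random_rotation(rng)
        qr = quat_multiply(q, r)
        assert quat_angle(q, qr) == pytest.approx(quat_angle(q, -np.asarray(qr)), abs=1e-9)


class TestQuatMean:
    def test_identical_inputs(self):
        q = axis_angle_quat([0, 1, 0], 33)
        np.testing.assert_allclose(quat_mean([q, q, q]), q, atol=1e-12)

    def test_symmetric_pair_averages_to_identity(self):
        qs = [axis_angle_quat([0, 0, 1], 10), axis_angle_quat([0, 0, 1], -10)]
        assert quat_angle(quat_mean(qs), Q_ID) < 1e-9

    def test_recovers_planted_under_small_perturbations(self, rng):
        planted = axis_angle_quat([1, 2, 0.5], 70)
        samples = []
        for _ in range(500):
            axis = rng.normal(size=3)
            noise = axis_angle_quat(axis, rng.uniform(0, 5))
            samples.append(quat_multiply(planted, noise))
        assert quat_angle(quat_mean(samples), planted) < 1.0

    def test_empty_and_degenerate(self):
        with pytest.raises(ValueError):
            quat_mean([])
        with pytest.raises(DegenerateGeometryError):
            quat_mean([Q_ID, np.array([0.0, 0, 0, 1])])  # orthogonal pair ties


class TestKabsch:
    def tetrahedron(self):
        return np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)

    def test_identity(self):
        pts = self.tetrahedron()
        tf, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(tf.apply(pts), pts, atol=1e-9)

    def test_recovers_constructed_transform(self):
        pts = self.tetrahedron()
        truth = RigidTransform(Q_90Z, np.array([5.0, 0, 0]))
        tf, rmsd = kabsch_superpose(pts, truth.apply(pts))
        assert rmsd < 1e-9
        assert quat_angle(tf.rotation, truth.rotation) < 1e-6
        np.testing.assert_allclose(tf.translation, truth.translation, atol=1e-9)

    def test_never_returns_reflection(self):
        chiral = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0], [0.3, 0.2, 1.5]])
        mirrored = chiral * np.array([1, 1, -1])
        tf, rmsd = kabsch_superpose(chiral, mirrored)
        assert np.linalg.det(quat_to_matrix(tf.rotation)) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_rmsd_invariant_under_joint_rigid_motion(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        _, rmsd0 = kabsch_superpose(a, b)
        tf = RigidTransform(random_rotation(rng), rng.normal(size=3))
        _, rmsd1 = kabsch_superpose(tf.apply(a), tf.apply(b))
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_subset_superposition(self):
        pts = np.vstack([self.tetrahedron(), [[3.0, 3, 3]]])
        moved = pts.copy()
        moved[4] += 5.0  # outlier outside the subset
        tf, rmsd = kabsch_superpose(moved, pts, subset=[0, 1, 2, 3])
        assert rmsd < 1e-9

    def test_degenerate_subset(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestPolyline:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Polyline([[0, 0, 0]])
        with pytest.raises(ValueError):
            Polyline([[0, 0, 0], [0, 0, 0]])
        line = Polyline([[0, 0, 0], [0, 0, 100]])
        assert line.total_length == 100.0

    def test_point_to_polyline_345(self):
        line = Polyline([[0, 0, 0], [0, 0, 100]])
        d, foot, arc = point_to_polyline([30, 40, 50], line)
        assert d == pytest.approx(50.0)
        assert arc == pytest.approx(50.0)
        np.testing.assert_allclose(foot, [0, 0, 50])

    def test_endpoint_clamp(self):
        line = Polyline([[0, 0, 0], [0, 0, 100]])
        d, foot, arc = point_to_polyline([0, 0, 150], line)
        assert d == pytest.approx(50.0)
        assert arc == pytest.approx(100.0)

    def test_matches_brute_force_on_random_polylines(self, rng):
        def brute(p, verts):
            best = np.inf
            for a, b in zip(verts[:-1], verts[1:]):
                ab = b - a
                t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                best = min(best, np.linalg.norm(a + t * ab - p))
            return best

        for _ in range(25):
            verts = np.cumsum(rng.normal(size=(6, 3)) + 0.5, axis=0)
            line = Polyline(verts)
            p = rng.normal(scale=5, size=3)
            d, _, _ = point_to_polyline(p, line)
            assert d == pytest.approx(brute(p, verts), abs=1e-9)


class TestAxisFit:
    def test_two_rings(self):
        ang = np.linspace(0, 2 * np.pi, 9)[:8]
        ring = np.column_stack([35 * np.cos(ang), 35 * np.sin(ang), np.zeros(8)])
        pts = np.vstack([ring, ring + [0, 0, 100]])
        axis = fit_axis_tls(pts)
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(axis.point, [0, 0, 50], atol=1e-9)

    def test_collinear_points(self):
        d = np.array([1, 1, 0]) / math.sqrt(2)
        pts = np.outer(np.arange(10, dtype=float), d)
        axis = fit_axis_tls(pts)
        assert abs(abs(np.dot(axis.direction, d)) - 1) < 1e-9
        r, _ = axis.radial_axial(pts)
        assert np.max(r) < 1e-9

    def test_noisy_cylinder_recovery(self, rng):
        n = 1000
        phi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-150, 150, n)
        pts = np.column_stack([35 * np.cos(phi), 35 * np.sin(phi), z])
        pts += rng.normal(scale=5, size=(n, 3))
        axis = fit_axis_tls(pts)
        tilt = math.degrees(math.acos(min(1.0, abs(axis.direction[2]))))
        assert tilt < 1.0

    def test_isotropic_cloud_is_ambiguous(self):
        ang = np.linspace(0, 2 * np.pi, 13)[:12]
        # points on a sphere-symmetric frame: three orthogonal rings
        ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(12)])
        pts = np.vstack([ring, ring[:, [2, 0, 1]], ring[:, [1, 2, 0]]])
        with pytest.raises(DegenerateGeometryError):
            fit_axis_tls(pts)

    def test_equivariance_under_rigid_motion(self, rng):
        phi = rng.uniform(0, 2 * np.pi, 200)
        pts = np.column_stack([20 * np.cos(phi), 20 * np.sin(phi), rng.uniform(0, 200, 200)])
        axis0 = fit_axis_tls(pts)
        tf = RigidTransform(random_rotation(rng), rng.normal(size=3))
        axis1 = fit_axis_tls(tf.apply(pts))
        d0 = rotate_vector(tf.rotation, axis0.direction)
        assert abs(abs(np.dot(axis1.direction, d0)) - 1) < 1e-9
        # transformed centroid must land on the transformed axis
        r, _ = axis1.radial_axial(tf.apply(axis0.point))
        assert r < 1e-9


class TestRigidTransform:
    def test_apply_then_invert_is_identity(self, rng):
        tf = RigidTransform(random_rotation(rng), rng.normal(size=3))
        pts = rng.normal(size=(5, 3))
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-9)

    def test_compose(self, rng):
        a = RigidTransform(random_rotation(rng), rng.normal(size=3))
        b = RigidTransform(random_rotation(rng), rng.normal(size=3))
        p = rng.normal(size=3)
        np.testing.assert_allclose(a.compose(b).apply(p), a.apply(b.apply(p)), atol=1e-9)
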