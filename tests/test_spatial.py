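import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turcmap.geometry import Axis, RigidTransform, random_rotation
from turcmap.spatial import (
    classify_pools,
    nearest_neighbor_distances,
    percentile_median_unbiased,
    radial_axial_profile,
    signed_mtt_distances,
    summarize_distribution,
)


class TestPercentile:
    @pytest.mark.parametrize(
        "values, p, expected",
        [
            # h = 0.5*(5 + 1/3) + 1/3 = 3.0 exactly
            ([10, 20, 30, 40, 50], 0.5, 30.0),
            # h = 0.25*(4 + 1/3) + 1/3 = 1.41667
            ([1, 2, 3, 4], 0.25, 1.41667),
            # h = 5.133 clamps to n
            ([10, 20, 30, 40, 50], 0.9, 50.0),
            ([7, 7, 7], 0.3, 7.0),
        ],
    )
    def test_closed_form_h(self, values, p, expected):
        assert percentile_median_unbiased(values, p) == pytest.approx(expected, abs=1e-5)

    def test_extremes(self, rng):
        v = rng.normal(size=37)
        assert percentile_median_unbiased(v, 0.0) == v.min()
        assert percentile_median_unbiased(v, 1.0) == v.max()

    def test_monotone_in_p(self, rng):
        v = rng.normal(size=23)
        qs = [percentile_median_unbiased(v, p) for p in np.linspace(0, 1, 21)]
        assert np.all(np.diff(qs) >= -1e-12)

    def test_matches_independent_type8_implementation(self, rng):
        # oracle: numpy's median-unbiased estimator (alpha = beta = 1/3)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            v = rng.normal(scale=rng.uniform(0.5, 50), size=n)
            p = float(rng.uniform())
            assert percentile_median_unbiased(v, p) == pytest.approx(
                float(np.quantile(v, p, method="median_unbiased")), rel=1e-12, abs=1e-12
            )

    def test_errors(self):
        with pytest.raises(ValueError):
            percentile_median_unbiased([], 0.5)
        with pytest.raises(ValueError):
            percentile_median_unbiased([1.0], 1.5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=30
        ),
        p=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_estimate_bounded_by_order_statistics(self, values, p):
        q = percentile_median_unbiased(values, p)
        assert min(values) <= q <= max(values)
        assert q == pytest.approx(
            float(np.quantile(values, p, method="median_unbiased")), rel=1e-9, abs=1e-9
        )


class TestSummary:
    def test_integer_ramp(self):
        s = summarize_distribution(np.arange(1, 101, dtype=float))
        assert s.median == pytest.approx(50.5)
        assert s.interval_90[0] == pytest.approx(
            float(np.quantile(np.arange(1, 101), 0.05, method="median_unbiased"))
        )
        assert s.n == 100

    def test_constant_vector(self):
        s = summarize_distribution([4.2] * 9)
        assert s.median == s.interval_90[0] == s.interval_95[1] == 4.2

    def test_gaussian_interval(self, rng):
        v = rng.normal(loc=0, scale=10, size=1000)
        s = summarize_distribution(v)
        assert s.interval_90[0] == pytest.approx(-16.45, abs=16.45 * 0.05 + 0.8)
        assert s.interval_90[1] == pytest.approx(16.45, abs=16.45 * 0.05 + 0.8)


def single_particle(x, y, z):
    return pd.DataFrame(
        {
            "particle_id": ["p1"],
            "tomo_id": ["t1"],
            "x_nm": [float(x)],
            "y_nm": [float(y)],
            "z_nm": [float(z)],
            "qw": [1.0],
            "qx": [0.0],
            "qy": [0.0],
            "qz": [0.0],
            "pool": ["unassigned"],
        }
    )


class TestClassifyPools:
    @pytest.mark.parametrize(
        "pos, expected",
        [
            ((40, 0, 0), "lumenal"),  # r=40 < 115-10, mid-length
            ((200, 0, 0), "pericentriolar"),  # outside the wall
            ((40, 0, 325), "pericentriolar"),  # 100 nm beyond the distal end
        ],
    )
    def test_rule(self, centriole, pos, expected):
        labeled = classify_pools(single_particle(*pos), centriole, margin=10.0)
        assert labeled["pool"].iloc[0] == expected

    def test_partition_and_rigid_invariance(self, particles, centriole, config, rng):
        labeled = classify_pools(particles, centriole)
        assert set(labeled["pool"]) <= {"lumenal", "pericentriolar"}
        # joint rigid motion of particles and model leaves labels unchanged
        from turcmap.synth import SimulationConfig, simulate_centriole

        tf = RigidTransform(random_rotation(rng), rng.normal(scale=100, size=3))
        moved = particles.copy()
        moved[["x_nm", "y_nm", "z_nm"]] = tf.apply(
            particles[["x_nm", "y_nm", "z_nm"]].to_numpy()
        )
        from turcmap.geometry import Polyline

        from dataclasses import replace

        moved_model = replace(
            centriole,
            axis=Axis(tf.apply(centriole.axis.point),
                      tf.apply(centriole.axis.point + centriole.axis.direction)
                      - tf.apply(centriole.axis.point)),
            mtt_b_tubule_lines=[Polyline(tf.apply(l.vertices)) for l in centriole.mtt_b_tubule_lines],
        )
        relabeled = classify_pools(moved, moved_model)
        assert list(relabeled["pool"]) == list(labeled["pool"])


class TestSignedDistances:
    def test_sign_convention(self, centriole):
        lum = single_particle(40, 0, 0)  # 75 nm inside the nearest B-tubule
        lum["pool"] = "lumenal"
        signed, _ = signed_mtt_distances(lum, centriole)
        assert signed[0] == pytest.approx(-75.0, abs=1e-6)
        peri = single_particle(200, 0, 0)
        peri["pool"] = "pericentriolar"
        signed, _ = signed_mtt_distances(peri, centriole)
        assert signed[0] == pytest.approx(85.0, abs=1e-6)

    def test_unassigned_rejected(self, centriole):
        with pytest.raises(ValueError, match="classify_pools"):
            signed_mtt_distances(single_particle(40, 0, 0), centriole)

    def test_planted_recovery(self, labeled, centriole):
        _, summary = signed_mtt_distances(labeled, centriole)
        assert summary.per_pool["lumenal"].median == pytest.approx(75.0, abs=1.5)
        assert summary.per_pool["pericentriolar"].median == pytest.approx(85.0, abs=1.5)


class TestNearestNeighbor:
    def frame(self, pts, pool="lumenal"):
        pts = np.asarray(pts, dtype=float)
        return pd.DataFrame(
            {
                "particle_id": [f"p{i}" for i in range(len(pts))],
                "tomo_id": "t1",
                "x_nm": pts[:, 0],
                "y_nm": pts[:, 1],
                "z_nm": pts[:, 2],
                "qw": 1.0,
                "qx": 0.0,
                "qy": 0.0,
                "qz": 0.0,
                "pool": pool,
            }
        )

    def test_collinear_enumeration(self):
        values, _ = nearest_neighbor_distances(self.frame([[0, 0, 0], [25, 0, 0], [60, 0, 0]]))
        assert sorted(values) == [25, 25, 35]

    def test_square_lattice(self):
        pts = [[25 * i, 25 * j, 0] for i in range(4) for j in range(4)]
        values, _ = nearest_neighbor_distances(self.frame(pts))
        np.testing.assert_allclose(values, 25.0)

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 200, size=(50, 3))
        values, _ = nearest_neighbor_distances(self.frame(pts))
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        np.testing.assert_allclose(np.sort(values), np.sort(dist.min(axis=1)), atol=1e-9)

    def test_singleton_group_excluded_with_warning(self):
        df = pd.concat(
            [self.frame([[0, 0, 0], [10, 0, 0]]), self.frame([[0, 0, 0]], pool="pericentriolar")],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="single particle"):
            values, _ = nearest_neighbor_distances(df)
        assert len(values) == 2


class TestRadialAxialProfile:
    def test_point_on_axis(self):
        axis = Axis([0, 0, 0], [0, 0, 1])
        prof = radial_axial_profile([[0, 0, 33]], axis, bins=4)
        assert prof.r[0] == pytest.approx(0.0)
        assert prof.s[0] == pytest.approx(33.0)

    def test_cartesian_example(self):
        axis = Axis([0, 0, 0], [0, 0, 1])
        prof = radial_axial_profile([[35, 0, 50]], axis, bins=2)
        assert prof.r[0] == pytest.approx(35.0)
        assert prof.s[0] == pytest.approx(50.0)

    def test_mode_bin_contains_planted_radius(self, rng):
        phi = rng.uniform(0, 2 * np.pi, 500)
        pts = np.column_stack([35 * np.cos(phi), 35 * np.sin(phi), rng.uniform(0, 100, 500)])
        pts += rng.normal(scale=2, size=pts.shape)
        prof = radial_axial_profile(pts, Axis([0, 0, 0], [0, 0, 1]), bins=20)
        mode = int(np.argmax(prof.counts))
        mode_center = 0.5 * (prof.bin_edges[mode] + prof.bin_edges[mode + 1])
        assert mode_center == pytest.approx(35.0, abs=2.5)  # within the noise scale
        assert prof.counts.sum() == 500
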