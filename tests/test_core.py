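import numpy as np
import pytest

from scag.core import (
    ClusterRef,
    GrowthError,
    OptimizationError,
    ScagParams,
    SelectionError,
    branch_angle,
    cluster_layer,
    detect_branch_layers,
    detect_nodes,
    locate_node,
    optimize_branch_points,
    run_scag,
    select_branch_pair,
    stratify,
)
from scag.geometry import geometric_median, knn_indices
from scag.io import PointCloud
from scag.synthetic import SamplingSpec, make_skeleton, make_y_skeleton, sample_cloud


def _line_cloud(zs):
    return PointCloud(np.column_stack([np.zeros(len(zs)), np.zeros(len(zs)), zs]), unit="cm")


class TestScagParams:
    def test_defaults_rescale_with_unit(self):
        cm = ScagParams.for_unit("cm")
        mm = ScagParams.for_unit("mm")
        assert mm.H == pytest.approx(10 * cm.H)
        assert mm.D == pytest.approx(10 * cm.D)
        assert mm.N == cm.N

    @pytest.mark.parametrize(
        "bad",
        [dict(H=0), dict(N=1), dict(D=-1), dict(eps=0), dict(min_samples=0),
         dict(merge_radius=-0.1), dict(max_growth_iters=0), dict(overlap_fraction=0.0),
         dict(overlap_fraction=1.5)],
    )
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            ScagParams(**bad)


class TestStratify:
    def test_uniform_partition(self):
        cloud = _line_cloud(np.linspace(0, 3, 30))
        layers = stratify(cloud, 1.0)
        assert len(layers) == 3
        assert [len(l.member_indices) for l in layers] == [10, 10, 10]
        assert layers[0].z_lo == pytest.approx(0.0)
        # layers cover [z_min, z_max]
        assert layers[-1].z_hi == pytest.approx(3.0)

    def test_single_z(self):
        cloud = _line_cloud([2.0, 2.0, 2.0])
        layers = stratify(cloud, 1.0)
        assert len(layers) == 1
        assert len(layers[0].member_indices) == 3

    def test_remainder_layer(self):
        cloud = _line_cloud(np.linspace(0, 2.5, 26))
        layers = stratify(cloud, 1.0)
        assert len(layers) == 3
        assert layers[-1].z_hi - layers[-1].z_lo == pytest.approx(0.5)

    def test_partition_is_disjoint_and_total(self):
        rng = np.random.default_rng(5)
        cloud = PointCloud(rng.uniform(0, 10, size=(200, 3)), unit="cm")
        layers = stratify(cloud, 0.7)
        all_idx = np.concatenate([l.member_indices for l in layers])
        assert sorted(all_idx.tolist()) == list(range(200))


class TestClusterLayer:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(scale=0.1, size=(30, 3))
        b = a + [5.0, 0, 0]  # 10 x eps apart
        clusters = cluster_layer(np.vstack([a, b]), eps=0.5, min_samples=5)
        assert len(clusters) == 2

    def test_all_noise(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]], float)
        assert cluster_layer(pts, eps=0.5, min_samples=5) == []

    def test_symmetric_blob_median_near_origin(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        ring = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        (c,) = cluster_layer(ring, eps=0.5, min_samples=3)
        np.testing.assert_allclose(c.median_point, [0, 0, 0], atol=1e-6)

    def test_empty_layer(self):
        assert cluster_layer(np.empty((0, 3)), 0.5, 5) == []


def _ref(x, y, z, layer=0):
    return ClusterRef(layer, np.arange(1), np.array([x, y, z], float))


class TestBranchLayerDetection:
    def _decide(self, lower, upper):
        (dec,) = detect_branch_layers([lower, upper])
        return dec

    def test_case1_count_increase_is_new_branch(self):
        dec = self._decide([_ref(0, 0, 0)], [_ref(0, 0, 1, 1), _ref(2, 0, 1, 1)])
        assert dec.case == 1 and dec.new_branch

    def test_case2_ratio_fires(self):
        # lower cluster 2 has its nearest upper at distance 3 > 2 x 1
        lower = [_ref(0, 0, 0), _ref(10, 0, 0)]
        upper = [_ref(0, 1, 0, 1), _ref(13, 0, 0, 1)]
        dec = self._decide(lower, upper)
        assert dec.case == 2
        assert dec.D_CNL == pytest.approx((1.0, 3.0))
        assert dec.new_branch

    def test_case2_ratio_does_not_fire(self):
        lower = [_ref(0, 0, 0), _ref(10, 0, 0)]
        upper = [_ref(0, 1, 0, 1), _ref(10, 1.5, 0, 1)]
        dec = self._decide(lower, upper)
        assert dec.case == 2
        assert dec.D_CNL == pytest.approx((1.0, 1.5))
        assert not dec.new_branch

    def test_case3_all_sourced(self):
        # D_CNL = [1.0, 1.1, 5.0] -> Nmin=2 >= CNU=2 -> no new branch
        lower = [_ref(0, 0, 0), _ref(10, 0, 0), _ref(30, 0, 0)]
        upper = [_ref(0, 1, 0, 1), _ref(10, 1.1, 0, 1)]
        dec = self._decide(lower, upper)
        assert dec.case == 3
        assert dec.Nmin == 2
        assert not dec.new_branch

    def test_case3_unsourced_cluster(self):
        # D_CNL = [1.0, 5.0, 6.0] -> Nmin=1 < CNU=2 -> new branch
        lower = [_ref(0, 0, 0), _ref(10, 0, 0), _ref(21, 0, 0)]
        upper = [_ref(0, 1, 0, 1), _ref(15, 0, 0, 1)]
        dec = self._decide(lower, upper)
        assert dec.case == 3
        assert dec.D_CNL == pytest.approx((1.0, 5.0, 6.0))
        assert dec.new_branch

    def test_empty_layers_are_bridged(self):
        layers = [[_ref(0, 0, 0)], [], [_ref(0, 0, 2, 2), _ref(2, 0, 2, 2)]]
        (dec,) = detect_branch_layers(layers)
        assert (dec.lower_layer, dec.upper_layer) == (0, 2)
        assert dec.new_branch

    def test_coincident_medians_do_not_fire_spuriously(self):
        # min distance 0 is floored, so a duplicated center cannot make
        # every other distance look "more than twice the minimum"
        lower = [_ref(0, 0, 0), _ref(10, 0, 0)]
        upper = [_ref(0, 0, 0, 1), _ref(10, 0, 1e-10, 1)]
        dec = self._decide(lower, upper)
        assert not dec.new_branch


class TestSelectBranchPair:
    def test_minimal_pair(self):
        a, b, c = _ref(0, 0, 0), _ref(1, 0, 0), _ref(5, 0, 0)
        # AB=1, AC=5, BC=4
        assert select_branch_pair([a, b, c]) == (a, b)

    def test_two_clusters(self):
        a, b = _ref(0, 0, 0), _ref(9, 0, 0)
        assert select_branch_pair([a, b]) == (a, b)

    def test_tie_breaks_to_lowest_indices(self):
        a, b, c = _ref(0, 0, 0), _ref(1, 0, 0), _ref(-1, 0, 0)
        # AB == AC == 1; pair containing the lowest indices wins
        assert select_branch_pair([a, b, c]) == (a, b)

    def test_single_cluster_raises(self):
        with pytest.raises(SelectionError):
            select_branch_pair([_ref(0, 0, 0)])


class TestBranchAngle:
    def test_orthogonal(self):
        assert branch_angle([0, 0, 0], [1, 0, 0], [0, 1, 0]) == pytest.approx(90.0, abs=1e-9)

    def test_identical(self):
        assert branch_angle([0, 0, 0], [1, 1, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel(self):
        assert branch_angle([0, 0, 0], [1, 2, 3], [-1, -2, -3]) == pytest.approx(180.0, abs=1e-9)

    def test_forty_five(self):
        assert branch_angle([0, 0, 0], [0, 0, 1], [1, 0, 1]) == pytest.approx(45.0, abs=1e-9)

    def test_zero_vector_error(self):
        with pytest.raises(ValueError):
            branch_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestLocateNode:
    def test_y_fixture_node_near_junction(self, y45, default_params):
        cloud, truth, _ = y45
        cands = detect_nodes(cloud, default_params)
        assert len(cands) == 1
        err = np.linalg.norm(cands[0].node.node_point - truth["nodes"][0])
        assert err < 1.5 * default_params.eps

    def test_coincident_seeds_terminate_immediately(self, default_params):
        rng = np.random.default_rng(1)
        blob = rng.normal(scale=0.3, size=(200, 3))
        seed = np.zeros(3)
        res = locate_node(blob, (seed, seed.copy()), default_params)
        assert res.iterations == 1
        assert not res.degraded
        np.testing.assert_allclose(res.node_point, geometric_median(blob), atol=0.2)

    def test_growth_error_when_too_few_points(self, default_params):
        pts = np.zeros((10, 3))
        with pytest.raises(GrowthError):
            locate_node(pts, (np.zeros(3), np.zeros(3)), default_params)

    def test_stem_side_descends_monotonically(self, y45, default_params):
        """Trace the growth recurrence: the stem-side seed median never rises."""
        cloud, truth, _ = y45
        pts = cloud.points
        node_z = truth["nodes"][0][2]
        seed = np.array([0.25, 0.0, node_z + 3.0])  # on the stem, above the node
        other = np.array(truth["nodes"][0]) + [2.5, 0.0, 2.5]
        zs = [seed[2]]
        for _ in range(6):
            cap = max(seed[2], other[2])
            sub = pts[pts[:, 2] <= cap]
            seed = geometric_median(sub[knn_indices(sub, seed, default_params.N)])
            other = geometric_median(sub[knn_indices(sub, other, default_params.N)])
            zs.append(seed[2])
        assert all(b <= a + 1e-9 for a, b in zip(zs, zs[1:]))


class TestOptimizeBranchPoints:
    def test_y_fixture_medians_on_both_axes(self, y45, default_params):
        import dataclasses

        cloud, truth, skel = y45
        node = np.array(truth["nodes"][0])
        params = dataclasses.replace(default_params, D=2.0)
        p1, p2 = optimize_branch_points(cloud.points, node, params)
        spacing = 0.2
        # one median hugs the stem axis (x=y=0)
        stem_p, branch_p = (p1, p2) if np.hypot(p1[0], p1[1]) < np.hypot(p2[0], p2[1]) else (p2, p1)
        assert np.hypot(stem_p[0], stem_p[1]) < 2 * spacing
        # the other lies near the known branch axis at its height
        br = skel.branches[0]
        t = (branch_p[2] - node[2]) / br.direction[2]
        expected = node + br.direction * t
        assert np.linalg.norm(branch_p[:2] - expected[:2]) < 2 * spacing

    def test_empty_slice_is_an_error(self, y45, default_params):
        cloud, _, _ = y45
        top = cloud.points[:, 2].max()
        with pytest.raises(OptimizationError):
            optimize_branch_points(cloud.points, np.array([0, 0, top + 1.0]), default_params)

    def test_tiny_cluster_ignored(self, y45, default_params):
        """A 3-point clump in the slice cannot displace the true pair."""
        cloud, truth, skel = y45
        node = np.array(truth["nodes"][0])
        clump = node + np.array([[-3.0, 3.0, 2.7]]) + 0.05 * np.eye(3)
        pts = np.vstack([cloud.points, clump])
        p1, p2 = optimize_branch_points(pts, node, default_params)
        for p in (p1, p2):
            assert np.linalg.norm(p - clump.mean(axis=0)) > 1.0


class TestRunScag:
    def test_y60_single_record(self, y60):
        cloud, truth, _ = y60
        records = run_scag(cloud)
        assert len(records) == 1
        assert abs(records[0].angle_deg - truth["angles_deg"][0]) <= 3.0

    def test_bare_stem_no_records(self):
        skel = make_skeleton(0, height=40.0, seed=2)
        cloud, _ = sample_cloud(skel, SamplingSpec())
        assert run_scag(cloud) == []

    def test_three_branch_plant(self):
        skel = make_skeleton(3, angle_range=(30.0, 60.0), height=50.0, seed=4)
        cloud, truth = sample_cloud(skel, SamplingSpec())
        records = run_scag(cloud)
        assert len(records) == 3
        for rec in records:
            d = np.linalg.norm(np.asarray(truth["nodes"]) - rec.node_point, axis=1)
            assert d.min() < 1.0

    def test_deterministic(self, y45):
        cloud, _, _ = y45
        r1 = run_scag(cloud)
        r2 = run_scag(cloud)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert a.angle_deg == b.angle_deg
            np.testing.assert_array_equal(a.node_point, b.node_point)

    def test_angles_in_open_range(self):
        skel = make_skeleton(5, angle_range=(20.0, 80.0), height=60.0, seed=9)
        cloud, _ = sample_cloud(skel, SamplingSpec())
        for rec in run_scag(cloud):
            assert 0.0 < rec.angle_deg < 180.0
            np.testing.assert_allclose(rec.vec_a, rec.branch_point_1 - rec.node_point)
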