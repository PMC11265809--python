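import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_dtw
from scag.core import run_scag
from scag.io import AngleRecord, PointCloud
from scag.synthetic import SamplingSpec, make_skeleton, sample_cloud
from scag.traits import (
    INDEX_NAMES,
    TraitRow,
    basic_traits,
    composite_indices,
    dtw_distance,
    dtw_repeatability,
    filter_varieties,
    heritability,
    minmax_normalize,
)


def _rec(angle):
    return AngleRecord([0, 0, 5], [0, 0, 8], [2, 0, 7], angle)


class TestBasicTraits:
    def test_vertical_stem_height_and_length(self):
        skel = make_skeleton(0, height=50.0, seed=0, drift_amplitude=0.0)
        cloud, _ = sample_cloud(skel, SamplingSpec())
        row = basic_traits(cloud, [])
        assert row.height == pytest.approx(50.0, rel=0.01)
        assert row.stem_length == pytest.approx(50.0, rel=0.02)
        assert row.angle_number == 0
        assert math.isnan(row.average_angle)

    def test_canopy_width_is_max_xy_distance(self):
        cloud = PointCloud([[0, 0, 0], [3, 4, 7], [1, 1, 3]], unit="cm")
        row = basic_traits(cloud, [])
        assert row.canopy_width == pytest.approx(5.0)

    def test_average_angle(self):
        cloud = PointCloud([[0, 0, 0], [0, 0, 1]], unit="cm")
        row = basic_traits(cloud, [_rec(30.0), _rec(60.0)])
        assert row.average_angle == pytest.approx(45.0)
        assert row.angle_number == 2

    def test_npd_matches_sampling(self):
        skel = make_skeleton(0, height=20.0, seed=0)
        cloud, _ = sample_cloud(skel, SamplingSpec(spacing=0.2))
        row = basic_traits(cloud, [])
        assert 0.05 < row.npd < 0.3  # of the order of the 2 mm grid

    def test_stem_length_robust_to_branches(self):
        skel = make_skeleton(3, (30, 60), 50.0, seed=8)
        cloud, _ = sample_cloud(skel, SamplingSpec())
        row = basic_traits(cloud, run_scag(cloud))
        assert row.stem_length == pytest.approx(50.0, rel=0.06)


class TestCompositeIndices:
    def _row(self, **kw):
        base = dict(height=60.0, canopy_width=30.0, stem_length=50.0,
                    average_angle=45.0, angle_number=3, npd=0.2)
        base.update(kw)
        return TraitRow(**base)

    def test_reported_ratios(self):
        idx = composite_indices(self._row())
        assert idx["CHR"] == pytest.approx(0.5)
        assert idx["AHR"] == pytest.approx(0.75)
        assert idx["ALR"] == pytest.approx(0.9)
        assert idx["ANR"] == pytest.approx(15.0)
        assert set(idx) == set(INDEX_NAMES)

    def test_products_consistent(self):
        idx = composite_indices(self._row())
        assert idx["ACHR"] == pytest.approx(45.0 * idx["CHR"])
        assert idx["ACLR"] == pytest.approx(45.0 * idx["CLR"])
        assert idx["ANRCHR"] == pytest.approx(idx["ANR"] * idx["CHR"])

    def test_nan_propagates(self):
        idx = composite_indices(self._row(average_angle=float("nan")))
        for name in ("CAR", "AHR", "ALR", "ANR", "ACHR", "ACLR", "ANRCHR"):
            assert math.isnan(idx[name])
        assert idx["CHR"] == pytest.approx(0.5)

    def test_zero_denominator_warns(self):
        with pytest.warns(RuntimeWarning):
            idx = composite_indices(self._row(angle_number=0))
        assert math.isnan(idx["ANR"])


class TestFilterVarieties:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["variety", "replicate", "year", "stem_length"]
        )

    def test_consistent_variety_kept(self):
        t = self._table([("a", 1, 2021, 50.0), ("a", 2, 2021, 50.0)])
        assert set(filter_varieties(t)["variety"]) == {"a"}

    def test_inconsistent_variety_dropped(self):
        t = self._table([
            ("a", 1, 2021, 40.0), ("a", 2, 2021, 60.0),  # RE = 0.4 > 0.3
            ("b", 1, 2021, 50.0), ("b", 2, 2021, 55.0),
        ])
        assert set(filter_varieties(t)["variety"]) == {"b"}

    def test_missing_replicate_dropped(self):
        t = self._table([
            ("a", 1, 2021, 50.0),
            ("b", 1, 2021, 50.0), ("b", 2, 2021, 52.0),
        ])
        assert set(filter_varieties(t)["variety"]) == {"b"}

    def test_boundary_is_strict(self):
        # RE exactly at the threshold stays in
        t = self._table([("a", 1, 2021, 100.0), ("a", 2, 2021, 100 * 7 / 13)])
        re = abs(100 - 100 * 7 / 13) / (0.5 * (100 + 100 * 7 / 13))
        assert re == pytest.approx(0.6)
        assert filter_varieties(t, threshold=0.6)["variety"].tolist() == ["a", "a"]


class TestMinMax:
    def test_basic(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_endpoints(self):
        x = np.random.default_rng(0).normal(size=20)
        y = minmax_normalize(x)
        assert y.min() == 0.0 and y.max() == 1.0

    def test_affine_invariance(self):
        x = np.array([1.0, 3.0, 7.0, 2.0])
        np.testing.assert_allclose(minmax_normalize(x), minmax_normalize(5 * x - 11))

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            minmax_normalize([3, 3, 3])


class TestDTW:
    def test_identical_is_zero(self):
        res = dtw_distance([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.distance == 0.0

    def test_warping_absorbs_repeat(self):
        assert dtw_distance([0, 1], [0, 1, 1]).distance == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(6), rng.random(5)
        assert dtw_distance(a, b).distance == pytest.approx(dtw_distance(b, a).distance)

    def test_path_is_monotone_and_complete(self):
        rng = np.random.default_rng(5)
        res = dtw_distance(rng.random(5), rng.random(7))
        assert res.path[0] == (0, 0)
        assert res.path[-1] == (4, 6)
        for (i0, j0), (i1, j1) in zip(res.path, res.path[1:]):
            assert (i1 - i0, j1 - j0) in {(0, 1), (1, 0), (1, 1)}

    def test_matches_exhaustive_search_short_sequences(self):
        rng = np.random.default_rng(6)
        for n, m in itertools.product(range(1, 7), range(1, 7)):
            a = tuple(rng.random(n).round(3))
            b = tuple(rng.random(m).round(3))
            assert dtw_distance(a, b).distance == pytest.approx(brute_force_dtw(a, b))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestDTWRepeatability:
    def _years(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        varieties = [f"v{i:02d}" for i in range(n)]
        base = {t: rng.random(n) * 10 for t in ("height", "CHR", "AHR")}
        ya = pd.DataFrame({"variety": varieties, **base})
        yb = pd.DataFrame(
            {"variety": varieties, **{t: v + rng.normal(0, 0.5, n) for t, v in base.items()}}
        )
        return ya, yb

    def test_trait_ranking_stable_under_common_permutation(self):
        ya, yb = self._years()
        d0 = dtw_repeatability(ya, yb, ["height", "CHR", "AHR"])
        perm = np.random.default_rng(1).permutation(len(ya))
        new_names = {f"v{i:02d}": f"w{j:02d}" for j, i in enumerate(perm)}
        ya2 = ya.assign(variety=ya["variety"].map(new_names))
        yb2 = yb.assign(variety=yb["variety"].map(new_names))
        d1 = dtw_repeatability(ya2, yb2, ["height", "CHR", "AHR"])
        assert list(d0.sort_values().index) == list(d1.sort_values().index)

    def test_rank_mode(self):
        ya, yb = self._years(seed=2)
        d = dtw_repeatability(ya, yb, ["height"], mode="rank")
        assert d["height"] >= 0.0

    def test_bad_mode(self):
        ya, yb = self._years()
        with pytest.raises(ValueError):
            dtw_repeatability(ya, yb, ["height"], mode="weird")


class TestHeritability:
    def test_perfect_repeatability(self):
        table = np.array([[10.0, 10.0], [20.0, 20.0], [15.0, 15.0]])
        res = heritability(table)
        assert res.H2 == pytest.approx(1.0)
        assert res.sigma2_e == pytest.approx(0.0)

    def test_no_genotypic_variance(self):
        rng = np.random.default_rng(12)
        table = rng.normal(50.0, 2.0, size=(200, 2))  # all varieties identical in truth
        res = heritability(table)
        assert res.H2 < 0.15

    def test_known_variance_ratio(self):
        # sigma_g = sigma_e  =>  entry-mean H2 = s/(s + s/2) = 2/3
        rng = np.random.default_rng(7)
        g = rng.normal(0.0, 1.0, size=500)
        table = g[:, None] + rng.normal(0.0, 1.0, size=(500, 2))
        res = heritability(table)
        assert abs(res.H2 - 2.0 / 3.0) < 0.05

    def test_unbalanced_data(self):
        table = np.array([[10.0, 11.0], [20.0, np.nan], [15.0, 16.0], [30.0, 29.0]])
        res = heritability(table)
        assert 0.0 <= res.H2 <= 1.0
        assert res.n_total == 7

    def test_errors(self):
        with pytest.raises(ValueError):
            heritability(np.array([[1.0, 2.0]]))  # one variety
        with pytest.raises(ValueError):
            heritability(np.array([[1.0], [2.0]]))  # all singletons
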