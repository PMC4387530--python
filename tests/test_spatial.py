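"""Spatial statistics: distances, rank tests, sweeps, summaries."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calsig import spatial as spa
from calsig.signatures import SignatureMetrics
from calsig.synth import WoundGeometry


def record(i, d, **metrics):
    return spa.SpatialRecord(i, d, SignatureMetrics(**metrics))


class TestDistance:
    EDGE = WoundGeometry(np.array([[60.0, 0.0], [60.0, 512.0]]))

    def test_on_edge_is_zero(self):
        assert spa.distance_to_wound((60.0, 100.0), self.EDGE, 0.65) == 0.0

    def test_vertical_edge_arithmetic(self):
        d = spa.distance_to_wound((110.0, 7.0), self.EDGE, 0.65)
        assert d == pytest.approx(50 * 0.65)

    def test_removed_side_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            d = spa.distance_to_wound((10.0, 5.0), self.EDGE, 0.65)
        assert d == 0.0

    def test_polyline_matches_dense_sampling(self):
        rng = np.random.default_rng(0)
        verts = np.cumsum(rng.uniform(5, 20, size=(6, 2)), axis=0)
        wound = WoundGeometry(verts)
        # dense point sampling of the polyline as the oracle
        pts = []
        for a, b in zip(verts[:-1], verts[1:]):
            ts = np.linspace(0, 1, int(np.linalg.norm(b - a) / 0.01) + 2)
            pts.append(a + ts[:, None] * (b - a))
        pts = np.vstack(pts)
        for _ in range(10):
            # stay on the surviving side of the scratch
            q = np.array([rng.uniform(verts[:, 0].min(), verts[:, 0].max()),
                          rng.uniform(verts[:, 1].min(), verts[:, 1].max())])
            oracle = np.sqrt(((pts - q) ** 2).sum(1)).min()
            got = spa.distance_to_wound(tuple(q), wound, 1.0)
            assert got == pytest.approx(oracle, abs=0.011)


class TestSplit:
    def test_basic_partition(self):
        recs = [record(1, 50.0), record(2, 150.0)]
        prox, dist = spa.split_proximal_distal(recs)
        assert [r.roi_id for r in prox] == [1]
        assert [r.roi_id for r in dist] == [2]

    def test_boundary_goes_distal(self):
        recs = [record(1, 100.0), record(2, 99.999)]
        prox, dist = spa.split_proximal_distal(recs)
        assert [r.roi_id for r in dist] == [1]
        assert [r.roi_id for r in prox] == [2]

    def test_empty_side_warns(self):
        with pytest.warns(UserWarning):
            spa.split_proximal_distal([record(1, 5.0)])


def exact_mw_p(x, y):
    """Brute-force two-tailed Mann-Whitney p by full enumeration."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = spa.mann_whitney_u(x, y)[0]
    us = []
    for comb in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(comb)]
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        rx = ranks[list(comb)].sum()
        us.append(rx - nx * (nx + 1) / 2)
    us = np.array(us)
    ge = np.mean(us >= u_obs)
    le = np.mean(us <= u_obs)
    return min(1.0, 2 * min(ge, le))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 1.0, 1.0])
        u, p = spa.mann_whitney_u(x, x)
        assert p == 1.0

    def test_small_exact_case(self):
        u, p = spa.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(1.0, size=10)
        assert spa.mann_whitney_u(x, y)[1] == pytest.approx(
            spa.mann_whitney_u(y, x)[1])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for nx in (2, 3, 4):
            for ny in (2, 3, 4):
                vals = rng.permutation(np.arange(1.0, nx + ny + 1.0))
                x, y = vals[:nx], vals[nx:]
                _, p = spa.mann_whitney_u(x, y)
                assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=15),
           st.lists(st.integers(0, 50), min_size=4, max_size=15))
    def test_monotone_transform_invariance(self, xs, ys):
        x, y = np.array(xs, float), np.array(ys, float)
        p1 = spa.mann_whitney_u(x, y)[1]
        p2 = spa.mann_whitney_u(np.exp(x / 10), np.exp(y / 10))[1]
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestKruskalDunn:
    def test_hand_computed_h(self):
        h, p, dunn = spa.kruskal_wallis_dunn(
            [np.array([1.0, 2.0]), np.array([3.0, 4.0]),
             np.array([5.0, 6.0])])
        assert h == pytest.approx(4.5714, abs=1e-3)
        assert len(dunn) == 3

    def test_identical_groups(self):
        g = np.array([2.0, 2.0, 2.0])
        h, p, dunn = spa.kruskal_wallis_dunn([g, g.copy(), g.copy()])
        assert h == 0.0 and p == 1.0
        assert np.all(dunn["p_adjusted"] == 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 12) for m in (0, 0.5, 2)]
        h1, p1, _ = spa.kruskal_wallis_dunn(groups)
        h2, p2, _ = spa.kruskal_wallis_dunn([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.2, 40)
        b = rng.normal(2, 0.2, 40)
        c = rng.normal(2.05, 0.2, 40)
        h, p, dunn = spa.kruskal_wallis_dunn([a, b, c], ["a", "b", "c"])
        assert p < 1e-6
        pv = dunn.set_index(["group_a", "group_b"])["p_adjusted"]
        assert pv[("a", "b")] < 0.001
        assert pv[("b", "c")] > 0.05


class TestSweep:
    def _records(self, n=120, change_at=None, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            d = rng.uniform(5, 300)
            plateau = 0.1
            if change_at is not None and d < change_at:
                plateau = 0.6
            recs.append(record(i, d,
                               plateau_height=plateau + rng.normal(0, 0.05),
                               peak_height=1.0))
        return recs

    def test_constant_feature_flat_p(self):
        recs = [record(i, d, peak_height=1.0)
                for i, d in enumerate(np.linspace(5, 395, 80))]
        out = spa.threshold_sweep(recs, ["peak_height"])
        p = out["peak_height"].p_values
        assert np.nanmin(p) > 0.5

    def test_changepoint_located(self):
        out = spa.threshold_sweep(self._records(change_at=100.0),
                                  ["plateau_height"])
        res = out["plateau_height"]
        best = res.thresholds_um[np.nanargmin(res.p_values)]
        assert 40 <= best <= 110

    def test_all_cells_beyond_range(self):
        recs = [record(i, 500.0 + i, peak_height=1.0) for i in range(10)]
        out = spa.threshold_sweep(recs, ["peak_height"])
        assert np.all(np.isnan(out["peak_height"].p_values))

    def test_null_sweep_rarely_significant(self):
        """Identically distributed sides: min p < 0.001 is rare."""
        hits = 0
        for rep in range(15):
            out = spa.threshold_sweep(self._records(seed=100 + rep),
                                      ["plateau_height"])
            if np.nanmin(out["plateau_height"].p_values) < 1e-3:
                hits += 1
        assert hits <= 2


class TestSummarize:
    def test_basic_moments(self):
        out = spa.summarize({"g": np.array([1.0, 2.0, 3.0])})
        assert out.loc["g", "mean"] == 2.0
        assert out.loc["g", "sd"] == pytest.approx(1.0)
        assert out.loc["g", "sem"] == pytest.approx(0.5774, abs=1e-4)

    def test_single_value_dispersion_na(self):
        out = spa.summarize({"g": np.array([4.2])})
        assert out.loc["g", "mean"] == 4.2
        assert np.isnan(out.loc["g", "sd"]) and np.isnan(out.loc["g", "sem"])
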