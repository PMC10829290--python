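"""Kernel UD estimation and isopleth geometry tests.

The KDE oracle is a deliberate brute-force double loop (grid cell x
point, full Gaussian formula) kept independent of the separable
implementation in the package.
"""

import numpy as np
import pytest
from scipy.stats import chi2

from preyscape.habitat import compare_periods, reference_bandwidth, ud_2d, ud_3d

RATIO = np.log(20) / np.log(2)  # bivariate-Gaussian 95%/50% HPD area ratio


def brute_kde_2d(points, h, x, y):
    out = np.zeros((x.size, y.size))
    for i, xi in enumerate(x):
        for j, yj in enumerate(y):
            s = 0.0
            for px, py in points:
                s += np.exp(-0.5 * (((xi - px) / h[0]) ** 2 + ((yj - py) / h[1]) ** 2))
            out[i, j] = s / (len(points) * 2 * np.pi * h[0] * h[1])
    return out


def brute_kde_3d(points, h, x, y, z):
    out = np.zeros((x.size, y.size, z.size))
    norm = len(points) * (2 * np.pi) ** 1.5 * h[0] * h[1] * h[2]
    for i, xi in enumerate(x):
        for j, yj in enumerate(y):
            for k, zk in enumerate(z):
                s = 0.0
                for px, py, pz in points:
                    q = ((xi - px) / h[0]) ** 2 + ((yj - py) / h[1]) ** 2 + ((zk - pz) / h[2]) ** 2
                    s += np.exp(-0.5 * q)
                out[i, j, k] = s / norm
    return out


class TestUD2D:
    def test_single_point_isopleth_area_ratio(self):
        s = ud_2d(np.array([[0.0, 0.0]]), cell_m=4.0, bandwidth=100.0)
        ratio = s.isopleths[0.95].measure / s.isopleths[0.5].measure
        assert ratio == pytest.approx(RATIO, rel=0.02)

    def test_single_point_absolute_areas(self):
        h = 100.0
        s = ud_2d(np.array([[0.0, 0.0]]), cell_m=4.0, bandwidth=h)
        for p in (0.5, 0.95):
            expect = np.pi * (-2 * h**2 * np.log(1 - p)) / 1e6
            assert s.isopleths[p].measure == pytest.approx(expect, rel=0.02)

    def test_normalisation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 500, size=(40, 2))
        s = ud_2d(pts, cell_m=50.0)
        assert s.density.sum() * s.cell_area_m2 == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 300, size=(30, 2))
        h = np.array([150.0, 200.0])
        s = ud_2d(pts, cell_m=100.0, bandwidth=h)
        brute = brute_kde_2d(pts, h, s.x, s.y)
        rel = np.abs(s.density - brute) / brute.max()
        assert rel.max() < 1e-8

    def test_two_separated_clusters_split_core(self):
        rng = np.random.default_rng(9)
        a = rng.normal([0, 0], 100, size=(40, 2))
        b = rng.normal([10000, 0], 100, size=(40, 2))
        s = ud_2d(np.vstack([a, b]), cell_m=50.0, bandwidth=150.0)
        polys = s.isopleths[0.5].polygons
        assert len(polys) == 2
        areas = sorted(p.area for p in polys)
        assert areas[1] / areas[0] == pytest.approx(1.0, abs=0.15)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 400, size=(25, 2))
        s0 = ud_2d(pts, cell_m=100.0, bandwidth=200.0)
        s1 = ud_2d(pts + [5000.0, -3000.0], cell_m=100.0, bandwidth=200.0)
        assert np.allclose(s0.density, s1.density, atol=1e-15)
        for p in (0.5, 0.95):
            assert s0.isopleths[p].measure == pytest.approx(
                s1.isopleths[p].measure, rel=1e-9
            )

    def test_nesting(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 400, size=(30, 2))
        s = ud_2d(pts, cell_m=100.0, levels=(0.2, 0.5, 0.8, 0.95))
        meas = [s.isopleths[p].measure for p in (0.2, 0.5, 0.8, 0.95)]
        assert np.all(np.diff(meas) > 0)
        thr = [s.isopleths[p].threshold for p in (0.2, 0.5, 0.8, 0.95)]
        assert np.all(np.diff(thr) < 0)  # lower level -> higher density cut

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ud_2d(np.empty((0, 2)))


class TestUD3D:
    def test_single_point_volumes_match_chi2_hpd(self):
        h = (100.0, 120.0, 10.0)
        v = ud_3d(np.array([[0.0, 0.0, 50.0]]), bandwidth=h)
        for p in (0.5, 0.95):
            r = np.sqrt(chi2.ppf(p, 3))
            expect = 4 / 3 * np.pi * h[0] * h[1] * h[2] * r**3 / 1e9
            assert v.isopleths[p].measure == pytest.approx(expect, rel=0.02)

    def test_levels_monotone(self):
        rng = np.random.default_rng(3)
        pts = rng.normal([0, 0, 30], [300, 300, 10], size=(40, 3))
        v = ud_3d(pts, bandwidth=(150.0, 150.0, 8.0))
        assert v.isopleths[0.5].measure < v.isopleths[0.95].measure

    def test_voxel_refinement_converged(self):
        rng = np.random.default_rng(12)
        pts = rng.normal([0, 0, 30], [200, 200, 8], size=(25, 3))
        h = np.array([150.0, 150.0, 8.0])
        v1 = ud_3d(pts, bandwidth=h, voxel_m=h / 8)
        v2 = ud_3d(pts, bandwidth=h, voxel_m=h / 16)
        for p in (0.5, 0.95):
            assert v1.isopleths[p].measure == pytest.approx(
                v2.isopleths[p].measure, rel=0.05
            )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal([0, 0, 30], [200, 200, 8], size=(20, 3))
        h = np.array([150.0, 180.0, 10.0])
        v = ud_3d(pts, bandwidth=h, voxel_m=h / 3)
        brute = brute_kde_3d(pts, h, v.x, v.y, v.z)
        rel = np.abs(v.density - brute) / brute.max()
        assert rel.max() < 1e-8

    def test_binned_method_approximates_exact(self):
        rng = np.random.default_rng(7)
        pts = rng.normal([0, 0, 30], [200, 200, 8], size=(500, 3))
        h = np.array([150.0, 150.0, 8.0])
        ve = ud_3d(pts, bandwidth=h, method="exact")
        vb = ud_3d(pts, bandwidth=h, method="binned")
        for p in (0.5, 0.95):
            assert vb.isopleths[p].measure == pytest.approx(
                ve.isopleths[p].measure, rel=0.05
            )

    def test_seabed_mask_renormalises(self):
        pts = np.array([[0.0, 0.0, 48.0], [50.0, 0.0, 45.0]])
        h = (100.0, 100.0, 5.0)
        v = ud_3d(pts, bandwidth=h, seabed=lambda x, y: np.full(np.broadcast(x, y).shape, 50.0))
        # no mass below the 50-m seabed, and still a probability density
        below = v.z > 50.0
        assert v.density[:, :, below].sum() == 0.0
        assert v.density.sum() * v.voxel_m3 == pytest.approx(1.0, abs=1e-9)

    def test_coarse_voxel_warns(self):
        with pytest.warns(UserWarning, match="resolution-limited"):
            ud_3d(np.array([[0.0, 0.0, 30.0]]), bandwidth=(100.0, 100.0, 10.0),
                  voxel_m=(80.0, 80.0, 8.0))


class TestPeriodComparison:
    def test_identical_groups_p_one(self):
        out = compare_periods([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert out["p"] == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact(self):
        """{1,2,3} vs {4,5,6}: W at its extreme; exact two-sided p = 2/20."""
        out = compare_periods([1, 2, 3], [4, 5, 6])
        assert out["W"] == 0.0
        assert out["p"] == pytest.approx(0.1)
        assert out["method"] == "exact"

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        assert compare_periods(a, b)["p"] < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_periods([1.0], [2.0, 3.0])


def test_reference_bandwidth_scaling():
    rng = np.random.default_rng(8)
    pts = rng.normal(0, 100, size=(64, 2))
    h = reference_bandwidth(pts)
    assert np.allclose(h, pts.std(axis=0, ddof=1) * 64 ** (-1 / 6))
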