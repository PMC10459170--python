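"""Scale recovery: calibrator ratios and the shared-normal plane-pair fit."""

import numpy as np
import pytest
from scipy.optimize import minimize

from endoscale import (
    BoxSpec,
    PointCloud,
    Region,
    RigidTransform,
    estimate_scale_from_box,
    fit_parallel_planes,
    plane_pair_distance,
    rescale_cloud,
    scale_from_length_pairs,
    select_plane_points,
)
from endoscale.geometry import InvalidInputError, UnitError
from endoscale.scale import DegenerateFitError, SelectionError
from endoscale.synth import SceneConfig, make_box_interior, make_grid_calibrator


def plane_pair_objective(params, top, bottom):
    """Literal residual sum of the parallel-plane objective: the summed squared
    point-to-plane distances of both walls under one shared normal."""
    L, J, K, d1, d2 = params
    nn = L * L + J * J + K * K
    r1 = top @ np.array([L, J, K]) + d1
    r2 = bottom @ np.array([L, J, K]) + d2
    return float(np.sum(r1**2) / nn + np.sum(r2**2) / nn)


def minimize_plane_pair(top, bottom):
    """Independent general-purpose numeric minimization of the objective."""
    best = None
    for trial_normal in (np.array([0.0, 0, 1]), np.array([1.0, 0, 0]), np.array([0.577, 0.577, 0.577])):
        d1 = -trial_normal @ top.mean(axis=0)
        d2 = -trial_normal @ bottom.mean(axis=0)
        x0 = np.concatenate([trial_normal, [d1, d2]])
        res = minimize(
            plane_pair_objective, x0, args=(top, bottom), method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.fun


class TestScaleFromLengthPairs:
    def test_single_pair(self):
        est = scale_from_length_pairs([(2.0, 1.0)])
        assert est.s == pytest.approx(2.0)

    @pytest.mark.parametrize("k", [0.1, 1.0, 3.7])
    def test_grid_ratios_exact(self, k):
        """Two grid lengths at 24 and 48 mm scaled by k recover s = k exactly."""
        est = scale_from_length_pairs([(24 * k, 24.0), (48 * k, 48.0)])
        assert est.s == pytest.approx(k, rel=1e-12)
        assert est.residual == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_grid_recovery(self):
        cfg = SceneConfig(seed=7, s_true=0.37, noise_sigma=0.05, rotation_deg=30.0)
        _result, pairs = make_grid_calibrator(cfg)
        est = scale_from_length_pairs(pairs)
        assert abs(est.s / 0.37 - 1.0) < 0.02

    def test_permutation_invariance_and_equivariance(self, rng):
        pairs = rng.uniform(1.0, 50.0, size=(8, 2))
        s1 = scale_from_length_pairs(pairs).s
        s2 = scale_from_length_pairs(pairs[::-1]).s
        assert s2 == pytest.approx(s1, rel=1e-12)
        scaled = pairs.copy()
        scaled[:, 0] *= 3.0
        assert scale_from_length_pairs(scaled).s == pytest.approx(3.0 * s1, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InvalidInputError):
            scale_from_length_pairs([(1.0, 0.0)])


class TestFitParallelPlanes:
    def test_exact_parallel_planes(self):
        top = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        bottom = top + [0, 0, 10.0]
        fit = fit_parallel_planes(top, bottom)
        np.testing.assert_allclose(fit.normal, [0, 0, 1], atol=1e-12)
        assert fit.d1 == pytest.approx(0.0, abs=1e-12)
        assert fit.d2 == pytest.approx(-10.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_coincident_planes_zero_separation(self, rng):
        pts = np.column_stack([rng.uniform(-5, 5, size=(20, 2)), np.zeros(20)])
        fit = fit_parallel_planes(pts[:10], pts[10:])
        assert plane_pair_distance(fit) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_closed_form_matches_numeric_minimizer(self, seed):
        """Closed-form eigen solution attains the same objective value as an
        independent general-purpose optimizer, over seeded noisy instances."""
        rng = np.random.default_rng(seed)
        from endoscale.synth import random_rotation

        R = random_rotation(rng, 180.0).rotation
        base = rng.uniform(-20, 20, size=(400, 2))
        top = np.column_stack([base[:200], np.full(200, 7.0)]) @ R.T
        bottom = np.column_stack([base[200:], np.full(200, -7.0)]) @ R.T
        top = top + rng.normal(scale=0.1, size=top.shape)
        bottom = bottom + rng.normal(scale=0.1, size=bottom.shape)
        fit = fit_parallel_planes(top, bottom)
        assert fit.rss == pytest.approx(
            plane_pair_objective([*fit.normal, fit.d1, fit.d2], top, bottom), rel=1e-9
        )
        oracle = minimize_plane_pair(top, bottom)
        assert fit.rss <= oracle * (1 + 1e-6)
        assert abs(fit.rss - oracle) <= 1e-6 * max(oracle, 1e-12)

    def test_local_optimality(self, rng):
        """Perturbing the solution never lowers the objective."""
        top = rng.normal(size=(50, 3)) * [10, 10, 0.1] + [0, 0, 5]
        bottom = rng.normal(size=(50, 3)) * [10, 10, 0.1] - [0, 0, 5]
        fit = fit_parallel_planes(top, bottom)
        for _ in range(20):
            delta = rng.normal(scale=1e-4, size=5)
            perturbed = plane_pair_objective(
                np.concatenate([fit.normal, [fit.d1, fit.d2]]) + delta, top, bottom
            )
            assert perturbed >= fit.rss - 1e-9

    def test_rigid_invariance_and_scale_equivariance(self, rng):
        from endoscale.synth import random_rotation

        top = rng.normal(size=(60, 3)) * [8, 8, 0.2] + [0, 0, 4]
        bottom = rng.normal(size=(60, 3)) * [8, 8, 0.2] - [0, 0, 4]
        fit0 = fit_parallel_planes(top, bottom)
        T = random_rotation(rng, 170.0)
        T = RigidTransform(T.rotation, rng.normal(scale=30, size=3))
        fit1 = fit_parallel_planes(T.apply(top), T.apply(bottom))
        assert fit1.rss == pytest.approx(fit0.rss, rel=1e-9)
        n_mapped = T.rotation @ fit0.normal
        assert abs(abs(n_mapped @ fit1.normal) - 1.0) < 1e-9
        c = 2.5
        fit2 = fit_parallel_planes(top * c, bottom * c)
        assert fit2.rss == pytest.approx(fit0.rss * c**2, rel=1e-9)
        assert plane_pair_distance(fit2) == pytest.approx(
            c * plane_pair_distance(fit0), rel=1e-9
        )

    def test_insufficient_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_parallel_planes([[0, 0, 0], [1, 0, 0]], [[0, 0, 1], [1, 0, 1], [0, 1, 1]])

    def test_degenerate_geometry_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(DegenerateFitError):
            fit_parallel_planes(line, line + [0, 0, 1e-15])


class TestPlanePairDistance:
    def test_offset_difference(self):
        from endoscale.scale import PlanePairFit

        fit = PlanePairFit(normal=[0, 0, 1], d1=0.0, d2=-10.0, rss=0.0, n_top=4, n_bottom=4)
        assert plane_pair_distance(fit) == 10.0
        fit.d2 = fit.d1
        assert plane_pair_distance(fit) == 0.0

    def test_synthetic_box_separation_scales(self):
        cfg = SceneConfig(seed=3, s_true=0.5, noise_sigma=0.05, box_separation_mm=60.0)
        result, labels = make_box_interior(cfg)
        pts = result.cloud.points
        fit = fit_parallel_planes(pts[labels == 0], pts[labels == 1])
        assert plane_pair_distance(fit) == pytest.approx(30.0, abs=0.05)


class TestSelectPlanePoints:
    @pytest.fixture
    def box_scene(self):
        cfg = SceneConfig(seed=11, s_true=1.0, noise_sigma=0.05)
        return cfg, *make_box_interior(cfg)

    def test_selection_purity_on_labeled_walls(self, box_scene):
        cfg, result, labels = box_scene
        half = cfg.box_separation_mm / 2
        ext = cfg.box_extent_mm
        top = Region([-ext, -ext, half - 5], [ext, ext, half + 5])
        bottom = Region([-ext, -ext, -half - 5], [ext, ext, -half + 5])
        sel_top, sel_bot = select_plane_points(
            result.cloud, top, bottom, 25.0, reference_normal=[0, 0, 1]
        )
        pts = result.cloud.points
        top_wall = set(map(tuple, pts[labels == 0]))
        bot_wall = set(map(tuple, pts[labels == 1]))
        purity_top = np.mean([tuple(p) in top_wall for p in sel_top])
        purity_bot = np.mean([tuple(p) in bot_wall for p in sel_bot])
        assert purity_top >= 0.95 and purity_bot >= 0.95

    def test_empty_region_errors_with_counts(self, box_scene):
        _cfg, result, _labels = box_scene
        far = Region([1000, 1000, 1000], [1001, 1001, 1001])
        with pytest.raises(SelectionError, match="0 in top region"):
            select_plane_points(result.cloud, far, far)

    def test_no_normals_falls_back_to_region_filter(self, box_scene):
        cfg, result, _labels = box_scene
        bare = PointCloud(result.cloud.points, unit=result.cloud.unit)
        half, ext = cfg.box_separation_mm / 2, cfg.box_extent_mm
        top = Region([-ext, -ext, half - 5], [ext, ext, half + 5])
        bottom = Region([-ext, -ext, -half - 5], [ext, ext, -half + 5])
        sel_top, _ = select_plane_points(bare, top, bottom, 25.0, reference_normal=[0, 0, 1])
        assert len(sel_top) >= 3


def box_regions(cfg: SceneConfig):
    """Generous axis-aligned bounds around each wall of a degraded box."""
    half = cfg.s_true * cfg.box_separation_mm / 2
    ext = cfg.s_true * cfg.box_extent_mm
    margin = 4.0 * cfg.noise_sigma + 0.25 * cfg.s_true * cfg.box_separation_mm
    top = Region([-ext, -ext, half - margin], [ext, ext, half + margin])
    bottom = Region([-ext, -ext, -half - margin], [ext, ext, -half + margin])
    return top, bottom


class TestEstimateScaleFromBox:
    @pytest.mark.parametrize("s_true", [0.3, 1.0, 4.2])
    def test_noiseless_recovery_exact(self, s_true):
        cfg = SceneConfig(seed=5, s_true=s_true, noise_sigma=0.0)
        result, _ = make_box_interior(cfg)
        top, bottom = box_regions(cfg)
        est, fit = estimate_scale_from_box(
            result.cloud, top, bottom, BoxSpec(cfg.box_separation_mm)
        )
        assert abs(est.s / s_true - 1.0) < 1e-9

    def test_noisy_with_outliers_recovery(self):
        cfg = SceneConfig(
            seed=21, s_true=0.42, noise_sigma=0.1, outlier_fraction=0.05
        )
        result, _ = make_box_interior(cfg)
        top, bottom = box_regions(cfg)
        est, _ = estimate_scale_from_box(
            result.cloud, top, bottom, BoxSpec(cfg.box_separation_mm)
        )
        assert abs(est.s / 0.42 - 1.0) < 0.03

    def test_max_iter_one_is_single_pass(self):
        cfg = SceneConfig(seed=5, s_true=1.0, noise_sigma=0.05)
        result, _ = make_box_interior(cfg)
        top, bottom = box_regions(cfg)
        est1, fit1 = estimate_scale_from_box(
            result.cloud, top, bottom, BoxSpec(cfg.box_separation_mm), max_iter=1
        )
        sel = select_plane_points(result.cloud, top, bottom)
        fit_direct = fit_parallel_planes(*sel)
        assert fit1.rss == pytest.approx(fit_direct.rss, rel=1e-12)
        assert est1.s == pytest.approx(
            plane_pair_distance(fit_direct) / cfg.box_separation_mm, rel=1e-12
        )

    def test_noise_ladder_error_decreases(self):
        """Median |ŝ/s* − 1| over seeds shrinks monotonically as σ → 0."""
        sigmas = [0.2, 0.05, 0.0125, 0.0]
        medians = []
        for sigma in sigmas:
            errors = []
            for seed in range(8):
                s_true = float(np.random.default_rng(seed).uniform(0.1, 10.0))
                cfg = SceneConfig(seed=100 + seed, s_true=s_true, noise_sigma=sigma)
                result, _ = make_box_interior(cfg)
                top, bottom = box_regions(cfg)
                est, _ = estimate_scale_from_box(
                    result.cloud, top, bottom, BoxSpec(cfg.box_separation_mm)
                )
                errors.append(abs(est.s / s_true - 1.0))
            medians.append(float(np.median(errors)))
        assert all(a >= b for a, b in zip(medians, medians[1:]))
        assert medians[-1] < 1e-6


class TestRescaleCloud:
    def test_divides_by_s(self):
        from endoscale.scale import ScaleEstimate

        cloud = PointCloud([[2.0, 4, 6]], unit="arbitrary")
        out = rescale_cloud(cloud, ScaleEstimate(s=2.0, method="calibrator"))
        np.testing.assert_allclose(out.points, [[1, 2, 3]])
        assert out.unit == "mm"

    def test_s_equal_one_is_identity(self):
        from endoscale.scale import ScaleEstimate

        cloud = PointCloud([[1.0, 2, 3]], unit="arbitrary")
        out = rescale_cloud(cloud, ScaleEstimate(s=1.0, method="calibrator"))
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_double_scaling_guard(self):
        from endoscale.scale import ScaleEstimate

        cloud = PointCloud([[1.0, 2, 3]], unit="mm")
        with pytest.raises(UnitError):
            rescale_cloud(cloud, ScaleEstimate(s=2.0, method="calibrator"))
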