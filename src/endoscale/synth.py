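"""Seeded synthetic scenes with known ground truth.

Three scene families emulate the phantom experiments that a monocular
endoscopic SLAM evaluation needs, with every generating parameter known:

* **box interior** — four inner walls of a pre-calibration box whose top and
  bottom walls are parallel planes a known distance apart;
* **grid calibrator** — the corner lattice of a planar checkerboard target
  of known square size;
* **organ surface** — an ellipsoid patch with sinusoidal wrinkles emulating
  a soft-tissue surface, carrying two labelled lesion endpoints a known
  chord distance apart.

Each clean scene is then degraded the way a monocular reconstruction
presents: an unknown global scale s*, an unknown rigid pose, isotropic
Gaussian noise (expressed in reconstructed units, i.e. applied after
scaling), uniformly scattered outlier points, and Bernoulli dropout.  That
order is fixed and part of the generator's contract.

All randomness flows from the seed in :class:`SceneConfig`; the same
config yields bit-identical clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ARBITRARY, InvalidInputError, PointCloud, RigidTransform

__all__ = [
    "SceneConfig",
    "DegradeResult",
    "make_box_interior",
    "make_grid_calibrator",
    "make_organ_surface",
    "degrade",
    "random_rotation",
]


@dataclass
class SceneConfig:
    """All knobs of a synthetic scene; the seed fixes every random draw.

    Geometry parameters are in mm (the clean scene is metric); degradation
    noise/outlier scales are in reconstructed units, i.e. they act after
    multiplication by the true scale ``s_true``.
    """

    seed: int = 0
    # degradation
    s_true: float = 1.0
    rotation_deg: float = 0.0  # magnitude of the random rigid rotation
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    outlier_fraction: float = 0.0
    dropout_fraction: float = 0.0
    # box geometry
    box_separation_mm: float = 60.0
    box_extent_mm: float = 80.0
    # grid geometry
    grid_rows: int = 9
    grid_cols: int = 7
    grid_spacing_mm: float = 24.0
    # organ geometry
    organ_radii_mm: tuple[float, float, float] = (45.0, 35.0, 30.0)
    wrinkle_amplitude_mm: float = 1.5
    wrinkle_frequency: float = 6.0
    lesion_length_mm: float = 20.80
    # sampling density
    points_per_unit_area: float = 0.25  # points per mm²

    def __post_init__(self):
        if not (self.s_true > 0):
            raise InvalidInputError("true scale must be positive")
        for name in ("outlier_fraction", "dropout_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise InvalidInputError(f"{name} must be in [0, 1)")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be non-negative")
        if self.points_per_unit_area <= 0:
            raise InvalidInputError("sampling density must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class DegradeResult:
    """Degraded cloud plus bookkeeping linking its points to the clean scene.

    ``source_index[i]`` is the index of point ``i`` in the clean cloud, or
    −1 for an injected outlier; the rigid pose and scale used are kept so
    ground-truth quantities can be mapped into reconstructed space.
    """

    cloud: PointCloud
    source_index: np.ndarray
    pose: RigidTransform
    s_true: float


def random_rotation(rng: np.random.Generator, max_angle_deg: float) -> RigidTransform:
    """Uniformly random rotation axis, angle uniform in [0, max_angle_deg]."""
    if max_angle_deg == 0.0:
        return RigidTransform.identity()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, np.zeros(3))


def degrade(cloud: PointCloud, config: SceneConfig, rng=None) -> DegradeResult:
    """Apply scale → rigid pose → noise → outliers → dropout, in that order."""
    rng = config.rng() if rng is None else rng
    pts = cloud.points * config.s_true
    pose = random_rotation(rng, config.rotation_deg)
    pose = RigidTransform(pose.rotation, np.asarray(config.translation, dtype=float))
    pts = pose.apply(pts)
    nrm = None if cloud.normals is None else cloud.normals @ pose.rotation.T
    idx = np.arange(pts.shape[0])
    if config.noise_sigma > 0:
        pts = pts + rng.normal(scale=config.noise_sigma, size=pts.shape)
    if config.outlier_fraction > 0 and pts.shape[0]:
        n_out = int(round(config.outlier_fraction * pts.shape[0]))
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        outliers = rng.uniform(lo, hi, size=(n_out, 3))
        pts = np.vstack([pts, outliers])
        idx = np.concatenate([idx, np.full(n_out, -1)])
        if nrm is not None:
            # outliers get arbitrary unit normals
            extra = rng.normal(size=(n_out, 3))
            extra /= np.linalg.norm(extra, axis=1, keepdims=True)
            nrm = np.vstack([nrm, extra])
    if config.dropout_fraction > 0 and pts.shape[0]:
        keep = rng.random(pts.shape[0]) >= config.dropout_fraction
        pts, idx = pts[keep], idx[keep]
        if nrm is not None:
            nrm = nrm[keep]
    unit = ARBITRARY if config.s_true != 1.0 or cloud.unit == ARBITRARY else cloud.unit
    degraded = PointCloud(pts, unit=unit, normals=nrm)
    return DegradeResult(cloud=degraded, source_index=idx, pose=pose, s_true=config.s_true)


def _sample_rect(rng, origin, u_vec, v_vec, u_len, v_len, density):
    """Uniform points on a rectangle origin + a·u + b·v, a∈[0,u_len], b∈[0,v_len]."""
    n = max(int(round(density * u_len * v_len)), 4)
    a = rng.uniform(0.0, u_len, size=n)
    b = rng.uniform(0.0, v_len, size=n)
    return np.asarray(origin) + a[:, None] * np.asarray(u_vec) + b[:, None] * np.asarray(v_vec)


def make_box_interior(config: SceneConfig) -> tuple[DegradeResult, np.ndarray]:
    """Sample the four inner walls of the calibration box.

    The top and bottom walls are the parallel pair at z = ±separation/2;
    two side walls close the x extremes.  Returns the degraded scene and a
    per-point wall label (0 top, 1 bottom, 2/3 sides, −1 outlier) aligned
    with the degraded cloud.
    """
    rng = config.rng()
    sep, ext = config.box_separation_mm, config.box_extent_mm
    dens = config.points_per_unit_area
    half = sep / 2.0
    ex = np.array([1.0, 0, 0])
    ey = np.array([0, 1.0, 0])
    walls = [
        # (origin, u, v, u_len, v_len, inward normal)
        ((-ext / 2, -ext / 2, half), ex, ey, ext, ext, np.array([0.0, 0, -1])),   # top
        ((-ext / 2, -ext / 2, -half), ex, ey, ext, ext, np.array([0.0, 0, 1])),   # bottom
        ((-ext / 2, -ext / 2, -half), ey, np.array([0, 0, 1.0]), ext, sep, ex),   # x−side
        ((ext / 2, -ext / 2, -half), ey, np.array([0, 0, 1.0]), ext, sep, -ex),   # x+side
    ]
    pts_list, nrm_list, lab_list = [], [], []
    for label, (origin, u, v, ul, vl, normal) in enumerate(walls):
        pts = _sample_rect(rng, origin, u, v, ul, vl, dens)
        pts_list.append(pts)
        nrm_list.append(np.tile(normal, (pts.shape[0], 1)))
        lab_list.append(np.full(pts.shape[0], label))
    clean = PointCloud(
        np.vstack(pts_list), unit="mm", normals=np.vstack(nrm_list)
    )
    clean_labels = np.concatenate(lab_list)
    result = degrade(clean, config, rng)
    labels = np.where(
        result.source_index >= 0, clean_labels[result.source_index], -1
    )
    return result, labels


def make_grid_calibrator(config: SceneConfig) -> tuple[DegradeResult, np.ndarray]:
    """Corner lattice of a planar checkerboard calibrator.

    Returns the degraded corner cloud and the matched
    ``(reconstructed_length, real_length_mm)`` pairs for every
    horizontal/vertical neighbour whose both corners survive degradation —
    ready for :func:`endoscale.scale.scale_from_length_pairs`.
    """
    if config.grid_rows < 2 or config.grid_cols < 2:
        raise InvalidInputError("grid needs at least 2 rows and 2 columns")
    if not (config.grid_spacing_mm > 0):
        raise InvalidInputError("grid spacing must be positive")
    rng = config.rng()
    r, c, sp = config.grid_rows, config.grid_cols, config.grid_spacing_mm
    ii, jj = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    corners = np.column_stack(
        [ii.ravel() * sp, jj.ravel() * sp, np.zeros(r * c)]
    )
    clean = PointCloud(corners, unit="mm")
    result = degrade(clean, config, rng)
    # map clean corner index -> degraded position (if it survived)
    pos = {int(src): result.cloud.points[k] for k, src in enumerate(result.source_index) if src >= 0}
    pairs = []
    for i in range(r):
        for j in range(c):
            flat = i * c + j
            for di, dj in ((0, 1), (1, 0)):
                ni, nj = i + di, j + dj
                if ni >= r or nj >= c:
                    continue
                nflat = ni * c + nj
                if flat in pos and nflat in pos:
                    recon_len = float(np.linalg.norm(pos[flat] - pos[nflat]))
                    pairs.append((recon_len, sp))
    return result, np.asarray(pairs, dtype=float).reshape(-1, 2)


def make_organ_surface(
    config: SceneConfig,
) -> tuple[DegradeResult, np.ndarray, float]:
    """Wrinkled ellipsoid patch with two labelled lesion endpoints.

    The patch covers the upper hemisphere of an ellipsoid with radii
    ``organ_radii_mm``; each surface point is displaced along the local
    normal by a sinusoidal wrinkle field.  Two lesion endpoints are placed
    symmetrically about the apex so that their clean chord distance equals
    ``lesion_length_mm``.  Returns the degraded scene, the degraded
    endpoint coordinates (2 × 3; exempt from dropout — they are tracked as
    named picks, not rediscovered in the cloud), and the true length in mm.
    """
    a, b, c = config.organ_radii_mm
    if min(a, b, c) <= 0:
        raise InvalidInputError("ellipsoid radii must be positive")
    rng = config.rng()

    def surface(theta, phi):
        # theta: polar from +z in [0, pi/2]; phi: azimuth
        x = a * np.sin(theta) * np.cos(phi)
        y = b * np.sin(theta) * np.sin(phi)
        z = c * np.cos(theta)
        base = np.column_stack([np.atleast_1d(x), np.atleast_1d(y), np.atleast_1d(z)])
        # outward normal of the ellipsoid (gradient of the implicit form)
        n = base / np.array([a**2, b**2, c**2])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        w = config.wrinkle_amplitude_mm * np.sin(
            config.wrinkle_frequency * np.atleast_1d(theta)
        ) * np.cos(config.wrinkle_frequency * np.atleast_1d(phi))
        return base + w[:, None] * n

    # lesion endpoints symmetric about the apex along the x direction
    def chord(theta_off):
        pts = surface(np.array([theta_off, theta_off]), np.array([0.0, np.pi]))
        return float(np.linalg.norm(pts[0] - pts[1]))

    theta_max = np.pi / 2
    if chord(theta_max * 0.98) < config.lesion_length_mm:
        raise InvalidInputError("lesion length exceeds the surface patch extent")
    lo, hi = 1e-6, theta_max * 0.98
    for _ in range(200):  # bisection on the symmetric chord length
        mid = 0.5 * (lo + hi)
        if chord(mid) < config.lesion_length_mm:
            lo = mid
        else:
            hi = mid
    theta_lesion = 0.5 * (lo + hi)
    endpoints_clean = surface(
        np.array([theta_lesion, theta_lesion]), np.array([0.0, np.pi])
    )
    true_length = chord(theta_lesion)

    area_estimate = 2 * np.pi * ((a * b + a * c + b * c) / 3)  # hemisphere-ish
    n_pts = max(int(round(config.points_per_unit_area * area_estimate)), 50)
    # area-weighted polar sampling on the hemisphere
    theta = np.arccos(rng.uniform(0.0, 1.0, size=n_pts))
    phi = rng.uniform(0.0, 2 * np.pi, size=n_pts)
    clean = PointCloud(surface(theta, phi), unit="mm")

    # degrade surface and endpoints with one RNG stream; endpoints ride along
    # as the last two points and are exempted from dropout/outlier accounting
    no_drop = replace(config, dropout_fraction=0.0, outlier_fraction=0.0)
    combined = PointCloud(
        np.vstack([clean.points, endpoints_clean]), unit="mm"
    )
    base = degrade(combined, no_drop, rng)
    endpoints_deg = base.cloud.points[-2:].copy()
    surface_deg = base.cloud.points[:-2]
    # outliers + dropout on the surface only, continuing the same stream
    pts, idx = surface_deg, np.arange(surface_deg.shape[0])
    if config.outlier_fraction > 0:
        n_out = int(round(config.outlier_fraction * pts.shape[0]))
        lo_b, hi_b = pts.min(axis=0), pts.max(axis=0)
        pts = np.vstack([pts, rng.uniform(lo_b, hi_b, size=(n_out, 3))])
        idx = np.concatenate([idx, np.full(n_out, -1)])
    if config.dropout_fraction > 0:
        keep = rng.random(pts.shape[0]) >= config.dropout_fraction
        pts, idx = pts[keep], idx[keep]
    unit = ARBITRARY if config.s_true != 1.0 else "mm"
    result = DegradeResult(
        cloud=PointCloud(pts, unit=unit),
        source_index=idx,
        pose=base.pose,
        s_true=config.s_true,
    )
    return result, endpoints_deg, true_length
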