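"""Metric-scale recovery for monocular-SLAM reconstructions.

A monocular reconstruction is only defined up to a global scale.  Two
routes recover it:

**In-scene calibrator.**  An object of known size (checkerboard grid,
instrument) is co-reconstructed with the scene.  Each known feature length
gives a ratio s_i = d'_i / d_i of reconstructed to real length; the scale
factor s is their aggregate (geometric mean).  By this convention s is the
size of the reconstruction *relative to reality*, so rescaling to metric
units divides coordinates by s.

**Pre-calibration box.**  Before entering the cavity the endoscope passes
through a box whose top and bottom inner walls are parallel planes a known
distance apart.  Both wall planes are fitted jointly under a shared-normal
(parallelism) constraint:

    argmin_{n, d1, d2}  Σ_i (n·p_i + d1)²  +  Σ_j (n·q_j + d2)²,   ‖n‖ = 1

which has a closed-form solution: each offset is fixed by its wall's
centroid (d_k = −n·c_k) and the shared normal is the eigenvector of the
summed centered scatter matrix with the smallest eigenvalue; the residual
sum of squares equals that eigenvalue.  The reconstructed plane separation
|d1 − d2| divided by the physically measured separation gives s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import ARBITRARY, InvalidInputError, Plane, PointCloud, UnitError

__all__ = [
    "DegenerateFitError",
    "SelectionError",
    "ScaleEstimate",
    "PlanePairFit",
    "BoxSpec",
    "Region",
    "scale_from_length_pairs",
    "fit_parallel_planes",
    "plane_pair_distance",
    "select_plane_points",
    "estimate_scale_from_box",
    "rescale_cloud",
]

log = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """The plane-pair normal is not identifiable (isotropic/ambiguous scatter)."""


class SelectionError(ValueError):
    """Too few points survived region/normal/inlier selection."""


@dataclass
class ScaleEstimate:
    """Recovered scale factor, convention reconstructed-over-real (s = d'/d)."""

    s: float
    method: str  # "calibrator" or "box"
    per_pair_values: np.ndarray | None = None
    residual: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if not (self.s > 0):
            raise InvalidInputError("scale factor must be positive")
        if self.per_pair_values is not None:
            self.per_pair_values = np.asarray(self.per_pair_values, dtype=float)


@dataclass
class PlanePairFit:
    """Joint fit of two parallel planes n·p + d1 = 0 and n·p + d2 = 0."""

    normal: np.ndarray
    d1: float
    d2: float
    rss: float
    n_top: int
    n_bottom: int

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)

    @property
    def top_plane(self) -> Plane:
        return Plane(self.normal.copy(), self.d1)

    @property
    def bottom_plane(self) -> Plane:
        return Plane(self.normal.copy(), self.d2)

    def separation(self) -> float:
        return abs(self.d1 - self.d2)


@dataclass
class BoxSpec:
    """Physically measured inner top-to-bottom plane separation, mm."""

    true_plane_separation_mm: float

    def __post_init__(self):
        if not (self.true_plane_separation_mm > 0):
            raise InvalidInputError("plane separation must be positive")


@dataclass
class Region:
    """Axis-aligned bounding box, inclusive of its faces."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float).reshape(3)
        self.upper = np.asarray(self.upper, dtype=float).reshape(3)
        if not (self.lower <= self.upper).all():
            raise InvalidInputError("region lower bound exceeds upper bound")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return ((pts >= self.lower) & (pts <= self.upper)).all(axis=1)


def scale_from_length_pairs(pairs) -> ScaleEstimate:
    """Scale factor from (reconstructed_length, real_length_mm) pairs.

    Each pair yields a ratio d'/d; the aggregate is their geometric mean
    (symmetric under inverting the ratio's orientation) and the residual is
    the coefficient of variation of the per-pair ratios.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise InvalidInputError("at least one length pair is required")
    pairs = pairs.reshape(-1, 2)
    if not (pairs > 0).all():
        raise InvalidInputError("all lengths must be positive")
    ratios = pairs[:, 0] / pairs[:, 1]
    s = float(np.exp(np.mean(np.log(ratios))))
    cv = float(np.std(ratios) / np.mean(ratios)) if len(ratios) > 1 else 0.0
    return ScaleEstimate(s=s, method="calibrator", per_pair_values=ratios, residual=cv)


def fit_parallel_planes(top_points, bottom_points) -> PlanePairFit:
    """Closed-form least-squares fit of two planes sharing one normal.

    Raises
    ------
    InvalidInputError
        Fewer than 3 points in either set.
    DegenerateFitError
        The two smallest eigenvalues of the summed scatter coincide, so the
        shared normal is not unique (e.g. both sets collinear or isotropic).
    """
    top = np.asarray(top_points, dtype=float).reshape(-1, 3)
    bot = np.asarray(bottom_points, dtype=float).reshape(-1, 3)
    if top.shape[0] < 3 or bot.shape[0] < 3:
        raise InvalidInputError(
            f"need at least 3 points per plane (got {top.shape[0]} top, {bot.shape[0]} bottom)"
        )
    c_top, c_bot = top.mean(axis=0), bot.mean(axis=0)
    dt, db = top - c_top, bot - c_bot
    scatter = dt.T @ dt + db.T @ db
    eigvals, eigvecs = np.linalg.eigh(scatter)  # ascending
    scale_ref = max(eigvals[-1], 1.0)
    if eigvals[1] - eigvals[0] <= 1e-12 * scale_ref:
        raise DegenerateFitError(
            "plane-pair normal is ambiguous: two smallest scatter eigenvalues coincide "
            f"({eigvals[0]:.3e} vs {eigvals[1]:.3e})"
        )
    n = eigvecs[:, 0]
    # canonical sign (match Plane convention: K >= 0, ties J then L)
    for component in (n[2], n[1], n[0]):
        if component != 0.0:
            if component < 0.0:
                n = -n
            break
    d1 = float(-n @ c_top)
    d2 = float(-n @ c_bot)
    return PlanePairFit(
        normal=n,
        d1=d1,
        d2=d2,
        rss=float(max(eigvals[0], 0.0)),
        n_top=top.shape[0],
        n_bottom=bot.shape[0],
    )


def plane_pair_distance(fit: PlanePairFit) -> float:
    """Distance between the two fitted parallel planes (unit normal ⇒ |d1 − d2|)."""
    return fit.separation()


def select_plane_points(
    cloud: PointCloud,
    region_top: Region,
    region_bottom: Region,
    normal_tolerance_deg: float = 25.0,
    reference_normal=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Select candidate wall points by region, optionally gated by normals.

    Points fall in either axis-aligned region; when the cloud carries
    normals and a current plane-pair normal estimate is supplied, only
    points whose normal lies within ``normal_tolerance_deg`` of it (sign
    ignored — walls face each other) are kept.
    """
    pts = cloud.points
    mask_top = region_top.contains(pts)
    mask_bot = region_bottom.contains(pts)
    if cloud.has_normals and reference_normal is not None:
        if not (0.0 < normal_tolerance_deg < 90.0):
            raise InvalidInputError("normal tolerance must be in (0°, 90°)")
        ref = np.asarray(reference_normal, dtype=float).reshape(3)
        ref = ref / np.linalg.norm(ref)
        cos_tol = np.cos(np.deg2rad(normal_tolerance_deg))
        aligned = np.abs(cloud.normals @ ref) >= cos_tol
        mask_top &= aligned
        mask_bot &= aligned
    elif not cloud.has_normals and reference_normal is not None:
        log.info("cloud has no normals; normal gating skipped (region filtering only)")
    n_top, n_bot = int(mask_top.sum()), int(mask_bot.sum())
    if n_top < 3 or n_bot < 3:
        raise SelectionError(
            f"too few points selected: {n_top} in top region, {n_bot} in bottom region "
            "(need ≥ 3 each)"
        )
    return pts[mask_top], pts[mask_bot]


def estimate_scale_from_box(
    cloud: PointCloud,
    region_top: Region,
    region_bottom: Region,
    box: BoxSpec,
    max_iter: int = 10,
    tol: float = 1e-10,
    normal_tolerance_deg: float = 25.0,
    mad_gate: float = 3.0,
) -> tuple[ScaleEstimate, PlanePairFit]:
    """Iteratively reselect wall points and refit the parallel plane pair.

    The first pass selects by region only.  Subsequent passes additionally
    gate on the current fitted normal (when the cloud has normals) and drop
    residual outliers beyond ``mad_gate`` × the robust residual spread
    (median absolute deviation, scaled to σ).  Iteration stops when the fit
    objective changes by less than ``tol`` or after ``max_iter`` passes.

    Returns the scale estimate s = reconstructed separation / true
    separation (reconstructed-over-real) together with the final fit.
    """
    if max_iter < 1:
        raise InvalidInputError("max_iter must be >= 1")
    top, bot = select_plane_points(cloud, region_top, region_bottom)
    fit = fit_parallel_planes(top, bot)
    converged = max_iter == 1
    prev_kept: tuple[np.ndarray, np.ndarray] | None = None
    for iteration in range(1, max_iter):
        top_c, bot_c = select_plane_points(
            cloud, region_top, region_bottom, normal_tolerance_deg, fit.normal
        )
        kept = []
        for pts, d in ((top_c, fit.d1), (bot_c, fit.d2)):
            resid = pts @ fit.normal + d
            center = np.median(resid)  # robust to an offset bias in the previous fit
            mad = np.median(np.abs(resid - center))
            sigma = 1.4826 * mad
            if sigma > 0:
                pts = pts[np.abs(resid - center) <= mad_gate * sigma]
            if pts.shape[0] < 3:
                raise SelectionError(
                    f"iteration {iteration}: fewer than 3 inliers survive the "
                    f"{mad_gate}×MAD residual gate"
                )
            kept.append(pts)
        new_fit = fit_parallel_planes(kept[0], kept[1])
        delta = abs(new_fit.rss - fit.rss)
        log.debug(
            "box-fit iteration %d: rss %.6g -> %.6g (Δ %.3g), %d/%d points",
            iteration, fit.rss, new_fit.rss, delta, new_fit.n_top, new_fit.n_bottom,
        )
        fit = new_fit
        # converged when the objective stalls or the inlier selection reaches
        # a fixed point (identical kept sets on consecutive passes)
        fixed_point = prev_kept is not None and all(
            a.shape == b.shape and np.array_equal(a, b)
            for a, b in zip(kept, prev_kept)
        )
        if delta < tol or fixed_point:
            converged = True
            break
        prev_kept = (kept[0].copy(), kept[1].copy())
    separation = plane_pair_distance(fit)
    if separation <= 0:
        raise DegenerateFitError("fitted plane pair has zero separation")
    s = separation / box.true_plane_separation_mm
    est = ScaleEstimate(
        s=s,
        method="box",
        per_pair_values=np.array([s]),
        residual=fit.rss,
        converged=converged,
    )
    if not converged:
        log.warning("box scale estimation did not converge within %d iterations", max_iter)
    return est, fit


def rescale_cloud(cloud: PointCloud, estimate: ScaleEstimate) -> PointCloud:
    """Divide coordinates by s, turning an arbitrary-unit cloud into mm.

    Guards against double-scaling: the input must carry the ``"arbitrary"``
    unit tag.
    """
    if cloud.unit != ARBITRARY:
        raise UnitError(
            f"cloud is already metric ({cloud.unit!r}); refusing to rescale twice"
        )
    return PointCloud(cloud.points / estimate.s, unit="mm", normals=cloud.normals)
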