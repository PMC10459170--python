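"""Global accuracy evaluation: rigid alignment plus cloud-to-reference distances.

When a metric reference model of the scene exists (e.g. a CT-derived or
scanned phantom surface), absolute reconstruction accuracy is assessed by
rigidly aligning the metric-scaled reconstruction to the reference with
point-to-point ICP, then computing, for every reconstructed point, the
distance to its nearest neighbour in the reference.  The RMSE of those
distances is the headline accuracy number: the smaller, the closer the
reconstruction tracks the reference geometry.

The distance direction is fixed reconstructed → reference; this makes the
statistic robust to holes in the reconstruction (missing reconstructed
points simply contribute nothing), at the cost of not penalising missing
coverage — a completeness metric is deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import InvalidInputError, PointCloud, RigidTransform, transform_cloud

__all__ = [
    "DegenerateAlignmentError",
    "AlignmentError",
    "AlignmentResult",
    "DistanceStats",
    "best_fit_rigid",
    "icp_align",
    "nn_distances",
    "evaluate_global",
]

log = logging.getLogger(__name__)


class DegenerateAlignmentError(ValueError):
    """Correspondences do not determine a unique rigid transform."""


class AlignmentError(RuntimeError):
    """ICP could not establish any usable correspondences."""


@dataclass
class AlignmentResult:
    transform: RigidTransform
    iterations: int
    final_mean_nn_distance: float
    converged: bool
    residual_trace: list[float]


@dataclass
class DistanceStats:
    """Per-point nearest-neighbour distances (source → reference) and summaries."""

    distances: np.ndarray
    rmse: float
    mean: float
    max: float
    n: int

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceStats":
        d = np.asarray(d, dtype=float)
        return cls(
            distances=d,
            rmse=float(np.sqrt(np.mean(d**2))) if d.size else 0.0,
            mean=float(np.mean(d)) if d.size else 0.0,
            max=float(np.max(d)) if d.size else 0.0,
            n=int(d.size),
        )

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mean": self.mean, "max": self.max, "n": self.n}


def best_fit_rigid(source_pts, target_pts) -> RigidTransform:
    """Least-squares rigid transform mapping paired sources onto targets.

    Solves argmin_{R,t} Σ‖R·s_i + t − t_i‖² via SVD of the cross-covariance
    (Kabsch), with the reflection case corrected so the rotation is always
    proper (det +1).
    """
    src = np.asarray(source_pts, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_pts, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise InvalidInputError("source/target correspondence counts differ")
    if src.shape[0] < 3:
        raise DegenerateAlignmentError("need at least 3 correspondence pairs")
    c_src, c_tgt = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - c_src).T @ (tgt - c_tgt)
    U, sing, Vt = np.linalg.svd(H)
    # collinear correspondences leave a rotation about the line free
    if sing[1] <= 1e-12 * max(sing[0], 1.0):
        raise DegenerateAlignmentError(
            "correspondences are (near-)collinear; rigid transform not unique"
        )
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    t = c_tgt - R @ c_src
    return RigidTransform(R, t)


def _median_nn_spacing(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return np.inf
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.median(d[:, 1]))


def icp_align(
    source: PointCloud,
    target: PointCloud,
    max_iter: int = 50,
    tol: float = 1e-8,
    max_corr_dist: float | None = None,
    init: RigidTransform | None = None,
) -> AlignmentResult:
    """Classic point-to-point ICP.

    Each pass finds nearest-neighbour correspondences (gated at
    ``max_corr_dist``; default 5× the median nearest-neighbour spacing of
    the target), solves the rigid least-squares step, and repeats until the
    mean correspondence residual changes by less than ``tol``.  A step that
    would increase the residual is rejected and iteration stops, so the
    recorded residual trace is non-increasing.
    """
    if source.unit != target.unit:
        raise InvalidInputError(
            f"clouds must share a unit (got {source.unit!r} vs {target.unit!r})"
        )
    if len(source) < 3 or len(target) < 3:
        raise InvalidInputError("both clouds need at least 3 points")
    if max_corr_dist is None:
        max_corr_dist = 5.0 * _median_nn_spacing(target.points)
    tree = cKDTree(target.points)
    transform = init if init is not None else RigidTransform.identity()
    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        moved = transform.apply(source.points)
        dist, idx = tree.query(moved)
        gate = dist <= max_corr_dist
        if not gate.any():
            raise AlignmentError(
                f"no correspondences within gate {max_corr_dist:.4g} at iteration {iterations}"
            )
        residual = float(np.mean(dist[gate]))
        if trace and residual > trace[-1]:
            # reject the step; keep the previous transform
            transform = prev_transform
            converged = abs(residual - trace[-1]) < tol
            iterations -= 1
            break
        trace.append(residual)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < tol:
            converged = True
            break
        prev_transform = transform
        step = best_fit_rigid(moved[gate], target.points[idx[gate]])
        transform = step.compose(transform)
    final_moved = transform.apply(source.points)
    dist, _ = tree.query(final_moved)
    gate = dist <= max_corr_dist
    final_residual = float(np.mean(dist[gate])) if gate.any() else float("inf")
    log.debug("ICP finished after %d iterations, residual %.6g", iterations, final_residual)
    return AlignmentResult(
        transform=transform,
        iterations=iterations,
        final_mean_nn_distance=final_residual,
        converged=converged,
        residual_trace=trace,
    )


def nn_distances(source: PointCloud, reference: PointCloud) -> DistanceStats:
    """Distance from each source point to its nearest reference point.

    Direction is source → reference only.  Ties are broken toward the
    smallest reference index (deterministic).
    """
    if len(reference) == 0:
        raise InvalidInputError("reference cloud is empty")
    if len(source) == 0:
        return DistanceStats.from_distances(np.zeros(0))
    tree = cKDTree(reference.points)
    d, _ = tree.query(source.points)
    return DistanceStats.from_distances(d)


def evaluate_global(
    recon: PointCloud,
    reference: PointCloud,
    max_iter: int = 50,
    tol: float = 1e-8,
    max_corr_dist: float | None = None,
    init: RigidTransform | None = None,
) -> tuple[AlignmentResult, DistanceStats]:
    """Align the reconstruction to the reference, then score NN distances.

    Both clouds must already be metric (mm): scale recovery is a separate,
    earlier pipeline stage and ICP performs no scale estimation.
    """
    for name, cloud in (("reconstruction", recon), ("reference", reference)):
        if cloud.unit != "mm":
            raise InvalidInputError(
                f"{name} cloud must be in mm (got {cloud.unit!r}); recover scale first"
            )
    alignment = icp_align(recon, reference, max_iter, tol, max_corr_dist, init)
    aligned = transform_cloud(recon, alignment.transform)
    stats = nn_distances(aligned, reference)
    return alignment, stats
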