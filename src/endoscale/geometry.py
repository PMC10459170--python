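"""Foundational geometric types and primitives.

A monocular-SLAM reconstruction is an unordered set of 3D map points whose
coordinates live either in an arbitrary (scale-ambiguous) unit or, after
scale recovery, in millimetres.  Everything downstream — plane fitting,
length measurement, rigid alignment — reduces to a handful of exact
primitives collected here.

The canonical internal length unit is the millimetre: all ground-truth
dimensions in this problem domain (lesion lengths, calibrator square sizes,
calibration-box plane separations) are naturally quoted in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidInputError",
    "UnitError",
    "PointCloud",
    "RigidTransform",
    "Plane",
    "euclidean_distance",
    "transform_cloud",
    "point_plane_distance",
    "convert_unit",
]

#: Supported metric unit tags and their size in millimetres.
_UNIT_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}

#: Unit tag for scale-ambiguous (pre-recovery) reconstructions.
ARBITRARY = "arbitrary"


class InvalidInputError(ValueError):
    """Raised for non-finite, empty or otherwise malformed geometric input."""


class UnitError(ValueError):
    """Raised for invalid or incompatible length-unit operations."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"expected an (N, 3) array of points, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise InvalidInputError("point coordinates must be finite")
    return pts


@dataclass
class PointCloud:
    """N unordered 3D points with a declared length unit.

    Parameters
    ----------
    points
        (N, 3) array of coordinates.
    unit
        ``"mm"``, ``"cm"``, ``"m"`` or ``"arbitrary"``.  The arbitrary tag
        marks a scale-ambiguous reconstruction whose metric scale has not
        yet been recovered.
    normals
        Optional (N, 3) array of unit surface normals.
    """

    points: np.ndarray
    unit: str = "mm"
    normals: np.ndarray | None = None

    def __post_init__(self):
        self.points = _as_points(self.points)
        if self.unit not in _UNIT_MM and self.unit != ARBITRARY:
            raise UnitError(f"unknown unit tag {self.unit!r}")
        if self.normals is not None:
            nrm = _as_points(self.normals)
            if nrm.shape[0] != self.points.shape[0]:
                raise InvalidInputError(
                    f"{nrm.shape[0]} normals for {self.points.shape[0]} points"
                )
            if nrm.shape[0] and not np.allclose(
                np.linalg.norm(nrm, axis=1), 1.0, rtol=0.0, atol=1e-9
            ):
                raise InvalidInputError("normals must have unit Euclidean norm (tol 1e-9)")
            self.normals = nrm

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            unit=self.unit,
            normals=None if self.normals is None else self.normals.copy(),
        )


@dataclass
class RigidTransform:
    """Proper rigid motion p ↦ R·p + t (rotation + translation, no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidInputError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), rtol=0.0, atol=1e-9):
            raise InvalidInputError("rotation must be orthonormal (R·Rᵀ = I within 1e-9)")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise InvalidInputError("rotation must be proper (det = +1 within 1e-9)")
        self.rotation, self.translation = R, t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class Plane:
    """Plane L·x + J·y + K·z + d = 0 with canonical unit normal.

    The stored normal has unit norm and a canonical sign (K ≥ 0; ties broken
    by J ≥ 0, then L ≥ 0) so that independently fitted planes compare
    stably across runs.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0.0:
            raise InvalidInputError("plane normal must be nonzero and finite")
        n = n / norm
        d = float(self.offset) / norm
        # canonical sign: first nonzero of (K, J, L) made positive
        for component in (n[2], n[1], n[0]):
            if component != 0.0:
                if component < 0.0:
                    n, d = -n, -d
                break
        self.normal, self.offset = n, d

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal + self.offset


def euclidean_distance(p, q) -> float:
    """Straight-line distance between two points in their common unit."""
    p = np.asarray(p, dtype=float).reshape(3)
    q = np.asarray(q, dtype=float).reshape(3)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise InvalidInputError("points must be finite")
    return float(np.linalg.norm(p - q))


def transform_cloud(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Apply a rigid motion to a cloud; normals are rotated only."""
    pts = transform.apply(cloud.points)
    nrm = None if cloud.normals is None else cloud.normals @ transform.rotation.T
    return PointCloud(pts, unit=cloud.unit, normals=nrm)


def point_plane_distance(p, plane: Plane) -> float:
    """Signed point-to-plane distance; the sign follows the canonical normal."""
    p = np.asarray(p, dtype=float).reshape(3)
    if not np.isfinite(p).all():
        raise InvalidInputError("point must be finite")
    return float(plane.signed_distance(p[None, :])[0])


def convert_unit(value, from_unit: str, to_unit: str):
    """Convert a length, an array of lengths/coordinates, or a PointCloud.

    Metric conversions are exact powers of ten.  The ``"arbitrary"`` tag is
    convertible only to itself: a scale-ambiguous cloud must go through
    scale recovery, never through a unit conversion.
    """
    if from_unit == ARBITRARY or to_unit == ARBITRARY:
        if from_unit == to_unit:
            return value.copy() if isinstance(value, PointCloud) else value
        raise UnitError(
            "cannot convert between 'arbitrary' and metric units; recover the scale first"
        )
    for tag in (from_unit, to_unit):
        if tag not in _UNIT_MM:
            raise UnitError(f"unknown unit tag {tag!r}")
    src, dst = _UNIT_MM[from_unit], _UNIT_MM[to_unit]

    # multiply or divide by the exact integer power of ten, never by an
    # inexact reciprocal such as 0.1
    def _conv(x):
        if src >= dst:
            return x * (src / dst)
        return x / (dst / src)

    if isinstance(value, PointCloud):
        return PointCloud(_conv(value.points), unit=to_unit, normals=value.normals)
    if from_unit == to_unit:
        return value
    return _conv(np.asarray(value, dtype=float)) if np.ndim(value) else float(_conv(value))
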