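"""Points, lines, cubic regions, image moments and centers of mass.

This module is the numeric substrate of the electrode-segmentation
algorithm.  All geometry lives in *physical millimetres*: voxel indices are
mapped to the physical coordinates of their voxel centers through the
volume affine, and every region, distance and centroid is expressed on
that scale (the only one on which statements like "a cubic region of
3 mm" are meaningful for anisotropic voxels).

The image is modelled as a set of samples ``(x, y, z, I(x, y, z))``.  For
a region ``R`` the raw moment of order ``p+q+r`` is

    M_pqr = sum_{(x,y,z) in R} x^p y^q z^r I(x, y, z)

with ``M_000`` the total mass and the center of mass

    c_R = (M_100 / M_000, M_010 / M_000, M_001 / M_000).

Only orders 0 and 1 are used by the algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import DegenerateAxisError, EmptyRegionError

if TYPE_CHECKING:  # pragma: no cover
    from .volume import VoxelVolume

__all__ = [
    "Point3",
    "as_point",
    "CubicRegion",
    "Line3",
    "unit_vector",
    "line_through",
    "point_at_distance",
    "segment_angle",
    "region_moment",
    "center_of_mass",
]

#: A point in physical space: any 3-sequence of finite floats.  Functions in
#: this package accept sequences/arrays and return ``numpy`` arrays of shape
#: ``(3,)``.
Point3 = np.ndarray


def as_point(p) -> np.ndarray:
    """Coerce ``p`` to a finite float64 vector of shape ``(3,)``."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point has non-finite components: {arr}")
    return arr


@dataclass
class CubicRegion:
    """Axis-aligned cube ``R(c, l)``: center ``c`` and side length ``l`` (mm).

    A voxel belongs to the region iff each coordinate of its center is
    within ``l/2`` of the region center (boundary inclusive).
    """

    center: Point3
    side: float

    def __post_init__(self):
        self.center = as_point(self.center)
        self.side = float(self.side)
        if not self.side > 0:
            raise ValueError(f"region side must be > 0, got {self.side}")

    def contains(self, points) -> np.ndarray:
        """Inclusive axis-aligned membership test for ``(..., 3)`` points."""
        pts = np.asarray(points, dtype=float)
        half = self.side / 2.0 + 1e-9
        return np.all(np.abs(pts - self.center) <= half, axis=-1)


@dataclass
class Line3:
    """Parametric line ``p = origin + unit_direction * t`` (t in mm)."""

    origin: Point3
    unit_direction: Point3

    def __post_init__(self):
        self.origin = as_point(self.origin)
        self.unit_direction = as_point(self.unit_direction)
        norm = float(np.linalg.norm(self.unit_direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length, |v| = {norm}")

    def at(self, t: float) -> np.ndarray:
        return self.origin + self.unit_direction * float(t)


def unit_vector(p1, p2) -> np.ndarray:
    """Unit direction from ``p1`` toward ``p2``.

    Raises
    ------
    DegenerateAxisError
        If the points coincide (the axis is undefined).
    """
    p1, p2 = as_point(p1), as_point(p2)
    v = p2 - p1
    norm = float(np.linalg.norm(v))
    if norm < 1e-12:
        raise DegenerateAxisError(
            f"cannot define an axis through coincident points {p1} and {p2}"
        )
    return v / norm


def line_through(p1, p2) -> Line3:
    """The line through two distinct points, directed ``p1 -> p2``."""
    return Line3(as_point(p1), unit_vector(p1, p2))


def point_at_distance(p1, p2, d: float) -> np.ndarray:
    """The point at signed distance ``d`` (mm) from ``p1`` toward ``p2``."""
    return as_point(p1) + unit_vector(p1, p2) * float(d)


def segment_angle(a, b, c) -> float:
    """Bend angle (degrees, in [0, 180]) at ``b`` of the polyline a-b-c.

    The angle between the directions ``b - a`` and ``c - b``; 0 for
    collinear continuation, 180 for a full reversal.
    """
    u = unit_vector(a, b)
    v = unit_vector(b, c)
    cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def region_moment(vol: "VoxelVolume", region: CubicRegion, p: int, q: int, r: int) -> float:
    """Raw image moment ``M_pqr`` of ``vol`` over the cubic region.

    Summation runs over the physical voxel-center coordinates of every
    voxel inside the region (clipped to the volume bounds).  A region that
    contains no voxels yields 0 with a warning.
    """
    if min(p, q, r) < 0:
        raise ValueError("moment orders must be non-negative")
    values, coords = vol.region_voxels(region)
    if values.size == 0:
        warnings.warn("region lies entirely outside the volume; moment is 0",
                      stacklevel=2)
        return 0.0
    term = values
    for order, axis in ((p, 0), (q, 1), (r, 2)):
        if order:
            term = term * coords[:, axis] ** order
    return float(np.sum(term))


def mass_moments(vol: "VoxelVolume", region: CubicRegion,
                 threshold: float | None = None) -> tuple[float, np.ndarray]:
    """``(M_000, [M_100, M_010, M_001])`` over a region in one pass.

    When ``threshold`` is given, voxels with intensity <= threshold
    contribute zero mass (the strict ``I > S`` electrode criterion).
    """
    block = vol.region_block(region)
    if block is not None:
        data, axes = block
        if threshold is not None:
            data = np.where(data > threshold, data, 0.0)
        m000 = float(data.sum())
        m1 = np.array([
            float(data.sum(axis=(1, 2)) @ axes[0]),
            float(data.sum(axis=(0, 2)) @ axes[1]),
            float(data.sum(axis=(0, 1)) @ axes[2]),
        ])
        return m000, m1
    values, coords = vol.region_voxels(region)
    if threshold is not None:
        values = np.where(values > threshold, values, 0.0)
    m000 = float(values.sum())
    return m000, coords.T @ values


def center_of_mass(vol: "VoxelVolume", region: CubicRegion,
                   threshold: float | None = None) -> np.ndarray:
    """Center of mass of ``vol`` over a cubic region, in physical mm.

    Raises
    ------
    EmptyRegionError
        If the total mass over the region is not positive (this drives the
        stop criteria of the axis-following search downstream).
    """
    m000, m1 = mass_moments(vol, region, threshold=threshold)
    if m000 <= 0.0:
        raise EmptyRegionError(
            f"region centered at {np.round(region.center, 3)} "
            f"(side {region.side} mm) has no mass"
        )
    return m1 / m000
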