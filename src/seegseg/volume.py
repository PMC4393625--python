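"""CT volume container, thresholding and the two primitive image searches.

A :class:`VoxelVolume` wraps a 3D scalar array together with a voxel-to-
physical affine (NIfTI convention, RAS millimetres).  Intensities are used
as stored: cone-beam CT is not reliably calibrated to the Hounsfield
scale, so nothing here assumes HU.

Two primitives recur throughout the segmentation algorithm:

``find_significant_voxel``
    scan a growing cubic neighbourhood for a voxel with intensity above
    the threshold ``S`` (absence is a value, not an error);

``refine_centroid``
    iterate the center-of-mass map of a fixed-size cubic region until it
    reaches a fixed point -- the contact (or screw) centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    ConvergenceError,
    EmptyRegionError,
    FormatError,
    GridMismatchError,
    ThresholdError,
)
from .geometry import CubicRegion, as_point, center_of_mass

__all__ = [
    "VoxelVolume",
    "Threshold",
    "load_volume",
    "subtract_volumes",
    "auto_threshold",
    "apply_threshold",
    "find_significant_voxel",
    "refine_centroid",
]

_TOL = 1e-9  # physical-boundary tolerance (mm): membership is inclusive


@dataclass(frozen=True)
class Threshold:
    """Intensity cut-off ``S`` separating electrode voxels (``I > S``) from
    background, in the same units as the volume intensities."""

    value: float

    def __float__(self) -> float:
        return float(self.value)


class VoxelVolume:
    """3D scalar grid with an affine voxel-index -> physical-mm mapping."""

    def __init__(self, data, affine):
        data = np.asarray(data, dtype=float)
        if data.ndim != 3:
            raise FormatError(f"expected a 3D scalar volume, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise FormatError(f"degenerate volume shape {data.shape}")
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        self.data = data
        self.affine = affine
        self._inv_affine = np.linalg.inv(affine)
        linear = affine[:3, :3]
        offdiag = linear - np.diag(np.diag(linear))
        # diagonal affines (no rotation/shear) get a fast separable region path
        self._diagonal = bool(np.all(np.abs(offdiag) < 1e-12))

    # -- basic properties -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.affine[:3, 3]) @ self._inv_affine[:3, :3].T

    def contains_point(self, p) -> bool:
        """True if ``p`` (mm) maps inside the voxel-index bounding box."""
        idx = self.world_to_index(as_point(p))
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def with_data(self, data) -> "VoxelVolume":
        return VoxelVolume(data, self.affine.copy())

    # -- region extraction ------------------------------------------------

    def _axis_range(self, axis: int, lo: float, hi: float) -> tuple[int, int]:
        """Index range [i0, i1) whose voxel centers fall in [lo, hi] on ``axis``
        (diagonal affine only)."""
        a = self.affine[axis, axis]
        b = self.affine[axis, 3]
        t0, t1 = sorted(((lo - b) / a, (hi - b) / a))
        i0 = max(int(np.ceil(t0 - 1e-7)), 0)
        i1 = min(int(np.floor(t1 + 1e-7)), self.shape[axis] - 1)
        return i0, i1 + 1

    def region_block(self, region: CubicRegion):
        """Fast path: contiguous sub-block covering the region exactly.

        Returns ``(block, (xs, ys, zs))`` with 1-D physical coordinate
        arrays per axis, or None when the affine has rotation/shear (use
        :meth:`region_voxels` instead).
        """
        if not self._diagonal:
            return None
        c = region.center
        h = region.side / 2.0 + _TOL
        ranges = [self._axis_range(k, c[k] - h, c[k] + h) for k in range(3)]
        if any(r[0] >= r[1] for r in ranges):
            empty = np.zeros((0, 0, 0))
            return empty, (np.zeros(0), np.zeros(0), np.zeros(0))
        (i0, i1), (j0, j1), (k0, k1) = ranges
        block = self.data[i0:i1, j0:j1, k0:k1]
        axes = tuple(
            self.affine[ax, ax] * np.arange(r0, r1) + self.affine[ax, 3]
            for ax, (r0, r1) in enumerate(ranges)
        )
        return block, axes

    def region_voxels(self, region: CubicRegion, above: float | None = None):
        """Voxel intensities and physical voxel-center coordinates in a region.

        Returns ``(values, coords)`` with ``values`` shape ``(n,)`` and
        ``coords`` shape ``(n, 3)``; regions are clipped to the volume.
        With ``above`` set, only voxels with ``I > above`` are returned.
        Ordering is C-order over the voxel index sub-grid (deterministic).
        """
        blk = self.region_block(region)
        if blk is not None:
            block, axes = blk
            if block.size == 0:
                return np.zeros(0), np.zeros((0, 3))
            if above is not None:
                ii, jj, kk = np.nonzero(block > above)
                values = block[ii, jj, kk]
                coords = np.column_stack((axes[0][ii], axes[1][jj], axes[2][kk]))
                return values, coords
            grid = np.meshgrid(*axes, indexing="ij")
            coords = np.stack([g.ravel() for g in grid], axis=1)
            return block.ravel(), coords
        # general affine: bound the cube in index space via its corners
        c, h = region.center, region.side / 2.0 + _TOL
        corners = c + np.array([[sx, sy, sz] for sx in (-h, h)
                                for sy in (-h, h) for sz in (-h, h)])
        idx = self.world_to_index(corners)
        lo = np.maximum(np.floor(idx.min(axis=0)).astype(int), 0)
        hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int), np.array(self.shape) - 1)
        if np.any(lo > hi):
            return np.zeros(0), np.zeros((0, 3))
        grids = np.meshgrid(*[np.arange(l, u + 1) for l, u in zip(lo, hi)],
                            indexing="ij")
        flat_idx = np.stack([g.ravel() for g in grids], axis=1)
        coords = self.index_to_world(flat_idx)
        inside = np.all(np.abs(coords - c) <= h, axis=1)
        values = self.data[grids[0].ravel()[inside],
                           grids[1].ravel()[inside],
                           grids[2].ravel()[inside]]
        coords = coords[inside]
        if above is not None:
            keep = values > above
            return values[keep], coords[keep]
        return values, coords

    # -- I/O --------------------------------------------------------------

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        self.to_nifti().to_filename(str(path))


def load_volume(path) -> VoxelVolume:
    """Load a NIfTI volume, preserving its affine and spacing.

    Trailing singleton dimensions (e.g. a 4D file with one frame) are
    squeezed; anything else non-3D is rejected.
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path} is not a 3D scalar volume (shape {data.shape})"
        )
    return VoxelVolume(np.asarray(data, dtype=float), img.affine)


def subtract_volumes(post: VoxelVolume, pre: VoxelVolume) -> VoxelVolume:
    """Voxelwise ``post - pre`` (bone removal), negatives clamped to 0.

    The grids must match exactly -- registration happens upstream and no
    implicit resampling is performed here.
    """
    if post.shape != pre.shape or not np.allclose(post.affine, pre.affine,
                                                  atol=1e-6):
        raise GridMismatchError(
            f"volumes are not on the same grid: shapes {post.shape} vs "
            f"{pre.shape}, affines differ: {not np.allclose(post.affine, pre.affine)}"
        )
    return post.with_data(np.clip(post.data - pre.data, 0.0, None))


def auto_threshold(vol: VoxelVolume, bins: int = 256) -> Threshold:
    """Pick ``S`` at the first local minimum of the intensity histogram.

    The histogram uses ``bins`` equal-width bins over the positive
    intensity range, smoothed with a short moving average.  Scanning
    upward from the lowest bin, the first interior local minimum that has
    genuinely descended from the background mode (below half the running
    maximum -- sampling wiggles inside a mode are not valleys) gives
    ``S`` at its bin center.
    """
    vals = vol.data[vol.data > 0]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ThresholdError(
            "volume has no interior histogram minimum (constant or empty "
            "positive range); supply a manual threshold"
        )
    hist, edges = np.histogram(vals, bins=bins)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(hist, kernel, mode="same")
    running_max = 0.0
    for i in range(1, bins - 1):
        running_max = max(running_max, smooth[i - 1])
        if smooth[i] <= smooth[i + 1] and smooth[i] < 0.5 * running_max:
            return Threshold(float(0.5 * (edges[i] + edges[i + 1])))
    raise ThresholdError(
        "histogram is monotone with no interior minimum; supply a manual "
        "threshold"
    )


def apply_threshold(vol: VoxelVolume, S) -> VoxelVolume:
    """Single-threshold filter: ``I'(p) = I(p) if I(p) > S else 0``.

    The comparison is strict -- a voxel exactly at ``S`` is background.
    Idempotent for any fixed ``S``.
    """
    s = float(S)
    return vol.with_data(np.where(vol.data > s, vol.data, 0.0))


def find_significant_voxel(vol: VoxelVolume, center, S,
                           l_init: float = 3.0, l_max: float = 10.0,
                           l_step: float = 1.0, prefer=None):
    """Search growing cubes around ``center`` for a voxel with ``I > S``.

    Cubes of side ``l_init, l_init + l_step, ..., l_max`` are scanned in
    turn; within the first non-empty cube the above-threshold voxel
    nearest to ``prefer`` (default: the cube center) is returned as its
    physical voxel-center coordinate.  Returns None when the search is
    exhausted -- absence is a value, not an error.
    """
    if l_step <= 0:
        raise ValueError("l_step must be > 0")
    if l_init > l_max:
        raise ValueError("l_init must be <= l_max")
    center = as_point(center)
    anchor = center if prefer is None else as_point(prefer)
    s = float(S)
    sides = list(np.arange(l_init, l_max + 1e-9, l_step))
    if not sides or sides[-1] < l_max - 1e-9:
        sides.append(l_max)
    for side in sides:
        values, coords = vol.region_voxels(CubicRegion(center, side), above=s)
        if values.size:
            d2 = np.sum((coords - anchor) ** 2, axis=1)
            return coords[int(np.argmin(d2))]  # first-in-C-order tie break
    return None


def refine_centroid(vol: VoxelVolume, start, side: float = 3.0, S=0.0,
                    eps: float = 1e-3, max_iter: int = 50) -> np.ndarray:
    """Iterate the center-of-mass map to its fixed point.

    From ``start``, repeatedly compute the center of mass of the cubic
    region of the given ``side`` centered on the previous iterate
    (intensities <= S carry no mass), until two subsequent centroids
    differ by less than ``eps`` (mm).  On isolated blobs the map is
    contractive and converges in a handful of iterations.

    Raises
    ------
    EmptyRegionError
        If a region along the way holds no above-threshold mass.
    ConvergenceError
        If ``max_iter`` is exceeded; the last iterate is attached.
    """
    cur = as_point(start)
    s = float(S)
    last = cur
    for _ in range(max_iter):
        com = center_of_mass(vol, CubicRegion(cur, side), threshold=s)
        if float(np.linalg.norm(com - cur)) < eps:
            return com
        last = cur = com
    raise ConvergenceError(
        f"centroid iteration did not converge within {max_iter} steps",
        last_point=last,
    )
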