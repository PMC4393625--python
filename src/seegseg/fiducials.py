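"""Planned entry/target fiducial files.

The planning workstation (e.g. 3DSlicer) exports one ASCII file per
implant: ``#``-prefixed comment lines plus ``label,x,y,z`` records, two
records per electrode label -- the planned entry point on the cortical
surface/skull screw and the planned target point deep in the brain, in
millimetres.  Which of the two comes first is not standardised, so the
parser accepts an explicit order or (given the CT volume) infers it from
depth: the record farther from the volume boundary is the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .errors import FiducialParseError
from .geometry import Point3, as_point

if TYPE_CHECKING:  # pragma: no cover
    from .volume import VoxelVolume

__all__ = [
    "PlannedTrajectory",
    "parse_fiducials",
    "write_fiducials",
    "orient_with_volume",
    "map_through_affine",
]


@dataclass
class PlannedTrajectory:
    """One electrode's planned trajectory: unique label, entry E, target T."""

    label: str
    entry: Point3
    target: Point3

    def __post_init__(self):
        self.entry = as_point(self.entry)
        self.target = as_point(self.target)
        if not self.label:
            raise ValueError("trajectory label must be non-empty")
        if np.linalg.norm(self.entry - self.target) < 1e-9:
            raise ValueError(
                f"trajectory {self.label!r}: entry and target coincide"
            )


def parse_fiducials(path, order: str = "entry-first") -> list[PlannedTrajectory]:
    """Parse a fiducial file into one trajectory per electrode label.

    Parameters
    ----------
    path
        Text file of ``label,x,y,z`` records; lines starting with ``#``
        and blank lines are ignored.
    order
        ``"entry-first"`` (default) or ``"target-first"``: which record of
        each label pair is the entry point.  Use
        :func:`orient_with_volume` afterwards to resolve the order from
        depth when it is unknown.

    Raises
    ------
    FiducialParseError
        On malformed lines, labels that do not appear exactly twice, or an
        unreadable file -- silent electrode drops are never allowed.
    """
    if order not in ("entry-first", "target-first"):
        raise ValueError(f"unknown order {order!r}")
    path = Path(path)
    if not path.exists():
        raise FiducialParseError(f"fiducial file not found: {path}")
    records: dict[str, list[np.ndarray]] = {}
    line_of: dict[str, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            raise FiducialParseError(
                f"{path}:{lineno}: expected 'label,x,y,z', got {raw!r}"
            )
        label = parts[0]
        if not label:
            raise FiducialParseError(f"{path}:{lineno}: empty label")
        try:
            point = as_point([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FiducialParseError(f"{path}:{lineno}: {exc}") from exc
        records.setdefault(label, []).append(point)
        line_of.setdefault(label, lineno)
        if len(records[label]) > 2:
            raise FiducialParseError(
                f"{path}:{lineno}: label {label!r} appears more than twice"
            )
    trajectories = []
    for label, points in records.items():
        if len(points) != 2:
            raise FiducialParseError(
                f"{path}:{line_of[label]}: label {label!r} has a single "
                f"record; every electrode needs an entry and a target point"
            )
        first, second = points
        if order == "entry-first":
            trajectories.append(PlannedTrajectory(label, first, second))
        else:
            trajectories.append(PlannedTrajectory(label, second, first))
    return trajectories


def write_fiducials(trajectories: Iterable[PlannedTrajectory], path) -> None:
    """Write trajectories as ``label,x,y,z`` records (entry line first).

    Coordinates are printed with 6 decimals so that
    ``parse(write(parse(f)))`` is the identity on labels and coordinates.
    An empty trajectory list produces a header-comment-only file.
    """
    lines = ["# label,x,y,z (planned entry then target per electrode)"]
    for traj in trajectories:
        for point in (traj.entry, traj.target):
            lines.append(
                f"{traj.label},{point[0]:.6f},{point[1]:.6f},{point[2]:.6f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def orient_with_volume(trajectories: Iterable[PlannedTrajectory],
                       vol: "VoxelVolume") -> list[PlannedTrajectory]:
    """Resolve entry/target order by depth inside the volume.

    For each trajectory the point lying deeper inside the volume's
    physical bounding box (larger minimum distance to any box face) is
    taken as the target; the swap is applied only where the recorded
    order disagrees.
    """
    corners_idx = np.array([[i, j, k] for i in (-0.5, vol.shape[0] - 0.5)
                            for j in (-0.5, vol.shape[1] - 0.5)
                            for k in (-0.5, vol.shape[2] - 0.5)])
    corners = vol.index_to_world(corners_idx)
    lo, hi = corners.min(axis=0), corners.max(axis=0)

    def depth(p: np.ndarray) -> float:
        return float(min(np.min(p - lo), np.min(hi - p)))

    oriented = []
    for traj in trajectories:
        if depth(traj.target) >= depth(traj.entry):
            oriented.append(traj)
        else:
            oriented.append(PlannedTrajectory(traj.label, traj.target,
                                              traj.entry))
    return oriented


def map_through_affine(trajectories: Iterable[PlannedTrajectory],
                       affine) -> list[PlannedTrajectory]:
    """Map fiducials given in voxel-index space into physical mm.

    Implements the ``-r/--noref`` semantics: when the fiducial file is
    not in CT physical space, its coordinates are interpreted as voxel
    indices and pushed through the volume affine.
    """
    affine = np.asarray(affine, dtype=float)
    out = []
    for traj in trajectories:
        entry = affine[:3, :3] @ traj.entry + affine[:3, 3]
        target = affine[:3, :3] @ traj.target + affine[:3, 3]
        out.append(PlannedTrajectory(traj.label, entry, target))
    return out
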