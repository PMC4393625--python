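"""Contact-coordinate and mesh output.

Two artefacts per reconstructed implant: a plain-text contact file in the
same ``label,x,y,z`` dialect (and coordinate system) as the input
fiducials, with labels like ``A1`` (electrode letter + 1-based contact
index, 1 = tip); and legacy ASCII VTK polydata of one cylinder per
contact at the contact's real dimensions, aligned to the local electrode
axis, for visual inspection in any VTK-aware viewer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .electrodes import DEFAULT_CONTACT_DIAMETER, DEFAULT_CONTACT_LENGTH
from .segment import SegmentedElectrode, SegmentedImplant

__all__ = ["write_contacts_text", "write_meshes"]


def write_contacts_text(implant: SegmentedImplant, path) -> None:
    """One ``label,x,y,z`` record per contact, tip (contact 1) first."""
    lines = ["# label,x,y,z  (contact centroids, mm; contact 1 = tip)"]
    if np.isfinite(implant.threshold):
        lines.append(f"# threshold S = {implant.threshold:g}")
    for label, reason in sorted(implant.failures.items()):
        lines.append(f"# FAILED {label}: {reason}")
    for elec in implant.electrodes:
        for i, c in enumerate(elec.contacts, start=1):
            lines.append(f"{elec.label}{i},{c[0]:.6f},{c[1]:.6f},{c[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _local_axis_directions(elec: SegmentedElectrode) -> np.ndarray:
    """Unit axis direction at each contact from its neighbours."""
    pts = elec.contacts
    n = len(pts)
    dirs = np.zeros_like(pts)
    if n == 1:
        v = elec.head - elec.tip
        dirs[0] = v / (np.linalg.norm(v) or 1.0)
        return dirs
    for i in range(n):
        a = pts[max(i - 1, 0)]
        b = pts[min(i + 1, n - 1)]
        v = b - a
        dirs[i] = v / np.linalg.norm(v)
    return dirs


def _cylinder_mesh(center, direction, length, radius, facets=24):
    """Triangulated closed cylinder; returns (points, triangles)."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(direction, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    ang = 2.0 * np.pi * np.arange(facets) / facets
    rim = radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    bottom = center - 0.5 * length * direction + rim
    top = center + 0.5 * length * direction + rim
    points = np.vstack([bottom, top,
                        center - 0.5 * length * direction,
                        center + 0.5 * length * direction])
    cb, ct = 2 * facets, 2 * facets + 1
    tris = []
    for i in range(facets):
        j = (i + 1) % facets
        tris.append((i, j, facets + i))            # side
        tris.append((j, facets + j, facets + i))
        tris.append((cb, j, i))                    # bottom cap
        tris.append((ct, facets + i, facets + j))  # top cap
    return points, np.array(tris, dtype=int)


def _write_polydata(path, points: np.ndarray, triangles: np.ndarray,
                    title: str) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
    ]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in points]
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def _electrode_mesh(elec: SegmentedElectrode, length, radius, facets):
    all_pts, all_tris = [], []
    offset = 0
    for center, direction in zip(elec.contacts, _local_axis_directions(elec)):
        pts, tris = _cylinder_mesh(center, direction, length, radius, facets)
        all_pts.append(pts)
        all_tris.append(tris + offset)
        offset += len(pts)
    return np.vstack(all_pts), np.vstack(all_tris)


def write_meshes(implant: SegmentedImplant, path, per_electrode: bool = False,
                 contact_length: float = DEFAULT_CONTACT_LENGTH,
                 contact_diameter: float = DEFAULT_CONTACT_DIAMETER,
                 facets: int = 24) -> list[Path]:
    """Write contact cylinders as legacy ASCII VTK polydata.

    With ``per_electrode`` one ``<stem>_<label>.vtk`` file per electrode
    is written; otherwise a single file holds the whole implant.  Returns
    the written paths.
    """
    path = Path(path)
    radius = contact_diameter / 2.0
    written = []
    if per_electrode:
        for elec in implant.electrodes:
            pts, tris = _electrode_mesh(elec, contact_length, radius, facets)
            out = path.with_name(f"{path.stem}_{elec.label}{path.suffix or '.vtk'}")
            _write_polydata(out, pts, tris, f"seegseg electrode {elec.label}")
            written.append(out)
        return written
    all_pts, all_tris = [], []
    offset = 0
    for elec in implant.electrodes:
        pts, tris = _electrode_mesh(elec, contact_length, radius, facets)
        all_pts.append(pts)
        all_tris.append(tris + offset)
        offset += len(pts)
    if not all_pts:
        raise ValueError("implant has no reconstructed electrodes to mesh")
    _write_polydata(path, np.vstack(all_pts), np.vstack(all_tris),
                    "seegseg implant contacts")
    written.append(path)
    return written
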