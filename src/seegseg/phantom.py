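"""Synthetic post-implant CT phantoms with ground truth, and the
target-displacement robustness experiment.

The generator emulates what the segmentation algorithm actually sees in a
thresholded cone-beam CT of an SEEG implant: anisotropic voxels (default
0.4 x 0.4 x 0.8 mm), cylindrical platinum-iridium contacts (2 mm long,
0.8 mm diameter, 1.5 mm gap), a high-intensity screw blob at each entry
point, a Gaussian metal-artifact blur that merges nearby contacts, and
sub-threshold background noise.  Shafts may be bent (piecewise-linear
axis), may cross, and may share one axis bilaterally.

Ground truth is the *post-blur rasterization centroid* of each contact --
the image mass the algorithm could at best recover -- not the ideal
cylinder center; this separates rasterization error from algorithm error.

The robustness experiment replays the published design: targets are
displaced on target-centered circles perpendicular to the entry-target
axis (radii 1-15 mm, 5 samples per radius) and the reconstruction is
compared against the undisplaced run (error) and against ground truth
(false positives / false negatives per total true contacts).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .electrodes import ElectrodeModel, default_model
from .errors import PhantomSpecError
from .fiducials import PlannedTrajectory, write_fiducials
from .geometry import as_point, unit_vector
from .segment import (
    SegmentationConfig,
    SegmentedImplant,
    segment_implant,
)
from .volume import VoxelVolume

__all__ = [
    "PhantomElectrode",
    "PhantomSpec",
    "PhantomTruth",
    "EvaluationReport",
    "make_phantom",
    "displace_target",
    "evaluate",
    "paired_distances",
    "robustness_runs",
    "summarize_runs",
    "robustness_experiment",
    "straight_implant_spec",
]


@dataclass
class PhantomElectrode:
    """Descriptor of one phantom shaft.

    The shaft is laid out from the tip: the deepest cylinder end sits at
    ``target`` and contact centers follow the (possibly bent) axis toward
    ``entry`` at the catalogue pitch; the screw blob is placed on the
    axis ``entry_gap`` mm beyond the last contact.  ``bend_angle`` bends
    the axis by that many degrees at ``bend_fraction`` of the shaft
    length from the tip, around a perpendicular axis selected by
    ``bend_azimuth``.
    """

    label: str
    entry: np.ndarray
    target: np.ndarray
    model: ElectrodeModel
    bend_angle: float = 0.0      # deg
    bend_fraction: float = 0.5   # of tip-to-screw arclength
    bend_azimuth: float = 0.0    # rad
    entry_gap: float = 3.0       # mm, last contact end to screw center

    def __post_init__(self):
        self.entry = as_point(self.entry)
        self.target = as_point(self.target)


@dataclass
class PhantomSpec:
    """Full description of one synthetic implant volume."""

    shape: tuple[int, int, int] = (180, 140, 100)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.8)
    electrodes: list[PhantomElectrode] = field(default_factory=list)
    blur_sigma: float = 0.4          # mm; merges nearby contacts
    noise_level: float = 300.0       # uniform background in [0, noise_level)
    contact_intensity: float = 10000.0  # pre-blur; post-blur cores ~3900
    screw_intensity: float = 12000.0
    screw_radius: float = 1.5        # mm
    truth_threshold: float = 1600.0  # S used for truth + segmentation
    seed: int = 0
    supersample: int = 3             # per-axis anti-aliasing subsamples

    def __post_init__(self):
        if not self.contact_intensity > self.truth_threshold:
            raise PhantomSpecError("contact intensity must exceed the threshold")
        if not self.noise_level < self.truth_threshold:
            raise PhantomSpecError("noise level must stay below the threshold")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom volume."""

    contacts: dict[str, np.ndarray]          # label -> (N, 3), tip first
    axes: dict[str, np.ndarray]              # label -> axis polyline
    models: dict[str, ElectrodeModel]
    trajectories: list[PlannedTrajectory]    # planned E/T fiducials
    screws: dict[str, np.ndarray]
    spec: PhantomSpec

    @property
    def n_contacts(self) -> int:
        return sum(len(c) for c in self.contacts.values())

    def write(self, base_path) -> None:
        """Write planned fiducials plus a JSON sidecar of truth centroids."""
        base = Path(base_path)
        write_fiducials(self.trajectories, base.with_suffix(".txt"))
        payload = {
            label: {
                "contacts": pts.tolist(),
                "n_contacts": self.models[label].n_contacts,
            }
            for label, pts in self.contacts.items()
        }
        base.with_suffix(".json").write_text(json.dumps(payload, indent=1))


@dataclass
class EvaluationReport:
    """Accuracy and detection-rate summary of one reconstruction."""

    mean_error: float
    sd_error: float
    fp_rate: float
    fn_rate: float
    n_true: int
    n_matched: int
    fp_count: int
    fn_count: int
    errors: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# geometry helpers


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c))


def electrode_geometry(e: PhantomElectrode):
    """Lay out one shaft: contact centers (tip first), per-contact axis
    directions (pointing tip -> head), the axis polyline and screw center."""
    model = e.model
    d = model.spacing
    length = model.contact_length
    n = model.n_contacts
    u0 = unit_vector(e.target, e.entry)  # tip -> head
    a_screw = length + (n - 1) * d + e.entry_gap
    if abs(e.bend_angle) > 1e-9:
        e1, e2 = _perp_basis(u0)
        w = np.cos(e.bend_azimuth) * e1 + np.sin(e.bend_azimuth) * e2
        u1 = _rotate(u0, w, np.radians(e.bend_angle))
        a_bend = e.bend_fraction * a_screw
    else:
        u1, a_bend = u0, np.inf
    bend_point = e.target + a_bend * u0 if np.isfinite(a_bend) else None

    def at(a: float) -> np.ndarray:
        if a <= a_bend:
            return e.target + a * u0
        return bend_point + (a - a_bend) * u1

    centers, dirs = [], []
    for k in range(n):
        a_k = length / 2.0 + k * d
        centers.append(at(a_k))
        dirs.append(u0 if a_k <= a_bend else u1)
    screw = at(a_screw)
    polyline = [e.target]
    if bend_point is not None and 0 < a_bend < a_screw:
        polyline.append(bend_point)
    polyline.append(screw)
    return (np.array(centers), np.array(dirs), np.array(polyline), screw)


# ---------------------------------------------------------------------------
# rasterization


def _subgrid(shape, spacing, lo, hi):
    """Index slices and per-axis physical coordinate arrays covering the
    physical box [lo, hi], clipped to the grid."""
    spacing = np.asarray(spacing)
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int), np.array(shape) - 1)
    if np.any(i0 > i1):
        return None
    slices = tuple(slice(a, b + 1) for a, b in zip(i0, i1))
    axes = [spacing[k] * np.arange(i0[k], i1[k] + 1) for k in range(3)]
    return slices, axes


def _coverage(axes, spacing, inside_fn, supersample: int) -> np.ndarray:
    """Fraction of each voxel inside the solid, by sub-voxel sampling."""
    ss = supersample
    offs1d = (np.arange(ss) + 0.5) / ss - 0.5
    acc = np.zeros(tuple(len(a) for a in axes))
    for ox in offs1d:
        for oy in offs1d:
            for oz in offs1d:
                pts = np.stack(np.meshgrid(
                    axes[0] + ox * spacing[0],
                    axes[1] + oy * spacing[1],
                    axes[2] + oz * spacing[2],
                    indexing="ij"), axis=-1)
                acc += inside_fn(pts)
    return acc / ss ** 3


def _cylinder_coverage(shape, spacing, center, direction, length, radius,
                       supersample):
    margin = np.asarray(spacing)
    half = length / 2.0 + radius
    sub = _subgrid(shape, spacing, center - half - margin, center + half + margin)
    if sub is None:
        raise PhantomSpecError(
            f"cylinder at {np.round(center, 2)} lies outside the grid")

    def inside(pts):
        rel = pts - center
        axial = rel @ direction
        rad2 = np.einsum("...k,...k->...", rel, rel) - axial ** 2
        return (np.abs(axial) <= length / 2.0) & (rad2 <= radius ** 2)

    slices, axes = sub
    return slices, axes, _coverage(axes, spacing, inside, supersample)


def _sphere_coverage(shape, spacing, center, radius, supersample):
    margin = np.asarray(spacing)
    sub = _subgrid(shape, spacing, center - radius - margin,
                   center + radius + margin)
    if sub is None:
        raise PhantomSpecError(
            f"screw at {np.round(center, 2)} lies outside the grid")

    def inside(pts):
        rel = pts - center
        return np.einsum("...k,...k->...", rel, rel) <= radius ** 2

    slices, axes = sub
    return slices, axes, _coverage(axes, spacing, inside, supersample)


def _contact_truth_centroid(shape, spacing, slices, frac, intensity,
                            blur_sigma, threshold) -> np.ndarray:
    """Centroid of one contact's own blurred rasterization (voxels above
    the threshold; falls back to all positive mass for faint contacts)."""
    spacing = np.asarray(spacing)
    pad = np.ceil(4.0 * blur_sigma / spacing).astype(int) + 1
    padded = np.pad(frac * intensity, [(p, p) for p in pad])
    blurred = gaussian_filter(padded, sigma=blur_sigma / spacing)
    sel = blurred > threshold
    if not np.any(sel):
        sel = blurred > 0
    idx = np.argwhere(sel)
    w = blurred[sel]
    origin_idx = np.array([s.start for s in slices]) - pad
    coords = (idx + origin_idx) * spacing
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def make_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Rasterize a phantom volume and its ground truth.

    Deterministic for a fixed spec (the seed drives only the background
    noise).  Raises :class:`PhantomSpecError` if any electrode exits the
    grid.
    """
    labels = [e.label for e in spec.electrodes]
    if len(set(labels)) != len(labels):
        raise PhantomSpecError(f"duplicate electrode labels: {labels}")
    field_arr = np.zeros(spec.shape)
    spacing = np.asarray(spec.spacing)
    truth_contacts: dict[str, np.ndarray] = {}
    truth_axes: dict[str, np.ndarray] = {}
    models: dict[str, ElectrodeModel] = {}
    screws: dict[str, np.ndarray] = {}
    trajectories: list[PlannedTrajectory] = []
    for e in spec.electrodes:
        centers, dirs, polyline, screw = electrode_geometry(e)
        per_contact = []
        for center, direction in zip(centers, dirs):
            slices, _axes, frac = _cylinder_coverage(
                spec.shape, spacing, center, direction,
                e.model.contact_length, e.model.contact_diameter / 2.0,
                spec.supersample)
            np.maximum(field_arr[slices], spec.contact_intensity * frac,
                       out=field_arr[slices])
            per_contact.append(_contact_truth_centroid(
                spec.shape, spacing, slices, frac, spec.contact_intensity,
                spec.blur_sigma, spec.truth_threshold))
        slices, _axes, frac = _sphere_coverage(
            spec.shape, spacing, screw, spec.screw_radius, spec.supersample)
        np.maximum(field_arr[slices], spec.screw_intensity * frac,
                   out=field_arr[slices])
        truth_contacts[e.label] = np.array(per_contact)
        truth_axes[e.label] = polyline
        models[e.label] = e.model
        screws[e.label] = screw
        trajectories.append(PlannedTrajectory(e.label, e.entry, e.target))
    blurred = gaussian_filter(field_arr, sigma=spec.blur_sigma / spacing)
    rng = np.random.default_rng(spec.seed)
    data = blurred + rng.uniform(0.0, spec.noise_level, size=spec.shape)
    vol = VoxelVolume(data, spec.affine)
    truth = PhantomTruth(contacts=truth_contacts, axes=truth_axes,
                         models=models, trajectories=trajectories,
                         screws=screws, spec=spec)
    return vol, truth


# ---------------------------------------------------------------------------
# displacement experiment


def displace_target(entry, target, radius: float, rng) -> np.ndarray:
    """A point at exactly ``radius`` mm from ``target`` on the circle
    perpendicular to the entry-target axis (uniform angle)."""
    entry, target = as_point(entry), as_point(target)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return target.copy()
    u = unit_vector(entry, target)
    e1, e2 = _perp_basis(u)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return target + radius * (np.cos(theta) * e1 + np.sin(theta) * e2)


def evaluate(predicted: SegmentedImplant, truth: PhantomTruth,
             match_tol: float = 1.75) -> EvaluationReport:
    """Match detections to ground-truth contacts and count FP/FN.

    Per electrode label, predictions are greedily matched to the nearest
    unmatched truth contact within ``match_tol`` mm (half the contact
    pitch by default: farther and the detection is ambiguous between
    neighbours).  Unmatched truth contacts count as false negatives,
    unmatched predictions (including whole predicted electrodes without a
    truth counterpart) as false positives; both rates are normalized by
    the total number of true contacts.
    """
    errors = []
    fp = fn = 0
    for label, t_pts in truth.contacts.items():
        elec = predicted.get(label)
        p_pts = elec.contacts if elec is not None else np.zeros((0, 3))
        if len(p_pts) == 0:
            fn += len(t_pts)
            continue
        dist = np.linalg.norm(t_pts[:, None, :] - p_pts[None, :, :], axis=2)
        open_t = np.ones(len(t_pts), bool)
        open_p = np.ones(len(p_pts), bool)
        while True:
            masked = np.where(np.outer(open_t, open_p), dist, np.inf)
            i, j = np.unravel_index(np.argmin(masked), masked.shape)
            if not np.isfinite(masked[i, j]) or masked[i, j] > match_tol:
                break
            errors.append(masked[i, j])
            open_t[i] = open_p[j] = False
        fn += int(open_t.sum())
        fp += int(open_p.sum())
    for elec in predicted.electrodes:
        if elec.label not in truth.contacts:
            fp += elec.n_contacts
    n_true = truth.n_contacts
    err = np.array(errors)
    return EvaluationReport(
        mean_error=float(err.mean()) if err.size else float("nan"),
        sd_error=float(err.std()) if err.size else float("nan"),
        fp_rate=fp / n_true if n_true else 0.0,
        fn_rate=fn / n_true if n_true else 0.0,
        n_true=n_true,
        n_matched=len(errors),
        fp_count=fp,
        fn_count=fn,
        errors=err,
    )


def paired_distances(a: SegmentedImplant, b: SegmentedImplant) -> np.ndarray:
    """Per-contact distances between two reconstructions, paired by
    electrode label and contact index (over the common contact count)."""
    out = []
    for elec in a.electrodes:
        other = b.get(elec.label)
        if other is None:
            continue
        n = min(elec.n_contacts, other.n_contacts)
        if n:
            out.append(np.linalg.norm(elec.contacts[:n] - other.contacts[:n],
                                      axis=1))
    return np.concatenate(out) if out else np.zeros(0)


def _experiment_config(spec: PhantomSpec,
                       config: SegmentationConfig | None) -> SegmentationConfig:
    if config is None:
        config = SegmentationConfig(threshold=spec.truth_threshold)
    elif config.threshold is None:
        config = replace(config, threshold=spec.truth_threshold)
    return config


def robustness_runs(spec: PhantomSpec, radii: Sequence[float],
                    n_samples: int = 5, seed: int = 0,
                    match_tol: float = 1.75,
                    config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Segment one phantom under displaced targets; one row per run.

    Every electrode's target is displaced by the row's radius on the
    perpendicular circle (independent random angles).  Columns report the
    paired per-contact distance to the undisplaced baseline run
    (``error_sum`` / ``n_pairs``) and FP/FN counts against ground truth.
    """
    vol, truth = make_phantom(spec)
    config = _experiment_config(spec, config)
    baseline = segment_implant(vol, truth.trajectories, models=truth.models,
                               config=config)
    rng = np.random.default_rng(seed)
    rows = []
    for radius in radii:
        for sample in range(n_samples):
            displaced = [
                PlannedTrajectory(t.label, t.entry,
                                  displace_target(t.entry, t.target, radius, rng))
                for t in truth.trajectories
            ]
            implant = segment_implant(vol, displaced, models=truth.models,
                                      config=config)
            dists = paired_distances(implant, baseline)
            report = evaluate(implant, truth, match_tol=match_tol)
            rows.append({
                "radius": float(radius),
                "sample": sample,
                "error_mean": float(dists.mean()) if dists.size else np.nan,
                "error_sum": float(dists.sum()),
                "n_pairs": int(dists.size),
                "fp": report.fp_count,
                "fn": report.fn_count,
                "n_true": report.n_true,
            })
    return pd.DataFrame(rows)


def summarize_runs(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-radius summary: pooled mean error, 5th/95th percentiles of the
    per-run mean errors, and FP/FN rates over total true contacts."""
    rows = []
    for radius, grp in runs.groupby("radius"):
        n_pairs = int(grp["n_pairs"].sum())
        rows.append({
            "radius": radius,
            "error_mean": grp["error_sum"].sum() / n_pairs if n_pairs else np.nan,
            "error_p05": float(np.nanpercentile(grp["error_mean"], 5)),
            "error_p95": float(np.nanpercentile(grp["error_mean"], 95)),
            "fp_rate": grp["fp"].sum() / grp["n_true"].sum(),
            "fn_rate": grp["fn"].sum() / grp["n_true"].sum(),
            "n_runs": len(grp),
        })
    return pd.DataFrame(rows).sort_values("radius", ignore_index=True)


def robustness_experiment(spec: PhantomSpec, radii: Sequence[float],
                          n_samples: int = 5, seed: int = 0,
                          match_tol: float = 1.75,
                          config: SegmentationConfig | None = None) -> pd.DataFrame:
    """The displacement experiment on one phantom: per-radius table."""
    runs = robustness_runs(spec, radii, n_samples=n_samples, seed=seed,
                           match_tol=match_tol, config=config)
    return summarize_runs(runs)


# ---------------------------------------------------------------------------
# study-condition cohort


def straight_implant_spec(seed: int = 0, n_electrodes: int = 10,
                          n_contacts_range: tuple[int, int] = (8, 18),
                          tilt_deg: float = 2.0) -> PhantomSpec:
    """One cohort implant: straight shafts on the standard CBCT grid.

    Ten electrodes enter from one face on a 5 x 2 grid of skull
    positions, run roughly along +x with small random tilts (up to
    ``tilt_deg``), and carry 8-18 contacts each -- the implant geometry
    the displacement experiment assumes (non-crossing, one hemisphere).
    """
    if not 1 <= n_electrodes <= 10:
        raise ValueError("cohort implants hold 1-10 electrodes")
    rng = np.random.default_rng(seed)
    ys = [8.0, 18.0, 28.0, 38.0, 48.0]
    zs = [24.0, 56.0]
    positions = [(y, z) for z in zs for y in ys][:n_electrodes]
    electrodes = []
    lo, hi = n_contacts_range
    for label, (y, z) in zip(string.ascii_uppercase, positions):
        n = int(rng.integers(lo, hi + 1))
        model = default_model(n)
        theta = np.radians(rng.uniform(0.0, tilt_deg))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(theta),
                      np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi)])
        entry = np.array([3.0, y, z])
        shaft = 3.0 + model.contact_length + model.span  # entry gap + contacts
        target = entry + shaft * u
        electrodes.append(PhantomElectrode(label=label, entry=entry,
                                           target=target, model=model))
    return PhantomSpec(electrodes=electrodes, seed=seed)
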