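"""Feasibility of a screw trajectory: containment in bone, passage through the
narrowest pedicle section, and no breach of the anterior vertebral cortex.

Containment is decided by thresholding the Euclidean distance map of the bone
mask along the screw centerline: the corridor is contained when every checked
centerline station keeps at least one screw radius (plus an optional safety
margin) of bone around it. A short segment behind the entry point is excluded
from the check — the screw necessarily crosses the posterior cortical surface
there, and the physical breach of interest is the shaft leaving bone beyond
the entry, not the entry hole itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Trajectory, cylinder_samples
from .volume import (BONE_LABELS, DistanceMap, LabelVolume, VolumeError,
                     distance_map, in_grid, sample_labels)

#: fraction of the screw diameter skipped at the entry end of the centerline
ENTRY_INSET_DIAMETERS = 0.75

_ROI_LABEL = {"left": 6, "right": 7}
_PEDICLE_LABEL = {"left": 3, "right": 4}


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of the three safety checks for one trajectory."""

    contained: bool
    containment_margin: float
    passes_pedicle_roi: bool
    anterior_safe: bool
    anterior_clearance: float

    @property
    def feasible(self) -> bool:
        return self.contained and self.passes_pedicle_roi and self.anterior_safe

    def to_dict(self) -> dict:
        return {"contained": self.contained,
                "containment_margin_mm": self.containment_margin,
                "passes_pedicle_roi": self.passes_pedicle_roi,
                "anterior_safe": self.anterior_safe,
                "anterior_clearance_mm": self.anterior_clearance,
                "feasible": self.feasible}


def bone_distance_map(l: LabelVolume) -> DistanceMap:
    """Distance map of the full bone mask (cortical, cancellous, pedicles,
    waist ROI disks)."""
    return distance_map(l, BONE_LABELS + (6, 7))


def _centerline_stations(t: Trajectory, spacing: np.ndarray,
                         entry_inset: float) -> np.ndarray:
    step = float(np.min(spacing)) / 2.0
    start = min(entry_inset, t.length)
    n = max(2, int(np.ceil((t.length - start) / step)) + 1)
    s = np.linspace(start, t.length, n)
    return t.entry[None, :] + s[:, None] * t.direction[None, :]


def check_containment(t: Trajectory, l: LabelVolume,
                      safety_margin: float = 0.0,
                      dmap: DistanceMap | None = None,
                      entry_inset: float | None = None) -> tuple[bool, float]:
    """Is the screw cylinder fully surrounded by bone?

    Samples the centerline at half-voxel steps (beyond the entry inset,
    default 0.75 screw diameters) and interpolates the bone distance map;
    contained iff min distance >= radius + safety_margin. Returns
    (contained, margin) with margin = min distance - radius - safety_margin;
    boundary equality counts as contained.
    """
    if dmap is None:
        dmap = bone_distance_map(l)
    if entry_inset is None:
        entry_inset = ENTRY_INSET_DIAMETERS * t.diameter
    pts = _centerline_stations(t, l.spacing, entry_inset)
    if not np.all(in_grid(l, pts)):
        raise VolumeError("trajectory centerline exits the scanned grid")
    dmin = float(dmap.sample(pts).min())
    margin = dmin - t.radius - safety_margin
    return margin >= 0.0, margin


def check_pedicle_passage(t: Trajectory, l: LabelVolume, side: str,
                          step_axial: float | None = None,
                          rings: int = 3) -> bool:
    """Does the screw cylinder intersect the narrowest-pedicle-section ROI?"""
    roi = _ROI_LABEL[side]
    if not l.mask(roi).any():
        raise VolumeError(f"ROI label {roi} ({side}) is empty")
    if step_axial is None:
        step_axial = float(np.min(l.spacing)) / 2.0
    pts, _ = cylinder_samples(t, step_axial, rings)
    return bool(np.any(sample_labels(l, pts) == roi))


def check_anterior_margin(t: Trajectory, l: LabelVolume,
                          safety_margin: float = 0.0,
                          dmap: DistanceMap | None = None) -> tuple[bool, float]:
    """Does the screw tip stay clear of the anterior vertebral cortex?

    Safe iff the tip lies inside the vertebral body (cortical shell or
    cancellous label) and its distance to the bone exterior covers the screw
    radius. Returns (safe, clearance) with clearance = tip distance - radius
    - safety_margin.
    """
    if dmap is None:
        dmap = bone_distance_map(l)
    tip = t.tip
    if not bool(in_grid(l, tip[None, :])[0]):
        raise VolumeError("screw tip lies outside the scanned grid")
    tip_label = int(sample_labels(l, tip[None, :])[0])
    tip_dist = float(dmap.sample(tip[None, :])[0])
    clearance = tip_dist - t.radius - safety_margin
    safe = tip_label in (1, 2) and clearance >= 0.0
    return safe, clearance


def feasible(t: Trajectory, l: LabelVolume, side: str,
             safety_margin: float = 0.0,
             dmap: DistanceMap | None = None) -> FeasibilityReport:
    """Aggregate the three safety checks into a FeasibilityReport.

    Structural errors (missing labels, corridor off-grid) propagate; a merely
    unsafe trajectory never raises.
    """
    if dmap is None:
        dmap = bone_distance_map(l)
    contained, margin = check_containment(t, l, safety_margin, dmap)
    passes = check_pedicle_passage(t, l, side)
    safe, clearance = check_anterior_margin(t, l, safety_margin, dmap)
    return FeasibilityReport(contained=contained, containment_margin=margin,
                             passes_pedicle_roi=passes, anterior_safe=safe,
                             anterior_clearance=clearance)


def voxelized_containment_oracle(t: Trajectory, l: LabelVolume,
                                 entry_inset: float | None = None) -> bool:
    """Brute-force containment check kept as an independent cross-check.

    Classifies every voxel whose center lies within one screw radius of the
    (inset) centerline segment and demands that all of them are bone. Slower
    than the distance-map route but free of interpolation.
    """
    if entry_inset is None:
        entry_inset = ENTRY_INSET_DIAMETERS * t.diameter
    bone = l.mask(BONE_LABELS + (6, 7))
    idx = np.argwhere(np.ones(l.shape, dtype=bool))
    # voxel centers in world mm
    centers = idx @ l.affine[:3, :3].T + l.affine[:3, 3]
    a = t.entry + entry_inset * t.direction
    seg = t.length - entry_inset
    v = centers - a
    s = np.clip(v @ t.direction, 0.0, seg)
    closest = a[None, :] + s[:, None] * t.direction[None, :]
    dist = np.linalg.norm(centers - closest, axis=1)
    inside = dist <= t.radius
    return bool(np.all(bone.reshape(-1)[inside]))
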