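"""Trajectory planners: the conventional manual baseline and the CT-value
maximizing automatic search, plus a brute-force enumeration oracle and a
screw-size recommendation heuristic.

The automatic planner solves

    maximize   mean HU over the screw cylinder
    subject to full containment in bone,
               passage through the narrowest-pedicle-section ROI,
               no breach of the anterior vertebral cortex,

with a deterministic two-stage scheme: exhaustive scoring over a grid of
entry points (on the posterior bone surface, within the pedicle's posterior
shadow) and directions (a cone around the pedicle axis), optionally followed
by a pattern-search refinement with step halving. There is no randomness
anywhere in the search; exact objective ties are broken lexicographically by
(entry grid index, direction grid index), so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .constraints import (FeasibilityReport, bone_distance_map,
                          check_anterior_margin, check_containment,
                          check_pedicle_passage, feasible)
from .geometry import (GeometryError, Line, Plane, Trajectory, VertebralFrame,
                       mean_ct_value)
from .volume import (BONE_LABELS, CtVolume, DistanceMap, LabelVolume,
                     VolumeError, sample_labels, voxel_to_world)

STANDARD_DIAMETERS_MM = (4.5, 5.0, 5.5, 6.0, 6.5, 7.0)
STANDARD_LENGTHS_MM = (25.0, 30.0, 35.0, 40.0, 45.0)
FILL_RATIO = 0.8

_SIDE_LABELS = {"left": (3, 6), "right": (4, 7)}


class PlanningError(RuntimeError):
    """Raised when no feasible trajectory exists at the search resolution."""


@dataclass(frozen=True)
class SearchSettings:
    """Grid and refinement parameters of the automatic search."""

    entry_grid_step: float = 1.0          # mm, on the posterior surface patch
    entry_patch_half_extent: float = 3.0  # mm, half extent of the entry patch
    cone_half_angle: float = 20.0         # deg, around the pedicle axis
    angular_step: float = 2.0             # deg
    refine: bool = True
    refine_min_step: float = 0.25         # mm and deg, pattern-search floor
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        if self.entry_grid_step <= 0 or self.angular_step <= 0:
            raise ValueError("grid steps must be positive")
        if not 0 < self.cone_half_angle <= 45:
            raise ValueError("cone_half_angle must lie in (0, 45]")
        if self.refine_min_step <= 0:
            raise ValueError("refine_min_step must be positive")
        if self.tie_break != "lexicographic":
            raise ValueError("only lexicographic tie-breaking is supported")

    def to_dict(self) -> dict:
        return {"entry_grid_step_mm": self.entry_grid_step,
                "entry_patch_half_extent_mm": self.entry_patch_half_extent,
                "cone_half_angle_deg": self.cone_half_angle,
                "angular_step_deg": self.angular_step,
                "refine": self.refine,
                "refine_min_step": self.refine_min_step,
                "tie_break": self.tie_break}


@dataclass(frozen=True)
class PlanResult:
    """A feasible planned trajectory with its score and provenance."""

    trajectory: Trajectory
    mean_hu: float
    feasibility: FeasibilityReport
    evaluations: int
    search_settings: Optional[SearchSettings] = None
    side: str = "left"
    method: str = "auto"

    def to_dict(self) -> dict:
        out = {"trajectory": self.trajectory.to_dict(side=self.side),
               "mean_hu": self.mean_hu,
               "feasibility": self.feasibility.to_dict(),
               "evaluations": self.evaluations,
               "method": self.method}
        if self.search_settings is not None:
            out["search_settings"] = self.search_settings.to_dict()
        return out


@dataclass(frozen=True)
class PedicleSection:
    """The minimal cross-section of a pedicle."""

    plane: Plane
    centroid: np.ndarray
    area: float           # mm^2
    width: float          # minimal caliper width, mm
    axis: Line = field(repr=False, default=None)  # pedicle principal axis


# ---------------------------------------------------------------------------
# pedicle analysis


def _pedicle_mask_coords(l: LabelVolume, side: str) -> np.ndarray:
    labels = _SIDE_LABELS[side]
    mask = l.mask(labels)
    if not mask.any():
        raise VolumeError(f"pedicle labels {labels} are empty")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]
    if n_comp != 1:
        raise VolumeError(f"{side} pedicle label is disconnected "
                          f"({n_comp} components)")
    idx = np.argwhere(mask)
    return voxel_to_world(l.affine, idx)


def pedicle_principal_axis(l: LabelVolume, side: str) -> Line:
    """Principal direction of the pedicle voxel cloud, oriented anteriorly."""
    pts = _pedicle_mask_coords(l, side)
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    axis = vt[0]
    if axis[1] < 0:  # world frame: +y is anterior
        axis = -axis
    return Line(center, axis)


def find_min_pedicle_section(l: LabelVolume, side: str) -> PedicleSection:
    """Sweep cutting planes along the pedicle axis for the minimal section.

    Stations are spaced at half-voxel steps; the cross-sectional area at a
    station is estimated from the voxels inside a two-voxel-thick slab. Ties
    in area are broken toward the station closest to pedicle mid-length.
    """
    pts = _pedicle_mask_coords(l, side)
    axis = pedicle_principal_axis(l, side)
    s = (pts - axis.point) @ axis.direction
    sp = float(np.min(l.spacing))
    half_thick = sp
    s_lo, s_hi = float(s.min()) + half_thick, float(s.max()) - half_thick
    if s_hi <= s_lo:
        raise VolumeError("pedicle label too thin to sweep")
    stations = np.arange(s_lo, s_hi + 1e-9, sp / 2.0)
    voxel_volume = float(np.prod(l.spacing))
    counts = np.array([(np.abs(s - st) <= half_thick).sum() for st in stations])
    areas = counts * voxel_volume / (2.0 * half_thick)
    mid = 0.5 * (float(s.min()) + float(s.max()))
    best = np.flatnonzero(counts == counts.min())
    best_i = best[np.argmin(np.abs(stations[best] - mid))]
    st = stations[best_i]
    slab = pts[np.abs(s - st) <= half_thick]
    centroid = slab.mean(axis=0)
    # minimal caliper width of the slab projected into the cutting plane
    d = axis.direction
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    proj = np.stack([(slab - centroid) @ u, (slab - centroid) @ w], axis=1)
    widths = []
    for ang in np.deg2rad(np.arange(0, 180, 2)):
        e = np.array([np.cos(ang), np.sin(ang)])
        p = proj @ e
        widths.append(p.max() - p.min() + sp)  # +sp: voxel footprint
    return PedicleSection(plane=Plane(centroid, d), centroid=centroid,
                          area=float(areas[best_i]), width=float(min(widths)),
                          axis=axis)


# ---------------------------------------------------------------------------
# entry surface ray casting


def _cast_to_surface(l: LabelVolume, origin: np.ndarray, direction: np.ndarray,
                     max_dist: float = 60.0) -> Optional[np.ndarray]:
    """First bone-surface point hit marching from ``origin`` along ``direction``.

    Returns the sub-voxel bisected transition point, or None if the ray never
    enters bone inside the grid.
    """
    step = float(np.min(l.spacing)) / 4.0
    ss = np.arange(0.0, max_dist, step)
    pts = origin[None, :] + ss[:, None] * direction[None, :]
    labs = sample_labels(l, pts)
    bone = np.isin(labs, BONE_LABELS + (6, 7))
    hits = np.flatnonzero(bone)
    if hits.size == 0:
        return None
    i = int(hits[0])
    if i == 0:
        return pts[0]
    lo, hi = ss[i - 1], ss[i]
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        p = origin + mid * direction
        if int(sample_labels(l, p[None, :])[0]) in BONE_LABELS + (6, 7):
            hi = mid
        else:
            lo = mid
    return origin + hi * direction


def _posterior_entry(l: LabelVolume, anchor: np.ndarray,
                     direction: np.ndarray) -> Optional[np.ndarray]:
    """Posterior bone-surface point of the line through ``anchor``."""
    origin = anchor - 60.0 * direction
    return _cast_to_surface(l, origin, direction, max_dist=65.0)


# ---------------------------------------------------------------------------
# manual baseline


def estimate_frame(l: LabelVolume, side: str) -> VertebralFrame:
    """Vertebral frame estimated from the label volume alone.

    Midline: the sagittal plane through the centroid of body + canal labels;
    lower endplate: the axial plane at the inferior extent of the cancellous
    body (shifted inward by the voxel size). Assumes the fixed RAS-like world
    orientation of this package.
    """
    body = l.mask((1, 2, 5))
    if not body.any():
        raise VolumeError("no body/canal labels to estimate a frame from")
    pts = voxel_to_world(l.affine, np.argwhere(body))
    center = pts.mean(axis=0)
    z_low = float(pts[:, 2].min()) + float(np.min(l.spacing))
    return VertebralFrame(
        midline_plane=Plane(np.array([center[0], center[1], 0.0]),
                            np.array([1.0, 0.0, 0.0])),
        lower_endplate_plane=Plane(np.array([center[0], center[1], z_low]),
                                   np.array([0.0, 0.0, 1.0])),
        axial_normal=np.array([0.0, 0.0, 1.0]),
        side=side)


def plan_manual(v: CtVolume, l: LabelVolume, f: VertebralFrame, side: str,
                length: float = 30.0, diameter: float = 6.0) -> PlanResult:
    """Conventional manual planning baseline.

    The trajectory passes through the midpoint of the minimal pedicle
    section, along the pedicle principal axis projected parallel to the
    lower endplate; the entry point is where that line meets the posterior
    bone surface.
    """
    l.check_companion(v)
    section = find_min_pedicle_section(l, side)
    n_e = f.lower_endplate_plane.normal
    axis = section.axis.direction
    proj = axis - (axis @ n_e) * n_e
    if np.linalg.norm(proj) < 1e-6:
        raise GeometryError("pedicle axis is perpendicular to the endplate; "
                            "endplate-parallel projection is degenerate")
    direction = proj / np.linalg.norm(proj)
    entry = _posterior_entry(l, section.centroid, direction)
    if entry is None:
        raise PlanningError("no posterior surface intersection for the manual line")
    traj = Trajectory(entry=entry, direction=direction,
                      length=length, diameter=diameter)
    report = feasible(traj, l, side)
    hu = mean_ct_value(traj, v)
    return PlanResult(trajectory=traj, mean_hu=hu, feasibility=report,
                      evaluations=1, side=side, method="manual")


# ---------------------------------------------------------------------------
# automatic search


def _search_basis(seed_dir: np.ndarray, axial_normal: np.ndarray):
    u = np.cross(seed_dir, axial_normal)
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise GeometryError("pedicle axis parallel to the craniocaudal axis")
    u /= nu
    w = np.cross(seed_dir, u)
    return u, w


def _direction_grid(settings: SearchSettings) -> list[tuple[float, float]]:
    n = int(np.floor(settings.cone_half_angle / settings.angular_step))
    vals = np.arange(-n, n + 1) * settings.angular_step
    out = []
    for au in vals:
        for av in vals:
            if au * au + av * av <= settings.cone_half_angle ** 2 + 1e-9:
                out.append((float(au), float(av)))
    return out


def _entry_grid(settings: SearchSettings) -> list[tuple[float, float]]:
    n = int(np.floor(settings.entry_patch_half_extent / settings.entry_grid_step))
    vals = np.arange(-n, n + 1) * settings.entry_grid_step
    return [(float(du), float(dv)) for du in vals for dv in vals]


def _make_direction(seed_dir, u, w, au: float, av: float) -> np.ndarray:
    d = (seed_dir + np.tan(np.deg2rad(au)) * u + np.tan(np.deg2rad(av)) * w)
    return d / np.linalg.norm(d)


class _CandidateFactory:
    """Builds and scores candidate trajectories for one (volume, side)."""

    def __init__(self, v: CtVolume, l: LabelVolume, f: VertebralFrame,
                 side: str, length: float, diameter: float,
                 settings: SearchSettings, dmap: DistanceMap):
        l.check_companion(v)
        self.v, self.l, self.f = v, l, f
        self.side, self.length, self.diameter = side, length, diameter
        self.settings, self.dmap = settings, dmap
        section = find_min_pedicle_section(l, side)
        self.seed_dir = section.axis.direction
        self.anchor = section.centroid
        self.u, self.w = _search_basis(self.seed_dir, f.axial_normal)
        base = _posterior_entry(l, self.anchor, self.seed_dir)
        if base is None:
            raise PlanningError("pedicle axis does not meet the posterior surface")
        self.base_entry = base
        self.scored = 0

    def entry_at(self, du: float, dv: float) -> Optional[np.ndarray]:
        anchor = self.anchor + du * self.u + dv * self.w
        return _posterior_entry(self.l, anchor, self.seed_dir)

    def trajectory(self, du: float, dv: float, au: float, av: float
                   ) -> Optional[Trajectory]:
        entry = self.entry_at(du, dv)
        if entry is None:
            return None
        direction = _make_direction(self.seed_dir, self.u, self.w, au, av)
        return Trajectory(entry=entry, direction=direction,
                          length=self.length, diameter=self.diameter)

    def evaluate(self, traj: Trajectory) -> Optional[float]:
        """Mean corridor HU if feasible, else None."""
        try:
            contained, _ = check_containment(traj, self.l, dmap=self.dmap)
            if not contained:
                return None
            if not check_pedicle_passage(traj, self.l, self.side):
                return None
            safe, _ = check_anterior_margin(traj, self.l, dmap=self.dmap)
            if not safe:
                return None
            hu = mean_ct_value(traj, self.v)
        except VolumeError:
            return None
        self.scored += 1
        return hu


def _grid_stage(factory: _CandidateFactory
                ) -> tuple[Optional[tuple], Optional[Trajectory], float]:
    """Exhaustive scoring over the (entry x direction) grid.

    Returns (best (du, dv, au, av), best trajectory, best score). Strictly
    greater scores win, so the first-visited candidate wins exact ties —
    lexicographic in (entry index, direction index).
    """
    settings = factory.settings
    entries = _entry_grid(settings)
    dirs = _direction_grid(settings)
    best_params, best_traj, best_hu = None, None, -np.inf
    for du, dv in entries:
        entry = factory.entry_at(du, dv)
        if entry is None:
            continue
        for au, av in dirs:
            direction = _make_direction(factory.seed_dir, factory.u,
                                        factory.w, au, av)
            traj = Trajectory(entry=entry, direction=direction,
                              length=factory.length, diameter=factory.diameter)
            hu = factory.evaluate(traj)
            if hu is not None and hu > best_hu:
                best_params, best_traj, best_hu = (du, dv, au, av), traj, hu
    return best_params, best_traj, best_hu


def _pattern_search(factory: _CandidateFactory, params: tuple,
                    traj: Trajectory, hu: float,
                    max_iter: int = 400) -> tuple[Trajectory, float]:
    """Deterministic compass search over (entry du, dv; direction au, av)."""
    settings = factory.settings
    step_mm = settings.entry_grid_step / 2.0
    step_deg = settings.angular_step / 2.0
    du, dv, au, av = params
    it = 0
    while (step_mm >= settings.refine_min_step
           or step_deg >= settings.refine_min_step) and it < max_iter:
        it += 1
        moves = [(step_mm, 0, 0, 0), (-step_mm, 0, 0, 0),
                 (0, step_mm, 0, 0), (0, -step_mm, 0, 0),
                 (0, 0, step_deg, 0), (0, 0, -step_deg, 0),
                 (0, 0, 0, step_deg), (0, 0, 0, -step_deg)]
        improved = False
        for ddu, ddv, dau, dav in moves:
            cau, cav = au + dau, av + dav
            if cau * cau + cav * cav > settings.cone_half_angle ** 2 + 1e-9:
                continue
            cand = factory.trajectory(du + ddu, dv + ddv, cau, cav)
            if cand is None:
                continue
            score = factory.evaluate(cand)
            if score is not None and score > hu:
                du, dv, au, av = du + ddu, dv + ddv, cau, cav
                traj, hu = cand, score
                improved = True
                break
        if not improved:
            step_mm /= 2.0
            step_deg /= 2.0
    return traj, hu


def plan_auto(v: CtVolume, l: LabelVolume, f: VertebralFrame, side: str,
              length: float = 30.0, diameter: float = 6.0,
              settings: SearchSettings | None = None) -> PlanResult:
    """Find the feasible trajectory maximizing mean corridor HU.

    Stage 1 scores every candidate on the entry/direction grid; stage 2
    (``settings.refine``) runs a pattern search with step halving down to
    ``refine_min_step``, rejecting infeasible moves. Raises PlanningError if
    the grid contains no feasible candidate.
    """
    settings = settings or SearchSettings()
    dmap = bone_distance_map(l)
    factory = _CandidateFactory(v, l, f, side, length, diameter, settings, dmap)
    params, traj, hu = _grid_stage(factory)
    if traj is None:
        raise PlanningError(
            "no feasible trajectory at this grid resolution; try a finer "
            "entry/angular step or a smaller screw")
    if settings.refine:
        traj, hu = _pattern_search(factory, params, traj, hu)
    report = feasible(traj, l, side)
    return PlanResult(trajectory=traj, mean_hu=hu, feasibility=report,
                      evaluations=factory.scored, search_settings=settings,
                      side=side, method="auto")


def brute_force_plan(v: CtVolume, l: LabelVolume, f: VertebralFrame, side: str,
                     length: float = 30.0, diameter: float = 6.0,
                     settings: SearchSettings | None = None,
                     max_candidates: int = 200_000) -> PlanResult:
    """Exhaustive enumeration oracle over the same candidate set as stage 1.

    Builds the full candidate list, scores every feasible member and takes
    the argmax under the shared lexicographic tie rule. Intended for coarse
    grids (guarded by ``max_candidates``).
    """
    settings = settings or SearchSettings(refine=False)
    n_cand = len(_entry_grid(settings)) * len(_direction_grid(settings))
    if n_cand > max_candidates:
        raise ValueError(f"{n_cand} candidates exceed the enumeration guard")
    dmap = bone_distance_map(l)
    factory = _CandidateFactory(v, l, f, side, length, diameter, settings, dmap)
    scores: list[float] = []
    trajs: list[Optional[Trajectory]] = []
    for du, dv in _entry_grid(settings):
        entry = factory.entry_at(du, dv)
        for au, av in _direction_grid(settings):
            if entry is None:
                scores.append(-np.inf)
                trajs.append(None)
                continue
            direction = _make_direction(factory.seed_dir, factory.u,
                                        factory.w, au, av)
            traj = Trajectory(entry=entry, direction=direction,
                              length=length, diameter=diameter)
            hu = factory.evaluate(traj)
            scores.append(-np.inf if hu is None else hu)
            trajs.append(traj)
    scores_arr = np.asarray(scores)
    if not np.any(np.isfinite(scores_arr)):
        raise PlanningError("no feasible candidate in the enumeration")
    best = int(np.argmax(scores_arr))  # first max: lexicographic tie rule
    traj = trajs[best]
    report = feasible(traj, l, side)
    return PlanResult(trajectory=traj, mean_hu=float(scores_arr[best]),
                      feasibility=report, evaluations=factory.scored,
                      search_settings=settings, side=side, method="brute_force")


# ---------------------------------------------------------------------------
# screw size recommendation


def recommend_screw(l: LabelVolume, side: str) -> tuple[float, float]:
    """Recommend (diameter, length) in mm from pedicle and chord geometry.

    Heuristic: the largest standard diameter not exceeding 80% of the
    minimal pedicle caliper width, and the largest standard length not
    exceeding 80% of the bone chord from the posterior surface through the
    min-section midpoint to the anterior inner cortex along the pedicle axis.
    """
    section = find_min_pedicle_section(l, side)
    max_d = FILL_RATIO * section.width
    diameters = [d for d in STANDARD_DIAMETERS_MM if d <= max_d]
    if not diameters:
        raise PlanningError(f"no admissible diameter: 0.8 x width = {max_d:.2f} mm "
                            f"is below the smallest standard size")
    axis = section.axis.direction
    entry = _posterior_entry(l, section.centroid, axis)
    if entry is None:
        raise PlanningError("pedicle axis does not meet the posterior surface")
    # march anteriorly from the centroid to the inner edge of the anterior cortex
    step = float(np.min(l.spacing)) / 4.0
    ss = np.arange(0.0, 80.0, step)
    pts = section.centroid[None, :] + ss[:, None] * axis[None, :]
    labs = sample_labels(l, pts)
    bone = np.isin(labs, BONE_LABELS + (6, 7))
    run_end = int(np.argmin(bone)) if not bone.all() else len(bone)
    cancellous = np.flatnonzero(labs[:run_end] == 2)
    if cancellous.size == 0:
        raise PlanningError("pedicle axis never reaches cancellous body")
    inner_cortex_s = ss[int(cancellous[-1])]
    chord = inner_cortex_s + float(np.linalg.norm(section.centroid - entry))
    max_l = FILL_RATIO * chord
    lengths = [x for x in STANDARD_LENGTHS_MM if x <= max_l]
    if not lengths:
        raise PlanningError(f"no admissible length: 0.8 x chord = {max_l:.2f} mm "
                            f"is below the smallest standard size")
    return max(diameters), max(lengths)
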