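"""Parametric synthetic vertebra CT phantom with an in vitro decalcification model.

The phantom is an idealized lumbar vertebra: an elliptical-cylinder body with
a cortical shell and cancellous interior, a circular spinal canal, a posterior
bone block (lamina/spinous stand-in, the screw entry surface), and two oblique
pedicle cylinders with a mild hourglass waist connecting the block to the
body. Analytic ground truth (midline plane, endplate plane, pedicle axes,
waist centroids) is returned alongside the voxelized volumes, so planner and
geometry code can be tested against closed-form answers.

Decalcification emulates EDTA demineralisation as a uniform multiplicative
attenuation of bone HU toward water (0 HU), resting on the linear CT-BMD
relationship: HU_new = factor * HU for bone voxels, factor 1 = untreated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import Line, Plane
from .volume import BONE_LABELS, CtVolume, LabelVolume, VolumeError

HU_WATER = 0.0


@dataclass(frozen=True)
class CorridorSpec:
    """An optional planted high-HU cylindrical corridor (recovery target)."""

    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius: float = 3.2
    hu_boost: float = 600.0

    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("corridor direction must be nonzero")
        return d / n


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic vertebra.

    Lengths in mm, HU in Hounsfield units. Defaults are sized so that a
    6 mm x 30 mm screw fits through the pedicle with margin, and the HU
    compartments sit on the micro-CT scale of embalmed porcine vertebrae
    (whole-bone mean near 2750 Hu).
    """

    body_half_axes: tuple[float, float] = (18.0, 14.0)
    body_height: float = 30.0
    cortical_thickness: float = 1.5
    pedicle_radius: float = 4.5
    pedicle_length: float = 18.0
    pedicle_convergence_angle: float = 15.0   # axial angle toward midline, deg
    pedicle_waist_fraction: float = 0.15      # waist radius = (1 - f) * radius
    pedicle_body_penetration: float = 6.0     # how deep the pedicle axis ends in the body
    canal_radius: float = 7.0
    canal_clearance: float = 1.5              # pedicle surface to canal surface
    hu_cortical: float = 3100.0
    hu_cancellous_mean: float = 2650.0
    hu_cancellous_sd: float = 60.0
    hu_soft_tissue: float = 30.0
    corridor: Optional[CorridorSpec] = None
    decalcification_factor: float = 1.0
    spacing: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        ax, ay = self.body_half_axes
        for name in ("body_height", "cortical_thickness", "pedicle_radius",
                     "pedicle_length", "canal_radius", "spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if ax <= 0 or ay <= 0:
            raise ValueError("body_half_axes must be positive")
        if self.cortical_thickness >= min(ax, ay):
            raise ValueError("cortical_thickness must be smaller than body_half_axes")
        if self.pedicle_radius >= min(ax, ay):
            raise ValueError("degenerate anatomy: pedicle_radius >= body half axis")
        if not 0.0 <= self.decalcification_factor <= 1.0:
            raise ValueError("decalcification_factor must lie in [0, 1]")
        if not 0.0 <= self.pedicle_waist_fraction < 1.0:
            raise ValueError("pedicle_waist_fraction must lie in [0, 1)")
        if self.hu_cancellous_sd < 0:
            raise ValueError("hu_cancellous_sd must be nonnegative")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Analytic geometry of the generated phantom, in world mm."""

    midline_plane: Plane
    lower_endplate_plane: Plane
    upper_endplate_plane: Plane
    axial_normal: np.ndarray
    pedicle_axes: dict[str, Line]          # side -> axis (posterior -> anterior)
    min_section_centroids: dict[str, np.ndarray]
    min_section_radius: float
    posterior_surface_y: float
    corridor_axis: Optional[Line] = None


def _symmetric_noise(rng: np.random.Generator, shape: tuple[int, int, int],
                     sd: float) -> np.ndarray:
    """i.i.d. Gaussian noise mirrored about the mid-x plane (nx must be odd)."""
    nx, ny, nz = shape
    half = rng.normal(0.0, sd, size=((nx + 1) // 2, ny, nz))
    return np.concatenate([half, half[:-1][::-1]], axis=0)


def _pedicle_geometry(spec: PhantomSpec, side: str):
    """Start point, unit direction and segment length of a pedicle axis."""
    ax, ay = spec.body_half_axes
    alpha = np.deg2rad(spec.pedicle_convergence_angle)
    sign = -1.0 if side == "left" else 1.0
    # direction points anterior and toward the midline
    d = np.array([-sign * np.sin(alpha), np.cos(alpha), 0.0])
    length = spec.pedicle_length
    end_y = -ay + spec.pedicle_body_penetration
    start_y = end_y - length * np.cos(alpha)
    waist_x = sign * (spec.canal_radius + spec.pedicle_radius + spec.canal_clearance)
    start_x = waist_x + sign * (length / 2.0) * np.sin(alpha)
    start = np.array([start_x, start_y, 0.0])
    return start, d, length


def _pedicle_radius_profile(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Hourglass radius along the axis: full at the ends, waist at mid-length."""
    mid = spec.pedicle_length / 2.0
    u = (t - mid) / mid
    return spec.pedicle_radius * (1.0 - spec.pedicle_waist_fraction * (1.0 - u ** 2))


def generate_phantom(spec: PhantomSpec) -> tuple[CtVolume, LabelVolume, PhantomGroundTruth]:
    """Voxelize the synthetic vertebra.

    Returns the HU volume, the compartment label volume and the analytic
    ground truth. Identical spec (including seed) yields bit-identical output.
    """
    ax, ay = spec.body_half_axes
    h = spec.body_height
    sp = spec.spacing

    start_l, dir_l, ped_len = _pedicle_geometry(spec, "left")
    start_r, dir_r, _ = _pedicle_geometry(spec, "right")
    block_back = start_l[1] - 2.0
    block_front = start_l[1] + 3.0
    block_half_width = abs(start_l[0]) + spec.pedicle_radius + 1.0
    block_half_height = min(9.0, h / 2.0 - 1.0)
    canal_center_y = start_l[1] + (ped_len / 2.0) * np.cos(
        np.deg2rad(spec.pedicle_convergence_angle))

    margin = 3.0
    x_half = max(ax, block_half_width) + margin
    y_lo, y_hi = block_back - margin, ay + margin
    z_half = h / 2.0 + margin

    # symmetric x grid (odd voxel count, includes x = 0) for mirror symmetry
    nx_half = int(np.ceil(x_half / sp))
    xs = np.arange(-nx_half, nx_half + 1) * sp
    ys = np.arange(np.floor(y_lo / sp), np.ceil(y_hi / sp) + 1) * sp
    zs = np.arange(-int(np.ceil(z_half / sp)), int(np.ceil(z_half / sp)) + 1) * sp

    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = sp
    affine[:3, 3] = (xs[0], ys[0], zs[0])

    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    rho2 = (X / ax) ** 2 + (Y / ay) ** 2
    body = (rho2 <= 1.0) & (np.abs(Z) <= h / 2.0)
    block = ((np.abs(X) <= block_half_width) & (Y >= block_back)
             & (Y <= block_front) & (np.abs(Z) <= block_half_height))
    canal = ((X ** 2 + (Y - canal_center_y) ** 2 <= spec.canal_radius ** 2)
             & (np.abs(Z) <= h / 2.0))

    shape = (len(xs), len(ys), len(zs))
    sleeve = np.zeros(shape, dtype=bool)      # cortical-HU sleeve of the pedicles
    ped_masks: dict[str, np.ndarray] = {}
    roi_masks: dict[str, np.ndarray] = {}
    for side, start, d in (("left", start_l, dir_l), ("right", start_r, dir_r)):
        vx, vy, vz = X - start[0], Y - start[1], Z - start[2]
        t = vx * d[0] + vy * d[1] + vz * d[2]
        rad2 = (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2
        rprof = _pedicle_radius_profile(spec, np.clip(t, 0.0, ped_len))
        inside = (t >= 0.0) & (t <= ped_len) & (rad2 <= rprof ** 2)
        # the pedicle channel overrides block/body voxels: its cross-section
        # stays a full hourglass disk along the whole axis
        ped_masks[side] = inside & ~canal
        sleeve |= inside & (rad2 >= (rprof - spec.cortical_thickness) ** 2)
        roi_masks[side] = ped_masks[side] & (np.abs(t - ped_len / 2.0) <= sp / 2.0)

    # cortical shells: outer band of the voxelized body/block masks
    labels = np.zeros(shape, dtype=np.int16)
    for mask in (body, block):
        edt = ndimage.distance_transform_edt(mask, sampling=(sp, sp, sp))
        shell = mask & (edt <= spec.cortical_thickness)
        labels[mask] = 2
        labels[shell] = 1
    labels[ped_masks["left"]] = 3
    labels[ped_masks["right"]] = 4
    labels[canal] = 5
    labels[roi_masks["left"]] = 6
    labels[roi_masks["right"]] = 7

    rng = np.random.default_rng(spec.seed)
    noise = _symmetric_noise(rng, shape, spec.hu_cancellous_sd)

    hu = np.full(shape, spec.hu_soft_tissue, dtype=float)
    cancellous_like = np.isin(labels, (2, 3, 4, 6, 7))
    hu[cancellous_like] = spec.hu_cancellous_mean + noise[cancellous_like]
    hu[labels == 1] = spec.hu_cortical
    ped_sleeve = sleeve & np.isin(labels, (3, 4, 6, 7))
    hu[ped_sleeve] = spec.hu_cortical

    if spec.corridor is not None:
        c = spec.corridor
        cd = c.unit_direction()
        vx, vy, vz = X - c.point[0], Y - c.point[1], Z - c.point[2]
        t = vx * cd[0] + vy * cd[1] + vz * cd[2]
        rad2 = (vx - t * cd[0]) ** 2 + (vy - t * cd[1]) ** 2 + (vz - t * cd[2]) ** 2
        in_corridor = rad2 <= c.radius ** 2
        bone = np.isin(labels, BONE_LABELS + (6, 7))
        hu[in_corridor & bone] += c.hu_boost

    ct = CtVolume(data=hu, affine=affine)
    lab = LabelVolume(data=labels, affine=affine)

    truth = PhantomGroundTruth(
        midline_plane=Plane(np.zeros(3), np.array([1.0, 0.0, 0.0])),
        lower_endplate_plane=Plane(np.array([0.0, 0.0, -h / 2.0]),
                                   np.array([0.0, 0.0, 1.0])),
        upper_endplate_plane=Plane(np.array([0.0, 0.0, h / 2.0]),
                                   np.array([0.0, 0.0, 1.0])),
        axial_normal=np.array([0.0, 0.0, 1.0]),
        pedicle_axes={"left": Line(start_l + (ped_len / 2) * dir_l, dir_l),
                      "right": Line(start_r + (ped_len / 2) * dir_r, dir_r)},
        min_section_centroids={"left": start_l + (ped_len / 2) * dir_l,
                               "right": start_r + (ped_len / 2) * dir_r},
        min_section_radius=spec.pedicle_radius * (1 - spec.pedicle_waist_fraction),
        posterior_surface_y=block_back,
        corridor_axis=(Line(np.asarray(spec.corridor.point, float),
                            spec.corridor.unit_direction())
                       if spec.corridor is not None else None),
    )
    if spec.decalcification_factor < 1.0:
        ct = apply_decalcification(ct, lab, spec.decalcification_factor)
    return ct, lab, truth


def default_corridor(spec: PhantomSpec, side: str = "left",
                     tilt_deg: float = 6.0, radius: float = 3.2,
                     hu_boost: float = 600.0) -> CorridorSpec:
    """A corridor anchored at the pedicle waist, tilted cranially.

    The tilt points the corridor toward the upper endplate while keeping it
    threadable through the narrow pedicle waist, so a constrained optimizer
    can recover it.
    """
    start, d, length = _pedicle_geometry(spec, side)
    waist = start + (length / 2.0) * d
    tilt = np.deg2rad(tilt_deg)
    direction = np.array([d[0] * np.cos(tilt), d[1] * np.cos(tilt), np.sin(tilt)])
    return CorridorSpec(point=tuple(waist), direction=tuple(direction),
                        radius=radius, hu_boost=hu_boost)


# ---------------------------------------------------------------------------
# decalcification model


def apply_decalcification(v: CtVolume, l: LabelVolume, factor: float) -> CtVolume:
    """Attenuate bone HU linearly toward water: HU -> factor * (HU - 0) + 0.

    Only bone compartments (cortical shell, cancellous body, both pedicles,
    and the pedicle-waist ROI disks) are affected; soft tissue and canal are
    untouched. factor = 1 is the identity, factor = 0 fully demineralised.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError(f"decalcification factor must lie in [0, 1], got {factor}")
    l.check_companion(v)
    bone = l.mask(BONE_LABELS + (6, 7))
    data = v.data.copy()
    data[bone] = HU_WATER + factor * (data[bone] - HU_WATER)
    return v.with_data(data)


def vertebral_mean_hu(v: CtVolume, l: LabelVolume) -> float:
    """Mean HU over all bone voxels — the whole-vertebra CT value that
    enters the T' densitometry score."""
    l.check_companion(v)
    bone = l.mask(BONE_LABELS + (6, 7))
    if not bone.any():
        raise VolumeError("no bone voxels in label volume")
    return float(v.data[bone].mean())


def calibrate_decalcification(target_t_prime: float, ref_mean: float,
                              ref_sd: float, v: CtVolume, l: LabelVolume) -> float:
    """Closed-form factor so the decalcified vertebra hits a target T' score.

    Because decalcification scales bone HU linearly (water = 0 HU), the mean
    bone HU after attenuation by ``factor`` is factor * mean, and
    T'(factor) = (factor * mean - ref_mean) / ref_sd is invertible.
    """
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    mean = vertebral_mean_hu(v, l)
    if mean <= 0:
        raise ValueError("mean bone HU must be positive to calibrate")
    factor = (ref_mean + target_t_prime * ref_sd) / mean
    if not 0.0 <= factor <= 1.0:
        lo = (HU_WATER - ref_mean) / ref_sd
        hi = (mean - ref_mean) / ref_sd
        raise ValueError(
            f"target T' {target_t_prime} requires factor {factor:.4f} outside "
            f"[0, 1]; feasible T' range is [{lo:.4f}, {hi:.4f}]")
    return float(factor)


def with_corridor(spec: PhantomSpec, **corridor_kwargs) -> PhantomSpec:
    """Convenience: a copy of ``spec`` with a default waist-anchored corridor."""
    return replace(spec, corridor=default_corridor(spec, **corridor_kwargs))
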