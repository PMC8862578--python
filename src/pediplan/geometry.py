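"""Trajectories, the vertebral measurement frame, corridor HU sampling and
the axial/sagittal position measurements.

Measurement conventions (all angles in degrees, distances in mm):

* ``d``   — unsigned axial distance from the screw entry point to the
  vertebral midline plane.
* ``theta`` — angle, in the axial projection, between the screw axis and the
  perpendicular dropped from the entry point to the midline. The abduction
  angle is ``90 - theta``: positive when the screw converges toward the
  midline.
* ``d_prime`` — unsigned sagittal distance from the entry point to the lower
  endplate guideline.
* ``theta_prime`` — angle, in the sagittal projection, between the screw axis
  and the perpendicular from the endplate guideline up to the entry point.
  The craniocaudal inclination is ``theta_prime - 90``: positive for caudal
  tilt, negative for cephalic tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .volume import CtVolume, sample_hu


class GeometryError(ValueError):
    """Raised for degenerate geometric configurations."""


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"{what} must be nonzero")
    return v / n


@dataclass(frozen=True)
class Plane:
    """point + unit normal, world mm."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal, "plane normal"))

    def signed_distance(self, p: np.ndarray):
        d = (np.asarray(p, dtype=float) - self.point) @ self.normal
        return float(d) if np.ndim(d) == 0 else d


@dataclass(frozen=True)
class Line:
    """point + unit direction, world mm."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction, "line direction"))

    def distance_to_point(self, p: np.ndarray) -> float:
        v = np.asarray(p, dtype=float) - self.point
        return float(np.linalg.norm(v - (v @ self.direction) * self.direction))

    def angle_to(self, other: "Line") -> float:
        """Acute angle between the two line directions, degrees."""
        c = abs(float(self.direction @ other.direction))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class Trajectory:
    """A screw corridor: entry point, unit direction, length and diameter."""

    entry: np.ndarray
    direction: np.ndarray
    length: float
    diameter: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise GeometryError("length and diameter must be positive")
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction, "direction"))

    @property
    def tip(self) -> np.ndarray:
        return self.entry + self.length * self.direction

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def axis(self) -> Line:
        return Line(self.entry, self.direction)

    def to_dict(self, side: str | None = None, meta: dict | None = None) -> dict:
        out = {"entry_mm": [float(x) for x in self.entry],
               "direction": [float(x) for x in self.direction],
               "length_mm": float(self.length),
               "diameter_mm": float(self.diameter)}
        if side is not None:
            out["side"] = side
        if meta:
            out["meta"] = meta
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        return cls(entry=np.asarray(d["entry_mm"], float),
                   direction=np.asarray(d["direction"], float),
                   length=float(d["length_mm"]), diameter=float(d["diameter_mm"]))


@dataclass(frozen=True)
class VertebralFrame:
    """Anatomical reference frame for the axial/sagittal measurements.

    The midline normal points left -> right, the endplate normal caudal ->
    cranial, and the axial normal along the craniocaudal axis. ``side`` is
    only consulted when the entry point lies exactly on the midline.
    """

    midline_plane: Plane
    lower_endplate_plane: Plane
    axial_normal: np.ndarray
    side: str = "left"

    def __post_init__(self) -> None:
        object.__setattr__(self, "axial_normal",
                           _unit(self.axial_normal, "axial normal"))
        if self.side not in ("left", "right"):
            raise GeometryError("side must be 'left' or 'right'")

    def anterior_axis(self) -> np.ndarray:
        # right-handed: cranial x left->right = anterior (RAS convention)
        a = np.cross(self.axial_normal, self.midline_plane.normal)
        return _unit(a, "anterior axis")


@dataclass(frozen=True)
class TrajectoryMeasurement:
    """The four primary position measurements plus the derived angles."""

    d: float
    theta: float
    d_prime: float
    theta_prime: float
    abduction: float = field(init=False)
    craniocaudal: float = field(init=False)

    def __post_init__(self) -> None:
        if self.d < 0 or self.d_prime < 0:
            raise GeometryError("distances must be nonnegative")
        object.__setattr__(self, "abduction", 90.0 - self.theta)
        object.__setattr__(self, "craniocaudal", self.theta_prime - 90.0)


@dataclass(frozen=True)
class PlacementError:
    """Signed planned-vs-actual differences: (d1 - d, theta1 - theta)."""

    displacement_error: float
    angle_error: float


# ---------------------------------------------------------------------------
# corridor sampling


def cylinder_samples(t: Trajectory, step_axial: float, rings: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic equal-volume lattice covering the screw cylinder.

    Axial stations are midpoints of ``ceil(length / step_axial)`` equal
    segments. At each station the disk of radius ``diameter / 2`` is split
    into ``rings`` equal-area zones: a central zone represented by the
    centerline point and, for ring j >= 1, an annulus represented by ``8 j``
    points at its equal-area mid radius. Weights sum to one.

    Returns (points (n, 3) world mm, weights (n,)).
    """
    if step_axial <= 0:
        raise GeometryError("step_axial must be positive")
    if rings < 1:
        raise GeometryError("rings must be >= 1")
    n_ax = max(1, int(np.ceil(t.length / step_axial)))
    stations = (np.arange(n_ax) + 0.5) * (t.length / n_ax)

    # orthonormal frame perpendicular to the axis
    d = t.direction
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(d, ref))
    w = np.cross(d, u)

    offsets = [np.zeros(3)]
    weights = [1.0 / rings]
    R = t.radius
    for j in range(1, rings):
        r_j = R * np.sqrt((j + 0.5) / rings)
        n_phi = 8 * j
        phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
        for phi in phis:
            offsets.append(r_j * (np.cos(phi) * u + np.sin(phi) * w))
            weights.append(1.0 / (rings * n_phi))
    offsets = np.asarray(offsets)
    weights = np.asarray(weights)

    pts = (t.entry[None, None, :]
           + stations[:, None, None] * d[None, None, :]
           + offsets[None, :, :]).reshape(-1, 3)
    wts = np.tile(weights / n_ax, n_ax)
    return pts, wts


def mean_ct_value(t: Trajectory, v: CtVolume, step_axial: float | None = None,
                  rings: int = 3, centerline_only: bool = False) -> float:
    """Quadrature-weighted mean HU over the screw corridor.

    By default the mean is taken over the full cylinder volume (the bone the
    screw thread occupies); ``centerline_only`` restricts it to the axis.
    Default resolution: axial step = half the minimum voxel spacing, three
    equal-volume radial zones. Raises if the corridor leaves the scanned grid.
    """
    if step_axial is None:
        step_axial = float(np.min(v.spacing)) / 2.0
    if centerline_only:
        rings = 1
    pts, wts = cylinder_samples(t, step_axial, rings)
    vals = sample_hu(v, pts)
    return float(np.sum(wts * vals))


# ---------------------------------------------------------------------------
# position measurements


def _project(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - (v @ normal) * normal


def _angle_between(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise GeometryError("degenerate projection: screw axis parallel to the "
                            "projection plane normal")
    c = float(a @ b) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _toward_midline(entry: np.ndarray, f: VertebralFrame) -> np.ndarray:
    s = f.midline_plane.signed_distance(entry)
    if abs(s) > 1e-9:
        return -np.sign(s) * f.midline_plane.normal
    return f.midline_plane.normal if f.side == "left" else -f.midline_plane.normal


def measure_trajectory(t: Trajectory, f: VertebralFrame) -> TrajectoryMeasurement:
    """Axial/sagittal position measurements of a trajectory in a frame.

    theta is measured in the axial projection against the entry-to-midline
    perpendicular; theta_prime in the sagittal projection against the
    endplate-to-entry perpendicular (so caudal tilt gives theta_prime > 90).
    """
    d = abs(f.midline_plane.signed_distance(t.entry))
    m_hat = _toward_midline(t.entry, f)
    dir_ax = _project(t.direction, f.axial_normal)
    m_ax = _project(m_hat, f.axial_normal)
    theta = _angle_between(dir_ax, m_ax)

    s_e = f.lower_endplate_plane.signed_distance(t.entry)
    d_prime = abs(s_e)
    e_hat = (np.sign(s_e) if abs(s_e) > 1e-9 else 1.0) * f.lower_endplate_plane.normal
    dir_sag = _project(t.direction, f.midline_plane.normal)
    e_sag = _project(e_hat, f.midline_plane.normal)
    theta_prime = _angle_between(dir_sag, e_sag)
    return TrajectoryMeasurement(d=d, theta=theta, d_prime=d_prime,
                                 theta_prime=theta_prime)


def reconstruct_trajectory(m: TrajectoryMeasurement, entry: np.ndarray,
                           f: VertebralFrame, length: float, diameter: float,
                           tol: float = 1e-6) -> Trajectory:
    """Rebuild a trajectory from its measurements and entry point.

    The direction is composed from the abduction angle (toward the midline)
    and the craniocaudal inclination in the frame's axes; the result is
    validated by re-measurement and rejected if inconsistent.
    """
    m_hat = _toward_midline(np.asarray(entry, float), f)
    a_hat = f.anterior_axis()
    c_hat = f.axial_normal
    alpha = np.deg2rad(m.abduction)
    gamma = np.deg2rad(m.craniocaudal)
    if not (-90.0 < m.abduction < 90.0) or not (-90.0 < m.craniocaudal < 90.0):
        raise GeometryError("angles outside the reconstructible range")
    direction = _unit(np.tan(alpha) * m_hat + a_hat - np.tan(gamma) * c_hat)
    traj = Trajectory(entry=entry, direction=direction,
                      length=length, diameter=diameter)
    check = measure_trajectory(traj, f)
    if (abs(check.theta - m.theta) > tol or abs(check.theta_prime - m.theta_prime) > tol
            or abs(check.d - m.d) > tol or abs(check.d_prime - m.d_prime) > tol):
        raise GeometryError("measurement is inconsistent with the given entry/frame")
    return traj


def placement_error(planned: TrajectoryMeasurement,
                    actual: TrajectoryMeasurement) -> PlacementError:
    """Signed screw placement error: displacement d1 - d, angle theta1 - theta."""
    return PlacementError(displacement_error=actual.d - planned.d,
                          angle_error=actual.theta - planned.theta)


def measurements_to_rows(ms: Iterable[TrajectoryMeasurement]) -> list[dict]:
    """Rows for the measurement CSV (d_mm, theta_deg, ...)."""
    return [{"d_mm": m.d, "theta_deg": m.theta, "d_prime_mm": m.d_prime,
             "theta_prime_deg": m.theta_prime, "abduction_deg": m.abduction,
             "craniocaudal_deg": m.craniocaudal} for m in ms]
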