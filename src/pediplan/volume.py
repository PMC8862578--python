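"""CT and label volumes, coordinate transforms, interpolation and distance maps.

All geometry in this package lives in a fixed right-handed, RAS-like world
frame measured in millimetres:

* x: left -> right (across the midline)
* y: posterior -> anterior
* z: caudal -> cranial

Voxel indices are 0-based; the affine maps continuous voxel indices to world
coordinates in mm. Hounsfield units (HU) are taken at face value from the
scan; water is 0 HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

WORLD_FRAME_TAG = "RAS-mm"

#: Integer compartment labels used throughout the package.
LABEL_SCHEME: dict[int, str] = {
    0: "background",
    1: "cortical_shell",
    2: "cancellous_body",
    3: "pedicle_left",
    4: "pedicle_right",
    5: "spinal_canal",
    6: "min_section_roi_left",
    7: "min_section_roi_right",
}

BONE_LABELS = (1, 2, 3, 4)


class VolumeError(ValueError):
    """Raised for structurally invalid volumes or out-of-domain queries."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeError("affine is singular")
    return affine


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass(frozen=True)
class CtVolume:
    """A 3D scalar field of HU values with a voxel->world mapping."""

    data: np.ndarray
    affine: np.ndarray
    world_frame_tag: str = WORLD_FRAME_TAG
    spacing: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise VolumeError(f"expected 3D volume, got {data.ndim}D")
        if not np.all(np.isfinite(data)):
            raise VolumeError("HU values must be finite")
        affine = _check_affine(self.affine)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        spacing = _spacing_from_affine(affine)
        if np.any(spacing <= 0):
            raise VolumeError("voxel spacing must be strictly positive")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "CtVolume":
        return CtVolume(data=data, affine=self.affine,
                        world_frame_tag=self.world_frame_tag)


@dataclass(frozen=True)
class LabelVolume:
    """Integer compartment map aligned voxel-for-voxel with a CtVolume."""

    data: np.ndarray
    affine: np.ndarray
    label_scheme: dict[int, str] = field(default_factory=lambda: dict(LABEL_SCHEME))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"expected 3D label volume, got {data.ndim}D")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise VolumeError("label volume must be integer-valued")
            data = rounded.astype(np.int16)
        affine = _check_affine(self.affine)
        present = set(np.unique(data).tolist())
        unknown = present - set(self.label_scheme)
        if unknown:
            raise VolumeError(f"labels outside the label scheme: {sorted(unknown)}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    def mask(self, labels) -> np.ndarray:
        """Boolean mask of voxels whose label is in ``labels``."""
        labels = np.atleast_1d(labels)
        return np.isin(self.data, labels)

    def check_companion(self, v: CtVolume) -> None:
        if self.shape != v.shape or not np.allclose(self.affine, v.affine):
            raise VolumeError("label volume does not align with CT volume")


@dataclass(frozen=True)
class DistanceMap:
    """Per-voxel Euclidean distance (mm) to the exterior of a mask.

    Distances are voxel-center to voxel-center and respect anisotropic
    spacing; the map is zero outside the mask and positive inside.
    """

    data: np.ndarray
    affine: np.ndarray
    mask_labels: tuple[int, ...]

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated distance at world points (n, 3)."""
        idx = world_to_voxel_grid(self.affine, points)
        return ndimage.map_coordinates(self.data, idx.T, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# coordinate transforms


def voxel_to_world(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices (..., 3) to world mm coordinates."""
    idx = np.asarray(idx, dtype=float)
    return idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def world_to_voxel_grid(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world mm coordinates (..., 3) to continuous voxel indices."""
    inv = np.linalg.inv(np.asarray(affine))
    pts = np.asarray(points, dtype=float)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def world_to_voxel(v: CtVolume | LabelVolume, p: np.ndarray) -> np.ndarray:
    return world_to_voxel_grid(v.affine, p)


def in_grid(v: CtVolume | LabelVolume, points: np.ndarray) -> np.ndarray:
    """True where world points fall inside the voxel-center bounding box."""
    idx = world_to_voxel_grid(v.affine, points)
    idx = np.atleast_2d(idx)
    hi = np.asarray(v.shape) - 1
    return np.all((idx >= -1e-9) & (idx <= hi + 1e-9), axis=-1)


def sample_hu(v: CtVolume, points: np.ndarray) -> np.ndarray | float:
    """Trilinear HU interpolation at world points.

    Accepts a single point (3,) or an array (n, 3). Points outside the grid
    raise: a screw corridor outside the scanned volume is meaningless.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inside = in_grid(v, pts)
    if not np.all(inside):
        bad = pts[~inside][0]
        raise VolumeError(f"point {bad} is outside the scanned grid")
    idx = world_to_voxel_grid(v.affine, pts)
    vals = ndimage.map_coordinates(v.data, idx.T, order=1, mode="nearest")
    if np.asarray(points).ndim == 1:
        return float(vals[0])
    return vals


def sample_labels(l: LabelVolume, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel label lookup at world points (n, 3); -1 off-grid."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = np.rint(world_to_voxel_grid(l.affine, pts)).astype(int)
    out = np.full(len(pts), -1, dtype=int)
    hi = np.asarray(l.shape)
    ok = np.all((idx >= 0) & (idx < hi), axis=1)
    if np.any(ok):
        g = idx[ok]
        out[ok] = l.data[g[:, 0], g[:, 1], g[:, 2]]
    return out


# ---------------------------------------------------------------------------
# distance maps


def distance_map(l: LabelVolume, labels) -> DistanceMap:
    """Euclidean distance transform (mm) of the union of ``labels``.

    The value at each in-mask voxel is the distance from its center to the
    nearest voxel center outside the mask; zero outside the mask.
    """
    labels = tuple(int(x) for x in np.atleast_1d(labels))
    if not labels:
        raise VolumeError("label subset must be nonempty")
    unknown = set(labels) - set(l.label_scheme)
    if unknown:
        raise VolumeError(f"labels not in scheme: {sorted(unknown)}")
    mask = l.mask(labels)
    if not mask.any():
        raise VolumeError(f"mask for labels {labels} is empty")
    dist = ndimage.distance_transform_edt(mask, sampling=l.spacing)
    return DistanceMap(data=dist, affine=l.affine, mask_labels=labels)


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_volume(v: CtVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume to NIfTI; label schemes go to a JSON sidecar."""
    path = Path(path)
    if isinstance(v, LabelVolume):
        img = nib.Nifti1Image(v.data.astype(np.int16), v.affine)
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii[.gz]
        sidecar = Path(str(sidecar) + ".labels.json")
        sidecar.write_text(json.dumps({str(k): n for k, n in v.label_scheme.items()},
                                      indent=2))
    else:
        img = nib.Nifti1Image(v.data, v.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> CtVolume:
    """Load a 3D scalar NIfTI as a CtVolume (HU values unmodified)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise VolumeError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"expected 3D volume, got {data.ndim}D in {path}")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise VolumeError(f"non-finite voxel values in {path}")
    return CtVolume(data=data, affine=np.asarray(img.affine, dtype=float))


def load_labels(path: str | Path) -> LabelVolume:
    """Load an integer label NIfTI; reads the .labels.json sidecar if present."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise VolumeError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"expected 3D label volume, got {data.ndim}D in {path}")
    sidecar = Path(str(Path(path)).replace(".nii.gz", "").replace(".nii", "")
                   + ".labels.json")
    scheme = dict(LABEL_SCHEME)
    if sidecar.exists():
        scheme = {int(k): str(n) for k, n in json.loads(sidecar.read_text()).items()}
    return LabelVolume(data=np.asarray(data), affine=np.asarray(img.affine, float),
                       label_scheme=scheme)
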