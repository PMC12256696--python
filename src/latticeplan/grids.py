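"""Raster types and geometry shared by every pipeline stage.

Conventions
-----------
* Voxel arrays are indexed ``(i, j, k)`` = ``(x, y, z)`` with ``z`` the axial
  slice index; indices are 0-based.
* Physical coordinates are millimetres in patient LPS; the ``origin`` is the
  position of the *center* of voxel ``(0, 0, 0)``, so voxel ``(i, j, k)`` sits
  at ``origin + (i, j, k) * spacing``.
* Displacement fields are stored in millimetres on the fixed-image grid; a
  zero field makes :func:`warp` the identity.
* Every out-of-bounds sample of a CT-like image takes air, ``-1024`` HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

AIR_HU = -1024.0
HU_MIN = -1024.0
HU_MAX = 3071.0

__all__ = [
    "AIR_HU",
    "HU_MIN",
    "HU_MAX",
    "ImageVolume",
    "BinaryMask",
    "DoseGrid",
    "DeformationField",
    "RigidTransform",
    "resample_to_shape",
    "warp",
    "apply_rigid",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "read_dvf",
    "write_dvf",
]


def _as_triple(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass
class _Grid:
    """Shared grid contract: spacing (mm/voxel) and origin (mm, LPS)."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.spacing)) or not np.all(np.isfinite(self.origin)):
            raise ValueError("spacing and origin must be finite")

    @property
    def shape(self) -> tuple:
        return tuple(self.voxels.shape[:3])

    def same_grid(self, other: "_Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center positions in mm."""
        idx = np.indices(self.shape, dtype=float)
        return np.moveaxis(idx, 0, -1) * self.spacing + self.origin

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    @property
    def center_mm(self) -> np.ndarray:
        """Physical center of the grid (mm)."""
        return self.origin + (np.array(self.shape, dtype=float) - 1.0) / 2.0 * self.spacing

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ImageVolume(_Grid):
    """3D scalar grid of Hounsfield units; the common currency of dCT/pCT/sCT."""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("ImageVolume voxels must be 3D")
        super().__post_init__()

    def clipped(self) -> "ImageVolume":
        """Clip HU to the CT range [-1024, 3071]."""
        return replace(self, voxels=np.clip(self.voxels, HU_MIN, HU_MAX))


@dataclass
class BinaryMask(_Grid):
    """3D {0,1} structure mask on the same grid contract as ImageVolume."""

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("BinaryMask voxels must be 3D")
        if not np.isin(np.unique(v), (0, 1)).all():
            raise ValueError("mask voxels must be 0 or 1")
        self.voxels = v.astype(np.uint8)
        super().__post_init__()

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_mm3 / 1000.0

    def astype_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


@dataclass
class DoseGrid(_Grid):
    """3D dose distribution in cGy, aligned to an ImageVolume grid."""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("DoseGrid voxels must be 3D")
        if np.any(self.voxels < 0):
            raise ValueError("dose values must be non-negative")
        super().__post_init__()


@dataclass
class DeformationField(_Grid):
    """Per-voxel displacement (mm), defined on the fixed-image grid.

    ``voxels`` has shape ``(nx, ny, nz, 3)``; component order matches the
    ``(x, y, z)`` index order. A zero field makes :func:`warp` the identity.
    """

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4 or self.voxels.shape[3] != 3:
            raise ValueError("DeformationField voxels must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("displacement must be finite")
        super().__post_init__()

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.voxels, axis=-1)


@dataclass
class RigidTransform:
    """6-parameter rigid map: Euler rotation (deg, about the grid center) + translation (mm).

    The transform defines the *sampling* map of :func:`apply_rigid`: the output
    image at physical point ``p`` takes the input's value at
    ``R (p - c) + c + t`` where ``c`` is the grid center. Rotations are applied
    in x, y, z order (extrinsic).
    """

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation_deg = _as_triple(self.rotation_deg)
        self.translation_mm = _as_triple(self.translation_mm)
        if not (np.all(np.isfinite(self.rotation_deg)) and np.all(np.isfinite(self.translation_mm))):
            raise ValueError("rigid parameters must be finite")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix Rz @ Ry @ Rx."""
        ax, ay, az = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def map_points(self, points_mm: np.ndarray, center_mm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_mm, dtype=float)
        return (p - center_mm) @ self.matrix.T + center_mm + self.translation_mm

    def inverse(self) -> "RigidTransform":
        """Transform whose point map inverts this one (about the same center)."""
        rinv = self.matrix.T
        # p' = R(p-c)+c+t  =>  p = R^T (p'-c-t) + c; express as rotation+translation
        ax = np.rad2deg(np.arctan2(rinv[2, 1], rinv[2, 2]))
        ay = np.rad2deg(np.arcsin(np.clip(-rinv[2, 0], -1, 1)))
        az = np.rad2deg(np.arctan2(rinv[1, 0], rinv[0, 0]))
        tinv = -rinv @ self.translation_mm
        return RigidTransform(np.array([ax, ay, az]), tinv)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.translation_mm, self.rotation_deg])

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, dtype=float).reshape(6)
        return cls(rotation_deg=p[3:], translation_mm=p[:3])

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


# ---------------------------------------------------------------------------
# resampling / warping
# ---------------------------------------------------------------------------


def resample_to_shape(v, target_shape):
    """Resample a volume or mask to ``target_shape``, preserving field of view.

    The physical extent (``shape * spacing``) is unchanged; spacing is rescaled
    accordingly and the origin shifted so the outer voxel *edges* coincide.
    Intensity images use trilinear interpolation, masks nearest-neighbor (so
    outputs stay binary).
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 2 for s in target_shape):
        raise ValueError(f"target_shape components must be >= 2, got {target_shape}")
    old_shape = np.array(v.shape, dtype=float)
    new_shape = np.array(target_shape, dtype=float)
    new_spacing = v.spacing * old_shape / new_shape
    # voxel-center origin: edge of grid is origin - spacing/2; keep edges fixed
    new_origin = v.origin + 0.5 * (new_spacing - v.spacing)
    centers = np.indices(target_shape, dtype=float)
    coords = [
        centers[a] * new_spacing[a] / v.spacing[a]
        + (new_origin[a] - v.origin[a]) / v.spacing[a]
        for a in range(3)
    ]
    order = 0 if isinstance(v, BinaryMask) else 1
    out = ndimage.map_coordinates(
        np.asarray(v.voxels, dtype=float), np.stack(coords), order=order, mode="nearest"
    )
    if isinstance(v, BinaryMask):
        return BinaryMask(out.astype(np.uint8), new_spacing, new_origin)
    return type(v)(out, new_spacing, new_origin)


def warp(moving: ImageVolume, dvf: DeformationField, fill=AIR_HU) -> ImageVolume:
    """Warp ``moving`` with a displacement field defined on the fixed grid.

    ``output(x) = moving(x + u(x))`` with trilinear interpolation; samples
    falling outside ``moving`` take ``fill`` (air by default). The output lives
    on the DVF's (fixed) grid.
    """
    if moving.voxels.ndim != 3:
        raise ValueError("warp expects a scalar 3D moving image")
    if dvf.voxels.shape[:3] != dvf.shape:
        raise ValueError("malformed DVF")
    sample_mm = dvf.voxel_centers_mm() + dvf.voxels
    idx = (sample_mm - moving.origin) / moving.spacing
    out = ndimage.map_coordinates(
        np.asarray(moving.voxels, dtype=float),
        np.moveaxis(idx, -1, 0),
        order=1,
        mode="constant",
        cval=fill,
    )
    return ImageVolume(out, dvf.spacing, dvf.origin)


def apply_rigid(v: ImageVolume, t: RigidTransform, fill=AIR_HU) -> ImageVolume:
    """Resample ``v`` under a rigid map (trilinear, air fill).

    The output at point ``p`` is ``v`` sampled at ``R (p - c) + c + t`` with
    ``c`` the grid center, so a pure translation ``t`` shifts content by
    ``-t``. Transforms within 1e-6 mm / 1e-6 deg of the identity return the
    input unchanged (resampling at a vanishing offset would only inject
    boundary fill and interpolation noise).
    """
    if (np.abs(t.rotation_deg).max() < 1e-6 and np.abs(t.translation_mm).max() < 1e-6):
        return ImageVolume(np.asarray(v.voxels, dtype=float), v.spacing, v.origin)
    r = t.matrix
    s_out = np.diag(v.spacing)
    s_in_inv = np.diag(1.0 / v.spacing)
    c = v.center_mm
    m = s_in_inv @ r @ s_out
    offset = s_in_inv @ (r @ (v.origin - c) + c + t.translation_mm - v.origin)
    out = ndimage.affine_transform(
        np.asarray(v.voxels, dtype=float), m, offset=offset, order=1,
        mode="constant", cval=fill,
    )
    return ImageVolume(out, v.spacing, v.origin)


# ---------------------------------------------------------------------------
# NIfTI / sidecar I/O
# ---------------------------------------------------------------------------

_LPS_FLIP = np.array([-1.0, -1.0, 1.0])


def _affine_from_grid(spacing, origin) -> np.ndarray:
    """Axis-aligned NIfTI affine (RAS) from our LPS spacing/origin."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing * _LPS_FLIP)
    aff[:3, 3] = origin * _LPS_FLIP
    return aff


def _grid_from_affine(aff: np.ndarray):
    lin = aff[:3, :3]
    if not np.allclose(lin - np.diag(np.diag(lin)), 0, atol=1e-6):
        raise IOError("only axis-aligned (scaling+translation) affines are supported")
    diag = np.diag(lin)
    if np.any(diag == 0) or not np.all(np.isfinite(diag)):
        raise IOError(f"degenerate affine diagonal: {diag}")
    sign = np.sign(diag)
    if np.allclose(sign, _LPS_FLIP):
        # our own convention: RAS affine encoding an LPS grid
        return np.abs(diag), aff[:3, 3] * _LPS_FLIP
    if np.allclose(sign, [1, 1, 1]):
        # positive-diagonal header: take values as LPS directly
        return diag.copy(), aff[:3, 3].copy()
    raise IOError("unsupported axis orientation in affine")


def _read_any(path: Path):
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix == ".json":
        with open(path) as f:
            meta = json.load(f)
        data_path = path.with_suffix(".npy")
        if "data" in meta:
            arr = np.asarray(meta["data"], dtype=float)
        elif data_path.exists():
            arr = np.load(data_path)
        else:
            raise IOError(f"sidecar {path} has no inline data and {data_path} is missing")
        spacing = np.asarray(meta["spacing"], dtype=float)
        origin = np.asarray(meta.get("origin", [0, 0, 0]), dtype=float)
    else:
        try:
            img = nib.load(str(path))
        except Exception as e:  # malformed header
            raise IOError(f"cannot read NIfTI {path}: {e}") from e
        arr = np.asanyarray(img.dataobj)
        spacing, origin = _grid_from_affine(img.affine)
    if np.any(spacing <= 0):
        raise IOError(f"non-positive spacing in {path}")
    return arr, spacing, origin


def _write_nifti(arr: np.ndarray, spacing, origin, path: Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(arr, _affine_from_grid(np.asarray(spacing), np.asarray(origin)))
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    arr, spacing, origin = _read_any(Path(path))
    return ImageVolume(np.asarray(arr, dtype=np.float32), spacing, origin)


def write_volume(v: ImageVolume, path) -> None:
    _write_nifti(np.asarray(v.voxels, dtype=np.float32), v.spacing, v.origin, path)


def read_mask(path) -> BinaryMask:
    arr, spacing, origin = _read_any(Path(path))
    return BinaryMask(np.asarray(arr).astype(np.uint8), spacing, origin)


def write_mask(m: BinaryMask, path) -> None:
    _write_nifti(np.asarray(m.voxels, dtype=np.uint8), m.spacing, m.origin, path)


def read_dose(path) -> DoseGrid:
    arr, spacing, origin = _read_any(Path(path))
    return DoseGrid(np.asarray(arr, dtype=np.float32), spacing, origin)


def write_dose(d: DoseGrid, path) -> None:
    _write_nifti(np.asarray(d.voxels, dtype=np.float32), d.spacing, d.origin, path)


def read_dvf(path) -> DeformationField:
    arr, spacing, origin = _read_any(Path(path))
    return DeformationField(np.asarray(arr, dtype=np.float64), spacing, origin)


def write_dvf(d: DeformationField, path) -> None:
    _write_nifti(np.asarray(d.voxels, dtype=np.float64), d.spacing, d.origin, path)
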