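"""Pre-processing of dCT/pCT pairs: couch removal, bony rigid alignment,
resampling to a common training grid.

Couch removal thresholds each axial slice at -200 HU, keeps the largest
2D connected region (which separates the patient from the narrower couch),
closes gaps and dilates in 3D for continuity, then sets everything outside
the final body mask to exactly -1024 HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, optimize
from skimage.morphology import ball

from .grids import (
    AIR_HU,
    BinaryMask,
    ImageVolume,
    RigidTransform,
    apply_rigid,
    resample_to_shape,
)
from .metrics import mae

TRAINING_SHAPE = (128, 128, 64)

__all__ = [
    "CouchRemovalParams",
    "PreprocessResult",
    "remove_couch",
    "rigid_register",
    "preprocess_pair",
    "TRAINING_SHAPE",
]


@dataclass
class CouchRemovalParams:
    body_threshold_HU: float = -200.0
    closing_radius_vox: int = 3
    dilation_radius_vox: int = 2
    background_fill_HU: float = AIR_HU  # fixed at -1024

    def __post_init__(self):
        if self.body_threshold_HU >= 0:
            raise ValueError("body threshold must be negative (soft tissue vs air)")
        if self.background_fill_HU != AIR_HU:
            raise ValueError("background fill is fixed at -1024 HU")


_CONN8 = np.ones((3, 3), dtype=bool)


def remove_couch(v: ImageVolume, params: Optional[CouchRemovalParams] = None):
    """Strip the couch (and any other non-body structure) from a CT.

    Per axial slice: threshold at ``body_threshold_HU`` and keep the largest
    8-connected 2D region; then 3D morphological closing (fill internal gaps)
    and dilation (skin continuity) with ball structuring elements. Returns the
    masked volume (exactly -1024 outside the mask) and the final body mask.
    """
    params = params or CouchRemovalParams()
    vox = np.asarray(v.voxels)
    core = np.zeros(v.shape, dtype=bool)
    any_body = False
    for k in range(v.shape[2]):
        sl = vox[:, :, k] > params.body_threshold_HU
        if not sl.any():
            continue  # empty slice (beyond anatomy) is allowed
        labels, n = ndimage.label(sl, structure=_CONN8)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        core[:, :, k] = labels == counts.argmax()
        any_body = True
    if not any_body:
        raise ValueError("empty body: no voxel above threshold in any slice")
    m = core
    if params.closing_radius_vox > 0:
        # pad with edge replication so anatomy touching the grid faces is not
        # eroded by the closing's implicit zero border
        r = params.closing_radius_vox
        mp = np.pad(m, r, mode="edge")
        mp = ndimage.binary_closing(mp, structure=ball(r))
        m = mp[r:-r, r:-r, r:-r]
    if params.dilation_radius_vox > 0:
        m = ndimage.binary_dilation(m, structure=ball(params.dilation_radius_vox))
    out = np.where(m, vox, np.float32(AIR_HU))
    return (
        ImageVolume(out, v.spacing, v.origin),
        BinaryMask(m.astype(np.uint8), v.spacing, v.origin),
    )


def _bone_feature(v: ImageVolume, bone_threshold_HU: float, blur_sigma_mm: float) -> np.ndarray:
    """Bone-emphasized feature map: soft threshold (linear ramp over 300 HU
    centered on the threshold, so partial-volume boundary voxels keep their
    sub-voxel information) followed by a Gaussian blur that widens the
    similarity metric's capture range without erasing fine bony structure."""
    feat = np.clip(
        (np.asarray(v.voxels, dtype=np.float64) - (bone_threshold_HU - 150.0)) / 300.0,
        0.0, 1.0,
    )
    return ndimage.gaussian_filter(feat, sigma=np.asarray(blur_sigma_mm) / v.spacing)


def _ncc_arrays(a: np.ndarray, b: np.ndarray) -> float:
    ad = a - a.mean()
    bd = b - b.mean()
    d = np.sqrt((ad ** 2).sum() * (bd ** 2).sum())
    if d == 0:
        return 0.0
    return float((ad * bd).sum() / d)


def rigid_register(moving: ImageVolume, fixed: ImageVolume,
                   bone_threshold_HU: float = 300.0,
                   blur_sigma_mm: float = 6.0) -> RigidTransform:
    """Bony rigid alignment: maximize NCC of bone-emphasized feature maps.

    Powell optimization of the 6 rigid parameters from the identity;
    convergence at 0.01 mm / 0.01 degree parameter steps. Returns the
    transform ``t`` such that ``apply_rigid(moving, t)`` best matches
    ``fixed``.
    """
    n_mov = int((np.asarray(moving.voxels) > bone_threshold_HU).sum())
    n_fix = int((np.asarray(fixed.voxels) > bone_threshold_HU).sum())
    if n_mov < 100 or n_fix < 100:
        raise ValueError(
            f"registration unavailable: need >= 100 bone voxels, got {n_mov} / {n_fix}"
        )
    feat_fix = ImageVolume(
        _bone_feature(fixed, bone_threshold_HU, blur_sigma_mm),
        fixed.spacing, fixed.origin,
    )
    feat_mov = ImageVolume(
        _bone_feature(moving, bone_threshold_HU, blur_sigma_mm),
        moving.spacing, moving.origin,
    )
    # Pre-shift the fixed feature by half a voxel: the warped moving image
    # always carries one trilinear-interpolation pass, and comparing it to an
    # un-resampled target gives integer-voxel offsets an artificial sharpness
    # bonus (a spurious NCC spike at zero shift). Sampling the target once at
    # a half-voxel offset puts equal interpolation blur on both sides; the
    # offset is folded back out of the returned transform.
    half = 0.5 * fixed.spacing
    target = np.asarray(
        apply_rigid(feat_fix, RigidTransform((0, 0, 0), half), fill=0.0).voxels,
        dtype=np.float64,
    )

    def neg_ncc(p):
        t = RigidTransform.from_params(p)
        warped = apply_rigid(feat_mov, t, fill=0.0)
        return -_ncc_arrays(np.asarray(warped.voxels, dtype=np.float64), target)

    res = optimize.minimize(
        neg_ncc,
        np.concatenate([half, np.zeros(3)]),
        method="Powell",
        options={"xtol": 0.01, "ftol": 1e-8, "maxiter": 50},
    )
    t_shift = RigidTransform.from_params(res.x)
    return RigidTransform(t_shift.rotation_deg,
                          t_shift.translation_mm - t_shift.matrix @ half)


@dataclass
class PreprocessResult:
    dct_ready: ImageVolume
    pct_ready: ImageVolume
    dct_body: BinaryMask
    pct_body: BinaryMask
    transform: RigidTransform
    stage_mae: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.dct_ready, self.pct_ready))


def preprocess_pair(dct: ImageVolume, pct: ImageVolume,
                    params: Optional[CouchRemovalParams] = None,
                    bone_threshold_HU: float = 300.0,
                    target_shape=TRAINING_SHAPE) -> PreprocessResult:
    """Full pre-processing pipeline for one dCT/pCT pair.

    Order of operations: couch removal on both -> rigid registration of the
    dCT onto the pCT (bony anatomy) and application of the transform ->
    resampling of both to the common training grid. A per-stage MAE log is
    kept for auditability.
    """
    stage_mae = {}
    if dct.shape == pct.shape:
        stage_mae["raw"] = mae(dct, pct)
    dct_nc, dct_body = remove_couch(dct, params)
    pct_nc, pct_body = remove_couch(pct, params)
    if dct_nc.shape == pct_nc.shape:
        stage_mae["couch_removed"] = mae(dct_nc, pct_nc)
    t = rigid_register(dct_nc, pct_nc, bone_threshold_HU=bone_threshold_HU)
    dct_al = apply_rigid(dct_nc, t)
    if dct_al.shape == pct_nc.shape:
        stage_mae["aligned"] = mae(dct_al, pct_nc)
    dct_ready = resample_to_shape(dct_al, target_shape)
    pct_ready = resample_to_shape(pct_nc, target_shape)
    stage_mae["resampled"] = mae(dct_ready, pct_ready)
    # body masks on the final grid (nearest-neighbor through the same ops)
    dct_body_rs = resample_to_shape(dct_body, target_shape)
    pct_body_rs = resample_to_shape(pct_body, target_shape)
    return PreprocessResult(
        dct_ready=dct_ready,
        pct_ready=pct_ready,
        dct_body=dct_body_rs,
        pct_body=pct_body_rs,
        transform=t,
        stage_mae=stage_mae,
    )
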