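"""Image-similarity metrics between co-registered CT volumes.

Four metrics standard in synthetic-CT evaluation: MAE (overall HU deviation),
NCC (intensity-pattern correlation, [-1, 1]), a global-statistics SSIM
([-1, 1], 1 = identical), and GMSD (gradient-magnitude similarity deviation;
larger = more structural distortion, 0 = identical edges). All accept an
optional evaluation mask (e.g. the union of body masks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ImageVolume, HU_MIN, HU_MAX

DEFAULT_DYNAMIC_RANGE = 4095.0  # HU in [-1024, 3071] shifted by +1024
GMSD_C = 170.0  # stabilizer on the [0, 255] intensity scale

__all__ = [
    "SimilarityReport",
    "mae",
    "ncc",
    "ssim",
    "gmsd",
    "similarity_report",
]


@dataclass
class SimilarityReport:
    mae_HU: float
    ncc: float
    ssim: float
    gmsd: float
    n_voxels: int
    mask_used: bool

    def as_dict(self) -> dict:
        return {
            "mae_HU": self.mae_HU,
            "ncc": self.ncc,
            "ssim": self.ssim,
            "gmsd": self.gmsd,
            "n_voxels": self.n_voxels,
            "mask_used": self.mask_used,
        }


def _check_pair(x: ImageVolume, y: ImageVolume, mask: Optional[BinaryMask]):
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    if mask is not None:
        if mask.shape != x.shape:
            raise ValueError("mask grid does not match images")
        sel = mask.astype_bool()
        if not sel.any():
            raise ValueError("empty evaluation mask")
        return sel
    return np.ones(x.shape, dtype=bool)


def mae(x: ImageVolume, y: ImageVolume, mask: Optional[BinaryMask] = None) -> float:
    """Mean absolute HU error over the evaluation region."""
    sel = _check_pair(x, y, mask)
    xf = np.asarray(x.voxels, dtype=np.float64)[sel]
    yf = np.asarray(y.voxels, dtype=np.float64)[sel]
    return float(np.mean(np.abs(xf - yf)))


def ncc(x: ImageVolume, y: ImageVolume, mask: Optional[BinaryMask] = None) -> float:
    """Normalized cross-correlation (Pearson form), in [-1, 1]."""
    sel = _check_pair(x, y, mask)
    xf = np.asarray(x.voxels, dtype=np.float64)[sel]
    yf = np.asarray(y.voxels, dtype=np.float64)[sel]
    xd = xf - xf.mean()
    yd = yf - yf.mean()
    denom = np.sqrt(np.mean(xd ** 2) * np.mean(yd ** 2))
    if denom == 0:
        raise ValueError("NCC undefined: zero variance over the evaluation region")
    v = float(np.mean(xd * yd) / denom)
    return float(np.clip(v, -1.0, 1.0))


def ssim(x: ImageVolume, y: ImageVolume, mask: Optional[BinaryMask] = None,
         dynamic_range: float = DEFAULT_DYNAMIC_RANGE) -> float:
    """Global SSIM from region means/variances/covariance.

    ``c1 = (0.01 L)^2`` and ``c2 = (0.03 L)^2`` with ``L = dynamic_range``
    (default 4095: the CT range shifted to non-negative values).
    """
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    sel = _check_pair(x, y, mask)
    xf = np.asarray(x.voxels, dtype=np.float64)[sel]
    yf = np.asarray(y.voxels, dtype=np.float64)[sel]
    mx, my = xf.mean(), yf.mean()
    vx = np.mean((xf - mx) ** 2)
    vy = np.mean((yf - my) ** 2)
    cov = np.mean((xf - mx) * (yf - my))
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    return float(
        (2 * mx * my + c1) * (2 * cov + c2) / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2))
    )


def _prewitt_magnitude(vol: np.ndarray) -> np.ndarray:
    """Per-axial-slice 2D Prewitt gradient magnitude (1/3-normalized kernels,
    reflect boundary)."""
    kx = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=np.float64) / 3.0
    out = np.empty_like(vol, dtype=np.float64)
    for k in range(vol.shape[2]):
        sl = vol[:, :, k]
        gx = ndimage.convolve(sl, kx, mode="reflect")
        gy = ndimage.convolve(sl, kx.T, mode="reflect")
        out[:, :, k] = np.sqrt(gx ** 2 + gy ** 2)
    return out


def gmsd(x: ImageVolume, y: ImageVolume, mask: Optional[BinaryMask] = None) -> float:
    """Gradient-magnitude similarity deviation.

    Intensities are mapped linearly from the CT range [-1024, 3071] to
    [0, 255] (the convention under which the stabilizer ``C = 170`` is
    defined); gradient magnitudes come from per-slice 2D Prewitt filters, and
    GMSD is the standard deviation of the gradient-magnitude similarity map
    over the evaluation region. 0 means identical edge structure.
    """
    sel = _check_pair(x, y, mask)
    scale = 255.0 / (HU_MAX - HU_MIN)
    xf = (np.asarray(x.voxels, dtype=np.float64) - HU_MIN) * scale
    yf = (np.asarray(y.voxels, dtype=np.float64) - HU_MIN) * scale
    m1 = _prewitt_magnitude(xf)
    m2 = _prewitt_magnitude(yf)
    gms = (2.0 * m1 * m2 + GMSD_C) / (m1 ** 2 + m2 ** 2 + GMSD_C)
    g = gms[sel]
    return float(np.sqrt(np.mean((g - g.mean()) ** 2)))


def similarity_report(x: ImageVolume, y: ImageVolume,
                      mask: Optional[BinaryMask] = None) -> SimilarityReport:
    """All four metrics with a shared evaluation mask."""
    sel = _check_pair(x, y, mask)
    return SimilarityReport(
        mae_HU=mae(x, y, mask),
        ncc=ncc(x, y, mask),
        ssim=ssim(x, y, mask),
        gmsd=gmsd(x, y, mask),
        n_voxels=int(sel.sum()),
        mask_used=mask is not None,
    )
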