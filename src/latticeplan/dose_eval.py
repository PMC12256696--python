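"""Dosimetric evaluation: DVH curves and metrics, isodose sphere fitting,
dose profiles, and paired plan comparison with the Wilcoxon signed-rank test.

Conventions
-----------
* Cumulative DVH: ``V(d)`` = fraction of the structure receiving >= d cGy
  (starts at 1 at 0 cGy, non-increasing).
* ``Dx%`` = minimum dose received by the hottest x% of the structure volume,
  linearly interpolated between sorted voxel doses; ``DV-cc`` analogous with
  an absolute volume.
* ``MVS(d)`` (mean volume sparing) = absolute volume (cc) receiving strictly
  less than d cGy.
* The "50% isodose" used for sphere fitting is referenced to the
  *prescription* (e.g. 1000 cGy for a 2000 cGy prescription).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage, stats

from .grids import BinaryMask, DoseGrid
from .lattice import SphereSet

__all__ = [
    "DVHCurve",
    "DVHMetrics",
    "PlanComparison",
    "dvh_curve",
    "dvh_metrics",
    "fit_spheres_from_isodose",
    "dose_profile",
    "compare_plans",
]


@dataclass
class DVHCurve:
    dose_cGy: np.ndarray  # ascending grid
    volume_fraction: np.ndarray  # non-increasing, starts at 1
    volume_cc: float


@dataclass
class DVHMetrics:
    Dmax: float
    Dmin: float
    Dmean: float
    D10: float
    D50: float
    D90: float
    D003cc: Optional[float] = None
    D1cc: Optional[float] = None
    MVS_cc: Optional[float] = None
    mvs_level_cGy: Optional[float] = None

    @property
    def heterogeneity(self) -> float:
        """Dose-heterogeneity index D10% / D90%."""
        return self.D10 / self.D90 if self.D90 > 0 else float("inf")

    def as_dict(self) -> dict:
        d = {
            "Dmax": self.Dmax, "Dmin": self.Dmin, "Dmean": self.Dmean,
            "D10%": self.D10, "D50%": self.D50, "D90%": self.D90,
            "D10%/D90%": self.heterogeneity,
        }
        if self.D003cc is not None:
            d["D0.03cc"] = self.D003cc
        if self.D1cc is not None:
            d["D1cc"] = self.D1cc
        if self.MVS_cc is not None:
            d[f"MVS{self.mvs_level_cGy:g}cGy"] = self.MVS_cc
        return d


def _masked_doses(dose: DoseGrid, mask: BinaryMask, name: str = "structure") -> np.ndarray:
    if dose.shape != mask.shape:
        raise ValueError(f"dose and {name} mask grids differ: {dose.shape} vs {mask.shape}")
    sel = mask.astype_bool()
    if not sel.any():
        raise ValueError(f"empty structure mask: {name}")
    return np.asarray(dose.voxels, dtype=np.float64)[sel]


def dvh_curve(dose: DoseGrid, mask: BinaryMask, bin_width_cGy: float = 1.0,
              name: str = "structure") -> DVHCurve:
    """Cumulative DVH with exact voxel-volume weighting."""
    d = _masked_doses(dose, mask, name)
    vol_cc = d.size * mask.voxel_volume_mm3 / 1000.0
    top = float(d.max())
    edges = np.arange(0.0, top + 2 * bin_width_cGy, bin_width_cGy)
    ds = np.sort(d)
    # V(edge) = fraction with dose >= edge
    frac = 1.0 - np.searchsorted(ds, edges, side="left") / d.size
    frac[0] = 1.0
    return DVHCurve(dose_cGy=edges, volume_fraction=frac, volume_cc=vol_cc)


def _dose_at_hot_volume(sorted_desc: np.ndarray, voxel_cc: float, v_cc: float) -> float:
    """Minimum dose to the hottest ``v_cc`` of the structure (linear interp).

    The cumulative hot volume after the i-th hottest voxel is (i+1) * voxel_cc;
    the dose is interpolated between consecutive sorted voxel doses.
    """
    n = sorted_desc.size
    total = n * voxel_cc
    if v_cc > total + 1e-9:
        raise ValueError(f"requested volume {v_cc} cc exceeds structure volume {total:.3f} cc")
    k = v_cc / voxel_cc  # voxel count, fractional
    if k <= 1.0:
        return float(sorted_desc[0])
    i = int(np.floor(k - 1.0))
    fr = (k - 1.0) - i
    if i >= n - 1:
        return float(sorted_desc[-1])
    return float(sorted_desc[i] * (1 - fr) + sorted_desc[i + 1] * fr)


def dvh_metrics(dose: DoseGrid, mask: BinaryMask, prescription_cGy: float = 2000.0,
                mvs_level_cGy: Optional[float] = None, dv_cc: tuple = (),
                name: str = "structure") -> DVHMetrics:
    """Point, percentile and absolute-volume DVH metrics for one structure.

    ``dv_cc`` may contain 0.03 and/or 1.0 to request D0.03cc / D1cc. When
    ``mvs_level_cGy`` is given, MVS (volume in cc receiving < level) is
    reported.
    """
    d = _masked_doses(dose, mask, name)
    voxel_cc = mask.voxel_volume_mm3 / 1000.0
    total_cc = d.size * voxel_cc
    sd = np.sort(d)[::-1]
    out = DVHMetrics(
        Dmax=float(sd[0]),
        Dmin=float(sd[-1]),
        Dmean=float(d.mean()),
        D10=_dose_at_hot_volume(sd, voxel_cc, 0.10 * total_cc),
        D50=_dose_at_hot_volume(sd, voxel_cc, 0.50 * total_cc),
        D90=_dose_at_hot_volume(sd, voxel_cc, 0.90 * total_cc),
    )
    for v in dv_cc:
        val = _dose_at_hot_volume(sd, voxel_cc, v)
        if abs(v - 0.03) < 1e-12:
            out.D003cc = val
        elif abs(v - 1.0) < 1e-12:
            out.D1cc = val
    if mvs_level_cGy is not None:
        out.MVS_cc = float((d < mvs_level_cGy).sum() * voxel_cc)
        out.mvs_level_cGy = float(mvs_level_cGy)
    return out


def fit_spheres_from_isodose(dose: DoseGrid, prescription_cGy: float,
                             level_fraction: float = 0.5,
                             fitted_diameter_mm: float = 15.0,
                             min_volume_cc: float = 0.1) -> SphereSet:
    """Fit fixed-diameter spheres to the connected components of an isodose.

    Thresholds the dose at ``level_fraction * prescription``, labels
    26-connected 3D components, drops components below ``min_volume_cc``
    (speckle), and places a sphere of ``fitted_diameter_mm`` at each
    component's geometric centroid (mean voxel-center position).
    """
    supra = np.asarray(dose.voxels) >= level_fraction * prescription_cGy
    if not supra.any():
        return SphereSet(np.empty((0, 3)), fitted_diameter_mm)
    labels, n = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=bool))
    voxel_cc = dose.voxel_volume_mm3 / 1000.0
    centers = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] * voxel_cc < min_volume_cc:
            continue
        centers.append(dose.index_to_world(idx.astype(float)).mean(axis=0))
    if not centers:
        return SphereSet(np.empty((0, 3)), fitted_diameter_mm)
    return SphereSet(np.asarray(centers), fitted_diameter_mm)


def dose_profile(dose: DoseGrid, start_mm, end_mm, n_samples: int = 100) -> np.ndarray:
    """Trilinear dose samples along a segment (both endpoints inside the grid)."""
    start = np.asarray(start_mm, dtype=float)
    end = np.asarray(end_mm, dtype=float)
    for p in (start, end):
        idx = dose.world_to_index(p)
        if np.any(idx < -0.5) or np.any(idx > np.asarray(dose.shape) - 0.5):
            raise ValueError(f"profile endpoint {p} mm is outside the dose grid")
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = start + t * (end - start)
    coords = dose.world_to_index(pts).T
    return ndimage.map_coordinates(np.asarray(dose.voxels, dtype=np.float64), coords,
                                   order=1, mode="nearest")


@dataclass
class PlanComparison:
    """Per-structure/metric paired deviations (a - b) and Wilcoxon tests."""

    deviations: Dict[str, Dict[str, np.ndarray]]  # structure -> metric -> per-case a-b
    tests: Dict[str, Dict[str, dict]] = field(default_factory=dict)
    alpha: float = 0.05


def _wilcoxon(diffs: np.ndarray, alpha: float) -> dict:
    """Two-sided Wilcoxon signed-rank; zeros dropped (classic convention),
    exact null for n <= 25 without ties, normal approximation with tie
    correction otherwise."""
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return {"statistic": float("nan"), "p_value": float("nan"),
                "n_effective": 0, "significant": False, "degenerate": True}
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return {"statistic": float(res.statistic), "p_value": p, "n_effective": int(nz.size),
            "significant": bool(p < alpha), "degenerate": False}


def compare_plans(metrics_a: List[Dict[str, DVHMetrics]],
                  metrics_b: List[Dict[str, DVHMetrics]],
                  alpha: float = 0.05) -> PlanComparison:
    """Paired comparison of two plan sets across cases.

    ``metrics_a`` / ``metrics_b`` are per-case dicts mapping structure name to
    DVHMetrics; structures must match by name across the two lists. Tests are
    computed when >= 5 paired cases are available; with fewer cases only the
    deviations are reported.
    """
    if len(metrics_a) != len(metrics_b):
        raise ValueError("paired comparison needs equal numbers of cases")
    if not metrics_a:
        raise ValueError("no cases to compare")
    names_a = set(metrics_a[0])
    for case in metrics_a + metrics_b:
        if set(case) != names_a:
            missing = sorted(names_a.symmetric_difference(case))
            raise ValueError(f"unmatched structures across cases: {missing}")
    metric_keys = ["Dmax", "Dmin", "Dmean", "D10%", "D50%", "D90%", "D10%/D90%",
                   "D0.03cc", "D1cc"]
    deviations: Dict[str, Dict[str, np.ndarray]] = {}
    tests: Dict[str, Dict[str, dict]] = {}
    n = len(metrics_a)
    for s in sorted(names_a):
        da = [m[s].as_dict() for m in metrics_a]
        db = [m[s].as_dict() for m in metrics_b]
        deviations[s] = {}
        tests[s] = {}
        for k in metric_keys:
            if k not in da[0] or k not in db[0]:
                continue
            diffs = np.array([a[k] - b[k] for a, b in zip(da, db)], dtype=float)
            deviations[s][k] = diffs
            if n >= 5:
                tests[s][k] = _wilcoxon(diffs, alpha)
    return PlanComparison(deviations=deviations, tests=tests, alpha=alpha)
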