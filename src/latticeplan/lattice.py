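"""Automated lattice-sphere placement inside a GTV.

Lattice radiotherapy delivers ablative dose to a 3D arrangement of 1.5-cm
spheres inside the gross tumor volume. Placement constraints:

* sphere centers at least 1.0 cm inside the GTV surface (contraction),
* at least 1.5 cm from every OAR voxel,
* same-axial-plane nearest-neighbor center spacing within 6-8 cm,
* no less than 3 cm center-to-center across different axial planes.

The search is a deterministic greedy sweep over axial planes in lexicographic
voxel order: a candidate is accepted iff all constraints hold against the
spheres already placed. Distances are Euclidean millimetres computed with
exact distance transforms on the mask grid, so the audit and the placement
agree by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .grids import BinaryMask

__all__ = [
    "PlacementParams",
    "SphereSet",
    "PlacementAudit",
    "place_spheres",
    "rasterize_spheres",
    "audit_placement",
]


@dataclass
class PlacementParams:
    sphere_diameter_mm: float = 15.0
    gtv_contraction_mm: float = 10.0
    oar_clearance_mm: float = 15.0
    axial_spacing_mm: tuple = (60.0, 80.0)
    out_of_plane_min_mm: float = 30.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.axial_spacing_mm
        if lo > hi:
            raise ValueError("axial spacing range must be (low, high) with low <= high")
        for v in (self.sphere_diameter_mm, self.gtv_contraction_mm,
                  self.oar_clearance_mm, lo, hi, self.out_of_plane_min_mm):
            if v <= 0:
                raise ValueError("all placement distances must be positive")


@dataclass
class SphereSet:
    """Lattice target: sphere centers (mm, patient coordinates) + common diameter."""

    centers_mm: np.ndarray
    diameter_mm: float = 15.0
    provenance: Optional[PlacementParams] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.centers_mm = np.asarray(self.centers_mm, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.centers_mm.shape[0]


@dataclass
class PlacementAudit:
    n_spheres: int
    min_center_to_gtv_surface_mm: float
    min_center_to_oar_mm: float
    min_same_plane_spacing_mm: float
    max_same_plane_nn_spacing_mm: float
    min_cross_plane_spacing_mm: float
    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def as_dict(self) -> dict:
        return {
            "n_spheres": self.n_spheres,
            "min_center_to_gtv_surface_mm": self.min_center_to_gtv_surface_mm,
            "min_center_to_oar_mm": self.min_center_to_oar_mm,
            "min_same_plane_spacing_mm": self.min_same_plane_spacing_mm,
            "max_same_plane_nn_spacing_mm": self.max_same_plane_nn_spacing_mm,
            "min_cross_plane_spacing_mm": self.min_cross_plane_spacing_mm,
            "violations": list(self.violations),
        }


def _interior_distance_mm(gtv: BinaryMask) -> np.ndarray:
    """Distance (mm) from each inside voxel to the nearest outside voxel."""
    return ndimage.distance_transform_edt(gtv.astype_bool(), sampling=gtv.spacing)


def _distance_to_mask_mm(mask: BinaryMask) -> np.ndarray:
    """Distance (mm) from every voxel to the nearest voxel of the mask."""
    return ndimage.distance_transform_edt(~mask.astype_bool(), sampling=mask.spacing)


def candidate_region(gtv: BinaryMask, oars: Sequence[BinaryMask],
                     params: PlacementParams) -> np.ndarray:
    """Boolean array of voxels eligible to host a sphere center."""
    cand = _interior_distance_mm(gtv) >= params.gtv_contraction_mm
    for oar in oars:
        if not oar.same_grid(gtv):
            raise ValueError("all masks must share one grid")
        if oar.astype_bool().any():
            cand &= _distance_to_mask_mm(oar) >= params.oar_clearance_mm
    return cand


def place_spheres(gtv: BinaryMask, oars: Sequence[BinaryMask] = (),
                  params: Optional[PlacementParams] = None) -> SphereSet:
    """Greedy deterministic lattice placement under the geometric constraints.

    An infeasible geometry (empty candidate region) yields an *empty*
    SphereSet carrying a structured warning rather than an exception.
    """
    params = params or PlacementParams()
    if not gtv.astype_bool().any():
        raise ValueError("GTV mask is empty")
    cand = candidate_region(gtv, oars, params)
    notes: list = []
    if not cand.any():
        msg = "infeasible geometry: no voxel satisfies contraction + OAR clearance"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
        return SphereSet(np.empty((0, 3)), params.sphere_diameter_mm, params, notes)

    lo, hi = params.axial_spacing_mm
    accepted: list = []
    accepted_k: list = []
    idx = np.argwhere(cand)  # sorted lexicographically (i, j, k)
    # sweep axial planes in order; within a plane, lexicographic (i, j)
    order = np.lexsort((idx[:, 1], idx[:, 0], idx[:, 2]))
    pts_all = gtv.index_to_world(idx[order].astype(float))
    ks_all = idx[order][:, 2]
    for p, k in zip(pts_all, ks_all):
        ok = True
        same_d = []
        for c, ck in zip(accepted, accepted_k):
            d = float(np.linalg.norm(p - c))
            if ck == k:
                if d < lo:
                    ok = False
                    break
                same_d.append(d)
            elif d < params.out_of_plane_min_mm:
                ok = False
                break
        if ok and same_d and min(same_d) > hi:
            ok = False  # nearest same-plane neighbor must fall inside the range
        if ok:
            accepted.append(p)
            accepted_k.append(int(k))
    if not accepted:
        msg = "infeasible geometry: candidate region too small for any sphere"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
        return SphereSet(np.empty((0, 3)), params.sphere_diameter_mm, params, notes)
    return SphereSet(np.asarray(accepted), params.sphere_diameter_mm, params, notes)


def rasterize_spheres(s: SphereSet, grid_like):
    """Rasterize each sphere (voxel-center inclusion) on ``grid_like``'s grid.

    Returns (list of per-sphere BinaryMask, union BinaryMask). Warns when the
    grid is too coarse to resolve the sphere radius or a sphere misses the
    grid entirely.
    """
    radius = s.diameter_mm / 2.0
    if np.any(np.asarray(grid_like.spacing) > radius):
        warnings.warn(
            f"grid spacing {grid_like.spacing} is coarse relative to sphere radius {radius} mm",
            stacklevel=2,
        )
    pts = grid_like.voxel_centers_mm()
    per: list = []
    union = np.zeros(grid_like.shape, dtype=np.uint8)
    for c in s.centers_mm:
        inside = ((pts - c) ** 2).sum(axis=-1) <= radius ** 2
        if not inside.any():
            warnings.warn(f"sphere at {c} mm lies outside the grid", stacklevel=2)
        per.append(BinaryMask(inside.astype(np.uint8), grid_like.spacing, grid_like.origin))
        union |= inside.astype(np.uint8)
    return per, BinaryMask(union, grid_like.spacing, grid_like.origin)


def _sample_map(dist_mm: np.ndarray, grid_like, centers: np.ndarray) -> np.ndarray:
    """Nearest-voxel sample of a distance map at physical points."""
    idx = np.rint(grid_like.world_to_index(centers)).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid_like.shape) - 1)
    return dist_mm[tuple(idx.T)]


def audit_placement(s: SphereSet, gtv: BinaryMask, oars: Sequence[BinaryMask] = (),
                    params: Optional[PlacementParams] = None) -> PlacementAudit:
    """Exact constraint audit of a sphere set against masks and parameters.

    Same-plane pairs are classified by the axial index of each center's
    nearest voxel plane; spacing minima are brute-force pairwise distances.
    """
    params = params or PlacementParams()
    inf = float("inf")
    if len(s) == 0:
        return PlacementAudit(0, inf, inf, inf, inf, inf, ["empty sphere set"])
    centers = s.centers_mm
    d_surface = _sample_map(_interior_distance_mm(gtv), gtv, centers)
    min_surf = float(d_surface.min())
    min_oar = inf
    for oar in oars:
        if oar.astype_bool().any():
            d = _sample_map(_distance_to_mask_mm(oar), gtv, centers)
            min_oar = min(min_oar, float(d.min()))
    ks = np.rint((centers[:, 2] - gtv.origin[2]) / gtv.spacing[2]).astype(int)
    lo, hi = params.axial_spacing_mm
    min_same, min_cross = inf, inf
    max_same_nn = 0.0
    for i in range(len(s)):
        same_d = []
        for j in range(len(s)):
            if i == j:
                continue
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if ks[i] == ks[j]:
                same_d.append(d)
                min_same = min(min_same, d)
            else:
                min_cross = min(min_cross, d)
        if same_d:
            max_same_nn = max(max_same_nn, min(same_d))
    violations = []
    if min_surf < params.gtv_contraction_mm:
        violations.append(
            f"center within {min_surf:.1f} mm of GTV surface (< {params.gtv_contraction_mm})"
        )
    if min_oar < params.oar_clearance_mm:
        violations.append(
            f"center within {min_oar:.1f} mm of an OAR (< {params.oar_clearance_mm})"
        )
    if min_same < lo:
        violations.append(f"same-plane spacing {min_same:.1f} mm below {lo}")
    if max_same_nn > hi:
        violations.append(f"same-plane nearest-neighbor spacing {max_same_nn:.1f} mm above {hi}")
    if min_cross < params.out_of_plane_min_mm:
        violations.append(
            f"cross-plane spacing {min_cross:.1f} mm below {params.out_of_plane_min_mm}"
        )
    return PlacementAudit(
        n_spheres=len(s),
        min_center_to_gtv_surface_mm=min_surf,
        min_center_to_oar_mm=min_oar,
        min_same_plane_spacing_mm=min_same,
        max_same_plane_nn_spacing_mm=max_same_nn,
        min_cross_plane_spacing_mm=min_cross,
        violations=violations,
    )
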