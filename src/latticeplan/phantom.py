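"""Seeded digital phantoms: paired diagnostic/planning CTs with known deformation.

The generator emulates the data a simulation-free lattice-RT workflow sees:

* a diagnostic CT (dCT) on a curved diagnostic couch, and a planning CT (pCT)
  on a flat couch (or none), of the same patient;
* a smooth inter-scan deformation between the two acquisitions, dominated by
  a systematic couch-induced posterior sag plus a seeded random residual —
  the ground-truth field downstream registration models try to recover;
* body / GTV / OAR masks in the planning frame, and lattice-shaped dose
  distributions with ablative peak spheres over a low valley plateau.

HU palette: air -1000, lung ~ -700, soft tissue ~ 40, bone ~ 700, couch 200.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .grids import (
    AIR_HU,
    BinaryMask,
    DeformationField,
    DoseGrid,
    ImageVolume,
)

HU_AIR_BODY = -1000.0
HU_LUNG = -700.0
HU_SOFT = 40.0
HU_BONE = 700.0
HU_COUCH = 200.0

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "make_phantom",
    "make_known_dvf",
    "augment",
    "synth_lattice_dose",
    "ellipsoid_mask",
]


@dataclass
class OarSpec:
    """Geometric OAR primitive: 'cylinder' (z-axis), 'slab' (axis-aligned), or 'sphere'."""

    name: str
    kind: str  # cylinder | slab | sphere
    center_mm: tuple = (0.0, 0.0, 0.0)
    radius_mm: float = 10.0
    # slab: half-thicknesses per axis
    half_size_mm: tuple = (100.0, 5.0, 100.0)


@dataclass
class PhantomSpec:
    region: str = "thorax"  # thorax | abdomen
    grid_shape: tuple = (128, 128, 64)
    spacing: tuple = (3.0, 3.0, 4.0)
    body_semiaxes_mm: tuple = (150.0, 95.0)  # in-plane ellipse; body spans z
    lungs: Optional[bool] = None  # default: region == thorax
    lung_semiaxes_mm: tuple = (55.0, 65.0, 90.0)
    gas_pocket: bool = False
    gas_pocket_pct_only: bool = True
    gas_center_mm: tuple = (60.0, -20.0, 0.0)
    gas_radius_mm: float = 25.0
    bone: bool = True
    couch_dct: str = "curved"  # none | flat | curved
    couch_pct: str = "flat"
    couch_hu: float = HU_COUCH
    couch_thickness_mm: float = 12.0
    body_z_halfextent_mm: Optional[float] = None  # None: body spans the grid in z
    gtv_center_mm: tuple = (60.0, 10.0, 0.0)
    gtv_semiaxes_mm: tuple = (45.0, 40.0, 40.0)
    oars: tuple = ()
    deform_amplitude_mm: float = 3.0  # random residual
    deform_smoothness_mm: float = 40.0
    sag_amplitude_mm: float = 3.0  # systematic couch-induced sag
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.lungs is None:
            self.lungs = self.region == "thorax"

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing)


@dataclass
class PhantomBundle:
    dct: ImageVolume
    pct: ImageVolume
    true_dvf: DeformationField  # maps dCT anatomy onto the pCT frame
    body: BinaryMask  # pCT frame
    gtv: BinaryMask
    oars: dict  # name -> BinaryMask
    provenance: PhantomSpec = field(repr=False, default=None)


def _grid_origin(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.grid_shape, dtype=float)
    sp = np.asarray(spec.spacing, dtype=float)
    return -(shape - 1.0) / 2.0 * sp  # centered grid


def ellipsoid_mask(grid_like, center_mm, semiaxes_mm) -> BinaryMask:
    """Rasterize an ellipsoid (voxel-center inclusion) on an existing grid."""
    pts = grid_like.voxel_centers_mm()
    r = (pts - np.asarray(center_mm, dtype=float)) / np.asarray(semiaxes_mm, dtype=float)
    inside = (r ** 2).sum(axis=-1) <= 1.0
    return BinaryMask(inside.astype(np.uint8), grid_like.spacing, grid_like.origin)


def _indicator_oar(oar: OarSpec, pts: np.ndarray) -> np.ndarray:
    c = np.asarray(oar.center_mm, dtype=float)
    if oar.kind == "cylinder":
        d2 = ((pts[..., 0] - c[0]) ** 2 + (pts[..., 1] - c[1]) ** 2)
        return d2 <= oar.radius_mm ** 2
    if oar.kind == "sphere":
        return ((pts - c) ** 2).sum(axis=-1) <= oar.radius_mm ** 2
    if oar.kind == "slab":
        h = np.asarray(oar.half_size_mm, dtype=float)
        return np.all(np.abs(pts - c) <= h, axis=-1)
    raise ValueError(f"unknown OAR kind {oar.kind!r}")


def _anatomy_hu(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Analytic HU at arbitrary physical points (no couch, no noise)."""
    a, b = spec.body_semiaxes_mm
    x, y = pts[..., 0], pts[..., 1]
    body = _body_indicator(spec, pts)
    hu = np.full(pts.shape[:-1], HU_AIR_BODY)
    hu[body] = HU_SOFT
    if spec.lungs:
        la, lb, lc = spec.lung_semiaxes_mm
        for sx in (-1.0, 1.0):
            c = np.array([sx * 0.45 * a, -0.08 * b, 0.0])
            r = (pts - c) / np.array([la, lb, lc])
            hu[((r ** 2).sum(axis=-1) <= 1.0) & body] = HU_LUNG
    if spec.bone:
        z = pts[..., 2]
        # spine: posterior column of vertebral bodies (37 mm period, 13 mm
        # disc gaps; the period is deliberately incommensurate with common
        # slice spacings so bony rigid alignment along z is well-posed) with
        # a marrow core
        sc = np.array([0.0, 0.62 * b])
        d2 = (x - sc[0]) ** 2 + (y - sc[1]) ** 2
        vert = np.mod(z + 1e4, 37.0) < 24.0
        hu[(d2 <= 18.0 ** 2) & body & vert] = HU_BONE
        hu[(d2 <= 6.0 ** 2) & body & vert] = 200.0
        # sternum: small anterior bone bar
        hu[(np.abs(x) <= 12.0) & (np.abs(y + 0.82 * b) <= 6.0) & body & vert] = HU_BONE
    if spec.gas_pocket:
        c = np.asarray(spec.gas_center_mm, dtype=float)
        r2 = ((pts - c) ** 2).sum(axis=-1)
        hu[(r2 <= spec.gas_radius_mm ** 2) & body] = HU_AIR_BODY
    return hu


def _body_indicator(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    a, b = spec.body_semiaxes_mm
    inside = (pts[..., 0] / a) ** 2 + (pts[..., 1] / b) ** 2 <= 1.0
    if spec.body_z_halfextent_mm is not None:
        # rounded superellipsoid caps: the torso ends inside the grid
        zr = np.abs(pts[..., 2]) / spec.body_z_halfextent_mm
        q = (pts[..., 0] / a) ** 2 + (pts[..., 1] / b) ** 2
        inside = (q + zr ** 8) <= 1.0
    return inside


def _couch_hu(spec: PhantomSpec, kind: str, pts: np.ndarray) -> np.ndarray:
    """Additive couch structure below (posterior to, +y) the body."""
    hu = np.zeros(pts.shape[:-1])
    if kind == "none":
        return hu
    _, b = spec.body_semiaxes_mm
    x, y = pts[..., 0], pts[..., 1]
    th = spec.couch_thickness_mm
    gap = 15.0
    if kind == "flat":
        y0 = b + gap
        inside = (np.abs(x) <= 220.0) & (y >= y0) & (y <= y0 + th)
    elif kind == "curved":
        # concave shell: arc of an annulus centered above the patient
        cy = -120.0
        r0 = b + gap + 120.0
        r = np.sqrt(x ** 2 + (y - cy) ** 2)
        inside = (r >= r0) & (r <= r0 + th) & (y > 0) & (np.abs(x) <= 220.0)
    else:
        raise ValueError(f"unknown couch kind {kind!r}")
    hu[inside] = spec.couch_hu
    return hu


def _scene_hu(spec: PhantomSpec, couch_kind: str, pts: np.ndarray,
              supersample: bool = True) -> np.ndarray:
    """Anatomy + couch HU with partial-volume anti-aliasing.

    The analytic scene has hard edges; averaging a 2x2x2 sub-voxel quadrature
    (offsets at +-spacing/4) emulates the partial-volume effect of a real CT,
    so sub-voxel shifts change boundary-voxel HU continuously.
    """
    f = lambda p: _anatomy_hu(spec, p) + _couch_hu(spec, couch_kind, p)
    if not supersample:
        return f(pts)
    return _aa(f, pts, np.asarray(spec.spacing, dtype=float))


def _aa(f, pts: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """2x2x2 sub-voxel quadrature average of a scalar field."""
    acc = np.zeros(pts.shape[:-1])
    for ox in (-0.25, 0.25):
        for oy in (-0.25, 0.25):
            for oz in (-0.25, 0.25):
                acc += f(pts + np.array([ox, oy, oz]) * spacing)
    return acc / 8.0


def rigidly_moved_phantom(spec: PhantomSpec, t, couch: str = "none",
                          noise_sd: float = 0.0, seed: int = 0) -> ImageVolume:
    """Phantom image whose anatomy is rigidly moved by ``t`` — analytically.

    The scene is evaluated at ``t``-mapped sample positions (about the grid
    center), so the motion is exact to machine precision with no resampling:
    the ground truth for rigid-registration recovery tests.
    """
    origin = _grid_origin(spec)
    ref = ImageVolume(np.zeros(spec.grid_shape, dtype=np.float32), spec.spacing, origin)
    pts = ref.voxel_centers_mm()
    mapped = t.map_points(pts.reshape(-1, 3), ref.center_mm).reshape(pts.shape)
    hu = _scene_hu(spec, couch, mapped)
    if noise_sd > 0:
        hu = hu + np.random.default_rng(seed).normal(0.0, noise_sd, hu.shape)
    return ImageVolume(hu, spec.spacing, origin)


def make_known_dvf(grid_like, amplitude_mm: float, smoothness_mm: float, seed: int) -> DeformationField:
    """Smooth seeded random displacement field with max magnitude <= amplitude.

    White noise per component is Gaussian-filtered at ``smoothness_mm`` (full
    support, smooth at the stated kernel width) and rescaled so the maximum
    displacement magnitude equals ``amplitude_mm``.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be non-negative")
    shape = grid_like.shape
    if amplitude_mm == 0:
        return DeformationField(np.zeros(shape + (3,)), grid_like.spacing, grid_like.origin)
    rng = np.random.default_rng(seed)
    sigma_vox = np.asarray(smoothness_mm, dtype=float) / grid_like.spacing
    comps = []
    for _ in range(3):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
        comps.append(f)
    u = np.stack(comps, axis=-1)
    mag = np.linalg.norm(u, axis=-1).max()
    if mag > 0:
        u *= amplitude_mm / mag
    return DeformationField(u, grid_like.spacing, grid_like.origin)


def _sag_field(spec: PhantomSpec, grid_like) -> np.ndarray:
    """Systematic couch-induced sag: posterior (+y) shift, strongest anteriorly.

    Moving from a curved diagnostic couch to a flat planning couch flattens the
    patient's back; modelled as a +y displacement that tapers towards the
    posterior body surface and laterally.
    """
    if spec.sag_amplitude_mm == 0:
        return np.zeros(grid_like.shape + (3,))
    pts = grid_like.voxel_centers_mm()
    a, b = spec.body_semiaxes_mm
    w = np.clip(1.0 - (pts[..., 1] / b + 1.0) / 2.0, 0.0, 1.0)  # 1 anterior, 0 posterior
    lat = np.exp(-(pts[..., 0] / a) ** 2)
    u = np.zeros(grid_like.shape + (3,))
    u[..., 1] = spec.sag_amplitude_mm * w * lat
    return u


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate a paired dCT/pCT bundle with known ground-truth deformation.

    The dCT holds pre-deformation anatomy on its couch variant; the pCT holds
    the anatomy displaced by ``true_dvf`` on the planning couch. Masks are
    rasterized analytically in the planning (pCT) frame, so they are exact
    (no interpolation error).
    """
    origin = _grid_origin(spec)
    ref = ImageVolume(np.zeros(spec.grid_shape, dtype=np.float32), spec.spacing, origin)
    pts = ref.voxel_centers_mm()

    gtv_c = np.asarray(spec.gtv_center_mm, dtype=float)
    gtv_r = np.asarray(spec.gtv_semiaxes_mm, dtype=float)
    a, b = spec.body_semiaxes_mm
    # GTV must fit inside the body in-plane ellipse
    corners = gtv_c[:2] + np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]]) * gtv_r[:2]
    if np.any((corners[:, 0] / a) ** 2 + (corners[:, 1] / b) ** 2 > 1.0):
        raise ValueError("GTV extends outside the body")

    rand = make_known_dvf(ref, spec.deform_amplitude_mm, spec.deform_smoothness_mm, spec.seed)
    u = rand.voxels + _sag_field(spec, ref)
    true_dvf = DeformationField(u, spec.spacing, origin)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0FFEE]))

    # dCT: anatomy at rest + diagnostic couch
    spec_d = spec
    if spec.gas_pocket and spec.gas_pocket_pct_only:
        from dataclasses import replace as _replace

        spec_d = _replace(spec, gas_pocket=False)
    sp = np.asarray(spec.spacing, dtype=float)
    hu_d = _scene_hu(spec_d, spec.couch_dct, pts)
    dct = ImageVolume(hu_d + rng.normal(0.0, spec.noise_sd, spec.grid_shape), spec.spacing, origin)

    # pCT: anatomy evaluated at displaced points (exact analytic warp); the
    # planning couch is static, so its overlay is evaluated at rest
    hu_p = _aa(lambda p: _anatomy_hu(spec, p + u), pts, sp) + _aa(
        lambda p: _couch_hu(spec, spec.couch_pct, p), pts, sp
    )
    pct = ImageVolume(hu_p + rng.normal(0.0, spec.noise_sd, spec.grid_shape), spec.spacing, origin)

    # planning-frame masks: indicator evaluated at displaced points
    body = BinaryMask(_body_indicator(spec, pts + u).astype(np.uint8), spec.spacing, origin)
    r = (pts + u - gtv_c) / gtv_r
    gtv = BinaryMask(((r ** 2).sum(axis=-1) <= 1.0).astype(np.uint8), spec.spacing, origin)
    oars = {
        o.name: BinaryMask(_indicator_oar(o, pts + u).astype(np.uint8), spec.spacing, origin)
        for o in spec.oars
    }
    return PhantomBundle(dct=dct, pct=pct, true_dvf=true_dvf, body=body, gtv=gtv,
                         oars=oars, provenance=spec)


# ---------------------------------------------------------------------------
# augmentation utilities
# ---------------------------------------------------------------------------


def augment(v: ImageVolume, op: str, shift_vox=(0, 0, 0)) -> ImageVolume:
    """Training-set augmentation ops: rotate90 (in-plane, clockwise), integer
    translate with air fill, or a centered 128x128 in-plane crop."""
    if op == "rotate90":
        # clockwise in the (x, y) axial plane: exact index permutation
        out = np.rot90(v.voxels, k=-1, axes=(0, 1)).copy()
        return ImageVolume(out, v.spacing[[1, 0, 2]], v.origin)
    if op == "translate":
        shift = tuple(int(s) for s in shift_vox)
        out = np.full_like(v.voxels, AIR_HU)
        src = [slice(max(0, -s), v.shape[a] - max(0, s)) for a, s in enumerate(shift)]
        dst = [slice(max(0, s), v.shape[a] - max(0, -s)) for a, s in enumerate(shift)]
        out[tuple(dst)] = v.voxels[tuple(src)]
        return ImageVolume(out, v.spacing, v.origin)
    if op == "crop128":
        nx, ny = v.shape[0], v.shape[1]
        if nx < 128 or ny < 128:
            raise ValueError(f"crop window 128x128 exceeds in-plane grid {nx}x{ny}")
        ox, oy = (nx - 128) // 2, (ny - 128) // 2
        out = v.voxels[ox:ox + 128, oy:oy + 128, :].copy()
        origin = v.origin + np.array([ox, oy, 0]) * v.spacing
        return ImageVolume(out, v.spacing, origin)
    raise ValueError(f"unknown augmentation op {op!r}")


# ---------------------------------------------------------------------------
# stand-in lattice dose painter
# ---------------------------------------------------------------------------


def _smoothstep_down(t: np.ndarray) -> np.ndarray:
    """1 at t=0 smoothly down to 0 at t=1 (clamped)."""
    t = np.clip(t, 0.0, 1.0)
    return 1.0 - (3.0 * t ** 2 - 2.0 * t ** 3)


def synth_lattice_dose(spheres, gtv: BinaryMask, prescription_cGy: float = 2000.0,
                       valley_ratio: float = 0.35, peak_factor: float = 1.35) -> DoseGrid:
    """Paint a lattice-shaped dose: peaked spheres over a valley plateau.

    A stand-in for a treatment planning system: inside the GTV the dose is a
    ``valley_ratio * prescription`` plateau; each lattice sphere adds an
    isotropic smoothstep kernel falling from its peak at the center to the
    valley at 1.5x the sphere radius. Kernels are scaled so each sphere's
    median dose equals the prescription (within 1%). Dose decays smoothly to
    zero outside the GTV.

    An empty sphere set yields the all-valley dose (with a warning).

    The kernel width is solved so that, for a continuous uniform ball, a peak
    of ``peak_factor * prescription`` at the center gives a median of exactly
    the prescription; the amplitude is then rescaled against the *discrete*
    voxel median so the 1% median contract holds on any grid.
    """
    import warnings

    if not (0.0 < valley_ratio < 1.0):
        raise ValueError("valley_ratio must be in (0, 1)")
    if peak_factor < 1.0:
        raise ValueError("peak_factor must be >= 1")
    gtv_b = gtv.astype_bool()
    # smooth decay outside the GTV (exp falloff over ~12 mm)
    d_out = ndimage.distance_transform_edt(~gtv_b, sampling=gtv.spacing)
    envelope = np.exp(-d_out / 12.0)
    dose = valley_ratio * prescription_cGy * envelope

    centers = np.asarray(getattr(spheres, "centers_mm", spheres), dtype=float).reshape(-1, 3)
    if centers.shape[0] == 0:
        warnings.warn("empty SphereSet: painting all-valley dose", stacklevel=2)
        return DoseGrid(np.maximum(dose, 0.0), gtv.spacing, gtv.origin)

    radius = float(getattr(spheres, "diameter_mm", 15.0)) / 2.0
    width = _kernel_width(radius, valley_ratio, peak_factor)
    pts = gtv.voxel_centers_mm()
    valley = valley_ratio * prescription_cGy
    for c in centers:
        r = np.linalg.norm(pts - c, axis=-1)
        s = _smoothstep_down(r / width)
        inside = r <= radius
        if inside.any():
            med_s = float(np.median(s[inside]))
            amp = (prescription_cGy - valley) / med_s if med_s > 0 else 0.0
        else:
            amp = (peak_factor - valley_ratio) * prescription_cGy
        dose = dose + amp * s
    return DoseGrid(np.maximum(dose, 0.0), gtv.spacing, gtv.origin)


def _kernel_width(radius: float, valley_ratio: float, peak_factor: float) -> float:
    """Smoothstep support radius giving (continuum) sphere-median = prescription
    when the center peak is peak_factor * prescription over the valley."""
    med_target = (1.0 - valley_ratio) / max(peak_factor - valley_ratio, 1e-9)
    if med_target >= 1.0:
        return 1.5 * radius
    r_med = 0.5 ** (1.0 / 3.0) * radius  # median radius of a uniform ball
    # solve smoothstep_down(t) = med_target, i.e. 3t^2 - 2t^3 = 1 - med_target
    lo, hi = 0.0, 1.0
    target = 1.0 - med_target
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if 3 * mid ** 2 - 2 * mid ** 3 < target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return r_med / max(t, 1e-6)
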