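"""Synthetic-CT prediction by deformable registration.

A 3D convolutional encoder-decoder maps a (couch-removed, rigidly aligned)
diagnostic CT to a dense deformation vector field (DVF); the synthetic CT is
the diagnostic CT warped by that field, so every sCT voxel is a trilinear
combination of dCT voxels (no intensity hallucination). Training minimizes an
image-similarity loss against the planning CT plus a diffusion (gradient-L2)
penalty on the field, weighted by ``reg_weight``.

The network is written in numpy with manual backpropagation and is meant for
toy-scale experiments on digital phantoms: it predicts the field at half the
input resolution (most inter-scan deformation is smooth) and upsamples it
trilinearly. The final layer is zero-initialized, so an untrained model is
exactly the identity warp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import _nn
from .grids import DeformationField, ImageVolume, HU_MIN, HU_MAX, warp

__all__ = ["ModelSpec", "TrainedModel", "build_model", "loss", "train", "predict_sct",
           "THORAX_PRESET", "ABDOMEN_PRESET"]

_NORM = HU_MAX - HU_MIN  # 4095


def _normalize(v: ImageVolume) -> np.ndarray:
    return ((np.clip(np.asarray(v.voxels, dtype=np.float32), HU_MIN, HU_MAX) - HU_MIN)
            / _NORM).astype(np.float32)


@dataclass
class ModelSpec:
    spatial_dims: int = 3
    in_channels: int = 1
    levels: int = 3  # resolution levels in the encoder (below the input halving)
    start_channels: int = 32
    similarity_loss: str = "mse"  # mse | lncc
    reg_weight: float = 0.01
    lncc_window_vox: int = 9
    epochs: int = 50
    lr: float = 1e-2
    seed: int = 0
    grid_shape: Optional[tuple] = None  # validated at build time if given

    def __post_init__(self):
        if self.spatial_dims != 3 or self.in_channels != 1:
            raise ValueError("only 3D single-channel inputs are supported")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.similarity_loss not in ("mse", "lncc"):
            raise ValueError(f"unknown similarity loss {self.similarity_loss!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    @property
    def downsample_factor(self) -> int:
        """Total required divisibility of the input grid."""
        return 2 ** self.levels


THORAX_PRESET = ModelSpec()
ABDOMEN_PRESET = ModelSpec()  # same architecture; regions differ only in data


def _channels(spec: ModelSpec) -> List[int]:
    return [spec.start_channels * 2 ** l for l in range(spec.levels)]


def _init_params(spec: ModelSpec) -> dict:
    rng = np.random.default_rng(spec.seed)
    ch = _channels(spec)
    p = {}
    c_in = 1
    for l, c in enumerate(ch):
        p[f"enc{l}_w"] = _nn.he_init(rng, c, c_in)
        p[f"enc{l}_b"] = np.zeros(c, dtype=np.float32)
        c_in = c
    p["bot_w"] = _nn.he_init(rng, ch[-1], ch[-1])
    p["bot_b"] = np.zeros(ch[-1], dtype=np.float32)
    c_up = ch[-1]
    for l in reversed(range(spec.levels - 1)):
        c = ch[l]
        p[f"dec{l}_w"] = _nn.he_init(rng, c, c_up + c)  # upsampled + skip concat
        p[f"dec{l}_b"] = np.zeros(c, dtype=np.float32)
        c_up = c
    # zero-initialized 1x1x1 head: identity warp at initialization
    p["head_w"] = np.zeros((3, c_up, 1, 1, 1), dtype=np.float32)
    p["head_b"] = np.zeros(3, dtype=np.float32)
    return p


def _check_grid(spec: ModelSpec, shape: tuple) -> None:
    f = spec.downsample_factor
    if any(s % f for s in shape):
        raise ValueError(f"grid {shape} not divisible by 2^levels = {f}")


@dataclass
class TrainedModel:
    """Network weights plus provenance (spec, training manifest, loss trace)."""

    spec: ModelSpec
    params: dict = field(repr=False, default=None)
    loss_trace: list = field(default_factory=list)
    manifest: list = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(self.spec).items()},
            "loss_trace": self.loss_trace,
            "manifest": self.manifest,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            params = {k: z[k].copy() for k in z.files if k != "__meta__"}
        spec_d = meta["spec"]
        if spec_d.get("grid_shape"):
            spec_d["grid_shape"] = tuple(spec_d["grid_shape"])
        spec = ModelSpec(**spec_d)
        return cls(spec=spec, params=params, loss_trace=meta["loss_trace"],
                   manifest=meta["manifest"])


def build_model(spec: ModelSpec) -> TrainedModel:
    """Instantiate an untrained model (zero-initialized head => identity warp)."""
    if spec.grid_shape is not None:
        _check_grid(spec, tuple(spec.grid_shape))
    return TrainedModel(spec=spec, params=_init_params(spec))


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _forward(model: TrainedModel, x_norm: np.ndarray, want_cache: bool):
    """x_norm: (X, Y, Z) normalized intensities -> u_mm: (X, Y, Z, 3) in mm.

    The field is predicted on the half-resolution grid and linearly upsampled.
    """
    spec = model.spec
    _check_grid(spec, x_norm.shape)
    p = model.params
    cache = {"acts": []}
    x = _nn.avgpool2(x_norm[None].astype(np.float32))  # (1, X/2, Y/2, Z/2)
    skips = []
    feats = []
    for l in range(spec.levels):
        if l > 0:
            x = _nn.avgpool2(x)
        pre = _nn.conv3_forward(x, p[f"enc{l}_w"], p[f"enc{l}_b"])
        act, neg = _nn.lrelu_forward(pre)
        feats.append((x, neg))
        skips.append(act)
        x = act
    pre = _nn.conv3_forward(x, p["bot_w"], p["bot_b"])
    act, neg_b = _nn.lrelu_forward(pre)
    cache["bot_in"] = x
    cache["bot_neg"] = neg_b
    x = act
    dec_caches = []
    for l in reversed(range(spec.levels - 1)):
        xu = _nn.upsample2_nearest(x)
        xin = np.concatenate([xu, skips[l]], axis=0)
        pre = _nn.conv3_forward(xin, p[f"dec{l}_w"], p[f"dec{l}_b"])
        act, neg = _nn.lrelu_forward(pre)
        dec_caches.append((l, xin, neg, xu.shape[0]))
        x = act
    u_half = _nn.conv3_forward(x, p["head_w"], p["head_b"])  # (3, X/2, Y/2, Z/2)
    cache["head_in"] = x
    u_full = _nn.upsample2_linear(u_half)  # (3, X, Y, Z), mm
    if want_cache:
        cache["enc"] = feats
        cache["dec"] = dec_caches
        return u_full, cache
    return u_full, None


def _backward(model: TrainedModel, cache: dict, g_u_full: np.ndarray) -> dict:
    spec = model.spec
    p = model.params
    grads = {}
    g = _nn.upsample2_linear_backward(g_u_full.astype(np.float32))
    gx, gw, gb = _nn.conv3_backward(cache["head_in"], p["head_w"], g)
    grads["head_w"], grads["head_b"] = gw, gb
    g = gx
    for l, xin, neg, c_up in reversed(cache["dec"]):
        g = _nn.lrelu_backward(g, neg)
        gx, gw, gb = _nn.conv3_backward(xin, p[f"dec{l}_w"], g)
        grads[f"dec{l}_w"], grads[f"dec{l}_b"] = gw, gb
        g_up, g_skip = gx[:c_up], gx[c_up:]
        # skip gradient joins the encoder gradient at level l
        cache.setdefault("skip_grads", {})[l] = g_skip
        g = _nn.upsample2_nearest_backward(g_up)
    g = _nn.lrelu_backward(g, cache["bot_neg"])
    gx, gw, gb = _nn.conv3_backward(cache["bot_in"], p["bot_w"], g)
    grads["bot_w"], grads["bot_b"] = gw, gb
    g = gx
    skip_grads = cache.get("skip_grads", {})
    for l in reversed(range(spec.levels)):
        if l in skip_grads:
            g = g + skip_grads[l]
        x_in, neg = cache["enc"][l]
        g = _nn.lrelu_backward(g, neg)
        gx, gw, gb = _nn.conv3_backward(x_in, p[f"enc{l}_w"], g)
        grads[f"enc{l}_w"], grads[f"enc{l}_b"] = gw, gb
        if l > 0:
            g = _nn.avgpool2_backward(gx)
    return grads


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def diffusion_penalty(u: np.ndarray) -> float:
    """Mean squared forward-difference gradient of the displacement field.

    ``u`` has shape (..., 3) in mm; differences are taken per voxel step along
    each axis and averaged over all (component, axis, position) entries,
    normalizing by 3N (N voxels) so the value is grid-size independent.
    """
    n = np.prod(u.shape[:3])
    total = 0.0
    for ax in range(3):
        d = np.diff(u, axis=ax)
        total += float((d ** 2).sum())
    return total / (3.0 * n)


def _diffusion_grad(u: np.ndarray) -> np.ndarray:
    n = np.prod(u.shape[:3])
    g = np.zeros_like(u)
    for ax in range(3):
        d = np.diff(u, axis=ax)
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        g[tuple(sl_lo)] -= 2.0 * d
        g[tuple(sl_hi)] += 2.0 * d
    return g / (3.0 * n)


def _lncc(a: np.ndarray, b: np.ndarray, win: int) -> np.ndarray:
    uf = lambda z: ndimage.uniform_filter(z, size=win, mode="reflect")
    ua, ub = uf(a), uf(b)
    ac, bc = a - ua, b - ub
    cross = uf(ac * bc)
    va = uf(ac * ac)
    vb = uf(bc * bc)
    eps = 1e-5
    return cross * cross / (va * vb + eps)


def similarity(warped: ImageVolume, target: ImageVolume, spec: ModelSpec) -> float:
    """Similarity loss on normalized intensities (0 iff images identical)."""
    a = _normalize(warped).astype(np.float64)
    b = _normalize(target).astype(np.float64)
    if spec.similarity_loss == "mse":
        return float(np.mean((a - b) ** 2))
    return float(1.0 - np.mean(_lncc(a, b, spec.lncc_window_vox)))


def loss(warped: ImageVolume, target: ImageVolume, dvf: DeformationField,
         spec: ModelSpec) -> Tuple[float, dict]:
    """Total loss = similarity(warped, target) + reg_weight * diffusion(dvf)."""
    if warped.shape != target.shape or dvf.shape != warped.shape:
        raise ValueError("loss requires a shared grid for warped, target and dvf")
    sim = similarity(warped, target, spec)
    reg = diffusion_penalty(np.asarray(dvf.voxels))
    return sim + spec.reg_weight * reg, {"similarity": sim, "regularization": reg}


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def _warp_norm(mov_norm: np.ndarray, u_mm: np.ndarray, spacing: np.ndarray):
    """Warp a normalized image by u (mm); also return sampled image gradients
    (d intensity / d mm displacement component).

    Edge handling is clamp-to-edge ("nearest") rather than constant fill: the
    training objective must be continuous in u at the grid boundary, and a
    constant-fill boundary introduces a jump discontinuity at u = 0.
    """
    idx = np.indices(mov_norm.shape, dtype=np.float64)
    pos = idx + np.moveaxis(u_mm, -1, 0) / spacing.reshape(3, 1, 1, 1)
    warped = ndimage.map_coordinates(mov_norm.astype(np.float64), pos, order=1,
                                     mode="nearest")
    gm = np.gradient(mov_norm.astype(np.float64), *spacing)
    sampled = [
        ndimage.map_coordinates(g, pos, order=1, mode="nearest") for g in gm
    ]
    return warped, np.stack(sampled, axis=-1)


def _pair_step(model: TrainedModel, mov_norm, tgt_norm, spacing, update: bool,
               opt: Optional[_nn.Adam]):
    spec = model.spec
    u_full, cache = _forward(model, mov_norm, want_cache=update)
    u_mm = np.moveaxis(u_full.astype(np.float64), 0, -1)
    warped, img_grad = _warp_norm(mov_norm, u_mm, spacing)
    n = warped.size
    resid = warped - tgt_norm
    if spec.similarity_loss == "mse":
        sim = float(np.mean(resid ** 2))
        g_warped = 2.0 * resid / n
    else:
        win = spec.lncc_window_vox
        uf = lambda z: ndimage.uniform_filter(z, size=win, mode="reflect")
        a = warped
        b = tgt_norm.astype(np.float64)
        ua, ub = uf(a), uf(b)
        ac, bc = a - ua, b - ub
        cross, va, vb = uf(ac * bc), uf(ac * ac), uf(bc * bc)
        eps = 1e-5
        cc = cross * cross / (va * vb + eps)
        sim = float(1.0 - np.mean(cc))
        # windowed-NCC gradient (standard local approximation)
        t1 = uf(2.0 * cross / (va * vb + eps)) * bc
        t2 = uf(2.0 * cross * cross / (va * va * vb + eps)) * ac
        g_warped = -(t1 - t2) / n
    reg = diffusion_penalty(u_mm)
    total = sim + spec.reg_weight * reg
    if not update:
        return total, sim, reg
    g_u = g_warped[..., None] * img_grad  # dL/du in mm^-1 terms
    g_u = g_u + spec.reg_weight * _diffusion_grad(u_mm)
    grads = _backward(model, cache, np.moveaxis(g_u, -1, 0))
    opt.step(model.params, grads)
    return total, sim, reg


def train(pairs: List[Tuple[ImageVolume, ImageVolume]], spec: ModelSpec) -> TrainedModel:
    """Train a DVF model on (dct_ready, pct_ready) pairs.

    Deterministic under a fixed spec.seed; records a per-epoch loss trace
    (mean total loss over pairs) in the returned model's provenance.
    """
    if not pairs:
        raise ValueError("train requires at least one (dct, pct) pair")
    shapes = {tuple(d.shape) for d, p in pairs} | {tuple(p.shape) for d, p in pairs}
    if len(shapes) != 1:
        raise ValueError(f"all training pairs must share one grid, got {shapes}")
    model = build_model(spec)
    spacing = pairs[0][0].spacing
    data = [(_normalize(d), _normalize(p)) for d, p in pairs]
    model.manifest = [
        {"pair": i, "shape": list(d.shape), "spacing": list(map(float, d.spacing))}
        for i, (d, p) in enumerate(pairs)
    ]
    opt = _nn.Adam(model.params, lr=spec.lr)
    initial = float(np.mean([
        _pair_step(model, m, t, spacing, update=False, opt=None)[0] for m, t in data
    ]))
    model.loss_trace.append(initial)
    for _ in range(spec.epochs):
        tot = 0.0
        for m, t in data:
            l, _, _ = _pair_step(model, m, t, spacing, update=True, opt=opt)
            tot += l
        model.loss_trace.append(tot / len(data))
    return model


def predict_sct(model: TrainedModel, dct_ready: ImageVolume) -> Tuple[ImageVolume, DeformationField]:
    """Predict the DVF for one diagnostic CT and warp it into a synthetic CT."""
    x = _normalize(dct_ready)
    u_full, _ = _forward(model, x, want_cache=False)
    dvf = DeformationField(np.moveaxis(u_full.astype(np.float64), 0, -1),
                           dct_ready.spacing, dct_ready.origin)
    sct = warp(dct_ready, dvf)
    return sct, dvf
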