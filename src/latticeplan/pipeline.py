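"""End-to-end orchestration: a reproducible lattice-RT study in miniature.

``run_pipeline`` chains every stage on seeded digital phantoms: phantom
generation -> couch removal / rigid alignment / resampling -> DVF model
training and synthetic-CT prediction -> image-similarity reports -> lattice
sphere placement and audit -> synthetic lattice dose -> DVH metrics against
both the original and the isodose-fitted sphere contours -> paired deviation
report with OAR-limit checks. The JSON report is bit-reproducible from
(config, seed): it contains no timestamps and every number is produced by a
module operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import dose_eval, lattice, metrics, phantom, preprocess, sct_model

DEFAULT_OAR_LIMITS = {
    # name pattern -> (metric, limit)
    "skin": ("D1cc", 600.0),
    "lung": ("MVS", (740.0, 1000.0)),  # >= 1000 cc below 740 cGy
    "liver": ("MVS", (910.0, 700.0)),
    "*": ("D0.03cc", 600.0),
}

__all__ = ["PipelineConfig", "run_pipeline", "render_report", "DEFAULT_OAR_LIMITS"]


@dataclass
class PipelineConfig:
    region: str = "thorax"
    n_cases: int = 3
    grid_shape: tuple = (64, 64, 32)
    spacing: tuple = (4.0, 4.0, 5.0)
    target_shape: tuple = (64, 64, 32)
    model_levels: int = 2
    model_channels: int = 4
    model_epochs: int = 8
    model_lr: float = 2e-2
    reg_weight: float = 0.01
    prescription_cGy: float = 2000.0
    valley_ratio: float = 0.35
    oar_limits: dict = field(default_factory=lambda: dict(DEFAULT_OAR_LIMITS))
    placement: lattice.PlacementParams = field(default_factory=lattice.PlacementParams)
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        for k, v in self.oar_limits.items():
            lim = v[1]
            lim = lim[1] if isinstance(lim, (tuple, list)) else lim
            if lim <= 0:
                raise ValueError(f"OAR limit for {k} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "placement" in raw:
            raw["placement"] = lattice.PlacementParams(**raw["placement"])
        for k in ("grid_shape", "spacing", "target_shape"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def _case_phantom(cfg: PipelineConfig, i: int) -> phantom.PhantomBundle:
    fov = np.asarray(cfg.grid_shape) * np.asarray(cfg.spacing)
    spec = phantom.PhantomSpec(
        region=cfg.region,
        grid_shape=cfg.grid_shape,
        spacing=cfg.spacing,
        body_semiaxes_mm=(0.39 * fov[0], 0.27 * fov[1]),
        lung_semiaxes_mm=(0.14 * fov[0], 0.17 * fov[1], 0.45 * fov[2]),
        body_z_halfextent_mm=0.47 * fov[2],
        gtv_center_mm=(0.16 * fov[0], 0.03 * fov[1], 0.0),
        gtv_semiaxes_mm=(0.14 * fov[0], 0.12 * fov[1], 0.19 * fov[2]),
        oars=(phantom.OarSpec("cord", "cylinder",
                              (0.0, 0.17 * fov[1], 0.0), radius_mm=8.0),),
        sag_amplitude_mm=4.0,
        deform_amplitude_mm=1.0,
        noise_sd=5.0,
        seed=(cfg.seed * 1000 + i) % (2 ** 31),
    )
    return phantom.make_phantom(spec)


def _oar_metrics(dose, mask, name, cfg) -> dose_eval.DVHMetrics:
    if "skin" in name:
        return dose_eval.dvh_metrics(dose, mask, cfg.prescription_cGy, dv_cc=(1.0,), name=name)
    if "lung" in name:
        return dose_eval.dvh_metrics(dose, mask, cfg.prescription_cGy,
                                     mvs_level_cGy=740.0, dv_cc=(0.03,), name=name)
    if "liver" in name:
        return dose_eval.dvh_metrics(dose, mask, cfg.prescription_cGy,
                                     mvs_level_cGy=910.0, dv_cc=(0.03,), name=name)
    return dose_eval.dvh_metrics(dose, mask, cfg.prescription_cGy, dv_cc=(0.03,), name=name)


def _check_limits(name: str, m: dose_eval.DVHMetrics, limits: dict) -> list:
    fails = []
    key = next((k for k in limits if k != "*" and k in name), "*")
    if key not in limits:
        return fails
    metric, lim = limits[key]
    if metric == "D1cc" and m.D1cc is not None and m.D1cc > lim:
        fails.append(f"{name}: D1cc {m.D1cc:.1f} cGy exceeds {lim}")
    elif metric == "D0.03cc" and m.D003cc is not None and m.D003cc > lim:
        fails.append(f"{name}: D0.03cc {m.D003cc:.1f} cGy exceeds {lim}")
    elif metric == "MVS" and m.MVS_cc is not None:
        level, min_cc = lim
        if m.MVS_cc < min_cc:
            fails.append(f"{name}: MVS{level:g} {m.MVS_cc:.0f} cc below required {min_cc} cc")
    return fails


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full study-in-miniature; returns (and optionally writes) the report."""
    bundles = [_case_phantom(cfg, i) for i in range(cfg.n_cases)]
    prep = [preprocess.preprocess_pair(b.dct, b.pct, target_shape=cfg.target_shape)
            for b in bundles]

    mspec = sct_model.ModelSpec(
        levels=cfg.model_levels, start_channels=cfg.model_channels,
        epochs=cfg.model_epochs, lr=cfg.model_lr, reg_weight=cfg.reg_weight,
        seed=cfg.seed % (2 ** 31),
    )
    model = sct_model.train([(p.dct_ready, p.pct_ready) for p in prep], mspec)

    report = {
        "config": _config_dict(cfg),
        "model": {"n_parameters": model.n_parameters,
                  "initial_loss": model.loss_trace[0],
                  "final_loss": model.loss_trace[-1]},
        "cases": [],
    }
    sim_rows = {"dct_vs_pct": [], "sct_vs_pct": []}
    metrics_orig, metrics_fitted = [], []
    all_limit_failures = []
    for i, (b, p) in enumerate(zip(bundles, prep)):
        sct, dvf = sct_model.predict_sct(model, p.dct_ready)
        mask = p.pct_body
        rep_d = metrics.similarity_report(p.dct_ready, p.pct_ready, mask)
        rep_s = metrics.similarity_report(sct, p.pct_ready, mask)
        sim_rows["dct_vs_pct"].append(rep_d.as_dict())
        sim_rows["sct_vs_pct"].append(rep_s.as_dict())

        spheres = lattice.place_spheres(b.gtv, list(b.oars.values()), cfg.placement)
        audit = lattice.audit_placement(spheres, b.gtv, list(b.oars.values()), cfg.placement)
        dose = phantom.synth_lattice_dose(spheres, b.gtv, cfg.prescription_cGy,
                                          cfg.valley_ratio)
        _, sphere_union = lattice.rasterize_spheres(spheres, b.gtv)
        fitted = dose_eval.fit_spheres_from_isodose(dose, cfg.prescription_cGy)
        _, fitted_union = lattice.rasterize_spheres(fitted, b.gtv)

        case_a = {"gtv": dose_eval.dvh_metrics(dose, b.gtv, cfg.prescription_cGy),
                  "spheres": dose_eval.dvh_metrics(dose, sphere_union, cfg.prescription_cGy)}
        case_b = {"gtv": case_a["gtv"],
                  "spheres": dose_eval.dvh_metrics(dose, fitted_union, cfg.prescription_cGy)}
        oar_block = {}
        for name, m in b.oars.items():
            om = _oar_metrics(dose, m, name, cfg)
            oar_block[name] = om.as_dict()
            case_a[name] = om
            case_b[name] = om
            all_limit_failures += _check_limits(name, om, cfg.oar_limits)
        metrics_orig.append(case_a)
        metrics_fitted.append(case_b)
        report["cases"].append({
            "case": i,
            "similarity": {"dct_vs_pct": rep_d.as_dict(), "sct_vs_pct": rep_s.as_dict()},
            "mean_dvf_magnitude_mm": float(dvf.magnitude.mean()),
            "sphere_audit": audit.as_dict(),
            "n_fitted_spheres": len(fitted),
            "dvh": {
                "gtv": case_a["gtv"].as_dict(),
                "spheres_original": case_a["spheres"].as_dict(),
                "spheres_fitted": case_b["spheres"].as_dict(),
                "oars": oar_block,
            },
        })

    comparison = dose_eval.compare_plans(metrics_orig, metrics_fitted)
    report["similarity_summary"] = {
        k: {m: float(np.mean([r[m] for r in rows])) for m in ("mae_HU", "ncc", "ssim", "gmsd")}
        for k, rows in sim_rows.items()
    }
    report["plan_comparison"] = {
        s: {m: {"deviations": [float(x) for x in d],
                "mean": float(np.mean(d)),
                **({"p_value": comparison.tests[s][m]["p_value"],
                    "significant": comparison.tests[s][m]["significant"]}
                   if s in comparison.tests and m in comparison.tests[s] else {})}
            for m, d in block.items()}
        for s, block in comparison.deviations.items()
    }
    report["oar_limit_failures"] = all_limit_failures
    report["pass"] = not all_limit_failures and all(
        not c["sphere_audit"]["violations"] for c in report["cases"]
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=2, sort_keys=True)
    return report


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    for k in ("grid_shape", "spacing", "target_shape"):
        d[k] = list(d[k])
    d["placement"]["axial_spacing_mm"] = list(cfg.placement.axial_spacing_mm)
    d["oar_limits"] = {k: [v[0], list(v[1]) if isinstance(v[1], (tuple, list)) else v[1]]
                       for k, v in cfg.oar_limits.items()}
    return d


def render_report(report: dict) -> str:
    """Human-readable summary: similarity table + deviation listing. No arithmetic
    beyond formatting."""
    lines = []
    lines.append("=== Image similarity (mean over cases) ===")
    summ = report.get("similarity_summary", {})
    if summ:
        lines.append(f"{'metric':<10}{'dCT vs pCT':>14}{'sCT vs pCT':>14}")
        names = {"mae_HU": "MAE (HU)", "ssim": "SSIM", "ncc": "NCC", "gmsd": "GMSD"}
        for m in ("mae_HU", "ssim", "ncc", "gmsd"):
            a = summ.get("dct_vs_pct", {}).get(m)
            b = summ.get("sct_vs_pct", {}).get(m)
            if a is not None and b is not None:
                lines.append(f"{names[m]:<10}{a:>14.4g}{b:>14.4g}")
    lines.append("")
    lines.append("=== DVH deviation (original vs fitted sphere contours) ===")
    cmp_block = report.get("plan_comparison", {})
    if not cmp_block or all(not v for v in cmp_block.values()):
        lines.append("no paired cases")
    else:
        for s, block in cmp_block.items():
            for m, info in block.items():
                devs = np.asarray(info["deviations"], dtype=float)
                med = float(np.median(devs))
                q1, q3 = (float(np.percentile(devs, q)) for q in (25, 75))
                p = info.get("p_value")
                ptxt = f"  p={p:.3g}" if p is not None else ""
                lines.append(f"{s:>10} {m:<10} median {med:+9.3g}  IQR [{q1:+.3g}, {q3:+.3g}]{ptxt}")
    fails = report.get("oar_limit_failures", [])
    if fails:
        lines.append("")
        lines.append("!!! OAR LIMIT VIOLATIONS !!!")
        lines += [f"  - {f}" for f in fails]
    audits = [c["sphere_audit"] for c in report.get("cases", [])]
    bad = [v for a in audits for v in a.get("violations", [])]
    if bad:
        lines.append("")
        lines.append("!!! PLACEMENT VIOLATIONS !!!")
        lines += [f"  - {v}" for v in bad]
    if not fails and not bad:
        lines.append("")
        lines.append("all OAR limits and placement constraints satisfied")
    return "\n".join(lines)
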