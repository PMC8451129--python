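"""Whole-study orchestration: phantom -> fits -> summaries -> statistics.

Simulates both cohorts over the four timepoints from one :class:`StudyConfig`,
runs every fitting stage per subject and timepoint, assembles the long-format
region table, and computes the study's contrast statistics (relative changes,
control-vs-remote bias, group tests, correlations).  All randomness derives
from the study base seed; reruns with the same seeds are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import diffusion as dti
from . import mechanics, relaxometry, scar, stats
from .config import PhantomConfig, StudyConfig, default_phantom_config
from .phantom import (
    GroundTruth,
    build_phantom,
    make_tensor_field,
    simulate_cavity_masks,
    simulate_contour_motion,
    simulate_dwi,
    simulate_lge,
    simulate_molli,
    simulate_multiecho,
    default_inversion_times,
)

log = logging.getLogger("cardiomicro")

PARAM_UNITS = {
    "t1_native": "ms", "t2": "ms", "ecv": "fraction",
    "md": "mm^2/s", "fa": "",
}


def jitter_config(cfg: PhantomConfig, rng: np.random.Generator,
                  sd: float) -> PhantomConfig:
    """Per-subject biological variation: one multiplicative factor per parameter.

    The factor is shared across regions and timepoints (a stable animal-level
    offset), so within-subject contrasts stay centred on the cohort values.
    """
    if sd <= 0:
        return cfg
    factors = {name: 1.0 + rng.normal(0.0, sd)
               for name in ("t1_native_ms", "t1_post_ms", "t2_ms",
                            "md_mm2s", "fa", "ha", "torsion", "strain")}
    data = cfg.model_dump()
    for tp in data["timepoints"]:
        for region in ("remote", "infarct", "blood"):
            rv = tp.get(region)
            if rv is None:
                continue
            for f in ("t1_native_ms", "t1_post_ms", "t2_ms", "md_mm2s"):
                rv[f] *= factors[f]
            rv["fa"] = min(rv["fa"] * factors["fa"], 0.99)
        tp["ha_endo_deg"] = min(tp["ha_endo_deg"] * factors["ha"], 89.0)
        tp["ha_epi_deg"] = max(tp["ha_epi_deg"] * factors["ha"], -89.0)
        tp["torsion_slope_deg_per_mm"] *= factors["torsion"]
        for f in ("grs_pct", "gcs_pct", "gls_pct"):
            tp[f] *= factors["strain"]
    return PhantomConfig(**data)


@dataclass
class TimepointAnalysis:
    """Fitted maps and scalar summaries for one subject at one timepoint."""

    gt: GroundTruth
    maps: dict[str, np.ndarray]
    function: dict[str, float]
    ha_gradient: Optional[dti.HAGradientResult] = None
    scar_result: Optional[scar.ScarResult] = None
    errors: dict[str, str] = field(default_factory=dict)


def analyze_timepoint(gt: GroundTruth, noise_sigma_frac: float,
                      seed: int, s0: float = 1000.0) -> TimepointAnalysis:
    """Simulate every acquisition for one phantom state and fit it back."""
    cfg = gt.config
    myo = gt.myocardium
    fitmask = myo | gt.blood
    seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    maps: dict[str, np.ndarray] = {}
    errors: dict[str, str] = {}

    # --- T2 mapping (9 echoes, dTE 8.8 ms)
    t2_series = simulate_multiecho(
        gt.t2, mask=fitmask, s0=s0, noise_sigma=noise_sigma_frac * s0,
        seed=int(seeds[0]), pixel_spacing_mm=cfg.pixel_spacing_mm,
        slice_spacing_mm=cfg.slice_spacing_mm)
    maps["t2"] = relaxometry.fit_t2_map(t2_series, fitmask)

    # --- native and post-contrast T1 (MOLLI), then ECV
    pre = simulate_molli(gt.t1_native, default_inversion_times(False),
                         mask=fitmask, a=s0, noise_sigma=noise_sigma_frac * s0,
                         seed=int(seeds[1]), pixel_spacing_mm=cfg.pixel_spacing_mm,
                         slice_spacing_mm=cfg.slice_spacing_mm)
    post = simulate_molli(gt.t1_post, default_inversion_times(True),
                          mask=fitmask, a=s0, noise_sigma=noise_sigma_frac * s0,
                          seed=int(seeds[2]), pixel_spacing_mm=cfg.pixel_spacing_mm,
                          slice_spacing_mm=cfg.slice_spacing_mm)
    t1n = relaxometry.fit_t1_map(pre, fitmask)
    t1p = relaxometry.fit_t1_map(post, fitmask)
    maps["t1_native"] = t1n.t1_ms
    maps["t1_post"] = t1p.t1_ms
    if gt.blood.any():
        blood_pre = float(np.nanmean(t1n.t1_ms[gt.blood]))
        blood_post = float(np.nanmean(t1p.t1_ms[gt.blood]))
    else:
        blood_pre, blood_post = cfg.blood_t1_pre_ms, cfg.blood_t1_post_ms
    ecv = relaxometry.compute_ecv_map(
        t1n.t1_ms, t1p.t1_ms, blood_pre, blood_post, cfg.hematocrit, mask=myo)
    maps["ecv"] = ecv.ecv

    # --- diffusion: sigma scaled to the b=100-shell mean myocardial signal
    tensors_true = make_tensor_field(gt)
    protocol = dti.default_protocol()
    b100_mean = s0 * float(np.exp(-100.0 * gt.md[myo]).mean())
    dwi = simulate_dwi(tensors_true, protocol, s0=s0,
                       noise_sigma=noise_sigma_frac * b100_mean,
                       seed=int(seeds[3]),
                       pixel_spacing_mm=cfg.pixel_spacing_mm,
                       slice_spacing_mm=cfg.slice_spacing_mm)
    tf = dti.fit_diffusion_tensor(dwi, protocol, myo)
    md, fa = dti.tensor_metrics(tf)
    maps["md"] = np.where(myo, md, np.nan)
    maps["fa"] = np.where(myo, fa, np.nan)
    ha_map = dti.helix_angle_map(tf, gt.frames)
    maps["ha"] = ha_map
    ha_grad: Optional[dti.HAGradientResult] = None
    try:
        ha_grad = dti.transmural_ha_gradient(ha_map, gt.frames, gt.aha)
    except ValueError as exc:  # pragma: no cover - geometry-dependent
        errors["ha_gradient"] = str(exc)

    # --- LGE scar (only meaningful when scar exists; always simulated)
    scar_res: Optional[scar.ScarResult] = None
    try:
        lge = simulate_lge(gt, seed=int(seeds[4]))
        scar_res = scar.segment_scar_5sd(lge, myo, gt.septum)
    except ValueError as exc:
        errors["scar"] = str(exc)

    # --- function: tracked contours -> torsion/strains; cavity masks -> volumes
    tc = simulate_contour_motion(gt)
    _, peak_torsion = mechanics.torsion_from_contours(tc)
    strains = mechanics.global_strains(tc)
    cavity = simulate_cavity_masks(gt, tc)
    vols = mechanics.lv_volumes(cavity, cfg.slice_spacing_mm, cfg.pixel_spacing_mm)
    function = {
        "lvedv_ml": vols.lvedv_ml, "lvesv_ml": vols.lvesv_ml,
        "sv_ml": vols.sv_ml, "lvef_pct": vols.lvef_pct,
        "peak_torsion_deg_per_mm": peak_torsion,
        "grs_pct": strains["grs_pct"], "gcs_pct": strains["gcs_pct"],
        "gls_pct": strains["gls_pct"],
    }
    if ha_grad is not None:
        function["ha_gradient_deg_per_pct"] = ha_grad.slope_deg_per_pct
    if scar_res is not None:
        function["scar_fraction_pct"] = scar_res.scar_fraction_pct
    return TimepointAnalysis(gt=gt, maps=maps, function=function,
                             ha_gradient=ha_grad, scar_result=scar_res,
                             errors=errors)


@dataclass
class StudyResult:
    region_table: pd.DataFrame
    function_table: pd.DataFrame
    contrasts: pd.DataFrame
    bias: pd.DataFrame
    correlations: dict
    failures: pd.DataFrame


def run_study(cfg: StudyConfig, outdir: Optional[str | Path] = None) -> StudyResult:
    """Simulate and analyse the full two-cohort longitudinal study."""
    t_start = time.time()
    rng = np.random.default_rng(cfg.base_seed)
    subjects = ([("control", f"C{i+1}") for i in range(cfg.n_control)]
                + [("infarct", f"I{i+1}") for i in range(cfg.n_infarct)])
    subject_seeds = rng.integers(0, 2**31 - 1, size=len(subjects))

    region_rows, fn_rows, fail_rows = [], [], []
    for (cohort, sid), sseed in zip(subjects, subject_seeds):
        srng = np.random.default_rng(sseed)
        base = default_phantom_config(
            cohort, grid_size=cfg.grid_size, n_slices=cfg.n_slices,
            noise_sigma_frac=cfg.noise_sigma_frac, seed=int(sseed))
        pcfg = jitter_config(base, srng, cfg.subject_variation)
        for label in cfg.timepoint_labels:
            t0 = time.time()
            try:
                gt = build_phantom(pcfg, label)
                tp_seed = int(srng.integers(0, 2**31 - 1))
                res = analyze_timepoint(gt, cfg.noise_sigma_frac, tp_seed)
            except Exception as exc:  # record and continue per spec
                fail_rows.append({"subject": sid, "timepoint": label,
                                  "stage": "analyze", "error": str(exc)})
                continue
            if cohort == "infarct":
                # the study's remote zone is the septum (AHA segments 8-9)
                rois = {"remote": gt.remote & gt.septum, "infarct": gt.infarct}
            else:
                rois = {"remote": gt.myocardium}
            table = stats.summarize_regions(
                {k: res.maps[k] for k in ("t1_native", "t2", "ecv", "md", "fa")},
                rois, subject=sid, group=cohort, timepoint=label,
                units=PARAM_UNITS)
            region_rows.append(table)
            fn_rows.append({"subject": sid, "group": cohort, "timepoint": label,
                            **res.function})
            for stage, msg in res.errors.items():
                fail_rows.append({"subject": sid, "timepoint": label,
                                  "stage": stage, "error": msg})
            log.info("%s %s done in %.1fs", sid, label, time.time() - t0)

    region_table = (pd.concat(region_rows, ignore_index=True)
                    if region_rows else pd.DataFrame(columns=stats.REGION_TABLE_COLUMNS))
    function_table = pd.DataFrame(fn_rows)
    failures = pd.DataFrame(fail_rows, columns=["subject", "timepoint", "stage", "error"])

    contrast_rows, bias_rows = [], []
    has_infarct = (region_table.get("group") == "infarct").any() if len(region_table) else False
    if has_infarct:
        for param in ("t1_native", "t2", "ecv", "md", "fa"):
            for label in cfg.timepoint_labels:
                for mode in ("infarct_vs_remote", "infarct_vs_baseline"):
                    try:
                        c = stats.relative_change(region_table, param, label, mode=mode)
                    except Exception as exc:
                        fail_rows.append({"subject": "-", "timepoint": label,
                                          "stage": f"contrast:{param}:{mode}",
                                          "error": str(exc)})
                        continue
                    contrast_rows.append({
                        "parameter": param, "timepoint": label, "mode": mode,
                        "mean_pct": c.mean_pct, "sd_pct": c.sd_pct,
                        "n": len(c.per_subject_pct), "p_value": c.p_value,
                    })
                if cfg.n_control > 0:
                    try:
                        b = stats.control_remote_bias(region_table, param, label)
                        bias_rows.append({"parameter": param, "timepoint": label,
                                          "mean_pct": b.mean_pct, "sd_pct": b.sd_pct,
                                          "n_pairs": b.n_pairs})
                    except Exception:
                        pass
    contrasts = pd.DataFrame(contrast_rows)
    bias = pd.DataFrame(bias_rows)

    correlations: dict = {}
    if len(function_table) >= 3 and "ha_gradient_deg_per_pct" in function_table:
        ft = function_table.dropna(subset=["ha_gradient_deg_per_pct", "gls_pct"])
        if len(ft) >= 3 and ft["ha_gradient_deg_per_pct"].std() > 0:
            cr = stats.correlate(ft["ha_gradient_deg_per_pct"], ft["gls_pct"])
            correlations["gls_vs_ha_gradient"] = {
                "r": cr.r, "p_value": cr.p_value, "n": cr.n,
                "slope": cr.slope, "intercept": cr.intercept,
            }

    result = StudyResult(region_table=region_table, function_table=function_table,
                         contrasts=contrasts, bias=bias,
                         correlations=correlations, failures=failures)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        region_table.to_csv(outdir / "region_table.csv", index=False)
        function_table.to_csv(outdir / "function_table.csv", index=False)
        contrasts.to_csv(outdir / "contrasts.csv", index=False)
        bias.to_csv(outdir / "bias.csv", index=False)
        failures.to_csv(outdir / "failures.csv", index=False)
        manifest = {
            "config": cfg.model_dump(mode="json"),
            "n_subjects": len(subjects),
            "runtime_s": round(time.time() - t_start, 2),
            "correlations": correlations,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
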