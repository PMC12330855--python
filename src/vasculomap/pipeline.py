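"""End-to-end orchestration: phantom → relaxometry → layers → bias
correction → vesselness → profiles → depth models → stepwise prediction →
parcel statistics.

The pipeline is configured by a YAML/dict config with stage toggles and
per-stage parameter blocks, runs stages in dependency order, and writes a
JSON manifest (parameters, seeds, output hashes) sufficient to reproduce
deterministic stages byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .depth_models import compare_models, fit_alternatives
from .laminar import equivolumetric_layers, offset_surface, ribbon_sample
from .orientation import correct_orientation_bias, fit_orientation_bias
from .parcel_stats import pearson_bootstrap
from .relaxometry import delta_r2star, fit_r2star
from .synthetic import (ParcelTableSpec, PhantomSpec, SyntheticBundleSpec,
                        make_bundles, make_cortical_phantom, make_parcel_table)
from .tracts import clean_bundle, extract_profile
from .vascular_model import PredictorSet, forward_stepwise, loobcv
from .vesselness import FrangiParams, average_echoes, frangi, vessel_mask_stats

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "r2star", "layers", "b0correct", "frangi",
               "profile", "depthfit", "predict", "stats"]

DEFAULT_CONFIG: dict = {
    "out_dir": "vasculomap_run",
    "seed": 0,
    "stages": {s: True for s in STAGE_ORDER},
    "phantom": {},
    "bundles": {"outlier_fraction": 0.05, "outlier_displacement_sd": 8.0},
    "parcels": {"n_areas": 103},
    "frangi": {"sigmas_mm": [0.25, 0.4, 0.6], "threshold": 0.05},
    "r2star": {"method": "loglinear"},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    import yaml

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    unknown = set(cfg.get("stages", {})) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages in config: {sorted(unknown)}")
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def run_pipeline(config: dict) -> dict:
    """Execute enabled stages in order; return (and write) the run manifest."""
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {})
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": config, "stages": {}}
    state: dict = {}

    for stage in STAGE_ORDER:
        if not stages.get(stage, True):
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, out_dir, seed)
        except Exception as exc:
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                              default=str))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        entry = {"elapsed_s": round(time.time() - t0, 3), "outputs": {}}
        for name, p in (outputs or {}).items():
            p = Path(p)
            entry["outputs"][name] = {"path": str(p), "sha256": _sha256(p)}
        manifest["stages"][stage] = entry
        log.info("stage %s done in %.2fs", stage, entry["elapsed_s"])

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    return manifest


def _stage_simulate(config, state, out_dir, seed):
    spec = PhantomSpec(seed=seed, **config.get("phantom", {}))
    phantom = make_cortical_phantom(spec)
    state["phantom"] = phantom
    bspec = SyntheticBundleSpec(seed=seed + 1, **config.get("bundles", {}))
    state["bundles"] = make_bundles(bspec)
    pspec = ParcelTableSpec(seed=seed + 2, **config.get("parcels", {}))
    state["parcel_table"] = make_parcel_table(pspec)

    outputs = {}
    io.save_nifti(out_dir / "labels.nii", phantom.tissue_labels, phantom.affine)
    io.save_nifti(out_dir / "true_delta_r2star.nii", phantom.true_delta_r2star,
                  phantom.affine)
    io.save_surface(out_dir / "white.surf.gii", phantom.white_surface)
    io.save_surface(out_dir / "pial.surf.gii", phantom.pial_surface)
    io.save_tck(out_dir / "bundles.tck",
                [s for b in state["bundles"] for s in b.streamlines])
    state["parcel_table"].to_csv(out_dir / "parcel_table.csv", index=False)
    for name in ("labels.nii", "true_delta_r2star.nii", "white.surf.gii",
                 "pial.surf.gii", "bundles.tck", "parcel_table.csv"):
        outputs[name] = out_dir / name
    return outputs


def _stage_r2star(config, state, out_dir, seed):
    phantom = state["phantom"]
    method = config.get("r2star", {}).get("method", "loglinear")
    mask = phantom.tissue_labels > 0
    pre = fit_r2star(phantom.pre_echoes, method=method, mask=mask)
    post = fit_r2star(phantom.post_echoes, method=method, mask=mask)
    dmap = delta_r2star(post, pre)
    state["delta_map"] = dmap
    io.save_nifti(out_dir / "delta_r2star.nii", np.nan_to_num(dmap.delta),
                  phantom.affine)
    return {"delta_r2star.nii": out_dir / "delta_r2star.nii"}


def _stage_layers(config, state, out_dir, seed):
    phantom = state["phantom"]
    stack = equivolumetric_layers(phantom.white_surface, phantom.pial_surface)
    swm = offset_surface(phantom.white_surface)
    state["layers"] = stack
    state["swm_surface"] = swm
    # sample ΔR2* on a mid-cortical layer (EL4a) and on the SWM shell
    delta = np.nan_to_num(state["delta_map"].delta)
    gm_idx = stack.names.index("EL4a")
    n_b = stack.n_layers
    inner = stack.layer_surfaces[n_b - 1 - gm_idx]
    outer = stack.layer_surfaces[n_b - gm_idx]
    gm_vals, _ = ribbon_sample(delta, inner, outer, phantom.affine)
    swm_vals, _ = ribbon_sample(delta, swm.mesh, phantom.white_surface,
                                phantom.affine)
    state["gm_metric"] = gm_vals
    state["swm_metric"] = swm_vals
    io.save_metric(out_dir / "delta_EL4a.func.gii", gm_vals)
    io.save_metric(out_dir / "delta_swm.func.gii", swm_vals)
    return {"delta_EL4a.func.gii": out_dir / "delta_EL4a.func.gii",
            "delta_swm.func.gii": out_dir / "delta_swm.func.gii"}


def _stage_b0correct(config, state, out_dir, seed):
    phantom = state["phantom"]
    cos2 = phantom.surface_normal_cos2()
    report = {}
    for key in ("gm_metric", "swm_metric"):
        fit = fit_orientation_bias(state[key], cos2)
        state[key + "_corrected"] = correct_orientation_bias(state[key], cos2, fit)
        report[key] = {"slope": fit.slope, "r": fit.pearson_r, "p": fit.p_value}
    path = out_dir / "b0_bias.json"
    path.write_text(json.dumps(report, indent=2))
    return {"b0_bias.json": path}


def _stage_frangi(config, state, out_dir, seed):
    phantom = state["phantom"]
    fcfg = dict(config.get("frangi", {}))
    threshold = fcfg.pop("threshold", 0.05)
    fcfg["sigmas_mm"] = tuple(fcfg.get("sigmas_mm", (0.25, 0.4, 0.6)))
    params = FrangiParams(**fcfg)
    vol = average_echoes(state["phantom"].post_echoes.echoes)
    vmap = frangi(vol, params, phantom.spec.voxel_size_mm)
    roi = phantom.tissue_labels > 0
    stats = vessel_mask_stats(vmap, threshold, roi,
                              phantom.spec.voxel_size_mm**3)
    state["vesselness"] = vmap
    io.save_nifti(out_dir / "vesselness.nii", vmap.response, phantom.affine)
    path = out_dir / "vessel_stats.json"
    path.write_text(json.dumps({**stats, **vmap.meta, "threshold": threshold},
                               indent=2))
    return {"vesselness.nii": out_dir / "vesselness.nii",
            "vessel_stats.json": path}


def _stage_profile(config, state, out_dir, seed):
    rows = []
    for bundle in state["bundles"]:
        cleaned = clean_bundle(bundle)
        if not cleaned.valid or not cleaned.meets_size_threshold:
            continue
        prof = extract_profile(cleaned)
        for j in range(prof.n_nodes):
            row = {"bundle": prof.name, "node": j,
                   "relative_distance": prof.relative_distance[j]}
            for metric, med in prof.medians.items():
                row[metric] = med[j]
            rows.append(row)
    table = pd.DataFrame(rows)
    state["profiles"] = table
    path = out_dir / "profiles.csv"
    table.to_csv(path, index=False)
    return {"profiles.csv": path}


def _stage_depthfit(config, state, out_dir, seed):
    table = state["profiles"]
    report = {}
    for metric in ("delta_r2star", "ndi", "odi"):
        if metric not in table.columns:
            continue
        grp = table.groupby("node").agg(
            d=("relative_distance", "mean"), y=(metric, "mean"))
        fits = fit_alternatives(grp["d"].to_numpy(), grp["y"].to_numpy())
        cmp_ = compare_models(fits)
        report[metric] = {
            "display_params": fits["exponential"].display_params,
            "winner_aicc": cmp_.winner_aicc,
            "winner_bic": cmp_.winner_bic,
            "criteria": {f: {"aicc": fit.aicc, "bic": fit.bic, "rss": fit.rss}
                         for f, fit in fits.items()},
        }
    path = out_dir / "depth_models.json"
    path.write_text(json.dumps(report, indent=2))
    state["depth_report"] = report
    return {"depth_models.json": path}


def _stage_predict(config, state, out_dir, seed):
    table = state["profiles"]
    data = PredictorSet(table)
    result = forward_stepwise(data)
    cv = loobcv(data, result)
    report = {
        "selected_terms": list(result.selected_terms),
        "coefficients": result.coefficients,
        "bic_path": result.bic_path,
        "in_sample_r": result.r,
        "in_sample_r_squared": result.r_squared,
        "cv_pooled_r": cv.pooled_r,
        "cv_per_bundle_r": cv.per_bundle_r,
    }
    path = out_dir / "stepwise.json"
    path.write_text(json.dumps(report, indent=2, default=float))
    cv.predictions.to_csv(out_dir / "cv_predictions.csv", index=False)
    return {"stepwise.json": path,
            "cv_predictions.csv": out_dir / "cv_predictions.csv"}


def _stage_stats(config, state, out_dir, seed):
    table = state["parcel_table"]
    metrics = [c for c in table.columns if c != "area"]
    report = {}
    base = metrics[0]
    for other in metrics[1:]:
        res = pearson_bootstrap(table[base], table[other], seed=seed)
        report[f"{base}_vs_{other}"] = {"r": res.r, "p_boot": res.p_boot,
                                        "n": res.n}
    path = out_dir / "parcel_stats.json"
    path.write_text(json.dumps(report, indent=2))
    return {"parcel_stats.json": path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "r2star": _stage_r2star,
    "layers": _stage_layers,
    "b0correct": _stage_b0correct,
    "frangi": _stage_frangi,
    "profile": _stage_profile,
    "depthfit": _stage_depthfit,
    "predict": _stage_predict,
    "stats": _stage_stats,
}
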