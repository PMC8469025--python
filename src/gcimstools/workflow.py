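"""End-to-end pipeline: simulate → preprocess → extract → model → compare.

A single structured config (YAML on disk, plain dict in memory) drives all
stages; intermediate artifacts are persisted so the four feature-extraction
methods share one pre-processed dataset container.  Outputs are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import PeakPickingParams, extract_features
from .io import Dataset, read_dataset_container, write_dataset_container
from .modeling import (evaluate_features, peak_vip_from_matrix,
                       peak_vip_from_ric, vip_concordance)
from .preprocess import (PreprocessParams, PsalsaParams, SGParams,
                         preprocess_dataset)
from .synthetic import SynthConfig, simulate_dataset

__all__ = ["default_config", "load_config", "run_workflow",
           "simulate_stage", "preprocess_stage", "extract_stage",
           "model_stage"]


def default_config() -> dict:
    """Demo configuration: a small two-class synthetic study.

    Synthetic intensity units differ from instrument exports, so the
    Psalsa parameters here are chosen for the simulator's scale; the
    instrument-scale defaults live in :class:`PreprocessParams`.
    """
    return {
        "seed": 0,
        "simulate": {
            "n_per_class": [6, 6],
            "n_retention": 600,
            "n_drift": 200,
            "peak_catalog_size": 30,
            "marker_count": 15,
            "marker_effect": 2.0,
            "noise_sd": 15.0,
            "drift_scale_jitter": 0.02,
            "retention_warp_amplitude": 8.0,
        },
        "preprocess": {
            "sg_drift": [5, 2],
            "sg_retention": [9, 2],
            "psalsa_drift": {"lam": 1e5, "p": 5e-3, "k": 50.0},
            "psalsa_retention": {"lam": 1e8, "p": 5e-3, "k": 50.0},
            "rip_retention_window": [0.0, 20.0],
            "tic_drift_window": [7.2, 15.0],
            "cow_segment": 25,
            "cow_slack": 10,
            "cow_overlap": 5,
            "optimize_cow": False,
        },
        "features": {
            "methods": ["ric_area", "ric", "full_matrix", "peak_table"],
            "rip_window": [6.0, 6.8],
            "peaks": {
                "noise_floor": None,
                "exclude_drift_below_ms": 7.2,
                "mode": "per_sample",
            },
        },
        "model": {
            "calibration_fraction": 0.66,
            "max_lv": 6,
            "n_boot": 50,
            "n_perm": 0,
            "reselect_lv": False,
        },
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Demo defaults, overlaid with a YAML file and/or an override dict."""
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def synth_config_from_dict(d: dict, seed: int) -> SynthConfig:
    cfg = SynthConfig(seed=seed)
    known = {k: v for k, v in d.items() if hasattr(cfg, k)}
    for k in ("n_per_class", "amplitude_range"):
        if k in known:
            known[k] = tuple(known[k])
    return replace(cfg, **known)


def preprocess_params_from_dict(d: dict) -> PreprocessParams:
    p = PreprocessParams()
    kw = {}
    for key in ("sg_drift", "sg_retention"):
        if key in d:
            kw[key] = SGParams(*d[key])
    for key in ("psalsa_drift", "psalsa_retention"):
        if key in d:
            kw[key] = PsalsaParams(**d[key])
    for key in ("rip_retention_window", "tic_drift_window"):
        if key in d and d[key] is not None:
            kw[key] = tuple(d[key])
    if "cow_tic_smooth" in d and d["cow_tic_smooth"] is not None:
        kw["cow_tic_smooth"] = SGParams(*d["cow_tic_smooth"])
    for key in ("cow_segment", "cow_slack", "cow_overlap", "optimize_cow",
                "psalsa_max_iter", "psalsa_tol"):
        if key in d:
            kw[key] = d[key]
    return replace(p, **kw)


def peak_params_from_dict(d: dict) -> PeakPickingParams:
    p = PeakPickingParams()
    kw = {k: v for k, v in d.items() if hasattr(p, k)}
    for key in ("min_separation", "axis_caps", "assign_window"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return replace(p, **kw)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def simulate_stage(cfg: dict, outdir: Path) -> tuple[Dataset, object]:
    scfg = synth_config_from_dict(cfg.get("simulate", {}), int(cfg.get("seed", 0)))
    ds, gt = simulate_dataset(scfg)
    write_dataset_container(ds, outdir / "dataset.h5")
    pd.DataFrame({
        "peak": np.arange(gt.peak_tr.size),
        "tr_index": gt.peak_tr,
        "td_index": gt.peak_td,
        "amplitude_class0": gt.amplitudes_class0,
        "amplitude_class1": gt.amplitudes_class1,
        "is_marker": np.isin(np.arange(gt.peak_tr.size), gt.marker_indices),
    }).to_csv(outdir / "ground_truth_peaks.csv", index=False)
    pd.DataFrame({
        "sample": np.arange(len(ds)),
        "label": ds.labels,
        "drift_scale": gt.drift_scales,
        "max_warp": [float(np.abs(w).max()) for w in gt.warp_displacements],
    }).to_csv(outdir / "ground_truth_samples.csv", index=False)
    return ds, gt


def preprocess_stage(cfg: dict, ds: Dataset, outdir: Path) -> tuple[Dataset, dict]:
    params = preprocess_params_from_dict(cfg.get("preprocess", {}))
    processed, log = preprocess_dataset(ds, params)
    write_dataset_container(processed, outdir / "preprocessed.h5")
    with open(outdir / "preprocess_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=float)
    return processed, log


def extract_stage(cfg: dict, ds: Dataset, method: str, outdir: Path):
    fcfg = cfg.get("features", {})
    fm = extract_features(
        ds, method,
        rip_window=tuple(fcfg.get("rip_window", (6.0, 6.8))),
        peak_params=peak_params_from_dict(fcfg.get("peaks", {})),
    )
    fm.to_csv(outdir / f"features_{method}.csv")
    if method == "peak_table":
        fm.metadata["peak_table"].to_csv(
            outdir / "peak_table.csv", outdir / "peak_table_flags.csv")
    return fm


def model_stage(cfg: dict, fm, labels: np.ndarray, seed_seq) -> tuple:
    mcfg = cfg.get("model", {})
    max_lv = mcfg.get("max_lv", 6)
    if fm.kind == "ric_area":
        max_lv = 1
    return evaluate_features(
        fm.values, labels,
        calibration_fraction=mcfg.get("calibration_fraction", 0.66),
        max_lv=max_lv,
        n_boot=mcfg.get("n_boot", 50),
        n_perm=mcfg.get("n_perm", 0),
        reselect_lv=mcfg.get("reselect_lv", False),
        seed=seed_seq,
    )


def run_workflow(cfg: dict, outdir, input_container=None) -> dict:
    """Execute the full pipeline and write a run report.

    Without ``input_container`` a synthetic dataset is simulated from the
    config; otherwise the container is loaded and the simulate stage
    skipped.  Returns the report dict (also written to ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    root_ss = np.random.SeedSequence([seed, 0xF10])

    if input_container is None:
        ds, _gt = simulate_stage(cfg, outdir)
    else:
        ds = read_dataset_container(input_container)
    processed, pre_log = preprocess_stage(cfg, ds, outdir)

    methods = list(cfg.get("features", {}).get(
        "methods", ["ric_area", "ric", "full_matrix", "peak_table"]))
    feature_sets = {m: extract_stage(cfg, processed, m, outdir)
                    for m in methods}

    report: dict = {
        "provenance": {
            "seed": seed,
            "config_hash": _config_hash(cfg),
            "gcimstools_version": __version__,
        },
        "preprocess": {
            "reference_rip_ms": pre_log["reference_rip_ms"],
            "cow_segment": pre_log["cow_segment"],
            "cow_slack": pre_log["cow_slack"],
            "mean_tic_correlation_before": float(np.mean(
                pre_log["tic_correlation_before"])) if pre_log[
                    "tic_correlation_before"] else None,
            "mean_tic_correlation_after": float(np.mean(
                pre_log["tic_correlation_after"])) if pre_log[
                    "tic_correlation_after"] else None,
        },
        "methods": {},
    }

    vips: dict[str, np.ndarray] = {}
    method_streams = root_ss.spawn(len(methods))
    for m, stream in zip(methods, method_streams):
        perf, vip, _model = model_stage(cfg, feature_sets[m], processed.labels,
                                        stream)
        vips[m] = vip
        entry = perf.to_dict()
        if m == "peak_table":
            entry["n_features"] = int(feature_sets[m].n_features)
            entry["fallback_fraction"] = feature_sets[m].metadata[
                "fallback_fraction"]
        report["methods"][m] = entry
        pd.DataFrame({"vip": vip}).to_csv(outdir / f"vip_{m}.csv",
                                          index_label="feature")

    if "peak_table" in vips:
        table = feature_sets["peak_table"].metadata["peak_table"]
        window = peak_params_from_dict(
            cfg.get("features", {}).get("peaks", {})).assign_window
        concordance = {}
        if "full_matrix" in vips:
            mapped = peak_vip_from_matrix(
                vips["full_matrix"], feature_sets["full_matrix"].metadata["shape"],
                table.tr_indices, table.td_indices, window=window)
            concordance["peak_table_vs_full_matrix"] = vip_concordance(
                vips["peak_table"], mapped)
        if "ric" in vips:
            mapped = peak_vip_from_ric(vips["ric"], table.tr_indices)
            concordance["peak_table_vs_ric"] = vip_concordance(
                vips["peak_table"], mapped)
        report["vip_concordance"] = concordance

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
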