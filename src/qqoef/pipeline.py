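"""Stage orchestration: simulate → fit → analyze → report.

Each stage reads only the previous stage's files, stamps its outputs
into an append-only manifest with the config hash and seed, and logs QC
counts (dropped voxels, failed fits).  Rerunning with the same config
and seed reproduces every CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .clustering import decay_features, xmeans
from .config import PipelineConfig
from .fitting import estimate_whole_brain_oef, fit_voxelwise
from .phantom import (make_cohort_roster, make_longitudinal_case, make_phantom)
from .roi import (apply_exclusions, classify_case, relative_metric, roi_mean)
from .stats import paired_t_two_tailed, summarize_cohort

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

_CASE_TYPE = {"dr": "DR", "ndr-enlarged": "NDR-enlarged", "ndr-equal": "NDR-equal"}


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the requested stages in order; returns the output manifest."""
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                      "case": cfg.case, "stages": [], "files": {}, "qc": {}}
    consts = cfg.physio_constants()
    vx = cfg.phantom_config().voxel_size_mm

    for stage in cfg.stages:
        t0 = time.time()
        if stage == "simulate":
            _stage_simulate(cfg, out, manifest, consts)
        elif stage == "fit":
            _stage_fit(cfg, out, manifest, consts)
        elif stage == "analyze":
            _stage_analyze(cfg, out, manifest, vx)
        elif stage == "report":
            _stage_report(cfg, out, manifest)
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 2)})
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

    qio.write_json(out / "manifest.json", manifest)
    return manifest


def _require(manifest_or_dir, out: Path, name: str, stage: str) -> Path:
    path = out / name
    if not path.exists():
        raise FileNotFoundError(f"stage '{stage}' needs missing input {path}")
    return path


def _stage_simulate(cfg: PipelineConfig, out: Path, manifest: dict, consts) -> None:
    pcfg = cfg.phantom_config()
    vx = pcfg.voxel_size_mm
    files = manifest["files"]
    if cfg.case == "cohort":
        roster = make_cohort_roster(seed=cfg.seed)
        roster.to_csv(out / "roster.csv", index=False)
        files["roster"] = "roster.csv"
        return
    if cfg.case == "single":
        truth, chi, echoes = make_phantom(pcfg, consts)
        scans = [(truth, chi, None, echoes)]
        idl = truth.masks["lesion"]
        fi = truth.masks["lesion"]
        midline = truth.midline
        masks = truth.masks
    else:
        case = make_longitudinal_case(_CASE_TYPE[cfg.case], cfg=pcfg,
                                      seed=cfg.seed, consts=consts)
        from .phantom import simulate_mgre
        scans = []
        for s in (0, 1):
            echoes = simulate_mgre(case.truths[s], snr=pcfg.snr,
                                   seed=cfg.seed + s, consts=consts)
            scans.append((case.truths[s], case.chis[s], case.cbfs[s], echoes))
        idl, fi, midline, masks = case.idl, case.fi, case.midline, case.masks

    qio.save_mask(out / "idl.nii.gz", idl, vx)
    qio.save_mask(out / "fi.nii.gz", fi, vx)
    qio.save_mask(out / "brain.nii.gz", masks["brain"], vx)
    qio.save_mask(out / "sinus.nii.gz", masks["sinus"], vx)
    files.update({"idl": "idl.nii.gz", "fi": "fi.nii.gz",
                  "brain": "brain.nii.gz", "sinus": "sinus.nii.gz"})
    qio.write_json(out / "geometry.json",
                   {"midline": float(midline), "voxel_size_mm": vx,
                    "n_scans": len(scans)})
    for s, (truth, chi, cbf, echoes) in enumerate(scans, start=1):
        qio.save_echo_series(out / f"mgre_scan{s}.nii.gz", echoes, vx)
        qio.save_volume(out / f"qsm_scan{s}.nii.gz", chi, vx)
        qio.save_volume(out / f"oef_truth_scan{s}.nii.gz", truth.oef, vx)
        if cbf is not None:
            qio.save_volume(out / f"cbf_scan{s}.nii.gz", cbf, vx)
        files[f"mgre_scan{s}"] = f"mgre_scan{s}.nii.gz"
        files[f"qsm_scan{s}"] = f"qsm_scan{s}.nii.gz"


def _stage_fit(cfg: PipelineConfig, out: Path, manifest: dict, consts) -> None:
    if cfg.case == "cohort":
        logger.info("fit: nothing to fit for a cohort-roster case")
        return
    fcfg = cfg.fit_config()
    geo = qio.read_json(_require(manifest, out, "geometry.json", "fit"))
    vx = geo["voxel_size_mm"]
    brain = qio.load_mask(_require(manifest, out, "brain.nii.gz", "fit"))
    sinus = qio.load_mask(_require(manifest, out, "sinus.nii.gz", "fit"))
    for s in range(1, geo["n_scans"] + 1):
        echoes = qio.load_echo_series(_require(manifest, out, f"mgre_scan{s}.nii.gz", "fit"))
        chi, _ = qio.load_volume(_require(manifest, out, f"qsm_scan{s}.nii.gz", "fit"))
        oef_wb = estimate_whole_brain_oef(chi, sinus, consts)
        tissue = brain & ~sinus      # vein voxels violate the tissue model
        feats = decay_features(echoes, brain_mask=tissue)
        clusters = xmeans(feats.features, seed=fcfg.seed)
        clusters.voxel_index = feats.voxel_index
        maps = fit_voxelwise(echoes, chi, clusters, tissue, fcfg, oef_wb,
                             consts=consts)
        qio.save_volume(out / f"oef_scan{s}.nii.gz", maps.oef, vx)
        for name in ("Y", "nu", "R2", "S0", "chi_nb"):
            qio.save_volume(out / f"{name.lower()}_scan{s}.nii.gz",
                            getattr(maps, name), vx)
        qio.write_json(out / f"fit_provenance_scan{s}.json", maps.provenance)
        manifest["files"][f"oef_scan{s}"] = f"oef_scan{s}.nii.gz"
        manifest["qc"][f"scan{s}"] = {
            "dropped_voxels": feats.dropped,
            "failed_fits": maps.provenance["failed_voxel_fits"],
            "K": maps.provenance["K"],
            "oef_wb": maps.provenance["oef_wb"],
        }


def _stage_analyze(cfg: PipelineConfig, out: Path, manifest: dict, vx: float) -> None:
    if cfg.case == "cohort":
        roster = pd.read_csv(_require(manifest, out, "roster.csv", "analyze"))
        included, tally = apply_exclusions(roster)
        included.to_csv(out / "included.csv", index=False)
        qio.write_json(out / "screening.json",
                       {"total": len(roster), "included": len(included),
                        "excluded": int(len(roster) - len(included)),
                        "tally": tally})
        manifest["files"]["included"] = "included.csv"
        return
    geo = qio.read_json(_require(manifest, out, "geometry.json", "analyze"))
    midline = geo["midline"]
    brain = qio.load_mask(out / "brain.nii.gz")
    idl = qio.load_mask(out / "idl.nii.gz")
    fi = qio.load_mask(out / "fi.nii.gz")
    from .roi import derive_regions
    rr, mismatch = derive_regions(idl, fi)
    vol = lambda m: float(m.sum()) * vx ** 3
    case_class = classify_case(vol(idl), vol(fi))

    regions = {"idl": idl, "fi": fi}
    if rr.any():
        regions["rr"] = rr
    if mismatch.any():
        regions["mismatch"] = mismatch
    rows = []
    for s in range(1, geo["n_scans"] + 1):
        metric_maps = {}
        oef_path = out / f"oef_scan{s}.nii.gz"
        if oef_path.exists():
            metric_maps["oef"], _ = qio.load_volume(oef_path)
        cbf_path = out / f"cbf_scan{s}.nii.gz"
        if cbf_path.exists():
            metric_maps["cbf"], _ = qio.load_volume(cbf_path)
        for metric, vol_map in metric_maps.items():
            for rname, rmask in regions.items():
                mean, excl = roi_mean(vol_map, rmask, brain)
                rel = relative_metric(vol_map, rmask, midline, brain)
                rows.append({"scan": s, "region": rname, "metric": metric,
                             "mean": mean, "relative": rel,
                             "edge_excluded_voxels": excl})
    df = pd.DataFrame(rows)
    df.to_csv(out / "roi_metrics.csv", index=False, float_format="%.6f")
    qio.write_json(out / "case_classification.json",
                   {"class": case_class, "vol_idl_ml": vol(idl) / 1000.0,
                    "vol_fi_ml": vol(fi) / 1000.0})
    manifest["files"]["roi_metrics"] = "roi_metrics.csv"
    manifest["files"]["case_classification"] = "case_classification.json"


def _stage_report(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    if cfg.case == "cohort":
        included = pd.read_csv(_require(manifest, out, "included.csv", "report"))
        summary = summarize_cohort(included)
        summary.table.to_csv(out / "phase_summary.csv", index=False)
        (out / "phase_summary.md").write_text(summary.to_markdown() + "\n")
        manifest["files"]["phase_summary"] = "phase_summary.csv"
        try:
            from .plots import phase_summary_figure
            phase_summary_figure(included, out / "phase_summary.png")
            manifest["files"]["phase_summary_figure"] = "phase_summary.png"
        except Exception as exc:     # plotting must never sink a run
            logger.warning("figure generation failed: %s", exc)
        return
    metrics_path = out / "roi_metrics.csv"
    if not metrics_path.exists():
        logger.info("report: no roi_metrics.csv; nothing to report")
        return
    df = pd.read_csv(metrics_path)
    lines = ["# Longitudinal ROI report", ""]
    for metric in sorted(df["metric"].unique()):
        lines.append(f"## {metric}")
        sub = df[df["metric"] == metric]
        piv = sub.pivot_table(index="region", columns="scan", values="relative")
        lines.append(piv.to_string())
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
    manifest["files"]["report"] = "report.md"
    try:
        from .plots import longitudinal_figure
        longitudinal_figure(df, out / "longitudinal.png")
        manifest["files"]["longitudinal_figure"] = "longitudinal.png"
    except Exception as exc:
        logger.warning("figure generation failed: %s", exc)
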