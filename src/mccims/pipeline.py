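"""End-to-end pipeline: simulate/read → homogenize → preprocess →
detect → merge/cluster → featurize → compare → evaluate.

Every run writes its artifacts plus a ``manifest.json`` recording the
config hash, the master seed, per-stage counts and success/failure, so
any output can be traced back to the exact configuration that produced
it.  The whole run is deterministic under a fixed master seed.
"""

from __future__ import annotations

import json
from dataclasses import replace
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import (
    classify,
    compare,
    detect_lms,
    detect_pme,
    detect_regionmerge,
    detect_watershed,
    io as mio,
    postprocess,
    synthdata,
)
from .config import PipelineConfig
from .homogenize import homogenize as homogenize_set
from .model import MeasurementGrid, PeakList

logger = logging.getLogger(__name__)

DETECTORS = ("lms", "watershed", "regionmerge", "pme")


def detect_peaks(grid: MeasurementGrid, method: str, config: PipelineConfig) -> PeakList:
    if method == "lms":
        return detect_lms.detect(grid, config.lms)
    if method == "watershed":
        return detect_watershed.detect(grid, config.watershed)
    if method == "regionmerge":
        return detect_regionmerge.detect(grid, config.regionmerge)
    if method == "pme":
        return detect_pme.detect(grid, config.pme)
    raise ValueError(f"unknown detector {method!r}")


def load_measurements(input_dir: Path) -> tuple[List[MeasurementGrid], Dict[str, str]]:
    """Read all measurement files and the labels table from a directory."""
    input_dir = Path(input_dir)
    grids = [
        mio.read_measurement(p) for p in sorted(input_dir.glob("*.ims.csv"))
    ]
    labels_path = input_dir / "labels.csv"
    labels_df = pd.read_csv(labels_path, dtype=str)
    labels = dict(zip(labels_df["measurement_id"], labels_df["label"]))
    return grids, labels


def write_cohort(cohort: synthdata.SyntheticCohort, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for grid in cohort.measurements:
        mio.write_measurement(grid, out_dir / f"{grid.metadata.measurement_id}.ims.csv")
    pd.DataFrame(
        {"measurement_id": list(cohort.labels), "label": list(cohort.labels.values())}
    ).to_csv(out_dir / "labels.csv", index=False)
    mio.write_peak_list(cohort.all_truth_peaks(), out_dir / "ground_truth_peaks.csv")


def run_pipeline(
    config: PipelineConfig,
    input_dir: Optional[Path] = None,
    output_dir: Path = Path("mccims_out"),
    detectors: Sequence[str] = DETECTORS,
    repeats: int = 20,
    folds: int = 10,
    evaluate: bool = True,
) -> Dict:
    """Run all stages; returns the manifest dictionary."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "status": "running",
    }
    try:
        if input_dir is None:
            spec = replace(config.simulate, seed=config.seed)
            cohort = synthdata.simulate_cohort(spec)
            measurements, labels = cohort.measurements, cohort.labels
        else:
            measurements, labels = load_measurements(Path(input_dir))
        manifest["stages"]["input"] = {"measurements": len(measurements)}

        kept = homogenize_set(measurements, config.homogenize)
        manifest["stages"]["homogenize"] = {"kept": len(kept)}

        from .preprocess import preprocess_pipeline

        processed = [preprocess_pipeline(g, config.preprocess) for g in kept]
        manifest["stages"]["preprocess"] = {"measurements": len(processed)}

        feature_paths = {}
        merged_lists: Dict[str, PeakList] = {}
        for method in detectors:
            peaks = [p for g in processed for p in detect_peaks(g, method, config)]
            raw = PeakList(detector=method, peaks=peaks)
            merged = postprocess.merge_all(raw, config.merge)
            merged_lists[method] = merged
            clusters = postprocess.cluster_across(merged.peaks, config.merge)
            fm = postprocess.build_feature_matrix(
                clusters, [g.metadata.measurement_id for g in processed], labels
            )
            mio.write_peak_list(merged, output_dir / f"peaks_{method}.csv")
            fm_path = output_dir / f"features_{method}.csv"
            mio.write_feature_matrix(fm, fm_path)
            feature_paths[method] = fm_path
            manifest["stages"][f"detect_{method}"] = {
                "peaks": len(merged),
                "clusters": len(clusters),
            }

        if len(merged_lists) > 1:
            table = compare.overlap_table(merged_lists, config.merge)
            table.to_csv(output_dir / "overlap_table.csv")
            manifest["stages"]["compare"] = {"lists": len(merged_lists)}

        if evaluate:
            rows = []
            for method, fm_path in feature_paths.items():
                fm = mio.read_feature_matrix(fm_path)
                for family in ("linear_svm", "random_forest"):
                    spec = classify.ModelSpec(family=family)
                    results = classify.repeated_cv(
                        fm, spec, repeats=repeats, k=folds, seed=config.seed
                    )
                    for rep, m in enumerate(results):
                        rows.append(
                            {"detector": method, "model": family, "repeat": rep, **m.as_dict()}
                        )
            metrics = pd.DataFrame(rows)
            metrics.to_csv(output_dir / "metrics.csv", index=False)
            summary = (
                metrics.drop(columns="repeat")
                .groupby(["detector", "model"])
                .agg(["mean", "std"])
            )
            summary.to_csv(output_dir / "metrics_summary.csv")
            manifest["stages"]["evaluate"] = {"rows": len(rows)}
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        _write_manifest(manifest, output_dir)
        raise
    _write_manifest(manifest, output_dir)
    return manifest


def _write_manifest(manifest: Dict, output_dir: Path) -> None:
    with open(Path(output_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
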