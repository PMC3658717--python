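"""End-to-end orchestration: segment -> extract -> calibrate / determine.

The two procedures share their first stages: raw data is read row-wise from
the store, plots are detected from the lower light curtain, and every
per-plot parameter is reduced into the result store.  In *calibrate* mode
the determined values are then regressed through the origin against a
reference-trait table; in *determine* mode an existing calibration model is
applied to produce trait estimates.

Extraction is idempotent: existing (plot, repetition, sensor, parameter)
rows in the result store are kept and only missing combinations are
recomputed, so an interrupted analysis resumes where it stopped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .calibrate import ThroughOriginCalibration, apply_calibration, fit_calibration
from .core import FeatureRecord, FieldPlan, PARAMETERS, RowRecording
from .features import FeatureParams, extract_plot_features
from .segment import SegmentationParams, detect_plots
from .store import (
    append_results,
    read_field_plan,
    read_raw_store,
    read_results,
    results_to_frame,
)

log = logging.getLogger(__name__)


def extract_pass(
    recordings: Iterable[RowRecording],
    plan: FieldPlan,
    seg_params: SegmentationParams | None = None,
    feat_params: FeatureParams | None = None,
    repetition: int = 1,
    skip_keys: set | None = None,
) -> list[FeatureRecord]:
    """Segment every row and reduce every plot to its parameter set.

    ``skip_keys`` is a set of (plot_id, repetition, parameter) combinations
    already present in the result store; matching records are not recomputed.
    """
    records: list[FeatureRecord] = []
    for rec in recordings:
        segments = detect_plots(rec, plan.plots_per_row[rec.row_id], seg_params)
        for seg in segments:
            if skip_keys is not None and all(
                (seg.plot_id, repetition, p) in skip_keys for p in PARAMETERS
            ):
                continue
            plot_records = extract_plot_features(seg, rec, feat_params, repetition)
            if skip_keys is not None:
                plot_records = [
                    r for r in plot_records
                    if (r.plot_id, r.repetition, r.parameter) not in skip_keys
                ]
            records.extend(plot_records)
    return records


def _existing_keys(results_path: Path) -> set:
    if not results_path.exists():
        return set()
    df = read_results(results_path)
    return {
        (str(r.plot_id), int(r.repetition), str(r.parameter))
        for r in df.itertuples(index=False)
    }


def calibrate_from_results(
    results: pd.DataFrame,
    reference: pd.DataFrame,
    parameter: str = "lc_height",
    trait: str = "height_mm",
    fit_intercept: bool = False,
) -> ThroughOriginCalibration:
    """Join determined values with reference traits and fit y = b*x.

    Determined values are averaged over available repetitions per plot;
    plots missing either side are dropped.
    """
    det = (
        results.loc[results["parameter"] == parameter]
        .dropna(subset=["value"])
        .groupby("plot_id", as_index=False)["value"].mean()
    )
    ref = reference[["plot_id", trait]].copy()
    ref["plot_id"] = ref["plot_id"].astype(str)
    merged = det.merge(ref, on="plot_id", how="inner").dropna()
    if len(merged) < 2:
        raise ValueError(
            f"calibration needs >= 2 plots with both {parameter} and {trait}; "
            f"got {len(merged)}"
        )
    return fit_calibration(
        merged["value"], merged[trait], trait=trait, fit_intercept=fit_intercept
    )


def run_pipeline(config: dict) -> dict:
    """Execute one full calibrate/determine procedure from a config mapping.

    Returns a summary dict of produced artifact paths and key numbers; also
    writes a JSON run log next to the result store.
    """
    mode = config.get("mode")
    if mode not in ("calibrate", "determine"):
        raise ValueError(f"mode must be 'calibrate' or 'determine', got {mode!r}")
    store_dir = Path(config["raw_store"])
    plan = read_field_plan(config["plan"])
    results_path = Path(config["results"])
    repetition = int(config.get("repetition", 1))
    seg_params = SegmentationParams(**config.get("segmentation", {}))
    feat_params = FeatureParams()

    existing = _existing_keys(results_path)
    expected = {
        (pid, repetition, p)
        for row in plan.rows
        for pid in plan.plots_per_row[row]
        for p in PARAMETERS
    }
    missing = expected - existing
    if missing:
        recordings = read_raw_store(store_dir)
        new_records = extract_pass(
            recordings, plan, seg_params, feat_params, repetition,
            skip_keys=existing if existing else None,
        )
        results = append_results(new_records, results_path)
        log.info("extracted %d new records into %s", len(new_records), results_path)
    else:
        results = read_results(results_path)
        log.info("result store up to date; no recomputation")

    summary: dict = {
        "mode": mode,
        "results": str(results_path),
        "n_records": int(len(results)),
        "up_to_date": not missing,
    }

    if mode == "calibrate":
        reference = pd.read_csv(config["reference"], dtype={"plot_id": str})
        model = calibrate_from_results(
            results,
            reference,
            parameter=config.get("parameter", "lc_height"),
            trait=config.get("trait", "height_mm"),
            fit_intercept=bool(config.get("fit_intercept", False)),
        )
        model_path = Path(config.get("model", results_path.with_name("model.json")))
        model.to_json(model_path)
        summary.update(model=str(model_path), slope=model.slope_, r2_c=model.r2_, mre_c=model.mre_)
    else:
        model_path = Path(config["model"])
        if not model_path.exists():
            raise FileNotFoundError(f"determine mode requires a calibration model: {model_path}")
        model = ThroughOriginCalibration.from_json(model_path)
        parameter = config.get("parameter", "lc_height")
        det = (
            results.loc[results["parameter"] == parameter]
            .dropna(subset=["value"])
            .groupby("plot_id", as_index=False)["value"].mean()
        )
        det[model.trait or "trait"] = apply_calibration(model, det["value"])
        out_path = Path(config.get("traits_out", results_path.with_name("traits.csv")))
        det.to_csv(out_path, index=False)
        summary.update(model=str(model_path), traits_out=str(out_path), n_plots=len(det))

    run_log = {
        "version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
        "segmentation": asdict(seg_params),
        "summary": summary,
    }
    log_path = results_path.with_suffix(".runlog.json")
    log_path.write_text(json.dumps(run_log, indent=2, default=str))
    summary["run_log"] = str(log_path)
    return summary
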