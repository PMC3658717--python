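"""File-backed raw and result stores.

The platform's acquisition side keeps one database table per sensor; here that
is emulated by a directory tree with a JSON manifest:

    rawstore/
      manifest.json              schema version, sensor specs, row index
      row_<id>/
        LDS1.csv                 scalar sensors: time_ms,position_mm,value
        LC_lower.npz             matrix sensors: time_ms, position_mm, payload
        ...

Matrix payloads (light-curtain columns, depth frames, hyperspectral lines) are
stored either in NumPy ``.npz`` containers (default) or as per-frame CSV rows
(``matrix_format="csv"``, payload flattened row-major after the two stamp
columns).  Both round-trip bit-exactly.

The result store is a flat CSV with columns
``plot_id,repetition,sensor,parameter,value``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    FieldPlan,
    FeatureRecord,
    Layout,
    RowRecording,
    SensorKind,
    SensorSpec,
    SensorStream,
    Stamp,
    View,
)

SCHEMA_VERSION = 1

_PAYLOAD_DTYPES = {
    SensorKind.LIGHT_CURTAIN: np.uint8,
    SensorKind.LASER_DISTANCE: np.float64,
    SensorKind.TOF_CAMERA: np.float64,
    SensorKind.HYPERSPECTRAL: np.uint8,
}


class RawStoreError(RuntimeError):
    pass


def _spec_to_json(spec: SensorSpec) -> dict:
    return {
        "name": spec.name,
        "kind": spec.kind.value,
        "view": spec.view.value,
        "frame_rate_hz": spec.frame_rate_hz,
        "offset_mm": spec.offset_mm,
        "geometry": dict(spec.geometry),
    }


def _spec_from_json(d: dict) -> SensorSpec:
    return SensorSpec(
        name=d["name"],
        kind=SensorKind(d["kind"]),
        view=View(d["view"]),
        frame_rate_hz=d["frame_rate_hz"],
        offset_mm=d["offset_mm"],
        geometry=d.get("geometry", {}),
    )


def _stream_filename(name: str, kind: SensorKind, matrix_format: str) -> str:
    if kind is SensorKind.LASER_DISTANCE:
        return f"{name}.csv"
    return f"{name}.npz" if matrix_format == "npz" else f"{name}.csv"


def _write_stream(stream: SensorStream, path: Path, matrix_format: str) -> None:
    kind = stream.spec.kind
    if kind is SensorKind.LASER_DISTANCE:
        df = pd.DataFrame(
            {"time_ms": stream.time_ms, "position_mm": stream.position_mm, "value": stream.payload}
        )
        df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    elif matrix_format == "npz":
        np.savez(path, time_ms=stream.time_ms, position_mm=stream.position_mm, payload=stream.payload)
    else:
        flat = stream.payload.reshape(len(stream), -1)
        cols = [f"v{i}" for i in range(flat.shape[1])]
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "position_mm", stream.position_mm)
        df.insert(0, "time_ms", stream.time_ms)
        df.to_csv(path, index=False, float_format="%.17g")


def _read_stream(spec: SensorSpec, path: Path) -> SensorStream:
    kind = spec.kind
    dtype = _PAYLOAD_DTYPES[kind]
    if path.suffix == ".npz":
        with np.load(path) as z:
            t, p, payload = z["time_ms"], z["position_mm"], z["payload"]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        t = df["time_ms"].to_numpy(np.int64)
        p = df["position_mm"].to_numpy(np.int64)
        if kind is SensorKind.LASER_DISTANCE:
            payload = df["value"].to_numpy(dtype)
        else:
            flat = df.drop(columns=["time_ms", "position_mm"]).to_numpy(dtype)
            payload = flat.reshape((len(df),) + spec.payload_shape())
    return SensorStream(spec=spec, time_ms=t, position_mm=p, payload=payload.astype(dtype, copy=False))


def write_raw_store(
    recordings: Sequence[RowRecording],
    directory: str | Path,
    matrix_format: str = "npz",
) -> dict:
    """Persist recordings to ``directory``; returns the manifest dict."""
    if matrix_format not in ("npz", "csv"):
        raise ValueError(f"matrix_format must be 'npz' or 'csv', got {matrix_format!r}")
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "matrix_format": matrix_format,
        "sensors": {},
        "rows": [],
    }
    for rec in recordings:
        row_dir = root / f"row_{rec.row_id}"
        row_dir.mkdir(exist_ok=True)
        files = {}
        for name, stream in rec.streams.items():
            manifest["sensors"].setdefault(name, _spec_to_json(stream.spec))
            fname = _stream_filename(name, stream.spec.kind, matrix_format)
            _write_stream(stream, row_dir / fname, matrix_format)
            files[name] = f"row_{rec.row_id}/{fname}"
        manifest["rows"].append(
            {
                "row_id": rec.row_id,
                "start": list(rec.start),
                "end": list(rec.end),
                "files": files,
            }
        )
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_raw_store(directory: str | Path) -> list[RowRecording]:
    """Load all row recordings previously written by :func:`write_raw_store`."""
    root = Path(directory)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise RawStoreError(f"no manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise RawStoreError(
            f"raw store schema version {version} is not supported (expected {SCHEMA_VERSION})"
        )
    specs = {name: _spec_from_json(d) for name, d in manifest["sensors"].items()}
    recordings = []
    for row in manifest["rows"]:
        streams = {}
        for name, rel in row["files"].items():
            path = root / rel
            if not path.exists():
                raise RawStoreError(
                    f"row {row['row_id']}: missing data file for sensor {name} ({rel})"
                )
            streams[name] = _read_stream(specs[name], path)
        recordings.append(
            RowRecording(
                row_id=row["row_id"],
                start=Stamp(*row["start"]),
                end=Stamp(*row["end"]),
                streams=streams,
            )
        )
    return recordings


# --- field plan ------------------------------------------------------------

def write_field_plan(plan: FieldPlan, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "rows": plan.rows,
            "plots_per_row": plan.plots_per_row,
            "layout": {
                "n_rows": plan.layout.n_rows,
                "m_plots": plan.layout.m_plots,
                "plot_length_mm": plan.layout.plot_length_mm,
                "gap_mm": plan.layout.gap_mm,
            },
        }
        path.write_text(json.dumps(payload, indent=2))
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row_id", "plot_id", "order"])
        for row_id in plan.rows:
            for order, plot_id in enumerate(plan.plots_per_row[row_id]):
                w.writerow([row_id, plot_id, order])
        # layout parameters ride along as a comment-free trailer file
    layout_path = path.with_suffix(".layout.json")
    layout_path.write_text(
        json.dumps(
            {
                "n_rows": plan.layout.n_rows,
                "m_plots": plan.layout.m_plots,
                "plot_length_mm": plan.layout.plot_length_mm,
                "gap_mm": plan.layout.gap_mm,
            }
        )
    )


def read_field_plan(path: str | Path) -> FieldPlan:
    path = Path(path)
    if path.suffix == ".json" and not path.name.endswith(".layout.json"):
        d = json.loads(path.read_text())
        return FieldPlan(
            rows=list(d["rows"]),
            plots_per_row={k: list(v) for k, v in d["plots_per_row"].items()},
            layout=Layout(**d["layout"]),
        )
    df = pd.read_csv(path, dtype={"row_id": str, "plot_id": str})
    df = df.sort_values(["row_id", "order"], kind="stable")
    rows = list(dict.fromkeys(df["row_id"]))
    plots = {r: list(df.loc[df["row_id"] == r, "plot_id"]) for r in rows}
    layout_path = path.with_suffix(".layout.json")
    if layout_path.exists():
        layout = Layout(**json.loads(layout_path.read_text()))
    else:
        layout = Layout(n_rows=len(rows), m_plots=max(len(p) for p in plots.values()))
    return FieldPlan(rows=rows, plots_per_row=plots, layout=layout)


# --- result store ----------------------------------------------------------

RESULT_COLUMNS = ["plot_id", "repetition", "sensor", "parameter", "value"]


def results_to_frame(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    rows = [
        {
            "plot_id": r.plot_id,
            "repetition": r.repetition,
            "sensor": r.sensor,
            "parameter": r.parameter,
            "value": r.value,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(records: Iterable[FeatureRecord] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else results_to_frame(records)
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"plot_id": str, "sensor": str, "parameter": str})


def append_results(records: Iterable[FeatureRecord], path: str | Path) -> pd.DataFrame:
    """Merge new records into an existing result CSV, keyed by
    (plot_id, repetition, sensor, parameter); new values win."""
    path = Path(path)
    new = results_to_frame(records)
    if path.exists():
        old = read_results(path)
        merged = pd.concat([old, new], ignore_index=True)
        merged = merged.drop_duplicates(
            subset=["plot_id", "repetition", "sensor", "parameter"], keep="last"
        )
    else:
        merged = new
    merged.to_csv(path, index=False)
    return merged
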