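"""Light-curtain-based plot detection within a row recording.

A moving coverage profile (fraction of interrupted barriers within a
position window) is computed from the lower curtain, thresholded with
hysteresis — a candidate plot opens when coverage rises above the threshold
and closes only after a sustained gap — and candidates shorter than a
minimum plot length are discarded.  Detected segment boundaries are then
refined to the first/last curtain column actually containing interrupted
barriers, and plot identities are assigned from the field plan in traversal
order.  A mismatch between detected and planned plot counts is an
operator-facing error, not something to silently repair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    FieldPlan,
    PlotSegment,
    RowRecording,
    SensorKind,
    SensorStream,
    Stamp,
    align_stream,
)

log = logging.getLogger(__name__)


class PlotCountError(RuntimeError):
    """Detected plot count disagrees with the field plan."""


@dataclass
class SegmentationParams:
    smoothing_window_mm: int = 100
    coverage_threshold: float = 0.05
    min_gap_mm: int = 300
    min_plot_mm: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_threshold < 1.0):
            raise ValueError("coverage_threshold must lie in (0,1)")
        if self.smoothing_window_mm <= 0:
            raise ValueError("smoothing_window_mm must be positive")


def coverage_profile(lc_stream: SensorStream, window_mm: int = 100):
    """Moving interrupted-barrier fraction along the row.

    For every curtain column, the fraction of interrupted barrier readings
    among all readings of columns within +-window/2 mm of it.  Returns
    ``(position_mm, coverage)`` arrays in aligned (ground) coordinates.
    """
    if lc_stream.spec.kind is not SensorKind.LIGHT_CURTAIN:
        raise ValueError("coverage_profile expects a light-curtain stream")
    if len(lc_stream) == 0:
        raise ValueError("coverage_profile: empty stream")
    stream = align_stream(lc_stream)
    pos = stream.position_mm
    per_column = stream.payload.astype(np.float64).mean(axis=1)
    half = window_mm / 2.0
    csum = np.concatenate([[0.0], np.cumsum(per_column)])
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    cov = (csum[hi] - csum[lo]) / (hi - lo)
    return pos, cov


def detect_plots(
    row: RowRecording,
    plan_plot_ids: list[str],
    params: SegmentationParams | None = None,
) -> list[PlotSegment]:
    """Divide a row recording into per-plot segments using the lower curtain.

    Raises :class:`PlotCountError` when the number of detected candidate
    plots differs from the field plan's count for this row.
    """
    if params is None:
        params = SegmentationParams()
    if "LC_lower" not in row.streams:
        raise ValueError(f"row {row.row_id}: lower light-curtain stream missing")
    stream = align_stream(row.streams["LC_lower"])
    pos, cov = coverage_profile(stream, params.smoothing_window_mm)
    above = cov > params.coverage_threshold

    # candidate regions of consecutive above-threshold columns
    regions = _runs(above)
    # hysteresis: close sub-min_gap dips between consecutive regions
    merged: list[list[int]] = []
    for lo, hi in regions:
        if merged and pos[lo] - pos[merged[-1][1] - 1] < params.min_gap_mm:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    # discard candidates shorter than the minimum plot length
    candidates = [
        (lo, hi) for lo, hi in merged if pos[hi - 1] - pos[lo] >= params.min_plot_mm
    ]
    if len(candidates) != len(plan_plot_ids):
        raise PlotCountError(
            f"row {row.row_id}: detected {len(candidates)} plots but the field "
            f"plan lists {len(plan_plot_ids)}"
        )

    # a genuine plant column interrupts a sizable barrier run; isolated
    # flipped barriers must not move the boundary
    col_fraction = stream.payload.astype(bool).mean(axis=1)
    col_has_plant = col_fraction > params.coverage_threshold
    segments = []
    for plot_id, (lo, hi) in zip(plan_plot_ids, candidates):
        # refine to the first/last plant column: the smoothing window
        # otherwise widens each plot by up to window/2
        inside = np.flatnonzero(col_has_plant[lo:hi]) + lo
        if inside.size:
            first, last = int(inside[0]), int(inside[-1])
        else:  # pathological: threshold crossed on smoothing alone
            first, last = lo, hi - 1
        segments.append(
            PlotSegment(
                plot_id=plot_id,
                start=Stamp(int(stream.time_ms[first]), int(pos[first])),
                end=Stamp(int(stream.time_ms[last]), int(pos[last])),
            )
        )
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index runs of True values."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return list(zip(starts.tolist(), ends.tolist()))


def plot_length(segment: PlotSegment) -> int:
    """Detected plot length: end position minus start position, mm."""
    return segment.length_mm


def segment_pass(
    recordings: list[RowRecording],
    plan: FieldPlan,
    params: SegmentationParams | None = None,
) -> dict[str, list[PlotSegment]]:
    """Detect plots in every row of a pass; returns segments per row id."""
    out = {}
    for rec in recordings:
        out[rec.row_id] = detect_plots(rec, plan.plots_per_row[rec.row_id], params)
    return out
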