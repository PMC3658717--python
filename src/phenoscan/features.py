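"""Per-plot statistical data reduction for every sensor modality.

All reductions are order statistics over the pooled samples of one plot:

* extreme-fraction means ("average of the 3% maximum distances", "1% highest
  interrupted light barriers") with selection count k = max(1, ceil(f*N));
* the light-curtain plant height combines the highest stacked barrier indices
  with the ground-distance profile measured by the laser under the curtain,
  so the height is expressed above actual ground rather than above the rig;
* the top-view laser / depth-camera height is the spread between the 3%
  largest distances (ground hits through canopy gaps) and the 3% smallest
  (canopy surface); penetration depths compare the mean return against the
  nearest surface;
* depth-camera statistics pool all pixels of all frames of the plot and then
  apply the identical reductions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    FeatureRecord,
    LC_BARRIER_PITCH_MM,
    LC_N_BARRIERS,
    PARAMETER_SENSORS,
    PlotSegment,
    RowRecording,
    SensorStream,
    align_stream,
    slice_by_position,
)
from .hsi import SamParams, hsi_coverage_density

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtremeFractionRule:
    """Mean of the most extreme ``fraction`` of values, k = max(1, ceil(f*N))."""

    fraction: float
    side: str = "highest"  # or "lowest"

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if self.side not in ("highest", "lowest"):
            raise ValueError("side must be 'highest' or 'lowest'")

    def count(self, n: int) -> int:
        return max(1, math.ceil(self.fraction * n))


TOP_RULE = ExtremeFractionRule(0.03, "highest")
BOTTOM_RULE = ExtremeFractionRule(0.03, "lowest")
LC_HEIGHT_RULE = ExtremeFractionRule(0.01, "highest")


def extreme_mean(values, rule: ExtremeFractionRule) -> float:
    """Mean of the k most extreme values (stable sort; ties deterministic)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("extreme_mean: empty input")
    k = rule.count(v.size)
    s = np.sort(v, kind="stable")
    sel = s[-k:] if rule.side == "highest" else s[:k]
    return float(sel.mean())


def lc_coverage_density(lc_lower_slice: SensorStream) -> float:
    """Fraction of interrupted barrier readings over all lower-curtain
    columns of the plot."""
    if len(lc_lower_slice) == 0:
        raise ValueError("lc_coverage_density: empty slice")
    return float(np.mean(lc_lower_slice.payload != 0))


@dataclass
class GroundProfile:
    """Step-function ground distance per 100-mm along-track increment."""

    increment_start_mm: np.ndarray
    ground_mm: np.ndarray
    increment_mm: int = 100

    def lookup(self, positions_mm: np.ndarray) -> np.ndarray:
        """Ground distance of the increment containing each position."""
        idx = np.searchsorted(self.increment_start_mm, positions_mm, side="right") - 1
        idx = np.clip(idx, 0, len(self.ground_mm) - 1)
        return self.ground_mm[idx]


def ground_distance_profile(
    lds3_slice: SensorStream,
    start_mm: int,
    end_mm: int,
    increment_mm: int = 100,
    rule: ExtremeFractionRule = TOP_RULE,
    min_partial_samples: int = 10,
) -> GroundProfile:
    """Per-increment 3%-maximum mean distance to ground under the curtain.

    The 3%-maximum rule keeps the ground hits and discards shorter returns
    off low plant parts.  A trailing partial increment keeps its own value
    when it holds at least ``min_partial_samples`` samples, otherwise it is
    merged with the previous increment.  Increments without samples are
    linearly interpolated from their neighbours and flagged in the log.
    """
    if len(lds3_slice) == 0:
        raise ValueError("ground_distance_profile: empty slice")
    pos = lds3_slice.aligned_position_mm
    d = np.asarray(lds3_slice.payload, dtype=float)
    starts = np.arange(start_mm, end_mm, increment_mm, dtype=np.int64)
    edges = np.append(starts, end_mm)
    counts, _ = np.histogram(pos, bins=edges)
    # merge an undersampled trailing partial increment into its neighbour
    if len(starts) > 1 and (end_mm - starts[-1]) < increment_mm and counts[-1] < min_partial_samples:
        starts = starts[:-1]
        edges = np.append(starts, end_mm)
        counts, _ = np.histogram(pos, bins=edges)
    values = np.full(len(starts), np.nan)
    bin_idx = np.searchsorted(edges, pos, side="right") - 1
    for i in range(len(starts)):
        sel = d[bin_idx == i]
        if sel.size:
            values[i] = extreme_mean(sel, rule)
    empty = ~np.isfinite(values)
    if empty.any():
        if empty.all():
            raise ValueError("ground_distance_profile: no samples in any increment")
        log.warning("interpolating %d empty ground increments", int(empty.sum()))
        centers = starts + increment_mm / 2.0
        values[empty] = np.interp(centers[empty], centers[~empty], values[~empty])
    return GroundProfile(increment_start_mm=starts, ground_mm=values, increment_mm=increment_mm)


def lc_plant_height(
    lc_lower_slice: SensorStream,
    lc_upper_slice: SensorStream | None,
    profile: GroundProfile,
    rule: ExtremeFractionRule = LC_HEIGHT_RULE,
    per_column: bool = False,
) -> float:
    """Plant height from the 1% highest interrupted light barriers.

    Interrupted (column, barrier) readings of both curtains are pooled over
    the plot on a stacked barrier index (lower 0-287, upper 288-575, pitch
    2.5 mm); each of the k highest readings contributes
    ``index * 2.5 mm + ground distance`` of its column's increment, and the
    mean is returned.  With ``per_column=True`` only each column's maximum
    index enters the pool (the alternative reading of the plot-level rule).
    """
    pools = []
    for stream, base in ((lc_lower_slice, 0), (lc_upper_slice, LC_N_BARRIERS)):
        if stream is None or len(stream) == 0:
            continue
        col, bar = np.nonzero(stream.payload)
        if col.size == 0:
            continue
        idx = bar + base
        pos = stream.aligned_position_mm[col]
        if per_column:
            # keep only the top barrier per column
            order = np.lexsort((idx, col))
            col_s, idx_s, pos_s = col[order], idx[order], pos[order]
            last = np.append(np.diff(col_s) != 0, True)
            idx, pos = idx_s[last], pos_s[last]
        pools.append((idx, pos))
    if not pools:
        raise ValueError("no canopy detected: zero interrupted barriers in plot")
    idx = np.concatenate([p[0] for p in pools])
    pos = np.concatenate([p[1] for p in pools])
    k = rule.count(idx.size)
    order = np.argsort(-idx, kind="stable")[:k]
    heights = idx[order] * LC_BARRIER_PITCH_MM + profile.lookup(pos[order])
    return float(heights.mean())


def lds_top_height(values) -> float:
    """3%-maximum mean minus 3%-minimum mean of top-view distances."""
    return extreme_mean(values, TOP_RULE) - extreme_mean(values, BOTTOM_RULE)


def lds_top_penetration(values) -> float:
    """Mean of all top-view distances minus the 3%-minimum mean."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("lds_top_penetration: empty input")
    return float(v.mean()) - extreme_mean(v, BOTTOM_RULE)


def lds_side_penetration(values) -> float:
    """Mean of all side-view distances."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("lds_side_penetration: empty input")
    return float(v.mean())


def tof_top_height(frames) -> float:
    """Top-view height statistic over the pooled pixels of all depth frames."""
    return lds_top_height(np.asarray(frames, dtype=float).ravel())


def tof_top_penetration(frames) -> float:
    return lds_top_penetration(np.asarray(frames, dtype=float).ravel())


def tof_side_penetration(frames) -> float:
    return lds_side_penetration(np.asarray(frames, dtype=float).ravel())


@dataclass
class FeatureParams:
    """Knobs of the per-plot reductions."""

    ground_increment_mm: int = 100
    lc_height_rule: ExtremeFractionRule = LC_HEIGHT_RULE
    extreme_rule: ExtremeFractionRule = TOP_RULE
    lc_per_column: bool = False
    sam: SamParams = field(default_factory=SamParams)


def extract_plot_features(
    plot: PlotSegment,
    row: RowRecording,
    params: FeatureParams | None = None,
    repetition: int = 1,
) -> list[FeatureRecord]:
    """Compute the full nine-parameter set for one plot.

    Streams are aligned into ground coordinates and sliced to the plot's
    half-open extent.  A failing parameter (for example an empty depth-camera
    slice on a very short plot) yields a NaN-valued record rather than
    aborting the plot.
    """
    if params is None:
        params = FeatureParams()
    a, b = plot.start.position_mm, plot.end.position_mm
    sl: dict[str, SensorStream | None] = {}
    for name, stream in row.streams.items():
        sl[name] = slice_by_position(align_stream(stream), a, b)

    profile = None
    if sl.get("LDS3") is not None and len(sl["LDS3"]):
        try:
            profile = ground_distance_profile(
                sl["LDS3"], a, b, params.ground_increment_mm, params.extreme_rule
            )
        except ValueError as exc:
            log.warning("plot %s: ground profile failed: %s", plot.plot_id, exc)

    def compute(parameter: str):
        if parameter == "lc_height":
            if profile is None:
                raise ValueError("no ground profile")
            return lc_plant_height(
                sl["LC_lower"], sl.get("LC_upper"), profile,
                params.lc_height_rule, params.lc_per_column,
            )
        if parameter == "lc_coverage_density":
            return lc_coverage_density(sl["LC_lower"])
        if parameter == "lds1_height":
            return lds_top_height(sl["LDS1"].payload)
        if parameter == "lds1_penetration_top":
            return lds_top_penetration(sl["LDS1"].payload)
        if parameter == "lds2_penetration_side":
            return lds_side_penetration(sl["LDS2"].payload)
        if parameter == "tof1_height":
            return tof_top_height(sl["ToF1"].payload)
        if parameter == "tof1_penetration_top":
            return tof_top_penetration(sl["ToF1"].payload)
        if parameter == "tof2_penetration_side":
            return tof_side_penetration(sl["ToF2"].payload)
        if parameter == "hsi_coverage_density":
            return hsi_coverage_density(sl["HSI"], params.sam)
        raise KeyError(parameter)

    records = []
    for parameter, sensor in PARAMETER_SENSORS.items():
        try:
            value = float(compute(parameter))
        except (ValueError, KeyError, AttributeError, TypeError) as exc:
            log.warning("plot %s: %s missing (%s)", plot.plot_id, parameter, exc)
            value = float("nan")
        records.append(
            FeatureRecord(
                plot_id=plot.plot_id,
                repetition=repetition,
                sensor=sensor,
                parameter=parameter,
                value=value,
            )
        )
    return records
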