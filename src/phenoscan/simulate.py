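"""Synthetic field-trial recordings with known ground truth.

The simulator emulates a tractor-pulled sensor rig traversing rows of yield
plots at constant speed, emitting all eight sensor streams with realistic
frame rates and position/time stamps, so that every downstream stage
(segmentation, feature extraction, calibration statistics) can be exercised
against exact truth without field data.

Canopy model
------------
Each row is a 1-D profile over integer ground millimetres.  Inside a plot a
column is plant with probability equal to the plot's coverage density; plant
columns get a canopy surface height drawn from Normal(true_height, sigma_h).
The ground under the curtain drifts slowly (sinusoidal terrain), moving the
curtain's nominal 200 mm clearance with it.  Between plots there is bare
ground.  The canopy realisation is a property of the field, so it is shared
between repeated passes; only sensor noise is redrawn per repetition.

Sensor forward models
---------------------
* light curtains: barrier ``i`` (stacked index, lower 0-287, upper 288-575)
  sits at ``clearance + i * 2.5 mm`` above ground and is interrupted when a
  plant column reaches it, with Bernoulli dropout of interrupted readings
  (missed detections);
* LDS1 / ToF1 (top view): distance = mount height minus canopy height over
  plant, minus zero over gaps (ground hit), plus Gaussian noise; the top
  mount tracks each plot's height at a constant canopy clearance;
* LDS2 / ToF2 (side view): near return off the outer plant rows, deeper
  returns through canopy gaps, far return between plots;
* LDS3 (ground): curtain-bottom-to-ground distance following the terrain,
  with occasional short returns off low plant parts;
* HSI: per line, a fixed count of plant pixels (rounded from the plot's
  coverage density) carrying a moisture-scaled plant endmember, the rest
  soil, plus band-wise Gaussian noise, quantised to byte counts.

All randomness flows from one master seed through named child seeds per
(row, sensor, repetition); the canopy realisation uses its own child seed
independent of the repetition index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_FRAME_RATES,
    DEFAULT_SENSOR_OFFSETS_MM,
    FieldPlan,
    HSI_N_SPATIAL,
    LC_BARRIER_PITCH_MM,
    LC_GROUND_CLEARANCE_MM,
    LC_N_BARRIERS,
    Layout,
    RowRecording,
    SENSOR_NAMES,
    SensorStream,
    Stamp,
    TOF_FRAME_SHAPE,
    default_sensor_suite,
)
from .hsi import plant_endmember, soil_endmember

#: platform height envelope, mm
MAX_PLANT_HEIGHT_MM = 1600.0

_MARGIN_MM = 600  # stamp lead-in/out so offset sensors cover the whole row
_HSI_CHUNK = 512  # frames per HSI generation block (memory bound)


@dataclass
class NoiseConfig:
    """Stochastic terms of the forward models.

    ``canopy_sigma_mm`` and ``terrain_amplitude_mm`` describe the field
    itself (shared between repeated passes); the remaining terms are sensor
    noise, redrawn independently per repetition.
    """

    canopy_sigma_mm: float = 25.0
    terrain_amplitude_mm: float = 15.0
    # light-barrier noise is missed detections (thin organs, occlusion
    # jitter), modelled as Bernoulli dropout of interrupted readings;
    # industrial barriers do not trigger falsely at random heights
    lc_dropout_prob: float = 0.02
    lds_sigma_mm: float = 8.0
    tof_sigma_mm: float = 15.0
    hsi_sigma_counts: float = 3.0
    lds3_short_prob: float = 0.03

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """Fully deterministic forward models (flat terrain, uniform canopy)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "NoiseConfig":
        """Scale the *sensor* noise terms; canopy and terrain are untouched."""
        return replace(
            self,
            lc_dropout_prob=self.lc_dropout_prob * factor,
            lds_sigma_mm=self.lds_sigma_mm * factor,
            tof_sigma_mm=self.tof_sigma_mm * factor,
            hsi_sigma_counts=self.hsi_sigma_counts * factor,
            lds3_short_prob=self.lds3_short_prob * factor,
        )


@dataclass
class SimConfig:
    """Study conditions for one simulated trial."""

    layout: Layout = field(default_factory=lambda: Layout(n_rows=2, m_plots=5))
    speed_mm_s: float = 500.0
    frame_rates_hz: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FRAME_RATES))
    sensor_offsets_mm: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SENSOR_OFFSETS_MM))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    height_range_mm: tuple[float, float] = (400.0, 1500.0)
    coverage_range: tuple[float, float] = (0.5, 0.95)
    moisture_range: tuple[float, float] = (0.1, 0.5)
    top_clearance_mm: float = 500.0
    side_distance_mm: float = 400.0
    side_gap_extra_mm: float = 600.0
    side_far_mm: float = 1500.0
    terrain_wavelength_mm: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0:
            raise ValueError("speed_mm_s must be positive")
        if any(r <= 0 for r in self.frame_rates_hz.values()):
            raise ValueError("all frame rates must be positive")
        if not (0 <= self.height_range_mm[0] <= self.height_range_mm[1] <= MAX_PLANT_HEIGHT_MM):
            raise ValueError(f"height range must lie within [0, {MAX_PLANT_HEIGHT_MM}] mm")

    def sensors(self) -> dict:
        return default_sensor_suite(self.sensor_offsets_mm, self.frame_rates_hz)


@dataclass
class PlotTruth:
    """Ground truth for one simulated plot (positions in row-local ground
    coordinates)."""

    plot_id: str
    row_id: str
    true_height_mm: float
    coverage_density: float
    moisture: float
    start_mm: int
    end_mm: int


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def simulate_field(config: SimConfig) -> tuple[FieldPlan, list[PlotTruth]]:
    """Draw per-plot truths for the configured layout; deterministic in seed."""
    lay = config.layout
    rng = _child_rng(config.seed, 101)
    rows = [f"R{r + 1:02d}" for r in range(lay.n_rows)]
    plots_per_row: dict[str, list[str]] = {}
    truths: list[PlotTruth] = []
    idx = 0
    for row_id in rows:
        ids = []
        for k in range(lay.m_plots):
            idx += 1
            pid = f"P{idx:03d}"
            ids.append(pid)
            start = lay.gap_mm + k * (lay.plot_length_mm + lay.gap_mm)
            truths.append(
                PlotTruth(
                    plot_id=pid,
                    row_id=row_id,
                    true_height_mm=float(rng.uniform(*config.height_range_mm)),
                    coverage_density=float(rng.uniform(*config.coverage_range)),
                    moisture=float(rng.uniform(*config.moisture_range)),
                    start_mm=start,
                    end_mm=start + lay.plot_length_mm,
                )
            )
        plots_per_row[row_id] = ids
    plan = FieldPlan(rows=rows, plots_per_row=plots_per_row, layout=lay)
    return plan, truths


@dataclass
class _RowCanopy:
    """Per-millimetre canopy realisation over one row."""

    length_mm: int
    plot_index: np.ndarray   # int, -1 between plots
    is_plant: np.ndarray     # bool
    height: np.ndarray       # canopy surface height above ground, mm
    clearance: np.ndarray    # curtain-bottom-to-ground distance, mm
    h_top: np.ndarray        # top-view mount height above ground, mm
    truths: list[PlotTruth]


def _build_canopy(row_truths: Sequence[PlotTruth], config: SimConfig,
                  rng: np.random.Generator) -> _RowCanopy:
    L = config.layout.row_length_mm
    g = np.arange(L)
    plot_index = np.full(L, -1, dtype=np.int64)
    for k, t in enumerate(row_truths):
        plot_index[t.start_mm:t.end_mm] = k

    noise = config.noise
    in_plot = plot_index >= 0
    coverage = np.zeros(L)
    true_h = np.zeros(L)
    for k, t in enumerate(row_truths):
        sel = plot_index == k
        coverage[sel] = t.coverage_density
        true_h[sel] = t.true_height_mm
    is_plant = in_plot & (rng.random(L) < coverage)
    height = np.where(
        is_plant,
        true_h + (noise.canopy_sigma_mm * rng.standard_normal(L) if noise.canopy_sigma_mm else 0.0),
        0.0,
    )
    np.clip(height, 0.0, MAX_PLANT_HEIGHT_MM, out=height)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    clearance = LC_GROUND_CLEARANCE_MM + noise.terrain_amplitude_mm * np.sin(
        2.0 * np.pi * g / config.terrain_wavelength_mm + phase
    )

    # operator keeps the top sensors ~constant clearance over each plot;
    # between plots the mount holds the nearest plot's setting
    centers = np.array([(t.start_mm + t.end_mm) / 2.0 for t in row_truths])
    nearest = np.argmin(np.abs(g[:, None] - centers[None, :]), axis=1) if len(row_truths) else np.zeros(L, int)
    h_top = np.array([t.true_height_mm for t in row_truths])[nearest] + config.top_clearance_mm

    return _RowCanopy(L, plot_index, is_plant, height, clearance, h_top, list(row_truths))


def _frame_stamps(rate_hz: float, speed_mm_s: float, extent_mm: int,
                  t0_ms: int) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative half-up-rounded stamps for a constant-speed traversal."""
    step_mm = speed_mm_s / rate_hz
    n = int(np.floor(extent_mm / step_mm)) + 1
    j = np.arange(n)
    pos = np.floor(j * step_mm + 0.5).astype(np.int64)
    t = t0_ms + np.floor(j * 1000.0 / rate_hz + 0.5).astype(np.int64)
    return t, pos


def _sample_canopy(canopy: _RowCanopy, ground_mm: np.ndarray):
    """Look up canopy columns at the given ground positions; positions off
    the row are bare ground."""
    valid = (ground_mm >= 0) & (ground_mm < canopy.length_mm)
    gc = np.clip(ground_mm, 0, canopy.length_mm - 1)
    plant = canopy.is_plant[gc] & valid
    height = np.where(plant, canopy.height[gc], 0.0)
    plot_index = np.where(valid, canopy.plot_index[gc], -1)
    return valid, plant, height, plot_index, canopy.clearance[gc], canopy.h_top[gc]


def _lc_payload(curtain: str, plant, height, clearance, dropout_prob, rng) -> np.ndarray:
    i_max = np.where(plant, np.floor((height - clearance) / LC_BARRIER_PITCH_MM), -1.0)
    if curtain == "upper":
        i_max = i_max - LC_N_BARRIERS
    idx = np.arange(LC_N_BARRIERS)
    interrupted = idx[None, :] <= i_max[:, None]
    if dropout_prob > 0:
        # missed detections only: interrupted readings drop out at random
        interrupted &= rng.random(interrupted.shape) >= dropout_prob
    return interrupted.astype(np.uint8)


def _hsi_payload(plot_index, config: SimConfig, truths: Sequence[PlotTruth],
                 structure_rng, noise_rng, sigma: float) -> np.ndarray:
    n = plot_index.shape[0]
    plant_specs = np.stack([plant_endmember(t.moisture) for t in truths]) if truths else np.zeros((1, 320))
    soil = soil_endmember()
    k_per_plot = np.array(
        [int(np.floor(t.coverage_density * HSI_N_SPATIAL + 0.5)) for t in truths] + [0]
    )
    k = k_per_plot[plot_index]  # -1 -> trailing 0 entry (all soil between plots)
    # fixed random spatial arrangement of plant pixels per line (plant
    # structure: shared across repetitions via the structure rng)
    r = structure_rng.random((n, HSI_N_SPATIAL))
    ranks = np.argsort(np.argsort(r, axis=1), axis=1)
    mask = ranks < k[:, None]

    out = np.empty((n, HSI_N_SPATIAL, soil.shape[0]), dtype=np.uint8)
    spec_idx = np.clip(plot_index, 0, max(len(truths) - 1, 0))
    if sigma > 0:
        spec_f32 = plant_specs.astype(np.float32)
        soil_f32 = soil.astype(np.float32)
        for lo in range(0, n, _HSI_CHUNK):
            hi = min(lo + _HSI_CHUNK, n)
            block = np.where(
                mask[lo:hi, :, None],
                spec_f32[spec_idx[lo:hi]][:, None, :],
                soil_f32[None, None, :],
            )
            block += sigma * noise_rng.standard_normal(block.shape, dtype=np.float32)
            np.clip(block, 0.0, 255.0, out=block)
            out[lo:hi] = (block + 0.5).astype(np.uint8)
    else:
        spec_u8 = np.floor(np.clip(plant_specs, 0, 255) + 0.5).astype(np.uint8)
        soil_u8 = np.floor(np.clip(soil, 0, 255) + 0.5).astype(np.uint8)
        for lo in range(0, n, _HSI_CHUNK):
            hi = min(lo + _HSI_CHUNK, n)
            out[lo:hi] = np.where(
                mask[lo:hi, :, None],
                spec_u8[spec_idx[lo:hi]][:, None, :],
                soil_u8[None, None, :],
            )
    return out


def iter_pass(field: FieldPlan, truths: Sequence[PlotTruth], config: SimConfig,
              repetition: int = 1) -> Iterator[RowRecording]:
    """Lazily generate one recording per row (memory-friendly for long rows)."""
    lay = config.layout
    sensors = config.sensors()
    # every stream must put at least one sample inside each plot
    slowest = min(config.frame_rates_hz.values())
    if lay.plot_length_mm < config.speed_mm_s / slowest:
        raise ValueError(
            "speed/frame-rate combination yields zero samples per plot "
            f"(coarsest along-track step {config.speed_mm_s / slowest:.0f} mm "
            f"> plot length {lay.plot_length_mm} mm)"
        )
    by_row: dict[str, list[PlotTruth]] = {r: [] for r in field.rows}
    for t in truths:
        by_row[t.row_id].append(t)

    extent = lay.row_length_mm + _MARGIN_MM
    row_duration_ms = int(np.ceil(extent / config.speed_mm_s * 1000.0)) + 30_000

    for row_idx, row_id in enumerate(field.rows):
        canopy_rng = _child_rng(config.seed, 11, row_idx)
        canopy = _build_canopy(by_row[row_id], config, canopy_rng)
        t0 = row_idx * row_duration_ms
        streams: dict[str, SensorStream] = {}
        noise = config.noise
        for s_idx, name in enumerate(SENSOR_NAMES):
            spec = sensors[name]
            rng = _child_rng(config.seed, 23, row_idx, s_idx, repetition)
            t, pos = _frame_stamps(spec.frame_rate_hz, config.speed_mm_s, extent, t0)
            # aligned (ground) coordinate convention: ground = position - offset,
            # so core.align_stream puts every sensor onto the truth coordinates
            ground = pos - spec.offset_mm
            valid, plant, height, plot_index, clearance, h_top = _sample_canopy(canopy, ground)
            n = pos.shape[0]
            if name in ("LC_lower", "LC_upper"):
                payload = _lc_payload(
                    "lower" if name == "LC_lower" else "upper",
                    plant, height, clearance, noise.lc_dropout_prob, rng,
                )
            elif name == "LDS1":
                payload = h_top - height
                if noise.lds_sigma_mm:
                    payload = payload + noise.lds_sigma_mm * rng.standard_normal(n)
            elif name == "LDS2":
                payload = np.where(
                    plot_index < 0, config.side_far_mm,
                    np.where(plant, config.side_distance_mm,
                             config.side_distance_mm + config.side_gap_extra_mm),
                )
                if noise.lds_sigma_mm:
                    payload = payload + noise.lds_sigma_mm * rng.standard_normal(n)
            elif name == "LDS3":
                payload = clearance.copy()
                if noise.lds_sigma_mm:
                    payload += noise.lds_sigma_mm * rng.standard_normal(n)
                if noise.lds3_short_prob > 0:
                    short = plant & (rng.random(n) < noise.lds3_short_prob)
                    payload[short] -= rng.uniform(50.0, 150.0, int(short.sum()))
            elif name == "ToF1":
                base = h_top - height
                payload = np.broadcast_to(
                    base[:, None, None], (n,) + TOF_FRAME_SHAPE
                ).copy()
                if noise.tof_sigma_mm:
                    payload += noise.tof_sigma_mm * rng.standard_normal(payload.shape)
            elif name == "ToF2":
                base = np.where(
                    plot_index < 0, config.side_far_mm,
                    np.where(plant, config.side_distance_mm,
                             config.side_distance_mm + config.side_gap_extra_mm),
                )
                payload = np.broadcast_to(
                    base[:, None, None], (n,) + TOF_FRAME_SHAPE
                ).copy()
                if noise.tof_sigma_mm:
                    payload += noise.tof_sigma_mm * rng.standard_normal(payload.shape)
            else:  # HSI
                structure_rng = _child_rng(config.seed, 31, row_idx)
                payload = _hsi_payload(
                    plot_index, config, by_row[row_id], structure_rng, rng,
                    noise.hsi_sigma_counts,
                )
            if payload.dtype == np.float64:
                np.clip(payload, 1.0, None, out=payload)  # distances stay positive
            streams[name] = SensorStream(spec=spec, time_ms=t, position_mm=pos, payload=payload)
        yield RowRecording(
            row_id=row_id,
            start=Stamp(t0, 0),
            end=Stamp(int(t0 + np.ceil(extent / config.speed_mm_s * 1000.0)), extent),
            streams=streams,
        )


def simulate_pass(field: FieldPlan, truths: Sequence[PlotTruth], config: SimConfig,
                  repetition: int = 1) -> list[RowRecording]:
    """Simulate one full pass over the trial; deterministic given the seed."""
    return list(iter_pass(field, truths, config, repetition))


def simulate_repeated_pass(
    field: FieldPlan, truths: Sequence[PlotTruth], config: SimConfig,
    rep_noise: float = 1.0,
) -> tuple[list[RowRecording], list[RowRecording]]:
    """Two passes over the identical field with independent sensor noise.

    ``rep_noise`` scales the sensor-noise terms for both passes; 0 makes the
    two passes bit-identical (the canopy realisation is shared)."""
    cfg = replace(config, noise=config.noise.scaled(rep_noise))
    return simulate_pass(field, truths, cfg, repetition=1), simulate_pass(
        field, truths, cfg, repetition=2
    )


def truth_to_frame(truths: Sequence[PlotTruth]):
    """Tabulate plot truths (plot_id, true_height_mm, coverage, moisture,
    start_mm, end_mm) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "plot_id": t.plot_id,
                "row_id": t.row_id,
                "true_height_mm": t.true_height_mm,
                "coverage": t.coverage_density,
                "moisture": t.moisture,
                "start_mm": t.start_mm,
                "end_mm": t.end_mm,
            }
            for t in truths
        ]
    )
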