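"""Core data model for stamped multi-sensor field recordings.

Every measurement on the platform carries a :class:`Stamp` — a global time in
integer milliseconds and an along-track odometer position in integer
millimetres.  A :class:`SensorStream` is the homogeneous sequence of stamped
frames produced by one sensor during one row traversal; frames are stored as
stacked NumPy arrays (stamps as two ``int64`` vectors, payloads as one array
whose leading axis is the frame index) so that downstream statistics are plain
vectorised reductions.

Sensors are mounted at different longitudinal positions on the platform, so a
raw position stamp refers to the odometer reading at acquisition, not to the
ground point being sensed.  :func:`align_stream` removes the mounting offset,
putting every sensor into a common along-track ground coordinate; all plot
slicing then happens in that coordinate via :func:`slice_by_position`, which
uses half-open ``[start, end)`` intervals so that adjacent slices partition a
stream without double counting.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

log = logging.getLogger(__name__)

# --- fixed sensor geometry -------------------------------------------------

#: number of light barriers per curtain
LC_N_BARRIERS = 288
#: vertical interspacing of light barriers, mm
LC_BARRIER_PITCH_MM = 2.5
#: nominal height of the lower curtain's bottom edge above ground, mm
LC_GROUND_CLEARANCE_MM = 200.0
#: depth-camera frame shape (rows, cols)
TOF_FRAME_SHAPE = (50, 64)
#: hyperspectral line geometry: spatial pixels x spectral bands
HSI_N_SPATIAL = 252
HSI_N_BANDS = 320
#: wavelength range covered by the spectrograph, nm
HSI_WAVELENGTH_RANGE_NM = (970.0, 1670.0)

#: canonical sensor names used throughout the pipeline
SENSOR_NAMES = ("LC_lower", "LC_upper", "LDS1", "LDS2", "LDS3", "ToF1", "ToF2", "HSI")

#: per-plot parameters produced by trait feature extraction
PARAMETERS = (
    "lc_height",
    "lc_coverage_density",
    "lds1_height",
    "lds1_penetration_top",
    "lds2_penetration_side",
    "tof1_height",
    "tof1_penetration_top",
    "tof2_penetration_side",
    "hsi_coverage_density",
)

#: which sensor each parameter is derived from (reporting key)
PARAMETER_SENSORS = {
    "lc_height": "LC",
    "lc_coverage_density": "LC",
    "lds1_height": "LDS1",
    "lds1_penetration_top": "LDS1",
    "lds2_penetration_side": "LDS2",
    "tof1_height": "ToF1",
    "tof1_penetration_top": "ToF1",
    "tof2_penetration_side": "ToF2",
    "hsi_coverage_density": "HSI",
}


class SensorKind(str, enum.Enum):
    LIGHT_CURTAIN = "light_curtain"
    LASER_DISTANCE = "laser_distance"
    TOF_CAMERA = "tof_camera"
    HYPERSPECTRAL = "hyperspectral"


class View(str, enum.Enum):
    TOP = "top"
    SIDE = "side"
    GROUND = "ground"


#: trailing payload shape per sensor kind (leading axis is the frame index)
PAYLOAD_SHAPE = {
    SensorKind.LIGHT_CURTAIN: (LC_N_BARRIERS,),
    SensorKind.LASER_DISTANCE: (),
    SensorKind.TOF_CAMERA: TOF_FRAME_SHAPE,
    SensorKind.HYPERSPECTRAL: (HSI_N_SPATIAL, HSI_N_BANDS),
}


class Stamp(NamedTuple):
    """Global time (ms) + odometer position (mm) of one measurement."""

    time_ms: int
    position_mm: int


@dataclass(frozen=True)
class SensorSpec:
    """Identity, mounting and geometry of one sensor.

    ``offset_mm`` is the signed along-track mounting offset of the sensor from
    the platform reference point: a sensor with offset ``o`` acquires the
    ground point ``position_mm - o`` when the odometer reads ``position_mm``.
    """

    name: str
    kind: SensorKind
    view: View
    frame_rate_hz: float
    offset_mm: int = 0
    geometry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")

    def payload_shape(self) -> tuple[int, ...]:
        return PAYLOAD_SHAPE[self.kind]


#: Table-style default frame rates, Hz
DEFAULT_FRAME_RATES = {
    "LC_lower": 170.0,
    "LC_upper": 170.0,
    "LDS1": 500.0,
    "LDS2": 1000.0,
    "LDS3": 1000.0,
    "ToF1": 5.0,
    "ToF2": 5.0,
    "HSI": 100.0,
}

#: simulator-default longitudinal mounting offsets, mm (config values; the
#: platform's true offsets are rig-specific and supplied by the user)
DEFAULT_SENSOR_OFFSETS_MM = {
    "LC_lower": 0,
    "LC_upper": 0,
    "LDS1": -300,
    "LDS2": 350,
    "LDS3": 0,
    "ToF1": -350,
    "ToF2": 400,
    "HSI": -250,
}

_SENSOR_KIND_VIEW = {
    "LC_lower": (SensorKind.LIGHT_CURTAIN, View.SIDE),
    "LC_upper": (SensorKind.LIGHT_CURTAIN, View.SIDE),
    "LDS1": (SensorKind.LASER_DISTANCE, View.TOP),
    "LDS2": (SensorKind.LASER_DISTANCE, View.SIDE),
    "LDS3": (SensorKind.LASER_DISTANCE, View.GROUND),
    "ToF1": (SensorKind.TOF_CAMERA, View.TOP),
    "ToF2": (SensorKind.TOF_CAMERA, View.SIDE),
    "HSI": (SensorKind.HYPERSPECTRAL, View.TOP),
}


def default_sensor_suite(
    offsets_mm: Mapping[str, int] | None = None,
    frame_rates_hz: Mapping[str, float] | None = None,
) -> dict[str, SensorSpec]:
    """Build the full eight-sensor suite with default rates and geometry."""
    offsets = dict(DEFAULT_SENSOR_OFFSETS_MM)
    if offsets_mm:
        offsets.update(offsets_mm)
    rates = dict(DEFAULT_FRAME_RATES)
    if frame_rates_hz:
        rates.update(frame_rates_hz)
    geometry = {
        SensorKind.LIGHT_CURTAIN: {
            "n_barriers": LC_N_BARRIERS,
            "barrier_pitch_mm": LC_BARRIER_PITCH_MM,
            "ground_clearance_mm": LC_GROUND_CLEARANCE_MM,
        },
        SensorKind.TOF_CAMERA: {"rows": TOF_FRAME_SHAPE[0], "cols": TOF_FRAME_SHAPE[1]},
        SensorKind.HYPERSPECTRAL: {
            "n_spatial": HSI_N_SPATIAL,
            "n_bands": HSI_N_BANDS,
            "wavelength_min_nm": HSI_WAVELENGTH_RANGE_NM[0],
            "wavelength_max_nm": HSI_WAVELENGTH_RANGE_NM[1],
        },
        SensorKind.LASER_DISTANCE: {},
    }
    suite = {}
    for name in SENSOR_NAMES:
        kind, view = _SENSOR_KIND_VIEW[name]
        suite[name] = SensorSpec(
            name=name,
            kind=kind,
            view=view,
            frame_rate_hz=rates[name],
            offset_mm=int(offsets[name]),
            geometry=geometry[kind],
        )
    return suite


@dataclass
class SensorStream:
    """Homogeneous sequence of stamped frames for one sensor.

    ``payload`` holds the frames stacked along axis 0: shape ``(n,)`` for
    scalar laser-distance samples, ``(n, 288)`` boolean for light-curtain
    columns, ``(n, 50, 64)`` for depth frames and ``(n, 252, 320)`` for
    hyperspectral lines.
    """

    spec: SensorSpec
    time_ms: np.ndarray
    position_mm: np.ndarray
    payload: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=np.int64)
        self.position_mm = np.asarray(self.position_mm, dtype=np.int64)
        self.payload = np.asarray(self.payload)
        n = self.time_ms.shape[0]
        if self.position_mm.shape != (n,):
            raise ValueError("time_ms and position_mm must have equal length")
        expected = (n,) + self.spec.payload_shape()
        if self.payload.shape != expected:
            raise ValueError(
                f"payload shape {self.payload.shape} does not match "
                f"{self.spec.kind.value} expectation {expected}"
            )
        if n > 1:
            if np.any(np.diff(self.time_ms) < 0):
                raise ValueError(f"{self.spec.name}: time stamps must be non-decreasing")
            if np.any(np.diff(self.position_mm) < 0):
                raise ValueError(f"{self.spec.name}: position stamps must be non-decreasing")
        if n and self.time_ms[0] < 0:
            raise ValueError("time stamps must be non-negative")

    def __len__(self) -> int:
        return int(self.time_ms.shape[0])

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def aligned_position_mm(self) -> np.ndarray:
        """Position stamps expressed in common ground coordinates."""
        return self.position_mm - self.spec.offset_mm

    def stamp(self, i: int) -> Stamp:
        return Stamp(int(self.time_ms[i]), int(self.position_mm[i]))

    def take(self, index: np.ndarray) -> "SensorStream":
        return SensorStream(
            spec=self.spec,
            time_ms=self.time_ms[index],
            position_mm=self.position_mm[index],
            payload=self.payload[index],
        )


def align_stream(stream: SensorStream) -> SensorStream:
    """Shift position stamps into common ground coordinates.

    Subtracts the mounting offset from every position stamp and zeroes the
    offset on the returned spec, so aligning twice is a no-op.  Time stamps
    and payloads are untouched; with offset 0 the stream is returned as-is.
    """
    o = stream.spec.offset_mm
    if o == 0:
        return stream
    return SensorStream(
        spec=replace(stream.spec, offset_mm=0),
        time_ms=stream.time_ms,
        position_mm=stream.position_mm - o,
        payload=stream.payload,
    )


def shift_positions(stream: SensorStream, delta_mm: int) -> SensorStream:
    """Return a copy with every position stamp shifted by ``delta_mm``."""
    return SensorStream(
        spec=stream.spec,
        time_ms=stream.time_ms,
        position_mm=stream.position_mm + int(delta_mm),
        payload=stream.payload,
    )


def slice_by_position(stream: SensorStream, start_mm: int, end_mm: int) -> SensorStream:
    """Select frames whose aligned position lies in ``[start_mm, end_mm)``.

    The interval is half-open so that consecutive slices partition the
    stream.  An empty result is legal and logged at debug level.
    """
    if start_mm >= end_mm:
        raise ValueError(f"start_mm ({start_mm}) must be < end_mm ({end_mm})")
    pos = stream.aligned_position_mm
    mask = (pos >= start_mm) & (pos < end_mm)
    if not mask.any():
        log.debug(
            "%s: empty slice [%d, %d) over stream extent [%s, %s]",
            stream.spec.name, start_mm, end_mm,
            pos[0] if len(stream) else "-", pos[-1] if len(stream) else "-",
        )
    return stream.take(np.flatnonzero(mask))


@dataclass(frozen=True)
class Layout:
    """Regular plot-trial layout: n rows of m plots separated by gaps."""

    n_rows: int
    m_plots: int
    plot_length_mm: int = 4000
    gap_mm: int = 500

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.m_plots < 1:
            raise ValueError("layout needs at least one row and one plot per row")
        if self.plot_length_mm <= 0 or self.gap_mm < 0:
            raise ValueError("plot_length_mm must be > 0 and gap_mm >= 0")

    @property
    def row_length_mm(self) -> int:
        """Ground extent of one row including lead-in and trailing gaps."""
        return self.gap_mm + self.m_plots * (self.plot_length_mm + self.gap_mm)


@dataclass
class FieldPlan:
    """Ordered plot identities for every row of the trial."""

    rows: list[str]
    plots_per_row: dict[str, list[str]]
    layout: Layout

    def __post_init__(self) -> None:
        all_plots = [p for r in self.rows for p in self.plots_per_row[r]]
        if len(set(all_plots)) != len(all_plots):
            raise ValueError("plot ids must be unique across the field plan")

    @property
    def n_plots(self) -> int:
        return sum(len(self.plots_per_row[r]) for r in self.rows)


@dataclass
class RowRecording:
    """All sensor streams recorded over one row traversal."""

    row_id: str
    start: Stamp
    end: Stamp
    streams: dict[str, SensorStream]

    def __post_init__(self) -> None:
        if not (self.start.time_ms <= self.end.time_ms and self.start.position_mm <= self.end.position_mm):
            raise ValueError("row start stamp must precede end stamp")


@dataclass
class PlotSegment:
    """Detected extent of one yield plot, in ground coordinates."""

    plot_id: str
    start: Stamp
    end: Stamp

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError(f"plot {self.plot_id}: non-positive length")

    @property
    def length_mm(self) -> int:
        return self.end.position_mm - self.start.position_mm


@dataclass
class FeatureRecord:
    """One reduced parameter value for one plot / sensor / repetition."""

    plot_id: str
    repetition: int
    sensor: str
    parameter: str
    value: float  # NaN encodes a per-parameter failure (missing value)

    def is_missing(self) -> bool:
        return not np.isfinite(self.value)


def validate_feature(record: FeatureRecord) -> None:
    """Check the physical range of a feature value (densities in [0,1],
    heights and depths non-negative)."""
    v = record.value
    if not np.isfinite(v):
        return
    if record.parameter.endswith("density"):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{record.parameter} out of [0,1]: {v}")
    elif v < 0:
        raise ValueError(f"{record.parameter} negative: {v}")


def segments_are_valid(segments: Sequence[PlotSegment]) -> bool:
    """True iff segments are ordered and pairwise disjoint."""
    for a, b in zip(segments, segments[1:]):
        if a.end.position_mm > b.start.position_mm:
            return False
    return True
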