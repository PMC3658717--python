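"""Plant/soil segmentation of hyperspectral line scans.

Each hyperspectral frame is one scan line of 252 spatial pixels, each with a
320-band reflectance spectrum over 970-1670 nm.  Pixels are classified as
plant or soil with the spectral angle mapper (SAM): the angle between a pixel
spectrum ``s`` and a plant reference spectrum ``r``,

    theta = arccos( <s, r> / (||s|| * ||r||) ),

is compared against a threshold.  Because the angle is invariant to positive
scaling of either spectrum, the classification is insensitive to overall
illumination level — the property that makes SAM practical on a moving field
platform with active lighting.

Canopy coverage density is then the fraction of plant-classified pixels over
all lines of a plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import HSI_N_BANDS, HSI_WAVELENGTH_RANGE_NM, SensorStream

log = logging.getLogger(__name__)

#: band-centre wavelengths, nm
WAVELENGTHS_NM = np.linspace(*HSI_WAVELENGTH_RANGE_NM, HSI_N_BANDS)

#: default SAM acceptance threshold, radians
DEFAULT_SAM_THRESHOLD_RAD = 0.15


def plant_endmember(moisture: float = 0.3) -> np.ndarray:
    """Synthetic green-vegetation NIR spectrum, counts in [0, 255].

    A high NIR plateau with a water-absorption dip centred at 1450 nm whose
    depth scales with canopy moisture content (fraction in [0, 1]).
    """
    wl = WAVELENGTHS_NM
    base = 210.0 - 0.03 * (wl - 970.0)  # gently declining NIR plateau
    dip = 140.0 * float(moisture) * np.exp(-0.5 * ((wl - 1450.0) / 60.0) ** 2)
    return np.clip(base - dip, 0.0, 255.0)


def soil_endmember() -> np.ndarray:
    """Synthetic bare-soil spectrum: dimmer, monotonically rising with
    wavelength and without the water feature."""
    wl = WAVELENGTHS_NM
    return np.clip(55.0 + 0.09 * (wl - 970.0), 0.0, 255.0)


def spectral_angle(s: np.ndarray, r: np.ndarray) -> float:
    """Angle in radians between two spectra; scale-invariant, in [0, pi]."""
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    ns = np.linalg.norm(s)
    nr = np.linalg.norm(r)
    if ns == 0.0 or nr == 0.0:
        raise ValueError("spectral_angle requires spectra with positive norm")
    c = float(np.dot(s, r) / (ns * nr))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def spectral_angles(frame: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorised SAM angles for a (pixels, bands) frame against ``reference``.

    Zero-norm pixels get angle pi/2 (classified soil downstream) and are
    counted in the log.
    """
    frame = np.asarray(frame)
    if frame.dtype not in (np.float32, np.float64):
        frame = frame.astype(np.float32)  # byte counts: single precision suffices
    reference = np.asarray(reference, dtype=frame.dtype)
    nr = float(np.linalg.norm(reference.astype(np.float64)))
    if nr == 0.0:
        raise ValueError("reference spectrum has zero norm")
    norms = np.sqrt(np.einsum("...b,...b->...", frame, frame))
    dead = norms == 0.0
    if dead.any():
        log.warning("%d zero-norm pixels classified as soil", int(dead.sum()))
    cos = np.einsum("...b,b->...", frame, reference) / (np.where(dead, 1.0, norms) * nr)
    ang = np.arccos(np.clip(cos, -1.0, 1.0))
    return np.where(dead, np.pi / 2.0, ang)


@dataclass
class SamParams:
    """Plant reference endmember and acceptance threshold for SAM."""

    reference: np.ndarray = field(default_factory=plant_endmember)
    threshold_rad: float = DEFAULT_SAM_THRESHOLD_RAD

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_rad < np.pi / 2):
            raise ValueError("threshold_rad must lie in (0, pi/2)")


class SpectralAngleMapper(BaseEstimator, ClassifierMixin):
    """Scikit-learn style SAM plant/soil classifier.

    Parameters
    ----------
    reference : array of shape (n_bands,), optional
        Plant endmember spectrum.  If None, ``fit`` uses the mean of the
        training spectra (assumed plant).
    threshold_rad : float
        Maximum angle to the reference for a pixel to count as plant.
    """

    def __init__(self, reference: np.ndarray | None = None,
                 threshold_rad: float = DEFAULT_SAM_THRESHOLD_RAD):
        self.reference = reference
        self.threshold_rad = threshold_rad

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
        else:
            ref = X.reshape(-1, X.shape[-1]).mean(axis=0)
        if np.linalg.norm(ref) == 0.0:
            raise ValueError("reference spectrum has zero norm")
        self.reference_ = ref
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Negative SAM angle (larger = more plant-like)."""
        return -spectral_angles(np.asarray(X, dtype=float), self.reference_)

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) >= -self.threshold_rad


def sam_classify(frame: np.ndarray, params: SamParams) -> np.ndarray:
    """Classify one 252x320 line: boolean mask, True = plant."""
    ang = spectral_angles(frame, params.reference)
    return ang <= params.threshold_rad


def hsi_coverage_density(hsi_slice: SensorStream | np.ndarray, params: SamParams | None = None) -> float:
    """Fraction of plant-classified pixels over all lines of a plot."""
    if params is None:
        params = SamParams()
    frames = hsi_slice.payload if isinstance(hsi_slice, SensorStream) else np.asarray(hsi_slice)
    if frames.size == 0:
        raise ValueError("hsi_coverage_density: empty slice")
    ang = spectral_angles(frames, params.reference)
    return float(np.mean(ang <= params.threshold_rad))
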