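"""Technical-repeatability and trait-calibration statistics.

Repeatability of a derived parameter between two immediate re-measurements
of the same plots is summarised by

    MRE_w = 1/n * sum |y1_i - y2_i| / y1_i      (normalised by repetition 1)
    R_w^2 = r^2(y1, y2)                          (squared Pearson correlation)

and trait calibration relates the platform-determined value x to the
reference value y by regression through the origin,

    y = b * x + eps,     b = sum(x*y) / sum(x^2)

with calibration accuracy quantified on the fitted predictions yhat = b*x as

    MRE_c = 1/n * sum |yhat_i - y_i| / y_i,      R_c^2 = r^2(yhat, y).

The through-origin form is the default; an intercept mode exists for
diagnostics only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 2 and a.shape[1] == 1:
        a = a[:, 0]
    if a.ndim != 1:
        raise ValueError(f"expected 1-D values, got shape {a.shape}")
    return a


def mre_repetition(y1, y2) -> float:
    """Mean relative error between repetitions, normalised by repetition 1."""
    y1, y2 = _as_1d(y1), _as_1d(y2)
    if y1.shape != y2.shape or y1.size == 0:
        raise ValueError("repetitions must be non-empty and of equal length")
    if np.any(y1 == 0):
        raise ValueError("mre_repetition undefined: repetition-1 value is zero")
    return float(np.mean(np.abs(y1 - y2) / y1))


def _r_squared(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        raise ValueError("r^2 requires at least two pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("r^2 undefined for a constant sequence")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def r2_repetition(y1, y2) -> float:
    """Squared Pearson correlation between the two repetitions."""
    return _r_squared(_as_1d(y1), _as_1d(y2))


def mre_calibration(y_hat, y) -> float:
    """Mean relative error of calibration, normalised by the reference."""
    y_hat, y = _as_1d(y_hat), _as_1d(y)
    if y_hat.shape != y.shape or y.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    if np.any(y == 0):
        raise ValueError("mre_calibration undefined: reference value is zero")
    return float(np.mean(np.abs(y_hat - y) / y))


def r2_calibration(y_hat, y) -> float:
    """Squared Pearson correlation between prediction and reference."""
    return _r_squared(_as_1d(y_hat), _as_1d(y))


class ThroughOriginCalibration(BaseEstimator, RegressorMixin):
    """Through-origin linear trait calibration, y = b*x.

    Parameters
    ----------
    trait : str
        Name of the calibrated trait (carried into reports and JSON).
    fit_intercept : bool
        Diagnostics-only mode fitting y = a + b*x by ordinary least squares;
        the default (False) is the proportional model.

    Attributes (after ``fit``)
    --------------------------
    slope_ : float           regression coefficient b
    intercept_ : float       0.0 unless ``fit_intercept``
    n_ : int                 number of calibration pairs
    r2_ : float              R_c^2 on the training pairs
    mre_ : float             MRE_c on the training pairs
    """

    def __init__(self, trait: str = "", fit_intercept: bool = False):
        self.trait = trait
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        x = _as_1d(X)
        y = _as_1d(y)
        if x.shape != y.shape or x.size < 2:
            raise ValueError("calibration requires >= 2 (x, y) pairs of equal length")
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            raise ValueError("all determined values are zero; slope undefined")
        if self.fit_intercept:
            b, a = np.polyfit(x, y, 1)
            self.intercept_ = float(a)
            self.slope_ = float(b)
        else:
            self.intercept_ = 0.0
            self.slope_ = float(np.dot(x, y) / sxx)
        self.n_ = int(x.size)
        y_hat = self.slope_ * x + self.intercept_
        self.mre_ = mre_calibration(y_hat, y) if not np.any(y == 0) else float("nan")
        try:
            self.r2_ = r2_calibration(y_hat, y)
        except ValueError:
            self.r2_ = float("nan")
        return self

    def predict(self, X) -> np.ndarray:
        return self.slope_ * _as_1d(X) + self.intercept_

    # --- persistence ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "trait": self.trait,
            "fit_intercept": self.fit_intercept,
            "slope": self.slope_,
            "intercept": self.intercept_,
            "n": self.n_,
            "r2_c": self.r2_,
            "mre_c": self.mre_,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "ThroughOriginCalibration":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        model = cls(trait=d.get("trait", ""), fit_intercept=d.get("fit_intercept", False))
        model.slope_ = float(d["slope"])
        model.intercept_ = float(d.get("intercept", 0.0))
        model.n_ = int(d.get("n", 0))
        model.r2_ = float(d.get("r2_c", float("nan")))
        model.mre_ = float(d.get("mre_c", float("nan")))
        return model


def fit_calibration(x, y, trait: str = "", fit_intercept: bool = False) -> ThroughOriginCalibration:
    """Fit the through-origin calibration model on (determined, reference)."""
    return ThroughOriginCalibration(trait=trait, fit_intercept=fit_intercept).fit(x, y)


def apply_calibration(model: ThroughOriginCalibration, x) -> np.ndarray:
    """Trait estimates yhat = b*x for new determined values."""
    return model.predict(x)


def evaluate_repeatability(
    results: pd.DataFrame,
    group_cols: Sequence[str] = ("sensor", "parameter"),
) -> pd.DataFrame:
    """Per-group technical repeatability from a long-format result store.

    ``results`` must hold columns plot_id, repetition (1 and 2), sensor,
    parameter, value, plus any extra grouping columns (e.g. harvest).  Pairs
    with a missing value in either repetition, or a zero repetition-1 value,
    are dropped per group and counted in ``n_dropped``.  Groups with fewer
    than two valid pairs report null statistics.
    """
    group_cols = list(group_cols)
    rows = []
    for key, g in results.groupby(group_cols, sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        wide = g.pivot_table(index="plot_id", columns="repetition", values="value", aggfunc="first")
        if not {1, 2}.issubset(wide.columns):
            y1 = np.array([])
            y2 = np.array([])
            dropped = len(wide)
        else:
            pair = wide[[1, 2]].to_numpy(float)
            ok = np.isfinite(pair).all(axis=1) & (pair[:, 0] != 0)
            dropped = int((~ok).sum())
            y1, y2 = pair[ok, 0], pair[ok, 1]
        entry = dict(zip(group_cols, key))
        entry["n"] = int(y1.size)
        entry["n_dropped"] = dropped
        if y1.size >= 2:
            entry["mre_w"] = float(np.mean(np.abs(y1 - y2) / y1))
            try:
                entry["r2_w"] = _r_squared(y1, y2)
            except ValueError:
                entry["r2_w"] = np.nan  # constant parameter across plots
        else:
            entry["mre_w"] = np.nan
            entry["r2_w"] = np.nan
            if y1.size < 2:
                log.warning("repeatability group %s: fewer than 2 valid pairs", key)
        rows.append(entry)
    return pd.DataFrame(rows, columns=group_cols + ["r2_w", "mre_w", "n", "n_dropped"])
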