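"""Signal-to-concentration quantification.

Three conversions used throughout the pipeline:

* external-standard ratio quantification of EPR signals (a known-concentration
  nitroxide solution measured in the same geometry),
* linear calibration curves with inverse prediction for the H2O2 assays
  (Fenton-EPR and 505 nm colorimetric share the abstraction; the assay
  identity is metadata), and
* first-order decay rates of nitroxide time courses (delegates to
  :mod:`rostrack.decay`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decay import DecaySeries, fit_decay_rate
from .exceptions import DomainError, FitError

#: Calibration-standard concentration range used by default, µmol/L.
DEFAULT_STANDARD_RANGE_UM = (0.0, 980.0)

#: External-standard concentration, mmol/L.
DEFAULT_STANDARD_MM = 2.0


@dataclass(frozen=True)
class ExternalStandard:
    """A known-concentration standard measured in identical geometry."""

    concentration_mM: float = DEFAULT_STANDARD_MM
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration_mM <= 0:
            raise DomainError("standard concentration must be > 0")
        if self.intensity <= 0:
            raise DomainError("standard intensity must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response model mapping analyte concentration to signal."""

    slope: float
    intercept: float
    residual_sd: float
    conc_range_uM: tuple[float, float]
    assay: str = "generic"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError(f"calibration slope must be > 0, got {self.slope}")
        lo, hi = self.conc_range_uM
        if not hi > lo:
            raise DomainError("calibration range is degenerate")

    def predict_signal(self, conc_uM: float) -> float:
        return self.intercept + self.slope * conc_uM


@dataclass(frozen=True)
class InversePrediction:
    """Result of inverse prediction: concentration plus quality flags."""

    conc_uM: float
    extrapolated: bool
    clamped: bool


@dataclass(frozen=True)
class TimeCourse:
    """Signal intensities over time for one condition label."""

    times_min: tuple[float, ...]
    intensities: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        if t.size < 3:
            raise DomainError("time course needs >= 3 points")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")


def signal_to_concentration(intensity: float, standard: ExternalStandard) -> float:
    """Concentration (mmol/L) by external-standard ratio.

    c = c_std * intensity / intensity_std.
    """
    if intensity < 0:
        raise DomainError(f"intensity must be >= 0, got {intensity}")
    return standard.concentration_mM * intensity / standard.intensity


def build_calibration(
    conc_uM,
    signal,
    assay: str = "generic",
    through_origin: bool = False,
) -> CalibrationCurve:
    """Ordinary least squares of signal on standard concentration.

    Requires >= 3 standards spanning a non-zero concentration range; stores
    the residual standard deviation and the calibration range for later
    extrapolation flagging.
    """
    x = np.asarray(conc_uM, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.size != y.size:
        raise DomainError("concentrations and signals must have equal length")
    if x.size < 3:
        raise DomainError(f"need >= 3 calibration standards, got {x.size}")
    if np.any(x < 0):
        raise DomainError("standard concentrations must be >= 0")
    if np.ptp(x) == 0.0:
        raise FitError("degenerate calibration design: all standards identical")

    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        dof = x.size - 1
    else:
        xbar, ybar = x.mean(), y.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        slope = float(np.sum((x - xbar) * (y - ybar))) / sxx
        intercept = float(ybar - slope * xbar)
        dof = x.size - 2
    resid = y - (intercept + slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    if slope <= 0:
        raise FitError(f"fitted calibration slope is not positive ({slope:.3g})")
    return CalibrationCurve(slope, intercept, residual_sd,
                            (float(x.min()), float(x.max())), assay)


def inverse_predict(curve: CalibrationCurve, signal: float) -> InversePrediction:
    """Invert the calibration line: c = (signal - intercept) / slope.

    Predictions outside the calibration range are flagged ``extrapolated``;
    negative concentrations are clamped to 0 with a warning (the analyte is
    physically non-negative).
    """
    conc = (signal - curve.intercept) / curve.slope
    lo, hi = curve.conc_range_uM
    extrapolated = conc < lo or conc > hi
    clamped = False
    if conc < 0:
        warnings.warn(f"negative inverse prediction {conc:.3g} µmol/L clamped to 0",
                      stacklevel=2)
        conc, clamped = 0.0, True
    return InversePrediction(conc, extrapolated, clamped)


def fit_timecourse_decay(tc: TimeCourse) -> float:
    """First-order rate (1/min) of a nitroxide time course (log-linear fit)."""
    series = DecaySeries(tc.times_min, tc.intensities)
    return fit_decay_rate(series).k
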