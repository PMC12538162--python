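"""Laser power calibration.

To deliver a requested optical power in mW rather than a raw percentage,
the laser's response is measured once: the controller emits a series of
long (10 s) pulses at stepped control fractions, an optical power meter
reads the output at each step, and an ordinary-least-squares line is fit
through (control fraction, measured mW).  Diode lasers driven through
their analog input are approximately linear above threshold, which this
procedure both exploits and checks (:func:`linearity_check`).

Requested powers outside the measured range are an error, not an
extrapolation — delivering more light than was ever measured is unsafe
around animals.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParamError

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "default_steps",
    "fit",
    "mw_to_fraction",
    "fraction_to_mw",
    "linearity_check",
    "CALIB_PULSE_S",
]

#: Duration of each calibration pulse emitted by the device, seconds.
CALIB_PULSE_S = 10.0

#: Default r^2 below which the response is flagged as non-linear.
R2_WARN_DEFAULT = 0.98


class CalibrationError(ValueError):
    pass


def default_steps() -> list[float]:
    """Default measurement intensities: ten equal steps, 10 %–100 %."""
    return [round(0.1 * k, 10) for k in range(1, 11)]


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear map between control fraction and optical power.

    ``measured_mW = slope * fraction + intercept``; slope is mW per unit
    control fraction.  A negative intercept is legitimate (lasing
    threshold).  Curves persist to JSON and reload field-identically.
    """

    laser_id: int
    steps: tuple[float, ...]
    measured_mW: tuple[float, ...]
    slope: float
    intercept: float
    r2: float
    created: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.measured_mW) or len(self.steps) < 2:
            raise CalibrationError("need >= 2 matched (step, mW) points")
        if not all(b > a for a, b in zip(self.steps, self.steps[1:])):
            raise CalibrationError("steps must be strictly increasing")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise CalibrationError(f"r2 out of [0, 1]: {self.r2}")

    @property
    def mw_range(self) -> tuple[float, float]:
        return (min(self.measured_mW), max(self.measured_mW))

    def mw_to_fraction(self, mW: float) -> float:
        return mw_to_fraction(self, mW)

    def fraction_to_mw(self, fraction: float) -> float:
        return fraction_to_mw(self, fraction)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        d["steps"] = tuple(d["steps"])
        d["measured_mW"] = tuple(d["measured_mW"])
        return cls(**d)


def fit(steps, measured_mW, laser_id: int = 1) -> CalibrationCurve:
    """Closed-form OLS line through (control fraction, measured mW).

    slope = sum((x - xbar)(y - ybar)) / sum((x - xbar)^2),
    intercept = ybar - slope * xbar.  Pairs are sorted by step before
    storage, so the fit is invariant to input ordering.
    """
    x = np.asarray(steps, dtype=float)
    y = np.asarray(measured_mW, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("steps and measured_mW must be matched 1-D sequences")
    if len(x) < 2:
        raise CalibrationError("need at least 2 calibration points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        raise CalibrationError("steps must be distinct (zero variance within ties)")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise CalibrationError("zero variance in steps")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / sst)
    return CalibrationCurve(
        laser_id=laser_id,
        steps=tuple(float(v) for v in x),
        measured_mW=tuple(float(v) for v in y),
        slope=slope,
        intercept=intercept,
        r2=min(r2, 1.0),
    )


def fit_csv(path: str | Path, laser_id: int = 1) -> CalibrationCurve:
    """Fit from a measurement CSV with columns ``fraction,mW``."""
    df = pd.read_csv(path)
    return fit(df["fraction"].to_numpy(), df["mW"].to_numpy(), laser_id=laser_id)


def mw_to_fraction(curve: CalibrationCurve, mW: float) -> float:
    """Invert the curve: control fraction delivering ``mW``.

    Errors outside the measured power range (no extrapolation).  Fractions
    implied below 0 or above 1 by a nonzero intercept are clamped with a
    warning.
    """
    if not np.isfinite(curve.slope) or curve.slope == 0:
        raise CalibrationError("curve slope is zero or non-finite")
    lo, hi = curve.mw_range
    tol = 1e-9 * max(1.0, hi - lo)
    if not (lo - tol <= mW <= hi + tol):
        raise CalibrationError(
            f"{mW} mW outside calibrated range [{lo}, {hi}] mW; re-calibrate to extend"
        )
    frac = (mW - curve.intercept) / curve.slope
    if frac < 0.0 or frac > 1.0:
        warnings.warn(
            f"fraction {frac:.4f} clamped to [0, 1] (nonzero intercept)", stacklevel=2
        )
        frac = min(1.0, max(0.0, frac))
    return float(frac)


def fraction_to_mw(curve: CalibrationCurve, fraction: float) -> float:
    return float(curve.slope * fraction + curve.intercept)


def linearity_check(curve: CalibrationCurve, r2_min: float = R2_WARN_DEFAULT) -> bool:
    """True when the response is acceptably linear (r^2 >= ``r2_min``).

    A False result warns: a laser with a strongly non-linear response
    should not be driven through this linear map near animals.
    """
    if curve.r2 < r2_min:
        warnings.warn(
            f"laser {curve.laser_id}: r^2 = {curve.r2:.4f} < {r2_min}; "
            "response curve is not approximately linear",
            stacklevel=2,
        )
        return False
    return True
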