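"""Stimulation parameter sets.

One :class:`StimParams` describes everything a single laser channel does
after an accepted trigger: which waveform to play, for how long, at what
frequency and power, and whether the matching masking-LED channel fires.

All durations are in milliseconds; frequency in Hz; power either as a
percentage of the maximum laser output or, after calibration, in mW.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Any

#: Number of laser channels the controller drives.
N_LASERS = 4

#: Tolerance used when checking pulse_ms against duty for consistency.
_DUTY_CONSISTENCY_TOL = 1e-9


class Waveform(str, enum.Enum):
    """Supported stimulation waveforms.

    SQUARE     TTL-like pulse train; the analog power line is held constant
               while the enable line is modulated.
    SINE       raised-cosine oscillation of the analog line, starting from 0
               (the enable line is held HIGH for the whole train).
    HALF_SINE  upper half of a sinusoid; the signal rests at 0 for the other
               half-phase.
    """

    SQUARE = "square"
    SINE = "sine"
    HALF_SINE = "half_sine"


class PowerUnit(str, enum.Enum):
    PERCENT = "percent"
    MILLIWATT = "mW"


class ParamError(ValueError):
    """Invalid or inconsistent stimulation parameters."""


@dataclass(frozen=True)
class StimParams:
    """Full stimulation description for one laser channel.

    Parameters
    ----------
    laser_id
        Channel index, 1–4.
    waveform
        One of :class:`Waveform` (strings ``"square"``, ``"sine"``,
        ``"half_sine"`` are accepted).
    burst_ms
        Total duration of the pulse train in ms (> 0).  For sinusoids the
        attenuation ramp *extends* the train beyond ``burst_ms``.
    freq_hz
        Pulse-train frequency in Hz (> 0).
    pulse_ms
        Single-pulse duration in ms (square only).  At least one of
        ``pulse_ms`` / ``duty`` must be given for square trains; if both are
        given they must agree.
    duty
        Fraction of each period spent HIGH, in (0, 1] (square only).
    atten_ms
        Linear amplitude ramp-down appended to sinusoidal trains, ms, >= 0.
        Ignored for square trains.
    delay_ms
        Delay between trigger acceptance and train start, ms, >= 0.
    power
        Output power: percent of maximum in [0, 100] when ``power_unit`` is
        ``"percent"``, otherwise calibrated mW.
    power_unit
        ``"percent"`` (default) or ``"mW"``.
    mask_enabled
        Whether the matching masking-LED channel fires with this laser.
    """

    laser_id: int
    waveform: Waveform
    burst_ms: float
    freq_hz: float
    pulse_ms: float | None = None
    duty: float | None = None
    atten_ms: float = 0.0
    delay_ms: float = 0.0
    power: float = 100.0
    power_unit: PowerUnit = PowerUnit.PERCENT
    mask_enabled: bool = field(default=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "waveform", Waveform(self.waveform))
        object.__setattr__(self, "power_unit", PowerUnit(self.power_unit))
        if self.laser_id not in range(1, N_LASERS + 1):
            raise ParamError(f"laser_id must be in 1..{N_LASERS}, got {self.laser_id}")
        if not (self.burst_ms > 0):
            raise ParamError(f"burst_ms must be > 0, got {self.burst_ms}")
        if not (self.freq_hz > 0):
            raise ParamError(f"freq_hz must be > 0, got {self.freq_hz}")
        if self.atten_ms < 0:
            raise ParamError(f"atten_ms must be >= 0, got {self.atten_ms}")
        if self.delay_ms < 0:
            raise ParamError(f"delay_ms must be >= 0, got {self.delay_ms}")
        if self.power_unit is PowerUnit.PERCENT and not (0 <= self.power <= 100):
            raise ParamError(f"percent power must be in [0, 100], got {self.power}")
        if self.power_unit is PowerUnit.MILLIWATT and self.power < 0:
            raise ParamError(f"mW power must be >= 0, got {self.power}")

        if self.waveform is Waveform.SQUARE:
            if self.pulse_ms is None and self.duty is None:
                raise ParamError("square waveform requires pulse_ms or duty")
            period = 1000.0 / self.freq_hz
            if self.pulse_ms is not None and self.duty is not None:
                implied = self.pulse_ms * self.freq_hz / 1000.0
                if abs(implied - self.duty) >= _DUTY_CONSISTENCY_TOL:
                    raise ParamError(
                        f"pulse_ms={self.pulse_ms} and duty={self.duty} disagree "
                        f"(pulse implies duty {implied:.9f})"
                    )
            if self.duty is not None and not (0 < self.duty <= 1):
                raise ParamError(f"duty must be in (0, 1], got {self.duty}")
            width = self.pulse_ms if self.pulse_ms is not None else self.duty * period
            if not (0 < width <= period + _DUTY_CONSISTENCY_TOL):
                raise ParamError(
                    f"pulse width {width} ms exceeds period {period} ms at {self.freq_hz} Hz"
                )
        else:
            if self.pulse_ms is not None or self.duty is not None:
                raise ParamError("pulse_ms/duty apply to square waveforms only")

    # -- derived quantities -------------------------------------------------

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.freq_hz

    @property
    def active_ms(self) -> float:
        """Total active duration after the trigger: delay + burst (+ ramp)."""
        atten = self.atten_ms if self.waveform is not Waveform.SQUARE else 0.0
        return self.delay_ms + self.burst_ms + atten

    def power_fraction(self, calibration: Any | None = None) -> float:
        """Control fraction in [0, 1] for the requested power.

        mW-denominated power requires a fitted calibration curve for this
        channel (see :mod:`optopulse.calibration`).
        """
        if self.power_unit is PowerUnit.PERCENT:
            return self.power / 100.0
        if calibration is None:
            raise ParamError(
                f"laser {self.laser_id}: power given in mW but no calibration curve supplied"
            )
        return calibration.mw_to_fraction(self.power)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["waveform"] = self.waveform.value
        d["power_unit"] = self.power_unit.value
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StimParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParamError(f"unknown StimParams fields: {sorted(unknown)}")
        missing = {"laser_id", "waveform", "burst_ms", "freq_hz"} - set(d)
        if missing:
            raise ParamError(f"missing StimParams fields: {sorted(missing)}")
        for key in ("burst_ms", "freq_hz", "atten_ms", "delay_ms", "power", "pulse_ms", "duty"):
            if key in d and d[key] is not None and not math.isfinite(float(d[key])):
                raise ParamError(f"non-finite value for {key}")
        return cls(**d)
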