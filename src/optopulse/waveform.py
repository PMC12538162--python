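"""Waveform synthesis: continuous-time definitions and discrete rendering.

Time ``t_ms`` is measured from trigger acceptance.  Each channel drives
three lines:

* ``ttl``      — digital laser-enable (square: modulated per pulse;
                 sinusoids: held HIGH across the whole train),
* ``analog_V`` — DAC output voltage in [0, vref] setting laser power,
* ``mask``     — digital masking-LED line (square: mirrors the TTL;
                 sinusoids: 50 % duty toggle at the train frequency, the
                 closest pattern a switched LED can realise).

The sinusoid is the raised cosine ``(1 - cos)/2``: the analog line drives
non-negative optical power, so the oscillation rests on zero and starts at
zero at train onset.  A pure-sine convention (``sin``, clipped at zero, i.e.
the half-sine) is available as its own waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .params import ParamError, StimParams, Waveform

__all__ = [
    "ChannelTrace",
    "period_ms",
    "resolve_pulse_width",
    "ttl_at",
    "analog_fraction_at",
    "attenuation_gain",
    "mask_at",
    "quantize_dac",
    "render",
]

DAC_BITS_DEFAULT = 12
DAC_VREF_DEFAULT = 5.0


def period_ms(freq_hz: float) -> float:
    """Pulse-train period in ms for a frequency in Hz (40 Hz -> 25 ms)."""
    if not (freq_hz > 0):
        raise ParamError(f"freq_hz must be > 0, got {freq_hz}")
    return 1000.0 / freq_hz


def resolve_pulse_width(params: StimParams) -> float:
    """Single-pulse HIGH duration in ms for a square train.

    ``pulse_ms`` is canonical; when only ``duty`` is given the width is
    ``duty * period``.  Consistency of the pair is enforced at construction.
    """
    if params.waveform is not Waveform.SQUARE:
        raise ParamError("pulse width is defined for square waveforms only")
    if params.pulse_ms is not None:
        return float(params.pulse_ms)
    assert params.duty is not None
    return params.duty * period_ms(params.freq_hz)


def _phase_ms(params: StimParams, t_ms: NDArray | float) -> NDArray | float:
    """Time since train start, folded into one period."""
    tau = np.asarray(t_ms, dtype=float) - params.delay_ms
    period = params.period_ms
    return tau - period * np.floor(tau / period)


def ttl_at(params: StimParams, t_ms: NDArray | float) -> NDArray | bool:
    """Laser-enable line at time(s) ``t_ms`` since trigger acceptance.

    Square trains modulate the enable per pulse; sinusoids hold it HIGH for
    the whole active window (delay .. delay + burst + attenuation).
    """
    t = np.asarray(t_ms, dtype=float)
    if params.waveform is Waveform.SQUARE:
        in_train = (t >= params.delay_ms) & (t < params.delay_ms + params.burst_ms)
        out = in_train & (_phase_ms(params, t) < resolve_pulse_width(params))
    else:
        out = (t >= params.delay_ms) & (t < params.active_ms)
    return bool(out) if np.isscalar(t_ms) else out


def attenuation_gain(params: StimParams, t_ms: NDArray | float) -> NDArray | float:
    """Linear ramp-down gain appended to sinusoidal trains.

    1 through the end of the burst, then a straight line to 0 over
    ``atten_ms``, 0 afterwards.  Square trains have no attenuation.
    """
    t = np.asarray(t_ms, dtype=float)
    ramp_start = params.delay_ms + params.burst_ms
    if params.waveform is Waveform.SQUARE or params.atten_ms == 0:
        gain = np.where(t <= ramp_start, 1.0, 0.0)
    else:
        gain = np.clip(1.0 - (t - ramp_start) / params.atten_ms, 0.0, 1.0)
    return float(gain) if np.isscalar(t_ms) else gain


def analog_fraction_at(params: StimParams, t_ms: NDArray | float) -> NDArray | float:
    """Analog control level as a fraction of full scale, before power scaling.

    SQUARE     constant 1 across the burst (amplitude lives on the power
               scaling; the TTL line does the pulsing),
    SINE       raised cosine ``(1 - cos(2 pi f (t - delay))) / 2`` times the
               attenuation gain — starts at 0, peaks at 1 mid-period,
    HALF_SINE  ``max(0, sin(2 pi f (t - delay)))`` times the gain — zero for
               the second half of every period.
    Outside the active window the fraction is 0.
    """
    t = np.asarray(t_ms, dtype=float)
    tau = t - params.delay_ms
    if params.waveform is Waveform.SQUARE:
        active = (t >= params.delay_ms) & (t < params.delay_ms + params.burst_ms)
        frac = np.where(active, 1.0, 0.0)
    else:
        active = (t >= params.delay_ms) & (t < params.active_ms)
        omega_t = 2.0 * np.pi * params.freq_hz * tau / 1000.0
        if params.waveform is Waveform.SINE:
            shape = 0.5 * (1.0 - np.cos(omega_t))
        else:
            shape = np.maximum(0.0, np.sin(omega_t))
        frac = np.where(active, shape * attenuation_gain(params, t), 0.0)
    return float(frac) if np.isscalar(t_ms) else frac


def mask_at(params: StimParams, t_ms: NDArray | float) -> NDArray | bool:
    """Masking-LED line at time(s) ``t_ms``.

    The mask flashes in the same pattern as the laser, at the level a
    switched LED can realise: square trains are mirrored exactly; for
    sinusoids the LED toggles at the train frequency with 50 % duty across
    the active window.  Callers apply ``mask_enabled`` / mock gating.
    """
    if params.waveform is Waveform.SQUARE:
        return ttl_at(params, t_ms)
    t = np.asarray(t_ms, dtype=float)
    active = (t >= params.delay_ms) & (t < params.active_ms)
    out = active & (_phase_ms(params, t) < 0.5 * params.period_ms)
    return bool(out) if np.isscalar(t_ms) else out


def quantize_dac(
    fraction: NDArray | float,
    bits: int = DAC_BITS_DEFAULT,
    vref: float = DAC_VREF_DEFAULT,
) -> tuple[NDArray | int, NDArray | float]:
    """Quantize a fraction of full scale to a DAC code and output voltage.

    Round-half-up to the nearest of ``2**bits`` codes; full scale maps to
    code ``2**bits - 1`` which outputs exactly ``vref``.  Quantization error
    is at most half an LSB.
    """
    frac = np.asarray(fraction, dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ParamError("fraction must lie in [0, 1]")
    full_scale = (1 << bits) - 1
    code = np.floor(frac * full_scale + 0.5).astype(np.int64)
    volts = code / full_scale * vref
    if np.isscalar(fraction):
        return int(code), float(volts)
    return code, volts


@dataclass(frozen=True)
class ChannelTrace:
    """Uniformly sampled record of one channel's three output lines.

    ``t_s`` is in seconds; ``analog_V`` holds exact DAC-representable
    voltages; ``ttl`` and ``mask`` are boolean.
    """

    t_s: NDArray
    analog_V: NDArray
    ttl: NDArray
    mask: NDArray

    def __post_init__(self) -> None:
        n = len(self.t_s)
        if not (len(self.analog_V) == len(self.ttl) == len(self.mask) == n):
            raise ValueError("all ChannelTrace arrays must have equal length")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.t_s[1] - self.t_s[0])

    def __len__(self) -> int:
        return len(self.t_s)


def render(
    params: StimParams,
    rate_hz: float,
    total_s: float,
    *,
    calibration=None,
    bits: int = DAC_BITS_DEFAULT,
    vref: float = DAC_VREF_DEFAULT,
) -> ChannelTrace:
    """Render one channel's episode (trigger at t=0) to a sampled trace.

    Per-sample evaluation of the TTL predicate and the analog fraction,
    scaled by the requested power fraction and quantized to the DAC grid.
    The mask line is filled whenever ``params.mask_enabled``.

    A warning is raised when ``rate_hz`` is at or below the Nyquist rate of
    the train frequency.
    """
    if not (rate_hz > 0):
        raise ParamError(f"rate_hz must be > 0, got {rate_hz}")
    if rate_hz <= 2.0 * params.freq_hz:
        warnings.warn(
            f"sampling rate {rate_hz} Hz does not resolve a {params.freq_hz} Hz train "
            "(need > 2x the train frequency)",
            stacklevel=2,
        )
    n = int(round(total_s * rate_hz))
    # sample times built in ms so grid points are exact at round rates
    t_ms = np.arange(n) * (1000.0 / rate_hz)
    t_s = t_ms / 1000.0
    ttl = ttl_at(params, t_ms)
    frac = analog_fraction_at(params, t_ms) * params.power_fraction(calibration)
    _, volts = quantize_dac(frac, bits=bits, vref=vref)
    if params.mask_enabled:
        mask = mask_at(params, t_ms)
    else:
        mask = np.zeros(n, dtype=bool)
    return ChannelTrace(t_s=t_s, analog_V=volts, ttl=np.asarray(ttl), mask=np.asarray(mask))
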