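"""Shared fixtures and the independent per-sample waveform oracle.

The oracle evaluates the waveform contract one sample at a time with plain
Python ``math`` — no numpy, no shared code path with the vectorised
renderer — so render/oracle agreement is a genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from optopulse.params import StimParams, Waveform


def oracle_lines(params: StimParams, t_ms: float, bits: int = 12, vref: float = 5.0):
    """(ttl, analog_V, mask) at one instant, from the defining predicates."""
    delay, burst, atten = params.delay_ms, params.burst_ms, params.atten_ms
    period = 1000.0 / params.freq_hz
    tau = t_ms - delay
    if params.waveform is Waveform.SQUARE:
        width = params.pulse_ms if params.pulse_ms is not None else params.duty * period
        phase = tau - period * math.floor(tau / period)
        in_train = delay <= t_ms < delay + burst
        ttl = in_train and phase < width
        frac = 1.0 if in_train else 0.0
        mask = ttl
    else:
        end = delay + burst + atten
        active = delay <= t_ms < end
        ttl = active
        if t_ms <= delay + burst:
            gain = 1.0
        elif atten > 0 and t_ms <= delay + burst + atten:
            gain = 1.0 - (t_ms - delay - burst) / atten
        else:
            gain = 0.0
        omega_t = 2.0 * math.pi * params.freq_hz * tau / 1000.0
        if params.waveform is Waveform.SINE:
            shape = 0.5 * (1.0 - math.cos(omega_t))
        else:
            shape = max(0.0, math.sin(omega_t))
        frac = shape * gain if active else 0.0
        phase = tau - period * math.floor(tau / period)
        mask = active and phase < 0.5 * period
    frac *= params.power / 100.0 if params.power_unit.value == "percent" else 1.0
    full = (1 << bits) - 1
    code = math.floor(frac * full + 0.5)
    volts = code / full * vref
    if not params.mask_enabled:
        mask = False
    return ttl, volts, mask


def random_params(rng: np.random.Generator, laser_id: int = 1) -> StimParams:
    """One random but valid parameter set across all waveforms."""
    waveform = [Waveform.SQUARE, Waveform.SINE, Waveform.HALF_SINE][int(rng.integers(3))]
    freq = float(rng.uniform(1.0, 200.0))
    period = 1000.0 / freq
    burst = float(rng.uniform(2 * period, 20 * period))
    kwargs = dict(
        laser_id=laser_id,
        waveform=waveform,
        burst_ms=burst,
        freq_hz=freq,
        delay_ms=float(rng.uniform(0, 50)),
        power=float(rng.uniform(5, 100)),
        mask_enabled=bool(rng.random() < 0.8),
    )
    if waveform is Waveform.SQUARE:
        if rng.random() < 0.5:
            kwargs["pulse_ms"] = float(rng.uniform(0.05, 1.0) * period)
        else:
            kwargs["duty"] = float(rng.uniform(0.05, 0.95))
    else:
        kwargs["atten_ms"] = float(rng.uniform(0, 5 * period)) if rng.random() < 0.5 else 0.0
    return StimParams(**kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def square40() -> StimParams:
    """The two-train timing-validation configuration: 40 Hz, 6 ms, 10 s."""
    return StimParams(laser_id=1, waveform=Waveform.SQUARE, burst_ms=10_000,
                      freq_hz=40.0, pulse_ms=6.0)
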