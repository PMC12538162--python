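"""Virtual-DAQ metrology: pulse timing and phase statistics on traces.

These are the measurements used to characterise the generator the same
way one would with a data-acquisition system on the physical outputs:
threshold-crossing edge detection with sub-sample interpolation, per-pulse
duration and onset-interval statistics, trigger lag, inter-channel onset
offsets, and circular statistics of the instantaneous phase difference
between two sinusoidal channels.

Conventions
-----------
* "Interpulse duration" is onset-to-onset (the reciprocal of the train
  frequency), not the offset-to-onset gap.
* Edges are detected at 50 % of the per-channel maximum by default, with
  linear interpolation between the bracketing samples.
* Phase is estimated by quadrature demodulation at the known train
  frequency f0 (f0 is always known in this tool), low-passed with a
  one-period moving average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import uniform_filter1d

from .params import ParamError
from .device import Event

__all__ = [
    "PulseStats",
    "PhaseStats",
    "detect_edges",
    "pulse_stats",
    "trigger_lag",
    "intersignal_offset",
    "instantaneous_phase",
    "phase_difference_stats",
    "fixture_trigger_train",
]


def _as_signal(channel: NDArray) -> NDArray:
    """Boolean/int channels become floats so thresholding works uniformly."""
    return np.asarray(channel, dtype=float)


def detect_edges(
    channel: NDArray,
    rate_hz: float,
    threshold_fraction: float = 0.5,
) -> tuple[NDArray, NDArray]:
    """Paired pulse onsets and offsets (ms) by threshold crossing.

    The threshold is ``threshold_fraction`` of the channel maximum;
    crossing times are refined by linear interpolation between the two
    bracketing samples.  A channel that is already above threshold at the
    first sample contributes an onset at t=0; one still above threshold at
    the last sample contributes an offset there, so every onset is paired.
    A flat channel yields empty arrays.
    """
    x = _as_signal(channel)
    if len(x) == 0 or np.ptp(x) == 0:
        return np.array([]), np.array([])
    thr = threshold_fraction * x.max()
    above = x > thr
    dt_ms = 1000.0 / rate_hz
    t_ms = np.arange(len(x)) * dt_ms

    onsets: list[float] = []
    offsets: list[float] = []
    if above[0]:
        onsets.append(t_ms[0])
    rising = np.nonzero(~above[:-1] & above[1:])[0]
    falling = np.nonzero(above[:-1] & ~above[1:])[0]
    for i in rising:
        frac = (thr - x[i]) / (x[i + 1] - x[i])
        onsets.append(t_ms[i] + frac * dt_ms)
    for i in falling:
        frac = (x[i] - thr) / (x[i] - x[i + 1])
        offsets.append(t_ms[i] + frac * dt_ms)
    if above[-1]:
        offsets.append(t_ms[-1])
    onsets_a = np.sort(np.asarray(onsets))
    offsets_a = np.sort(np.asarray(offsets))
    # pair strictly: each onset matched with the first offset after it
    n = min(len(onsets_a), len(offsets_a))
    return onsets_a[:n], offsets_a[:n]


@dataclass(frozen=True)
class PulseStats:
    """Per-pulse timing statistics for one pulsatile channel."""

    onsets_ms: NDArray
    offsets_ms: NDArray
    durations_ms: NDArray
    onset_intervals_ms: NDArray

    @property
    def n_pulses(self) -> int:
        return len(self.onsets_ms)

    @property
    def mean_duration_ms(self) -> float:
        return float(np.mean(self.durations_ms))

    @property
    def sd_duration_ms(self) -> float:
        return float(np.std(self.durations_ms, ddof=1)) if len(self.durations_ms) > 1 else 0.0

    @property
    def mean_interval_ms(self) -> float:
        return float(np.mean(self.onset_intervals_ms))

    @property
    def sd_interval_ms(self) -> float:
        return float(np.std(self.onset_intervals_ms, ddof=1)) if len(self.onset_intervals_ms) > 1 else 0.0

    @property
    def freq_hz_est(self) -> float:
        """Train frequency estimated from mean onset-to-onset interval."""
        return 1000.0 / self.mean_interval_ms

    def summary(self) -> dict[str, float]:
        return {
            "n_pulses": self.n_pulses,
            "mean_duration_ms": self.mean_duration_ms,
            "sd_duration_ms": self.sd_duration_ms,
            "mean_interval_ms": self.mean_interval_ms,
            "sd_interval_ms": self.sd_interval_ms,
            "freq_hz_est": self.freq_hz_est,
        }


def pulse_stats(channel: NDArray, rate_hz: float, threshold_fraction: float = 0.5) -> PulseStats:
    """Detect pulses and compute duration/interval statistics (>= 2 pulses)."""
    onsets, offsets = detect_edges(channel, rate_hz, threshold_fraction)
    if len(onsets) < 2:
        raise ParamError(f"need >= 2 pulses for statistics, found {len(onsets)}")
    durations = offsets - onsets
    if np.any(durations <= 0):
        raise ParamError("mis-paired edges: nonpositive pulse duration")
    intervals = np.diff(onsets)
    return PulseStats(
        onsets_ms=onsets,
        offsets_ms=offsets,
        durations_ms=durations,
        onset_intervals_ms=intervals,
    )


def trigger_lag(
    trigger_channel: NDArray,
    output_channel: NDArray,
    rate_hz: float,
) -> NDArray:
    """Per-episode lag (ms): first output onset after each trigger onset.

    Triggers with no subsequent output onset are flagged with NaN.
    Trigger onsets must be sorted (they are, coming from a real record).
    """
    trig_on, _ = detect_edges(trigger_channel, rate_hz)
    out_on, _ = detect_edges(output_channel, rate_hz)
    if np.any(np.diff(trig_on) < 0):
        raise ParamError("trigger onsets must be sorted in time")
    lags = np.full(len(trig_on), np.nan)
    for k, t0 in enumerate(trig_on):
        later = out_on[out_on >= t0]
        # attribute only onsets before the next trigger to this episode
        if k + 1 < len(trig_on):
            later = later[later < trig_on[k + 1]]
        if len(later):
            lags[k] = later[0] - t0
    return lags


def intersignal_offset(
    channel_a: NDArray,
    channel_b: NDArray,
    rate_hz: float,
    pairing_window_ms: float | None = None,
) -> NDArray:
    """Per-pulse onset differences (b - a, ms) after nearest-neighbour pairing.

    Each onset in ``a`` is paired with the nearest onset in ``b``; pairs
    further apart than ``pairing_window_ms`` (when given) are dropped.
    With unequal pulse counts only matched pairs are reported.
    """
    on_a, _ = detect_edges(channel_a, rate_hz)
    on_b, _ = detect_edges(channel_b, rate_hz)
    if len(on_a) == 0 or len(on_b) == 0:
        return np.array([])
    idx = np.searchsorted(on_b, on_a)
    offsets = np.empty(len(on_a))
    for k, t in enumerate(on_a):
        cands = []
        if idx[k] > 0:
            cands.append(on_b[idx[k] - 1])
        if idx[k] < len(on_b):
            cands.append(on_b[idx[k]])
        nearest = min(cands, key=lambda c: abs(c - t))
        offsets[k] = nearest - t
    if pairing_window_ms is not None:
        offsets = offsets[np.abs(offsets) <= pairing_window_ms]
    return offsets


def instantaneous_phase(channel: NDArray, f0_hz: float, rate_hz: float) -> NDArray:
    """Per-sample phase (rad, wrapped to (-pi, pi]) of an f0 oscillation.

    Quadrature demodulation: the (mean-subtracted) signal is multiplied by
    cos/-sin at f0 and low-passed with a moving average spanning one
    period; phase = atan2(Q, I).  A signal ``cos(2 pi f0 t - phi)`` returns
    ``-phi`` + 0; the raised-cosine waveform used for sinusoidal
    stimulation, delayed by d, returns ``pi - 2 pi f0 d`` in steady state
    (its oscillatory part is a negated cosine).
    """
    if f0_hz <= 0:
        raise ParamError("f0_hz must be > 0")
    x = _as_signal(channel)
    n_period = int(round(rate_hz / f0_hz))
    if len(x) < 2 * n_period:
        raise ParamError("record shorter than 2 periods of f0")
    t = np.arange(len(x)) / rate_hz
    xc = x - x.mean()
    omega_t = 2.0 * np.pi * f0_hz * t
    i_raw = xc * np.cos(omega_t)
    q_raw = -xc * np.sin(omega_t)
    i_lp = uniform_filter1d(i_raw, size=n_period, mode="nearest")
    q_lp = uniform_filter1d(q_raw, size=n_period, mode="nearest")
    return np.arctan2(q_lp, i_lp)


def wrap_phase(phi: NDArray | float) -> NDArray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class PhaseStats:
    """Circular summary of a per-sample phase-difference series."""

    phase_diffs_rad: NDArray
    circ_mean_rad: float
    resultant_length: float

    def summary(self) -> dict[str, float]:
        return {
            "circ_mean_rad": self.circ_mean_rad,
            "resultant_length": self.resultant_length,
            "n_samples": len(self.phase_diffs_rad),
        }


def circular_mean(angles: NDArray) -> tuple[float, float]:
    """Mean direction in (-pi, pi] and resultant length R of angles."""
    s, c = np.sum(np.sin(angles)), np.sum(np.cos(angles))
    mean = float(np.arctan2(s, c))
    r = float(np.hypot(s, c) / len(angles))
    if mean <= -np.pi:  # map -pi to +pi, same direction
        mean += 2.0 * np.pi
    return mean, r


def phase_difference_stats(
    channel_a: NDArray,
    channel_b: NDArray,
    f0_hz: float,
    rate_hz: float,
) -> PhaseStats:
    """Circular statistics of the instantaneous phase difference a - b.

    One period is trimmed from each end before the statistics to discard
    the demodulation-filter transients.
    """
    pa = instantaneous_phase(channel_a, f0_hz, rate_hz)
    pb = instantaneous_phase(channel_b, f0_hz, rate_hz)
    n_period = int(round(rate_hz / f0_hz))
    diffs = wrap_phase(pa - pb)[n_period:-n_period]
    if len(diffs) == 0:
        raise ParamError("record too short after transient trimming")
    mean, r = circular_mean(diffs)
    return PhaseStats(phase_diffs_rad=diffs, circ_mean_rad=mean, resultant_length=r)


def zero_crossing_phase(channel: NDArray, f0_hz: float, rate_hz: float) -> NDArray:
    """Independent offset-phase estimator from mean-crossing times.

    A signal ``A cos(2 pi f0 t + phi)`` crosses its mean upward when the
    argument equals ``-pi/2`` (mod 2 pi), so each rising crossing at time
    ``tc`` pins the offset ``phi = -pi/2 - 2 pi f0 tc`` (mod 2 pi).  The
    per-cycle estimate is held constant until the next crossing.  Serves
    in tests as a second method against quadrature demodulation; samples
    before the first crossing are NaN.
    """
    x = _as_signal(channel)
    xc = x - x.mean()
    above = xc > 0
    rising = np.nonzero(~above[:-1] & above[1:])[0]
    if len(rising) < 2:
        raise ParamError("too few mean crossings for phase estimation")
    t = np.arange(len(x)) / rate_hz
    cross_t = np.array(
        [t[i] + (0.0 - xc[i]) / (xc[i + 1] - xc[i]) / rate_hz for i in rising]
    )
    phase = np.full(len(x), np.nan)
    for k, t0 in enumerate(cross_t):
        t1 = cross_t[k + 1] if k + 1 < len(cross_t) else t[-1] + 1 / rate_hz
        sel = (t >= t0) & (t < t1)
        phase[sel] = -np.pi / 2 - 2.0 * np.pi * f0_hz * t0
    return wrap_phase(phase)


def fixture_trigger_train(
    seed: int,
    n: int,
    min_gap_ms: float,
    t_max_s: float,
    line: int = 1,
) -> list[Event]:
    """Seeded random trigger times with an enforced minimum gap.

    Emulates a trigger source firing at random time points: n times are
    drawn uniformly on the feasible range, sorted, and spread by
    ``min_gap_ms``.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ParamError("n must be >= 1")
    t_max_ms = t_max_s * 1000.0
    slack = t_max_ms - (n - 1) * min_gap_ms
    if slack <= 0:
        raise ParamError(
            f"infeasible: {n} triggers with {min_gap_ms} ms gaps exceed {t_max_s} s"
        )
    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(0.0, slack, size=n))
    times = base + np.arange(n) * min_gap_ms
    return [Event(t_ms=float(t), kind="trigger", line=line) for t in times]
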