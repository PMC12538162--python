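"""Virtual pulse-generator device: state machine, triggering and rendering.

The real controller runs a main loop on a microcontroller: it watches a
selectable trigger input (debounced, optionally gated by a priming pin),
and on an accepted edge starts every configured laser channel, each with
its own delay/burst/waveform.  This module reproduces that behaviour as a
discrete-event simulation with an explicit clock.

States
------
IDLE         no stimulation active; parameters may be replaced.
PRIMED       the priming pin armed exactly one trigger acceptance.
STIMULATING  at least one channel is inside its active window.

Mock ("null") trials drive only the masking-LED lines: the laser analog
and enable lines stay at zero for the whole episode, so control trials are
indistinguishable to the animal but deliver no light to the brain.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .params import N_LASERS, ParamError, StimParams
from . import waveform as wf

__all__ = ["DeviceConfig", "DeviceState", "Event", "Trace", "VirtualDevice", "DeviceBusyError"]


class DeviceBusyError(RuntimeError):
    """Raised when a command requires an idle device."""


class DeviceState(enum.Enum):
    IDLE = "idle"
    PRIMED = "primed"
    STIMULATING = "stimulating"


@dataclass(frozen=True)
class DeviceConfig:
    """Static device configuration.

    ``debounce_ms`` is the trigger debounce window (firmware default 5 ms);
    edges closer than this to the previous edge on the selected line are
    ignored.  ``loop_latency_ms`` optionally emulates the measured
    trigger-to-output lag of the physical hardware (default 0: ideal
    device).  ``trigger_polarity`` selects which transition counts as a
    trigger; rising (LOW->HIGH) is the documented operating default.
    """

    n_lasers: int = N_LASERS
    debounce_ms: float = 5.0
    trigger_line: int = 1
    priming_required: bool = False
    standalone: bool = False
    trigger_polarity: str = "rising"
    ttl_high_V: float = 3.3
    dac_bits: int = 12
    dac_vref_V: float = 5.0
    heartbeat_hz: float = 6.0
    loop_latency_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.debounce_ms < 0:
            raise ParamError("debounce_ms must be >= 0")
        if self.trigger_line not in range(1, 7):
            raise ParamError(f"trigger_line must be in 1..6, got {self.trigger_line}")
        if self.dac_bits < 1:
            raise ParamError("dac_bits must be >= 1")
        if self.trigger_polarity not in ("rising", "falling"):
            raise ParamError("trigger_polarity must be 'rising' or 'falling'")
        if self.loop_latency_ms < 0:
            raise ParamError("loop_latency_ms must be >= 0")


@dataclass(frozen=True)
class Event:
    """One timestamped input event for :meth:`VirtualDevice.run`.

    ``kind`` is one of ``trigger``, ``prime``, ``prime_release``,
    ``mock_on``, ``mock_off``, ``software_trigger``; ``line`` matters for
    ``trigger`` only.
    """

    t_ms: float
    kind: str
    line: int = 1

    KINDS = ("trigger", "prime", "prime_release", "mock_on", "mock_off", "software_trigger")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ParamError(f"unknown event kind {self.kind!r}")


@dataclass
class _LaserChannel:
    """Per-laser state: parameters plus the episode start register."""

    params: StimParams | None = None
    active: bool = False
    t_start_ms: float = 0.0


@dataclass
class Trace:
    """Multichannel sampled record of a device run.

    One column group per configured laser: ``laserN_V`` (DAC volts),
    ``laserN_ttl`` and ``maskN`` (0/1), plus the shared time axis ``t_s``
    in seconds and, when trigger events were supplied, a ``trigger``
    0/1 column reflecting the raw trigger line.
    """

    t_s: NDArray
    channels: dict[int, wf.ChannelTrace]
    trigger: NDArray | None = None
    episodes: list[dict] = field(default_factory=list)

    def channel(self, laser_id: int) -> wf.ChannelTrace:
        return self.channels[laser_id]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, NDArray] = {"t_s": self.t_s}
        for lid in sorted(self.channels):
            ch = self.channels[lid]
            cols[f"laser{lid}_V"] = ch.analog_V
            cols[f"laser{lid}_ttl"] = ch.ttl.astype(int)
            cols[f"mask{lid}"] = ch.mask.astype(int)
        if self.trigger is not None:
            cols["trigger"] = self.trigger.astype(int)
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        df = pd.read_csv(path)
        t_s = df["t_s"].to_numpy(dtype=float)
        channels: dict[int, wf.ChannelTrace] = {}
        for lid in range(1, N_LASERS + 1):
            if f"laser{lid}_V" in df.columns:
                channels[lid] = wf.ChannelTrace(
                    t_s=t_s,
                    analog_V=df[f"laser{lid}_V"].to_numpy(dtype=float),
                    ttl=df[f"laser{lid}_ttl"].to_numpy(dtype=float) > 0.5,
                    mask=df[f"mask{lid}"].to_numpy(dtype=float) > 0.5,
                )
        trig = df["trigger"].to_numpy(dtype=float) > 0.5 if "trigger" in df.columns else None
        return cls(t_s=t_s, channels=channels, trigger=trig)

    def save_episode_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ep in self.episodes:
                fh.write(json.dumps(ep) + "\n")


class VirtualDevice:
    """Software emulation of the four-laser pulse generator.

    The device is driven either event-by-event (:meth:`on_trigger_edge`,
    :meth:`step`, ...) with a caller-supplied monotone clock in ms, or in
    batch via :meth:`run`, which replays a timestamped event list and
    samples all output lines at a fixed rate.
    """

    def __init__(self, config: DeviceConfig | None = None):
        self.config = config or DeviceConfig()
        self.state = DeviceState.IDLE
        self.mock = False
        self.channels: dict[int, _LaserChannel] = {
            i: _LaserChannel() for i in range(1, self.config.n_lasers + 1)
        }
        self.calibrations: dict[int, object] = {}
        self._t_last_edge_ms = -np.inf   # last edge on the selected line
        self._t_last_soft_ms = -np.inf
        self._t_now_ms = -np.inf
        self._episode_end_ms = -np.inf
        self.episode_log: list[dict] = []

    # -- configuration ------------------------------------------------------

    @property
    def stimulating(self) -> bool:
        return self.state is DeviceState.STIMULATING

    def comm_enable(self) -> bool:
        """CommEnable line: HIGH while the device only awaits triggers.

        LOW when idle and ready for new parameters; always LOW in
        standalone mode (the line is disabled there).
        """
        if self.config.standalone:
            return False
        return self.state is not DeviceState.IDLE

    def set_params(self, params_list: list[StimParams]) -> dict:
        """Replace per-channel parameters; requires CommEnable LOW."""
        if self.comm_enable() or self.stimulating:
            raise DeviceBusyError("device busy: cannot accept parameters")
        seen: set[int] = set()
        for p in params_list:
            if not isinstance(p, StimParams):
                p = StimParams.from_dict(dict(p))
            if p.laser_id not in self.channels:
                raise ParamError(f"laser_id {p.laser_id} out of range 1..{self.config.n_lasers}")
            if p.laser_id in seen:
                raise ParamError(f"duplicate parameters for laser {p.laser_id}")
            seen.add(p.laser_id)
        # validate all, then commit atomically
        for i in self.channels:
            self.channels[i].params = None
        for p in params_list:
            if not isinstance(p, StimParams):
                p = StimParams.from_dict(dict(p))
            self.channels[p.laser_id].params = p
        return {"status": "ok", "configured": sorted(seen)}

    def set_mock(self, flag: bool) -> None:
        """Arm/disarm mock (mask-only) mode for subsequent episodes."""
        if self.stimulating:
            raise DeviceBusyError("device busy: cannot change mock flag during an episode")
        self.mock = bool(flag)

    def set_calibration(self, laser_id: int, curve) -> None:
        self.calibrations[laser_id] = curve

    # -- input edges ---------------------------------------------------------

    def on_prime_edge(self, t_ms: float) -> None:
        """Priming-pin active edge: arm exactly one trigger acceptance."""
        self._advance(t_ms)
        if self.config.priming_required and not self.stimulating:
            self.state = DeviceState.PRIMED

    def on_prime_release(self, t_ms: float) -> None:
        """Priming-pin release: a pending, unused arm is cleared."""
        self._advance(t_ms)
        if self.state is DeviceState.PRIMED:
            self.state = DeviceState.IDLE

    def on_trigger_edge(self, t_ms: float, line: int | None = None) -> bool:
        """Hardware trigger edge; returns True iff the edge was accepted.

        Acceptance requires: the edge is on the configured line, at least
        ``debounce_ms`` after the previous edge on that line, the device is
        not already stimulating, and (when priming is required) the device
        is primed.  On acceptance every configured channel starts its own
        episode clock and the prime is consumed.
        """
        self._advance(t_ms)
        if line is not None and line != self.config.trigger_line:
            self._log_edge(t_ms, "trigger", False, "wrong-line")
            return False
        debounced = (t_ms - self._t_last_edge_ms) >= self.config.debounce_ms
        self._t_last_edge_ms = t_ms
        if not debounced:
            self._log_edge(t_ms, "trigger", False, "debounce")
            return False
        return self._try_start(t_ms, "trigger", gate_priming=True)

    def software_trigger(self, t_ms: float) -> bool:
        """GUI/API trigger: bypasses line selection and priming."""
        self._advance(t_ms)
        debounced = (t_ms - self._t_last_soft_ms) >= self.config.debounce_ms
        self._t_last_soft_ms = t_ms
        if not debounced:
            self._log_edge(t_ms, "software_trigger", False, "debounce")
            return False
        return self._try_start(t_ms, "software_trigger", gate_priming=False)

    def _try_start(self, t_ms: float, kind: str, gate_priming: bool) -> bool:
        if self.stimulating:
            self._log_edge(t_ms, kind, False, "busy")
            return False
        if gate_priming and self.config.priming_required and self.state is not DeviceState.PRIMED:
            self._log_edge(t_ms, kind, False, "not-primed")
            return False
        configured = [c for c in self.channels.values() if c.params is not None]
        if not configured:
            self._log_edge(t_ms, kind, False, "no-params")
            return False
        t_start = t_ms + self.config.loop_latency_ms
        for ch in configured:
            ch.active = True
            ch.t_start_ms = t_start
        self._episode_end_ms = t_start + max(c.params.active_ms for c in configured)
        self.state = DeviceState.STIMULATING
        self._log_edge(t_ms, kind, True, "mock" if self.mock else "stim")
        return True

    def _log_edge(self, t_ms: float, kind: str, accepted: bool, reason: str) -> None:
        self.episode_log.append(
            {"t_ms": float(t_ms), "kind": kind, "accepted": accepted, "reason": reason}
        )

    def _advance(self, t_ms: float) -> None:
        if t_ms < self._t_now_ms:
            raise ParamError(f"time moved backwards: {t_ms} < {self._t_now_ms}")
        self._t_now_ms = t_ms

    # -- output sampling -----------------------------------------------------

    def step(self, t_ms: float) -> dict[int, dict]:
        """Sample all output lines at ``t_ms`` (monotone nondecreasing).

        Returns ``{laser_id: {"analog_V", "ttl", "mask"}}``.  Transitions
        back to IDLE once every channel has passed the end of its active
        window.
        """
        self._advance(t_ms)
        if self.stimulating and t_ms >= self._episode_end_ms:
            for ch in self.channels.values():
                ch.active = False
            self.state = DeviceState.IDLE
        snapshot: dict[int, dict] = {}
        for lid, ch in self.channels.items():
            if ch.active and ch.params is not None and t_ms >= ch.t_start_ms:
                p = ch.params
                tau = t_ms - ch.t_start_ms
                calib = self.calibrations.get(lid)
                if self.mock:
                    volts, ttl = 0.0, False
                else:
                    frac = wf.analog_fraction_at(p, tau) * p.power_fraction(calib)
                    _, volts = wf.quantize_dac(
                        frac, bits=self.config.dac_bits, vref=self.config.dac_vref_V
                    )
                    ttl = bool(wf.ttl_at(p, tau))
                mask = bool(wf.mask_at(p, tau)) if p.mask_enabled else False
            else:
                volts, ttl, mask = 0.0, False, False
            snapshot[lid] = {"analog_V": volts, "ttl": ttl, "mask": mask}
        return snapshot

    def heartbeat(self, t_ms: float) -> bool:
        """Status-LED blink: square wave at ``heartbeat_hz`` while idle.

        Suppressed (LOW) during an episode; HIGH at t=0 by convention.
        """
        if self.stimulating:
            return False
        period = 1000.0 / self.config.heartbeat_hz
        return (t_ms % period) < 0.5 * period

    # -- batch simulation ----------------------------------------------------

    def run(self, events: list[Event], rate_hz: float, t_end_s: float) -> Trace:
        """Replay an event list, sampling every line at ``rate_hz``.

        Events are applied in time order, interleaved exactly with the
        sample clock; an episode log (accepted/rejected edges with reasons)
        is attached to the returned :class:`Trace`.
        """
        if not (rate_hz > 0):
            raise ParamError("rate_hz must be > 0")
        events = sorted(events, key=lambda e: e.t_ms)
        n = int(round(t_end_s * rate_hz))
        dt_ms = 1000.0 / rate_hz
        t_s = np.arange(n) * dt_ms / 1000.0
        out = {
            lid: {
                "analog_V": np.zeros(n),
                "ttl": np.zeros(n, dtype=bool),
                "mask": np.zeros(n, dtype=bool),
            }
            for lid in self.channels
        }
        trigger_line = np.zeros(n, dtype=bool)
        self.episode_log = []

        ei = 0
        for i in range(n):
            t_ms = i * dt_ms
            while ei < len(events) and events[ei].t_ms <= t_ms:
                self._apply_event(events[ei])
                ei += 1
            snap = self.step(t_ms)
            for lid, lines in snap.items():
                out[lid]["analog_V"][i] = lines["analog_V"]
                out[lid]["ttl"][i] = lines["ttl"]
                out[lid]["mask"][i] = lines["mask"]
        # mark a one-sample-wide pulse on the trigger column per trigger event
        for ev in events:
            if ev.kind in ("trigger", "software_trigger"):
                idx = int(np.ceil(ev.t_ms / 1000.0 * rate_hz - 1e-9))
                if 0 <= idx < n:
                    trigger_line[idx] = True

        channels = {
            lid: wf.ChannelTrace(
                t_s=t_s, analog_V=d["analog_V"], ttl=d["ttl"], mask=d["mask"]
            )
            for lid, d in out.items()
        }
        return Trace(t_s=t_s, channels=channels, trigger=trigger_line,
                     episodes=list(self.episode_log))

    def _apply_event(self, ev: Event) -> None:
        if ev.kind == "trigger":
            self.on_trigger_edge(ev.t_ms, line=ev.line)
        elif ev.kind == "software_trigger":
            self.software_trigger(ev.t_ms)
        elif ev.kind == "prime":
            self.on_prime_edge(ev.t_ms)
        elif ev.kind == "prime_release":
            self.on_prime_release(ev.t_ms)
        elif ev.kind == "mock_on":
            if not self.stimulating:
                self.set_mock(True)
        elif ev.kind == "mock_off":
            if not self.stimulating:
                self.set_mock(False)


def events_from_csv(path: str | Path) -> list[Event]:
    """Read an event list from CSV with columns ``t_ms,kind,line``."""
    df = pd.read_csv(path)
    line = df["line"] if "line" in df.columns else pd.Series([1] * len(df))
    return [
        Event(t_ms=float(t), kind=str(k), line=int(l))
        for t, k, l in zip(df["t_ms"], df["kind"], line.fillna(1))
    ]
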