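# optopulse

A pure-software virtual device and analysis toolkit for a four-channel
optogenetic laser stimulation controller.

Optogenetic experiments drive genetically targeted neurons with precisely
timed light. Tabletop diode lasers (Omicron LuxX, Coherent OBIS, and
similar) are controlled through two inputs per laser: a digital
**enable/TTL** line (3.3 V logic) that gates emission, and an **analog**
line (0–5 V, 12-bit DAC) that sets output power. `optopulse` emulates a
microcontroller-based pulse generator for up to four such lasers plus four
masking-LED channels, entirely in software, so that stimulation protocols,
triggering logic and timing claims can be designed, tested and validated
without hardware on the bench — and so that recorded traces from the real
device can be analysed with the same metrology.

The package provides:

* **Waveform synthesis** (`optopulse.waveform`) — square, sinusoidal
  (raised cosine, starting from zero) and half-sinusoidal pulse trains,
  with burst duration, frequency, pulse width / duty cycle, trigger delay,
  linear amplitude attenuation (ramp-down to zero for sinusoids), power
  scaling, and 12-bit DAC quantization over 0–5 V.
* **The device state machine** (`optopulse.device`) — a virtual controller
  with six selectable trigger inputs, a 5 ms trigger debounce, an optional
  priming gate (a prime arms exactly one trigger acceptance, so beam-break
  chatter cannot re-trigger), mock (mask-only) control trials, CommEnable
  semantics, a 6 Hz status heartbeat, and an optional constant
  loop-latency emulation of the physical hardware's trigger lag.
* **A line-delimited JSON control protocol** (`optopulse.protocol`) —
  parameter upload, software trigger, mock flag, ping/echo and calibration
  commands, one JSON object per line over any byte-stream transport.
* **Power calibration** (`optopulse.calibration`) — stepped-intensity
  measurement plan, closed-form OLS line through (control fraction,
  measured mW), JSON persistence, and safe mW → fraction inversion
  (out-of-range requests are errors, not extrapolations).
* **Metrology** (`optopulse.analysis`) — threshold-crossing edge detection
  with sub-sample interpolation, pulse duration / interpulse-interval
  statistics, frequency estimation, trigger lag, inter-channel onset
  offsets, and circular statistics of the instantaneous phase difference
  between sinusoidal channels (quadrature demodulation at the known train
  frequency).

## The timing model

A trigger accepted at time 0 starts, for each configured laser `i`, a
train with period `T_i = 1000 / f_i` ms after a per-channel delay `d_i`:

* **square** — TTL HIGH iff `d ≤ t < d + burst` and
  `(t − d) mod T < w`, where `w` is the pulse width (`w = duty · T`);
  the analog line holds the power level across the burst.
* **sine** — analog level `P · g(t) · (1 − cos(2πf(t−d)))/2`, TTL held
  HIGH for the whole train; `g(t)` ramps linearly from 1 to 0 over the
  attenuation window appended after the burst.
* **half-sine** — `P · g(t) · max(0, sin(2πf(t−d)))`.

Analog levels are quantized to the 4096-step DAC grid (`round` half-up,
full scale = 5 V). Validation metrics are defined exactly as they would be
measured with a DAQ on the physical outputs: interpulse duration is
onset-to-onset (so its mean is the period, 25 ms at 40 Hz), frequency is
`1000 / mean(onset interval in ms)`, and the phase offset between two
sinusoids is the circular mean `atan2(Σ sin Δφ, Σ cos Δφ)` of the
per-sample phase difference.

## Worked example

Two lasers with identical 40 Hz / 6 ms square trains, the second delayed
by 200 ms, triggered once and sampled at 2 kHz:

```python
import json
import optopulse as op

p1 = op.StimParams(laser_id=1, waveform="square", burst_ms=10_000,
                   freq_hz=40.0, pulse_ms=6.0)
p2 = op.StimParams(laser_id=2, waveform="square", burst_ms=10_000,
                   freq_hz=40.0, pulse_ms=6.0, delay_ms=200.0)

dev = op.VirtualDevice()
dev.set_params([p1, p2])
trace = dev.run([op.Event(t_ms=50.0, kind="trigger")],
                rate_hz=2000.0, t_end_s=10.5)

print(json.dumps(op.pulse_stats(trace.channel(1).ttl, 2000.0).summary(), indent=2))
```

prints

```json
{
  "n_pulses": 400,
  "mean_duration_ms": 6.0,
  "sd_duration_ms": 0.0,
  "mean_interval_ms": 25.0,
  "sd_interval_ms": 0.0,
  "freq_hz_est": 40.0
}
```

— the 10 s burst contains exactly `burst · f = 400` pulses, every detected
pulse is 6 ms wide, and consecutive onsets are 25 ms apart, i.e. the
measured frequency equals the 40 Hz setting. The trigger lag of the ideal
device is zero (`op.trigger_lag(trace.trigger, trace.channel(1).ttl, 2000.0)`
→ `[0.]`), and the second train's first onset trails the first train by
exactly the configured 200 ms.

The same pipeline runs from the shell:

```sh
optopulse simulate --params params.json --events events.csv \
    --rate 2000 --duration 30 -o trace.csv
optopulse analyze trace.csv --metrics pulses,lag,offset
optopulse calib fit measurements.csv -o calib_laser1.json
```

## Limitations

The emulation is of an ideal controller: the physical device's intrinsic
trigger lag (hardware-measured ≈1.7 ms) and its control-to-light delay are
properties of the microcontroller loop and the laser electronics, not of
the waveform logic, and are represented only by the configurable constant
`loop_latency_ms`. Microsecond-scale (spike-triggered) timing guarantees
are out of scope, as is relaying an external analog control signal.
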