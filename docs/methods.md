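# Methods

This note records the models, conventions and numerical choices behind
`optopulse`, and what its tests do and do not demonstrate.

## Device model

The emulated controller is a single-threaded state machine with three
states — IDLE, PRIMED, STIMULATING — driven by a caller-supplied monotone
clock in milliseconds. A hardware trigger edge is accepted iff

1. it arrives on the configured trigger line (1–6),
2. at least `debounce_ms` (default 5 ms) has elapsed since the *previous
   edge on that line, accepted or not* — i.e. chatter restarts the
   debounce window, which is the conservative reading of a debounce and
   guarantees at most one acceptance per window,
3. the device is not already stimulating, and
4. when priming is required, the device is PRIMED.

A prime arms exactly one acceptance: it is consumed by the accepted
trigger and cleared by a priming-line release. Software triggers bypass
line selection and priming (they are explicit operator actions) but are
still debounced against repeated software sends. On acceptance every
configured channel latches the same start time (plus the optional
`loop_latency_ms`) and runs independently; the episode ends when the last
channel passes `delay + burst (+ attenuation)`.

Trigger polarity: the package uses rising-edge (LOW→HIGH) triggering by
default — the documented operating procedure (drive the pin HIGH to
start, return it LOW to re-arm) — with a `trigger_polarity` configuration
field for falling-edge wiring.

CommEnable is HIGH whenever the device is not IDLE (it "only awaits
trigger signals" in both the primed and stimulating states), and is
forced LOW in standalone mode. `set_params` therefore requires IDLE (or
standalone); parameter uploads during an episode are rejected, not
queued.

Mock ("null") trials apply to the whole episode and all channels: laser
analog and TTL lines are held at zero while mask lines run normally. This
is a safety invariant, fuzz-tested over random event streams.

## Waveforms

Time is in ms in all parameter structures and in seconds on trace time
axes; the conversion lives in the rendering layer only. For a channel
with delay `d`, burst `B`, frequency `f` (period `T = 1000/f`):

* **Square**: TTL HIGH iff `d ≤ t < d+B` and `(t−d) mod T < w`. The pulse
  width `w` comes from `pulse_ms` (canonical) or `duty·T`; when both are
  supplied they must agree to 1e-9. The analog line is constant at the
  power level across the burst — the TTL does the pulsing. If `B` is not
  an integer number of periods the final pulse is truncated at the burst
  end, never extended.
* **Sine**: the analog line is the raised cosine
  `(1 − cos(2πf(t−d)))/2`. The oscillation must rest on zero because the
  line drives non-negative optical power, and the raised-cosine
  convention makes the signal start at exactly 0 at train onset. TTL is
  held HIGH for the whole active window.
* **Half-sine**: `max(0, sin(2πf(t−d)))` — zero for the second half of
  every period.
* **Attenuation** applies to sinusoids only (square trains have no
  amplitude trajectory to ramp): gain 1 up to `d+B`, then linear to 0
  over `atten_ms`, which *extends* the train — the total active duration
  is `delay + burst + atten`.

Mask channels are digital. For square trains the mask mirrors the laser
TTL sample-for-sample. For sinusoids a switched LED cannot reproduce an
analog waveform, so the mask toggles at the train frequency with 50 %
duty over the active window — the same rhythm at the level the masking
circuit can realise.

DAC quantization: `code = floor(frac·(2^bits − 1) + 0.5)` (round half
up), `volts = code/(2^bits − 1)·vref`, defaults 12 bits / 5.0 V, so full
scale is exactly 5 V and quantization error is at most half an LSB
(0.61 mV). Rendered sample times are generated directly on the
millisecond grid (`arange(n)·(1000/rate)`) so that at round rates like
2 kHz the grid is exact in floating point; building the grid in seconds
and rescaling loses ~1e-12 and occasionally flips a `phase < width`
comparison at pulse boundaries.

## Calibration

The control-fraction → optical-power map is fit by closed-form OLS
(slope `Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²`), with r² reported and checked against a
default linearity threshold of r² ≥ 0.98 — a deliberate, configurable
choice: diode lasers above threshold are very nearly linear, and a lower
r² usually means the measurement included the sub-threshold knee. The
default measurement plan is ten equal steps at 10–100 % of full scale,
10 s per step (long enough for a handheld power-meter reading), both
overridable. Inversion (mW → fraction) refuses requests outside the
measured power range rather than extrapolating — the cautious choice for
animal work — and clamps fractions to [0, 1] with a warning when a
nonzero intercept (lasing threshold) pushes the algebraic inverse out of
range.

## Metrology

* **Edges**: threshold crossings at 50 % of the per-channel maximum, with
  linear interpolation between the bracketing samples. A channel already
  above threshold at the first sample contributes an onset there, so a
  train that starts at t = 0 still counts its first pulse.
* **Interpulse duration** is onset-to-onset: its mean is the period
  (25 ms at 40 Hz), and the frequency estimate is
  `1000/mean(interval in ms)`. The offset-to-onset gap reading would give
  `T − w` instead and is not what the validation numbers describe.
* **Trigger lag** is the first output onset following each trigger onset
  (onsets after the next trigger are not attributed); missing outputs are
  flagged as NaN rather than silently dropped.
* **Intersignal offset** pairs each pulse onset in channel A with the
  nearest onset in channel B, optionally within a pairing window; with
  unequal counts only matched pairs are reported.
* **Instantaneous phase** is estimated by quadrature demodulation at the
  known train frequency f0 (f0 is always known in this tool): multiply
  the mean-subtracted signal by cos/−sin at f0, low-pass both products
  with a one-period moving average, take `atan2(Q, I)`. For the
  raised-cosine waveform the oscillatory part is a *negated* cosine, so a
  channel delayed by `d` reads `π − 2πf0·d` — differences between two
  channels, which is what the validation uses, cancel the π. One period
  is trimmed at each end before circular statistics to discard the
  filter transient. An independent zero-crossing estimator (each rising
  mean-crossing at time `tc` pins the offset `−π/2 − 2πf0·tc`) serves as
  a second method in tests; the two agree to < 0.02 rad away from record
  edges.
* **Circular statistics**: mean direction `atan2(Σsin, Σcos)` mapped to
  (−π, π], resultant length `R = |Σe^{iφ}|/n`. A half-cycle offset sits
  at the branch point ±π (the same angle); consumers that compare
  against the expected half-cycle value should use the offset magnitude
  `|circ mean|`, which is what the acceptance script reports.

## Synthetic inputs

`fixture_trigger_train` emulates the external trigger source used in the
timing validation: n trigger times drawn uniformly (seeded) over the
feasible range with a minimum-gap constraint. It reproduces randomness of
trigger arrival, not electrical properties of a real line — no contact
bounce, noise or slew; debounce behaviour is therefore exercised by
explicitly constructed edge pairs, not by the fixture. Passing tests show
the *logic* is right (timing, gating, statistics on ideal rendered
signals); they cannot show anything about the physical device's intrinsic
latency (~1.7 ms trigger lag, ≈0.25 ms control-to-light delay), which
enters the emulation only as the constant `loop_latency_ms`.

## Problem sizes and tolerances

Validation-style computations use the study conditions directly: 10 s
bursts at 2 kHz sampling for the timing and phase runs, 5 s for the
frequency-fidelity trains — small enough to run in seconds, long enough
for 250–2000 pulses per estimate. Timing assertions use one sample period
of the analysing rate as the tolerance (0.5 ms at 2 kHz), the resolution
limit of the virtual DAQ, matching how the hardware characterisation was
bounded by its recording rate. The render-vs-oracle property compares the
vectorised renderer against a pure-Python per-sample evaluator on 100
seeded random parameter sets: digital lines must match exactly; analog
voltages to within one LSB (the two code paths may round a half-LSB
boundary differently in the last ulp of the trig functions).

## Known limitations

* The protocol's wire schema (key names, reply format) is canonical to
  this package; the physical firmware's exact key names may differ.
* Masks mirror their laser's parameters; fully independent mask-only
  parameter sets are not modelled.
* The loop latency is a constant, not a distribution; the emulator makes
  no real-time claims.
* Only linear calibration is supported (no polynomial/spline response
  models), by design.
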