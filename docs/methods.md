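# Methods

This note documents the models, conventions and numerical choices behind
`sleeppos`, and what the synthetic-data tests do and do not establish about
real recordings.

## Body frame and angle conventions

The device sits on the sternum with +X right→left, +Y toe→head, +Z
front→back, so gravity points along +Z when the wearer lies supine. Both
orientation angles are planar projections of the (filtered) acceleration
vector:

* sleep angle from `(X, Z)` with sign carrier `c = Z`: left 0°, supine
  90°, right ±180°, prone −90°;
* stand angle from `(Y, Z)` with `c = Z`: laying ±90°, upright ±180°,
  headstand 0°.

All angles live on `(-180°, 180°]`; −180 is normalised to +180, so a pure
right-lateral posture has one representation. `sign(0)` is taken as +1,
which places the Z = 0 boundary on the supine side. A zero in-plane vector
has no orientation; such samples are flagged invalid rather than guessed.
The formula normalises by `|a|`, so results are independent of
accelerometer scale (g vs m/s² only matters for magnitude diagnostics).

## Preprocessing

* **Resampling** — per-axis linear interpolation onto a uniform 10 Hz grid
  starting at t = 0, never extrapolating past the last raw sample. At
  10 Hz, with a 60 s median filter downstream, anything fancier than
  linear interpolation is indistinguishable.
* **Median filter** — a 60 s window (±30 s) around each sample, per axis.
  At the edges the window shrinks instead of padding: fabricating data at
  the boundary would bias the calibration window. Implemented as a
  centred rolling median (601 samples at 10 Hz).
* **Validity** — recordings shorter than 2 minutes are discarded
  (inclusive: exactly 120 s is kept). The 0.2 Hz "low-res" export takes
  the filtered sample nearest each 5 s grid point; it exists for
  visualisation, and the 60 s median already acts as its low-pass.

## Calibration

θ_initial corrects for mounting anatomy. Each recording's first 600 s are
assumed supine; the offset per angle is the wrapped difference between 90°
and the circular mean of the raw angle over that window, so the calibration
window's mean maps exactly to 90°. Sleep and stand offsets are separate.
If the recording is shorter than the window the offsets fall back to zero
with a warning, and both can be overridden (or auto-calibration disabled)
from the CLI — necessary for treated nights, where vibration ends the
opening supine bout early and the supine assumption fails.

## Discrete positions

Quadrants centred on the pure orientations, half-open toward the next
quadrant: left [−45, 45), supine [45, 135), right [135, 180] ∪ (−180,
−135), prone [−135, −45). Laying vs standing splits at |stand| = 135°, the
midpoint of the pure poses; |stand| < 45° (headstand-like) cannot be a
laying posture and is binned as standing with a log warning — on real data
it means the device is mounted wrong, on pipeline output it marks brief
transition artifacts where the median filter mixes postures. Within-label
angle statistics use the circular mean and circular SD
(σ = √(−2 ln R) in degrees): the right-lateral label straddles ±180°,
where arithmetic moments are meaningless. Position-shift counting drops
runs shorter than 30 s first; the median filter already suppresses shorter
excursions, and the dwell guard makes the count robust to boundary
chatter.

## Desaturation scoring

An event is a drop of ≥ 3.0 points (inclusive) below the local baseline,
reached within 120 s. The baseline is the running maximum of SpO2 over the
30 s preceding the onset of the fall — the published definition only says
"the baseline prior to the drop", and a short running maximum is standard
scoring practice; the window is configurable. The event runs from the last
departure from baseline to recovery within 1 point of baseline; its nadir
is the minimum over that run. Anchoring the event at the qualifying fall
and terminating at recovery makes back-to-back obstruction cycles score as
separate events without fragmenting a single long hypoxic episode.
Detection is invariant to adding a constant to the whole trace. A
pre-scored event CSV can be ingested in place of the detector when an
oximeter's native event list is available.

ODI = events per hour of sleep; laying time from the linked angle series
serves as sleep time when available, else total recording time. Severity
uses the AASM-derived bands applied to ODI with lower edges inclusive:
< 5 Healthy, 5–15 Mild, 15–30 Moderate, ≥ 30 Severe.

## Angle-resolved statistics

The grid is the 360 integer angles −180…179 (+180 is identified with
−180); every window is circular. Counting bins angles into 1° bins with
edges on the half-degree and convolves with a 15-bin boxcar — exact for
the half-open window [θ−7.5°, θ+7.5°) and it makes the conservation law
Σ_θ %Position(θ) = 15 × 100 hold to machine precision (each sample sits in
exactly 15 windows). The boundary case of a sample exactly 7.5° from an
integer angle has measure zero for continuous data.

* **%Position(θ)** — windowed share of valid laying samples. Standing time
  is excluded from the denominator: the statistic describes sleep
  positions, and standing is reported separately.
* **%DE(θ)** — windowed share of desaturation events, each event assigned
  the circular mean of the sleep angle over its span (a circular median is
  available as an option; for the short, unimodal spans of real events the
  two rarely differ).
* **local ODI(θ)** — windowed events over windowed hours
  (samples / 36,000 at 10 Hz), with the denominator floored at 10 min to
  suppress artifacts from barely visited angles; angles with no laying
  samples are masked rather than reported as zero. The profile is then
  smoothed with a circular 5-point moving average over valid cells; masked
  cells are excluded from their neighbours' averages, not treated as
  zeros. The clamp is applied before smoothing.
* **ratio %DE/%Position(θ)** — with the denominator floored at 1 % and
  masked where %Position is zero. A ratio above 2 means events are at
  least doubly over-represented at that angle.

## Vibration treatment

While the classified position is supine, pulses of 300 ms fire every 3 s,
the first immediately on entry (a grace option can delay it). Pulses are
suppressed while standing: an upright posture with a supine-like sleep
angle is not a sleep position. Total vibration time is 0.3 s × pulse
count, and a bout of length d receives ⌊d/3⌋ + 1 pulses.

## The synthetic-night generator

The generator is the test bed: it emulates the statistical structure the
pipeline assumes and records complete ground truth.

* **Posture** — a semi-Markov chain over the four positions; transition
  matrix defaults to uniform over the other three (no position is
  privileged a priori; cohort presets can override it), dwells log-normal
  with median 20 min and log-σ 0.6. Per bout the trunk angle is a
  von-Mises draw around the pure orientation (σ: left/right 12°, supine
  8°, prone 10° — supine postures vary less across people than lateral
  ones), plus a slow AR(1) wobble (σ 1°, ~30 s correlation). Untreated
  nights open with ≥ 12 min supine at exactly 90°, the posture the
  calibration step assumes the wearer was instructed to adopt. Two 120 s
  standing bouts are inserted by default (~0.8 % of the night).
* **Accelerometry** — the angle formula inverted: laying samples emit the
  unit vector `(cos φ, Z·cot ψ, sin φ)` normalised (φ the sleep angle, ψ
  the stand angle near ±90°); standing bouts emit −Y-dominant vectors with
  a small +Z component. Gaussian sensor noise (σ 0.02 g per axis) and
  uniform ±20 ms timestamp jitter emulate a phone's non-uniform ~10 Hz
  sensor. Optional mount roll/pitch rotations exercise the calibration.
* **SpO2** — 1 Hz, baseline 97 % with AR(1) noise (φ = 0.9, σ 0.3 %).
  Desaturations are trapezoidal dips: descent 20–90 s, plateau 0–20 s,
  recovery 10–60 s (uniform draws), depth 4–8 points. Onsets follow a
  modulated renewal process: after each episode plus a 5 s re-saturation
  guard, the gap to the next onset is exponential with mean
  3600/rate − (mean episode length), so the realized onset rate per hour
  spent in a label equals the planted per-label rate even when the trace
  cycles nearly continuously, and episodes never overlap — an obstruction
  cannot begin before the previous one has recovered. The default subject
  is mildly positional (supine 20/h, elsewhere 5/h).
* **Severity presets** — healthy/mild/moderate/severe models whose overall
  planted rates land in the four ODI bands (≈1.4, 8.5, 21, 38 h⁻¹ at the
  default posture mix). The moderate and severe presets draw episode
  durations from the short end of their supports: a mean ~100 s episode
  cannot physically sustain more than ~30 events per hour, and severe
  apnea cycles faster in reality.
* **Treatment** — during a treated supine bout the wearer responds with
  probability 0.9 per vibration minute and then leaves supine after a
  log-normal latency (median 10 s); the bout is truncated accordingly and
  the response logged.

**What the synthetic tests do not show.** The generator plants piecewise-
constant postures with clean trapezoidal desaturations; real recordings
contain motion artifacts, oximeter dropouts, gradual postural drift, and
apneas without desaturation. Passing the round-trip and recovery tests
demonstrates the pipeline's internal consistency and statistical
calibration under the stated noise model, not clinical accuracy.

## Numerical choices and test design

* Steady-state angle recovery is asserted at 2° RMS excluding ±35 s around
  posture changes: the 60 s median filter is designed to smooth straight
  through those transients, so they are not informative about steady-state
  accuracy.
* Band-averaged rate recovery (planted 40/h supine vs 5/h lateral, 20
  seeds × 8 h) averages the unsmoothed local ODI over cells whose
  denominator is unclamped (≥ 10 min occupancy); at clamped cells the
  statistic measures the artifact floor, not the rate. Agreement is
  required within 3 standard errors across seeds, and the supine-band
  %DE/%Position ratio must exceed 2 (expected ≈ 40/(5 + 35·p) ≈ 2.9 at a
  supine fraction p ≈ 0.25).
* Detector fidelity is scored by interval overlap between detected and
  planted events (sensitivity and precision ≥ 0.95 over 20 nights);
  nadir-time agreement within ±5 s is asserted on clean planted dips,
  where the nadir is unambiguous.
* Oracle equivalence (naive double-loop counting, naive sliding median) is
  checked to 1e-9 on ≤ 10 min random inputs; problem sizes throughout the
  suite (2–8 h nights, 10–20 seeds) were chosen to keep the full run in
  the low minutes while leaving the statistical assertions well-powered.
* All simulations derive from a single `numpy` `default_rng` seed;
  identical inputs give byte-identical outputs.

## Known limitations

* The supine-calibration assumption is unverifiable from the data alone;
  a wearer who never lies supine in the first 10 min silently
  mis-calibrates unless `--no-autocal` or manual offsets are used.
* Pure lateral postures (Z ≈ 0) leave the stand angle ill-conditioned;
  with realistic noise this only affects bouts within ~0.1° of exactly 0°
  or ±180°.
* The detector reports depth relative to a running-maximum baseline, which
  can overstate depth by the noise amplitude (~0.5 % at default noise).
* Apnea–hypopnea scoring from airflow is out of scope; ODI is known to
  underestimate AHI when events do not desaturate.
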