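# Methods

## Orientation estimation

The wrist exercise lasts a few seconds and starts from rest, so a full
Kalman filter is unnecessary; a single-gain complementary filter is
reproducible and sufficient. The device-to-world quaternion is
initialized by aligning the first accelerometer sample's gravity
direction with world −z, then propagated per sample as
q ← q ⊗ exp(ω̄ Δt) with the trapezoidal mean ω̄ of consecutive gyro
readings (device-frame rates, right multiplication). After each
propagation step the predicted gravity direction q⁻¹·(0,0,−1) is
compared with the measured accelerometer direction, and q is rotated
toward the measurement by the fraction `filter_gain` of the angular
error (spherical interpolation along the geodesic). Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `filter_gain` | 0.02 /sample | tilt-correction weight at 100 Hz; 0 = pure gyro |
| `still_window` | 1.0 s | calibration window defining the reference orientation |
| `still_gyro_threshold` | 0.05 rad/s | gyro magnitude counted as "still" |
| `still_fraction` | 0.8 | fraction of window that must be still |
| `movement_threshold` | 0.2 rad/s | gyro magnitude feeding the axis estimate |
| `min_duration` | 2.0 s | traces shorter than this are rejected |
| `max_dt_jitter` | 0.10 | median Δt deviation triggering linear resampling |
| g | 9.80665 m/s² | standard gravity |

Accelerometer corrections are skipped when ‖a‖ lies outside
[0.5 g, 1.5 g]; sub-0.5 g samples raise the `freefall_samples` flag.
The reference orientation is the sign-aligned normalized mean quaternion
over the still window; if less than 80 % of the window is still, the
first sample is used instead and `no_still_start` is flagged. Irregular
timestamps (median |Δt − 1/rate| > 10 % of 1/rate) are linearly
resampled to the nominal rate and flagged.

## ROM extraction

The flexion axis is the first right-singular vector of the gyro samples
above the movement threshold. The exercise is nearly planar, so this
principal direction is well conditioned; when the residual angular-rate
energy off that axis exceeds 30 % of the on-axis energy,
`off_axis_motion` is flagged. Each orientation is expressed relative to
the calibration reference and decomposed into swing and twist about the
axis; the twist angle, wrapped to (−180°, 180°], is the signed wrist
angle. The sign is fixed so the first excursion reaching half the peak
magnitude is positive (extension first, matching the exercise protocol);
extension = max angle, flexion = |min angle|, ROM = their sum, which
equals max − min of the series because the series starts at ≈ 0 in the
calibration window. If no sample exceeds the movement threshold the
result is a zero ROM with the ordinary flags. Flexion and extension are
exposed separately as well as summed, since either convention is usable
downstream.

## Synthetic traces

The ground-truth wrist angle is zero during the still window and then
follows raised-cosine (sin²) half-cycle pulses: each cycle rises to
+extension and dips to −flexion. The profile has continuous velocity,
zero at half-cycle boundaries, and an analytic derivative, which makes
it its own integration oracle. The gyro x-channel is that derivative;
small off-axis wobble (default 5 % of the peak rate, two incommensurate
sinusoids on y/z) and white noise (defaults 0.02 rad/s gyro,
0.3 m/s² accel) are added. The accelerometer is the gravity vector
rotated into the device frame by the internally integrated true
orientation, so gyro and accel are mutually consistent by construction.
Defaults: 100 Hz, 8 s, 2 cycles, 1 s calibration.

## Synthetic cohort

The generator emulates the record-level structure of a one-month remote
recruitment: 1170 downloads thinning by a consent probability (0.366),
an outside-window consent fraction (0.068) and an enrollment probability
(1.0), giving ≈ 399 enrolled; unstratified 1:1 randomization; and
discrete-time weekly dropout with per-arm geometric hazards. A single
constant hazard cannot produce both a steep initial drop and a shallow
tail, so the defaults (A 0.17, B 0.19 per week) were set to land the
week-12 retention near the low-teens with arm A slightly above arm B;
the curve's early shape is therefore smoother than a real cohort's.

Joint-map prevalences anchor the right wrist at 0.58 and left knee at
0.577 (the two highest) with a plausible large-to-small-joint gradient
elsewhere; severity given pain is {mild 0.6, moderate 0.3, severe 0.1},
so mild pain is most common. Task-completion probabilities (joint map
0.837, ROM task 0.714, medications question 0.972) model item-level
nonresponse, which is why analysis denominators differ between tables.
Demographics are drawn from configured marginals (80.7 % female, age
47.9 ± 12.28, etc.); they are fixture realism, not reproduction targets.

Ground-truth ROM per participant is Normal(μ(s), 15°) clipped to
[20°, 170°], with μ = 120/110/100/80° for week-1 right-wrist severity
s = 0/1/2/3, split roughly evenly between flexion and extension. Week-1
and week-12 sessions store the truth plus a trace seed; the raw trace is
regenerated on demand, so cohorts stay lightweight until the IMU
pipeline is run (`measure_rom_sessions`).

What the simulator does **not** model: missing-not-at-random response
patterns beyond dropout, within-participant symptom trajectories,
hand-tremor or grip artifacts in the traces, device heterogeneity, and
any app-UX effects. Passing tests therefore demonstrate algorithmic
correctness on physically plausible signals, not clinical validity.

## Analyses

Every printed ratio uses `pct()` — exact rational arithmetic with
half-up rounding at the requested precision (tables conventionally print
one decimal; funnel shares two). Retention uses the monotone
last-activity definition (retained at week w = any completed assessment
at week ≥ w), which guarantees a non-increasing curve; the alternative
"active that week" definition is also computable. Quantiles use linear
interpolation between order statistics. Arm columns always sum to the
total; each summary reports its own denominator.

## Verification sizes and numerical checks

Quaternion propagation is checked against brute-force rotation-matrix
product integration (identical trapezoidal increments) on 100 random
noiseless traces, agreeing to < 1e-3° per sample (in practice machine
precision). Parameter recovery runs a 6×6 grid of true angles in
{20..90}° × 20 noise seeds (720 traces); with default noise ≥ 90 % of
runs recover total ROM within 5°, and noiseless runs within 1°. The
inverse pain–ROM link is checked on five default cohorts (~400 enrolled,
~280 measured week-1 sessions each). Retention monotonicity and count
conservation run over 50 cohorts of ~40 enrolled. These sizes keep the
full suite a few minutes on one core while leaving the binomial checks
well powered.

## Known limitations

- The flexion-axis PCA assumes one dominant rotation plane; exercises
  with large swing components bias the twist angle (flagged, not fixed).
- Yaw (rotation about gravity) is unobservable to the accelerometer, so
  gyro bias about the vertical axis is uncorrected; the ROM is a
  relative angle over ~8 s, keeping the effect small.
- The complementary filter slightly attenuates the measured angle at
  large gains because the gravity correction drags the estimate toward
  the tilted-rest prediction during motion; the default gain 0.02
  balances drift correction against this attenuation.
- EQ-5D-5L index values require a country value set, which is not
  bundled; only profile and VAS are computed unless a table is supplied.
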