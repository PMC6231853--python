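# siteless

A toolkit for fully remote ("siteless") smartphone observational studies
of rheumatoid arthritis and similar joint conditions, in which
participants self-enroll through an app, answer weekly patient-reported
outcome (PRO) instruments, mark painful joints on a 55-joint body map,
and perform an objective wrist range-of-movement (ROM) exercise measured
by the phone's own gyroscope and accelerometer.

The package bundles four things:

1. **IMU wrist ROM pipeline** — converts a raw gyroscope + accelerometer
   trace of the wrist flexo-extension exercise into an objective ROM
   measurement. Orientation is propagated as a unit quaternion
   q<sub>k+1</sub> = q<sub>k</sub> ⊗ exp(½ ω̄<sub>k</sub> Δt), with tilt
   corrected toward the accelerometer gravity direction by a single-gain
   complementary filter (default gain 0.02 per sample at 100 Hz, applied
   only when ‖a‖ ∈ [0.5 g, 1.5 g]). The flexion axis **n** is the first
   principal component of the high-rate gyro samples; the signed wrist
   angle is the twist component of r<sub>k</sub> = q<sub>ref</sub>⁻¹ ⊗ q<sub>k</sub>
   about **n** (swing–twist decomposition, θ<sub>k</sub> = 2 atan2(⟨v<sub>k</sub>, n⟩, w<sub>k</sub>)),
   and ROM = max θ + |min θ| = extension + flexion, in degrees.
2. **Joint-pain map & PRO scoring** — the canonical 55-joint body map
   (27 bilateral pairs + neck) with 0–3 severities, per-joint prevalence,
   and standard scoring of HAQ-DI (8-category max with aids adjustment),
   FACIT-Fatigue (reverse-and-prorate, 0–52) and EQ-5D-5L (profile + VAS).
3. **Cohort analytics** — enrollment funnel, demographic and medication
   tables, per-arm retention curves (monotone last-activity definition),
   study-mode preference, and box statistics of measured ROM grouped by
   reported wrist-pain severity. Every "n/N (x%)" figure uses half-up
   rounding at the printed precision.
4. **Synthetic cohort generator** — a record-level simulator (enrollment
   funnel, 1:1 randomization, per-arm geometric weekly dropout, body-map
   prevalences, physically consistent IMU traces) whose ground-truth ROM
   decreases with reported wrist-pain severity, so the entire pipeline
   runs and is testable with no external data.

## Worked example

```bash
python examples/02_measure_wrist_rom.py
```

```
ground truth : flexion 60.0 deg, extension 75.0 deg, ROM 135.0 deg
measured     : flexion 60.6 deg, extension 74.5 deg, ROM 135.1 deg
error        : +0.06 deg
quality flags: none
```

A synthetic exercise trace (60° flexion / 75° extension, default sensor
noise) is pushed through the full pipeline; the total ROM is recovered
within a fraction of a degree, and no quality flags (no-still-start,
irregular sampling, free-fall, off-axis motion) were raised.

```bash
python examples/04_cohort_analytics.py
```

```
enrolled: 398 of 1170 downloads
measured 277 week-1 wrist ROM sessions

retention (% of enrolled): w1=100.0, w2=83.4, w4=55.5, w8=22.1, w12=9.8

measured ROM by reported right-wrist pain severity (week 1):
  severity 0: n=100  median  117.3 deg  IQR [ 108.5,  129.7]
  severity 1: n=101  median  109.0 deg  IQR [ 100.5,  117.9]
  severity 2: n= 35  median  100.4 deg  IQR [  87.3,  108.3]
  severity 3: n=  8  median   79.9 deg  IQR [  77.1,   86.6]
```

The median measured ROM falls monotonically from the no-pain to the
severe-pain group: the pipeline recovers, from raw simulated sensor
data, the inverse link between reported wrist pain and objective wrist
mobility that the generator encodes.

The other examples cover cohort simulation (`01`) and instrument scoring
(`03`); a thin CLI (`siteless simulate|rom|analyze|report`) wraps the
same functions for shell use.

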