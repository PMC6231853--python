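"""Synthetic cohort and IMU-trace generator with known ground truth.

Emulates the statistical structure of a fully remote, app-based
observational study of rheumatoid arthritis:

* an enrollment funnel (app downloads -> consent -> enrolled), with a
  fraction of consents falling outside the recruitment window;
* unstratified 1:1 randomization into arms A and B;
* discrete-time weekly dropout with a per-arm geometric hazard;
* per-joint pain prevalence and severity on the 55-joint body map, with
  wrists and knees most prevalent and mild pain most common;
* wrist flexo-extension IMU traces whose ground-truth ROM decreases with
  the participant's reported wrist-pain severity.

Everything is driven by one seed in :class:`CohortConfig`; identical
config implies identical cohort and traces.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .imu import G, IMUTrace, RomSettings, measure_wrist, quat_conjugate, \
    quat_from_rotvec, quat_multiply, quat_normalize, quat_rotate
from .joints import JOINT_CANON, JointPainMap
from .records import (Demographics, FunnelCounts, ParticipantRecord, ProPanel,
                      RomMeasurement, RomSession, WeeklyResponse)


def default_joint_prevalence() -> dict[str, float]:
    """Plausible per-joint any-pain prevalences: wrists and knees highest.

    The two anchor values (right wrist 0.58, left knee 0.577) match the
    most frequently cited locations; the remaining joints are free
    parameters set to a realistic gradient from large to small joints.
    """
    base = {
        "temporomandibular": 0.20, "shoulder": 0.45, "elbow": 0.38,
        "wrist": 0.56, "hip": 0.40, "knee": 0.56, "ankle": 0.46,
        "midfoot": 0.30,
        "mcp1": 0.42, "mcp2": 0.44, "mcp3": 0.42, "mcp4": 0.38, "mcp5": 0.35,
        "pip1": 0.40, "pip2": 0.42, "pip3": 0.40, "pip4": 0.36, "pip5": 0.33,
        "dip2": 0.30, "dip3": 0.30, "dip4": 0.28, "dip5": 0.26,
        "mtp1": 0.36, "mtp2": 0.33, "mtp3": 0.31, "mtp4": 0.30, "mtp5": 0.29,
    }
    prev = {}
    for joint in JOINT_CANON:
        if joint == "neck":
            prev[joint] = 0.44
        else:
            side, name = joint.split("_", 1)
            prev[joint] = base[name]
    prev["right_wrist"] = 0.58
    prev["left_knee"] = 0.577
    return prev


class TraceConfig(BaseModel):
    """Parameters of one synthetic wrist-exercise IMU trace."""

    sample_rate: float = Field(default=100.0, gt=0)     # Hz
    duration: float = Field(default=8.0, gt=0)          # s
    n_cycles: int = Field(default=2, ge=1)
    calibration_still: float = Field(default=1.0, gt=0)  # s
    gyro_noise_sd: float = Field(default=0.02, ge=0)    # rad/s
    accel_noise_sd: float = Field(default=0.3, ge=0)    # m/s^2
    off_axis_fraction: float = Field(default=0.05, ge=0)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "TraceConfig":
        if self.duration <= self.calibration_still:
            raise ValueError("duration must exceed calibration_still")
        return self


class CohortConfig(BaseModel):
    """All distributions, rates and the seed of the synthetic study.

    Funnel and demographic defaults mirror the marginal structure of a
    one-month remote recruitment of roughly 400 enrolled participants;
    they are configuration values, not targets the simulator guarantees.
    """

    n_downloads: int = Field(default=1170, ge=0)
    p_consent: float = Field(default=428 / 1170, ge=0, le=1)
    p_consent_outside_window: float = Field(default=29 / 428, ge=0, le=1)
    p_enroll_given_consent: float = Field(default=1.0, ge=0, le=1)
    p_group_A: float = Field(default=0.5, ge=0, le=1)
    weekly_dropout_hazard_A: float = Field(default=0.17, ge=0, le=1)
    weekly_dropout_hazard_B: float = Field(default=0.19, ge=0, le=1)
    n_weeks: int = Field(default=12, ge=1, le=12)

    joint_prevalence: dict[str, float] = Field(default_factory=default_joint_prevalence)
    severity_given_pain: dict[int, float] = Field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})

    rom_mean_by_wrist_severity: dict[int, float] = Field(
        default_factory=lambda: {0: 120.0, 1: 110.0, 2: 100.0, 3: 80.0})
    rom_sd: float = Field(default=15.0, gt=0)

    # task-completion probabilities (week-level item nonresponse)
    p_jointmap: float = Field(default=334 / 399, ge=0, le=1)
    p_rom_task: float = Field(default=285 / 399, ge=0, le=1)
    p_answer_medications: float = Field(default=388 / 399, ge=0, le=1)
    p_pro_panel: float = Field(default=0.9, ge=0, le=1)

    # demographics
    p_female: float = Field(default=0.807, ge=0, le=1)
    age_mean: float = 47.9
    age_sd: float = Field(default=12.28, gt=0)
    bmi_mean: float = 29.5
    bmi_sd: float = Field(default=7.29, gt=0)
    ethnicity_p: dict[str, float] = Field(default_factory=lambda: {
        "white": 0.807, "african_american": 0.040, "hispanic": 0.100,
        "asian": 0.028, "other": 0.025})
    education_p: dict[str, float] = Field(default_factory=lambda: {
        "middle_school": 0.013, "high_school": 0.216,
        "college": 0.506, "graduate_school": 0.265})
    smoking_p: dict[str, float] = Field(default_factory=lambda: {
        "current": 0.093, "previous": 0.303, "never": 0.604})
    disease_duration_p: dict[str, float] = Field(default_factory=lambda: {
        "<2": 0.306, "2-5": 0.228, "5-10": 0.228, ">10": 0.238})
    medication_p: dict[str, float] = Field(default_factory=lambda: {
        "painkillers": 0.438, "nsaids": 0.500, "corticosteroids": 0.302,
        "methotrexate": 0.399, "azathioprine": 0.013, "auranofin": 0.003,
        "chloroquine": 0.003, "hydroxychloroquine": 0.276,
        "leflunomide": 0.077, "mycophenolate": 0.008, "sulfasalazine": 0.075,
        "abatacept": 0.075, "adalimumab": 0.108, "certolizumab": 0.026,
        "etanercept": 0.088, "golimumab": 0.028, "infliximab": 0.041,
        "rituximab": 0.028, "tocilizumab": 0.034, "tofacitinib": 0.046,
        "others": 0.103})
    preference_p: dict[str, float] = Field(default_factory=lambda: {
        "app": 0.732, "clinic": 0.030, "both": 0.138, "none": 0.100})

    trace: TraceConfig = Field(default_factory=TraceConfig)
    seed: int = Field(default=0, ge=0)

    @field_validator("joint_prevalence")
    @classmethod
    def _check_prevalence(cls, prev: dict[str, float]) -> dict[str, float]:
        if set(prev) != set(JOINT_CANON):
            raise ValueError("joint_prevalence must have exactly the 55 canonical joints")
        for j, p in prev.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {j} out of [0, 1]: {p}")
        return prev

    @field_validator("severity_given_pain")
    @classmethod
    def _check_severity(cls, d: dict[int, float]) -> dict[int, float]:
        if set(d) != {1, 2, 3} or any(p < 0 for p in d.values()):
            raise ValueError("severity_given_pain needs non-negative weights for 1, 2, 3")
        total = sum(d.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("severity_given_pain must sum to 1")
        return d

    @field_validator("rom_mean_by_wrist_severity")
    @classmethod
    def _check_rom_means(cls, d: dict[int, float]) -> dict[int, float]:
        if set(d) != {0, 1, 2, 3}:
            raise ValueError("rom means needed for severities 0..3")
        if any(v <= 0 for v in d.values()):
            raise ValueError("rom means must be strictly positive")
        return d


# ---------------------------------------------------------------------------
# IMU trace synthesis

def _angle_profile(t: np.ndarray, flexion: float, extension: float,
                   tc: TraceConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth wrist angle theta(t) in degrees and its analytic
    derivative in rad/s.

    After the still calibration window the angle follows raised-cosine
    half-cycle pulses (sin^2 ramps): each cycle rises to +extension and
    then dips to -flexion, returning to neutral.  The profile has
    continuous velocity, zero at every half-cycle boundary, and is
    analytically integrable, so it doubles as the oracle for the
    orientation estimator.
    """
    active = np.clip(t - tc.calibration_still, 0.0, None)
    total = tc.duration - tc.calibration_still
    cycle = total / tc.n_cycles
    half = cycle / 2.0
    s = np.mod(active, cycle)
    in_motion = (t >= tc.calibration_still) & (t < tc.calibration_still + total)
    first = s < half

    theta = np.zeros_like(t)
    dtheta = np.zeros_like(t)     # deg/s

    m1 = in_motion & first
    theta[m1] = extension * np.sin(np.pi * s[m1] / half) ** 2
    dtheta[m1] = extension * (np.pi / half) * np.sin(2 * np.pi * s[m1] / half)

    m2 = in_motion & ~first
    s2 = s[m2] - half
    theta[m2] = -flexion * np.sin(np.pi * s2 / half) ** 2
    dtheta[m2] = -flexion * (np.pi / half) * np.sin(2 * np.pi * s2 / half)

    return theta, np.radians(dtheta)


def generate_rom_trace(true_flexion: float, true_extension: float,
                       tc: TraceConfig | None = None
                       ) -> tuple[IMUTrace, dict]:
    """Synthesize one wrist-exercise IMU trace with known ground truth.

    The wrist rotates about the device x-axis following the raised-cosine
    profile; a small smooth off-axis wobble (fraction of the peak angular
    rate) and white sensor noise are added.  The accelerometer reports
    the gravity vector rotated into the device frame (gravity along -z at
    calibration) plus noise.  Returns the trace and a ground-truth dict
    with the input angles and the per-sample true angle.
    """
    tc = tc or TraceConfig()
    if not (0 <= true_flexion < 180 and 0 <= true_extension < 180):
        raise ValueError("true angles must lie in [0, 180) degrees")

    rng = np.random.default_rng(tc.seed)
    dt = 1.0 / tc.sample_rate
    n = int(round(tc.duration * tc.sample_rate))
    t = np.arange(n) * dt

    theta_deg, omega_x = _angle_profile(t, true_flexion, true_extension, tc)

    omega = np.zeros((n, 3))
    omega[:, 0] = omega_x
    if tc.off_axis_fraction > 0:
        peak = np.max(np.abs(omega_x)) if np.any(omega_x) else 0.0
        active = (t >= tc.calibration_still).astype(float)
        tau = t - tc.calibration_still
        omega[:, 1] = tc.off_axis_fraction * peak * np.sin(2 * np.pi * 0.9 * tau) * active
        omega[:, 2] = tc.off_axis_fraction * peak * np.sin(2 * np.pi * 1.7 * tau + 1.0) * active

    # integrate the true angular velocity for a consistent accelerometer
    g_world = np.array([0.0, 0.0, -G])
    accel = np.empty((n, 3))
    q = np.array([1.0, 0.0, 0.0, 0.0])
    accel[0] = quat_rotate(quat_conjugate(q), g_world)
    for k in range(n - 1):
        w_avg = 0.5 * (omega[k] + omega[k + 1])
        q = quat_normalize(quat_multiply(q, quat_from_rotvec(w_avg * dt)))
        accel[k + 1] = quat_rotate(quat_conjugate(q), g_world)

    gyro = omega + rng.normal(0.0, tc.gyro_noise_sd, size=(n, 3))
    accel = accel + rng.normal(0.0, tc.accel_noise_sd, size=(n, 3))

    trace = IMUTrace(t=t, gyro=gyro, accel=accel, nominal_rate=tc.sample_rate)
    truth = {
        "flexion": float(true_flexion),
        "extension": float(true_extension),
        "rom": float(true_flexion + true_extension),
        "angle_deg": theta_deg,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# cohort synthesis

def _categorical(rng: np.random.Generator, p: dict) -> object:
    keys = list(p)
    weights = np.asarray([p[k] for k in keys], dtype=float)
    weights = weights / weights.sum()
    return keys[rng.choice(len(keys), p=weights)]


def _sample_joint_map(rng: np.random.Generator, cfg: CohortConfig,
                      pid: str, week: int) -> JointPainMap:
    sev_levels = np.array([1, 2, 3])
    sev_p = np.array([cfg.severity_given_pain[s] for s in (1, 2, 3)])
    sev_p = sev_p / sev_p.sum()
    scores: dict[str, int] = {}
    for joint in JOINT_CANON:
        if rng.random() < cfg.joint_prevalence[joint]:
            scores[joint] = int(rng.choice(sev_levels, p=sev_p))
    return JointPainMap(participant_id=pid, week=week, scores=scores)


def _sample_demographics(rng: np.random.Generator, cfg: CohortConfig) -> Demographics:
    return Demographics(
        sex="female" if rng.random() < cfg.p_female else "male",
        age=float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 21, 95)),
        ethnicity=_categorical(rng, cfg.ethnicity_p),
        bmi=float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 15, 70)),
        education=_categorical(rng, cfg.education_p),
        smoking=_categorical(rng, cfg.smoking_p),
        disease_duration=_categorical(rng, cfg.disease_duration_p),
    )


def _sample_pro_panel(rng: np.random.Generator, week: int) -> ProPanel:
    dims = [int(x) for x in rng.choice([1, 2, 3, 4, 5],
                                       p=[0.25, 0.35, 0.25, 0.10, 0.05], size=5)]
    haq = [int(x) for x in rng.choice([0, 1, 2, 3],
                                      p=[0.45, 0.30, 0.17, 0.08], size=20)]
    aids = [bool(rng.random() < 0.15) for _ in range(8)]
    facit = [int(x) for x in rng.choice([0, 1, 2, 3, 4],
                                        p=[0.15, 0.2, 0.3, 0.2, 0.15], size=13)]
    return ProPanel(week=week, eq5d_dimensions=dims,
                    eq5d_vas=int(np.clip(rng.normal(65, 20), 0, 100)),
                    haqdi_items=haq, haqdi_aids=aids, facitf_items=facit)


def _sample_rom_session(rng: np.random.Generator, cfg: CohortConfig,
                        week: int, wrist_severity: int) -> RomSession:
    mean = cfg.rom_mean_by_wrist_severity[wrist_severity]
    rom = float(np.clip(rng.normal(mean, cfg.rom_sd), 20.0, 170.0))
    ext_share = rng.uniform(0.45, 0.55)
    extension = rom * ext_share
    flexion = rom - extension
    return RomSession(week=week, side="right",
                      true_flexion=flexion, true_extension=extension,
                      trace_seed=int(rng.integers(0, 2**31 - 1)))


def generate_cohort(config: CohortConfig | None = None
                    ) -> tuple[list[ParticipantRecord], FunnelCounts]:
    """Draw a full synthetic cohort: funnel, randomization, weekly
    responses with dropout, joint maps, PRO panels and ROM sessions.

    Deterministic under a fixed config (including seed).  ROM sessions
    carry ground-truth angles and a trace seed; the raw traces themselves
    are produced on demand by :func:`generate_rom_trace` or in bulk by
    :func:`measure_rom_sessions`.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    consented = int(rng.binomial(cfg.n_downloads, cfg.p_consent))
    outside = int(rng.binomial(consented, cfg.p_consent_outside_window))
    eligible = consented - outside
    enrolled = int(rng.binomial(eligible, cfg.p_enroll_given_consent))
    funnel = FunnelCounts(downloads=cfg.n_downloads, consented=consented,
                          consented_outside_window=outside, enrolled=enrolled)

    hazards = {"A": cfg.weekly_dropout_hazard_A, "B": cfg.weekly_dropout_hazard_B}
    records: list[ParticipantRecord] = []
    for i in range(enrolled):
        pid = f"p{i:04d}"
        group = "A" if rng.random() < cfg.p_group_A else "B"

        last_active = 1
        for week in range(2, cfg.n_weeks + 1):
            if rng.random() < hazards[group]:
                break
            last_active = week

        demographics = _sample_demographics(rng, cfg)
        medications: Optional[list[str]] = None
        if rng.random() < cfg.p_answer_medications:
            medications = [m for m, p in cfg.medication_p.items()
                           if rng.random() < p]
        preference = (_categorical(rng, cfg.preference_p)
                      if rng.random() < 0.98 else "missing")

        latent = rng.uniform()   # participant-level symptom burden
        weekly = []
        for week in range(1, last_active + 1):
            pain = int(np.clip(round(rng.normal(3 + 5 * latent, 1.5)), 0, 10))
            weekly.append(WeeklyResponse(
                week=week,
                global_assessment=int(np.clip(rng.normal(30 + 50 * latent, 12), 0, 100)),
                pain=pain,
                stiffness=int(np.clip(round(rng.normal(pain, 1.5)), 0, 10)),
                mood=int(np.clip(round(rng.normal(7 - 3 * latent, 1.5)), 0, 10)),
                satisfaction=int(np.clip(round(rng.normal(7, 2)), 0, 10)),
            ))

        joint_maps = []
        for week in (1, 8):
            if week <= last_active and rng.random() < cfg.p_jointmap:
                joint_maps.append(_sample_joint_map(rng, cfg, pid, week))

        pro_panels = [
            _sample_pro_panel(rng, week)
            for week in (1, 4, 8, 12)
            if week <= last_active and rng.random() < cfg.p_pro_panel
        ]

        week1_map = next((m for m in joint_maps if m.week == 1), None)
        wrist_sev = week1_map.severity("right_wrist") if week1_map else \
            int(rng.choice([0, 1, 2, 3], p=[0.42, 0.35, 0.17, 0.06]))
        rom_sessions = [
            _sample_rom_session(rng, cfg, week, wrist_sev)
            for week in (1, cfg.n_weeks)
            if week <= last_active and rng.random() < cfg.p_rom_task
        ]

        records.append(ParticipantRecord(
            id=pid, group=group, demographics=demographics,
            medications=medications, preference=preference,
            weekly=weekly, pro_panels=pro_panels, joint_maps=joint_maps,
            rom_sessions=rom_sessions, last_active_week=last_active))

    return records, funnel


def measure_rom_sessions(records: list[ParticipantRecord],
                         trace_config: TraceConfig | None = None,
                         settings: RomSettings | None = None,
                         weeks: tuple[int, ...] | None = None) -> int:
    """Run the full IMU pipeline over every (selected) ROM session.

    Regenerates each session's raw trace from its stored seed, measures
    it with :func:`siteless.imu.measure_wrist`, and attaches the result
    to the record in place.  Returns the number of sessions measured.
    """
    base = trace_config or TraceConfig()
    settings = settings or RomSettings()
    n_measured = 0
    for rec in records:
        for session in rec.rom_sessions:
            if weeks is not None and session.week not in weeks:
                continue
            tc = base.model_copy(update={"seed": session.trace_seed})
            trace, _ = generate_rom_trace(session.true_flexion,
                                          session.true_extension, tc)
            result = measure_wrist(trace, settings)
            session.measured = RomMeasurement(
                flexion=result.flexion, extension=result.extension,
                rom=result.rom, quality_flags=sorted(result.quality_flags))
            n_measured += 1
    return n_measured
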