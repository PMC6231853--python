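"""Wrist range-of-movement extraction from smartphone inertial sensors.

During the wrist exercise the participant rests the forearm on a table
edge, holds the phone, and flexes/extends the wrist to its maximum range.
The phone's gyroscope (rad/s) and accelerometer (m/s^2, gravity included)
are recorded; the flexo-extension range of movement (ROM) is the angular
span of the phone's orientation about the flexion axis, relative to the
orientation during an initial still calibration window.

Pipeline:

1. :func:`estimate_orientation` - propagate a unit quaternion by gyro
   integration, correcting tilt toward the accelerometer gravity
   direction with a single-gain complementary filter.
2. :func:`extract_rom` - find the flexion axis as the principal direction
   of the high-rate gyro samples, take the twist component (swing-twist
   decomposition) of each orientation relative to the calibration
   reference about that axis, and read flexion/extension off the signed
   angle series.

Conventions: device frame, SI inputs; gravity lies along device -z when
the phone is held flat at calibration; extension is the positive angle
direction (the first excursion of the exercise); outputs in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G = 9.80665  # standard gravity, m/s^2

#: Quality flags a ROM measurement can carry.
QUALITY_FLAGS = frozenset(
    {"no_still_start", "irregular_sampling", "off_axis_motion",
     "freefall_samples", "too_short"}
)


class TraceFormatError(ValueError):
    """Malformed IMU trace (bad columns, non-monotone timestamps...)."""


class TraceTooShortError(ValueError):
    """Trace shorter than the minimum usable duration."""


@dataclass(frozen=True)
class IMUTrace:
    """Uniformly-sampled (nominally) 3-axis gyro + accelerometer trace.

    t in seconds, gyro in rad/s, accel in m/s^2, all in the device frame;
    accel includes gravity.
    """

    t: np.ndarray          # (n,)
    gyro: np.ndarray       # (n, 3)
    accel: np.ndarray      # (n, 3)
    nominal_rate: float    # Hz

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        gyro = np.asarray(self.gyro, dtype=float)
        accel = np.asarray(self.accel, dtype=float)
        if t.ndim != 1 or gyro.shape != (t.size, 3) or accel.shape != (t.size, 3):
            raise TraceFormatError("trace arrays must be t:(n,), gyro/accel:(n,3)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(gyro))
                and np.all(np.isfinite(accel))):
            raise TraceFormatError("trace contains non-finite values")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise TraceFormatError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "gyro", gyro)
        object.__setattr__(self, "accel", accel)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


@dataclass
class OrientationSeries:
    """Per-sample device-to-world unit quaternions (w, x, y, z) plus the
    calibration reference orientation and the (possibly resampled) gyro."""

    t: np.ndarray               # (n,)
    quats: np.ndarray           # (n, 4), unit norm
    reference: np.ndarray       # (4,), unit norm
    gyro: np.ndarray            # (n, 3) gyro aligned with t (post-resampling)
    quality_flags: set[str] = field(default_factory=set)


@dataclass
class ROMResult:
    """Wrist flexo-extension measurement, degrees."""

    flexion: float
    extension: float
    rom: float
    angle_series: np.ndarray        # (n,) signed degrees; extension positive
    flexion_axis: np.ndarray        # (3,) unit vector, device frame
    quality_flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        """JSON-serializable summary (angle series rounded to 3 decimals)."""
        return {
            "flexion_deg": round(self.flexion, 3),
            "extension_deg": round(self.extension, 3),
            "rom_deg": round(self.rom, 3),
            "flexion_axis": [round(float(x), 6) for x in self.flexion_axis],
            "quality_flags": sorted(self.quality_flags),
            "angle_series_deg": [round(float(a), 3) for a in self.angle_series],
        }


@dataclass(frozen=True)
class RomSettings:
    """Tunable parameters of the ROM pipeline.

    filter_gain: per-sample complementary-filter weight in [0, 1]; 0 means
    pure gyro integration.  still_window: length (s) of the calibration
    window at the start of the trace.  still_gyro_threshold: gyro
    magnitude (rad/s) below which a sample counts as still.
    movement_threshold: gyro magnitude (rad/s) above which a sample
    contributes to the flexion-axis estimate.
    """

    filter_gain: float = 0.02
    still_window: float = 1.0
    still_gyro_threshold: float = 0.05
    still_fraction: float = 0.8
    movement_threshold: float = 0.2
    min_duration: float = 2.0
    max_dt_jitter: float = 0.10     # fraction of 1/rate triggering resampling
    g: float = G

    def __post_init__(self) -> None:
        if not 0.0 <= self.filter_gain <= 1.0:
            raise ValueError("filter_gain must be in [0, 1]")
        if self.still_window <= 0 or self.min_duration <= 0:
            raise ValueError("windows must be positive")


# ---------------------------------------------------------------------------
# quaternion primitives (scalar-first, w x y z)

def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("zero quaternion")
    return q / n


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation vector (axis * angle, radians)."""
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        # first-order expansion, renormalized
        q = np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]])
        return quat_normalize(q)
    axis = v / angle
    half = 0.5 * angle
    s = np.sin(half)
    return np.array([np.cos(half), s * axis[0], s * axis[1], s * axis[2]])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector v by quaternion q (device->world if q is so defined)."""
    qv = np.array([0.0, v[0], v[1], v[2]])
    return quat_multiply(quat_multiply(q, qv), quat_conjugate(q))[1:]


def mean_quaternion(quats: np.ndarray) -> np.ndarray:
    """Sign-aligned component mean, renormalized.  Adequate for a tight
    cluster of orientations such as a still calibration window."""
    quats = np.asarray(quats, dtype=float)
    ref = quats[0]
    signs = np.where(quats @ ref < 0, -1.0, 1.0)
    return quat_normalize((quats * signs[:, None]).mean(axis=0))


def twist_angle(q_rel: np.ndarray, axis: np.ndarray) -> float:
    """Signed twist angle (radians, wrapped to [-pi, pi]) of a relative
    rotation about a unit axis (swing-twist decomposition)."""
    w = q_rel[0]
    proj = float(q_rel[1:] @ axis)
    angle = 2.0 * np.arctan2(proj, w)
    # map to [-pi, pi]
    return float((angle + np.pi) % (2.0 * np.pi) - np.pi)


# ---------------------------------------------------------------------------

def _resample_if_irregular(trace: IMUTrace, settings: RomSettings,
                           flags: set[str]) -> IMUTrace:
    dt = np.diff(trace.t)
    target = 1.0 / trace.nominal_rate
    if np.median(np.abs(dt - target)) <= settings.max_dt_jitter * target:
        return trace
    flags.add("irregular_sampling")
    n = int(np.floor(trace.duration / target)) + 1
    t_new = trace.t[0] + np.arange(n) * target
    gyro = np.column_stack(
        [np.interp(t_new, trace.t, trace.gyro[:, i]) for i in range(3)])
    accel = np.column_stack(
        [np.interp(t_new, trace.t, trace.accel[:, i]) for i in range(3)])
    return IMUTrace(t=t_new, gyro=gyro, accel=accel,
                    nominal_rate=trace.nominal_rate)


def _initial_orientation(accel0: np.ndarray, g: float) -> np.ndarray:
    """Device-to-world quaternion aligning the measured gravity direction
    with world -z; identity when the accelerometer is unusable."""
    norm = np.linalg.norm(accel0)
    if not 0.5 * g <= norm <= 1.5 * g:
        return np.array([1.0, 0.0, 0.0, 0.0])
    v = accel0 / norm                     # gravity direction, device frame
    u = np.array([0.0, 0.0, -1.0])        # gravity direction, world frame
    # rotation R with R v = u
    c = float(v @ u)
    axis = np.cross(v, u)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        return np.array([0.0, 1.0, 0.0, 0.0])   # antipodal: 180 deg about x
    angle = np.arctan2(s, c)
    return quat_from_rotvec(axis / s * angle)


def estimate_orientation(trace: IMUTrace,
                         settings: RomSettings | None = None) -> OrientationSeries:
    """Estimate per-sample orientation with a gyro+accelerometer
    complementary filter.

    The quaternion is propagated by trapezoidal gyro integration; at each
    step the tilt is nudged toward the accelerometer gravity direction by
    the fraction ``settings.filter_gain`` of the observed tilt error
    (spherical interpolation toward the measurement).  Accelerometer
    corrections are applied only when the accel magnitude is within
    [0.5 g, 1.5 g]; samples below 0.5 g are flagged as free fall.

    The reference orientation is the normalized mean quaternion over the
    initial still window; if the gyro is not quiet there, the flag
    ``no_still_start`` is set and the first sample serves as reference.
    """
    settings = settings or RomSettings()
    flags: set[str] = set()

    if trace.t.size < 2 or trace.duration < settings.min_duration:
        raise TraceTooShortError(
            f"trace of {trace.duration:.2f} s is shorter than the "
            f"{settings.min_duration:.1f} s minimum")

    trace = _resample_if_irregular(trace, settings, flags)

    t, gyro, accel = trace.t, trace.gyro, trace.accel
    n = t.size
    g = settings.g
    gain = settings.filter_gain

    accel_norm = np.linalg.norm(accel, axis=1)
    usable = (accel_norm >= 0.5 * g) & (accel_norm <= 1.5 * g)
    if np.any(accel_norm < 0.5 * g):
        flags.add("freefall_samples")

    u_world = np.array([0.0, 0.0, -1.0])

    quats = np.empty((n, 4))
    quats[0] = _initial_orientation(accel[0], g)
    q = quats[0]
    for k in range(n - 1):
        dt = t[k + 1] - t[k]
        omega = 0.5 * (gyro[k] + gyro[k + 1])   # trapezoidal
        q = quat_multiply(q, quat_from_rotvec(omega * dt))
        if gain > 0.0 and usable[k + 1]:
            v_meas = accel[k + 1] / accel_norm[k + 1]
            v_pred = quat_rotate(quat_conjugate(q), u_world)
            axis = np.cross(v_meas, v_pred)
            s = np.linalg.norm(axis)
            c = float(v_meas @ v_pred)
            if s > 1e-12:
                err = np.arctan2(s, c)
                q = quat_multiply(q, quat_from_rotvec(axis / s * (gain * err)))
        q = quat_normalize(q)
        quats[k + 1] = q

    # calibration reference
    still_mask = t - t[0] <= settings.still_window
    win_gyro = np.linalg.norm(gyro[still_mask], axis=1)
    quiet = np.mean(win_gyro < settings.still_gyro_threshold)
    if quiet >= settings.still_fraction:
        reference = mean_quaternion(quats[still_mask])
    else:
        flags.add("no_still_start")
        reference = quats[0].copy()

    return OrientationSeries(t=t, quats=quats, reference=reference,
                             gyro=gyro, quality_flags=flags)


def extract_rom(orientations: OrientationSeries,
                settings: RomSettings | None = None) -> ROMResult:
    """Read the flexo-extension ROM off an orientation series.

    The flexion axis is the first principal component of gyro samples
    whose magnitude exceeds the movement threshold; the signed angle per
    sample is the twist of reference^-1 * orientation about that axis.
    The sign is fixed so that the first large excursion is positive
    (extension first, by the exercise protocol).  Extension is the maximum
    positive angle, flexion the magnitude of the most negative one.
    """
    settings = settings or RomSettings()
    flags = set(orientations.quality_flags)

    gyro = orientations.gyro
    mags = np.linalg.norm(gyro, axis=1)
    moving = mags > settings.movement_threshold

    if not np.any(moving):
        n = orientations.t.size
        return ROMResult(flexion=0.0, extension=0.0, rom=0.0,
                         angle_series=np.zeros(n),
                         flexion_axis=np.array([1.0, 0.0, 0.0]),
                         quality_flags=flags)

    active = gyro[moving]
    # principal direction of angular velocity = flexion axis
    _, svals, vt = np.linalg.svd(active, full_matrices=False)
    axis = vt[0]
    # off-axis energy relative to on-axis energy
    if svals[0] > 0 and np.hypot(svals[1], svals[2]) > 0.3 * svals[0]:
        flags.add("off_axis_motion")

    ref_conj = quat_conjugate(orientations.reference)
    n = orientations.t.size
    angles = np.empty(n)
    for k in range(n):
        q_rel = quat_multiply(ref_conj, orientations.quats[k])
        angles[k] = twist_angle(quat_normalize(q_rel), axis)
    angles = np.degrees(angles)

    # sign convention: first large excursion positive
    peak = np.max(np.abs(angles))
    if peak > 0:
        first_big = np.argmax(np.abs(angles) >= 0.5 * peak)
        if angles[first_big] < 0:
            angles = -angles
            axis = -axis

    extension = float(max(np.max(angles), 0.0))
    flexion = float(max(-np.min(angles), 0.0))
    return ROMResult(flexion=flexion, extension=extension,
                     rom=flexion + extension, angle_series=angles,
                     flexion_axis=axis, quality_flags=flags)


def measure_wrist(trace: IMUTrace,
                  settings: RomSettings | None = None) -> ROMResult:
    """Full pipeline: orientation estimation followed by ROM extraction."""
    settings = settings or RomSettings()
    return extract_rom(estimate_orientation(trace, settings), settings)
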