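"""Commanded yaw angular-velocity motion profiles.

A stimulus is one period of an acceleration waveform whose second half is
the exact negative mirror of the first, so the chair accelerates to a peak
yaw velocity and brakes back to standstill.  Three acceleration shapes are
supported -- triangular, sinusoidal and trapezoidal -- named after the shape
of the *acceleration* trace; the corresponding velocity traces are all
unipolar bumps that start and end at zero.  Velocity is computed from the
closed-form integral of the acceleration so that the peak-velocity scaling
is exact, not a property of the sample grid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

SHAPES = ("triangular", "sinusoidal", "trapezoidal")

#: Minimum number of samples per period accepted by the generator.
MIN_SAMPLES_PER_PERIOD = 20

PROFILE_CSV_COLUMNS = ("time_s", "velocity_deg_s")


@dataclass(frozen=True)
class ProfileSpec:
    """Specification of a commanded single-cycle motion stimulus.

    Parameters
    ----------
    shape:
        Acceleration shape, one of ``triangular``, ``sinusoidal``,
        ``trapezoidal``.
    period_T:
        Stimulus period in seconds (total duration of the motion).
    peak_velocity:
        Peak yaw velocity in deg/s (positive; sign conventions are applied
        per trial, not here).
    sample_rate:
        Sampling rate of the generated time grid in Hz.
    trapezoid_rise_fraction:
        Rise time of the trapezoidal acceleration as a fraction of the
        period; the default 0.1 gives dt = T/10.
    """

    shape: str
    period_T: float
    peak_velocity: float
    sample_rate: float = 1000.0
    trapezoid_rise_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if not self.period_T > 0:
            raise ValueError("period_T must be positive")
        if not self.peak_velocity > 0:
            raise ValueError("peak_velocity must be positive")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not 0.0 < self.trapezoid_rise_fraction < 0.25:
            raise ValueError("trapezoid_rise_fraction must lie in (0, 0.25)")
        if self.period_T * self.sample_rate < MIN_SAMPLES_PER_PERIOD:
            raise ValueError(
                "under-resolved profile: period_T * sample_rate = "
                f"{self.period_T * self.sample_rate:.1f} < {MIN_SAMPLES_PER_PERIOD}"
            )


@dataclass
class MotionProfile:
    """A uniformly sampled angular-velocity time series (deg/s)."""

    t: np.ndarray
    velocity: np.ndarray
    meta: Optional[object] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.velocity.shape:
            raise ValueError("t and velocity must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("profile needs at least two samples")
        _check_uniform_grid(self.t)

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def peak_velocity(self) -> float:
        return float(np.max(np.abs(self.velocity)))

    def scaled(self, factor: float) -> "MotionProfile":
        """Profile with every velocity sample multiplied by ``factor``."""
        return MotionProfile(self.t.copy(), self.velocity * factor, meta=self.meta)


def _check_uniform_grid(t: np.ndarray, rel_tol: float = 1e-6) -> float:
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError("time grid must be strictly increasing")
    step = steps.mean()
    if np.max(np.abs(steps - step)) > rel_tol * step:
        raise ValueError("time grid is not uniform within tolerance")
    return float(step)


def peak_acceleration_for(
    shape: str,
    period_T: float,
    peak_velocity: float,
    rise_fraction: float = 0.1,
) -> float:
    """Peak acceleration (deg/s^2) reaching ``peak_velocity`` in half a period.

    The velocity attained at T/2 equals the area under the first half of the
    acceleration trace: A*T/4 (triangle), A*T/pi (sine half-cycle),
    A*(T/2 - dt) (trapezoid with rise dt = rise_fraction*T).
    """
    if period_T <= 0:
        raise ValueError("period_T must be positive")
    if shape == "sinusoidal":
        return np.pi * peak_velocity / period_T
    if shape == "triangular":
        return 4.0 * peak_velocity / period_T
    if shape == "trapezoidal":
        if not 0.0 < rise_fraction < 0.25:
            raise ValueError("rise_fraction must lie in (0, 0.25)")
        return peak_velocity / ((0.5 - rise_fraction) * period_T)
    raise ValueError(f"unknown shape {shape!r}")


def _velocity_half(shape: str, x: np.ndarray, T: float, A: float, rise: float) -> np.ndarray:
    """Closed-form velocity gained over the accelerating half, x in [0, T/2]."""
    if shape == "sinusoidal":
        # a(t) = A sin(2 pi t / T) over the full period already integrates to
        # the raised cosine; the half-wave view is not needed.
        raise RuntimeError("sinusoidal handled separately")
    if shape == "triangular":
        q = T / 4.0
        # second segment: a = A (T/2 - x)/q  ->  v = v(q) + A[(T/2)(x-q) - (x^2-q^2)/2]/q
        seg2 = A * q / 2.0 + A * ((T / 2.0) * (x - q) - (x**2 - q**2) / 2.0) / q
        return np.where(x <= q, A * x**2 / (2.0 * q), seg2)
    if shape == "trapezoidal":
        dt = rise * T
        half = T / 2.0
        v_lin = A * dt / 2.0 + A * (x - dt)
        v_peak = A * (half - dt)
        return np.where(
            x < dt,
            A * x**2 / (2.0 * dt),
            np.where(x <= half - dt, v_lin, v_peak - A * (half - x) ** 2 / (2.0 * dt)),
        )
    raise ValueError(f"unknown shape {shape!r}")


def _acceleration(shape: str, t: np.ndarray, T: float, A: float, rise: float) -> np.ndarray:
    """Closed-form acceleration over one period (antisymmetric about T/2)."""
    if shape == "sinusoidal":
        return A * np.sin(2.0 * np.pi * t / T)
    half = T / 2.0
    x = np.where(t <= half, t, t - half)
    sign = np.where(t <= half, 1.0, -1.0)
    if shape == "triangular":
        q = T / 4.0
        a_half = np.where(x <= q, A * x / q, A * (half - x) / q)
    else:  # trapezoidal
        dt = rise * T
        a_half = np.where(x < dt, A * x / dt, np.where(x <= half - dt, A, A * (half - x) / dt))
    return sign * a_half


def generate_profile(spec: ProfileSpec) -> MotionProfile:
    """Generate the commanded velocity profile for ``spec``.

    The velocity is the exact closed-form integral of the acceleration,
    scaled so that ``max(velocity) == spec.peak_velocity``; it starts at 0
    and returns to 0 at t = T because the acceleration is odd-symmetric
    about T/2.
    """
    T = spec.period_T
    fs = spec.sample_rate
    n = int(round(T * fs))
    t = np.arange(n + 1) / fs
    A = peak_acceleration_for(spec.shape, T, spec.peak_velocity, spec.trapezoid_rise_fraction)
    if spec.shape == "sinusoidal":
        v = A * T / (2.0 * np.pi) * (1.0 - np.cos(2.0 * np.pi * t / T))
    else:
        half = T / 2.0
        x = np.minimum(t, half)
        v_rise = _velocity_half(spec.shape, x, T, A, spec.trapezoid_rise_fraction)
        # velocity is symmetric about T/2 (braking mirrors the acceleration)
        v_fall = _velocity_half(
            spec.shape, np.maximum(T - t, 0.0), T, A, spec.trapezoid_rise_fraction
        )
        v = np.where(t <= half, v_rise, v_fall)
    # guard against last-digit rounding so the contract max == peak holds
    v = v * (spec.peak_velocity / np.max(v))
    v[0] = 0.0
    v[-1] = 0.0 if abs(v[-1]) <= 1e-9 * spec.peak_velocity else v[-1]
    return MotionProfile(t, v, meta=spec)


def acceleration_profile(spec: ProfileSpec) -> np.ndarray:
    """Closed-form acceleration samples matching :func:`generate_profile`'s grid."""
    T, fs = spec.period_T, spec.sample_rate
    t = np.arange(int(round(T * fs)) + 1) / fs
    A = peak_acceleration_for(spec.shape, T, spec.peak_velocity, spec.trapezoid_rise_fraction)
    return _acceleration(spec.shape, t, T, A, spec.trapezoid_rise_fraction)


def write_profile_csv(profile: MotionProfile, path, header_comment: Optional[str] = None) -> None:
    """Write a profile as a two-column CSV ``time_s,velocity_deg_s``."""
    df = pd.DataFrame({"time_s": profile.t, "velocity_deg_s": profile.velocity})
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_profile_csv(path) -> MotionProfile:
    """Read a two-column profile CSV written by :func:`write_profile_csv`.

    Requires the ``time_s,velocity_deg_s`` header and a uniform time grid
    (relative step tolerance 1e-6); leading ``#`` comment lines are ignored.
    """
    df = pd.read_csv(path, comment="#")
    cols = tuple(df.columns[:2])
    if len(df.columns) < 2 or cols != PROFILE_CSV_COLUMNS:
        raise ValueError(
            f"profile CSV must have header {','.join(PROFILE_CSV_COLUMNS)}; got {list(df.columns)}"
        )
    return MotionProfile(df["time_s"].to_numpy(), df["velocity_deg_s"].to_numpy(), meta=str(path))


def resample(profile: MotionProfile, new_rate: float) -> MotionProfile:
    """Linearly interpolate a profile onto a new uniform grid (endpoints kept)."""
    if not new_rate > 0:
        raise ValueError("new_rate must be positive")
    duration = profile.duration
    n = int(round(duration * new_rate))
    if n < MIN_SAMPLES_PER_PERIOD:
        raise ValueError("under-resolved grid after resampling")
    t_new = profile.t[0] + np.arange(n + 1) * (duration / n)
    v_new = np.interp(t_new, profile.t, profile.velocity)
    return MotionProfile(t_new, v_new, meta=profile.meta)
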