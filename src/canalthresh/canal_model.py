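"""Transient firing-rate response of a semicircular-canal afferent.

The afferent firing rate (in arbitrary units, linear in the true rate) is
modelled as the output of the linear system

    H(s) = K * s * (1 + tauN*s) / ((1 + tau1*s) * (1 + tau2*s))

driven by head angular velocity in deg/s.  The two poles come from the
torsion-pendulum mechanics of the cupula/endolymph (slow time constant tau1,
fast time constant tau2), the numerator ``s`` converts velocity input to the
acceleration the cupula senses, and the lead term (1 + tauN*s) adds
sensitivity to the rate of cupular displacement.  K is a scale factor in
s^2/deg that makes the output dimensionless; it trades off exactly against
the firing-rate noise level, which is therefore fixed to 1 by convention.

Simulation is done in the time domain (bilinear-transform discretization of
H at the profile's sample rate, zero initial conditions), so the *transient*
of the response to a single-cycle stimulus is captured -- the peak transient
response can exceed the steady-state amplitude substantially, which is the
point of operating on time series rather than on the steady-state gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .profiles import MotionProfile


@dataclass(frozen=True)
class CanalParams:
    """Canal transfer-function parameters plus the firing-rate noise level.

    Units: K in s^2/deg; tau1, tau2, tauN in seconds; noise_level in the
    same arbitrary firing-rate units as the model output.
    """

    K: float
    tau1: float
    tauN: float
    tau2: float = 0.005
    noise_level: float = 1.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError("K must be positive")
        if not self.tau1 > 0 or not self.tau2 > 0:
            raise ValueError("tau1 and tau2 must be positive")
        if self.tauN < 0:
            raise ValueError("tauN must be non-negative")
        if not self.noise_level > 0:
            raise ValueError("noise_level must be positive")
        if not self.tau2 < self.tau1:
            raise ValueError("tau2 (fast pole) must be smaller than tau1 (slow pole)")

    @property
    def num(self) -> list:
        """Numerator polynomial coefficients of H(s), highest order first."""
        return [self.K * self.tauN, self.K, 0.0]

    @property
    def den(self) -> list:
        """Denominator polynomial coefficients of H(s), highest order first."""
        return [self.tau1 * self.tau2, self.tau1 + self.tau2, 1.0]


@dataclass
class FiringRateResponse:
    """Simulated firing-rate deviation from rest (arbitrary units)."""

    t: np.ndarray
    rate: np.ndarray

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.rate)))


def frequency_response(params: CanalParams, f) -> np.ndarray:
    """Complex gain H(i*2*pi*f) per (deg/s) of velocity input; H(0) = 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    s = 1j * 2.0 * np.pi * f
    H = params.K * s * (1.0 + params.tauN * s) / ((1.0 + params.tau1 * s) * (1.0 + params.tau2 * s))
    return H


def simulate_firing_rate(
    params: CanalParams,
    profile: MotionProfile,
    pad_after_s: float | None = None,
) -> FiringRateResponse:
    """Drive the canal transfer function with a velocity profile.

    Zero initial conditions (resting rate before stimulus onset).  The input
    is zero-padded for ``pad_after_s`` seconds (default 5*tau1) after the
    stimulus so slow-pole transients cannot hide the global response peak.
    """
    if profile.velocity.size == 0 or profile.t.size < 2:
        raise ValueError("empty profile")
    if pad_after_s is None:
        pad_after_s = 5.0 * params.tau1
    if pad_after_s < 0:
        raise ValueError("pad_after_s must be non-negative")
    fs = profile.sample_rate
    n_pad = int(round(pad_after_s * fs))
    x = np.concatenate([profile.velocity, np.zeros(n_pad)])
    bz, az = signal.bilinear(params.num, params.den, fs)
    y = signal.lfilter(bz, az, x)
    t = profile.t[0] + np.arange(x.size) / fs
    return FiringRateResponse(t, y)


def peak_response(
    params: CanalParams,
    profile: MotionProfile,
    pad_after_s: float | None = None,
) -> float:
    """Peak |firing-rate deviation| over stimulus plus post-stimulus window.

    Linear in the stimulus amplitude: doubling every velocity sample doubles
    the returned value.
    """
    return simulate_firing_rate(params, profile, pad_after_s).peak
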