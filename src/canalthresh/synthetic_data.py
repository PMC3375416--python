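"""Bundled study fixtures and synthetic-experiment generators.

Ships the measured nine-condition threshold table (condition labels I-IX,
three acceleration shapes x three periods 0.3/1.4/6.7 s) with its
asymmetric log-scale SEMs, the per-period 20-intensity stimulus grids, and
generators that replay the whole study against simulated observers:
model-true thresholds feed log-normal 2AFC observers, adaptive sessions
estimate them back, and the resulting table can be refit to check parameter
recovery end to end.  A generic gyroscope-style distortion (harmonic
attenuation plus additive white velocity noise) exercises the
measured-profile code path; it does not claim to reproduce any specific
motion platform's dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .canal_model import CanalParams
from .fitting import profile_provider_commanded
from .profiles import MotionProfile
from .psychophysics import (
    PsychometricParams,
    SessionConfig,
    SessionResult,
    StimulusGrid,
    run_session,
)
from .threshold_model import Condition, ThresholdDataset, predict_threshold



def _data_path(name: str):
    return resources.files("canalthresh").joinpath("data", name)


def table1_dataset() -> ThresholdDataset:
    """The bundled measured threshold table (nine conditions, deg/s).

    Thresholds were averaged over participants on a logarithmic scale, hence
    the asymmetric SEMs; the 3-Hz rows are already corrected for the motion
    platform's peak-velocity offsets.
    """
    with resources.as_file(_data_path("table1.csv")) as path:
        return ThresholdDataset.from_csv(path)


def stimulus_grids() -> Dict[float, StimulusGrid]:
    """Per-period 20-point log-spaced stimulus grids (peak velocity, deg/s)."""
    with resources.as_file(_data_path("grids.csv")) as path:
        df = pd.read_csv(path)
    return {
        float(row.period_s): StimulusGrid.log_spaced(row.lo_deg_s, row.hi_deg_s, int(row.n))
        for row in df.itertuples()
    }


def study_conditions() -> List[Condition]:
    """The nine study conditions (3 shapes x 3 periods), labels I-IX."""
    return table1_dataset().conditions()


@dataclass(frozen=True)
class DistortionSpec:
    """Generic platform distortion: harmonic attenuation + velocity noise."""

    additive_noise_sd: float = 0.0
    harmonic_attenuation: Tuple[float, ...] = ()  # gains for harmonics 2, 3, ...
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        for g in self.harmonic_attenuation:
            if not 0.0 < g <= 1.0:
                raise ValueError("harmonic gains must lie in (0, 1]")


def distort_profile(profile: MotionProfile, spec: DistortionSpec) -> MotionProfile:
    """Attenuate harmonics above the fundamental and add white noise.

    The fundamental is 1/duration of the profile; harmonic h (h >= 2) is
    attenuated by ``spec.harmonic_attenuation[h - 2]`` over a band of one
    fundamental width centred on h/duration.  The sample grid is preserved.
    """
    v = profile.velocity.copy()
    n = v.size
    if spec.harmonic_attenuation:
        f0 = 1.0 / profile.duration
        freqs = np.fft.rfftfreq(n, d=1.0 / profile.sample_rate)
        spectrum = np.fft.rfft(v)
        for h, gain in enumerate(spec.harmonic_attenuation, start=2):
            band = np.abs(freqs - h * f0) < 0.5 * f0
            spectrum[band] *= gain
        v = np.fft.irfft(spectrum, n=n)
    if spec.additive_noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        v = v + rng.normal(0.0, spec.additive_noise_sd, size=n)
    return MotionProfile(profile.t.copy(), v, meta=profile.meta)


@dataclass
class ExperimentResult:
    """Synthetic replica of the study: estimated thresholds + trial logs."""

    dataset: ThresholdDataset
    true_thresholds: Dict[str, float]
    sessions: Dict[str, SessionResult]


def generate_experiment(
    true_params: CanalParams,
    observer_sigma: float = 0.4,
    observer_lapse: float = 0.02,
    break_value: float = 1e-3,
    seed: int = 0,
    sample_rate: float = 1000.0,
    session_kwargs: Optional[dict] = None,
) -> ExperimentResult:
    """Simulate the full nine-condition experiment for one observer.

    For every condition the canal model's true threshold becomes the
    location of a log-normal 2AFC observer (mu = ln threshold), an adaptive
    session estimates it on that period's stimulus grid, and the estimates
    are returned as a threshold table ready for refitting.  Fully
    reproducible from ``seed``.
    """
    conditions = study_conditions()
    provider = profile_provider_commanded(conditions, sample_rate)
    grids = stimulus_grids()
    rows = []
    sessions: Dict[str, SessionResult] = {}
    true_thresholds: Dict[str, float] = {}
    for k, cond in enumerate(conditions):
        true_thr = predict_threshold(true_params, provider(cond))
        true_thresholds[cond.label] = true_thr
        observer = PsychometricParams(
            mu=float(np.log(true_thr)), sigma=observer_sigma, lapse=observer_lapse
        )
        cfg = SessionConfig(
            grid=grids[cond.period_s],
            break_value=break_value,
            rng_seed=seed * 1009 + k,
            **(session_kwargs or {}),
        )
        result = run_session(observer, cfg)
        sessions[cond.label] = result
        rows.append(
            {
                "condition": cond.label,
                "shape": cond.shape,
                "frequency_hz": cond.frequency,
                "period_s": cond.period_s,
                "threshold_deg_s": result.threshold_estimate,
                "sem_plus": np.nan,
                "sem_minus": np.nan,
                "source": "simulated",
            }
        )
    return ExperimentResult(
        dataset=ThresholdDataset(pd.DataFrame(rows)),
        true_thresholds=true_thresholds,
        sessions=sessions,
    )
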