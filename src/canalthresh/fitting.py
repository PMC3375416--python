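"""Nonlinear least-squares estimation of the canal parameters.

The free parameters (K, tau1, tauN) are estimated from a threshold table by
minimising the sum of squared errors between predicted and measured
thresholds; tau2 stays fixed at 0.005 s, the value derived from canal
anatomy, which is far too fast to be constrained by thresholds at 0.15-3 Hz.
The free parameters are optimised on a log scale, which enforces positivity
without explicit bounds and gives scale-appropriate steps, and a small
deterministic multistart guards against local minima.

The estimator :class:`CanalThresholdModel` exposes the fit in the
fit/predict idiom; :func:`fit_params` is the equivalent functional surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .canal_model import CanalParams
from .profiles import MotionProfile, ProfileSpec, generate_profile
from .threshold_model import Condition, ThresholdDataset, predict_threshold

#: Initial guess taken from regular canal afferent recordings in rhesus
#: monkeys (tau1 = 4 s, tauN = 0.013 s); K has no physiological prior and
#: starts at 1.
DEFAULT_INIT = CanalParams(K=1.0, tau1=4.0, tauN=0.013)

#: Deterministic multistart perturbations applied to log(K, tau1, tauN).
_MULTISTART_STEPS = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.7, 0.7, 0.7],
        [-0.7, -0.7, -0.7],
        [0.7, -0.7, 0.7],
        [-0.7, 0.7, -0.7],
        [1.4, 0.0, -1.4],
        [-1.4, 0.0, 1.4],
    ]
)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the least-squares fit."""

    init: CanalParams = DEFAULT_INIT
    fix_tau2: bool = True
    tau2: float = 0.005
    objective_space: str = "linear"  # or "log"
    weight_by_sem: bool = False
    multistart: int = 5
    sample_rate: float = 1000.0
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self) -> None:
        if self.objective_space not in ("linear", "log"):
            raise ValueError("objective_space must be 'linear' or 'log'")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        if not self.fix_tau2:
            raise ValueError("freeing tau2 is not supported; it is anatomically fixed")


@dataclass
class FitResult:
    """Outcome of :func:`fit_params`."""

    params: CanalParams
    sse: float
    residuals: np.ndarray
    converged: bool
    n_evaluations: int
    start_used: int

    def __post_init__(self) -> None:
        assert self.sse >= 0.0


def profile_provider_commanded(
    conditions: Sequence[Condition],
    sample_rate: float = 1000.0,
) -> Callable[[Condition], MotionProfile]:
    """Provider mapping each condition to its unit-peak commanded profile.

    Deterministic: profiles are built once and cached by condition label.
    """
    cache: Dict[str, MotionProfile] = {}
    for cond in conditions:
        spec = ProfileSpec(
            shape=cond.shape,
            period_T=cond.period_s,
            peak_velocity=1.0,
            sample_rate=sample_rate,
        )
        cache[cond.label] = generate_profile(spec)

    def provider(cond: Condition) -> MotionProfile:
        if cond.label not in cache:
            spec = ProfileSpec(cond.shape, cond.period_s, 1.0, sample_rate)
            cache[cond.label] = generate_profile(spec)
        return cache[cond.label]

    return provider


def _residuals(
    params: CanalParams,
    dataset: ThresholdDataset,
    conditions: Sequence[Condition],
    provider: Callable[[Condition], MotionProfile],
    objective_space: str,
    weights: Optional[np.ndarray],
) -> np.ndarray:
    predicted = np.array([predict_threshold(params, provider(c)) for c in conditions])
    measured = dataset.thresholds
    if objective_space == "log":
        res = np.log(predicted) - np.log(measured)
    else:
        res = predicted - measured
    if weights is not None:
        res = res * weights
    return res


def sse(
    params: CanalParams,
    dataset: ThresholdDataset,
    profile_provider: Callable[[Condition], MotionProfile],
    objective_space: str = "linear",
) -> float:
    """Sum of squared threshold errors in linear (deg/s) or log space."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    conditions = dataset.conditions()
    res = _residuals(params, dataset, conditions, profile_provider, objective_space, None)
    return float(np.sum(res**2))


def fit_params(
    dataset: ThresholdDataset,
    profile_provider: Optional[Callable[[Condition], MotionProfile]] = None,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Least-squares fit of (K, tau1, tauN) to a threshold table.

    Requires at least 3 conditions spanning at least 2 distinct frequencies,
    otherwise the 3 free parameters are under-determined.  Returns the best
    of ``config.multistart`` deterministic starts; if no start converges the
    best iterate is still returned with ``converged=False``.
    """
    conditions = dataset.conditions()
    freqs = {round(1.0 / c.period_s, 6) for c in conditions}
    if len(conditions) < 3 or len(freqs) < 2:
        raise ValueError("under-determined: need >= 3 conditions over >= 2 frequencies")
    if profile_provider is None:
        profile_provider = profile_provider_commanded(conditions, config.sample_rate)
    weights = None
    if config.weight_by_sem:
        sem = 0.5 * (
            dataset.data["sem_plus"].to_numpy(float) + dataset.data["sem_minus"].to_numpy(float)
        )
        weights = 1.0 / sem

    noise = config.init.noise_level

    def residual_vec(theta: np.ndarray) -> np.ndarray:
        K, tau1, tauN = np.exp(theta)
        params = CanalParams(K=K, tau1=tau1, tauN=tauN, tau2=config.tau2, noise_level=noise)
        return _residuals(
            params, dataset, conditions, profile_provider, config.objective_space, weights
        )

    theta0 = np.log([config.init.K, config.init.tau1, max(config.init.tauN, 1e-6)])
    best = None
    for i in range(config.multistart):
        start = theta0 + _MULTISTART_STEPS[i % len(_MULTISTART_STEPS)]
        sol = optimize.least_squares(
            residual_vec, start, xtol=config.xtol, ftol=config.ftol, gtol=config.gtol
        )
        this_sse = float(np.sum(sol.fun**2))
        if best is None or this_sse < best[0]:
            best = (this_sse, sol, i)
    best_sse, sol, start_used = best
    K, tau1, tauN = np.exp(sol.x)
    # a tiny fitted tauN is a boundary solution at tauN = 0
    if tauN < 1e-9:
        tauN = 0.0
    params = CanalParams(K=K, tau1=tau1, tauN=tauN, tau2=config.tau2, noise_level=noise)
    return FitResult(
        params=params,
        sse=best_sse,
        residuals=sol.fun.copy(),
        converged=bool(sol.status > 0),
        n_evaluations=int(sol.nfev),
        start_used=start_used,
    )


class CanalThresholdModel:
    """Canal-threshold regressor in the scikit-learn estimator idiom.

    ``fit(X, y)`` takes a condition table ``X`` (DataFrame with columns
    ``shape`` and ``period_s``, or a sequence of :class:`Condition`) and
    measured thresholds ``y`` in deg/s; ``predict(X)`` returns model
    thresholds.  Fitted attributes: ``K_``, ``tau1_``, ``tauN_``, ``sse_``,
    ``residuals_``, ``params_``.

    Parameters mirror :class:`FitConfig`; ``profile_provider`` optionally
    supplies measured velocity profiles per condition in place of the
    commanded shapes.
    """

    def __init__(
        self,
        K_init: float = 1.0,
        tau1_init: float = 4.0,
        tauN_init: float = 0.013,
        tau2: float = 0.005,
        noise_level: float = 1.0,
        objective_space: str = "linear",
        multistart: int = 5,
        sample_rate: float = 1000.0,
        profile_provider: Optional[Callable[[Condition], MotionProfile]] = None,
    ):
        self.K_init = K_init
        self.tau1_init = tau1_init
        self.tauN_init = tauN_init
        self.tau2 = tau2
        self.noise_level = noise_level
        self.objective_space = objective_space
        self.multistart = multistart
        self.sample_rate = sample_rate
        self.profile_provider = profile_provider

    # -- sklearn plumbing ------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "K_init": self.K_init,
            "tau1_init": self.tau1_init,
            "tauN_init": self.tauN_init,
            "tau2": self.tau2,
            "noise_level": self.noise_level,
            "objective_space": self.objective_space,
            "multistart": self.multistart,
            "sample_rate": self.sample_rate,
            "profile_provider": self.profile_provider,
        }

    def set_params(self, **params) -> "CanalThresholdModel":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    @staticmethod
    def _as_conditions(X) -> list:
        if isinstance(X, pd.DataFrame):
            conds = []
            for i, row in X.iterrows():
                period = row["period_s"] if "period_s" in row else 1.0 / row["frequency_hz"]
                label = str(row["condition"]) if "condition" in row else str(i)
                freq = float(row["frequency_hz"]) if "frequency_hz" in row else None
                conds.append(Condition(label, str(row["shape"]), float(period), freq))
            return conds
        return list(X)

    def _config(self) -> FitConfig:
        return FitConfig(
            init=CanalParams(
                K=self.K_init,
                tau1=self.tau1_init,
                tauN=self.tauN_init,
                tau2=self.tau2,
                noise_level=self.noise_level,
            ),
            tau2=self.tau2,
            objective_space=self.objective_space,
            multistart=self.multistart,
            sample_rate=self.sample_rate,
        )

    # -- estimation ------------------------------------------------------
    def fit(self, X, y) -> "CanalThresholdModel":
        conditions = self._as_conditions(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (len(conditions),):
            raise ValueError("y must hold one threshold per condition")
        rows = [
            {
                "condition": c.label,
                "shape": c.shape,
                "frequency_hz": c.frequency,
                "period_s": c.period_s,
                "threshold_deg_s": t,
                "source": "measured",
            }
            for c, t in zip(conditions, y)
        ]
        dataset = ThresholdDataset(pd.DataFrame(rows))
        result = fit_params(dataset, self.profile_provider, self._config())
        self.params_ = result.params
        self.K_ = result.params.K
        self.tau1_ = result.params.tau1
        self.tauN_ = result.params.tauN
        self.sse_ = result.sse
        self.residuals_ = result.residuals
        self.converged_ = result.converged
        self.n_evaluations_ = result.n_evaluations
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("CanalThresholdModel is not fitted yet; call fit first")
        conditions = self._as_conditions(X)
        provider = self.profile_provider or profile_provider_commanded(
            conditions, self.sample_rate
        )
        return np.array([predict_threshold(self.params_, provider(c)) for c in conditions])

    def score(self, X, y) -> float:
        """Coefficient of determination R^2 of threshold predictions."""
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot)
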