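"""2AFC measurement machinery: psychometric model, ML fit, psi staircase.

The probability of a correct direction report is modelled as a cumulative
normal in log stimulus space with a lapse parameter,

    p(correct | s) = g + (1 - g - lambda) * Phi((ln s - mu) / sigma),

with guess rate g = 0.5 for the two-alternative task and lambda in
[0, 0.05].  The reported threshold is e^mu, the stimulus at the mean of the
underlying normal (with lambda = 0 this is exactly the 75 % point; with
lambda > 0 the 75 % convention is kept although p(e^mu) = 0.75 - lambda/2 --
see the methods note).

Stimulus placement uses a Kontsevich-Tyler-style Bayesian adaptive
procedure: a posterior over a (mu, sigma, lapse) grid is updated after every
trial, and the next stimulus is the grid intensity that minimises the
expected posterior variance of the threshold.  A session stops once that
variance has stayed below a pre-chosen *break value* for 20 consecutive
trials and at least 80 trials have been run; the break value itself is
calibrated so that the running estimate is already within 10 % of the
long-run estimate whenever the rule can fire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

# ---------------------------------------------------------------------------
# psychometric function


@dataclass(frozen=True)
class PsychometricParams:
    """Location/spread/lapse of the 2AFC psychometric function (log space)."""

    mu: float  # log(deg/s)
    sigma: float  # log-units
    lapse: float = 0.0
    guess: float = 0.5

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lapse <= 0.05:
            raise ValueError("lapse must lie in [0, 0.05]")

    @property
    def threshold(self) -> float:
        """Threshold in deg/s (stimulus at the mean of the underlying normal)."""
        return float(np.exp(self.mu))


def p_correct(params: PsychometricParams, stimulus) -> np.ndarray:
    """Probability of a correct direction report at a peak velocity (deg/s)."""
    stimulus = np.asarray(stimulus, dtype=float)
    if np.any(stimulus <= 0):
        raise ValueError("stimulus must be positive")
    z = (np.log(stimulus) - params.mu) / params.sigma
    p = params.guess + (1.0 - params.guess - params.lapse) * norm.cdf(z)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class Trial:
    """One 2AFC trial: peak velocity, motion direction and outcome."""

    stimulus: float
    direction: int
    correct: bool

    def __post_init__(self) -> None:
        if not self.stimulus > 0:
            raise ValueError("stimulus must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


def simulate_response(
    observer: PsychometricParams,
    stimulus: float,
    direction: int,
    rng: np.random.Generator,
) -> Trial:
    """Draw one Bernoulli response from a simulated observer."""
    p = p_correct(observer, stimulus)
    return Trial(stimulus=stimulus, direction=direction, correct=bool(rng.random() < p))


# ---------------------------------------------------------------------------
# maximum-likelihood fit


@dataclass
class PsychometricFit:
    """Result of the maximum-likelihood psychometric fit."""

    params: PsychometricParams
    threshold: float
    log_likelihood: float
    degenerate: bool


def _neg_loglik(theta: np.ndarray, log_s: np.ndarray, correct: np.ndarray, guess: float) -> float:
    mu, log_sigma, lapse = theta
    sigma = np.exp(log_sigma)
    p = guess + (1.0 - guess - lapse) * norm.cdf((log_s - mu) / sigma)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(correct, np.log(p), np.log1p(-p))))


class PsychometricModel:
    """Maximum-likelihood psychometric fit in the sklearn estimator idiom.

    ``fit(X, y)`` takes stimuli in deg/s and boolean correctness; fitted
    attributes are ``mu_``, ``sigma_``, ``lapse_``, ``threshold_``,
    ``log_likelihood_`` and ``degenerate_``.  ``predict_proba(X)`` returns
    the fitted probability of a correct report.
    """

    def __init__(self, lapse_bounds: Tuple[float, float] = (0.0, 0.05), guess: float = 0.5):
        self.lapse_bounds = lapse_bounds
        self.guess = guess

    def get_params(self, deep: bool = True) -> dict:
        return {"lapse_bounds": self.lapse_bounds, "guess": self.guess}

    def set_params(self, **params) -> "PsychometricModel":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "PsychometricModel":
        stimuli = np.asarray(X, dtype=float).ravel()
        correct = np.asarray(y, dtype=bool).ravel()
        if stimuli.shape != correct.shape or stimuli.size == 0:
            raise ValueError("X and y must be non-empty and of equal length")
        if np.any(stimuli <= 0):
            raise ValueError("stimuli must be positive")
        log_s = np.log(stimuli)
        levels = np.unique(stimuli)
        self.degenerate_ = bool(levels.size < 2 or correct.all() or (~correct).all())
        if self.degenerate_:
            # boundary estimate: threshold below the tested range when the
            # observer was always right, above it when always wrong
            if levels.size < 2:
                mu = float(log_s[0])
            elif correct.all():
                mu = float(log_s.min())
            else:
                mu = float(log_s.max())
            sigma = max(float(np.ptp(log_s)), 1e-2)
            self._set_fitted(mu, sigma, 0.0, log_s, correct)
            return self

        lo, hi = self.lapse_bounds
        spread = max(float(np.ptp(log_s)) / 2.0, 1e-2)
        best = None
        for mu0 in (float(np.median(log_s)), float(log_s.min()), float(log_s.max())):
            res = optimize.minimize(
                _neg_loglik,
                x0=np.array([mu0, np.log(spread), 0.5 * (lo + hi)]),
                args=(log_s, correct, self.guess),
                method="L-BFGS-B",
                bounds=[
                    (log_s.min() - 5.0, log_s.max() + 5.0),
                    (np.log(1e-3), np.log(10.0)),
                    (lo, hi),
                ],
            )
            if best is None or res.fun < best.fun:
                best = res
        mu, log_sigma, lapse = best.x
        self._set_fitted(float(mu), float(np.exp(log_sigma)), float(lapse), log_s, correct)
        return self

    def _set_fitted(self, mu, sigma, lapse, log_s, correct) -> None:
        self.mu_ = mu
        self.sigma_ = sigma
        self.lapse_ = lapse
        self.threshold_ = float(np.exp(mu))
        self.log_likelihood_ = -_neg_loglik(
            np.array([mu, np.log(sigma), lapse]), log_s, correct, self.guess
        )

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "mu_"):
            raise RuntimeError("PsychometricModel is not fitted yet")
        return p_correct(
            PsychometricParams(self.mu_, self.sigma_, self.lapse_, self.guess), X
        )


def fit_psychometric(
    trials: Sequence[Trial],
    lapse_bounds: Tuple[float, float] = (0.0, 0.05),
) -> PsychometricFit:
    """ML fit of the psychometric function to a trial log.

    Degenerate data (a single stimulus level, or all-correct/all-incorrect
    outcomes) are flagged and produce a boundary estimate instead of an
    interior maximum.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    stimuli = np.array([t.stimulus for t in trials])
    correct = np.array([t.correct for t in trials])
    model = PsychometricModel(lapse_bounds=lapse_bounds).fit(stimuli, correct)
    return PsychometricFit(
        params=PsychometricParams(model.mu_, model.sigma_, model.lapse_),
        threshold=model.threshold_,
        log_likelihood=model.log_likelihood_,
        degenerate=model.degenerate_,
    )


# ---------------------------------------------------------------------------
# stimulus grid and adaptive procedure


@dataclass(frozen=True)
class StimulusGrid:
    """Log-spaced peak-velocity intensities for one period length."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least two values")
        if np.any(np.diff(values) <= 0) or values[0] <= 0:
            raise ValueError("grid must be positive and strictly increasing")
        object.__setattr__(self, "values", values)

    @classmethod
    def log_spaced(cls, lo: float, hi: float, n: int = 20) -> "StimulusGrid":
        return cls(np.geomspace(lo, hi, n))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SessionConfig:
    """Adaptive-session settings: grid, stopping rule, posterior grids."""

    grid: StimulusGrid
    break_value: float
    min_trials: int = 80
    consecutive_required: int = 20
    max_trials: int = 300
    n_mu: int = 41
    mu_extension: float = 0.2  # fraction of the log-range added on each side
    sigma_range: Tuple[float, float] = (0.05, 1.5)
    n_sigma: int = 21
    lapse_values: Tuple[float, ...] = (0.0, 0.0125, 0.025, 0.0375, 0.05)
    variance_scale: str = "linear"  # posterior variance of e^mu; "log" -> of mu
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.break_value > 0:
            raise ValueError("break_value must be positive")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")
        if self.max_trials < self.min_trials:
            raise ValueError("max_trials must be >= min_trials")
        if self.variance_scale not in ("linear", "log"):
            raise ValueError("variance_scale must be 'linear' or 'log'")


class AdaptiveState:
    """Posterior over (mu, sigma, lapse) plus the trial history.

    The posterior lives on a dense product grid with uniform prior; the
    per-stimulus correct-response probabilities are precomputed once, so a
    trial update is a single reweighting.  ``threshold_estimate`` is the
    posterior mean of e^mu in deg/s and ``estimate_variance`` its posterior
    variance in (deg/s)^2 (or of mu in log units when configured).
    """

    def __init__(self, config: SessionConfig):
        self.config = config
        grid = config.grid.values
        log_lo, log_hi = np.log(grid[0]), np.log(grid[-1])
        ext = config.mu_extension * (log_hi - log_lo)
        mu = np.linspace(log_lo - ext, log_hi + ext, config.n_mu)
        sigma = np.geomspace(config.sigma_range[0], config.sigma_range[1], config.n_sigma)
        lapse = np.asarray(config.lapse_values, dtype=float)
        MU, SIG, LAP = np.meshgrid(mu, sigma, lapse, indexing="ij")
        self.mu_flat = MU.ravel()
        self.sigma_flat = SIG.ravel()
        self.lapse_flat = LAP.ravel()
        self.exp_mu = np.exp(self.mu_flat)
        z = (np.log(grid)[:, None] - self.mu_flat[None, :]) / self.sigma_flat[None, :]
        self.lik_correct = 0.5 + (0.5 - self.lapse_flat[None, :]) * norm.cdf(z)
        self.posterior = np.full(self.mu_flat.size, 1.0 / self.mu_flat.size)
        self.history: List[Trial] = []
        self.consecutive_below = 0

    @property
    def _stat(self) -> np.ndarray:
        return self.exp_mu if self.config.variance_scale == "linear" else self.mu_flat

    @property
    def threshold_estimate(self) -> float:
        """Posterior-mean threshold in deg/s."""
        if self.config.variance_scale == "linear":
            return float(self.posterior @ self.exp_mu)
        return float(np.exp(self.posterior @ self.mu_flat))

    @property
    def estimate_variance(self) -> float:
        stat = self._stat
        m1 = self.posterior @ stat
        m2 = self.posterior @ (stat**2)
        return max(float(m2 - m1**2), 0.0)

    def stimulus_index(self, stimulus: float) -> int:
        grid = self.config.grid.values
        i = int(np.argmin(np.abs(grid - stimulus)))
        if not np.isclose(grid[i], stimulus, rtol=1e-9, atol=0.0):
            raise ValueError(f"stimulus {stimulus} is not on the session grid")
        return i


def psi_update(state: AdaptiveState, trial: Trial) -> AdaptiveState:
    """Multiply the posterior by the trial's Bernoulli likelihood.

    Raises on numerical underflow (zero total posterior mass).
    """
    i = state.stimulus_index(trial.stimulus)
    like = state.lik_correct[i] if trial.correct else 1.0 - state.lik_correct[i]
    w = state.posterior * like
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise FloatingPointError(
            "posterior mass underflow in psi_update "
            f"(trial {len(state.history) + 1}, stimulus {trial.stimulus})"
        )
    state.posterior = w / total
    state.history.append(trial)
    return state


def psi_next_stimulus(state: AdaptiveState) -> float:
    """Grid stimulus minimising the expected posterior threshold variance.

    The expectation runs over the two trial outcomes weighted by their
    posterior-predictive probabilities; ties resolve to the lowest stimulus.
    """
    w = state.posterior
    P = state.lik_correct  # (n_stim, n_theta)
    stat = state._stat
    A = P * w[None, :]
    B = (1.0 - P) * w[None, :]
    pc = A.sum(axis=1)
    pi = B.sum(axis=1)
    s1c, s2c = A @ stat, A @ stat**2
    s1i, s2i = B @ stat, B @ stat**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_c = np.where(pc > 0, s2c - s1c**2 / np.where(pc > 0, pc, 1.0), 0.0)
        var_i = np.where(pi > 0, s2i - s1i**2 / np.where(pi > 0, pi, 1.0), 0.0)
    expected = var_c + var_i  # = pc*Var_c + pi*Var_i, each term pre-multiplied
    # ties (within rounding of the current posterior moments) -> lowest stimulus
    tol = 1e-9 * state.estimate_variance + 1e-13 * float(w @ stat**2)
    best = int(np.flatnonzero(expected <= expected.min() + tol)[0])
    return float(state.config.grid.values[best])


@dataclass
class SessionResult:
    """Completed adaptive session: trial log and final estimate."""

    trials: List[Trial]
    threshold_estimate: float
    stopped_reason: str  # "break_value" or "cap"
    log: pd.DataFrame
    state: AdaptiveState

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def run_session(observer: PsychometricParams, config: SessionConfig) -> SessionResult:
    """Run one simulated adaptive session against a synthetic observer.

    Loop: select the most informative stimulus, draw a response, update the
    posterior.  Stops when the estimate variance has been below
    ``config.break_value`` for ``consecutive_required`` consecutive trials
    and at least ``min_trials`` trials were run; a hard cap of
    ``max_trials`` guarantees termination (``stopped_reason == "cap"``).
    """
    rng = np.random.default_rng(config.rng_seed)
    state = AdaptiveState(config)
    rows = []
    stopped = "cap"
    for n in range(1, config.max_trials + 1):
        stimulus = psi_next_stimulus(state)
        direction = 1 if rng.random() < 0.5 else -1
        trial = simulate_response(observer, stimulus, direction, rng)
        psi_update(state, trial)
        est, var = state.threshold_estimate, state.estimate_variance
        state.consecutive_below = state.consecutive_below + 1 if var < config.break_value else 0
        rows.append(
            {
                "trial": n,
                "stimulus_deg_s": stimulus,
                "direction": direction,
                "correct": trial.correct,
                "estimate_deg_s": est,
                "variance": var,
            }
        )
        if n >= config.min_trials and state.consecutive_below >= config.consecutive_required:
            stopped = "break_value"
            break
    return SessionResult(
        trials=list(state.history),
        threshold_estimate=state.threshold_estimate,
        stopped_reason=stopped,
        log=pd.DataFrame(rows),
        state=state,
    )


def calibrate_break_value(
    observer_set: Sequence[PsychometricParams],
    grid: StimulusGrid,
    accuracy_fraction: float = 0.10,
    long_run_trials: int = 200,
    seed: int = 0,
    config: Optional[SessionConfig] = None,
) -> float:
    """Choose the stopping variance so early stops stay near the long-run estimate.

    For each calibration observer a fixed-length session of
    ``long_run_trials`` trials is run (no stopping rule); the final estimate
    is taken as the best possible one.  Per trial the pair (variance,
    AD = |estimate - best|) is recorded, and the returned break value is the
    largest variance level guaranteeing AD < ``accuracy_fraction`` times the
    average best-estimate threshold on *every* calibration trial whose
    variance falls below it.
    """
    if not observer_set:
        raise ValueError("observer_set is empty")
    logs = []
    for k, observer in enumerate(observer_set):
        cfg = SessionConfig(
            grid=grid,
            break_value=1e-300,  # never fires; fixed-length run
            min_trials=long_run_trials,
            max_trials=long_run_trials,
            rng_seed=seed + k,
            **(
                {}
                if config is None
                else {
                    "n_mu": config.n_mu,
                    "mu_extension": config.mu_extension,
                    "sigma_range": config.sigma_range,
                    "n_sigma": config.n_sigma,
                    "lapse_values": config.lapse_values,
                    "variance_scale": config.variance_scale,
                }
            ),
        )
        result = run_session(observer, cfg)
        log = result.log.copy()
        log["ad"] = np.abs(log["estimate_deg_s"] - result.threshold_estimate)
        logs.append((log, result.threshold_estimate))

    criterion = accuracy_fraction * float(np.mean([best for _, best in logs]))
    all_var = np.concatenate([log["variance"].to_numpy() for log, _ in logs])
    all_ad = np.concatenate([log["ad"].to_numpy() for log, _ in logs])
    violating = all_var[all_ad >= criterion]
    if violating.size == 0:
        return float(all_var.max())
    break_value = float(violating.min()) * (1.0 - 1e-9)
    reachable = any(np.any(log["variance"].to_numpy() < break_value) for log, _ in logs)
    if not reachable or break_value <= 0.0:
        raise RuntimeError(
            "accuracy criterion unattainable within "
            f"{long_run_trials} trials (break value {break_value:.3e})"
        )
    return break_value
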