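"""Psychometric model, ML fit, psi staircase and stopping-rule calibration."""

import numpy as np
import pytest

from canalthresh import (
    PsychometricModel,
    PsychometricParams,
    SessionConfig,
    StimulusGrid,
    Trial,
    calibrate_break_value,
    fit_psychometric,
    p_correct,
    psi_next_stimulus,
    psi_update,
    run_session,
    simulate_response,
)
from canalthresh.psychophysics import AdaptiveState

GRID = StimulusGrid.log_spaced(0.053, 8.4, 20)  # 1.4-s period grid


class TestPCorrect:
    def test_threshold_point_is_75_percent_without_lapse(self):
        params = PsychometricParams(mu=np.log(1.0), sigma=0.4, lapse=0.0)
        assert p_correct(params, 1.0) == pytest.approx(0.75, abs=1e-12)

    def test_limits(self):
        params = PsychometricParams(mu=0.0, sigma=0.4, lapse=0.05)
        assert p_correct(params, 1e-12) == pytest.approx(0.5, abs=1e-9)
        assert p_correct(params, 1e12) == pytest.approx(0.95, abs=1e-9)

    def test_non_positive_stimulus_rejected(self):
        with pytest.raises(ValueError):
            p_correct(PsychometricParams(0.0, 0.4), 0.0)


class TestMLFit:
    def test_large_sample_recovery(self):
        """10k trials on a 20-point grid recover mu within 0.05 and sigma within 0.1."""
        truth = PsychometricParams(mu=np.log(1.0), sigma=0.4, lapse=0.02)
        rng = np.random.default_rng(42)
        stimuli = rng.choice(GRID.values, size=10_000)
        correct = rng.random(10_000) < p_correct(truth, stimuli)
        model = PsychometricModel().fit(stimuli, correct)
        assert not model.degenerate_
        assert model.mu_ == pytest.approx(truth.mu, abs=0.05)
        assert model.sigma_ == pytest.approx(truth.sigma, abs=0.1)
        assert 0.0 <= model.lapse_ <= 0.05

    def test_likelihood_at_fit_beats_generator(self):
        truth = PsychometricParams(mu=np.log(0.9), sigma=0.4, lapse=0.02)
        rng = np.random.default_rng(3)
        trials = []
        for _ in range(500):
            s = float(rng.choice(GRID.values))
            trials.append(simulate_response(truth, s, 1, rng))
        fit = fit_psychometric(trials)
        log_s = np.log([t.stimulus for t in trials])
        correct = np.array([t.correct for t in trials])
        p_true = np.clip(p_correct(truth, np.exp(log_s)), 1e-12, 1 - 1e-12)
        ll_true = np.sum(np.where(correct, np.log(p_true), np.log1p(-p_true)))
        assert fit.log_likelihood >= ll_true - 1e-9

    def test_degenerate_single_level(self):
        trials = [Trial(1.0, 1, bool(i % 2)) for i in range(10)]
        fit = fit_psychometric(trials)
        assert fit.degenerate

    def test_degenerate_all_correct_boundary(self):
        trials = [Trial(s, 1, True) for s in GRID.values]
        fit = fit_psychometric(trials)
        assert fit.degenerate
        assert fit.threshold == pytest.approx(GRID.values[0], rel=1e-9)


class TestSimulateResponse:
    def test_reproducible_and_records_direction(self):
        obs = PsychometricParams(np.log(1.0), 0.4, 0.02)
        t1 = [simulate_response(obs, 1.0, -1, np.random.default_rng(5)) for _ in range(1)][0]
        t2 = simulate_response(obs, 1.0, -1, np.random.default_rng(5))
        assert t1 == t2
        assert t1.direction == -1

    def test_empirical_rate_at_threshold(self):
        obs = PsychometricParams(np.log(1.0), 0.4, 0.0)
        rng = np.random.default_rng(11)
        hits = sum(simulate_response(obs, 1.0, 1, rng).correct for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.75, abs=0.01)


def make_state(**kwargs):
    cfg = SessionConfig(grid=GRID, break_value=1e-3, **kwargs)
    return AdaptiveState(cfg), cfg


class TestPsiUpdate:
    def test_posterior_normalized_after_many_updates(self):
        state, _ = make_state()
        obs = PsychometricParams(np.log(0.9), 0.4, 0.02)
        rng = np.random.default_rng(8)
        for _ in range(500):
            s = float(rng.choice(GRID.values))
            psi_update(state, simulate_response(obs, s, 1, rng))
        assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert state.estimate_variance >= 0.0

    def test_correct_answer_shifts_mu_down(self):
        """A correct report at a high stimulus cannot raise the posterior-mean mu."""
        state, _ = make_state()
        before = float(state.posterior @ state.mu_flat)
        psi_update(state, Trial(float(GRID.values[-1]), 1, True))
        after = float(state.posterior @ state.mu_flat)
        assert after <= before + 1e-12

    def test_underflow_raises(self):
        state, _ = make_state()
        # point mass on a lapse-free observer far below the grid: an incorrect
        # answer at the top stimulus has probability exactly 0 in float
        idx = int(np.argmin(state.mu_flat + 1e3 * state.sigma_flat + 1e3 * state.lapse_flat))
        state.posterior[:] = 0.0
        state.posterior[idx] = 1.0
        with pytest.raises(FloatingPointError):
            psi_update(state, Trial(float(GRID.values[-1]), 1, False))

    def test_off_grid_stimulus_rejected(self):
        state, _ = make_state()
        with pytest.raises(ValueError):
            psi_update(state, Trial(1.2345, 1, True))


class TestPsiNextStimulus:
    def brute_force_expected_variance(self, state):
        w = state.posterior
        out = []
        for i in range(len(state.config.grid)):
            pc_theta = state.lik_correct[i]
            total = 0.0
            for like in (pc_theta, 1.0 - pc_theta):
                p_out = float(np.sum(w * like))
                if p_out <= 0:
                    continue
                post = w * like / p_out
                m1 = float(post @ state.exp_mu)
                m2 = float(post @ state.exp_mu**2)
                total += p_out * (m2 - m1**2)
            out.append(total)
        return np.array(out)

    def test_matches_brute_force(self):
        state, _ = make_state()
        rng = np.random.default_rng(17)
        w = rng.random(state.posterior.size)
        state.posterior = w / w.sum()
        expected = self.brute_force_expected_variance(state)
        chosen = psi_next_stimulus(state)
        assert chosen == pytest.approx(GRID.values[int(np.argmin(expected))], rel=1e-12)

    def test_point_mass_tie_breaks_to_lowest(self):
        state, _ = make_state()
        state.posterior[:] = 0.0
        state.posterior[1000] = 1.0
        assert psi_next_stimulus(state) == pytest.approx(GRID.values[0], rel=1e-12)

    def test_invariant_to_weight_rescaling(self):
        state, _ = make_state()
        rng = np.random.default_rng(23)
        w = rng.random(state.posterior.size)
        state.posterior = w / w.sum()
        first = psi_next_stimulus(state)
        state.posterior = state.posterior * 37.0  # unnormalized on purpose
        assert psi_next_stimulus(state) == first


class TestRunSession:
    def test_minimum_trial_count_enforced(self):
        obs = PsychometricParams(np.log(0.9), 0.4, 0.02)
        cfg = SessionConfig(grid=GRID, break_value=1e30, rng_seed=2)
        result = run_session(obs, cfg)
        assert result.n_trials == cfg.min_trials  # infinite break: stops at the floor
        assert result.stopped_reason == "break_value"

    def test_all_sessions_reach_eighty_trials(self):
        obs = PsychometricParams(np.log(0.9), 0.4, 0.02)
        for seed in range(3):
            result = run_session(obs, SessionConfig(grid=GRID, break_value=5e-3, rng_seed=seed))
            assert result.n_trials >= 80

    def test_estimates_tighten_as_break_value_shrinks(self):
        """Posterior-mean estimates converge toward e^mu as the break value drops."""
        obs = PsychometricParams(np.log(0.9), 0.3, 0.0)
        errors = []
        for bv in (3e-2, 5e-3, 5e-4):
            ests = [
                run_session(
                    obs, SessionConfig(grid=GRID, break_value=bv, min_trials=20, rng_seed=100 + s)
                ).threshold_estimate
                for s in range(40)
            ]
            errors.append(np.mean(np.abs(np.array(ests) / 0.9 - 1.0)))
        assert errors[0] > errors[1] > errors[2]

    def test_ml_refit_agrees_with_posterior_mean(self):
        """Two estimators of the same session agree within 15 %."""
        obs = PsychometricParams(np.log(0.9), 0.4, 0.02)
        result = run_session(obs, SessionConfig(grid=GRID, break_value=5e-3, rng_seed=9))
        refit = fit_psychometric(result.trials)
        assert refit.threshold == pytest.approx(result.threshold_estimate, rel=0.15)

    def test_log_reproducible(self):
        obs = PsychometricParams(np.log(0.9), 0.4, 0.02)
        cfg = SessionConfig(grid=GRID, break_value=5e-3, rng_seed=4)
        a, b = run_session(obs, cfg), run_session(obs, cfg)
        assert a.log.equals(b.log)


CAL_OBSERVERS = [PsychometricParams(np.log(x), 0.4, 0.02) for x in (0.939, 1.051, 0.897)]


@pytest.fixture(scope="module")
def calibration():
    return calibrate_break_value(
        CAL_OBSERVERS, GRID, accuracy_fraction=0.10, long_run_trials=120, seed=31
    )


class TestCalibration:
    OBSERVERS = CAL_OBSERVERS

    def test_replay_satisfies_accuracy_criterion(self, calibration):
        """Whenever the variance is below the break value, the running estimate
        is within 10 % of the long-run estimate, on every calibration run."""
        bests = []
        logs = []
        for k, obs in enumerate(self.OBSERVERS):
            cfg = SessionConfig(
                grid=GRID, break_value=1e-300, min_trials=120, max_trials=120, rng_seed=31 + k
            )
            r = run_session(obs, cfg)
            logs.append(r.log)
            bests.append(r.threshold_estimate)
        criterion = 0.10 * np.mean(bests)
        for log, best in zip(logs, bests):
            below = log[log["variance"] < calibration]
            assert np.all(np.abs(below["estimate_deg_s"] - best) < criterion)

    def test_stricter_accuracy_gives_smaller_break_value(self, calibration):
        tighter = calibrate_break_value(
            self.OBSERVERS, GRID, accuracy_fraction=0.05, long_run_trials=120, seed=31
        )
        assert tighter <= calibration

    def test_empty_observer_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_break_value([], GRID)
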