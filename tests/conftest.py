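"""Shared fixtures: study conditions, commanded profiles, the bundled fit.

The bisection oracle lives here: it finds the threshold by searching the
stimulus amplitude until the peak firing-rate response crosses the noise
level, independently of the closed-form linear rescaling used by the
package.
"""

import pytest

from canalthresh import (
    CanalParams,
    FitConfig,
    fit_params,
    peak_response,
    profile_provider_commanded,
    table1_dataset,
)


def bisection_threshold(params, profile, lo=1e-4, hi=1e4, tol=1e-9):
    """Brute-force threshold: bisect the amplitude scale of a unit-peak profile
    until the peak response crosses the noise level."""
    unit = profile.scaled(1.0 / profile.peak_velocity)
    f = lambda amp: peak_response(params, unit.scaled(amp)) - params.noise_level
    assert f(lo) < 0 < f(hi), "bracket does not contain the threshold"
    while (hi - lo) / hi > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def table1():
    return table1_dataset()


@pytest.fixture(scope="session")
def conditions(table1):
    return table1.conditions()


@pytest.fixture(scope="session")
def commanded(conditions):
    return profile_provider_commanded(conditions, 1000.0)


@pytest.fixture(scope="session")
def table1_fit(table1):
    """The least-squares fit of the bundled threshold table (commanded profiles)."""
    return fit_params(table1, None, FitConfig())


@pytest.fixture(scope="session")
def reference_params():
    """Canal parameters as estimated from measured (distorted) profiles."""
    return CanalParams(K=0.68, tau1=0.68, tauN=0.030)
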