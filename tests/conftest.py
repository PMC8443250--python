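import numpy as np
import pytest

from extinctrl.hybrid_model import HybridParams, InitialState, simulate_latents
from extinctrl.paradigm import (
    CSType,
    build_acquisition,
    build_day3,
    build_extinction,
    outcomes_for_cs,
)


@pytest.fixture(scope="session")
def day1_schedule():
    return build_acquisition(0)


@pytest.fixture(scope="session")
def day2_schedule():
    return build_extinction(1)


@pytest.fixture(scope="session")
def day3_schedule():
    return build_day3(2)


@pytest.fixture(scope="session")
def extinction_outcomes(day2_schedule):
    return outcomes_for_cs(day2_schedule, CSType.CS_PLUS).astype(float)


@pytest.fixture(scope="session")
def recovery_outcomes():
    """T=500 extinction-structured outcome stream for recovery studies.

    Repeated acquisition -> extinction cycles of the CS+ stream keep
    prediction errors (and therefore the likelihood) informative across the
    whole sequence; a pure all-omission stream flatlines after ~20 trials.
    """
    acq = outcomes_for_cs(
        build_acquisition(0), CSType.CS_PLUS, phases={"acquisition"}
    ).astype(float)
    ext = outcomes_for_cs(build_extinction(0), CSType.CS_PLUS).astype(float)
    cycle = np.concatenate([acq, ext])
    reps = int(np.ceil(500 / cycle.size))
    return np.tile(cycle, reps)[:500]


def naive_nll(alpha, omega, beta, outcomes, ratings, v0=0.75, eta0=1.0, eps=1e-9):
    """Per-trial loop oracle for the Bernoulli negative log-likelihood.

    Written independently of the package kernels: plain Python floats,
    explicit recursion, no vectorisation.
    """
    v, eta = v0, eta0
    total = 0.0
    for ro, r in zip(outcomes, ratings):
        if not np.isnan(r):
            p = 1.0 / (1.0 + np.exp(-v / beta))
            p = min(max(p, eps), 1.0 - eps)
            total -= r * np.log(p) + (1.0 - r) * np.log(1.0 - p)
        pe = ro - v
        v = v + alpha * eta * pe
        eta = omega * abs(pe) + (1.0 - omega) * eta
    return total


def naive_latents(alpha, omega, outcomes, v0=0.75, eta0=1.0):
    """Loop oracle for the latent recursion (independent of the package)."""
    v, eta = v0, eta0
    vs, etas, pes = [], [], []
    for ro in outcomes:
        pe = ro - v
        vs.append(v)
        etas.append(eta)
        pes.append(pe)
        v = v + alpha * eta * pe
        eta = omega * abs(pe) + (1.0 - omega) * eta
    return np.array(vs), np.array(etas), np.array(pes)


@pytest.fixture(scope="session")
def simulated_agent(extinction_outcomes):
    from extinctrl.hybrid_model import simulate_ratings

    params = HybridParams(0.4, 0.3, 1.0)
    traj = simulate_latents(params, extinction_outcomes)
    ratings = simulate_ratings(traj, params.beta, 123).astype(float)
    return params, traj, ratings
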