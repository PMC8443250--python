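"""Rescorla-Wagner / Pearce-Hall hybrid learning model.

Latent recursion for one CS stream, given binary received outcomes RO_t
(1 = US delivered, 0 = US omitted):

    PE_t      = RO_t - v_t
    v_{t+1}   = v_t + alpha * eta_t * PE_t
    eta_{t+1} = omega * |PE_t| + (1 - omega) * eta_t

with v_1 = v0 and eta_1 = eta0 (the associability entering trial 1's update
is the starting associability).  Binary yes/no expectancy reports follow a
logistic observation model p_t = 1 / (1 + exp(-v_t / beta)); note that the
value is *divided* by beta, so larger beta flattens responding.  The fitted
objective is the Bernoulli negative log-likelihood summed over observed
trials; missing reports are masked out but the latents still update (learning
is outcome-driven).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import latents_core, nll_core

__all__ = [
    "HybridParams",
    "InitialState",
    "LatentTrajectory",
    "simulate_latents",
    "response_probability",
    "simulate_ratings",
    "negative_log_likelihood",
    "write_trajectory_csv",
]

MISSING = np.nan

#: initial free-parameter values used by the original fitting procedure
DEFAULT_INIT_PARAMS = (0.5, 0.5, 4.0)


@dataclass(frozen=True)
class HybridParams:
    """The three free parameters of the hybrid model."""

    alpha: float  # learning rate, in [0, 1]
    omega: float  # associability scaling, in [0, 1]
    beta: float   # softmax scale (value is divided by beta), > 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be positive, got {self.beta}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.omega, self.beta)


@dataclass(frozen=True)
class InitialState:
    """Fixed latent starting points.

    The default v0 = 0.75 matches the CS+ reinforcement rate during
    acquisition; eta0 = 1 makes the first update fully prediction-error
    driven.
    """

    v0: float = 0.75
    eta0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.v0 <= 1.0:
            raise ValueError(f"v0 must be in [0, 1], got {self.v0}")
        if not 0.0 <= self.eta0 <= 1.0:
            raise ValueError(f"eta0 must be in [0, 1], got {self.eta0}")


@dataclass(frozen=True)
class LatentTrajectory:
    """Per-trial latent sequences for one CS stream (all length T).

    ``v`` and ``eta`` are the pre-update quantities entering each trial;
    ``v_next`` holds the post-update values v_{t+1}.
    """

    v: np.ndarray
    eta: np.ndarray
    pe: np.ndarray
    v_next: np.ndarray

    def __len__(self) -> int:
        return len(self.v)


def _as_outcomes(outcomes) -> np.ndarray:
    arr = np.asarray(outcomes, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("outcomes must be a non-empty 1-D sequence")
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValueError("outcomes must be binary (0 or 1)")
    return arr


def simulate_latents(
    params: HybridParams,
    outcomes,
    init: InitialState = InitialState(),
) -> LatentTrajectory:
    """Run the value/associability recursion over a binary outcome sequence."""
    ro = _as_outcomes(outcomes)
    v, eta, pe = latents_core(params.alpha, params.omega, ro, init.v0, init.eta0)
    return LatentTrajectory(v=v[:-1], eta=eta[:-1], pe=pe, v_next=v[1:])


def response_probability(v, beta: float):
    """Probability of a 'yes' expectancy report: 1 / (1 + exp(-v / beta))."""
    if not beta > 0.0:
        raise ValueError(f"beta must be positive, got {beta}")
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float) / beta))


def simulate_ratings(
    trajectory: LatentTrajectory, beta: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw Bernoulli yes/no reports from the trajectory's trial-wise values."""
    p = response_probability(trajectory.v, beta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (rng.random(p.shape) < p).astype(int)


def _as_ratings(ratings, n: int) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(ratings, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"ratings must have length {n}, got shape {arr.shape}")
    observed = ~np.isnan(arr)
    vals = arr[observed]
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("observed ratings must be binary (0 or 1)")
    if not observed.any():
        raise ValueError("all ratings are missing; likelihood is undefined")
    return arr, observed


def negative_log_likelihood(
    params: HybridParams,
    outcomes,
    ratings,
    init: InitialState = InitialState(),
) -> float:
    """Bernoulli negative log-likelihood of the observed ratings.

    Missing ratings (NaN) contribute nothing to the sum but the latents
    still update on those trials.  Probabilities are clipped to
    [eps, 1 - eps] with eps = 1e-9 before taking logs.
    """
    ro = _as_outcomes(outcomes)
    arr, observed = _as_ratings(ratings, ro.size)
    clean = np.where(observed, arr, 0.0)
    return float(
        nll_core(
            params.alpha, params.omega, params.beta,
            ro, clean, observed, init.v0, init.eta0,
        )
    )


def write_trajectory_csv(trajectory: LatentTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "trial_index": np.arange(1, len(trajectory) + 1),
            "v": trajectory.v,
            "eta": trajectory.eta,
            "pe": trajectory.pe,
        }
    ).to_csv(path, index=False)
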