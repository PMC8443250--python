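"""Subject- and cohort-level maximum-likelihood estimation.

Parameters are estimated by Nelder-Mead simplex search on an unconstrained
reparameterisation: alpha and omega through a logistic transform, beta
through a log transform capped at BETA_MAX.  The printed initialisation
(0.5, 0.5, 4) is always among the starting points; optional random restarts
are drawn from alpha, omega ~ U(0.1, 0.9) and beta ~ U(0.5, 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from ._kernels import nll_core
from .hybrid_model import (
    DEFAULT_INIT_PARAMS,
    HybridParams,
    InitialState,
    _as_outcomes,
    _as_ratings,
    negative_log_likelihood,
    simulate_latents,
)
from .paradigm import CSType, Day

__all__ = ["FitResult", "fit_subject", "fit_cohort", "BETA_MAX"]

BETA_MAX = 50.0
MIN_OBSERVED = 5
_XATOL = 1e-6
_FATOL = 1e-6
_MAXITER = 2000
_BOUNDARY_TOL = 1e-3


@dataclass(frozen=True)
class FitResult:
    params: HybridParams
    nll: float
    n_trials_used: int
    converged: bool
    n_restarts_used: int
    init_used: HybridParams
    boundary: bool


def _to_x(p: HybridParams) -> np.ndarray:
    return np.array([logit(p.alpha), logit(p.omega), np.log(p.beta)])


def _from_x(x: np.ndarray) -> HybridParams:
    log_beta = min(float(x[2]), np.log(BETA_MAX))
    return HybridParams(
        alpha=float(expit(x[0])),
        omega=float(expit(x[1])),
        beta=float(np.exp(log_beta)),
    )


def _is_boundary(p: HybridParams) -> bool:
    return (
        p.alpha < _BOUNDARY_TOL
        or p.alpha > 1.0 - _BOUNDARY_TOL
        or p.omega < _BOUNDARY_TOL
        or p.omega > 1.0 - _BOUNDARY_TOL
        or p.beta < _BOUNDARY_TOL
        or p.beta > BETA_MAX * (1.0 - 1e-6)
    )


# coarse deterministic pre-scan grid (on the natural scale, interior so the
# logit/log transforms stay finite); the likelihood is multimodal in omega,
# so the scan must be dense enough to seed the right basin
_PRESCAN_ALPHA = (0.002, 0.02, 0.15, 0.3, 0.5, 0.7, 0.85, 0.98, 0.998)
_PRESCAN_OMEGA = (0.002, 0.02, 0.15, 0.3, 0.5, 0.7, 0.85, 0.98, 0.998)
_PRESCAN_BETA = (0.1, 0.3, 0.8, 1.6, 3.2, 8.0, 20.0, 45.0)


def _prescan_starts(objective, n_keep: int = 3) -> list[HybridParams]:
    """Best points of a fixed coarse grid, used as extra simplex starts.

    The likelihood is multimodal in omega (pure-RW and saturated-PH basins),
    so the best point of each omega-extreme slice is always kept alongside
    the overall best points.
    """
    scored = []
    for a in _PRESCAN_ALPHA:
        for w in _PRESCAN_OMEGA:
            for b in _PRESCAN_BETA:
                p = HybridParams(a, w, b)
                scored.append((objective(_to_x(p)), p))
    scored.sort(key=lambda t: t[0])
    starts = [p for _, p in scored[:n_keep]]
    for w_edge in (_PRESCAN_OMEGA[0], _PRESCAN_OMEGA[-1]):
        best_slice = min(
            (s for s in scored if s[1].omega == w_edge), key=lambda t: t[0]
        )[1]
        if best_slice not in starts:
            starts.append(best_slice)
    return starts


def _best_of_starts(objective, starts):
    best = None
    for start in starts:
        res = minimize(
            objective,
            _to_x(start),
            method="Nelder-Mead",
            options=dict(xatol=_XATOL, fatol=_FATOL, maxiter=_MAXITER),
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best[0].fun):
            best = (res, start)
    if best is None:
        raise RuntimeError("likelihood was non-finite at every starting point")
    # polish: restart the simplex at the incumbent optimum; a fresh simplex
    # often escapes premature collapse
    for _ in range(3):
        res, start = best
        res2 = minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            options=dict(xatol=_XATOL, fatol=_FATOL, maxiter=_MAXITER),
        )
        if np.isfinite(res2.fun) and res2.fun < res.fun - _FATOL:
            best = (res2, start)
        else:
            break
    return best


def fit_subject(
    outcomes,
    ratings,
    init: HybridParams | tuple = DEFAULT_INIT_PARAMS,
    state: InitialState = InitialState(),
    restarts: int = 0,
    seed: int | None = None,
    grid_prescan: bool = True,
) -> FitResult:
    """Fit (alpha, omega, beta) to one subject's binary ratings by MLE.

    The printed initialisation is always used; a deterministic coarse-grid
    pre-scan contributes two further simplex starts (disable with
    ``grid_prescan=False``), and ``restarts`` adds seeded random restarts.
    The best of all runs is returned.  Requires at least 5 observed ratings.
    """
    if not isinstance(init, HybridParams):
        init = HybridParams(*init)
    # validate once; the optimiser objective then calls the kernel directly
    ro = _as_outcomes(outcomes)
    arr, observed = _as_ratings(np.asarray(ratings, dtype=float), ro.size)
    n_obs = int(observed.sum())
    if n_obs < MIN_OBSERVED:
        raise ValueError(
            f"need at least {MIN_OBSERVED} observed ratings, got {n_obs}"
        )
    clean = np.where(observed, arr, 0.0)

    def objective(x: np.ndarray) -> float:
        p = _from_x(x)
        return nll_core(
            p.alpha, p.omega, p.beta, ro, clean, observed, state.v0, state.eta0
        )

    starts = list(_prescan_starts(objective)) if grid_prescan else []
    starts.insert(0, init)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            starts.append(
                HybridParams(
                    alpha=float(rng.uniform(0.1, 0.9)),
                    omega=float(rng.uniform(0.1, 0.9)),
                    beta=float(rng.uniform(0.5, 4.0)),
                )
            )

    res, start_used = _best_of_starts(objective, starts)
    params = _from_x(res.x)
    return FitResult(
        params=params,
        nll=float(res.fun),
        n_trials_used=n_obs,
        converged=bool(res.success),
        n_restarts_used=restarts,
        init_used=start_used,
        boundary=_is_boundary(params),
    )


def fit_cohort(
    datasets,
    restarts: int = 0,
    seed: int | None = None,
    streams: str = "csplus",
) -> pd.DataFrame:
    """Fit every subject in a cohort on day-2 extinction trials.

    ``streams='csplus'`` fits CS+ trials only (v0 = 0.75); ``'both'`` fits
    CS+ and CS- as two independent streams sharing one parameter set
    (CS- starts at v0 = 0).  Per-subject failures are returned as flagged
    rows rather than raised.

    Returns one row per subject with the fitted parameters plus the
    trial-averaged prediction error, associability, and effective learning
    rate (alpha * eta) used for group comparisons.
    """
    if streams not in ("csplus", "both"):
        raise ValueError(f"streams must be 'csplus' or 'both', got {streams!r}")
    rows = []
    rng = np.random.default_rng(seed)
    for ds in datasets:
        sub_seed = int(rng.integers(2**31)) if restarts > 0 else None
        row: dict = {"subject": ds.subject, "group": ds.group}
        try:
            outcomes = np.asarray(ds.outcomes(Day.DAY2, CSType.CS_PLUS), dtype=float)
            ratings = np.asarray(ds.ratings_for(Day.DAY2, CSType.CS_PLUS), dtype=float)
            if streams == "both":
                # independent streams sharing (alpha, omega, beta)
                out_m = np.asarray(ds.outcomes(Day.DAY2, CSType.CS_MINUS), dtype=float)
                rat_m = np.asarray(ds.ratings_for(Day.DAY2, CSType.CS_MINUS), dtype=float)
                fit = _fit_two_streams(
                    outcomes, ratings, out_m, rat_m, restarts, sub_seed
                )
            else:
                fit = fit_subject(outcomes, ratings, restarts=restarts, seed=sub_seed)
            traj = simulate_latents(fit.params, outcomes)
            row.update(
                alpha=fit.params.alpha,
                omega=fit.params.omega,
                beta=fit.params.beta,
                nll=fit.nll,
                n_trials=fit.n_trials_used,
                converged=fit.converged,
                boundary=fit.boundary,
                mean_pe=float(np.mean(traj.pe)),
                mean_assoc=float(np.mean(traj.eta)),
                mean_learning_rate=float(np.mean(fit.params.alpha * traj.eta)),
                error="",
            )
        except (ValueError, RuntimeError) as exc:
            row.update(
                alpha=np.nan, omega=np.nan, beta=np.nan, nll=np.nan,
                n_trials=0, converged=False, boundary=False,
                mean_pe=np.nan, mean_assoc=np.nan, mean_learning_rate=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_two_streams(out_p, rat_p, out_m, rat_m, restarts, seed) -> FitResult:
    state_p = InitialState(v0=0.75, eta0=1.0)
    state_m = InitialState(v0=0.0, eta0=1.0)
    n_obs = int(np.sum(~np.isnan(rat_p)) + np.sum(~np.isnan(rat_m)))
    if n_obs < MIN_OBSERVED:
        raise ValueError(f"need at least {MIN_OBSERVED} observed ratings, got {n_obs}")

    def objective(x: np.ndarray) -> float:
        p = _from_x(x)
        return negative_log_likelihood(p, out_p, rat_p, state_p) + (
            negative_log_likelihood(p, out_m, rat_m, state_m)
        )

    starts = [HybridParams(*DEFAULT_INIT_PARAMS)] + _prescan_starts(objective)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            starts.append(
                HybridParams(
                    alpha=float(rng.uniform(0.1, 0.9)),
                    omega=float(rng.uniform(0.1, 0.9)),
                    beta=float(rng.uniform(0.5, 4.0)),
                )
            )
    res, start_used = _best_of_starts(objective, starts)
    params = _from_x(res.x)
    return FitResult(
        params=params, nll=float(res.fun), n_trials_used=n_obs,
        converged=bool(res.success), n_restarts_used=restarts,
        init_used=start_used, boundary=_is_boundary(params),
    )
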