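"""Two-path causal mediation analysis.

The mediator model M ~ 1 + T and the outcome model Y ~ 1 + T + M are fit by
OLS (treatment coded Placebo = 0, L-DOPA = 1, no treatment-mediator
interaction).  The average causal mediation effect (ACME) is the product of
the treatment->mediator coefficient ``a`` and the mediator->outcome
coefficient ``b``; uncertainty comes either from quasi-Bayesian draws of the
coefficients from each model's asymptotic normal (independently across the
two models) or from a nonparametric bootstrap over subjects.  Point
estimates are medians of the draws; intervals are percentile intervals; the
two-sided Monte-Carlo p-value is floored at 1/n_draws.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "PathFit",
    "MediationResult",
    "fit_paths",
    "acme_quasi_bayesian",
    "acme_bootstrap",
]

MIN_DRAWS = 100


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and their covariance; raises on rank deficiency."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - k
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    # pinv: near-singular (but full-rank) designs from degenerate simulated
    # data should degrade gracefully rather than raise
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return coef, cov


@dataclass(frozen=True)
class PathFit:
    """OLS coefficients of the mediator and outcome models."""

    a: float          # T -> M
    b: float          # M -> Y, adjusted for T
    c: float          # total effect, Y ~ 1 + T
    c_prime: float    # direct effect, T coefficient in Y ~ 1 + T + M
    se_a: float
    se_b: float
    se_c: float
    se_c_prime: float
    mediator_coefs: np.ndarray   # (intercept, a)
    mediator_cov: np.ndarray
    outcome_coefs: np.ndarray    # (intercept, c_prime, b)
    outcome_cov: np.ndarray
    n: int


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    acme: float
    acme_mean: float
    ade: float
    total: float
    ci_low: float
    ci_high: float
    level: float
    p: float
    n_draws: int
    method: str
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_inputs(treatment, mediator, outcome):
    t = np.asarray(treatment, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (t.shape == m.shape == y.shape) or t.ndim != 1:
        raise ValueError("treatment, mediator and outcome must be equal-length 1-D")
    if t.size < 6:
        raise ValueError("need at least 6 subjects")
    if np.unique(t).size < 2:
        raise ValueError("treatment must have both levels")
    return t, m, y


def fit_paths(treatment, mediator, outcome) -> PathFit:
    """Fit the mediator and outcome regressions and extract path coefficients."""
    t, m, y = _validate_inputs(treatment, mediator, outcome)
    ones = np.ones_like(t)
    Xm = np.column_stack([ones, t])
    med_coef, med_cov = _ols(Xm, m)
    Xy = np.column_stack([ones, t, m])
    out_coef, out_cov = _ols(Xy, y)
    tot_coef, tot_cov = _ols(Xm, y)
    return PathFit(
        a=float(med_coef[1]),
        b=float(out_coef[2]),
        c=float(tot_coef[1]),
        c_prime=float(out_coef[1]),
        se_a=float(np.sqrt(med_cov[1, 1])),
        se_b=float(np.sqrt(out_cov[2, 2])),
        se_c=float(np.sqrt(tot_cov[1, 1])),
        se_c_prime=float(np.sqrt(out_cov[1, 1])),
        mediator_coefs=med_coef,
        mediator_cov=med_cov,
        outcome_coefs=out_coef,
        outcome_cov=out_cov,
        n=t.size,
    )


def _summarise(
    acme_draws: np.ndarray,
    ade_draws: np.ndarray,
    paths: PathFit,
    level: float,
    method: str,
    seed: int | None,
) -> MediationResult:
    n_draws = acme_draws.size
    lo, hi = np.percentile(acme_draws, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    point = float(np.median(acme_draws))
    if point == 0.0:
        p = 1.0  # degenerate product, matches the zero-estimate convention
    else:
        p_pos = float(np.mean(acme_draws > 0))
        p_neg = float(np.mean(acme_draws < 0))
        p = min(max(2 * min(p_pos, p_neg), 1.0 / n_draws), 1.0)
    return MediationResult(
        a=paths.a,
        b=paths.b,
        c=paths.c,
        c_prime=paths.c_prime,
        acme=float(np.median(acme_draws)),
        acme_mean=float(np.mean(acme_draws)),
        ade=float(np.median(ade_draws)),
        total=float(np.median(acme_draws + ade_draws)),
        ci_low=float(min(lo, np.median(acme_draws))),
        ci_high=float(max(hi, np.median(acme_draws))),
        level=level,
        p=p,
        n_draws=n_draws,
        method=method,
        seed=seed,
    )


def acme_quasi_bayesian(
    paths: PathFit,
    n_draws: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> MediationResult:
    """Monte-Carlo ACME from normal approximations to the two fitted models."""
    if n_draws < MIN_DRAWS:
        raise ValueError(f"n_draws must be >= {MIN_DRAWS}")
    if not (np.all(np.isfinite(paths.mediator_cov)) and np.all(np.isfinite(paths.outcome_cov))):
        raise ValueError("path covariance is not finite")
    rng = np.random.default_rng(seed)
    med = rng.multivariate_normal(paths.mediator_coefs, paths.mediator_cov, size=n_draws)
    out = rng.multivariate_normal(paths.outcome_coefs, paths.outcome_cov, size=n_draws)
    acme_draws = med[:, 1] * out[:, 2]
    ade_draws = out[:, 1]
    return _summarise(acme_draws, ade_draws, paths, level, "quasi_bayesian", seed)


def acme_bootstrap(
    treatment,
    mediator,
    outcome,
    n_draws: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    max_retries: int = 100,
) -> MediationResult:
    """Nonparametric bootstrap over subjects, refitting both regressions."""
    if n_draws < MIN_DRAWS:
        raise ValueError(f"n_draws must be >= {MIN_DRAWS}")
    t, m, y = _validate_inputs(treatment, mediator, outcome)
    paths = fit_paths(t, m, y)
    rng = np.random.default_rng(seed)
    n = t.size
    acme_draws = np.empty(n_draws)
    ade_draws = np.empty(n_draws)
    for i in range(n_draws):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            if np.unique(t[idx]).size >= 2:
                break
        else:
            raise RuntimeError("could not draw a two-level bootstrap resample")
        tb, mb, yb = t[idx], m[idx], y[idx]
        ones = np.ones(n)
        a_b = _ols(np.column_stack([ones, tb]), mb)[0][1]
        out_coef = _ols(np.column_stack([ones, tb, mb]), yb)[0]
        acme_draws[i] = a_b * out_coef[2]
        ade_draws[i] = out_coef[1]
    return _summarise(acme_draws, ade_draws, paths, level, "bootstrap", seed)
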