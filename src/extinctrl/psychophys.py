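"""Skin-conductance and fear-rating post-processing and contrasts.

Amplitudes are log-transformed as ln(1 + x) (zero-scored non-reactions make
a bare log undefined) and range-corrected by the per-subject-per-day maximum
across both CS types.  VAS fear ratings are range-corrected by the daily
maximum.  Trial series are averaged in blocks of eight; reinstatement
effects are quantified as means over the last/first k trials around the
unsignalled USs (k = 3 by default, k = 8 for whole-block mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "log_range_correct",
    "range_correct_rating",
    "correct_scr_table",
    "correct_rating_table",
    "block_average",
    "differential",
    "reinstatement_contrast",
    "ReinstatementContrast",
    "group_test",
    "GroupTestResult",
    "holm_correct",
    "pearson_correlation",
    "PearsonResult",
    "exclude_incomplete",
]


def log_range_correct(amplitudes) -> np.ndarray:
    """ln(1 + x) then division by the maximum, for one subject-day.

    The input should pool both CS types for that subject and day.  Missing
    trials (NaN) are ignored by the maximum and propagate through.  An
    all-zero (or all-missing) day is returned as zeros.
    """
    amp = np.asarray(amplitudes, dtype=float)
    finite = amp[~np.isnan(amp)]
    if finite.size and finite.min() < 0:
        raise ValueError("amplitudes must be non-negative")
    logged = np.log1p(amp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peak = np.nanmax(logged) if np.any(~np.isnan(logged)) else 0.0
    if not peak > 0:
        return np.where(np.isnan(amp), np.nan, 0.0)
    return logged / peak


def range_correct_rating(ratings) -> np.ndarray:
    """Divide VAS ratings (0-100) by the day's maximum rating."""
    r = np.asarray(ratings, dtype=float)
    finite = r[~np.isnan(r)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ValueError("VAS ratings must lie in [0, 100]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peak = np.nanmax(r) if finite.size else 0.0
    if not peak > 0:
        return np.where(np.isnan(r), np.nan, 0.0)
    return r / peak


def _correct_table(df: pd.DataFrame, func) -> pd.DataFrame:
    out = df.copy()
    out["corrected"] = np.nan
    for _, idx in df.groupby(["subject", "day"]).groups.items():
        out.loc[idx, "corrected"] = func(df.loc[idx, "value"].to_numpy())
    return out


def correct_scr_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`log_range_correct` per subject-day on a tidy SCR table.

    Expects columns ``subject``, ``day``, ``trial_index``, ``cs_type``,
    ``value``; adds ``corrected``.
    """
    return _correct_table(df, log_range_correct)


def correct_rating_table(df: pd.DataFrame) -> pd.DataFrame:
    return _correct_table(df, range_correct_rating)


def block_average(values, block_size: int = 8) -> np.ndarray:
    """Per-block means ignoring missing values; all-missing block -> NaN.

    A trailing partial block is averaged and flagged with a warning.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    v = np.asarray(values, dtype=float)
    n_full, rem = divmod(v.size, block_size)
    if rem:
        warnings.warn(
            f"trailing partial block of {rem} trials", UserWarning, stacklevel=2
        )
    blocks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_full + (1 if rem else 0)):
            blocks.append(np.nanmean(v[i * block_size : (i + 1) * block_size]))
    return np.asarray(blocks)


def differential(csplus, csminus) -> np.ndarray:
    """Element-wise CS+ minus CS-."""
    a = np.asarray(csplus, dtype=float)
    b = np.asarray(csminus, dtype=float)
    if a.shape != b.shape:
        raise ValueError("CS+ and CS- series must have equal length")
    return a - b


@dataclass(frozen=True)
class ReinstatementContrast:
    pre_csplus: float
    post_csplus: float
    pre_csminus: float
    post_csminus: float
    k: int

    @property
    def pre_differential(self) -> float:
        return self.pre_csplus - self.pre_csminus

    @property
    def post_differential(self) -> float:
        return self.post_csplus - self.post_csminus


def reinstatement_contrast(
    pre_csplus, pre_csminus, post_csplus, post_csminus, k: int = 3
) -> ReinstatementContrast:
    """Mean of the last k pre- and first k post-reinstatement trials per CS.

    ``k=3`` targets the transient reinstatement window; ``k=8`` averages the
    whole flanking block.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    series = dict(
        pre_csplus=pre_csplus, pre_csminus=pre_csminus,
        post_csplus=post_csplus, post_csminus=post_csminus,
    )
    means = {}
    for name, s in series.items():
        arr = np.asarray(s, dtype=float)
        if arr.size < k:
            raise ValueError(f"{name} has {arr.size} trials, fewer than k={k}")
        window = arr[-k:] if name.startswith("pre") else arr[:k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means[name] = float(np.nanmean(window))
    return ReinstatementContrast(k=k, **means)


@dataclass(frozen=True)
class GroupTestResult:
    t: float
    p: float
    cohens_d: float
    df: float
    sided: str


def group_test(
    values_a, values_b, sided: str = "two-sided", equal_var: bool = True
) -> GroupTestResult:
    """Independent-samples t-test (pooled by default) with Cohen's d.

    ``sided`` is ``'two-sided'``, ``'less'`` (mean_a < mean_b) or
    ``'greater'``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=sided)
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return GroupTestResult(
        t=float(res.statistic), p=float(res.pvalue), cohens_d=float(d),
        df=float(res.df), sided=sided,
    )


def holm_correct(pvalues) -> np.ndarray:
    """Holm step-down family-wise correction."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


@dataclass(frozen=True)
class PearsonResult:
    r: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    n: int


def pearson_correlation(x, y, level: float = 0.95) -> PearsonResult:
    """Two-sided Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x and y with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    n = x.size
    r, p = stats.pearsonr(x, y)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    z = np.arctanh(r)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    halfwidth = zcrit / np.sqrt(n - 3)
    return PearsonResult(
        r=float(r), t=float(t), p=float(p),
        ci_low=float(np.tanh(z - halfwidth)),
        ci_high=float(np.tanh(z + halfwidth)),
        n=n,
    )


def exclude_incomplete(
    df: pd.DataFrame, max_missing_frac: float = 1 / 3
) -> pd.DataFrame:
    """Drop subject-days whose fraction of missing values exceeds the cutoff."""
    keep = []
    for key, idx in df.groupby(["subject", "day"]).groups.items():
        vals = df.loc[idx, "value"]
        if vals.isna().mean() <= max_missing_frac:
            keep.extend(idx)
    return df.loc[sorted(keep)].reset_index(drop=True)
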