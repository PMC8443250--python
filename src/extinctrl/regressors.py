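"""First-level design construction and OLS estimation at desk scale.

Events are modelled as zero-duration sticks on an oversampled time grid,
convolved with a canonical double-gamma haemodynamic response and sampled
at the scan times (default TR = 1.493 s).  Parametric modulators are
mean-centred and placed on their parent events; the associability modulator
is residualised on the prediction-error modulator *before* convolution.
High-pass filtering, autocorrelation modelling and nuisance regressors are
deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .hybrid_model import LatentTrajectory
from .paradigm import CSType, SessionSchedule, US_OFFSET_S

__all__ = [
    "DesignMatrix",
    "group_mean_modulators",
    "orthogonalize",
    "canonical_hrf",
    "build_design",
    "fit_first_level",
    "FirstLevelResult",
    "write_design",
    "read_design",
]

DEFAULT_TR_S = 1.493
_OVERSAMPLE = 16


@dataclass
class DesignMatrix:
    times_s: np.ndarray      # scan-onset grid, length n_scans
    columns: np.ndarray      # n_scans x n_regressors
    names: list[str]
    TR_s: float

    @property
    def n_scans(self) -> int:
        return self.columns.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.columns[:, self.names.index(name)]


def group_mean_modulators(
    trajectories: Sequence[LatentTrajectory],
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-aligned sample means of PE and associability across subjects."""
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    lengths = {len(t) for t in trajectories}
    if len(lengths) != 1:
        raise ValueError(f"trajectories differ in length: {sorted(lengths)}")
    pe = np.mean([t.pe for t in trajectories], axis=0)
    assoc = np.mean([t.eta for t in trajectories], axis=0)
    return pe, assoc


def orthogonalize(x, wrt) -> np.ndarray:
    """Residualise ``x`` on ``wrt`` (both mean-centred first)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(wrt, dtype=float)
    if x.shape != w.shape:
        raise ValueError("x and wrt must have the same length")
    xc = x - x.mean()
    wc = w - w.mean()
    denom = wc @ wc
    if denom < 1e-30:
        raise ValueError("wrt is constant (zero after mean-centring)")
    return xc - (xc @ wc) / denom * wc


def canonical_hrf(TR_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma HRF sampled at TR, peak-normalised to 1.

    Response gamma peaks near 5-6 s, undershoot near 16 s, undershoot
    ratio 1/6.
    """
    if not TR_s > 0:
        raise ValueError("TR_s must be positive")
    t = np.arange(0.0, duration_s, TR_s)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.max()


def _stick_convolve(
    onsets: np.ndarray,
    weights: np.ndarray,
    n_scans: int,
    TR_s: float,
) -> np.ndarray:
    dt = TR_s / _OVERSAMPLE
    n_fine = n_scans * _OVERSAMPLE
    fine = np.zeros(n_fine)
    idx = np.round(np.asarray(onsets) / dt).astype(int)
    if np.any(idx < 0) or np.any(idx >= n_fine):
        raise ValueError("event onsets fall outside the scan window")
    np.add.at(fine, idx, weights)
    t = np.arange(0.0, 32.0, dt)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    h = h / h.max()
    conv = np.convolve(fine, h)[:n_fine]
    return conv[:: _OVERSAMPLE]


def build_design(
    schedule: SessionSchedule,
    modulators: Mapping[str, tuple[str, Sequence[float]]],
    n_scans: int,
    TR_s: float = DEFAULT_TR_S,
) -> DesignMatrix:
    """Build a first-level design for one session.

    Base columns are unit sticks at CS+ onsets, CS- onsets, and US-omission
    time-points (CS+ onset + 5 s on unreinforced CS+ trials), each convolved
    with the canonical HRF, plus an intercept.  ``modulators`` maps a column
    name to ``(parent, values)`` where parent is one of ``'csplus'``,
    ``'csminus'``, ``'us_omission'``; values are mean-centred and placed on
    the parent's events.
    """
    csplus = [e.onset_s for e in schedule.events if e.cs_type is CSType.CS_PLUS]
    csminus = [e.onset_s for e in schedule.events if e.cs_type is CSType.CS_MINUS]
    omission = [
        e.onset_s + US_OFFSET_S
        for e in schedule.events
        if e.cs_type is CSType.CS_PLUS and not e.reinforced
    ]
    parents = {
        "csplus": np.asarray(csplus),
        "csminus": np.asarray(csminus),
        "us_omission": np.asarray(omission),
    }
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name, onsets in parents.items():
        names.append(name)
        cols.append(_stick_convolve(onsets, np.ones(onsets.size), n_scans, TR_s))
    for name, (parent, values) in modulators.items():
        if parent not in parents:
            raise ValueError(f"unknown parent stream {parent!r}")
        vals = np.asarray(values, dtype=float)
        if vals.size != parents[parent].size:
            raise ValueError(
                f"modulator {name!r} has {vals.size} values for "
                f"{parents[parent].size} {parent} events"
            )
        centred = vals - vals.mean()
        names.append(name)
        cols.append(_stick_convolve(parents[parent], centred, n_scans, TR_s))
    names.append("intercept")
    cols.append(np.ones(n_scans))
    return DesignMatrix(
        times_s=np.arange(n_scans) * TR_s,
        columns=np.column_stack(cols),
        names=names,
        TR_s=TR_s,
    )


@dataclass
class FirstLevelResult:
    betas: np.ndarray        # n_regressors x n_voxels
    sigma2: np.ndarray       # residual variance per voxel
    dof: int
    xtx_inv: np.ndarray
    names: list[str]

    def contrast(self, c) -> tuple[np.ndarray, np.ndarray]:
        """Return (c'beta, t-statistic) per voxel."""
        c = np.asarray(c, dtype=float)
        est = c @ self.betas
        var = (c @ self.xtx_inv @ c) * self.sigma2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, est / np.sqrt(var), 0.0)
        return est, t


def fit_first_level(Y, X: DesignMatrix) -> FirstLevelResult:
    """Ordinary least squares per voxel; errors name collinear columns."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    M = X.columns
    if Y.shape[0] != M.shape[0]:
        raise ValueError(
            f"Y has {Y.shape[0]} rows but the design has {M.shape[0]} scans"
        )
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # locate near-dependent columns via the R diagonal of a pivoted QR
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        bad = [X.names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    betas, _, _, _ = np.linalg.lstsq(M, Y, rcond=None)
    resid = Y - M @ betas
    dof = M.shape[0] - M.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(M.T @ M)
    return FirstLevelResult(
        betas=betas, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv, names=list(X.names)
    )


def write_design(design: DesignMatrix, tsv_path: str | Path) -> None:
    """TSV of regressor columns plus a JSON sidecar (names, TR)."""
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(design.columns, columns=design.names)
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    sidecar = tsv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"names": design.names, "TR_s": design.TR_s}, indent=2)
    )


def read_design(tsv_path: str | Path) -> DesignMatrix:
    tsv_path = Path(tsv_path)
    meta = json.loads(tsv_path.with_suffix(".json").read_text())
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    cols = df[meta["names"]].to_numpy(dtype=float)
    return DesignMatrix(
        times_s=np.arange(cols.shape[0]) * meta["TR_s"],
        columns=cols,
        names=list(meta["names"]),
        TR_s=float(meta["TR_s"]),
    )
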