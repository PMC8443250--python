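"""Ground-truth cohort generation for end-to-end pipeline testing.

A cohort consists of two groups (placebo = 0, ldopa = 1).  Each subject gets
seeded three-day schedules, hybrid-model parameters drawn on transformed
scales (logit for alpha/omega, log for beta), simulated binary expectancy
ratings, SCR trial series built as a monotone function of the latent value,
a vmPFC proxy shifted by group, and a differential-SCR retrieval score that
depends on the vmPFC proxy (mediated group effect).  Default mediation
coefficients reproduce an indirect-only group effect of realistic size.

By default the two groups share identical learning-parameter distributions;
``group_param_shift`` injects a shift for power studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import psychophys
from .hybrid_model import (
    HybridParams,
    InitialState,
    LatentTrajectory,
    response_probability,
    simulate_latents,
    simulate_ratings,
)
from .paradigm import (
    CSType,
    Day,
    SessionSchedule,
    build_acquisition,
    build_day3,
    build_extinction,
    outcomes_for_cs,
    write_events_tsv,
)
from .regressors import DesignMatrix

__all__ = [
    "CohortConfig",
    "SubjectDataset",
    "generate_cohort",
    "generate_agent",
    "generate_bold",
    "write_cohort",
]

GROUPS = ("placebo", "ldopa")

# Default mediation magnitudes for the synthetic generator.
DEFAULT_A = -2.2957        # group -> vmPFC proxy
DEFAULT_B = -0.01898       # vmPFC proxy -> differential SCR
DEFAULT_DIRECT = 0.02644   # residual direct group effect


@dataclass
class CohortConfig:
    n_placebo: int = 22
    n_ldopa: int = 24
    # (logit alpha, logit omega, log beta) population means and SDs
    param_means: tuple[float, float, float] = (0.0, 0.0, np.log(2.0))
    param_sds: tuple[float, float, float] = (0.8, 0.8, 0.4)
    # additive shift applied to the ldopa group's transformed means
    group_param_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    direct: float = DEFAULT_DIRECT
    vmpfc_intercept: float = 0.0
    scr_diff_intercept: float = 0.3
    vmpfc_noise_sd: float = 1.3
    scr_outcome_noise_sd: float = 0.05
    scr_trial_noise_sd: float = 0.1
    missing_rate: float = 0.0
    master_seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_placebo < 2 or self.n_ldopa < 2:
            problems.append("group sizes must be >= 2")
        for name in ("param_sds",):
            if any(s < 0 for s in getattr(self, name)):
                problems.append(f"{name} must be non-negative")
        for name in ("vmpfc_noise_sd", "scr_outcome_noise_sd", "scr_trial_noise_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            problems.append("missing_rate must be in [0, 1)")
        if self.master_seed < 0:
            problems.append("master_seed must be non-negative")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))


@dataclass
class SubjectDataset:
    subject: str
    group: str  # 'placebo' or 'ldopa'
    schedules: dict[Day, SessionSchedule]
    true_params: HybridParams
    ratings: dict[Day, dict[CSType, np.ndarray]]
    scr: dict[Day, dict[CSType, np.ndarray]]  # range-corrected trial series
    fear_ratings: dict[Day, dict[CSType, np.ndarray]]  # (start, end) VAS
    vmpfc: float
    scr_diff_retrieval: float

    @property
    def group_code(self) -> int:
        return GROUPS.index(self.group)

    def outcomes(self, day: Day, cs_type: CSType) -> np.ndarray:
        phases = None if day is not Day.DAY1 else {"acquisition"}
        return outcomes_for_cs(self.schedules[day], cs_type, phases=phases)

    def ratings_for(self, day: Day, cs_type: CSType) -> np.ndarray:
        return self.ratings[day][cs_type]


def _draw_params(rng: np.random.Generator, config: CohortConfig, group: str) -> HybridParams:
    means = np.asarray(config.param_means, dtype=float)
    if group == "ldopa":
        means = means + np.asarray(config.group_param_shift, dtype=float)
    z = rng.normal(means, config.param_sds)
    return HybridParams(
        alpha=float(expit(z[0])), omega=float(expit(z[1])),
        beta=float(np.exp(z[2])),
    )


def _simulate_day(
    rng: np.random.Generator,
    params: HybridParams,
    schedule: SessionSchedule,
    config: CohortConfig,
) -> tuple[dict, dict, dict]:
    """Ratings, corrected SCR and fear ratings for both CS streams of a day."""
    phases = {"acquisition"} if schedule.day is Day.DAY1 else None
    ratings: dict[CSType, np.ndarray] = {}
    raw_scr: dict[CSType, np.ndarray] = {}
    fear: dict[CSType, np.ndarray] = {}
    values: dict[CSType, np.ndarray] = {}
    for cs, v0 in ((CSType.CS_PLUS, 0.75), (CSType.CS_MINUS, 0.0)):
        ro = outcomes_for_cs(schedule, cs, phases=phases)
        traj = simulate_latents(params, ro, InitialState(v0=v0, eta0=1.0))
        r = simulate_ratings(traj, params.beta, rng).astype(float)
        if config.missing_rate > 0:
            r[rng.random(r.shape) < config.missing_rate] = np.nan
        ratings[cs] = r
        values[cs] = traj.v
        # monotone SCR link: amplitude rises with the latent value
        amp = np.clip(
            0.1 + 1.0 * traj.v + rng.normal(0.0, config.scr_trial_noise_sd, traj.v.shape),
            0.0, None,
        )
        raw_scr[cs] = amp
        fear[cs] = np.clip(
            100.0 * np.array([traj.v[0], traj.v[-1]]) + rng.normal(0, 5.0, 2),
            0.0, 100.0,
        )
    # range correction pools both CS types within the day
    pooled = np.concatenate([raw_scr[CSType.CS_PLUS], raw_scr[CSType.CS_MINUS]])
    corrected = psychophys.log_range_correct(pooled)
    n_plus = raw_scr[CSType.CS_PLUS].size
    scr = {
        CSType.CS_PLUS: corrected[:n_plus],
        CSType.CS_MINUS: corrected[n_plus:],
    }
    return ratings, scr, fear


def generate_cohort(config: CohortConfig | None = None) -> list[SubjectDataset]:
    """Generate a fully reproducible two-group cohort."""
    config = config or CohortConfig()
    config.validate()
    subjects: list[SubjectDataset] = []
    counts = {"placebo": config.n_placebo, "ldopa": config.n_ldopa}
    idx = 0
    for group in GROUPS:
        for _ in range(counts[group]):
            rng = np.random.default_rng([config.master_seed, idx])
            sched_seed = int(rng.integers(2**31))
            schedules = {
                Day.DAY1: build_acquisition(sched_seed),
                Day.DAY2: build_extinction(sched_seed),
                Day.DAY3: build_day3(sched_seed),
            }
            params = _draw_params(rng, config, group)
            ratings, scr, fear = {}, {}, {}
            for day in (Day.DAY1, Day.DAY2, Day.DAY3):
                ratings[day], scr[day], fear[day] = _simulate_day(
                    rng, params, schedules[day], config
                )
            g = GROUPS.index(group)
            vmpfc = (
                config.vmpfc_intercept + config.a * g
                + rng.normal(0.0, config.vmpfc_noise_sd)
            )
            scr_diff = (
                config.scr_diff_intercept + config.direct * g
                + config.b * vmpfc
                + rng.normal(0.0, config.scr_outcome_noise_sd)
            )
            subjects.append(
                SubjectDataset(
                    subject=f"sub-{idx + 1:03d}",
                    group=group,
                    schedules=schedules,
                    true_params=params,
                    ratings=ratings,
                    scr=scr,
                    fear_ratings=fear,
                    vmpfc=float(vmpfc),
                    scr_diff_retrieval=float(scr_diff),
                )
            )
            idx += 1
    return subjects


def generate_agent(
    params: HybridParams,
    schedule: SessionSchedule,
    seed: int,
    cs_type: CSType = CSType.CS_PLUS,
    init: InitialState = InitialState(),
) -> tuple[np.ndarray, LatentTrajectory]:
    """Simulate one agent's ratings over a schedule's outcome stream."""
    phases = {"acquisition"} if schedule.day is Day.DAY1 else None
    ro = outcomes_for_cs(schedule, cs_type, phases=phases)
    traj = simulate_latents(params, ro, init)
    ratings = simulate_ratings(traj, params.beta, seed)
    return ratings, traj


def generate_bold(
    X: DesignMatrix, betas, noise_sd: float, seed: int | None = None
) -> np.ndarray:
    """Y = X beta + white noise on the scan grid."""
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] != X.columns.shape[1]:
        raise ValueError(
            f"betas has {betas.shape[0]} entries for {X.columns.shape[1]} columns"
        )
    rng = np.random.default_rng(seed)
    signal = X.columns @ betas
    return signal + rng.normal(0.0, noise_sd, signal.shape)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

_DAY_NUM = {Day.DAY1: 1, Day.DAY2: 2, Day.DAY3: 3}


def write_cohort(subjects: list[SubjectDataset], out_dir: str | Path) -> None:
    """Emit events TSVs, ratings/SCR CSVs, a mediation CSV and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rating_rows, scr_rows, med_rows, truth = [], [], [], {}
    for ds in subjects:
        subj_dir = out / ds.subject
        subj_dir.mkdir(exist_ok=True)
        for day, schedule in ds.schedules.items():
            write_events_tsv(
                schedule, subj_dir / f"events_day{_DAY_NUM[day]}.tsv"
            )
        for day in ds.ratings:
            for cs in ds.ratings[day]:
                for i, val in enumerate(ds.ratings[day][cs], start=1):
                    rating_rows.append(
                        dict(
                            subject=ds.subject, day=_DAY_NUM[day],
                            trial_index=i, cs_type=cs.value,
                            rating=("n/a" if np.isnan(val) else int(val)),
                        )
                    )
                for i, val in enumerate(ds.scr[day][cs], start=1):
                    scr_rows.append(
                        dict(
                            subject=ds.subject, group=ds.group,
                            day=_DAY_NUM[day], trial_index=i,
                            cs_type=cs.value, value=val,
                        )
                    )
        med_rows.append(
            dict(
                subject=ds.subject, group=ds.group,
                vmpfc=ds.vmpfc, scr_diff=ds.scr_diff_retrieval,
            )
        )
        truth[ds.subject] = dict(
            group=ds.group,
            alpha=ds.true_params.alpha,
            omega=ds.true_params.omega,
            beta=ds.true_params.beta,
            vmpfc=ds.vmpfc,
            scr_diff_retrieval=ds.scr_diff_retrieval,
        )
    pd.DataFrame(rating_rows).to_csv(out / "ratings.csv", index=False)
    pd.DataFrame(scr_rows).to_csv(out / "scr.csv", index=False)
    pd.DataFrame(med_rows).to_csv(out / "mediation.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
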