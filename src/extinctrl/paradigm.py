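"""Three-day fear-conditioning trial schedules.

Day 1: habituation (3 CS+ / 3 CS-, never reinforced) followed by acquisition
training (24 CS+ / 24 CS-, 18 CS+ reinforced) in context A.
Day 2: extinction training (24 CS+ / 24 CS-, nothing reinforced) in context B.
Day 3: retrieval test (8 + 8), four unsignalled reinstatement USs, then a
reinstatement test (16 + 16) in the mixed context.

Schedules are deterministic functions of an integer seed.  CS order is
pseudo-randomised with at most two consecutive trials of the same CS type;
reinforced CS+ trials are spread so that no more than three consecutive CS+
trials (in CS+ stream order) are reinforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache as _lru_cache
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CSType",
    "Context",
    "Day",
    "TrialEvent",
    "SessionSchedule",
    "build_acquisition",
    "build_extinction",
    "build_day3",
    "outcomes_for_cs",
    "write_events_tsv",
    "read_events_tsv",
]

CS_DURATION_S = 6.0
US_OFFSET_S = 5.0  # US onset relative to CS+ onset on reinforced trials
ITI_VALUES_S = (7.0, 8.0, 9.0, 10.0, 11.0)
# Discrete ITI distribution over 7..11 s with expectation 7.8 s.
ITI_WEIGHTS = (0.55, 0.25, 0.10, 0.05, 0.05)

N_HABITUATION_PER_CS = 3
N_ACQUISITION_PER_CS = 24
N_ACQUISITION_REINFORCED = 18
N_EXTINCTION_PER_CS = 24
N_RETRIEVAL_PER_CS = 8
N_REINSTATEMENT_US = 4
N_REINSTATEMENT_TEST_PER_CS = 16

MAX_CS_RUN = 2
MAX_REINFORCED_RUN = 3


class CSType(str, Enum):
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"


class Context(str, Enum):
    A = "A"
    B = "B"
    MIX = "MIX"


class Day(str, Enum):
    DAY1 = "DAY1"
    DAY2 = "DAY2"
    DAY3 = "DAY3"


@dataclass(frozen=True)
class TrialEvent:
    """One CS presentation."""

    index: int  # 1-based position within the session
    cs_type: CSType
    reinforced: bool
    onset_s: float
    duration_s: float
    iti_s: float
    context: Context

    def __post_init__(self) -> None:
        if self.reinforced and self.cs_type is not CSType.CS_PLUS:
            raise ValueError("only the CS+ can be reinforced")


@dataclass
class SessionSchedule:
    """Ordered trial events for one experimental day."""

    day: Day
    phase_labels: list[str]
    events: list[TrialEvent]
    reinstatement_us_onsets_s: list[float] = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def events_in_phase(self, phase: str) -> list[TrialEvent]:
        return [e for e, p in zip(self.events, self.phase_labels) if p == phase]

    def same_protocol(self, other: "SessionSchedule") -> bool:
        """Equality ignoring the seed (used for file round-trips)."""
        return (
            self.day == other.day
            and self.phase_labels == other.phase_labels
            and self.events == other.events
            and np.allclose(
                self.reinstatement_us_onsets_s, other.reinstatement_us_onsets_s
            )
        )


def _check_seed(seed: int) -> None:
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")


def _cs_sequence(
    rng: np.random.Generator,
    n_plus: int,
    n_minus: int,
    first_cs: CSType | None = None,
    prefix: Sequence[CSType] = (),
    max_tries: int = 10_000,
) -> list[CSType]:
    """Random CS order with at most MAX_CS_RUN consecutive identical types.

    ``prefix`` is the tail of a preceding block whose runs continue into this
    one; an explicit ``first_cs`` takes precedence over the run constraint.
    """
    for _ in range(max_tries):
        remaining = {CSType.CS_PLUS: n_plus, CSType.CS_MINUS: n_minus}
        seq: list[CSType] = list(prefix[-MAX_CS_RUN:])
        n_prefix = len(seq)
        ok = True
        while sum(remaining.values()) > 0:
            options = [cs for cs, n in remaining.items() if n > 0]
            if len(seq) >= MAX_CS_RUN and len(set(seq[-MAX_CS_RUN:])) == 1:
                options = [cs for cs in options if cs != seq[-1]]
            if len(seq) == n_prefix and first_cs is not None:
                options = [first_cs] if remaining[first_cs] > 0 else options
            if not options:
                ok = False
                break
            weights = np.array([remaining[cs] for cs in options], dtype=float)
            pick = options[rng.choice(len(options), p=weights / weights.sum())]
            seq.append(pick)
            remaining[pick] -= 1
        if ok:
            return seq[n_prefix:]
    raise RuntimeError("could not construct a constrained CS sequence")


@_lru_cache(maxsize=8)
def _run_compositions(n_reinforced: int, n_gaps: int, max_run: int) -> tuple:
    """All ways to split n_reinforced into n_gaps runs of length <= max_run."""
    from itertools import product

    return tuple(
        c for c in product(range(max_run + 1), repeat=n_gaps) if sum(c) == n_reinforced
    )


def _reinforcement_pattern(
    rng: np.random.Generator, n_plus: int, n_reinforced: int
) -> np.ndarray:
    """Boolean pattern over CS+ stream positions; runs of True capped.

    Valid patterns are in bijection with compositions of the reinforced count
    into runs separated by single unreinforced trials, so sampling a uniform
    composition samples a uniform valid pattern.
    """
    n_gaps = n_plus - n_reinforced + 1
    if n_reinforced > n_gaps * MAX_REINFORCED_RUN:
        raise ValueError("run constraint is infeasible for these counts")
    comps = _run_compositions(n_reinforced, n_gaps, MAX_REINFORCED_RUN)
    runs = comps[rng.integers(len(comps))]
    flags: list[bool] = []
    for i, r in enumerate(runs):
        flags.extend([True] * r)
        if i < len(runs) - 1:
            flags.append(False)
    return np.asarray(flags, dtype=bool)


def _sample_iti(rng: np.random.Generator) -> float:
    return float(rng.choice(ITI_VALUES_S, p=ITI_WEIGHTS))


def _lay_out(
    rng: np.random.Generator,
    cs_seq: Sequence[CSType],
    reinforced_seq: Sequence[bool],
    context: Context,
    start_s: float,
    start_index: int,
) -> list[TrialEvent]:
    events = []
    onset = start_s
    for i, (cs, rf) in enumerate(zip(cs_seq, reinforced_seq)):
        iti = _sample_iti(rng)
        events.append(
            TrialEvent(
                index=start_index + i,
                cs_type=cs,
                reinforced=bool(rf),
                onset_s=onset,
                duration_s=CS_DURATION_S,
                iti_s=iti,
                context=context,
            )
        )
        onset += CS_DURATION_S + iti
    return events


def build_acquisition(seed: int) -> SessionSchedule:
    """Day-1 schedule: habituation then acquisition in context A."""
    _check_seed(seed)
    rng = np.random.default_rng([seed, 1])
    hab_seq = _cs_sequence(rng, N_HABITUATION_PER_CS, N_HABITUATION_PER_CS)
    hab = _lay_out(rng, hab_seq, [False] * len(hab_seq), Context.A, 0.0, 1)
    acq_seq = _cs_sequence(
        rng, N_ACQUISITION_PER_CS, N_ACQUISITION_PER_CS, prefix=hab_seq
    )
    pattern = _reinforcement_pattern(rng, N_ACQUISITION_PER_CS, N_ACQUISITION_REINFORCED)
    plus_i = iter(pattern)
    reinforced = [next(plus_i) if cs is CSType.CS_PLUS else False for cs in acq_seq]
    last = hab[-1]
    start = last.onset_s + last.duration_s + last.iti_s
    acq = _lay_out(rng, acq_seq, reinforced, Context.A, start, len(hab) + 1)
    return SessionSchedule(
        day=Day.DAY1,
        phase_labels=["habituation"] * len(hab) + ["acquisition"] * len(acq),
        events=hab + acq,
        seed=seed,
    )


def build_extinction(seed: int) -> SessionSchedule:
    """Day-2 schedule: 24 + 24 unreinforced trials in context B."""
    _check_seed(seed)
    rng = np.random.default_rng([seed, 2])
    seq = _cs_sequence(rng, N_EXTINCTION_PER_CS, N_EXTINCTION_PER_CS)
    events = _lay_out(rng, seq, [False] * len(seq), Context.B, 0.0, 1)
    return SessionSchedule(
        day=Day.DAY2,
        phase_labels=["extinction"] * len(events),
        events=events,
        seed=seed,
    )


def build_day3(seed: int, first_cs: CSType | None = None) -> SessionSchedule:
    """Day-3 schedule: retrieval, unsignalled USs, reinstatement test (mixed context).

    ``first_cs`` fixes the CS type of the first post-reinstatement trial
    (counterbalancing hook); by default it is randomised.
    """
    _check_seed(seed)
    rng = np.random.default_rng([seed, 3])
    ret_seq = _cs_sequence(rng, N_RETRIEVAL_PER_CS, N_RETRIEVAL_PER_CS)
    retrieval = _lay_out(rng, ret_seq, [False] * len(ret_seq), Context.MIX, 0.0, 1)

    last = retrieval[-1]
    t = last.onset_s + last.duration_s + last.iti_s
    us_onsets = []
    for i in range(N_REINSTATEMENT_US):
        if i > 0:
            t += rng.uniform(10.0, 15.0)
        us_onsets.append(float(t))

    test_start = us_onsets[-1] + rng.uniform(6.0, 10.0)
    test_seq = _cs_sequence(
        rng, N_REINSTATEMENT_TEST_PER_CS, N_REINSTATEMENT_TEST_PER_CS,
        first_cs=first_cs, prefix=ret_seq,
    )
    test = _lay_out(
        rng, test_seq, [False] * len(test_seq), Context.MIX, test_start,
        len(retrieval) + 1,
    )
    return SessionSchedule(
        day=Day.DAY3,
        phase_labels=["retrieval"] * len(retrieval)
        + ["reinstatement_test"] * len(test),
        events=retrieval + test,
        reinstatement_us_onsets_s=us_onsets,
        seed=seed,
    )


def outcomes_for_cs(
    schedule: SessionSchedule,
    cs_type: CSType,
    phases: Iterable[str] | None = None,
) -> np.ndarray:
    """Binary received-outcome sequence for one CS stream.

    Returns 1 where the US was delivered on that trial, 0 otherwise, in trial
    order.  ``phases`` optionally restricts to a subset of phase labels
    (e.g. excluding habituation before model fitting).
    """
    if not isinstance(cs_type, CSType):
        raise ValueError(f"unknown cs_type: {cs_type!r}")
    wanted = None if phases is None else set(phases)
    out = [
        int(e.reinforced)
        for e, p in zip(schedule.events, schedule.phase_labels)
        if e.cs_type is cs_type and (wanted is None or p in wanted)
    ]
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# BIDS-style events TSV
# ---------------------------------------------------------------------------

def _trial_type(event: TrialEvent) -> str:
    if event.cs_type is CSType.CS_MINUS:
        return "csminus"
    return "csplus_reinforced" if event.reinforced else "csplus_omission"


def write_events_tsv(schedule: SessionSchedule, path: str | Path) -> None:
    """Write a schedule as a BIDS-style events TSV (plus bookkeeping columns)."""
    rows = []
    for event, phase in zip(schedule.events, schedule.phase_labels):
        rows.append(
            dict(
                onset=event.onset_s,
                duration=event.duration_s,
                trial_type=_trial_type(event),
                phase=phase,
                context=event.context.value,
                iti=event.iti_s,
                day=schedule.day.value,
            )
        )
    for onset in schedule.reinstatement_us_onsets_s:
        rows.append(
            dict(
                onset=onset,
                duration=0.0,
                trial_type="reinstatement_us",
                phase="reinstatement_us",
                context=Context.MIX.value,
                iti=None,
                day=schedule.day.value,
            )
        )
    df = pd.DataFrame(rows).sort_values("onset", kind="stable")
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.17g")


def read_events_tsv(path: str | Path) -> SessionSchedule:
    """Reconstruct a SessionSchedule from :func:`write_events_tsv` output."""
    df = pd.read_csv(
        path, sep="\t", na_values=["n/a"], keep_default_na=False,
        float_precision="round_trip",
    )
    days = df["day"].unique()
    if len(days) != 1:
        raise ValueError(f"events file must contain exactly one day, got {days}")
    day = Day(days[0])
    us_onsets = [float(r.onset) for r in df.itertuples() if r.trial_type == "reinstatement_us"]
    events, phases = [], []
    index = 1
    for r in df.itertuples():
        if r.trial_type == "reinstatement_us":
            continue
        cs = CSType.CS_MINUS if r.trial_type == "csminus" else CSType.CS_PLUS
        events.append(
            TrialEvent(
                index=index,
                cs_type=cs,
                reinforced=r.trial_type == "csplus_reinforced",
                onset_s=float(r.onset),
                duration_s=float(r.duration),
                iti_s=float(r.iti),
                context=Context(r.context),
            )
        )
        phases.append(r.phase)
        index += 1
    return SessionSchedule(
        day=day,
        phase_labels=phases,
        events=events,
        reinstatement_us_onsets_s=us_onsets,
    )
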