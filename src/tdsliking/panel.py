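"""Synthetic sensory-panel event logs.

Generates raw trial records with the statistical structure the downstream
analysis assumes: for each panelist x condition x repetition, one TDS trial
(a semi-Markov sequence of dominant-attribute episodes with exponential
dwell times and phase-dependent attribute emission) and one TL trial
(a Poisson stream of liking presses on the 1-9 scale, driven by the
attribute currently dominant in the companion TDS trial plus Gaussian
noise, rounded and clipped).

Reproducibility: one global seed expands to independent per-trial streams
via ``numpy.random.SeedSequence`` spawn keys (a counter-based scheme), so
any single trial can be regenerated without replaying the session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    ATTRIBUTES,
    LIKING_MAX,
    LIKING_MIN,
    ConditionProfile,
    ConfigurationError,
    FoodCondition,
    StudyDesign,
    validate_profiles,
)

Task = Literal["TDS", "TL"]

EVENT_LOG_COLUMNS = (
    "panelist_id",
    "condition_id",
    "task",
    "repetition",
    "duration_s",
    "time_s",
    "payload",
)


@dataclass(frozen=True)
class TrialRecord:
    """One task execution by one panelist on one condition."""

    panelist_id: str
    condition_id: str
    task: Task
    repetition: int
    duration_s: float
    events: tuple[tuple[float, str | int], ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration_s) or self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive and finite, got {self.duration_s}")
        if self.task not in ("TDS", "TL"):
            raise ValueError(f"task must be 'TDS' or 'TL', got {self.task!r}")
        last = 0.0
        for t, payload in self.events:
            if not (0.0 <= t <= self.duration_s):
                raise ValueError(f"event time {t} outside [0, {self.duration_s}]")
            if t <= last and (t, payload) != self.events[0]:
                raise ValueError("event times must be strictly increasing")
            last = t
            if self.task == "TDS":
                if payload not in ATTRIBUTES:
                    raise ValueError(f"unknown TDS attribute {payload!r}")
            else:
                if not (isinstance(payload, (int, np.integer)) and LIKING_MIN <= payload <= LIKING_MAX):
                    raise ValueError(f"TL payload must be an integer in 1..9, got {payload!r}")


def _trial_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent per-trial stream from the global seed and a counter key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def sample_duration(
    design: StudyDesign, condition: FoodCondition, rng: np.random.Generator
) -> float:
    """Lognormal tasting duration around the condition-class mean."""
    mean = design.duration_mean(condition)
    cv = design.duration_cv
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def sample_tds_trial(
    profile: ConditionProfile,
    duration_s: float,
    seed: int | np.random.Generator,
    *,
    panelist_id: str = "p01",
    condition_id: str = "unknown",
    repetition: int = 1,
) -> TrialRecord:
    """Draw one TDS trial: exponential-dwell episodes, phase-dependent emission.

    Each episode's attribute is drawn from the probability vector of the
    phase active at the episode's normalized start time; only one attribute
    is dominant at a time. The first selection happens after a short
    exponential delay, so an initial no-selection period always exists.
    """
    if not np.isfinite(duration_s) or duration_s <= 0:
        raise ValueError(f"duration_s must be positive and finite, got {duration_s}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[tuple[float, str]] = []
    t = rng.exponential(profile.tds_delay_frac * duration_s)
    while t < duration_s:
        p = profile.phase_probs(t / duration_s)
        attr = ATTRIBUTES[rng.choice(len(ATTRIBUTES), p=p)]
        # merge consecutive episodes of the same attribute (one button press)
        if not events or events[-1][1] != attr:
            events.append((float(t), attr))
        t += rng.exponential(profile.dwell_mean_s)
    return TrialRecord(panelist_id, condition_id, "TDS", repetition, float(duration_s), tuple(events))


def dominant_attribute_at(trial: TrialRecord, time_s: float) -> str | None:
    """Attribute dominant at ``time_s`` in a TDS trial, or None before the first press."""
    if trial.task != "TDS":
        raise ValueError("dominant_attribute_at expects a TDS trial")
    current: str | None = None
    for t, payload in trial.events:
        if t <= time_s:
            current = payload  # type: ignore[assignment]
        else:
            break
    return current


def sample_tl_trial(
    profile: ConditionProfile,
    companion_tds: TrialRecord,
    seed: int | np.random.Generator,
    *,
    repetition: int = 1,
) -> TrialRecord:
    """Draw one TL trial driven by the companion TDS trial.

    Press times follow a Poisson process (rate ``press_rate`` per unit of
    normalized time) starting after an exponential delay; each press reports
    the hedonic weight of the currently dominant attribute plus
    ``N(0, noise_sd)`` noise, rounded and clipped to the 1-9 scale.
    """
    if companion_tds.task != "TDS":
        raise ValueError("companion trial must be a TDS trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = companion_tds.duration_s
    events: list[tuple[float, int]] = []
    t = rng.exponential(profile.tl_delay_frac * duration)
    mean_gap = duration / profile.press_rate  # rate per normalized-time unit
    while t < duration:
        attr = dominant_attribute_at(companion_tds, t)
        if attr is None:
            level = profile.baseline_liking
        else:
            level = float(profile.hedonic_weights[ATTRIBUTES.index(attr)])
        value = int(np.clip(round(level + rng.normal(0.0, profile.noise_sd)), LIKING_MIN, LIKING_MAX))
        events.append((float(t), value))
        t += rng.exponential(mean_gap)
    return TrialRecord(
        companion_tds.panelist_id,
        companion_tds.condition_id,
        "TL",
        repetition,
        float(duration),
        tuple(events),
    )


def generate_session(
    design: StudyDesign,
    profiles: Mapping[str, ConditionProfile],
    seed: int,
) -> list[TrialRecord]:
    """Generate the full panel session: panelists x conditions x 2 tasks x reps.

    Deterministic in ``seed``; each trial uses an independent sub-stream keyed
    by (panelist, condition, repetition, task).
    """
    validate_profiles(design, profiles)
    trials: list[TrialRecord] = []
    for ip in range(design.n_panelists):
        pid = f"p{ip + 1:02d}"
        for ic, cond in enumerate(design.conditions):
            profile = profiles[cond.condition_id]
            for rep in range(1, design.n_repetitions + 1):
                rng_tds = _trial_rng(seed, ip, ic, rep, 0)
                duration = sample_duration(design, cond, rng_tds)
                tds = sample_tds_trial(
                    profile,
                    duration,
                    rng_tds,
                    panelist_id=pid,
                    condition_id=cond.condition_id,
                    repetition=rep,
                )
                trials.append(tds)
                # the TL task is a separate trial with its own duration; its
                # liking dynamics follow a freshly drawn dominance trajectory
                rng_tl = _trial_rng(seed, ip, ic, rep, 1)
                duration_tl = sample_duration(design, cond, rng_tl)
                companion = sample_tds_trial(
                    profile,
                    duration_tl,
                    rng_tl,
                    panelist_id=pid,
                    condition_id=cond.condition_id,
                    repetition=rep,
                )
                trials.append(sample_tl_trial(profile, companion, rng_tl, repetition=rep))
    return trials


# ---------------------------------------------------------------------------
# event-log CSV round trip


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        for t, payload in tr.events:
            rows.append(
                (tr.panelist_id, tr.condition_id, tr.task, tr.repetition, tr.duration_s, t, payload)
            )
        if not tr.events:  # keep empty trials visible in the log
            rows.append(
                (tr.panelist_id, tr.condition_id, tr.task, tr.repetition, tr.duration_s, np.nan, "")
            )
    return pd.DataFrame(rows, columns=list(EVENT_LOG_COLUMNS))


def write_event_log(path, trials: Iterable[TrialRecord]) -> None:
    # full-precision floats so the round trip through the reader is exact
    trials_to_frame(trials).to_csv(path, index=False, encoding="utf-8")


def read_event_log(path) -> list[TrialRecord]:
    df = pd.read_csv(
        path, dtype={"payload": str}, keep_default_na=False, na_values=[],
        float_precision="round_trip",
    )
    required = set(EVENT_LOG_COLUMNS)
    if not required.issubset(df.columns):
        raise ValueError(f"event log missing columns: {sorted(required - set(df.columns))}")
    trials: list[TrialRecord] = []
    keys = ["panelist_id", "condition_id", "task", "repetition"]
    for (pid, cid, task, rep), grp in df.groupby(keys, sort=False):
        duration = float(grp["duration_s"].iloc[0])
        events: list[tuple[float, str | int]] = []
        for idx, row in zip(grp.index, grp.itertuples(index=False)):
            raw_t = row.time_s
            if raw_t == "" or (isinstance(raw_t, float) and np.isnan(raw_t)):
                continue  # placeholder row of an event-less trial
            try:
                payload: str | int = row.payload if task == "TDS" else int(row.payload)
                events.append((float(raw_t), payload))
            except ValueError as exc:
                raise ValueError(f"malformed event log row {idx + 2}: {exc}") from exc
        trials.append(TrialRecord(str(pid), str(cid), task, int(rep), duration, tuple(events)))
    return trials
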