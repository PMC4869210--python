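"""Synthetic cohort generator with known ground truth.

Emulates the design of a 7-day wear study in young adult women: each
participant wears a minute-resolution MET monitor for ``n_days``
consecutive days (Monday start, so a full week always contains both
weekend days), undertakes a small number of deliberate activity bouts
per day, occasionally removes the monitor (logged on paper), and then
answers two activity questionnaires about the same week.  Self-reported
durations are the true bout durations scaled by a configurable
over-reporting factor plus multiplicative recall noise, which lets every
downstream stage — blocking, valid-day filtering, weekly scoring,
questionnaire scoring, agreement statistics — be tested against exact
ground truth.

What the generator deliberately does *not* emulate: raw sensor
channels, demographic structure, weekday/weekend activity asymmetries,
or seasonal trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .armband import MetMinuteSeries, MonitorLog, MonitorLogEntry
from .questionnaires import QuestionnaireResponse, ResponseItem

__all__ = ["CohortConfig", "GroundTruth", "CohortData", "generate_cohort", "truth_from_series"]

#: Monday at the start of the emulated monitoring period.
START_DATE = pd.Timestamp("2012-06-04")

WAKING_START_MIN = 7 * 60    # bouts are placed between 07:00
WAKING_END_MIN = 23 * 60     # and 23:00 by default


class CohortConfig(BaseModel):
    """Parameters of the simulated cohort.

    Durations are minutes, rates are per day, MET levels are multiples
    of resting energy expenditure.  ``overreport_factor`` multiplies the
    true bout minutes when questionnaire answers are generated (> 1
    means self-report exceeds the device), and ``reporting_noise_sd`` is
    the log-scale SD of multiplicative recall noise.
    """

    n_participants: int = Field(gt=0)
    n_days: int = Field(default=7, ge=1)
    seed: int = 0
    bout_rate_per_day: float = Field(default=2.0, gt=0)
    #: log-scale SD of a per-participant multiplier on the bout rate;
    #: spreads the cohort across low/moderate/high activity levels
    activity_heterogeneity_sd: float = Field(default=0.6, ge=0)
    bout_duration_location: float = Field(default=math.log(30.0))
    bout_duration_scale: float = Field(default=0.4, gt=0)
    bout_met_level: float = Field(default=5.0, ge=3.3)
    bout_met_sd: float = Field(default=0.8, ge=0)
    baseline_met: float = Field(default=1.3, gt=0, lt=3.3)
    met_threshold: float = 3.3
    rest_insertion_prob: float = Field(default=0.05, ge=0, le=1)
    offbody_minutes_per_day: float = Field(default=30.0, ge=0)
    overreport_factor: float = Field(default=1.5, gt=0)
    reporting_noise_sd: float = Field(default=0.1, ge=0)
    allow_midnight_bouts: bool = False
    exercised_more_prob: float = Field(default=0.04, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.bout_met_level < self.met_threshold:
            raise ValueError("bout MET level must sit at or above the activity threshold")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Per-participant truth the generator bookkeeps (and the stream can reproduce)."""

    participant_id: str
    true_bout_minutes_per_day: tuple[int, ...]
    true_weekly_met_minutes: float

    @property
    def total_bout_minutes(self) -> int:
        return int(sum(self.true_bout_minutes_per_day))


@dataclass
class CohortData:
    """Everything one simulated study produces."""

    series: list[MetMinuteSeries]
    logs: list[MonitorLog]
    responses: list[QuestionnaireResponse]
    truths: list[GroundTruth]
    #: follow-up feedback: did wearing the device itself increase activity?
    exercised_more: dict[str, bool]


def _simulate_participant(
    pid: str, config: CohortConfig, rng: np.random.Generator
) -> tuple[MetMinuteSeries, MonitorLog, GroundTruth, list[QuestionnaireResponse], bool]:
    thr = config.met_threshold
    n_min = config.n_days * 1440
    met = rng.normal(config.baseline_met, 0.15, size=n_min)
    met = np.clip(met, 0.9, thr - 0.05)
    on_body = np.ones(n_min, dtype=bool)

    bout_min_day = np.zeros(config.n_days, dtype=int)
    vig_min_day = np.zeros(config.n_days, dtype=int)
    mod_min_day = np.zeros(config.n_days, dtype=int)

    # --- deliberate activity bouts, placed without overlap in waking hours
    rate = config.bout_rate_per_day * (
        rng.lognormal(0.0, config.activity_heterogeneity_sd)
        if config.activity_heterogeneity_sd
        else 1.0
    )
    for day in range(config.n_days):
        n_bouts = rng.poisson(rate)
        day0 = day * 1440
        occupied: list[tuple[int, int]] = []
        for _ in range(n_bouts):
            dur = int(round(rng.lognormal(config.bout_duration_location, config.bout_duration_scale)))
            dur = max(dur, 2)
            hi = (1440 if config.allow_midnight_bouts else WAKING_END_MIN) - dur
            if hi <= WAKING_START_MIN:
                continue
            placed = False
            for _attempt in range(20):
                start = int(rng.integers(WAKING_START_MIN, hi))
                if all(start + dur <= s or start >= e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                continue
            occupied.append((start, start + dur))
            level = max(rng.normal(config.bout_met_level, config.bout_met_sd), thr + 0.2)
            minute_met = np.clip(rng.normal(level, 0.3, size=dur), thr, None)
            rest_mask = rng.random(dur) < config.rest_insertion_prob
            minute_met[rest_mask] = rng.uniform(1.0, thr - 0.1, size=int(rest_mask.sum()))
            sl = slice(day0 + start, day0 + start + dur)
            met[sl] = minute_met
            n_active = int(dur - rest_mask.sum())
            bout_min_day[day] += n_active
            if level >= 6.0:
                vig_min_day[day] += n_active
            else:
                mod_min_day[day] += n_active

    # --- off-body gaps (showers etc.), one per day, logged on paper
    entries: list[MonitorLogEntry] = []
    if config.offbody_minutes_per_day > 0:
        for day in range(config.n_days):
            gap = int(round(rng.exponential(config.offbody_minutes_per_day)))
            if gap < 1:
                continue
            # keep the gap inside the early morning (before any bout can
            # start) so removal never eats into ground-truth bout minutes
            gap = min(gap, 115)
            start = int(rng.integers(5 * 60, WAKING_START_MIN - gap))
            day0 = day * 1440
            on_body[day0 + start : day0 + start + gap] = False
            t0 = START_DATE + pd.Timedelta(minutes=day0 + start)
            intensity = rng.choice(["low", "moderate", "vigorous"], p=[0.8, 0.15, 0.05])
            entries.append(
                MonitorLogEntry(
                    time_removed=t0,
                    time_replaced=t0 + pd.Timedelta(minutes=gap),
                    activity="showering" if intensity == "low" else "swimming",
                    intensity=str(intensity),
                )
            )

    timestamps = START_DATE + pd.to_timedelta(np.arange(n_min), unit="m")
    frame = pd.DataFrame(
        {"timestamp": timestamps, "met": met, "on_body": on_body, "imputed": False}
    )
    series = MetMinuteSeries(pid, frame)
    log = MonitorLog(pid, entries)

    # ground truth from the generator's own bookkeeping; weekly MET-minutes
    # are recomputed from the emitted stream so the two always agree
    active = (met >= thr) & on_body
    truth = GroundTruth(
        participant_id=pid,
        true_bout_minutes_per_day=tuple(int(x) for x in bout_min_day),
        true_weekly_met_minutes=float(met[active].sum()),
    )

    responses = [
        _make_response(pid, instrument, timepoint, vig_min_day, mod_min_day, config, rng)
        for timepoint in ("baseline", "followup")
        for instrument in ("IPAQ", "MAAS")
    ]
    exercised_more = bool(rng.random() < config.exercised_more_prob)
    return series, log, truth, responses, exercised_more


def _make_response(
    pid: str,
    instrument: str,
    timepoint: str,
    vig_min_day: np.ndarray,
    mod_min_day: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> QuestionnaireResponse:
    """Map true bout minutes into one instrument's answer structure.

    All simulated activity is reported under the leisure domain
    (moderate and vigorous items; walking items stay zero).  The weekly
    reported duration per intensity is true minutes x overreport_factor
    x lognormal noise, rounded to whole minutes; days/week is the count
    of days with at least 10 true bout minutes of that intensity, and
    minutes/day is reported as weekly/days so the weekly total is
    preserved exactly.
    """
    items: list[ResponseItem] = []
    for intensity, per_day in (("moderate", mod_min_day), ("vigorous", vig_min_day)):
        true_weekly = int(per_day.sum())
        noise = rng.lognormal(0.0, config.reporting_noise_sd) if config.reporting_noise_sd else 1.0
        reported_weekly = round(true_weekly * config.overreport_factor * noise)
        days = int((per_day >= 10).sum())
        if days == 0 or reported_weekly == 0:
            items.append(ResponseItem("leisure", intensity, 0, 0.0))
        else:
            items.append(ResponseItem("leisure", intensity, days, reported_weekly / days))
    items.append(ResponseItem("leisure", "walking", 0, 0.0))
    return QuestionnaireResponse(pid, instrument, timepoint, items)


def generate_cohort(config: CohortConfig) -> CohortData:
    """Simulate a full cohort; identical config + seed gives identical output."""
    root = np.random.default_rng(config.seed)
    child_seeds = root.integers(0, 2**31 - 1, size=config.n_participants)
    series, logs, responses, truths = [], [], [], []
    exercised: dict[str, bool] = {}
    for k, s in enumerate(child_seeds):
        pid = f"P{k + 1:03d}"
        rng = np.random.default_rng(int(s))
        ser, log, truth, resp, more = _simulate_participant(pid, config, rng)
        series.append(ser)
        logs.append(log)
        truths.append(truth)
        responses.extend(resp)
        exercised[pid] = more
    return CohortData(series, logs, responses, truths, exercised)


def truth_from_series(series: MetMinuteSeries, threshold: float = 3.3) -> GroundTruth:
    """Recompute ground truth directly from a minute stream.

    Counts device-measured on-body minutes at or above ``threshold``
    (per day, and their MET sum for the week); used to cross-check the
    generator's bookkeeping.
    """
    df = series.minutes
    measured = df["on_body"].to_numpy() & ~df["imputed"].to_numpy()
    active = measured & (df["met"].to_numpy() >= threshold)
    per_day = (
        pd.Series(active, index=df["timestamp"].dt.date).groupby(level=0).sum().sort_index()
    )
    return GroundTruth(
        participant_id=series.participant_id,
        true_bout_minutes_per_day=tuple(int(x) for x in per_day),
        true_weekly_met_minutes=float(df["met"].to_numpy()[active].sum()),
    )
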