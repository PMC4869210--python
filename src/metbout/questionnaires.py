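"""Scoring of self-report activity questionnaires (IPAQ long form, MAAS).

Both instruments ask how many days in the preceding week, and how long
per day, the respondent was active in various domains and intensities.
Scoring turns this into:

* a continuous total in MET-minutes/week — for each item,
  ``MET weight x min(minutes/day, cap) x days/week`` summed over items;
* a categorical level — ``low`` / ``moderate`` / ``high`` by ordered
  instrument-specific rules on occasions and minutes of activity, with
  "none" (zero total) grouped into ``low``.

Every weight and cut-off lives in :class:`ScoringRules` configuration
rather than code, because published protocols differ in detail and the
conventional defaults here (IPAQ protocol weights and categories;
Active-Australia-style MAAS rules with double-weighted vigorous minutes)
should be swappable for alternative published rule sets.

The continuous totals are strongly right-skewed in practice, so scores
carry a natural-log transform ``ln(total + 1)``; the +1 offset makes the
transform defined at zero and is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Literal

__all__ = [
    "ResponseItem",
    "QuestionnaireResponse",
    "ScoringRules",
    "ActivityScore",
    "ipaq_rules",
    "maas_rules",
    "default_rules",
    "score_continuous",
    "classify",
    "score_response",
    "score_batch",
]

Intensity = Literal["walking", "moderate", "vigorous"]


@dataclass(frozen=True)
class ResponseItem:
    """One questionnaire item: activity in a (domain, intensity) cell."""

    domain: str
    intensity: Intensity
    days_per_week: int
    minutes_per_day: float | None  # None = item left blank

    def __post_init__(self) -> None:
        if not (0 <= self.days_per_week <= 7):
            raise ValueError("days_per_week must lie in [0, 7]")
        if self.minutes_per_day is not None and self.minutes_per_day < 0:
            raise ValueError("minutes_per_day must be nonnegative")


@dataclass(frozen=True)
class QuestionnaireResponse:
    participant_id: str
    instrument: Literal["IPAQ", "MAAS"]
    timepoint: Literal["baseline", "followup"]
    items: tuple[ResponseItem, ...]

    def __init__(self, participant_id, instrument, timepoint, items):
        object.__setattr__(self, "participant_id", participant_id)
        object.__setattr__(self, "instrument", instrument)
        object.__setattr__(self, "timepoint", timepoint)
        object.__setattr__(self, "items", tuple(items))

    @property
    def is_complete(self) -> bool:
        return all(i.minutes_per_day is not None for i in self.items)


@dataclass(frozen=True)
class ScoringRules:
    """Instrument scoring configuration (weights, caps, category cut-offs)."""

    instrument: str
    met_weights: dict[tuple[str, str], float]
    per_item_daily_cap_minutes: float | None = None
    none_maps_to_low: bool = True
    ln_offset: float = 1.0
    category_scheme: Literal["ipaq", "maas"] = "ipaq"
    # ipaq category cut-offs
    high_vig_days: int = 3
    high_vig_met: float = 1500.0
    high_any_days: int = 7
    high_any_met: float = 3000.0
    mod_vig_days: int = 3
    mod_vig_minutes: float = 20.0
    mod_modwalk_days: int = 5
    mod_modwalk_minutes: float = 30.0
    mod_any_days: int = 5
    mod_any_met: float = 600.0
    # maas category cut-offs (weighted minutes/week; vigorous doubled)
    maas_low_minutes: float = 150.0
    maas_high_minutes: float = 300.0
    maas_min_sessions: int = 5
    maas_vigorous_double: bool = True

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.met_weights.values()):
            raise ValueError("MET weights must be positive")


def ipaq_rules() -> ScoringRules:
    """Conventional long-form IPAQ weights, 180-min/day item truncation,
    and the three-level categorical algorithm."""
    return ScoringRules(
        instrument="IPAQ",
        met_weights={
            ("work", "walking"): 3.3,
            ("work", "moderate"): 4.0,
            ("work", "vigorous"): 8.0,
            ("transport", "walking"): 3.3,
            ("transport", "moderate"): 6.0,  # cycling for transport
            ("yard", "moderate"): 4.0,
            ("yard", "vigorous"): 5.5,
            ("domestic", "moderate"): 3.0,  # chores inside the home
            ("leisure", "walking"): 3.3,
            ("leisure", "moderate"): 4.0,
            ("leisure", "vigorous"): 8.0,
        },
        per_item_daily_cap_minutes=180.0,
        category_scheme="ipaq",
    )


def maas_rules() -> ScoringRules:
    """Active-Australia-style MAAS weights and time/session categories."""
    return ScoringRules(
        instrument="MAAS",
        met_weights={
            ("leisure", "walking"): 3.33,
            ("leisure", "moderate"): 3.33,
            ("leisure", "vigorous"): 6.66,
            ("yard", "moderate"): 3.33,
            ("yard", "vigorous"): 6.66,
        },
        per_item_daily_cap_minutes=None,
        category_scheme="maas",
    )


def default_rules(instrument: str) -> ScoringRules:
    if instrument.upper() == "IPAQ":
        return ipaq_rules()
    if instrument.upper() == "MAAS":
        return maas_rules()
    raise ValueError(f"unknown instrument {instrument!r}")


@dataclass(frozen=True)
class ActivityScore:
    participant_id: str
    instrument: str
    timepoint: str
    total_met_minutes_per_week: float | None
    total_sessions_per_week: int | None
    category: str | None
    ln_score: float | None
    ln_offset: float = 1.0
    missing: bool = False


@dataclass(frozen=True)
class _Summary:
    """Per-intensity aggregates the categorical rules need."""

    total_met: float
    sessions: int
    days: dict[str, int]            # days/week per intensity (capped at 7)
    minutes_week: dict[str, float]  # minutes/week per intensity
    met_week: dict[str, float]      # MET-min/week per intensity
    days_ge: dict[tuple[str, float], int]  # days on items with >= X min/day


def _summarise(response: QuestionnaireResponse, rules: ScoringRules) -> _Summary:
    total = 0.0
    sessions = 0
    days = {"walking": 0, "moderate": 0, "vigorous": 0}
    minutes_week = {"walking": 0.0, "moderate": 0.0, "vigorous": 0.0}
    met_week = {"walking": 0.0, "moderate": 0.0, "vigorous": 0.0}
    days_ge: dict[tuple[str, float], int] = {}
    thresholds = (rules.mod_vig_minutes, rules.mod_modwalk_minutes)
    for item in response.items:
        key = (item.domain, item.intensity)
        if key not in rules.met_weights:
            raise ValueError(
                f"no MET weight for item {key} on instrument {rules.instrument}"
            )
        minutes = float(item.minutes_per_day)  # validated complete upstream
        if rules.per_item_daily_cap_minutes is not None:
            minutes = min(minutes, rules.per_item_daily_cap_minutes)
        weekly_minutes = minutes * item.days_per_week
        contribution = rules.met_weights[key] * weekly_minutes
        total += contribution
        sessions += item.days_per_week
        days[item.intensity] = min(7, days[item.intensity] + item.days_per_week)
        minutes_week[item.intensity] += weekly_minutes
        met_week[item.intensity] += contribution
        for t in thresholds:
            if minutes >= t:
                k = (item.intensity, t)
                days_ge[k] = min(7, days_ge.get(k, 0) + item.days_per_week)
    return _Summary(total, sessions, days, minutes_week, met_week, days_ge)


def _classify_ipaq(s: _Summary, rules: ScoringRules) -> str:
    any_days = min(7, s.days["walking"] + s.days["moderate"] + s.days["vigorous"])
    if s.days["vigorous"] >= rules.high_vig_days and s.total_met >= rules.high_vig_met:
        return "high"
    if any_days >= rules.high_any_days and s.total_met >= rules.high_any_met:
        return "high"
    if s.days_ge.get(("vigorous", rules.mod_vig_minutes), 0) >= rules.mod_vig_days:
        return "moderate"
    modwalk_days = s.days_ge.get(("moderate", rules.mod_modwalk_minutes), 0) + s.days_ge.get(
        ("walking", rules.mod_modwalk_minutes), 0
    )
    if modwalk_days >= rules.mod_modwalk_days:
        return "moderate"
    if any_days >= rules.mod_any_days and s.total_met >= rules.mod_any_met:
        return "moderate"
    return "low"


def _classify_maas(s: _Summary, rules: ScoringRules) -> str:
    weighted = (
        s.minutes_week["walking"]
        + s.minutes_week["moderate"]
        + (2.0 if rules.maas_vigorous_double else 1.0) * s.minutes_week["vigorous"]
    )
    if weighted >= rules.maas_high_minutes and s.sessions >= rules.maas_min_sessions:
        return "high"
    if weighted >= rules.maas_low_minutes and s.sessions >= rules.maas_min_sessions:
        return "moderate"
    return "low"


def classify(response: QuestionnaireResponse, rules: ScoringRules) -> str:
    """Categorical activity level for one response (first matching rule wins)."""
    s = _summarise(response, rules)
    if s.total_met == 0 and rules.none_maps_to_low:
        return "low"
    if rules.category_scheme == "maas":
        return _classify_maas(s, rules)
    return _classify_ipaq(s, rules)


def score_continuous(
    response: QuestionnaireResponse, rules: ScoringRules
) -> tuple[float, int]:
    """Continuous total (MET-min/week) and session count for one response."""
    s = _summarise(response, rules)
    return s.total_met, s.sessions


def score_response(response: QuestionnaireResponse, rules: ScoringRules) -> ActivityScore:
    if not response.is_complete:
        return ActivityScore(
            response.participant_id,
            response.instrument,
            response.timepoint,
            None,
            None,
            None,
            None,
            rules.ln_offset,
            missing=True,
        )
    total, sessions = score_continuous(response, rules)
    return ActivityScore(
        participant_id=response.participant_id,
        instrument=response.instrument,
        timepoint=response.timepoint,
        total_met_minutes_per_week=total,
        total_sessions_per_week=sessions,
        category=classify(response, rules),
        ln_score=log(total + rules.ln_offset),
        ln_offset=rules.ln_offset,
    )


def score_batch(
    responses: list[QuestionnaireResponse],
    rules_by_instrument: dict[str, ScoringRules] | None = None,
) -> list[ActivityScore]:
    """Score many responses; incomplete ones become missing scores.

    One response per (participant, instrument, timepoint) — duplicates
    raise ``ValueError``.
    """
    if rules_by_instrument is None:
        rules_by_instrument = {"IPAQ": ipaq_rules(), "MAAS": maas_rules()}
    seen: set[tuple[str, str, str]] = set()
    out: list[ActivityScore] = []
    for r in responses:
        key = (r.participant_id, r.instrument, r.timepoint)
        if key in seen:
            raise ValueError(f"duplicate response for {key}")
        seen.add(key)
        out.append(score_response(r, rules_by_instrument[r.instrument]))
    return out
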