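"""Armband (body-worn monitor) data reduction.

This module turns a minute-by-minute MET stream from a multi-sensor
armband into the quantities a questionnaire-validation analysis needs:

1. **Wear-time imputation** — off-body gaps covered by the participant's
   paper monitor log are credited back as wear time, optionally with a
   nominal MET value for the logged intensity (:func:`impute_wear_time`).
2. **Bout blocking** — contiguous runs of minutes are grouped into
   activity *blocks* of at least 10 minutes using nine explicit
   conditions on duration, endpoint intensity, active fraction and
   interior rest runs (:func:`is_valid_block`, :func:`find_blocks`).
   Blocking makes the monitor comparable with questionnaires that only
   ask about activity sustained for 10 minutes or more.
3. **Valid-day filtering** — a day counts only if the monitor was on the
   body for at least 1296 minutes (90 % of 24 h) after log imputation
   (:func:`validate_day`).
4. **Weekly scoring** — valid weekday and weekend-day scores are averaged
   separately and combined as ``5 * avg_weekday + 2 * avg_weekend``;
   participants need at least 4 valid days including both weekend days
   (:func:`weekly_score`).

MET (metabolic equivalent of task) is a multiple of resting energy
expenditure; minutes at or above the activity threshold (default 3.3 MET)
are "active", minutes below it are "rest".
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetMinuteSeries",
    "MonitorLog",
    "MonitorLogEntry",
    "BlockingConfig",
    "ActivityBlock",
    "DayRecord",
    "WeeklyDeviceScore",
    "impute_wear_time",
    "is_valid_block",
    "find_blocks",
    "validate_day",
    "process_series",
    "weekly_score",
    "DEFAULT_INTENSITY_MET",
    "VALID_DAY_MINUTES",
]

#: Nominal MET assigned to logged off-body activity when imputation is on.
DEFAULT_INTENSITY_MET = {"low": 2.0, "moderate": 4.0, "vigorous": 8.0}

#: On-body minutes needed for a valid monitoring day (90 % of 24 h).
VALID_DAY_MINUTES = 1296

MINUTE = pd.Timedelta(minutes=1)


@dataclass
class MetMinuteSeries:
    """One participant's minute-level MET stream.

    ``minutes`` holds one row per minute with columns ``timestamp``
    (minute resolution, strictly increasing), ``met`` (finite, >= 0),
    ``on_body`` (bool) and ``imputed`` (bool; True for minutes whose
    wear/MET status came from the monitor log rather than the device).
    """

    participant_id: str
    minutes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.minutes
        required = {"timestamp", "met", "on_body"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"minute frame missing columns: {sorted(missing)}")
        if "imputed" not in df.columns:
            df = df.assign(imputed=False)
        df = df.copy()
        if not pd.api.types.is_datetime64_any_dtype(df["timestamp"]):
            df["timestamp"] = pd.to_datetime(df["timestamp"])
        if df["met"].dtype != float:
            df["met"] = df["met"].astype(float)
        if df["on_body"].dtype != bool:
            df["on_body"] = df["on_body"].astype(bool)
        if df["imputed"].dtype != bool:
            df["imputed"] = df["imputed"].astype(bool)
        ts = df["timestamp"].to_numpy()
        if len(ts) > 1:
            deltas = np.diff(ts)
            if (deltas <= np.timedelta64(0, "m")).any():
                raise ValueError("timestamps must be strictly increasing")
            same_day = (
                df["timestamp"].dt.normalize().to_numpy()[:-1]
                == df["timestamp"].dt.normalize().to_numpy()[1:]
            )
            if (deltas[same_day] != np.timedelta64(1, "m")).any():
                raise ValueError("timestamps must be minute-spaced within a day")
        met = df["met"].to_numpy()
        if not np.isfinite(met).all() or (met < 0).any():
            raise ValueError("met values must be finite and nonnegative")
        self.minutes = df.reset_index(drop=True)

    def days(self) -> "Iterable[tuple[_dt.date, pd.DataFrame]]":
        """Yield (calendar date, minute frame) pairs in order."""
        for date, g in self.minutes.groupby(self.minutes["timestamp"].dt.date, sort=True):
            yield date, g.reset_index(drop=True)


@dataclass(frozen=True)
class MonitorLogEntry:
    time_removed: pd.Timestamp
    time_replaced: pd.Timestamp
    activity: str
    intensity: Literal["low", "moderate", "vigorous"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_removed", pd.Timestamp(self.time_removed))
        object.__setattr__(self, "time_replaced", pd.Timestamp(self.time_replaced))
        if self.time_removed >= self.time_replaced:
            raise ValueError("time_removed must precede time_replaced")
        if self.intensity not in ("low", "moderate", "vigorous"):
            raise ValueError(f"unknown intensity {self.intensity!r}")


@dataclass
class MonitorLog:
    """Participant's paper log of off-body intervals (non-overlapping)."""

    participant_id: str
    entries: list[MonitorLogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        entries = sorted(self.entries, key=lambda e: e.time_removed)
        for a, b in zip(entries, entries[1:]):
            if b.time_removed < a.time_replaced:
                raise ValueError("monitor-log entries overlap")
        self.entries = entries


@dataclass(frozen=True)
class BlockingConfig:
    """Parameters of the nine-condition bout-blocking rule.

    Defaults encode the published rule set: blocks are >= 10 minute
    readings, must start and end on an active minute, need 80 % (<= 15
    min) or 75 % (> 15 min) of minutes at or above ``met_threshold``,
    tolerate interior rest runs of at most 2 min (<= 15 min blocks) or
    3 min (longer blocks), and 30-60-min blocks may carry one exactly
    4-minute rest while > 60-min blocks may carry two.  The 4-minute
    allowance replaces the cap for those runs only; rests of 5+ minutes
    always invalidate a block.
    """

    min_block_minutes: int = 10
    met_threshold: float = 3.3
    short_block_limit_minutes: int = 15
    frac_active_short: float = 0.80
    frac_active_long: float = 0.75
    max_rest_short: int = 2
    max_rest_long: int = 3
    four_rest_length: int = 4
    four_rest_mid_range: tuple[int, int] = (30, 60)
    four_rest_mid_count: int = 1
    four_rest_long_count: int = 2
    #: "max_coverage" selects the non-overlapping block set covering the
    #: most minutes (exact, deterministic); "greedy" is a faster
    #: left-to-right longest-window scan that can under-cover when rest
    #: runs interact with the duration-dependent allowances.
    block_strategy: Literal["max_coverage", "greedy"] = "max_coverage"
    # scoring/formation switches (see module docs)
    count_rest_met_in_blocks: bool = False
    minutewise_all_minutes: bool = False
    include_imputed_in_blocks: bool = False

    def __post_init__(self) -> None:
        if self.min_block_minutes <= 0 or self.met_threshold <= 0:
            raise ValueError("block duration and MET threshold must be positive")
        for f in (self.frac_active_short, self.frac_active_long):
            if not (0 < f <= 1):
                raise ValueError("active fractions must lie in (0, 1]")
        if self.max_rest_short <= 0 or self.max_rest_long <= 0:
            raise ValueError("rest caps must be positive")

    def rest_cap(self, duration: int) -> int:
        return (
            self.max_rest_short
            if duration <= self.short_block_limit_minutes
            else self.max_rest_long
        )

    def four_rest_allowance(self, duration: int) -> int:
        lo, hi = self.four_rest_mid_range
        if lo <= duration <= hi:
            return self.four_rest_mid_count
        if duration > hi:
            return self.four_rest_long_count
        return 0

    def frac_required(self, duration: int) -> float:
        return (
            self.frac_active_short
            if duration <= self.short_block_limit_minutes
            else self.frac_active_long
        )


@dataclass(frozen=True)
class ActivityBlock:
    """A contiguous minute interval passing all blocking conditions."""

    participant_id: str
    start: pd.Timestamp
    end: pd.Timestamp  # inclusive
    duration_minutes: int
    met_minutes: float
    n_rest_minutes: int


@dataclass(frozen=True)
class DayRecord:
    participant_id: str
    date: _dt.date
    is_weekend: bool
    on_body_minutes: int
    is_valid: bool
    daily_score_blocked: float
    daily_score_minutewise: float
    blocks: tuple[ActivityBlock, ...] = ()


@dataclass(frozen=True)
class WeeklyDeviceScore:
    participant_id: str
    n_valid_weekdays: int
    n_valid_weekend_days: int
    avg_weekday_score: float | None
    avg_weekend_score: float | None
    weekly_total: float | None
    included: bool


# ---------------------------------------------------------------------------
# wear-time imputation


def impute_wear_time(
    series: MetMinuteSeries,
    log: MonitorLog,
    intensity_met_map: dict[str, float] | None = None,
    impute_met: bool = True,
) -> MetMinuteSeries:
    """Credit logged off-body intervals back as wear time.

    Minutes with ``time_removed <= t < time_replaced`` for some log entry
    are flagged on-body (and ``imputed``).  If the minute was off-body and
    ``impute_met`` is true its MET becomes the map value for the logged
    intensity; with ``impute_met`` false it counts for wear time only
    (MET 0).  Minutes the device already recorded on-body keep their MET.

    Raises ``ValueError`` for entries outside the series' time range
    (overlap is rejected by :class:`MonitorLog` itself).
    """
    if intensity_met_map is None:
        intensity_met_map = DEFAULT_INTENSITY_MET
    if not log.entries:
        return series
    df = series.minutes.copy()
    ts = df["timestamp"]
    t0, t1 = ts.iloc[0], ts.iloc[-1]
    for entry in log.entries:
        if entry.time_replaced <= t0 or entry.time_removed > t1 + MINUTE:
            raise ValueError(
                f"log entry {entry.time_removed}–{entry.time_replaced} outside series range"
            )
        covered = (ts >= entry.time_removed) & (ts < entry.time_replaced)
        newly = covered & ~df["on_body"]
        df.loc[newly, "met"] = (
            float(intensity_met_map[entry.intensity]) if impute_met else 0.0
        )
        df.loc[newly, "imputed"] = True
        df.loc[covered, "on_body"] = True
    return MetMinuteSeries(series.participant_id, df)


# ---------------------------------------------------------------------------
# blocking


def _rest_runs(active: np.ndarray) -> list[int]:
    """Lengths of maximal runs of inactive minutes, in order."""
    runs: list[int] = []
    cur = 0
    for a in active:
        if a:
            if cur:
                runs.append(cur)
                cur = 0
        else:
            cur += 1
    if cur:
        runs.append(cur)
    return runs


def _rests_ok(runs: Sequence[int], duration: int, config: BlockingConfig) -> bool:
    cap = config.rest_cap(duration)
    quota = config.four_rest_allowance(duration)
    for length in runs:
        if length <= cap:
            continue
        if length == config.four_rest_length and quota > 0:
            quota -= 1
            continue
        return False
    return True


def is_valid_block(
    met: Sequence[float] | np.ndarray, config: BlockingConfig | None = None
) -> tuple[bool, str | None]:
    """Evaluate the nine blocking conditions on one contiguous window.

    ``met`` is the minute-level MET sequence of a candidate window that is
    fully on-body.  Returns ``(True, None)`` or ``(False, reason)`` where
    ``reason`` names the first violated condition.  Windows of fewer than
    2 minutes raise ``ValueError``.
    """
    if config is None:
        config = BlockingConfig()
    met = np.asarray(met, dtype=float)
    if met.size < 2:
        raise ValueError("a candidate window needs at least 2 minutes")
    duration = int(met.size)
    if duration < config.min_block_minutes:
        return False, "duration_below_minimum"
    active = met >= config.met_threshold
    if not (active[0] and active[-1]):
        return False, "endpoint_not_active"
    if active.mean() < config.frac_required(duration):
        return False, "active_fraction_too_low"
    if not _rests_ok(_rest_runs(active), duration, config):
        return False, "rest_run_too_long"
    return True, None


def _greedy_blocks(met: np.ndarray, config: BlockingConfig) -> list[tuple[int, int]]:
    """Greedy left-to-right block scan on one contiguous segment.

    At each active minute not yet consumed, grow the longest window that
    passes every blocking condition, emit it, and resume after its end.
    A rest run reaching 5 minutes can never sit inside a block, so the
    scan from a given start stops there.
    """
    thr = config.met_threshold
    n = met.size
    active = met >= thr
    out: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not active[i]:
            i += 1
            continue
        best = -1
        runs: list[int] = []
        cur_rest = 0
        n_act = 0
        j = i
        while j < n:
            if active[j]:
                if cur_rest:
                    runs.append(cur_rest)
                    cur_rest = 0
                n_act += 1
                d = j - i + 1
                if (
                    d >= config.min_block_minutes
                    and n_act >= config.frac_required(d) * d
                    and _rests_ok(runs, d, config)
                ):
                    best = j
            else:
                cur_rest += 1
                if cur_rest > config.four_rest_length:
                    break
            j += 1
        if best >= 0:
            out.append((i, best))
            i = best + 1
        else:
            i += 1
    return out


def _scan_valid_windows(met: np.ndarray, config: BlockingConfig) -> list[tuple[int, int]]:
    """All valid windows of one contiguous segment, by incremental scan.

    From every active start minute, extend rightward keeping O(1)
    per-minute state (active count, rest-run class counters); a rest run
    of 5+ minutes can never sit inside a block, so the scan from a start
    stops there.  Every active end minute where all conditions hold is a
    valid window.
    """
    thr = config.met_threshold
    n = met.size
    active = met >= thr
    limit = config.short_block_limit_minutes
    windows: list[tuple[int, int]] = []
    for i in range(n):
        if not active[i]:
            continue
        n_act = 0
        cur_rest = 0
        over_short = 0  # completed rest runs longer than the short cap
        n_four = 0      # completed rest runs of exactly the allowance length
        j = i
        while j < n:
            if active[j]:
                if cur_rest:
                    if cur_rest > config.max_rest_short:
                        over_short += 1
                    if cur_rest == config.four_rest_length:
                        n_four += 1
                    cur_rest = 0
                n_act += 1
                d = j - i + 1
                if d >= config.min_block_minutes and n_act >= config.frac_required(d) * d:
                    if d <= limit:
                        rests_ok = over_short == 0
                    else:
                        # runs above the long cap are exactly-4 runs only
                        # (5+ runs break the scan below)
                        rests_ok = n_four <= config.four_rest_allowance(d)
                    if rests_ok:
                        windows.append((i, j))
            else:
                cur_rest += 1
                if cur_rest > config.four_rest_length:
                    break
            j += 1
    return windows


def _select_max_coverage(
    windows: list[tuple[int, int]], met: np.ndarray, config: BlockingConfig
) -> list[tuple[int, int]]:
    """Non-overlapping window subset maximising (covered minutes, MET).

    Weighted-interval dynamic programming over windows sorted by end;
    deterministic, with supra-threshold MET as tie-break.
    """
    if not windows:
        return []
    active_met = np.where(met >= config.met_threshold, met, 0.0)
    pref = np.concatenate([[0.0], np.cumsum(active_met)])
    windows = sorted(windows, key=lambda w: (w[1], w[0]))
    ends = [w[1] for w in windows]
    from bisect import bisect_right

    m = len(windows)
    best: list[tuple[int, float]] = [(0, 0.0)] * (m + 1)
    back: list[tuple[int, bool]] = [(0, False)] * (m + 1)
    for k in range(1, m + 1):
        i, j = windows[k - 1]
        p = bisect_right(ends, i - 1, 0, k - 1)
        take = (best[p][0] + (j - i + 1), best[p][1] + float(pref[j + 1] - pref[i]))
        if take > best[k - 1]:
            best[k], back[k] = take, (p, True)
        else:
            best[k], back[k] = best[k - 1], (k - 1, False)
    chosen: list[tuple[int, int]] = []
    k = m
    while k > 0:
        p, taken = back[k]
        if taken:
            chosen.append(windows[k - 1])
        k = p
    chosen.reverse()
    return chosen


def _segment_blocks(met: np.ndarray, config: BlockingConfig) -> list[tuple[int, int]]:
    if config.block_strategy == "greedy":
        return _greedy_blocks(met, config)
    return _select_max_coverage(_scan_valid_windows(met, config), met, config)


def _eligible_segments(day: pd.DataFrame, config: BlockingConfig) -> list[pd.DataFrame]:
    """Split a day into contiguous runs of block-eligible minutes."""
    eligible = day["on_body"].to_numpy()
    if not config.include_imputed_in_blocks:
        eligible = eligible & ~day["imputed"].to_numpy()
    n = len(day)
    if n == 0 or not eligible.any():
        return []
    ts = day["timestamp"].to_numpy()
    # a new segment starts wherever eligibility switches on, or the
    # minute grid has a gap inside an eligible stretch
    gap = np.ones(n, dtype=bool)
    gap[1:] = np.diff(ts) != np.timedelta64(1, "m")
    prev_eligible = np.concatenate([[False], eligible[:-1]])
    starts = np.flatnonzero(eligible & (~prev_eligible | gap))
    next_eligible = np.concatenate([eligible[1:], [False]])
    next_gap = np.concatenate([gap[1:], [True]])
    ends = np.flatnonzero(eligible & (~next_eligible | next_gap))
    return [day.iloc[s : e + 1] for s, e in zip(starts, ends)]


def find_blocks(
    day_minutes: pd.DataFrame,
    config: BlockingConfig | None = None,
    participant_id: str = "",
) -> list[ActivityBlock]:
    """Block one calendar day of minutes into activity bouts.

    ``day_minutes`` is a frame with ``timestamp``/``met``/``on_body``
    (and optionally ``imputed``) columns covering a single calendar day.
    Returns non-overlapping :class:`ActivityBlock` objects, each passing
    :func:`is_valid_block`, found by a deterministic greedy scan.  A
    block's ``met_minutes`` sums the MET of its active minutes only,
    unless ``config.count_rest_met_in_blocks`` is set.
    """
    if config is None:
        config = BlockingConfig()
    if len(day_minutes) == 0:
        return []
    if "imputed" not in day_minutes.columns:
        day_minutes = day_minutes.assign(imputed=False)
    blocks: list[ActivityBlock] = []
    for seg in _eligible_segments(day_minutes, config):
        met = seg["met"].to_numpy(dtype=float)
        ts = seg["timestamp"].reset_index(drop=True)
        for i, j in _segment_blocks(met, config):
            window = met[i : j + 1]
            active = window >= config.met_threshold
            met_minutes = float(
                window.sum() if config.count_rest_met_in_blocks else window[active].sum()
            )
            blocks.append(
                ActivityBlock(
                    participant_id=participant_id,
                    start=ts.iloc[i],
                    end=ts.iloc[j],
                    duration_minutes=j - i + 1,
                    met_minutes=met_minutes,
                    n_rest_minutes=int((~active).sum()),
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# daily and weekly scores


def validate_day(
    day_minutes: pd.DataFrame,
    participant_id: str = "",
    config: BlockingConfig | None = None,
    valid_day_minutes: int = VALID_DAY_MINUTES,
) -> DayRecord:
    """Assess one calendar day: wear-time validity and daily scores.

    ``daily_score_blocked`` sums MET over the supra-threshold minutes of
    every activity block; ``daily_score_minutewise`` sums MET over all
    on-body minutes at or above the threshold (or over all on-body
    minutes when ``config.minutewise_all_minutes`` is set).
    """
    if config is None:
        config = BlockingConfig()
    if len(day_minutes) == 0:
        raise ValueError("validate_day needs at least one minute")
    if "imputed" not in day_minutes.columns:
        day_minutes = day_minutes.assign(imputed=False)
    dates = day_minutes["timestamp"].dt.date.unique()
    if len(dates) != 1:
        raise ValueError("validate_day expects minutes from a single calendar day")
    date = dates[0]
    on_body = day_minutes["on_body"].to_numpy()
    met = day_minutes["met"].to_numpy(dtype=float)
    on_body_minutes = int(on_body.sum())
    blocks = find_blocks(day_minutes, config, participant_id)
    if config.minutewise_all_minutes:
        minutewise = float(met[on_body].sum())
    else:
        minutewise = float(met[on_body & (met >= config.met_threshold)].sum())
    return DayRecord(
        participant_id=participant_id,
        date=date,
        is_weekend=pd.Timestamp(date).dayofweek >= 5,
        on_body_minutes=on_body_minutes,
        is_valid=on_body_minutes >= valid_day_minutes,
        daily_score_blocked=float(sum(b.met_minutes for b in blocks)),
        daily_score_minutewise=minutewise,
        blocks=tuple(blocks),
    )


def process_series(
    series: MetMinuteSeries,
    log: MonitorLog | None = None,
    config: BlockingConfig | None = None,
    intensity_met_map: dict[str, float] | None = None,
    impute_met: bool = True,
) -> list[DayRecord]:
    """Impute wear time from the log, then validate every day."""
    if log is not None:
        series = impute_wear_time(series, log, intensity_met_map, impute_met)
    return [
        validate_day(day, series.participant_id, config) for _, day in series.days()
    ]


def weekly_score(
    days: Sequence[DayRecord],
    score_field: Literal["blocked", "minutewise"] = "blocked",
    min_valid_days: int = 4,
    min_weekend_days: int = 2,
) -> WeeklyDeviceScore:
    """Combine daily scores into the 5/2-weighted weekly total.

    Only valid days contribute.  A participant is included when they have
    at least ``min_valid_days`` valid days of which at least
    ``min_weekend_days`` are weekend days; otherwise the weekly total is
    missing (``None``).
    """
    if not days:
        raise ValueError("weekly_score needs at least one day record")
    pid = days[0].participant_id
    if len({d.date for d in days}) != len(days):
        raise ValueError("duplicate day records for one participant")
    attr = "daily_score_blocked" if score_field == "blocked" else "daily_score_minutewise"
    weekday = [getattr(d, attr) for d in days if d.is_valid and not d.is_weekend]
    weekend = [getattr(d, attr) for d in days if d.is_valid and d.is_weekend]
    n_wd, n_we = len(weekday), len(weekend)
    included = (n_wd + n_we >= min_valid_days) and (n_we >= min_weekend_days)
    avg_wd = float(np.mean(weekday)) if weekday else None
    avg_we = float(np.mean(weekend)) if weekend else None
    if included and (avg_wd is None or avg_we is None):
        # a weekly total needs both averages; report not-included instead
        included = False
    total = 5.0 * avg_wd + 2.0 * avg_we if included else None
    return WeeklyDeviceScore(
        participant_id=pid,
        n_valid_weekdays=n_wd,
        n_valid_weekend_days=n_we,
        avg_weekday_score=avg_wd,
        avg_weekend_score=avg_we,
        weekly_total=total,
        included=included,
    )
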