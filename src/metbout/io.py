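"""CSV dialects shared by the generator and the pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .armband import MetMinuteSeries, MonitorLog, MonitorLogEntry
from .questionnaires import QuestionnaireResponse, ResponseItem
from .synthetic import GroundTruth

__all__ = [
    "write_minutes_csv", "read_minutes_csv",
    "write_log_csv", "read_log_csv",
    "write_responses_csv", "read_responses_csv",
    "write_ground_truth_csv", "read_ground_truth_csv",
]

MINUTE_COLUMNS = ["participant_id", "timestamp", "met", "on_body"]
LOG_COLUMNS = ["participant_id", "time_removed", "time_replaced", "activity", "intensity"]
RESPONSE_COLUMNS = [
    "participant_id", "instrument", "timepoint",
    "domain", "intensity", "days_per_week", "minutes_per_day",
]


def write_minutes_csv(series_list: list[MetMinuteSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        df = s.minutes[["timestamp", "met", "on_body"]].copy()
        df.insert(0, "participant_id", s.participant_id)
        df["on_body"] = df["on_body"].astype(int)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_minutes_csv(path: str | Path) -> list[MetMinuteSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(MINUTE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        out.append(
            MetMinuteSeries(
                str(pid),
                g.assign(on_body=g["on_body"].astype(bool))[["timestamp", "met", "on_body"]],
            )
        )
    return out


def write_log_csv(logs: list[MonitorLog], path: str | Path) -> None:
    rows = [
        {
            "participant_id": log.participant_id,
            "time_removed": e.time_removed,
            "time_replaced": e.time_replaced,
            "activity": e.activity,
            "intensity": e.intensity,
        }
        for log in logs
        for e in log.entries
    ]
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def read_log_csv(path: str | Path) -> dict[str, MonitorLog]:
    df = pd.read_csv(path, parse_dates=["time_removed", "time_replaced"])
    logs: dict[str, MonitorLog] = {}
    for pid, g in df.groupby("participant_id", sort=True):
        entries = [
            MonitorLogEntry(r.time_removed, r.time_replaced, str(r.activity), str(r.intensity))
            for r in g.itertuples()
        ]
        logs[str(pid)] = MonitorLog(str(pid), entries)
    return logs


def write_responses_csv(responses: list[QuestionnaireResponse], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "instrument": r.instrument,
            "timepoint": r.timepoint,
            "domain": it.domain,
            "intensity": it.intensity,
            "days_per_week": it.days_per_week,
            "minutes_per_day": it.minutes_per_day,
        }
        for r in responses
        for it in r.items
    ]
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def read_responses_csv(path: str | Path) -> list[QuestionnaireResponse]:
    df = pd.read_csv(path)
    out = []
    for (pid, inst, tp), g in df.groupby(
        ["participant_id", "instrument", "timepoint"], sort=True
    ):
        items = [
            ResponseItem(
                str(r.domain),
                str(r.intensity),
                int(r.days_per_week),
                None if pd.isna(r.minutes_per_day) else float(r.minutes_per_day),
            )
            for r in g.itertuples()
        ]
        out.append(QuestionnaireResponse(str(pid), str(inst), str(tp), items))
    return out


def write_ground_truth_csv(truths: list[GroundTruth], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in truths],
            "true_bout_minutes_per_day": [
                ";".join(str(x) for x in t.true_bout_minutes_per_day) for t in truths
            ],
            "true_weekly_met_minutes": [t.true_weekly_met_minutes for t in truths],
        }
    ).to_csv(path, index=False)


def read_ground_truth_csv(path: str | Path) -> list[GroundTruth]:
    df = pd.read_csv(path)
    return [
        GroundTruth(
            str(r.participant_id),
            tuple(int(x) for x in str(r.true_bout_minutes_per_day).split(";")),
            float(r.true_weekly_met_minutes),
        )
        for r in df.itertuples()
    ]
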