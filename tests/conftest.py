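import numpy as np
import pandas as pd
import pytest

from metbout.armband import MetMinuteSeries

DAY_START = pd.Timestamp("2012-06-04 00:00")  # a Monday


def minute_frame(met, start=DAY_START, on_body=True):
    """Build a minute frame from a MET sequence (helper, not a fixture)."""
    met = np.asarray(met, dtype=float)
    n = met.size
    ts = start + pd.to_timedelta(np.arange(n), unit="m")
    ob = np.full(n, True) if on_body is True else np.asarray(on_body, dtype=bool)
    return pd.DataFrame({"timestamp": ts, "met": met, "on_body": ob, "imputed": False})


def full_day(met_by_minute=None, start=DAY_START, fill=1.2):
    """A complete 1440-minute day, sedentary except for given (idx, met) pairs."""
    met = np.full(1440, float(fill))
    if met_by_minute:
        for idx, value in met_by_minute:
            met[idx] = value
    return minute_frame(met, start=start)


def series_from_days(pid, day_frames):
    return MetMinuteSeries(pid, pd.concat(day_frames, ignore_index=True))


@pytest.fixture(scope="session")
def random_day_mets():
    """Seeded bank of random MET days (<= 200 min) spanning sparse to dense."""
    rng = np.random.default_rng(20120604)
    days = []
    for _ in range(500):
        n = int(rng.integers(20, 201))
        p_active = rng.uniform(0.15, 0.9)
        active = rng.random(n) < p_active
        met = np.where(active, rng.uniform(3.3, 9.0, n), rng.uniform(0.8, 3.29, n))
        days.append(met)
    return days
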