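"""Shared fixtures: canonical event-log lines and small synthetic inputs."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from wanderlens import sensing_io

# The canonical 10-line sample of the CASAS event dialect (motion, door).
EVENT_LOG_SAMPLE = [
    "09:10:00.094833\tM001\tON",
    "09:10:01.014748\tM023\tON",
    "09:10:01.045917\tM021\tOFF",
    "09:10:01.093183\tM022\tOFF",
    "09:10:02.087933\tM023\tOFF",
    "09:10:03.072194\tM023\tON",
    "09:10:05.014012\tD012\tOPEN",
    "09:10:05.043057\tM001\tOFF",
    "09:10:06.038858\tM023\tOFF",
    "09:10:19.094168\tD012\tCLOSE",
]

# A 10-row sensor position table (ids and coordinates in meters).
POSITION_TABLE_SAMPLE = [
    "sensor_id,x,y",
    "M025,0.95,1.26",
    "I012,1.07,8.78",
    "I011,0.76,9.10",
    "M024,2.99,1.21",
    "D001,2.17,0.23",
    "T003,3.02,4.67",
    "M036,5.26,4.97",
    "M030,5.81,6.06",
    "D003,5.56,6.40",
    "M029,5.84,7.16",
]


@pytest.fixture
def event_lines():
    return list(EVENT_LOG_SAMPLE)


@pytest.fixture
def position_lines():
    return list(POSITION_TABLE_SAMPLE)


def make_history(points, subject_id="s1", label="unknown", t0=None, category="motion"):
    """PositionHistory from (x, y, t_seconds) triples — test helper."""
    t0 = t0 or datetime(2024, 1, 1, 9, 0, 0)
    records = [
        sensing_io.PositionRecord(
            x=float(x),
            y=float(y),
            t=t0 + timedelta(seconds=float(t)),
            s_id=f"M{i + 1:03d}",
            category=category,
        )
        for i, (x, y, t) in enumerate(points)
    ]
    return sensing_io.PositionHistory(records=records, subject_id=subject_id, label=label)


def random_history(rng, n=30, dt_range=(0.5, 5.0), step_range=(0.0, 8.0)):
    """A random walk history; some steps violate the noise gates on purpose."""
    t = 0.0
    x, y = 5.0, 5.0
    pts = []
    for _ in range(n):
        pts.append((x, y, t))
        t += rng.uniform(*dt_range)
        ang = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(*step_range)
        x += step * np.cos(ang)
        y += step * np.sin(ang)
    return make_history(pts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
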