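from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from somnoview.core_model import (
    Channel,
    ChannelSeries,
    EpisodicKind,
    EpisodicMeasurement,
    build_record,
)

UTC = timezone.utc

# Day 1 of the reference record: 2016-01-04 16:00 UTC.
DAY1_START = int(datetime(2016, 1, 4, 16, tzinfo=UTC).timestamp())


def epoch(y, m, d, hh=0, mm=0, ss=0):
    return int(datetime(y, m, d, hh, mm, ss, tzinfo=UTC).timestamp())


def series_1hz(channel, start_epoch, n, value=96.0):
    """n samples at 1 Hz, constant value (or per-sample array)."""
    t = np.arange(start_epoch, start_epoch + n, dtype=np.int64)
    v = np.full(n, value, dtype=float) if np.isscalar(value) else np.asarray(value, float)
    return ChannelSeries(Channel(channel), t, v)


def make_record(channels=None, episodic=(), patient_id="p1", tz="UTC"):
    return build_record(
        patient_id=patient_id,
        display_name="Test Patient",
        channels=channels or {},
        episodic=list(episodic),
        timezone_name=tz,
    )


@pytest.fixture
def night_record():
    """One night: SpO2 + HR 23:00-06:00, activity alongside, two BP readings,
    one weight and one subjective entry."""
    start = epoch(2016, 1, 4, 23)
    n = 7 * 3600
    channels = {
        Channel.SPO2: series_1hz(Channel.SPO2, start, n, 96.0),
        Channel.HEART_RATE: series_1hz(Channel.HEART_RATE, start, n, 72.0),
        Channel.ACTIVITY: series_1hz(Channel.ACTIVITY, start, n, 1.0),
    }
    episodic = [
        EpisodicMeasurement(
            kind=EpisodicKind.BLOOD_PRESSURE,
            t=datetime(2016, 1, 4, 20, 5, tzinfo=UTC),
            systolic_mmhg=126.0, diastolic_mmhg=78.0,
        ),
        EpisodicMeasurement(
            kind=EpisodicKind.BLOOD_PRESSURE,
            t=datetime(2016, 1, 5, 7, 10, tzinfo=UTC),
            systolic_mmhg=131.0, diastolic_mmhg=82.0,
        ),
        EpisodicMeasurement(
            kind=EpisodicKind.WEIGHT,
            t=datetime(2016, 1, 5, 7, 0, tzinfo=UTC),
            weight_kg=82.4,
        ),
        EpisodicMeasurement(
            kind=EpisodicKind.SUBJECTIVE,
            t=datetime(2016, 1, 4, 21, 30, tzinfo=UTC),
            subjective_score=4.5,
            subjective_items=(("breathlessness", 5.0), ("fatigue", 4.0)),
        ),
    ]
    return make_record(channels, episodic)
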