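"""Domain types and clinical-day partitioning.

All continuous data live in :class:`ChannelSeries` objects backed by numpy
arrays of epoch seconds / float values; episodic measurements (weight, blood
pressure, subjective state) are small dataclasses.  A patient's data are
partitioned into "clinical days": 24-hour windows starting at a boundary hour
(default 16:00 local) so that one full night always falls inside one window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from enum import Enum
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np

__all__ = [
    "Channel",
    "CHANNEL_UNITS",
    "Sample",
    "ChannelSeries",
    "EpisodicKind",
    "EpisodicMeasurement",
    "DayWindow",
    "PatientRecord",
    "ThresholdConfig",
    "ValidationError",
    "partition_days",
    "validate_record",
]


class ValidationError(ValueError):
    """Raised when input data violate a structural contract."""


class Channel(str, Enum):
    SPO2 = "spo2"
    HEART_RATE = "heart_rate"
    ACTIVITY = "activity"


#: Unit attached to each continuous channel.
CHANNEL_UNITS = {
    Channel.SPO2: "percent",
    Channel.HEART_RATE: "bpm",
    Channel.ACTIVITY: "vmu",
}


class Sample(NamedTuple):
    """A single timestamped reading (timezone-aware datetime, channel units)."""

    t: datetime
    value: float


def _to_epoch(t: datetime) -> int:
    if t.tzinfo is None:
        raise ValidationError(f"naive timestamp not allowed: {t!r}")
    return int(t.timestamp())


def _resolve_tz(tz: str | ZoneInfo) -> ZoneInfo:
    return tz if isinstance(tz, ZoneInfo) else ZoneInfo(tz)


@dataclass(frozen=True)
class ChannelSeries:
    """One continuous channel as parallel (epoch-second, value) arrays.

    ``times`` must be strictly increasing; values must be finite, within
    [0, 100] for SpO2 and non-negative for heart rate and activity.
    """

    channel: Channel
    times: np.ndarray  # int64 epoch seconds, strictly increasing
    values: np.ndarray  # float64

    def __post_init__(self) -> None:
        # Structural checks only; content problems (ordering, ranges) are
        # reported — not raised — by validate_record.
        times = np.asarray(self.times, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValidationError("times and values must be 1-D arrays of equal length")

    @property
    def unit(self) -> str:
        return CHANNEL_UNITS[self.channel]

    def __len__(self) -> int:
        return int(self.times.size)

    def problems(self) -> list[str]:
        """Content-invariant violations: ordering, ranges, finiteness."""
        messages: list[str] = []
        t, vals = self.times, self.values
        if t.size > 1:
            diffs = np.diff(t)
            if np.any(diffs <= 0):
                i = int(np.argmax(diffs <= 0))
                messages.append(
                    f"{self.channel.value}: samples not strictly increasing at "
                    f"index {i + 1} (t={int(t[i + 1])})"
                )
        if vals.size and not np.all(np.isfinite(vals)):
            messages.append(f"{self.channel.value}: non-finite value present")
        if self.channel is Channel.SPO2:
            bad = np.flatnonzero((vals < 0) | (vals > 100))
            for i in bad[:5]:
                messages.append(
                    f"spo2: value {vals[i]:g} at t={int(t[i])} outside [0, 100]"
                )
        else:
            bad = np.flatnonzero(vals < 0)
            for i in bad[:5]:
                messages.append(
                    f"{self.channel.value}: negative value {vals[i]:g} at t={int(t[i])}"
                )
        return messages

    @classmethod
    def from_samples(cls, channel: Channel, samples: Iterable[Sample]) -> "ChannelSeries":
        """Build a series from (datetime, value) samples, sorting by time."""
        pairs = sorted((_to_epoch(s.t), float(s.value)) for s in samples)
        times = np.array([p[0] for p in pairs], dtype=np.int64)
        values = np.array([p[1] for p in pairs], dtype=np.float64)
        return cls(channel, times, values)

    def iter_samples(self, tz: str | ZoneInfo = "UTC") -> Iterator[Sample]:
        zone = _resolve_tz(tz)
        for t, v in zip(self.times, self.values):
            yield Sample(datetime.fromtimestamp(int(t), tz=zone), float(v))

    def slice_epoch(self, start: int, end: int) -> "ChannelSeries":
        """Samples with start <= t < end (half-open)."""
        i = int(np.searchsorted(self.times, start, side="left"))
        j = int(np.searchsorted(self.times, end, side="left"))
        return ChannelSeries(self.channel, self.times[i:j], self.values[i:j])


class EpisodicKind(str, Enum):
    WEIGHT = "weight"
    BLOOD_PRESSURE = "blood_pressure"
    SUBJECTIVE = "subjective"


@dataclass(frozen=True)
class EpisodicMeasurement:
    """A once-or-few-per-day measurement: weight, blood pressure or a
    subjective question-set entry.  Only the fields for its kind are set."""

    kind: EpisodicKind
    t: datetime
    weight_kg: Optional[float] = None
    systolic_mmhg: Optional[float] = None
    diastolic_mmhg: Optional[float] = None
    subjective_score: Optional[float] = None
    subjective_items: tuple = ()

    def __post_init__(self) -> None:
        _to_epoch(self.t)  # rejects naive timestamps
        populated = {
            "weight_kg": self.weight_kg is not None,
            "blood_pressure": self.systolic_mmhg is not None or self.diastolic_mmhg is not None,
            "subjective": self.subjective_score is not None or bool(self.subjective_items),
        }
        if self.kind is EpisodicKind.WEIGHT:
            if self.weight_kg is None or self.weight_kg <= 0:
                raise ValidationError("weight measurement requires positive weight_kg")
            if populated["blood_pressure"] or populated["subjective"]:
                raise ValidationError("weight measurement carries extraneous fields")
        elif self.kind is EpisodicKind.BLOOD_PRESSURE:
            if self.systolic_mmhg is None or self.diastolic_mmhg is None:
                raise ValidationError("blood pressure requires systolic and diastolic")
            if self.systolic_mmhg <= 0 or self.diastolic_mmhg <= 0:
                raise ValidationError("blood pressure values must be positive")
            if not self.systolic_mmhg > self.diastolic_mmhg:
                raise ValidationError("systolic must exceed diastolic")
            if populated["weight_kg"] or populated["subjective"]:
                raise ValidationError("blood pressure measurement carries extraneous fields")
        elif self.kind is EpisodicKind.SUBJECTIVE:
            if self.subjective_score is None:
                raise ValidationError("subjective measurement requires subjective_score")
            if populated["weight_kg"] or populated["blood_pressure"]:
                raise ValidationError("subjective measurement carries extraneous fields")
        object.__setattr__(self, "subjective_items", tuple(self.subjective_items))

    @property
    def epoch(self) -> int:
        return _to_epoch(self.t)


@dataclass(frozen=True)
class DayWindow:
    """One clinical day: a half-open 24-h window [start, end) beginning at the
    day-boundary hour (default 16:00 local)."""

    index: int
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError("day index must be >= 1")
        if not self.end > self.start:
            raise ValidationError("day window must have positive duration")

    @property
    def start_epoch(self) -> int:
        return _to_epoch(self.start)

    @property
    def end_epoch(self) -> int:
        return _to_epoch(self.end)

    @property
    def duration_s(self) -> int:
        return self.end_epoch - self.start_epoch

    def contains_epoch(self, t: int) -> bool:
        return self.start_epoch <= t < self.end_epoch


@dataclass(frozen=True)
class ThresholdConfig:
    """Channel thresholds and block size for violation detection.

    Defaults: SpO2 low 92 %, heart-rate 60–100 bpm, activity 12 VMU (mean over
    the block), 30-minute blocks.  All comparisons are strict inequalities.
    """

    spo2_low: float = 92.0
    hr_low: float = 60.0
    hr_high: float = 100.0
    activity_high: float = 12.0
    block_minutes: int = 30
    min_violation_samples: int = 1  # minimum violating samples for SpO2/HR flags
    wear_gap_tolerance_s: int = 60

    def __post_init__(self) -> None:
        if not self.hr_low < self.hr_high:
            raise ValidationError("hr_low must be less than hr_high")
        for name in ("spo2_low", "hr_low", "hr_high", "activity_high"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.block_minutes <= 0 or 60 % self.block_minutes != 0:
            raise ValidationError("block_minutes must be a positive divisor of 60")
        if self.min_violation_samples < 1:
            raise ValidationError("min_violation_samples must be >= 1")

    @property
    def block_seconds(self) -> int:
        return self.block_minutes * 60


@dataclass
class PatientRecord:
    """All continuous and episodic data for one patient over N clinical days."""

    patient_id: str
    display_name: str
    timezone: str = "UTC"
    channels: dict = field(default_factory=dict)  # Channel -> ChannelSeries
    episodic: list = field(default_factory=list)  # list[EpisodicMeasurement]
    days: list = field(default_factory=list)  # list[DayWindow]

    def channel(self, channel: Channel) -> Optional[ChannelSeries]:
        return self.channels.get(Channel(channel))

    def day(self, index: int) -> DayWindow:
        for d in self.days:
            if d.index == index:
                return d
        raise KeyError(f"no day with index {index} (have 1..{len(self.days)})")

    def all_epochs(self) -> np.ndarray:
        parts = [s.times for s in self.channels.values() if len(s)]
        parts.extend(np.array([e.epoch], dtype=np.int64) for e in self.episodic)
        if not parts:
            return np.array([], dtype=np.int64)
        return np.concatenate(parts)

    def episodic_in_day(self, day: DayWindow) -> list:
        return sorted(
            (e for e in self.episodic if day.contains_epoch(e.epoch)),
            key=lambda e: (e.epoch, e.kind.value),
        )


def _floor_to_boundary(t: datetime, boundary_hour: int, zone: ZoneInfo) -> datetime:
    """Latest boundary-hour instant at or before ``t`` in ``zone``."""
    local = t.astimezone(zone)
    anchor = local.replace(hour=boundary_hour, minute=0, second=0, microsecond=0)
    if local < anchor:
        anchor = (local - timedelta(days=1)).replace(
            hour=boundary_hour, minute=0, second=0, microsecond=0
        )
    # re-resolve tzinfo so DST offsets are correct for the anchor date
    return anchor.replace(tzinfo=None).replace(tzinfo=zone) if zone else anchor


def partition_days(
    timestamps: Iterable[datetime],
    day_boundary_hour: int = 16,
    tz: str | ZoneInfo = "UTC",
) -> list[DayWindow]:
    """Partition timestamped data into contiguous 24-h clinical-day windows.

    Windows are half-open [start, end), start at ``day_boundary_hour`` local
    time in ``tz``, cover every supplied timestamp, and are numbered Day 1..N
    from the earliest datum.  All timestamps must be timezone-aware (or all
    naive, in which case they are interpreted in ``tz``).
    """
    ts = list(timestamps)
    if not ts:
        raise ValidationError("no data: cannot partition an empty timestamp set")
    if not 0 <= day_boundary_hour <= 23:
        raise ValidationError("day_boundary_hour must be in 0..23")
    zone = _resolve_tz(tz)
    aware = [t.tzinfo is not None for t in ts]
    if any(aware) and not all(aware):
        raise ValidationError("mixed naive and timezone-aware timestamps")
    if not any(aware):
        ts = [t.replace(tzinfo=zone) for t in ts]

    lo, hi = min(ts), max(ts)
    start = _floor_to_boundary(lo, day_boundary_hour, zone)
    windows: list[DayWindow] = []
    index = 1
    while True:
        nxt_local = (start.astimezone(zone) + timedelta(days=1)).replace(
            hour=day_boundary_hour, minute=0, second=0, microsecond=0
        )
        end = nxt_local.replace(tzinfo=None).replace(tzinfo=zone)
        windows.append(DayWindow(index=index, start=start, end=end))
        if hi < end:
            break
        start = end
        index += 1
        if index > 100000:  # pragma: no cover - guard against degenerate input
            raise ValidationError("timestamp span too large to partition")
    return windows


def validate_record(record: PatientRecord) -> list[str]:
    """Return one human-readable message per broken invariant (empty = valid).

    Content problems never raise; structurally impossible objects (which the
    dataclass constructors reject) cannot reach this function.
    """
    messages: list[str] = []
    seen: set[Channel] = set()
    for channel, series in record.channels.items():
        channel = Channel(channel)
        if channel in seen:
            messages.append(f"channel {channel.value} appears more than once")
        seen.add(channel)
        if series.channel is not channel:
            messages.append(
                f"channel key {channel.value} holds a series labelled {series.channel.value}"
            )
        messages.extend(series.problems())

    if record.days:
        day_start = record.days[0].start_epoch
        day_end = record.days[-1].end_epoch
        for prev, nxt in zip(record.days, record.days[1:]):
            if prev.end_epoch != nxt.start_epoch:
                messages.append(
                    f"day windows {prev.index} and {nxt.index} are not contiguous"
                )
            if nxt.index != prev.index + 1:
                messages.append(
                    f"day indices {prev.index} -> {nxt.index} are not consecutive"
                )
        for channel, series in record.channels.items():
            if len(series) and (
                series.times[0] < day_start or series.times[-1] >= day_end
            ):
                messages.append(
                    f"{Channel(channel).value}: samples fall outside the day windows"
                )
        for e in record.episodic:
            if not day_start <= e.epoch < day_end:
                messages.append(
                    f"episodic {e.kind.value} at t={e.epoch} outside the day windows"
                )
    elif record.channels or record.episodic:
        messages.append("record has data but no day windows")
    return messages


def build_record(
    patient_id: str,
    display_name: str,
    channels: dict,
    episodic: Sequence[EpisodicMeasurement] = (),
    timezone_name: str = "UTC",
    day_boundary_hour: int = 16,
) -> PatientRecord:
    """Assemble a :class:`PatientRecord`, deriving the day windows from the data."""
    zone = ZoneInfo(timezone_name)
    epochs: list[datetime] = []
    for series in channels.values():
        if len(series):
            epochs.append(datetime.fromtimestamp(int(series.times[0]), tz=zone))
            epochs.append(datetime.fromtimestamp(int(series.times[-1]), tz=zone))
    epochs.extend(e.t for e in episodic)
    days = (
        partition_days(epochs, day_boundary_hour=day_boundary_hour, tz=zone)
        if epochs
        else []
    )
    return PatientRecord(
        patient_id=patient_id,
        display_name=display_name,
        timezone=timezone_name,
        channels={Channel(c): s for c, s in channels.items()},
        episodic=sorted(episodic, key=lambda e: e.epoch),
        days=days,
    )
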