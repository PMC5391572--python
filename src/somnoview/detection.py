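"""Sleep/wear-period detection and 30-minute threshold-violation blocking.

The detection rules, per channel:

* SpO2 — a block is flagged *low* when at least ``min_violation_samples``
  samples fall strictly below the low threshold (default 92 %).
* Heart rate — flagged *low* below 60 bpm and/or *high* above 100 bpm; a
  single block may carry both flags.
* Activity — flagged *high* when the mean over the block is strictly above
  the threshold (default 12 VMU).

Blocks lie on a grid anchored at the clinical-day start (16:00); the sleep
period spans from the first to the last grid slot containing any SpO2 or
heart-rate sample, and only blocks overlapping the sleep period are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Optional
from zoneinfo import ZoneInfo

import numpy as np

from .core_model import (
    Channel,
    ChannelSeries,
    DayWindow,
    EpisodicMeasurement,
    PatientRecord,
    ThresholdConfig,
    ValidationError,
)

__all__ = [
    "FlagKind",
    "SleepPeriod",
    "WearPeriod",
    "ViolationBlock",
    "DaySummary",
    "detect_sleep_period",
    "detect_wear",
    "block_grid",
    "flag_activity_blocks",
    "flag_range_blocks",
    "summarize_day",
]


class FlagKind(str, Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class SleepPeriod:
    """Span from the first to the last slot with SpO2 or HR data in a day."""

    day_index: int
    start: int  # epoch seconds, slot-aligned
    end: int  # epoch seconds, exclusive

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError("sleep period must have positive duration")


@dataclass(frozen=True)
class WearPeriod:
    """Maximal intervals during which the pulse oximeter produced data."""

    day_index: int
    intervals: tuple  # tuple[(start_epoch, end_epoch), ...], disjoint, sorted

    def __post_init__(self) -> None:
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for (a, b) in ivs:
            if a > b:
                raise ValidationError("wear interval reversed")
        for (_, b), (c, _) in zip(ivs, ivs[1:]):
            if c <= b:
                raise ValidationError("wear intervals overlap or are unsorted")


@dataclass(frozen=True, order=True)
class ViolationBlock:
    """One grid-aligned block of one channel flagged against its threshold."""

    channel: Channel
    start: int  # epoch seconds, grid-aligned
    end: int
    kind: FlagKind
    statistic: float  # min (low) / max (high) / mean (activity) that triggered
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("a flagged block must contain samples")
        if self.channel is Channel.SPO2 and self.kind is not FlagKind.LOW:
            raise ValidationError("spo2 blocks can only be flagged low")
        if self.channel is Channel.ACTIVITY and self.kind is not FlagKind.HIGH:
            raise ValidationError("activity blocks can only be flagged high")


@dataclass
class DaySummary:
    """Everything the display needs for one clinical day."""

    day: DayWindow
    sleep: Optional[SleepPeriod]
    wear: WearPeriod
    blocks: list = field(default_factory=list)  # list[ViolationBlock], sorted
    episodic: list = field(default_factory=list)  # list[EpisodicMeasurement]

    def to_json_dict(self, tz: str = "UTC") -> dict:
        zone = ZoneInfo(tz)

        def iso(t: int) -> str:
            return datetime.fromtimestamp(t, tz=zone).isoformat()

        out: dict = {
            "day_index": self.day.index,
            "day_start": iso(self.day.start_epoch),
            "day_end": iso(self.day.end_epoch),
            "sleep": None,
            "wear": [[iso(a), iso(b)] for a, b in self.wear.intervals],
            "blocks": [
                {
                    "channel": b.channel.value,
                    "kind": b.kind.value,
                    "start": iso(b.start),
                    "end": iso(b.end),
                    "statistic": b.statistic,
                    "n_samples": b.n_samples,
                }
                for b in self.blocks
            ],
            "episodic": [],
        }
        if self.sleep is not None:
            out["sleep"] = {"start": iso(self.sleep.start), "end": iso(self.sleep.end)}
        for e in self.episodic:
            item: dict = {"kind": e.kind.value, "t": iso(e.epoch)}
            if e.weight_kg is not None:
                item["weight_kg"] = e.weight_kg
            if e.systolic_mmhg is not None:
                item["systolic_mmhg"] = e.systolic_mmhg
                item["diastolic_mmhg"] = e.diastolic_mmhg
            if e.subjective_score is not None:
                item["subjective_score"] = e.subjective_score
                item["subjective_items"] = [list(p) for p in e.subjective_items]
            out["episodic"].append(item)
        return out


def block_grid(day: DayWindow, block_minutes: int = 30) -> list[tuple[int, int]]:
    """Contiguous half-open block intervals anchored at the day start."""
    if block_minutes <= 0 or 1440 % block_minutes != 0:
        raise ValidationError("block_minutes must divide 1440")
    step = block_minutes * 60
    starts = np.arange(day.start_epoch, day.end_epoch, step, dtype=np.int64)
    return [(int(s), int(min(s + step, day.end_epoch))) for s in starts]


def _slot_index(times: np.ndarray, day: DayWindow, slot_s: int) -> np.ndarray:
    return (times - day.start_epoch) // slot_s


def detect_sleep_period(
    record: PatientRecord, day: DayWindow, slot_minutes: int = 30
) -> Optional[SleepPeriod]:
    """First-to-last slot with any SpO2 or HR sample; ``None`` when neither
    channel has data inside the day."""
    slot_s = slot_minutes * 60
    slots: list[int] = []
    for channel in (Channel.SPO2, Channel.HEART_RATE):
        series = record.channel(channel)
        if series is None or not len(series):
            continue
        sub = series.slice_epoch(day.start_epoch, day.end_epoch)
        if len(sub):
            idx = _slot_index(sub.times, day, slot_s)
            slots.append(int(idx.min()))
            slots.append(int(idx.max()))
    if not slots:
        return None
    start = day.start_epoch + min(slots) * slot_s
    end = min(day.start_epoch + (max(slots) + 1) * slot_s, day.end_epoch)
    return SleepPeriod(day_index=day.index, start=start, end=end)


def detect_wear(
    record: PatientRecord, day: DayWindow, gap_tolerance_s: int = 60
) -> WearPeriod:
    """Maximal intervals in which SpO2 inter-sample gaps are <= tolerance."""
    series = record.channel(Channel.SPO2)
    if series is None or not len(series):
        return WearPeriod(day_index=day.index, intervals=())
    sub = series.slice_epoch(day.start_epoch, day.end_epoch)
    if not len(sub):
        return WearPeriod(day_index=day.index, intervals=())
    t = sub.times
    breaks = np.flatnonzero(np.diff(t) > gap_tolerance_s)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    intervals = tuple((int(t[i]), int(t[j])) for i, j in zip(starts, ends))
    return WearPeriod(day_index=day.index, intervals=intervals)


def _block_groups(series: ChannelSeries, day: DayWindow, block_s: int):
    """Yield (block_start, values_in_block) for every non-empty grid block."""
    sub = series.slice_epoch(day.start_epoch, day.end_epoch)
    if not len(sub):
        return
    idx = _slot_index(sub.times, day, block_s)
    boundaries = np.flatnonzero(np.diff(idx)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [idx.size]))
    for i, j in zip(starts, ends):
        yield day.start_epoch + int(idx[i]) * block_s, sub.values[i:j]


def flag_activity_blocks(
    activity: ChannelSeries, day: DayWindow, cfg: ThresholdConfig
) -> list[ViolationBlock]:
    """Flag blocks whose sample mean is strictly above ``cfg.activity_high``."""
    if activity.channel is not Channel.ACTIVITY:
        raise ValidationError("flag_activity_blocks requires the activity channel")
    blocks: list[ViolationBlock] = []
    for start, vals in _block_groups(activity, day, cfg.block_seconds):
        mean = float(vals.mean())
        if mean > cfg.activity_high:
            blocks.append(
                ViolationBlock(
                    channel=Channel.ACTIVITY,
                    start=start,
                    end=start + cfg.block_seconds,
                    kind=FlagKind.HIGH,
                    statistic=mean,
                    n_samples=int(vals.size),
                )
            )
    return blocks


def flag_range_blocks(
    series: ChannelSeries, day: DayWindow, cfg: ThresholdConfig
) -> list[ViolationBlock]:
    """Flag SpO2/HR blocks containing samples strictly beyond a threshold.

    SpO2 only has a low rule; heart rate has both, and one block may yield
    both a low and a high flag.
    """
    if series.channel is Channel.SPO2:
        rules = [(FlagKind.LOW, cfg.spo2_low)]
    elif series.channel is Channel.HEART_RATE:
        rules = [(FlagKind.LOW, cfg.hr_low), (FlagKind.HIGH, cfg.hr_high)]
    else:
        raise ValidationError("flag_range_blocks requires the spo2 or heart_rate channel")
    blocks: list[ViolationBlock] = []
    for start, vals in _block_groups(series, day, cfg.block_seconds):
        for kind, threshold in rules:
            if kind is FlagKind.LOW:
                n_violating = int(np.count_nonzero(vals < threshold))
                stat = float(vals.min())
            else:
                n_violating = int(np.count_nonzero(vals > threshold))
                stat = float(vals.max())
            if n_violating >= cfg.min_violation_samples:
                blocks.append(
                    ViolationBlock(
                        channel=series.channel,
                        start=start,
                        end=start + cfg.block_seconds,
                        kind=kind,
                        statistic=stat,
                        n_samples=int(vals.size),
                    )
                )
    return blocks


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def summarize_day(
    record: PatientRecord, day: DayWindow, cfg: ThresholdConfig = ThresholdConfig()
) -> DaySummary:
    """Aggregate sleep period, wear intervals, violation blocks and episodic
    items for one clinical day.

    Violation blocks are restricted to grid intervals overlapping the sleep
    period (the middle display layer shows sleeping-period detail only).
    """
    sleep = detect_sleep_period(record, day, slot_minutes=cfg.block_minutes)
    wear = detect_wear(record, day, gap_tolerance_s=cfg.wear_gap_tolerance_s)
    blocks: list[ViolationBlock] = []
    if sleep is not None:
        for channel in (Channel.SPO2, Channel.HEART_RATE):
            series = record.channel(channel)
            if series is not None and len(series):
                blocks.extend(flag_range_blocks(series, day, cfg))
        activity = record.channel(Channel.ACTIVITY)
        if activity is not None and len(activity):
            blocks.extend(flag_activity_blocks(activity, day, cfg))
        blocks = [
            b for b in blocks if _overlaps(b.start, b.end, sleep.start, sleep.end)
        ]
    blocks.sort(key=lambda b: (b.start, b.channel.value, b.kind.value))
    return DaySummary(
        day=day,
        sleep=sleep,
        wear=wear,
        blocks=blocks,
        episodic=record.episodic_in_day(day),
    )
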