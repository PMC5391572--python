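"""Seeded generator of multi-night patient records with planted events.

Signals are piecewise-constant baselines plus truncated Gaussian jitter plus
trapezoidal event excursions (desaturations, brady/tachycardia, activity
bouts).  During an event excursion the signal follows the noise-free event
waveform exactly, so the set of grid blocks each planted event must flag
under the default thresholds is computable in closed form and recorded in a
:class:`GroundTruthLog`; with baselines at least two jitter-SDs away from
every threshold the detection module's flag set equals the log exactly.

Jitter is truncated at +/- 2 SD; activity bouts are aligned to whole grid
blocks so no block mixes bout and baseline samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np

from .core_model import (
    Channel,
    ChannelSeries,
    EpisodicKind,
    EpisodicMeasurement,
    PatientRecord,
    ThresholdConfig,
    build_record,
)
from .detection import FlagKind
from .usability_stats import SusResponse, score_sus

__all__ = [
    "GeneratorConfig",
    "PlantedEvent",
    "GroundTruthLog",
    "generate_record",
    "generate_sus_responses",
]

_JITTER_TRUNC_SD = 2.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic six-night heart-failure record generator."""

    seed: int = 0
    n_nights: int = 6
    patient_id: str = "synthetic-001"
    display_name: str = "Synthetic Patient"
    timezone: str = "UTC"
    start_date: str = "2016-01-04"  # first clinical day starts 16:00 this date
    day_boundary_hour: int = 16

    # sleep timing
    sleep_start_hour: float = 23.0  # mean clock hour of sleep onset
    sleep_start_sd_minutes: float = 25.0
    sleep_duration_mean_h: float = 7.5
    sleep_duration_sd_h: float = 0.5

    # SpO2
    spo2_baseline_mean: float = 96.0
    spo2_baseline_sd: float = 0.4  # jitter SD, truncated at 2 SD
    desat_events_per_night: int = 2
    desat_depth_range: tuple = (85.0, 91.0)
    desat_duration_range: tuple = (90, 300)  # seconds, plateau

    # heart rate
    hr_baseline_mean: float = 72.0
    hr_baseline_sd: float = 2.0
    brady_events_per_night: int = 1
    brady_magnitude_range: tuple = (45.0, 55.0)
    brady_duration_range: tuple = (90, 240)
    tachy_events_per_night: int = 1
    tachy_magnitude_range: tuple = (105.0, 120.0)
    tachy_duration_range: tuple = (90, 240)

    # activity
    activity_baseline_mean: float = 1.5
    activity_baseline_sd: float = 0.5
    activity_bouts_per_night: int = 1
    activity_bout_intensity_range: tuple = (20.0, 40.0)
    activity_bout_blocks_range: tuple = (1, 2)  # duration in whole grid blocks

    # sampling artifacts
    gap_rate: float = 0.005  # per-sample Bernoulli dropout
    long_gap_probability: float = 0.3  # per night, pulse-ox removal
    long_gap_duration_range: tuple = (600, 1800)  # seconds

    # episodic
    weight_start_kg: float = 82.0
    weight_daily_drift_kg: float = 0.25
    weight_noise_sd_kg: float = 0.1
    bp_systolic_mean: float = 126.0
    bp_systolic_sd: float = 8.0
    bp_diastolic_mean: float = 78.0
    bp_diastolic_sd: float = 6.0
    subjective_score_range: tuple = (0.0, 10.0)
    subjective_categories: tuple = ("breathlessness", "fatigue", "swelling")

    event_ramp_s: int = 20
    min_event_separation_blocks: int = 1
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def __post_init__(self) -> None:
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        for name in (
            "sleep_start_sd_minutes", "sleep_duration_sd_h", "spo2_baseline_sd",
            "hr_baseline_sd", "activity_baseline_sd", "weight_noise_sd_kg",
            "bp_systolic_sd", "bp_diastolic_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "desat_depth_range", "desat_duration_range", "brady_magnitude_range",
            "brady_duration_range", "tachy_magnitude_range", "tachy_duration_range",
            "activity_bout_intensity_range", "activity_bout_blocks_range",
            "long_gap_duration_range", "subjective_score_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be an ordered (low, high) pair")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")


@dataclass(frozen=True)
class PlantedEvent:
    night: int  # day index, 1-based
    channel: Channel
    kind: FlagKind
    start: int  # epoch seconds
    end: int
    magnitude: float  # plateau value (desat depth / HR extreme / bout VMU)


@dataclass
class GroundTruthLog:
    """Planted events plus the grid blocks that must flag under the config's
    thresholds, keyed (day_index, channel, kind, block_start_epoch)."""

    events: list = field(default_factory=list)  # list[PlantedEvent]
    expected_blocks: set = field(default_factory=set)
    clipped_events: int = 0  # events dropped for lack of placement room

    def to_json_dict(self) -> dict:
        return {
            "events": [
                {
                    "night": e.night,
                    "channel": e.channel.value,
                    "kind": e.kind.value,
                    "start": e.start,
                    "end": e.end,
                    "magnitude": e.magnitude,
                }
                for e in self.events
            ],
            "expected_blocks": [
                {"day_index": d, "channel": c, "kind": k, "block_start": s}
                for d, c, k, s in sorted(self.expected_blocks)
            ],
            "clipped_events": self.clipped_events,
        }


def _truncated_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    j = rng.normal(0.0, sd, size)
    return np.clip(j, -_JITTER_TRUNC_SD * sd, _JITTER_TRUNC_SD * sd)


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    dur_lo: int,
    dur_hi: int,
    lo: int,
    hi: int,
    min_sep_s: int,
) -> list[tuple[int, int]]:
    """Non-overlapping (start, duration) pairs inside [lo, hi) separated by
    at least ``min_sep_s``; events that cannot be placed are dropped."""
    placed: list[tuple[int, int]] = []
    for _ in range(n_events):
        ok = False
        for _attempt in range(200):
            dur = int(rng.integers(dur_lo, dur_hi + 1))
            if hi - lo <= dur:
                break
            start = int(rng.integers(lo, hi - dur))
            if all(
                start + dur + min_sep_s <= s or e + min_sep_s <= start
                for s, e in ((s, s + d) for s, d in placed)
            ):
                placed.append((start, dur))
                ok = True
                break
        if not ok:
            continue
    return sorted(placed)


def _trapezoid(
    nf: np.ndarray, mask: np.ndarray, t0: int, start: int, dur: int,
    baseline: float, plateau: float, ramp_s: int,
) -> None:
    """Write a baseline->plateau->baseline trapezoid into ``nf`` (indexed by
    epoch - t0) and mark the touched samples in ``mask``."""
    n = nf.size
    a = start - t0
    ramp = max(1, ramp_s)
    down = np.arange(ramp)
    i0, i1 = max(0, a - ramp), min(n, a)
    if i1 > i0:
        seg = baseline + (plateau - baseline) * (down + 1) / ramp
        nf[i0:i1] = seg[ramp - (i1 - i0):]
        mask[i0:i1] = True
    j0, j1 = max(0, a), min(n, a + dur)
    if j1 > j0:
        nf[j0:j1] = plateau
        mask[j0:j1] = True
    k0, k1 = max(0, a + dur), min(n, a + dur + ramp)
    if k1 > k0:
        seg = plateau + (baseline - plateau) * (down + 1) / ramp
        nf[k0:k1] = seg[: k1 - k0]
        mask[k0:k1] = True


def _expected_blocks_for_day(
    day_index: int,
    day_start: int,
    block_s: int,
    kept: dict,
    nf_kept: dict,
    min_violation_samples: int,
    cfg: ThresholdConfig,
) -> set:
    """Blocks that must flag, computed from the noise-free values of the
    samples that survived dropout, restricted to the sleep period implied by
    the kept SpO2/HR sample times (mirrors the display's sleep restriction)."""
    slot_ids: list[int] = []
    for ch in (Channel.SPO2, Channel.HEART_RATE):
        t = kept[ch]
        if t.size:
            idx = (t - day_start) // block_s
            slot_ids.extend((int(idx.min()), int(idx.max())))
    if not slot_ids:
        return set()
    first_slot, last_slot = min(slot_ids), max(slot_ids)
    out: set = set()

    def blocks_of(ch: Channel):
        t = kept[ch]
        v = nf_kept[ch]
        if not t.size:
            return
        idx = (t - day_start) // block_s
        bounds = np.flatnonzero(np.diff(idx)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [idx.size]))
        for i, j in zip(starts, ends):
            yield int(idx[i]), v[i:j]

    for slot, vals in blocks_of(Channel.SPO2):
        if first_slot <= slot <= last_slot:
            if int(np.count_nonzero(vals < cfg.spo2_low)) >= min_violation_samples:
                out.add((day_index, Channel.SPO2.value, FlagKind.LOW.value, day_start + slot * block_s))
    for slot, vals in blocks_of(Channel.HEART_RATE):
        if first_slot <= slot <= last_slot:
            if int(np.count_nonzero(vals < cfg.hr_low)) >= min_violation_samples:
                out.add((day_index, Channel.HEART_RATE.value, FlagKind.LOW.value, day_start + slot * block_s))
            if int(np.count_nonzero(vals > cfg.hr_high)) >= min_violation_samples:
                out.add((day_index, Channel.HEART_RATE.value, FlagKind.HIGH.value, day_start + slot * block_s))
    for slot, vals in blocks_of(Channel.ACTIVITY):
        if first_slot <= slot <= last_slot and vals.size:
            if float(vals.mean()) > cfg.activity_high:
                out.add((day_index, Channel.ACTIVITY.value, FlagKind.HIGH.value, day_start + slot * block_s))
    return out


def generate_record(cfg: GeneratorConfig) -> tuple[PatientRecord, GroundTruthLog]:
    """Generate one patient's record plus its ground-truth event log.

    Identical configs produce identical output (one ``numpy`` Generator
    seeded from ``cfg.seed`` drives everything).
    """
    rng = np.random.default_rng(cfg.seed)
    zone = ZoneInfo(cfg.timezone)
    y, m, d = (int(p) for p in cfg.start_date.split("-"))
    first_day_start = datetime(y, m, d, cfg.day_boundary_hour, tzinfo=zone)
    block_s = cfg.thresholds.block_seconds
    log = GroundTruthLog()

    times: dict[Channel, list] = {ch: [] for ch in Channel}
    values: dict[Channel, list] = {ch: [] for ch in Channel}
    episodic: list[EpisodicMeasurement] = []

    for night in range(1, cfg.n_nights + 1):
        day_start_dt = first_day_start + timedelta(days=night - 1)
        day_start = int(day_start_dt.timestamp())
        day_end = day_start + 86400

        onset_offset_h = (cfg.sleep_start_hour - cfg.day_boundary_hour) % 24
        onset = day_start + int(
            onset_offset_h * 3600 + rng.normal(0, cfg.sleep_start_sd_minutes * 60)
        )
        onset = max(day_start, min(onset, day_end - 3600))
        duration = int(
            max(1.0, rng.normal(cfg.sleep_duration_mean_h, cfg.sleep_duration_sd_h))
            * 3600
        )
        sleep_end = min(onset + duration, day_end - 1)
        t = np.arange(onset, sleep_end, dtype=np.int64)
        n = t.size
        min_sep_s = cfg.min_event_separation_blocks * block_s
        margin = cfg.event_ramp_s + 1
        ev_lo, ev_hi = onset + margin, sleep_end - margin

        # --- SpO2: baseline + desaturation dips -------------------------------
        spo2_nf = np.full(n, cfg.spo2_baseline_mean)
        spo2_mask = np.zeros(n, dtype=bool)
        desats = _place_events(
            rng, cfg.desat_events_per_night,
            int(cfg.desat_duration_range[0]), int(cfg.desat_duration_range[1]),
            ev_lo, ev_hi, min_sep_s,
        )
        log.clipped_events += cfg.desat_events_per_night - len(desats)
        for start, dur in desats:
            depth = float(rng.uniform(*cfg.desat_depth_range))
            _trapezoid(spo2_nf, spo2_mask, onset, start, dur,
                       cfg.spo2_baseline_mean, depth, cfg.event_ramp_s)
            log.events.append(PlantedEvent(night, Channel.SPO2, FlagKind.LOW,
                                           start, start + dur, depth))

        # --- heart rate: brady dips and tachy rises (shared separation) -------
        hr_nf = np.full(n, cfg.hr_baseline_mean)
        hr_mask = np.zeros(n, dtype=bool)
        n_brady, n_tachy = cfg.brady_events_per_night, cfg.tachy_events_per_night
        hr_events = _place_events(
            rng, n_brady + n_tachy,
            int(min(cfg.brady_duration_range[0], cfg.tachy_duration_range[0])),
            int(max(cfg.brady_duration_range[1], cfg.tachy_duration_range[1])),
            ev_lo, ev_hi, min_sep_s,
        )
        log.clipped_events += n_brady + n_tachy - len(hr_events)
        kinds = [FlagKind.LOW] * min(n_brady, len(hr_events))
        kinds += [FlagKind.HIGH] * (len(hr_events) - len(kinds))
        for (start, dur), kind in zip(hr_events, kinds):
            if kind is FlagKind.LOW:
                magnitude = float(rng.uniform(*cfg.brady_magnitude_range))
            else:
                magnitude = float(rng.uniform(*cfg.tachy_magnitude_range))
            _trapezoid(hr_nf, hr_mask, onset, start, dur,
                       cfg.hr_baseline_mean, magnitude, cfg.event_ramp_s)
            log.events.append(PlantedEvent(night, Channel.HEART_RATE, kind,
                                           start, start + dur, magnitude))

        # --- activity: block-aligned bouts ------------------------------------
        act_nf = np.full(n, cfg.activity_baseline_mean)
        act_mask = np.zeros(n, dtype=bool)
        first_block = -((onset - day_start) // -block_s)  # ceil
        last_block = (sleep_end - day_start) // block_s  # exclusive
        free = list(range(first_block, last_block))
        for _ in range(cfg.activity_bouts_per_night):
            span = int(rng.integers(cfg.activity_bout_blocks_range[0],
                                    cfg.activity_bout_blocks_range[1] + 1))
            candidates = [
                b for b in free
                if all(b + o in free for o in range(span))
            ]
            if not candidates:
                log.clipped_events += 1
                continue
            b0 = int(candidates[rng.integers(0, len(candidates))])
            intensity = float(rng.uniform(*cfg.activity_bout_intensity_range))
            bs = day_start + b0 * block_s
            be = bs + span * block_s
            sel = (t >= bs) & (t < be)
            act_nf[sel] = intensity
            act_mask[sel] = True
            log.events.append(PlantedEvent(night, Channel.ACTIVITY, FlagKind.HIGH,
                                           bs, be, intensity))
            for o in range(-cfg.min_event_separation_blocks,
                           span + cfg.min_event_separation_blocks):
                if b0 + o in free:
                    free.remove(b0 + o)

        # --- jitter (suppressed inside event excursions) and dropout ----------
        spo2 = np.where(spo2_mask, spo2_nf,
                        spo2_nf + _truncated_normal(rng, cfg.spo2_baseline_sd, n))
        spo2 = np.clip(spo2, 0.0, 100.0)
        hr = np.where(hr_mask, hr_nf,
                      hr_nf + _truncated_normal(rng, cfg.hr_baseline_sd, n))
        hr = np.maximum(hr, 0.0)
        act = np.where(act_mask, act_nf,
                       act_nf + _truncated_normal(rng, cfg.activity_baseline_sd, n))
        act = np.maximum(act, 0.0)

        keep = {ch: rng.random(n) >= cfg.gap_rate for ch in Channel}
        if rng.random() < cfg.long_gap_probability and n > 0:
            gap_dur = int(rng.integers(*cfg.long_gap_duration_range))
            gap_start = int(rng.integers(onset, max(onset + 1, sleep_end - gap_dur)))
            in_gap = (t >= gap_start) & (t < gap_start + gap_dur)
            keep[Channel.SPO2] &= ~in_gap  # pulse-ox removed: SpO2 and HR
            keep[Channel.HEART_RATE] &= ~in_gap

        kept_t = {ch: t[keep[ch]] for ch in Channel}
        kept_v = {
            Channel.SPO2: spo2[keep[Channel.SPO2]],
            Channel.HEART_RATE: hr[keep[Channel.HEART_RATE]],
            Channel.ACTIVITY: act[keep[Channel.ACTIVITY]],
        }
        nf_kept = {
            Channel.SPO2: spo2_nf[keep[Channel.SPO2]],
            Channel.HEART_RATE: hr_nf[keep[Channel.HEART_RATE]],
            Channel.ACTIVITY: act_nf[keep[Channel.ACTIVITY]],
        }
        for ch in Channel:
            times[ch].append(kept_t[ch])
            values[ch].append(kept_v[ch])

        log.expected_blocks |= _expected_blocks_for_day(
            night, day_start, block_s, kept_t, nf_kept,
            cfg.thresholds.min_violation_samples, cfg.thresholds,
        )

        # --- episodic entries -------------------------------------------------
        def dt(offset_s: int) -> datetime:
            return datetime.fromtimestamp(day_start + offset_s, tz=zone)

        weight = cfg.weight_start_kg + cfg.weight_daily_drift_kg * (night - 1)
        weight += float(rng.normal(0, cfg.weight_noise_sd_kg))
        episodic.append(EpisodicMeasurement(
            kind=EpisodicKind.WEIGHT, t=dt(15 * 3600), weight_kg=round(weight, 2)))
        for offset in (4 * 3600 + 300, 15 * 3600 + 600):
            sys_bp = float(rng.normal(cfg.bp_systolic_mean, cfg.bp_systolic_sd))
            dia_bp = float(rng.normal(cfg.bp_diastolic_mean, cfg.bp_diastolic_sd))
            dia_bp = min(dia_bp, sys_bp - 10.0)
            episodic.append(EpisodicMeasurement(
                kind=EpisodicKind.BLOOD_PRESSURE, t=dt(offset),
                systolic_mmhg=round(sys_bp, 0), diastolic_mmhg=round(dia_bp, 0)))
        lo, hi = cfg.subjective_score_range
        items = tuple(
            (cat, float(np.round(rng.uniform(lo, hi), 1)))
            for cat in cfg.subjective_categories
        )
        score = float(np.round(np.mean([v for _, v in items]), 1)) if items else lo
        episodic.append(EpisodicMeasurement(
            kind=EpisodicKind.SUBJECTIVE, t=dt(5 * 3600),
            subjective_score=score, subjective_items=items))

    channels = {
        ch: ChannelSeries(
            ch,
            np.concatenate(times[ch]) if times[ch] else np.array([], dtype=np.int64),
            np.concatenate(values[ch]) if values[ch] else np.array([]),
        )
        for ch in Channel
    }
    record = build_record(
        patient_id=cfg.patient_id,
        display_name=cfg.display_name,
        channels=channels,
        episodic=episodic,
        timezone_name=cfg.timezone,
        day_boundary_hour=cfg.day_boundary_hour,
    )
    log.events.sort(key=lambda e: (e.night, e.start, e.channel.value))
    return record, log


def _pattern_for_total(total: int) -> tuple:
    """A 10-item Likert response whose summed contribution equals ``total``
    (0..40), spreading the contribution as evenly as possible."""
    base, rem = divmod(total, 10)
    items = []
    for i in range(10):
        c = base + (1 if i < rem else 0)
        items.append(c + 1 if i % 2 == 0 else 5 - c)
    return tuple(items)


def generate_sus_responses(
    n: int, target_mean: float, target_sd: float, seed: int,
    tolerance: float = 1.0, max_attempts: int = 500,
) -> list[SusResponse]:
    """Likert responses whose transformed overall scores hit a target
    mean/SD within ``tolerance`` points (rejection resampling).

    Raises ``ValueError`` when the target is infeasible (e.g. mean 100 with a
    positive SD: every score saturates at 100, so the sample SD is 0).
    """
    if not 0 <= target_mean <= 100:
        raise ValueError("target_mean must lie in [0, 100]")
    if target_sd < 0:
        raise ValueError("target_sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if target_sd == 0:
        total = int(round(target_mean / 2.5))
        if abs(total * 2.5 - target_mean) > tolerance:
            raise ValueError("target_mean not representable with zero SD")
        return [
            SusResponse(respondent_id=f"r{i + 1:02d}", items=_pattern_for_total(total))
            for i in range(n)
        ]
    for _ in range(max_attempts):
        raw = rng.normal(target_mean, target_sd, n)
        totals = np.clip(np.round(raw / 2.5), 0, 40).astype(int)
        scores = totals * 2.5
        if n >= 2:
            ok_sd = abs(float(np.std(scores, ddof=1)) - target_sd) <= tolerance
        else:
            ok_sd = True
        if abs(float(scores.mean()) - target_mean) <= tolerance and ok_sd:
            responses = [
                SusResponse(respondent_id=f"r{i + 1:02d}", items=_pattern_for_total(int(tt)))
                for i, tt in enumerate(totals)
            ]
            assert all(
                abs(score_sus(r).overall - s) < 1e-9
                for r, s in zip(responses, scores)
            )
            return responses
    raise ValueError(
        f"could not hit mean {target_mean} / SD {target_sd} with n={n} "
        f"within +/-{tolerance} after {max_attempts} attempts (target infeasible?)"
    )
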