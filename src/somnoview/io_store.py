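"""CSV readers/writers and the file-backed per-patient store.

The store keeps the episodic/continuous split as two separate CSV tables per
patient (plus a JSON manifest) — continuous samples in ``continuous.csv``
(``timestamp,channel,value``) and episodic measurements in long form in
``episodic.csv`` (``timestamp,kind,key,value``).  Timestamps are ISO-8601
with UTC offset so round-trips are exact to one second.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .core_model import (
    Channel,
    ChannelSeries,
    EpisodicKind,
    EpisodicMeasurement,
    PatientRecord,
    ValidationError,
    build_record,
)
from .usability_stats import RatingsMatrix, SusResponse

logger = logging.getLogger(__name__)

__all__ = [
    "read_channel_csv",
    "read_episodic_csv",
    "write_store",
    "read_store",
    "list_patients",
    "read_sus_csv",
    "read_ratings_csv",
]

_CONTINUOUS_FILE = "continuous.csv"
_EPISODIC_FILE = "episodic.csv"
_MANIFEST_FILE = "manifest.json"


def _parse_timestamps(raw: pd.Series, path: Path) -> np.ndarray:
    """Parse an ISO-8601 timestamp column to epoch seconds, reporting the
    CSV line number (1-based, header = line 1) of the first bad entry."""
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValidationError(
            f"{path}: unparseable timestamp {raw[bad].iloc[0]!r} on line {line}"
        )
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise ValidationError(f"{path}: missing timestamp on line {line}")
    return (parsed.astype("int64") // 10**9).to_numpy()


def read_channel_csv(path: str | Path, channel: Channel | str) -> ChannelSeries:
    """Read one continuous channel from a ``timestamp,value`` CSV.

    Rows are sorted by time; duplicate timestamps are collapsed to their mean
    with a logged warning (device re-transmission artifacts).
    """
    path = Path(path)
    channel = Channel(channel)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"timestamp", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        return ChannelSeries(channel, np.array([], dtype=np.int64), np.array([]))
    epochs = _parse_timestamps(df["timestamp"], path)
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        line = int(np.flatnonzero(values.isna().to_numpy())[0]) + 2
        raise ValidationError(f"{path}: unparseable value on line {line}")
    frame = pd.DataFrame({"t": epochs, "value": values.to_numpy(dtype=float)})
    if frame["t"].duplicated().any():
        n_dup = int(frame["t"].duplicated().sum())
        logger.warning(
            "%s: %d duplicate timestamp(s) in %s channel collapsed to mean",
            path,
            n_dup,
            channel.value,
        )
        frame = frame.groupby("t", as_index=False)["value"].mean()
    frame = frame.sort_values("t", kind="mergesort")
    return ChannelSeries(
        channel,
        frame["t"].to_numpy(dtype=np.int64),
        frame["value"].to_numpy(dtype=float),
    )


def _episodic_to_rows(e: EpisodicMeasurement, zone: ZoneInfo) -> list[dict]:
    iso = datetime.fromtimestamp(e.epoch, tz=zone).isoformat()
    rows = []
    if e.kind is EpisodicKind.WEIGHT:
        rows.append({"timestamp": iso, "kind": e.kind.value, "key": "weight_kg", "value": e.weight_kg})
    elif e.kind is EpisodicKind.BLOOD_PRESSURE:
        rows.append({"timestamp": iso, "kind": e.kind.value, "key": "systolic_mmhg", "value": e.systolic_mmhg})
        rows.append({"timestamp": iso, "kind": e.kind.value, "key": "diastolic_mmhg", "value": e.diastolic_mmhg})
    else:
        rows.append({"timestamp": iso, "kind": e.kind.value, "key": "score", "value": e.subjective_score})
        for category, value in e.subjective_items:
            rows.append({"timestamp": iso, "kind": e.kind.value, "key": f"item:{category}", "value": value})
    return rows


def _episodic_from_group(epoch: int, kind: str, pairs: list[tuple[str, float]], tz: ZoneInfo) -> EpisodicMeasurement:
    t = datetime.fromtimestamp(epoch, tz=tz)
    kv = dict(pairs)
    kind_e = EpisodicKind(kind)
    if kind_e is EpisodicKind.WEIGHT:
        return EpisodicMeasurement(kind=kind_e, t=t, weight_kg=kv["weight_kg"])
    if kind_e is EpisodicKind.BLOOD_PRESSURE:
        return EpisodicMeasurement(
            kind=kind_e, t=t,
            systolic_mmhg=kv["systolic_mmhg"], diastolic_mmhg=kv["diastolic_mmhg"],
        )
    items = tuple(
        (k[len("item:"):], v) for k, v in pairs if k.startswith("item:")
    )
    return EpisodicMeasurement(
        kind=kind_e, t=t, subjective_score=kv["score"], subjective_items=items
    )


def read_episodic_csv(path: str | Path, tz: str = "UTC") -> list[EpisodicMeasurement]:
    """Read episodic measurements from a long-form ``timestamp,kind,key,value`` CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"timestamp", "kind", "key", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        return []
    epochs = _parse_timestamps(df["timestamp"], path)
    zone = ZoneInfo(tz)
    groups: dict[tuple[int, str], list[tuple[str, float]]] = {}
    order: list[tuple[int, str]] = []
    for epoch, kind, key, value in zip(epochs, df["kind"], df["key"], df["value"]):
        gk = (int(epoch), str(kind))
        if gk not in groups:
            groups[gk] = []
            order.append(gk)
        groups[gk].append((str(key), float(value)))
    out = [_episodic_from_group(e, k, groups[(e, k)], zone) for e, k in order]
    out.sort(key=lambda m: m.epoch)
    return out


def write_store(record: PatientRecord, store_dir: str | Path) -> Path:
    """Write one patient's data as two CSV tables plus a JSON manifest.

    Returns the per-patient directory.  The continuous and episodic tables
    are always both written, even when empty.
    """
    patient_dir = Path(store_dir) / record.patient_id
    patient_dir.mkdir(parents=True, exist_ok=True)
    zone = ZoneInfo(record.timezone)

    rows = []
    for channel in Channel:
        series = record.channel(channel)
        if series is None:
            continue
        for t, v in zip(series.times, series.values):
            rows.append(
                {
                    "timestamp": datetime.fromtimestamp(int(t), tz=zone).isoformat(),
                    "channel": channel.value,
                    "value": float(v),
                }
            )
    pd.DataFrame(rows, columns=["timestamp", "channel", "value"]).to_csv(
        patient_dir / _CONTINUOUS_FILE, index=False, float_format="%.17g"
    )

    erows: list[dict] = []
    for e in record.episodic:
        erows.extend(_episodic_to_rows(e, zone))
    pd.DataFrame(erows, columns=["timestamp", "kind", "key", "value"]).to_csv(
        patient_dir / _EPISODIC_FILE, index=False, float_format="%.17g"
    )

    manifest = {
        "patient_id": record.patient_id,
        "display_name": record.display_name,
        "timezone": record.timezone,
        "day_boundary_hour": 16,
        "files": {"continuous": _CONTINUOUS_FILE, "episodic": _EPISODIC_FILE},
    }
    if record.days:
        manifest["day_boundary_hour"] = record.days[0].start.astimezone(zone).hour
    (patient_dir / _MANIFEST_FILE).write_text(json.dumps(manifest, indent=2))
    return patient_dir


def read_store(store_dir: str | Path, patient_id: str) -> PatientRecord:
    """Load one patient from the store; raises ``FileNotFoundError`` for an
    unknown patient id."""
    patient_dir = Path(store_dir) / patient_id
    manifest_path = patient_dir / _MANIFEST_FILE
    if not manifest_path.exists():
        raise FileNotFoundError(f"patient {patient_id!r} not found in {store_dir}")
    manifest = json.loads(manifest_path.read_text())
    tz = manifest.get("timezone", "UTC")

    df = pd.read_csv(
        patient_dir / manifest["files"]["continuous"], float_precision="round_trip"
    )
    channels: dict[Channel, ChannelSeries] = {}
    if not df.empty:
        epochs = _parse_timestamps(df["timestamp"], patient_dir / _CONTINUOUS_FILE)
        for channel in Channel:
            mask = (df["channel"] == channel.value).to_numpy()
            if mask.any():
                t = epochs[mask]
                v = df["value"].to_numpy(dtype=float)[mask]
                order = np.argsort(t, kind="mergesort")
                channels[channel] = ChannelSeries(channel, t[order], v[order])

    episodic = read_episodic_csv(patient_dir / manifest["files"]["episodic"], tz=tz)
    return build_record(
        patient_id=manifest["patient_id"],
        display_name=manifest.get("display_name", manifest["patient_id"]),
        channels=channels,
        episodic=episodic,
        timezone_name=tz,
        day_boundary_hour=int(manifest.get("day_boundary_hour", 16)),
    )


def list_patients(store_dir: str | Path) -> list[str]:
    """Patient ids present in a store directory (those with a manifest)."""
    root = Path(store_dir)
    if not root.exists():
        return []
    return sorted(
        p.name for p in root.iterdir() if (p / _MANIFEST_FILE).exists()
    )


def read_sus_csv(path: str | Path) -> list[SusResponse]:
    """Read SUS questionnaires: ``respondent_id,item1,...,item10``, entries 1..5."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    item_cols = [f"item{i}" for i in range(1, 11)]
    missing = {"respondent_id", *item_cols} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    responses = []
    for _, row in df.iterrows():
        items = []
        for col in item_cols:
            value = row[col]
            if not float(value).is_integer() or not 1 <= int(value) <= 5:
                raise ValidationError(
                    f"{path}: respondent {row['respondent_id']!r} {col} = {value!r} "
                    "is not an integer in 1..5"
                )
            items.append(int(value))
        responses.append(SusResponse(respondent_id=str(row["respondent_id"]), items=tuple(items)))
    return responses


def read_ratings_csv(path: str | Path) -> RatingsMatrix:
    """Read a ratings matrix: first column target id, one column per rater."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.empty or df.shape[1] < 2:
        raise ValidationError(f"{path}: ratings matrix needs >= 2 targets and >= 2 raters")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: ratings matrix contains missing/non-finite cells")
    return RatingsMatrix(
        values=values,
        targets=tuple(str(i) for i in df.index),
        raters=tuple(str(c) for c in df.columns),
    )
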