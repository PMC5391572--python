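"""Static SVG rendering of the three-layer single-screen display.

The screen stacks, top to bottom: a header (patient/day, blood-pressure,
weight and subjective entries with times), a 24-h overview with the
pulse-oximeter wear line and the red 8-h band, an 8-h strip of 30-minute
violation blocks in three rows (SpO2, heart rate, activity), and three
temporally aligned 30-minute waveform panels.  Interactivity is replaced by
an explicit :class:`SelectionState`; rendering is a pure function of the
scene, so identical scenes produce byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional
from xml.sax.saxutils import escape
from zoneinfo import ZoneInfo

import numpy as np

from .core_model import (
    Channel,
    DayWindow,
    EpisodicKind,
    PatientRecord,
    ThresholdConfig,
    ValidationError,
)
from .detection import DaySummary, FlagKind

__all__ = [
    "SelectionState",
    "RenderScene",
    "SPO2_DISPLAY_RANGE",
    "HR_DISPLAY_RANGE",
    "COLORS",
    "build_scene",
    "render_svg",
    "cursor_readout",
    "default_selection",
]

#: Fixed waveform display ranges (values outside are clipped to the edge).
SPO2_DISPLAY_RANGE = (82.0, 100.0)
HR_DISPLAY_RANGE = (35.0, 125.0)

EIGHT_HOURS = 8 * 3600

COLORS = {
    "wear": "#1565c0",
    "band": "#d32f2f",
    "selected": "#d32f2f",
    "block": "#444444",
    "subjective": "#1565c0",
    "axis": "#888888",
    "wave": "#000000",
    "threshold": "#d32f2f",
    "cursor": "#2e7d32",
}

CANVAS = (1366, 768)
# vertical fractions: header / layer1 / layer2 / layer3
LAYOUT = (0.10, 0.20, 0.25, 0.45)
MARGIN_X = 60.0

_ROW_ORDER = (Channel.SPO2, Channel.HEART_RATE, Channel.ACTIVITY)
_ROW_LABEL = {Channel.SPO2: "SaO2", Channel.HEART_RATE: "HR", Channel.ACTIVITY: "Activity"}


@dataclass(frozen=True)
class SelectionState:
    """Which 8-h band and which 30-min block the screen focuses on."""

    day_index: int
    window8h_start: int  # epoch seconds
    block_start: int  # epoch seconds, on the block grid


@dataclass
class RenderScene:
    """Fully resolved content + geometry of one day's screen."""

    patient_label: str
    day_label: str
    tz: str
    day_start: int
    day_end: int
    bp_entries: list = field(default_factory=list)  # [{t, text}]
    weight_entries: list = field(default_factory=list)
    subjective_entries: list = field(default_factory=list)  # [{t, score, items}]
    wear_intervals: list = field(default_factory=list)  # [(start, end)]
    band: tuple = (0, 0)  # (start, end) of the 8-h interval
    rows: dict = field(default_factory=dict)  # channel -> [block dict]
    block_window: tuple = (0, 0)  # (start, end) of the selected 30 min
    panels: dict = field(default_factory=dict)  # channel -> panel dict
    cursor_t: Optional[int] = None
    cursor_values: tuple = (None, None, None)
    canvas: tuple = CANVAS
    layout: tuple = LAYOUT

    def to_json_dict(self) -> dict:
        return {
            "patient_label": self.patient_label,
            "day_label": self.day_label,
            "tz": self.tz,
            "day_start": self.day_start,
            "day_end": self.day_end,
            "bp_entries": self.bp_entries,
            "weight_entries": self.weight_entries,
            "subjective_entries": self.subjective_entries,
            "wear_intervals": [list(i) for i in self.wear_intervals],
            "band": list(self.band),
            "rows": {
                ch.value: blocks for ch, blocks in self.rows.items()
            },
            "block_window": list(self.block_window),
            "panels": {
                ch.value: {
                    "y_range": list(p["y_range"]),
                    "thresholds": list(p["thresholds"]),
                    "points": [[int(t), float(v)] for t, v in p["points"]],
                }
                for ch, p in self.panels.items()
            },
            "cursor_t": self.cursor_t,
            "cursor_values": list(self.cursor_values),
            "canvas": list(self.canvas),
            "layout": list(self.layout),
        }


def _clock(t: int, tz: str) -> str:
    return datetime.fromtimestamp(t, tz=ZoneInfo(tz)).strftime("%H:%M")


def cursor_readout(record: PatientRecord, t: int | datetime) -> tuple:
    """Nearest sample value within 1 s of ``t`` for each channel, else None.

    Returns (spo2, heart_rate, activity)."""
    epoch = int(t.timestamp()) if isinstance(t, datetime) else int(t)
    out = []
    for channel in _ROW_ORDER:
        series = record.channel(channel)
        if series is None or not len(series):
            out.append(None)
            continue
        i = int(np.searchsorted(series.times, epoch))
        best: Optional[float] = None
        best_d = 2
        for j in (i - 1, i):
            if 0 <= j < len(series):
                d = abs(int(series.times[j]) - epoch)
                if d <= 1 and d < best_d:
                    best, best_d = float(series.values[j]), d
        out.append(best)
    return tuple(out)


def default_selection(summary: DaySummary, cfg: ThresholdConfig = ThresholdConfig()) -> SelectionState:
    """8-h band anchored at sleep onset (floored to the block grid, clamped
    inside the day); selected block = first flagged block in the band, else
    the band's first grid block."""
    if summary.sleep is None:
        raise ValidationError(
            "day has no sleep period; pass an explicit SelectionState"
        )
    day = summary.day
    step = cfg.block_seconds
    band_start = day.start_epoch + ((summary.sleep.start - day.start_epoch) // step) * step
    band_start = min(band_start, day.end_epoch - EIGHT_HOURS)
    band_start = max(band_start, day.start_epoch)
    band_end = band_start + EIGHT_HOURS
    block = None
    for b in summary.blocks:
        if band_start <= b.start < band_end:
            block = b.start
            break
    if block is None:
        block = band_start
    return SelectionState(day_index=day.index, window8h_start=band_start, block_start=block)


def _panel_range(channel: Channel, values: np.ndarray, cfg: ThresholdConfig) -> tuple[float, float]:
    if channel is Channel.SPO2:
        return SPO2_DISPLAY_RANGE
    if channel is Channel.HEART_RATE:
        return HR_DISPLAY_RANGE
    hi = 2 * cfg.activity_high
    if values.size:
        hi = max(hi, float(values.max()))
    return (0.0, hi)


def build_scene(
    summary: DaySummary,
    record: PatientRecord,
    selection: SelectionState,
    cfg: ThresholdConfig = ThresholdConfig(),
    cursor_t: Optional[int] = None,
) -> RenderScene:
    """Resolve one day's screen content for a given selection.

    The selection must name this summary's day; its 8-h window must lie
    inside the day and its block on the grid inside the window.
    """
    day: DayWindow = summary.day
    if selection.day_index != day.index:
        raise ValidationError(
            f"selection is for day {selection.day_index}, summary is day {day.index}"
        )
    w = selection.window8h_start
    if not (day.start_epoch <= w and w + EIGHT_HOURS <= day.end_epoch):
        raise ValidationError("8-h window must lie inside the day")
    step = cfg.block_seconds
    if (w - day.start_epoch) % step != 0:
        raise ValidationError("8-h window start must lie on the block grid")
    b = selection.block_start
    if not (w <= b < w + EIGHT_HOURS) or (b - day.start_epoch) % step != 0:
        raise ValidationError("selected block must be a grid block inside the 8-h window")

    tz = record.timezone
    scene = RenderScene(
        patient_label=record.display_name,
        day_label=f"Day {day.index} ({day.start.astimezone(ZoneInfo(tz)).date().isoformat()})",
        tz=tz,
        day_start=day.start_epoch,
        day_end=day.end_epoch,
        band=(w, w + EIGHT_HOURS),
        block_window=(b, b + step),
    )

    for e in summary.episodic:
        when = _clock(e.epoch, tz)
        if e.kind is EpisodicKind.BLOOD_PRESSURE:
            scene.bp_entries.append(
                {"t": e.epoch, "text": f"BP {e.systolic_mmhg:.0f}/{e.diastolic_mmhg:.0f} mmHg @ {when}"}
            )
        elif e.kind is EpisodicKind.WEIGHT:
            scene.weight_entries.append(
                {"t": e.epoch, "text": f"Weight {e.weight_kg:.1f} kg @ {when}"}
            )
        else:
            scene.subjective_entries.append(
                {
                    "t": e.epoch,
                    "score": e.subjective_score,
                    "items": [list(p) for p in e.subjective_items],
                    "text": f"Subjective {e.subjective_score:g} @ {when}",
                }
            )

    scene.wear_intervals = [tuple(i) for i in summary.wear.intervals]

    # layer 2: merge flags into one block element per (channel, block start)
    merged: dict[tuple[Channel, int], dict] = {}
    for blk in summary.blocks:
        key = (blk.channel, blk.start)
        entry = merged.setdefault(
            key,
            {
                "start": blk.start,
                "end": blk.end,
                "kinds": [],
                "statistics": {},
                "selected": blk.start == selection.block_start,
            },
        )
        entry["kinds"].append(blk.kind.value)
        entry["statistics"][blk.kind.value] = blk.statistic
    scene.rows = {
        ch: sorted(
            (e for (c, _), e in merged.items() if c is ch),
            key=lambda d: d["start"],
        )
        for ch in _ROW_ORDER
    }

    # layer 3: clipped waveforms over the selected 30 minutes
    for channel in _ROW_ORDER:
        series = record.channel(channel)
        if series is None:
            points: list = []
            vals = np.array([])
        else:
            sub = series.slice_epoch(b, b + step)
            vals = sub.values
            lo, hi = _panel_range(channel, vals, cfg)
            points = [
                (int(t), float(np.clip(v, lo, hi)))
                for t, v in zip(sub.times, sub.values)
            ]
        lo, hi = _panel_range(channel, vals, cfg)
        if channel is Channel.SPO2:
            thresholds = [cfg.spo2_low]
        elif channel is Channel.HEART_RATE:
            thresholds = [cfg.hr_low, cfg.hr_high]
        else:
            thresholds = [cfg.activity_high]
        scene.panels[channel] = {
            "y_range": (lo, hi),
            "thresholds": thresholds,
            "points": points,
        }

    if cursor_t is not None:
        scene.cursor_t = int(cursor_t)
        scene.cursor_values = cursor_readout(record, int(cursor_t))
    return scene


# ---------------------------------------------------------------------------
# SVG emission
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _x_of(t: int, t0: int, t1: int, x0: float, x1: float) -> float:
    return x0 + (t - t0) / (t1 - t0) * (x1 - x0)


def _y_of(v: float, lo: float, hi: float, y_top: float, y_bot: float) -> float:
    if hi == lo:
        return y_bot
    return y_bot - (v - lo) / (hi - lo) * (y_bot - y_top)


def render_svg(scene: RenderScene) -> str:
    """Emit the scene as a standalone SVG document (deterministic text)."""
    W, H = scene.canvas
    f_head, f_l1, f_l2, f_l3 = scene.layout
    y_head = 0.0
    y_l1 = H * f_head
    y_l2 = y_l1 + H * f_l1
    y_l3 = y_l2 + H * f_l2
    x0, x1 = MARGIN_X, W - MARGIN_X
    out: list[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W}" height="{H}" '
        f'viewBox="0 0 {W} {H}" font-family="Helvetica, Arial, sans-serif">'
    )
    out.append(f'<rect id="background" x="0" y="0" width="{W}" height="{H}" fill="#ffffff"/>')

    # ---- header -----------------------------------------------------------
    out.append('<g id="header">')
    out.append(
        f'<text id="header.title" x="{_fmt(x0)}" y="{_fmt(y_head + 18)}" '
        f'font-size="16" font-weight="bold">{escape(scene.patient_label)} &#8212; '
        f'{escape(scene.day_label)}</text>'
    )
    bp_text = "   ".join(e["text"] for e in scene.bp_entries) or "no blood pressure readings"
    out.append(
        f'<text id="header.bp" x="{_fmt(x0)}" y="{_fmt(y_head + 36)}" font-size="12">'
        f'{escape(bp_text)}</text>'
    )
    wt_text = "   ".join(e["text"] for e in scene.weight_entries) or "no weight readings"
    out.append(
        f'<text id="header.weight" x="{_fmt(x0)}" y="{_fmt(y_head + 52)}" font-size="12">'
        f'{escape(wt_text)}</text>'
    )
    sx = x0
    out.append('<g id="header.subjective">')
    for i, e in enumerate(scene.subjective_entries):
        out.append(
            f'<rect id="header.subjective.block_{i}" x="{_fmt(sx)}" y="{_fmt(y_head + 58)}" '
            f'width="14" height="14" fill="{COLORS["subjective"]}"/>'
        )
        items = "; ".join(f"{c}: {_fmt(v)}" for c, v in e["items"])
        label = e["text"] + (f" [{items}]" if items else "")
        out.append(
            f'<text x="{_fmt(sx + 18)}" y="{_fmt(y_head + 69)}" font-size="12">'
            f'{escape(label)}</text>'
        )
        sx += 24 + 7.2 * len(label)
    if not scene.subjective_entries:
        out.append(
            f'<text x="{_fmt(x0)}" y="{_fmt(y_head + 69)}" font-size="12">no subjective entries</text>'
        )
    out.append("</g>")
    out.append("</g>")

    # ---- layer 1: 24-h overview ------------------------------------------
    t0, t1 = scene.day_start, scene.day_end
    axis_y = y_l1 + H * f_l1 * 0.55
    out.append('<g id="layer1">')
    out.append(
        f'<line id="layer1.axis" x1="{_fmt(x0)}" y1="{_fmt(axis_y)}" x2="{_fmt(x1)}" '
        f'y2="{_fmt(axis_y)}" stroke="{COLORS["axis"]}" stroke-width="1"/>'
    )
    for h in range(0, 25, 2):
        xt = _x_of(t0 + h * 3600, t0, t1, x0, x1)
        out.append(
            f'<line x1="{_fmt(xt)}" y1="{_fmt(axis_y - 4)}" x2="{_fmt(xt)}" '
            f'y2="{_fmt(axis_y + 4)}" stroke="{COLORS["axis"]}" stroke-width="1"/>'
        )
        label = _clock(min(t0 + h * 3600, t1), scene.tz)
        out.append(
            f'<text x="{_fmt(xt)}" y="{_fmt(axis_y + 18)}" font-size="10" '
            f'text-anchor="middle" fill="{COLORS["axis"]}">{escape(label)}</text>'
        )
    bs, be = scene.band
    out.append(
        f'<rect id="layer1.band" x="{_fmt(_x_of(bs, t0, t1, x0, x1))}" '
        f'y="{_fmt(axis_y - 22)}" width="{_fmt(_x_of(be, t0, t1, x0, x1) - _x_of(bs, t0, t1, x0, x1))}" '
        f'height="30" fill="{COLORS["band"]}" fill-opacity="0.25" stroke="{COLORS["band"]}"/>'
    )
    if scene.wear_intervals:
        out.append('<g id="layer1.wear">')
        for i, (a, bnd) in enumerate(scene.wear_intervals):
            out.append(
                f'<line id="layer1.wear.seg_{i}" x1="{_fmt(_x_of(a, t0, t1, x0, x1))}" '
                f'y1="{_fmt(axis_y - 10)}" x2="{_fmt(_x_of(bnd, t0, t1, x0, x1))}" '
                f'y2="{_fmt(axis_y - 10)}" stroke="{COLORS["wear"]}" stroke-width="4"/>'
            )
        out.append("</g>")
    out.append("</g>")

    # ---- layer 2: 8-h violation blocks -----------------------------------
    w0, w1 = scene.band
    row_h = (H * f_l2 - 20) / 3
    out.append('<g id="layer2">')
    for r, channel in enumerate(_ROW_ORDER):
        ry = y_l2 + 10 + r * row_h
        out.append(f'<g id="layer2.row_{channel.value}">')
        out.append(
            f'<text x="{_fmt(x0 - 6)}" y="{_fmt(ry + row_h / 2 + 4)}" font-size="12" '
            f'text-anchor="end">{escape(_ROW_LABEL[channel])}</text>'
        )
        out.append(
            f'<line x1="{_fmt(x0)}" y1="{_fmt(ry + row_h - 4)}" x2="{_fmt(x1)}" '
            f'y2="{_fmt(ry + row_h - 4)}" stroke="{COLORS["axis"]}" stroke-width="0.5"/>'
        )
        for blk in scene.rows.get(channel, []):
            bx0 = _x_of(max(blk["start"], w0), w0, w1, x0, x1)
            bx1 = _x_of(min(blk["end"], w1), w0, w1, x0, x1)
            if bx1 <= bx0:
                continue
            cls = "violation selected" if blk["selected"] else "violation"
            fill = COLORS["selected"] if blk["selected"] else COLORS["block"]
            label = _clock(blk["start"], scene.tz).replace(":", "")
            out.append(
                f'<rect id="layer2.row_{channel.value}.block_{label}" class="{cls}" '
                f'x="{_fmt(bx0)}" y="{_fmt(ry)}" width="{_fmt(bx1 - bx0)}" '
                f'height="{_fmt(row_h - 8)}" fill="{fill}"/>'
            )
        out.append("</g>")
    out.append("</g>")

    # ---- layer 3: 30-min waveforms ---------------------------------------
    c0, c1 = scene.block_window
    panel_h = (H * f_l3 - 30) / 3
    out.append('<g id="layer3">')
    for r, channel in enumerate(_ROW_ORDER):
        panel = scene.panels.get(channel, {"y_range": (0, 1), "thresholds": [], "points": []})
        py = y_l3 + 10 + r * panel_h
        py_bot = py + panel_h - 14
        lo, hi = panel["y_range"]
        out.append(f'<g id="layer3.panel_{channel.value}">')
        out.append(
            f'<rect x="{_fmt(x0)}" y="{_fmt(py)}" width="{_fmt(x1 - x0)}" '
            f'height="{_fmt(py_bot - py)}" fill="none" stroke="{COLORS["axis"]}" stroke-width="0.5"/>'
        )
        out.append(
            f'<text x="{_fmt(x0 - 6)}" y="{_fmt(py + 10)}" font-size="10" '
            f'text-anchor="end">{_fmt(hi)}</text>'
        )
        out.append(
            f'<text x="{_fmt(x0 - 6)}" y="{_fmt(py_bot)}" font-size="10" '
            f'text-anchor="end">{_fmt(lo)}</text>'
        )
        out.append(
            f'<text x="{_fmt(x0 - 36)}" y="{_fmt((py + py_bot) / 2)}" font-size="11" '
            f'text-anchor="middle" transform="rotate(-90 {_fmt(x0 - 36)} {_fmt((py + py_bot) / 2)})">'
            f'{escape(_ROW_LABEL[channel])}</text>'
        )
        for th in panel["thresholds"]:
            if lo <= th <= hi:
                ty = _y_of(th, lo, hi, py, py_bot)
                out.append(
                    f'<line class="threshold" x1="{_fmt(x0)}" y1="{_fmt(ty)}" '
                    f'x2="{_fmt(x1)}" y2="{_fmt(ty)}" stroke="{COLORS["threshold"]}" '
                    f'stroke-width="0.75" stroke-dasharray="4 3"/>'
                )
        points = panel["points"]
        if points:
            coords = " ".join(
                f"{_fmt(_x_of(t, c0, c1, x0, x1))},{_fmt(_y_of(v, lo, hi, py, py_bot))}"
                for t, v in points
            )
            out.append(
                f'<polyline id="layer3.panel_{channel.value}.wave" points="{coords}" '
                f'fill="none" stroke="{COLORS["wave"]}" stroke-width="1"/>'
            )
        else:
            out.append(
                f'<text id="layer3.panel_{channel.value}.nodata" '
                f'x="{_fmt((x0 + x1) / 2)}" y="{_fmt((py + py_bot) / 2)}" font-size="12" '
                f'text-anchor="middle" fill="{COLORS["axis"]}">no data</text>'
            )
        out.append("</g>")
    if scene.cursor_t is not None and c0 <= scene.cursor_t < c1:
        cx = _x_of(scene.cursor_t, c0, c1, x0, x1)
        out.append(
            f'<line id="layer3.cursor" x1="{_fmt(cx)}" y1="{_fmt(y_l3 + 10)}" '
            f'x2="{_fmt(cx)}" y2="{_fmt(H - 20)}" stroke="{COLORS["cursor"]}" stroke-width="1"/>'
        )
        labels = []
        for channel, value in zip(_ROW_ORDER, scene.cursor_values):
            labels.append(
                f"{_ROW_LABEL[channel]}: " + (_fmt(value) if value is not None else "-")
            )
        out.append(
            f'<text id="layer3.cursor.readout" x="{_fmt(min(cx + 6, x1 - 160))}" '
            f'y="{_fmt(y_l3 + 24)}" font-size="11" fill="{COLORS["cursor"]}">'
            f'{escape("  ".join(labels))}</text>'
        )
    tick_labels = (
        (c0, _clock(c0, scene.tz)),
        ((c0 + c1) // 2, _clock((c0 + c1) // 2, scene.tz)),
        (c1, _clock(c1, scene.tz)),
    )
    for t, label in tick_labels:
        xt = _x_of(t, c0, c1, x0, x1)
        out.append(
            f'<text x="{_fmt(xt)}" y="{_fmt(H - 6)}" font-size="10" text-anchor="middle" '
            f'fill="{COLORS["axis"]}">{escape(label)}</text>'
        )
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out)
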