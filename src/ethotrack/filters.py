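"""Event-level and record-level quality filters.

Event filters never delete events: they *convert* artifact events to
not-detected events of identical span, so the events still partition the trial
timeline exactly and detection-fraction accounting stays consistent.  The
original (pre-filter) state of every event is retained in
``EventSeries.source_state``; the incomplete-event filter keys on it so that
events converted by *other* filters do not count as tracking dropouts, which
also makes every filter idempotent.

Record filters drop whole arenas whose data are unusable — a dead or inactive
insect, poor tracking, or too few events.  All three comparisons are strict:
a record is removed when its longest halt exceeds the inactivity limit, its
detected-time fraction is below the detection minimum, or its moving+halting
event count is below the event minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ethotrack.segmentation import EventSeries, MovementState

__all__ = [
    "EventFilterConfig",
    "RecordFilterConfig",
    "FilterReport",
    "filter_extreme_velocity",
    "filter_zone_boundary_pairs",
    "filter_incomplete",
    "apply_event_filters",
    "apply_record_filters",
]

_ND = int(MovementState.NOT_DETECTED)
_H = int(MovementState.HALTING)
_M = int(MovementState.MOVING)


@dataclass(frozen=True)
class EventFilterConfig:
    """Which event filters to run, in pipeline order
    (extreme velocity -> zone boundary -> incomplete)."""

    v_extreme: float | None = 5.0          # mm/s cap; None disables
    drop_zone_boundary_pairs: bool = False
    drop_incomplete: bool = False

    def __post_init__(self):
        if self.v_extreme is not None and self.v_extreme <= 0:
            raise ValueError("v_extreme must be > 0")


@dataclass(frozen=True)
class RecordFilterConfig:
    """Record-removal thresholds (strict comparisons).

    max_inactivity : s; longest single halting event allowed.
    min_detection : fraction of trial time with a tracking fix.
    min_event_count : moving + halting events required (counted on the
        segmented series, before event filters).
    """

    max_inactivity: float = 3600.0
    min_detection: float = 0.5
    min_event_count: int = 1000

    def __post_init__(self):
        if min(self.max_inactivity, self.min_detection,
               self.min_event_count) < 0:
            raise ValueError("record-filter thresholds must be >= 0")


@dataclass
class FilterReport:
    """Outcome of record filtering plus event-conversion counts."""

    kept: list[str] = field(default_factory=list)
    removed: dict[str, list[str]] = field(default_factory=dict)  # id -> criteria
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    events_converted: dict[str, int] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for rid in list(self.kept) + list(self.removed):
            m = self.metrics.get(rid, {})
            rows.append({
                "record_id": rid,
                "kept": rid in self.kept,
                "criteria": ";".join(self.removed.get(rid, [])),
                **m,
            })
        return pd.DataFrame(rows)


def _convert(series: EventSeries, mask: np.ndarray) -> EventSeries:
    """Turn the masked events into not-detected events of identical span."""
    out = series.copy()
    out.state[mask] = _ND
    out.zone[mask] = 0
    out.distance[mask] = np.nan
    return out


def filter_extreme_velocity(series: EventSeries,
                            v_extreme: float = 5.0) -> EventSeries:
    """Convert moving events faster than ``v_extreme`` to not-detected.

    Such events come from tracking artifacts — a reflection or dirt particle
    momentarily mistaken for the insect produces a physically impossible jump.
    The cap applies to the event's mean velocity (distance / duration).
    """
    mv = series.mean_velocity
    mask = (series.state == _M) & np.isfinite(mv) & (mv > v_extreme)
    return _convert(series, mask) if mask.any() else series.copy()


def filter_zone_boundary_pairs(series: EventSeries) -> EventSeries:
    """Convert moving events that are zone-transition fragments.

    Small displacements on a zone boundary, and movements split by a zone
    change, create moving events that do not both start and end at halting
    events within their own zone.  Those fragments are converted to
    not-detected; halting events are never touched.  A moving event at the
    trial edge has no flanking halt on that side and is converted too.
    """
    n = series.n_events
    mask = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(series.state == _M):
        ok_prev = (i > 0 and series.state[i - 1] == _H
                   and series.zone[i - 1] == series.zone[i])
        ok_next = (i < n - 1 and series.state[i + 1] == _H
                   and series.zone[i + 1] == series.zone[i])
        if not (ok_prev and ok_next):
            mask[i] = True
    return _convert(series, mask) if mask.any() else series.copy()


def filter_incomplete(series: EventSeries) -> EventSeries:
    """Convert moving/halting events clipped by a tracking dropout.

    An event whose immediate neighbour is a genuine not-detected interval
    (``source_state`` not-detected, i.e. a dropout rather than a filtered
    artifact) has an unknown true start or end and is converted.  Events
    touching the trial boundaries are *not* incomplete: the trial edge is not
    a dropout.
    """
    n = series.n_events
    dropout = (series.state == _ND) & (series.source_state == _ND)
    mask = np.zeros(n, dtype=bool)
    behav = (series.state == _H) | (series.state == _M)
    if n > 1:
        mask[1:] |= behav[1:] & dropout[:-1]
        mask[:-1] |= behav[:-1] & dropout[1:]
    return _convert(series, mask) if mask.any() else series.copy()


def apply_event_filters(series: EventSeries,
                        config: EventFilterConfig,
                        counts: dict[str, int] | None = None) -> EventSeries:
    """Run the enabled event filters in pipeline order.

    ``counts`` (optional, mutated) accumulates per-filter conversion totals.
    """
    out = series
    def _run(name, fn):
        nonlocal out
        before = int(np.sum(out.state == _ND))
        out = fn(out)
        if counts is not None:
            counts[name] = counts.get(name, 0) + int(
                np.sum(out.state == _ND)) - before
    if config.v_extreme is not None:
        _run("extreme_velocity",
             lambda s: filter_extreme_velocity(s, config.v_extreme))
    if config.drop_zone_boundary_pairs:
        _run("zone_boundary", filter_zone_boundary_pairs)
    if config.drop_incomplete:
        _run("incomplete", filter_incomplete)
    return out


# ---------------------------------------------------------------------------
# record filters


def record_metrics(series: EventSeries) -> dict[str, float]:
    dur = series.duration
    halts = series.state == _H
    moves = series.state == _M
    total = series.total_duration
    det_time = float(dur[halts | moves].sum())
    return {
        "longest_halt_s": float(dur[halts].max()) if halts.any() else 0.0,
        "detection_fraction": det_time / total if total > 0 else 0.0,
        "event_count": int(halts.sum() + moves.sum()),
    }


def apply_record_filters(series_set, config: RecordFilterConfig
                         ) -> FilterReport:
    """Decide which records to keep; returns a :class:`FilterReport`.

    A record is removed iff its longest single halting event exceeds
    ``max_inactivity`` (a dead or torpid insect yields one trial-long halt),
    its detected-time fraction is below ``min_detection``, or its
    moving+halting event count is below ``min_event_count``.  Every removed
    record is reported with all the criteria it triggered.
    """
    report = FilterReport()
    for series in series_set:
        m = record_metrics(series)
        report.metrics[series.record_id] = m
        hit = []
        if m["longest_halt_s"] > config.max_inactivity:
            hit.append("inactivity")
        if m["detection_fraction"] < config.min_detection:
            hit.append("detection")
        if m["event_count"] < config.min_event_count:
            hit.append("event_count")
        if hit:
            report.removed[series.record_id] = hit
        else:
            report.kept.append(series.record_id)
    return report
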