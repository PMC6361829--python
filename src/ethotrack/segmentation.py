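"""Per-sample movement-state classification and behavior-event construction.

A track is classified sample by sample into three states — moving, halting,
not-detected — with a velocity threshold and a look-ahead window of ``n``
samples.  The look-ahead exists to ignore single velocity spikes while
halting and minor dips below threshold within a movement.  Evaluated in order
for each sample (previous state of the first sample is *unknown*, which is
neither moving nor halting):

1. moving, if either
   - start moving: previous state is not moving, current velocity >= threshold,
     and any of the *next* n samples has velocity >= threshold; or
   - remain moving: previous state is moving and any velocity among the
     current or next n samples is >= threshold;
2. else halting, if either
   - start halting: previous state is not halting and the current sample is
     detected; or
   - remain halting: previous state is halting and any of the current or next
     n samples is detected;
3. else not-detected.

Not-detected samples have no velocity, which counts as below threshold.
Maximal runs of constant (state, zone) become :class:`BehaviorEvent`s — a
state change *or a zone change* ends an event, so one physical movement that
crosses a zone boundary is split in two.  Optionally, halting interrupted by a
tracking dropout is recovered: a halt / not-detect / halt triplet is merged
into a single halt when the second halt starts within a radius of where the
first one ended, the radius being the first halt's own start-to-end
displacement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from ethotrack.track_io import TrackRecord

__all__ = [
    "MovementState",
    "SegmentationConfig",
    "BehaviorEvent",
    "EventSeries",
    "classify_samples",
    "build_events",
    "recover_halts",
    "segment_record",
]


class MovementState(enum.IntEnum):
    NOT_DETECTED = 0
    HALTING = 1
    MOVING = 2
    UNKNOWN = -1


#: default velocity threshold (mm/s): the dip of the bimodal velocity
#: distribution observed for walking thrips
DEFAULT_V_THRESHOLD = 0.05
#: default look-ahead window (samples)
DEFAULT_LOOKAHEAD = 4


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings of the state machine.

    v_threshold : mm/s; speeds at or above it count as moving evidence.
    lookahead_n : number of future samples consulted by the start/remain rules.
    recover_halts : merge halt/dropout/halt triplets (on by default).
    recover_radius_floor : lower bound (mm) on the merge radius, so that a
        perfectly still first halt (zero displacement, common under pixel
        quantization) can still absorb a dropout; default is one pixel.
    empty_window_passes : how an *empty* strictly-future look-ahead window is
        scored by the start-moving rule (empty happens for ``lookahead_n == 0``
        or at the very last sample).  False (default) scores it as "no
        qualifying sample", so movement is never fabricated at track end; True
        makes ``lookahead_n == 0`` degenerate to plain thresholding.
    """

    v_threshold: float = DEFAULT_V_THRESHOLD
    lookahead_n: int = DEFAULT_LOOKAHEAD
    recover_halts: bool = True
    recover_radius_floor: float = 0.05
    empty_window_passes: bool = False

    def __post_init__(self):
        if self.v_threshold <= 0:
            raise ValueError("v_threshold must be > 0")
        if self.lookahead_n < 0:
            raise ValueError("lookahead_n must be >= 0")


@dataclass
class BehaviorEvent:
    """One contiguous interval of a single state within a single zone."""

    state: MovementState
    zone: int                  # 1..3, 0 = none (not-detected)
    t_start: float
    t_end: float
    distance: float = float("nan")   # mm, moving events only
    start_pos: tuple[float, float] | None = None
    end_pos: tuple[float, float] | None = None
    source_state: MovementState | None = None  # pre-filter state

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def mean_velocity(self) -> float:
        if self.state is not MovementState.MOVING or self.duration <= 0:
            return float("nan")
        return self.distance / self.duration


@dataclass
class EventSeries:
    """Time-ordered events partitioning one record's trial span.

    Stored as parallel arrays for speed; ``events()`` yields
    :class:`BehaviorEvent` views and ``to_frame()`` a pandas table.
    ``source_state`` records what each event was before any quality filter
    converted it to not-detected (filters never delete events, so the
    partition of the timeline is preserved exactly).
    """

    record_id: str
    sample_rate: float
    state: np.ndarray        # int8, MovementState values
    zone: np.ndarray         # int8
    t_start: np.ndarray
    t_end: np.ndarray
    distance: np.ndarray     # NaN for non-moving
    sx: np.ndarray           # start position (NaN when unknown)
    sy: np.ndarray
    ex: np.ndarray           # end position
    ey: np.ndarray
    source_state: np.ndarray = None  # int8; defaults to state
    config: SegmentationConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.source_state is None:
            self.source_state = self.state.copy()

    @property
    def n_events(self) -> int:
        return int(self.state.size)

    @property
    def duration(self) -> np.ndarray:
        return self.t_end - self.t_start

    @property
    def total_duration(self) -> float:
        if self.n_events == 0:
            return 0.0
        return float(self.t_end[-1] - self.t_start[0])

    @property
    def mean_velocity(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.distance / self.duration

    def events(self):
        for i in range(self.n_events):
            sp = None if np.isnan(self.sx[i]) else (float(self.sx[i]),
                                                    float(self.sy[i]))
            ep = None if np.isnan(self.ex[i]) else (float(self.ex[i]),
                                                    float(self.ey[i]))
            yield BehaviorEvent(
                state=MovementState(int(self.state[i])),
                zone=int(self.zone[i]),
                t_start=float(self.t_start[i]), t_end=float(self.t_end[i]),
                distance=float(self.distance[i]),
                start_pos=sp, end_pos=ep,
                source_state=MovementState(int(self.source_state[i])))

    def copy(self) -> "EventSeries":
        return replace(
            self,
            state=self.state.copy(), zone=self.zone.copy(),
            t_start=self.t_start.copy(), t_end=self.t_end.copy(),
            distance=self.distance.copy(),
            sx=self.sx.copy(), sy=self.sy.copy(),
            ex=self.ex.copy(), ey=self.ey.copy(),
            source_state=self.source_state.copy(),
            meta=dict(self.meta))

    def to_frame(self):
        import pandas as pd
        names = np.array(["not_detected", "halting", "moving"])
        return pd.DataFrame({
            "record_id": self.record_id,
            "state": names[self.state],
            "zone": self.zone,
            "t_start_s": self.t_start,
            "t_end_s": self.t_end,
            "duration_s": self.duration,
            "distance_mm": self.distance,
            "mean_velocity_mm_s": self.mean_velocity,
        })


# ---------------------------------------------------------------------------
# classification

try:  # tight per-sample loop; compiled when numba is available
    import numba as _numba

    @_numba.njit(cache=True)
    def _state_loop(above, start_ok, incl_above, incl_det, det):  # pragma: no cover
        n = above.size
        out = np.empty(n, dtype=np.int8)
        prev = -1  # unknown
        for i in range(n):
            if (prev != 2 and above[i] and start_ok[i]) or \
               (prev == 2 and incl_above[i]):
                s = 2
            elif (prev != 1 and det[i]) or (prev == 1 and incl_det[i]):
                s = 1
            else:
                s = 0
            out[i] = s
            prev = s
        return out

except ImportError:  # pragma: no cover
    def _state_loop(above, start_ok, incl_above, incl_det, det):
        n = above.size
        out = np.empty(n, dtype=np.int8)
        prev = -1
        for i in range(n):
            if (prev != 2 and above[i] and start_ok[i]) or \
               (prev == 2 and incl_above[i]):
                s = 2
            elif (prev != 1 and det[i]) or (prev == 1 and incl_det[i]):
                s = 1
            else:
                s = 0
            out[i] = s
            prev = s
        return out


def _next_true_index(flags: np.ndarray) -> np.ndarray:
    """next_idx[i] = smallest j >= i with flags[j], else n."""
    n = flags.size
    idx = np.where(flags, np.arange(n), n)
    return np.minimum.accumulate(idx[::-1])[::-1]


def classify_samples(record: TrackRecord,
                     config: SegmentationConfig | None = None) -> np.ndarray:
    """Assign a :class:`MovementState` to every sample of ``record``.

    Returns an int8 array of state codes aligned 1:1 with the samples.  The
    look-ahead existentials are precomputed with next-occurrence indices so the
    remaining per-sample recursion is a trivial loop.
    """
    if config is None:
        config = SegmentationConfig()
    n = record.n_samples
    if n == 0:
        raise ValueError("empty record")
    nsteps = config.lookahead_n
    v = record.v
    above = np.zeros(n, dtype=bool)
    fin = np.isfinite(v)
    above[fin] = v[fin] >= config.v_threshold
    above &= record.detected
    det = record.detected.astype(bool)

    next_above = _next_true_index(above)
    next_det = _next_true_index(det)
    idx = np.arange(n)
    incl_above = next_above <= np.minimum(idx + nsteps, n - 1)
    incl_det = next_det <= np.minimum(idx + nsteps, n - 1)
    # strictly-future window for the start-moving rule
    win_end = np.minimum(idx + nsteps, n - 1)
    has_window = (nsteps > 0) & (idx < n - 1)
    start_ok = np.empty(n, dtype=bool)
    start_ok[:] = config.empty_window_passes
    if nsteps > 0:
        nxt = np.empty(n, dtype=np.int64)
        nxt[:-1] = next_above[1:]
        nxt[-1] = n
        start_ok[has_window] = nxt[has_window] <= win_end[has_window]
    return _state_loop(above, start_ok, incl_above, incl_det, det)


# ---------------------------------------------------------------------------
# event construction


def build_events(record: TrackRecord, states: np.ndarray,
                 config: SegmentationConfig | None = None) -> EventSeries:
    """Cut the classified sample stream into zone-delimited events.

    An event ends where the state or the zone changes.  Samples that are
    classified moving/halting while the tracker had no fix (bridged by the
    look-ahead rules) inherit the zone of the previous sample.  Event start
    times are the time of the first sample of the run; the final event ends
    one sample interval after the last sample, so the events exactly partition
    ``[t_first, t_last + 1/sample_rate]``.
    """
    states = np.asarray(states, dtype=np.int8)
    n = record.n_samples
    if states.shape != (n,):
        raise ValueError("states not aligned with samples")
    zone = record.zone.astype(np.int16).copy()
    # carry zone forward onto bridged moving/halting samples without a fix
    need_fill = (zone == 0) & (states != MovementState.NOT_DETECTED)
    if need_fill.any():
        src = np.where(zone != 0, np.arange(n), 0)
        src = np.maximum.accumulate(src)
        filled = zone[src]
        zone[need_fill] = filled[need_fill]
    zone[states == MovementState.NOT_DETECTED] = 0

    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = (states[1:] != states[:-1]) | (zone[1:] != zone[:-1])
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n)

    dt = 1.0 / record.sample_rate
    t_start = record.t[starts]
    t_end = np.append(record.t[starts[1:]], record.t[-1] + dt)

    # per-sample path step between consecutive detected samples
    step = np.zeros(n)
    if n > 1:
        pair = record.detected[1:] & record.detected[:-1]
        d = np.hypot(np.diff(record.x), np.diff(record.y))
        step[1:][pair] = d[pair]
    cstep = np.concatenate(([0.0], np.cumsum(step)))

    m = starts.size
    ev_state = states[starts]
    ev_zone = zone[starts].astype(np.int8)
    distance = np.full(m, np.nan)
    moving = ev_state == MovementState.MOVING
    # distance within a run = sum of steps strictly inside it
    distance[moving] = cstep[ends[moving]] - cstep[starts[moving] + 1]

    sx = np.full(m, np.nan)
    sy = np.full(m, np.nan)
    ex = np.full(m, np.nan)
    ey = np.full(m, np.nan)
    det_idx = np.flatnonzero(record.detected)
    if det_idx.size:
        lo = np.searchsorted(det_idx, starts, side="left")
        hi = np.searchsorted(det_idx, ends, side="left") - 1
        has = (hi >= lo) & (ev_state != MovementState.NOT_DETECTED)
        first = det_idx[np.clip(lo, 0, det_idx.size - 1)]
        last = det_idx[np.clip(hi, 0, det_idx.size - 1)]
        sx[has] = record.x[first[has]]
        sy[has] = record.y[first[has]]
        ex[has] = record.x[last[has]]
        ey[has] = record.y[last[has]]

    return EventSeries(
        record_id=record.record_id, sample_rate=record.sample_rate,
        state=ev_state.astype(np.int8), zone=ev_zone,
        t_start=t_start, t_end=t_end, distance=distance,
        sx=sx, sy=sy, ex=ex, ey=ey, config=config,
        meta={"genotype_by_zone": dict(record.genotype_by_zone),
              "arena_id": record.arena_id, "trial_id": record.trial_id})


# ---------------------------------------------------------------------------
# halt recovery across dropouts


def recover_halts(series: EventSeries,
                  radius_floor: float = 0.05) -> EventSeries:
    """Merge halt / not-detected / halt triplets interrupted by dropout.

    The merge requires both halts in the same zone and the second halt to
    start within a radius of the first halt's end position; the radius is the
    first halt's own start-to-end displacement (floored at ``radius_floor`` mm
    so that a perfectly still halt is not barred from merging by pixel
    quantization).  The scan repeats until no further merge applies, and the
    merged halt spans all three events.
    """
    s = series.copy()
    H, ND = int(MovementState.HALTING), int(MovementState.NOT_DETECTED)
    changed = True
    while changed:
        changed = False
        keep = np.ones(s.n_events, dtype=bool)
        i = 0
        while i + 2 < s.n_events:
            if (s.state[i] == H and s.state[i + 1] == ND
                    and s.state[i + 2] == H and keep[i]
                    and s.zone[i] == s.zone[i + 2]):
                if not (np.isnan(s.ex[i]) or np.isnan(s.sx[i + 2])):
                    radius = float(np.hypot(s.ex[i] - s.sx[i],
                                            s.ey[i] - s.sy[i]))
                    radius = max(radius, radius_floor)
                    gap = float(np.hypot(s.sx[i + 2] - s.ex[i],
                                         s.sy[i + 2] - s.ey[i]))
                    if gap <= radius:
                        # merge i..i+2 into i
                        s.t_end[i] = s.t_end[i + 2]
                        s.ex[i] = s.ex[i + 2]
                        s.ey[i] = s.ey[i + 2]
                        keep[i + 1] = keep[i + 2] = False
                        changed = True
                        i += 3
                        continue
            i += 1
        if changed:
            for name in ("state", "zone", "t_start", "t_end", "distance",
                         "sx", "sy", "ex", "ey", "source_state"):
                setattr(s, name, getattr(s, name)[keep])
    return s


def segment_record(record: TrackRecord,
                   config: SegmentationConfig | None = None) -> EventSeries:
    """Classify, build events and (optionally) recover halts in one call."""
    if config is None:
        config = SegmentationConfig()
    states = classify_samples(record, config)
    series = build_events(record, states, config)
    if config.recover_halts:
        series = recover_halts(series, config.recover_radius_floor)
    return series
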