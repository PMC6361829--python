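"""Shared fixtures and builders for the test suite.

Tracks and event series used in tests are built programmatically; nothing is
read from disk except where a test explicitly writes first.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ethotrack.track_io import TrackRecord
from ethotrack.segmentation import EventSeries, MovementState
from ethotrack.simulate import BehaviorParams, ZoneBehavior

_STATE = {"nd": MovementState.NOT_DETECTED, "halt": MovementState.HALTING,
          "move": MovementState.MOVING}


def make_record(v=None, detected=None, zone=None, x=None, y=None,
                rate=1.0, arena="A01", trial="T1") -> TrackRecord:
    """Build a TrackRecord from short per-sample lists.

    ``v=None`` entries mean "no velocity"; positions default to a 1-D walk
    consistent with the velocities so distance-based logic has something to
    chew on.
    """
    n = max(len(a) for a in (v, detected, zone, x) if a is not None)
    det = np.ones(n, dtype=bool) if detected is None else np.asarray(
        detected, dtype=bool)
    vv = np.full(n, np.nan)
    if v is not None:
        for i, val in enumerate(v):
            if val is not None:
                vv[i] = val
    vv[~det] = np.nan
    if x is None:
        # integrate |v| so displacement matches velocity at the given rate
        steps = np.where(np.isfinite(vv), vv, 0.0) / rate
        xx = np.concatenate(([0.0], np.cumsum(steps[1:])))
    else:
        xx = np.asarray(x, dtype=float)
    yy = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    xx = np.where(det, xx, np.nan)
    yy = np.where(det, yy, np.nan)
    zz = np.ones(n, dtype=np.int8) if zone is None else np.asarray(
        zone, dtype=np.int8)
    zz = np.where(det, zz, 0).astype(np.int8)
    return TrackRecord(
        arena_id=arena, trial_id=trial,
        genotype_by_zone={1: "genoA", 2: "genoB"},
        sample_rate=rate, t=np.arange(n) / rate,
        x=xx, y=yy, v=vv, zone=zz, detected=det)


def make_series(events, rate=1.0, record_id="T1/A01") -> EventSeries:
    """Build an EventSeries from (state, zone, t_start, t_end[, distance])
    tuples; states given as 'move'/'halt'/'nd'."""
    states, zones, ts, te, dist = [], [], [], [], []
    sx = []
    for ev in events:
        st, zn, t0, t1 = ev[:4]
        states.append(int(_STATE[st]))
        zones.append(zn)
        ts.append(t0)
        te.append(t1)
        dist.append(ev[4] if len(ev) > 4 else
                    (math.nan if st != "move" else 0.1 * (t1 - t0)))
    n = len(states)
    nan = np.full(n, np.nan)
    s = EventSeries(
        record_id=record_id, sample_rate=rate,
        state=np.array(states, dtype=np.int8),
        zone=np.array(zones, dtype=np.int8),
        t_start=np.array(ts, dtype=float), t_end=np.array(te, dtype=float),
        distance=np.array(dist, dtype=float),
        sx=nan.copy(), sy=nan.copy(), ex=nan.copy(), ey=nan.copy())
    s.distance[s.state != MovementState.MOVING] = np.nan
    return s


def random_track(rng, max_len=500, rate=3.33) -> TrackRecord:
    """Random track exercising all classification branches: halting jitter,
    moving stretches, isolated spikes/dips and dropout."""
    n = int(rng.integers(5, max_len + 1))
    regime = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        k = int(rng.integers(1, 30))
        regime[i:i + k] = rng.integers(0, 3)  # 0 jitter, 1 move, 2 dropout
        i += k
    v = np.where(regime == 1, rng.lognormal(np.log(0.2), 0.6, n),
                 np.abs(rng.normal(0, 0.015, n)))
    # sprinkle single-sample spikes and dips
    flips = rng.random(n) < 0.05
    v[flips] = np.where(v[flips] > 0.05, 0.0,
                        rng.uniform(0.06, 0.5, flips.sum()))
    det = regime != 2
    det &= rng.random(n) > 0.02
    zone = rng.integers(1, 4, n)
    # zones change in runs, not i.i.d.
    for j in range(1, n):
        if rng.random() < 0.9:
            zone[j] = zone[j - 1]
    return make_record(v=v.tolist(), detected=det.tolist(),
                       zone=zone.tolist(), rate=rate)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def clean_params() -> BehaviorParams:
    """Simulation regime with clearly separated speed modes and bouts long
    relative to the look-ahead window: halting jitter ~0.01 mm/s, moving
    speeds ~0.3 mm/s, median bouts of several seconds, no dropout."""
    slow = ZoneBehavior(halt_meanlog=math.log(12.0), halt_sdlog=0.7,
                        move_meanlog=math.log(4.0), move_sdlog=0.6)
    return BehaviorParams(zone1=slow, zone2=slow,
                          neutral=ZoneBehavior(
                              halt_meanlog=math.log(8.0), halt_sdlog=0.7,
                              move_meanlog=math.log(4.0), move_sdlog=0.6),
                          halt_jitter_speed=0.01,
                          dropout_rate=0.0, trial_length=1200.0)
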