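"""Seeded simulator of T-maze insect trajectories with known ground truth.

The simulated arena is the three-zone T-maze: two circular leaf-disc zones of
6 mm diameter joined to a central release zone through 2 mm channels.  The
insect is modelled as a two-state (halt / move) semi-Markov walker on the 1-D
channel axis through the three zones: bout durations and moving speeds are
drawn from per-zone lognormal distributions (right-skewed, as bout data
generically are), halting positions jitter with a small residual speed well
below the halting/moving threshold — which reproduces the bimodal "camel"
velocity histogram of real tracks — and at each departure from the neutral
zone the walker heads toward zone 1 with probability ``p_choose_zone1``.
Tracking dropout is emulated by geometric-length not-detected gaps at random
onsets, a fraction of which is deliberately placed inside halting bouts so
the halt-recovery logic is exercised.

Every sample's true behavioral state is returned alongside the track, so the
whole pipeline (segmentation, filters, statistics, inference) can be scored
against known truth.  :func:`simulate_experiment` additionally emulates the
experimental design: leaves drawn from finite plant pools (by default 4
leaves from each of 10 plants per genotype), lognormal per-plant and
per-trial multipliers on halt-bout length, and a design table linking each
arena to its plants and trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ethotrack.track_io import TrackRecord, DEFAULT_SAMPLE_RATE

__all__ = [
    "ZoneBehavior",
    "BehaviorParams",
    "ArenaGeometry",
    "simulate_track",
    "simulate_experiment",
]


@dataclass(frozen=True)
class ZoneBehavior:
    """Lognormal bout parameters while the insect is in one zone.

    meanlog/sdlog are the log-scale location and scale; the median bout
    length is exp(meanlog) seconds (resp. mm/s for speed).
    """

    halt_meanlog: float = math.log(8.0)
    halt_sdlog: float = 1.0
    move_meanlog: float = math.log(2.5)
    move_sdlog: float = 0.8
    speed_meanlog: float = math.log(0.3)
    speed_sdlog: float = 0.4

    def scaled_halts(self, log_multiplier: float) -> "ZoneBehavior":
        return replace(self, halt_meanlog=self.halt_meanlog + log_multiplier)


@dataclass(frozen=True)
class ArenaGeometry:
    """1-D channel-axis geometry of one T-maze arena.

    The axis runs zone 1 disc (6 mm), channel (2 mm), central zone (6 mm),
    channel (2 mm), zone 2 disc (6 mm); channels belong to the neutral zone 3.
    """

    zone_diameter: float = 6.0
    channel_length: float = 2.0

    @property
    def length(self) -> float:
        return 3 * self.zone_diameter + 2 * self.channel_length

    def zone_of(self, s: np.ndarray) -> np.ndarray:
        """Zone id for every 1-D position; channels map to zone 3."""
        s = np.asarray(s, dtype=float)
        z = np.full(s.shape, 3, dtype=np.int8)
        z[s < self.zone_diameter] = 1
        z[s > self.length - self.zone_diameter] = 2
        return z

    def xy_of(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Embed the channel axis in the plane (x along the axis)."""
        s = np.asarray(s, dtype=float)
        return s, np.zeros_like(s)

    @property
    def center(self) -> float:
        return self.length / 2.0


@dataclass(frozen=True)
class BehaviorParams:
    """Full parameterization of one simulated arena.

    zone1/zone2 carry the leaf-dependent bout behavior (one per genotype);
    neutral governs the central zone and channels.  ``p_choose_zone1`` is the
    probability of heading toward zone 1 when a movement starts in the
    neutral zone; ``p_leave`` the probability that a movement starting on a
    leaf heads out toward the center.  Dropout is a per-sample not-detect
    probability realised as geometric gaps of mean ``dropout_mean_gap``
    samples, with a fraction ``dropout_in_halts`` of gap onsets forced into
    halting bouts.
    """

    zone1: ZoneBehavior = field(default_factory=ZoneBehavior)
    zone2: ZoneBehavior = field(default_factory=ZoneBehavior)
    neutral: ZoneBehavior = field(default_factory=lambda: ZoneBehavior(
        halt_meanlog=math.log(3.0), move_meanlog=math.log(2.0)))
    halt_jitter_speed: float = 0.01    # mm/s mean residual speed while halting
    p_choose_zone1: float = 0.5
    p_leave: float = 0.3
    heading_persistence: float = 0.8   # keep heading between moves in zone 3
    dropout_rate: float = 0.10
    dropout_mean_gap: float = 5.0      # samples
    dropout_in_halts: float = 0.5
    trial_length: float = 28800.0      # s (8 h)
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        for p in (self.p_choose_zone1, self.p_leave, self.dropout_rate,
                  self.dropout_in_halts):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.trial_length <= 0 or self.sample_rate <= 0:
            raise ValueError("trial_length and sample_rate must be positive")

    def zone_behavior(self, zone: int) -> ZoneBehavior:
        return {1: self.zone1, 2: self.zone2, 3: self.neutral}[zone]


_HALT, _MOVE = 1, 2


def simulate_track(params: BehaviorParams,
                   geometry: ArenaGeometry | None = None,
                   seed: int | np.random.Generator = 0,
                   arena_id: str = "A01", trial_id: str = "T1",
                   genotype_by_zone: dict[int, str] | None = None
                   ) -> tuple[TrackRecord, pd.DataFrame]:
    """Simulate one arena; returns (track, truth).

    ``truth`` has one row per sample: ``t, true_state`` ("halting"/"moving"),
    ``true_zone`` and ``detected``.  Velocities in the track are the
    sample-to-sample displacements times the sample rate, as a tracker would
    report them; not-detected samples carry no position, velocity or zone.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    geom = geometry or ArenaGeometry()
    rate = params.sample_rate
    dt = 1.0 / rate
    n = int(round(params.trial_length * rate))
    if n < 2:
        raise ValueError("trial shorter than one bout")

    pos = np.empty(n)
    state = np.empty(n, dtype=np.int8)

    s = geom.center + rng.uniform(-1.0, 1.0)
    i = 0
    cur_state = _HALT if rng.random() < 0.5 else _MOVE
    halt_anchor = s
    heading = None
    zone_d, length = geom.zone_diameter, geom.length
    while i < n:
        zone = 1 if s < zone_d else (2 if s > length - zone_d else 3)
        zb = params.zone_behavior(zone)
        if cur_state == _HALT:
            dur = rng.lognormal(zb.halt_meanlog, zb.halt_sdlog)
            k = max(1, int(round(dur * rate)))
            k = min(k, n - i)
            # residual jitter around the anchor, bounded so the per-sample
            # displacement stays well below the halting/moving threshold
            step = rng.normal(0.0, params.halt_jitter_speed * dt, size=k)
            jit = np.clip(np.cumsum(step), -0.05, 0.05)
            pos[i:i + k] = np.clip(halt_anchor + jit, 0.0, geom.length)
            state[i:i + k] = _HALT
            s = pos[i + k - 1]
            i += k
            cur_state = _MOVE
        else:
            dur = rng.lognormal(zb.move_meanlog, zb.move_sdlog)
            speed = rng.lognormal(zb.speed_meanlog, zb.speed_sdlog)
            k = max(1, int(round(dur * rate)))
            k = min(k, n - i)
            if zone == 3:
                # the first heading after entering the neutral zone is the
                # "choice"; later moves mostly persist, so the walker actually
                # crosses to the other leaf instead of diffusing back
                if heading is not None and \
                        rng.random() < params.heading_persistence:
                    direction = heading
                else:
                    direction = (-1.0 if rng.random() < params.p_choose_zone1
                                 else 1.0)
                heading = direction
            elif rng.random() < params.p_leave:
                direction = 1.0 if zone == 1 else -1.0
                heading = None
            else:
                direction = -1.0 if rng.random() < 0.5 else 1.0
                heading = None
            steps = np.full(k, direction * speed * dt)
            path = s + np.cumsum(steps)
            # reflect at the arena ends
            L = geom.length
            path = np.abs(np.mod(path, 2 * L))
            path = np.where(path > L, 2 * L - path, path)
            pos[i:i + k] = path
            state[i:i + k] = _MOVE
            s = path[-1]
            halt_anchor = s
            i += k
            cur_state = _HALT

    zone = geom.zone_of(pos)
    x, y = geom.xy_of(pos)

    detected = np.ones(n, dtype=bool)
    if params.dropout_rate > 0:
        mean_gap = max(params.dropout_mean_gap, 1.0)
        n_gaps = int(round(params.dropout_rate * n / mean_gap))
        halt_idx = np.flatnonzero(state == _HALT)
        for _ in range(n_gaps):
            glen = rng.geometric(1.0 / mean_gap)
            if halt_idx.size and rng.random() < params.dropout_in_halts:
                start = int(rng.choice(halt_idx))
            else:
                start = int(rng.integers(0, n))
            detected[start:start + glen] = False

    t = np.arange(n) / rate
    v = np.full(n, np.nan)
    disp = np.abs(np.diff(pos)) * rate
    pair = detected[1:] & detected[:-1]
    v[1:][pair] = disp[pair]
    first = detected & ~np.concatenate(([False], detected[:-1]))
    for j in np.flatnonzero(first):
        v[j] = disp[j] if (j + 1 < n and detected[j + 1]) else 0.0

    xx = np.where(detected, x, np.nan)
    yy = np.where(detected, y, np.nan)
    vv = np.where(detected, v, np.nan)
    zz = np.where(detected, zone, 0).astype(np.int8)

    rec = TrackRecord(
        arena_id=arena_id, trial_id=trial_id,
        genotype_by_zone=genotype_by_zone or {1: "genoA", 2: "genoB"},
        sample_rate=rate, t=t, x=xx, y=yy, v=vv, zone=zz,
        detected=detected,
        extra_metadata={"simulated": "1"})
    truth = pd.DataFrame({
        "t": t,
        "true_state": np.where(state == _HALT, "halting", "moving"),
        "true_zone": zone,
        "detected": detected,
    })
    return rec, truth


def simulate_experiment(params_a: ZoneBehavior, params_b: ZoneBehavior,
                        n_arenas: int = 40, n_trials: int = 1,
                        plants_per_genotype: int = 10,
                        leaves_per_plant: int = 4,
                        sigma_plant: float = 0.1,
                        sigma_trial: float = 0.0,
                        base: BehaviorParams | None = None,
                        geometry: ArenaGeometry | None = None,
                        seed: int | np.random.Generator = 0,
                        genotype_a: str = "genoA", genotype_b: str = "genoB",
                        ) -> tuple[list[TrackRecord], pd.DataFrame,
                                   list[pd.DataFrame]]:
    """Simulate a multi-arena two-choice experiment.

    Each arena gets one leaf of genotype A in zone 1 and one of genotype B in
    zone 2, leaves drawn without replacement from finite per-trial plant
    pools (``leaves_per_plant`` each from ``plants_per_genotype`` plants).
    Per-plant and per-trial effects are normal on the log scale with standard
    deviations ``sigma_plant``/``sigma_trial`` and shift the halt-bout
    meanlog, i.e. they multiply the median halt duration; the trial effect is
    applied antisymmetrically (+/- half per genotype), acting on the
    trial-level preference contrast.

    Returns (records, design, truths); ``design`` has one row per arena with
    plant/trial assignments and the injected effects.
    """
    if n_arenas < 1:
        raise ValueError("n_arenas must be >= 1")
    capacity = plants_per_genotype * leaves_per_plant
    if n_arenas > capacity:
        raise ValueError(
            f"plant pool exhausted: {n_arenas} arenas need more than "
            f"{capacity} leaves per genotype per trial")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = base or BehaviorParams()
    records, truths, rows = [], [], []
    for trial in range(1, n_trials + 1):
        trial_id = f"T{trial}"
        trial_eff = float(rng.normal(0.0, sigma_trial)) if sigma_trial else 0.0
        plant_eff_a = rng.normal(0.0, sigma_plant, plants_per_genotype)
        plant_eff_b = rng.normal(0.0, sigma_plant, plants_per_genotype)
        pool_a = rng.permutation(np.repeat(np.arange(plants_per_genotype),
                                           leaves_per_plant))[:n_arenas]
        pool_b = rng.permutation(np.repeat(np.arange(plants_per_genotype),
                                           leaves_per_plant))[:n_arenas]
        for a in range(n_arenas):
            pa, pb = int(pool_a[a]), int(pool_b[a])
            # the trial effect acts on the preference contrast (half up on
            # one genotype, half down on the other); a symmetric shift would
            # cancel out of every A-vs-B ratio and be unrecoverable
            za = params_a.scaled_halts(plant_eff_a[pa] + trial_eff / 2)
            zb = params_b.scaled_halts(plant_eff_b[pb] - trial_eff / 2)
            params = replace(base, zone1=za, zone2=zb)
            arena_id = f"A{a + 1:02d}"
            rec, truth = simulate_track(
                params, geometry, rng, arena_id=arena_id, trial_id=trial_id,
                genotype_by_zone={1: genotype_a, 2: genotype_b})
            records.append(rec)
            truths.append(truth)
            rows.append({
                "record_id": rec.record_id,
                "arena_id": arena_id, "trial_id": trial_id,
                "plant_a": f"{trial_id}:{genotype_a}:P{pa:02d}",
                "plant_b": f"{trial_id}:{genotype_b}:P{pb:02d}",
                "genotype_a": genotype_a, "genotype_b": genotype_b,
                "plant_effect_a": plant_eff_a[pa],
                "plant_effect_b": plant_eff_b[pb],
                "trial_effect": trial_eff,
            })
    return records, pd.DataFrame(rows), truths
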