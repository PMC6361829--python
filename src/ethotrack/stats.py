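"""The behavior-statistic catalogue: per record x zone x time bin.

Thirty-eight statistics are computed from an event series, organised in three
overarching categories — choice, movement and halting:

* ``choice``: detected time in a zone / total trial duration, the classical
  preference measure;
* ``average_velocity``: moving distance / moving time;
* halting and moving **total durations** with short/medium/long duration
  subcategories (and slow/medium/fast velocity subcategories for moving);
* halting and moving **frequencies** with the same subcategories;
* total ``moving_distance``;
* **per-event averages** of halting/moving duration (with duration
  subcategories) and of moving distance;
* four **ratios**: halting/trial, halting/detection, moving/halting,
  moving/detection.

Duration subcategories split events at two cuts (default 2 s and 10 s for
halts, 2 s and 5 s for movements — separating brief probing from sustained
feeding bouts); velocity subcategories split moving events at 0.025 and
0.075 mm/s.  Totals and frequencies are also available in time bins (hourly
by default); totals are clipped exactly at bin boundaries (distance pro rata
by time) so binned values sum to whole-trial values, while frequencies and
per-event averages attribute each event to the bin containing its start so
counts stay integral.

Detection correction divides observed totals by the record's overall
detected-time fraction for the same bin ("estimated" values), making
statistics comparable between records with different tracking success.
Frequencies are left uncorrected by default; per-event averages and
detection-relative ratios are unaffected by correction by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ethotrack.segmentation import EventSeries, MovementState

__all__ = [
    "StatisticConfig",
    "CATALOGUE",
    "TIMEBIN_SUBSET",
    "detection_fraction",
    "compute_statistics",
    "choice_ratio_table",
    "spearman_matrix",
]

_ND = int(MovementState.NOT_DETECTED)
_H = int(MovementState.HALTING)
_M = int(MovementState.MOVING)


@dataclass(frozen=True)
class StatisticConfig:
    """Cuts, binning and correction options for the catalogue."""

    halt_duration_thresholds: tuple[float, float] = (2.0, 10.0)
    move_duration_thresholds: tuple[float, float] = (2.0, 5.0)
    velocity_thresholds: tuple[float, float] = (0.025, 0.075)
    bin_width: float = 0.0        # s; 0 = whole trial
    detection_correct: bool = True
    correct_frequencies: bool = False
    log_transform_for_averaging: bool = True

    def __post_init__(self):
        for pair in (self.halt_duration_thresholds,
                     self.move_duration_thresholds,
                     self.velocity_thresholds):
            if not pair[0] < pair[1]:
                raise ValueError(f"threshold pair {pair} must be increasing")
        if self.bin_width < 0:
            raise ValueError("bin_width must be >= 0")


# name -> (unit, kind); kinds drive the correction rule
CATALOGUE: dict[str, tuple[str, str]] = {}


def _add(name, unit, kind):
    CATALOGUE[name] = (unit, kind)


_add("choice", "ratio", "choice")
_add("average_velocity", "mm/s", "avg_velocity")
for sub in ("", "_short", "_medium", "_long"):
    _add(f"halting_duration{sub}", "s", "total")
for sub in ("", "_short", "_medium", "_long"):
    _add(f"halting_frequency{sub}", "count", "frequency")
for sub in ("", "_short", "_medium", "_long", "_slow", "_medium_speed",
            "_fast"):
    _add(f"moving_duration{sub}", "s", "total")
for sub in ("", "_short", "_medium", "_long", "_slow", "_medium_speed",
            "_fast"):
    _add(f"moving_frequency{sub}", "count", "frequency")
_add("moving_distance", "mm", "total")
for sub in ("", "_short", "_medium", "_long"):
    _add(f"halting_event_duration{sub}", "s", "event_avg")
for sub in ("", "_short", "_medium", "_long"):
    _add(f"moving_event_duration{sub}", "s", "event_avg")
_add("moving_event_distance", "mm", "event_avg")
_add("halting_to_trial", "ratio", "ratio")
_add("halting_to_detection", "ratio", "ratio")
_add("moving_to_halting", "ratio", "ratio")
_add("moving_to_detection", "ratio", "ratio")

assert len(CATALOGUE) == 38

#: statistics reported per time bin by default (all 38 are computable per
#: bin; this subset governs default time-course reporting)
TIMEBIN_SUBSET = (
    "choice", "average_velocity",
    "halting_duration", "halting_frequency",
    "moving_duration", "moving_frequency", "moving_distance",
    "halting_event_duration", "moving_event_duration",
    "moving_event_distance",
    "halting_to_trial", "halting_to_detection",
    "moving_to_halting", "moving_to_detection",
)


def _overlap(t_start, t_end, lo, hi):
    """Per-event overlap duration with the interval [lo, hi)."""
    return np.clip(np.minimum(t_end, hi) - np.maximum(t_start, lo), 0.0, None)


def detection_fraction(series: EventSeries, zone: int | None = None,
                       bin_interval: tuple[float, float] | None = None
                       ) -> float:
    """Fraction of a bin during which the subject had a tracking fix.

    ``zone=None`` gives the overall (per-subject) fraction used for detection
    correction; a specific zone gives the detected time spent in that zone
    divided by the bin duration (the "choice" statistic).
    """
    if bin_interval is None:
        bin_interval = (float(series.t_start[0]), float(series.t_end[-1]))
    lo, hi = bin_interval
    if hi <= lo:
        raise ValueError("zero-length bin")
    mask = (series.state == _H) | (series.state == _M)
    if zone is not None:
        mask &= series.zone == zone
    ov = _overlap(series.t_start[mask], series.t_end[mask], lo, hi)
    return float(ov.sum() / (hi - lo))


def _bin_edges(series: EventSeries, bin_width: float) -> np.ndarray:
    t0 = float(series.t_start[0])
    t1 = float(series.t_end[-1])
    if bin_width <= 0:
        return np.array([t0, t1])
    edges = np.arange(t0, t1, bin_width)
    return np.append(edges, t1)


def _subcat_masks(values, cuts):
    lo, hi = cuts
    return {"_short": values < lo,
            "_medium": (values >= lo) & (values < hi),
            "_long": values >= hi}


def _speed_masks(values, cuts):
    lo, hi = cuts
    return {"_slow": values < lo,
            "_medium_speed": (values >= lo) & (values < hi),
            "_fast": values >= hi}


def compute_statistics(series: EventSeries,
                       config: StatisticConfig | None = None) -> pd.DataFrame:
    """Compute every catalogue statistic for every (zone, bin) cell.

    Returns a long-format frame with columns ``record_id, zone, bin,
    statistic, observed, corrected, unit``.  ``bin`` is -1 for the whole
    trial (``bin_width == 0``), else the 0-based bin index.  Cells with no
    events report 0 for totals and frequencies and NaN for averages and
    ratios with empty denominators; ``corrected`` is NaN when the bin's
    detection fraction is 0.
    """
    if config is None:
        config = StatisticConfig()
    edges = _bin_edges(series, config.bin_width)
    n_bins = edges.size - 1
    whole = config.bin_width <= 0

    st = series.state
    zn = series.zone
    ts, te = series.t_start, series.t_end
    dur = series.duration
    dist = series.distance
    mv = series.mean_velocity

    halt = st == _H
    move = st == _M
    hsub = _subcat_masks(dur, config.halt_duration_thresholds)
    msub = _subcat_masks(dur, config.move_duration_thresholds)
    vsub = _speed_masks(np.nan_to_num(mv), config.velocity_thresholds)

    rows_zone, rows_bin, rows_stat, rows_obs, rows_corr = [], [], [], [], []

    def emit(zone, b, name, observed, corrected):
        rows_zone.append(zone)
        rows_bin.append(-1 if whole else b)
        rows_stat.append(name)
        rows_obs.append(observed)
        rows_corr.append(corrected)

    for b in range(n_bins):
        lo, hi = float(edges[b]), float(edges[b + 1])
        bdur = hi - lo
        ov = _overlap(ts, te, lo, hi)
        inbin = ov > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(dur > 0, ov / dur, 0.0)
        starts = (ts >= lo) & (ts < hi)
        det_frac = float(ov[halt | move].sum() / bdur)
        cf = (1.0 / det_frac) if det_frac > 0 else np.nan
        if not config.detection_correct:
            cf = 1.0

        for zone in (1, 2, 3):
            zh = halt & (zn == zone)
            zm = move & (zn == zone)

            halt_tot = float(ov[zh].sum())
            move_tot = float(ov[zm].sum())
            dist_tot = float(np.nansum(dist[zm] * frac[zm]))
            det_zone = halt_tot + move_tot

            def corr_total(x):
                return x * cf if cf == cf else np.nan

            # choice & average velocity
            emit(zone, b, "choice", det_zone / bdur,
                 corr_total(det_zone / bdur))
            avg_v = dist_tot / move_tot if move_tot > 0 else np.nan
            emit(zone, b, "average_velocity", avg_v, avg_v)

            # totals with subcategories
            emit(zone, b, "halting_duration", halt_tot, corr_total(halt_tot))
            for sub, m in hsub.items():
                x = float(ov[zh & m].sum())
                emit(zone, b, f"halting_duration{sub}", x, corr_total(x))
            emit(zone, b, "moving_duration", move_tot, corr_total(move_tot))
            for sub, m in msub.items():
                x = float(ov[zm & m].sum())
                emit(zone, b, f"moving_duration{sub}", x, corr_total(x))
            for sub, m in vsub.items():
                x = float(ov[zm & m].sum())
                emit(zone, b, f"moving_duration{sub}", x, corr_total(x))
            emit(zone, b, "moving_distance", dist_tot, corr_total(dist_tot))

            # frequencies (events starting in the bin)
            fcf = cf if config.correct_frequencies else 1.0
            def corr_freq(x):
                return x * fcf if fcf == fcf else np.nan
            hstart = zh & starts
            mstart = zm & starts
            emit(zone, b, "halting_frequency", float(hstart.sum()),
                 corr_freq(float(hstart.sum())))
            for sub, m in hsub.items():
                x = float((hstart & m).sum())
                emit(zone, b, f"halting_frequency{sub}", x, corr_freq(x))
            emit(zone, b, "moving_frequency", float(mstart.sum()),
                 corr_freq(float(mstart.sum())))
            for sub, m in msub.items():
                x = float((mstart & m).sum())
                emit(zone, b, f"moving_frequency{sub}", x, corr_freq(x))
            for sub, m in vsub.items():
                x = float((mstart & m).sum())
                emit(zone, b, f"moving_frequency{sub}", x, corr_freq(x))

            # per-event averages (full event values, attributed by start)
            def avg(mask, values):
                k = int(mask.sum())
                return float(np.nanmean(values[mask])) if k else np.nan
            x = avg(hstart, dur)
            emit(zone, b, "halting_event_duration", x, x)
            for sub, m in hsub.items():
                x = avg(hstart & m, dur)
                emit(zone, b, f"halting_event_duration{sub}", x, x)
            x = avg(mstart, dur)
            emit(zone, b, "moving_event_duration", x, x)
            for sub, m in msub.items():
                x = avg(mstart & m, dur)
                emit(zone, b, f"moving_event_duration{sub}", x, x)
            x = avg(mstart, dist)
            emit(zone, b, "moving_event_distance", x, x)

            # ratios, computed from corrected components (the correction
            # cancels wherever both numerator and denominator are corrected)
            c_halt = corr_total(halt_tot)
            c_move = corr_total(move_tot)
            c_det = corr_total(det_zone)
            emit(zone, b, "halting_to_trial", halt_tot / bdur,
                 c_halt / bdur if c_halt == c_halt else np.nan)

            def ratio(num, den, cnum, cden):
                obs = num / den if den > 0 else np.nan
                cor = cnum / cden if (cden == cden and cden > 0) else np.nan
                return obs, cor
            o, c = ratio(halt_tot, det_zone, c_halt, c_det)
            emit(zone, b, "halting_to_detection", o, c)
            o, c = ratio(move_tot, halt_tot, c_move, c_halt)
            emit(zone, b, "moving_to_halting", o, c)
            o, c = ratio(move_tot, det_zone, c_move, c_det)
            emit(zone, b, "moving_to_detection", o, c)

    out = pd.DataFrame({
        "record_id": series.record_id,
        "zone": np.array(rows_zone, dtype=np.int8),
        "bin": np.array(rows_bin, dtype=np.int64),
        "statistic": rows_stat,
        "observed": np.array(rows_obs, dtype=float),
        "corrected": np.array(rows_corr, dtype=float),
    })
    out["unit"] = out["statistic"].map(lambda s: CATALOGUE[s][0])
    return out


# ---------------------------------------------------------------------------
# pairing for inference


def choice_ratio_table(stats: pd.DataFrame,
                       design: pd.DataFrame | None = None,
                       zone_a: int = 1, zone_b: int = 2,
                       use_corrected: bool = True) -> pd.DataFrame:
    """Pair the two leaf zones into (y_A, y_B) rows for the choice models.

    ``stats`` is the long frame from :func:`compute_statistics` (one or many
    records concatenated).  ``design`` optionally maps ``record_id`` to
    ``arena_id, trial_id, plant_a, plant_b, genotype_a, genotype_b``; absent
    columns default to one pseudo-trial and per-record pseudo-plants (each
    arena its own plant), which makes the plant variance unidentifiable but
    keeps the fixed-effect contrast valid.

    Records missing one of the two zones for a statistic are excluded with a
    warning.
    """
    val = "corrected" if use_corrected else "observed"
    sub = stats[stats["zone"].isin([zone_a, zone_b])]
    wide = sub.pivot_table(index=["record_id", "statistic", "bin"],
                           columns="zone", values=val, aggfunc="first")
    missing = wide[zone_a].isna() & wide[zone_b].isna()
    incomplete = (wide[zone_a].isna() ^ wide[zone_b].isna())
    if incomplete.any():
        warnings.warn(f"{int(incomplete.sum())} (record, statistic, bin) "
                      "cells missing one zone; excluded")
    wide = wide[~(missing | incomplete)]
    out = wide.reset_index().rename(columns={zone_a: "y_a", zone_b: "y_b"})
    out.columns.name = None
    if design is not None:
        cols = [c for c in ("arena_id", "trial_id", "plant_a", "plant_b",
                            "genotype_a", "genotype_b") if c in design.columns]
        out = out.merge(design[["record_id"] + cols], on="record_id",
                        how="left")
    if "trial_id" not in out.columns:
        out["trial_id"] = "T0"
    if "plant_a" not in out.columns:
        out["plant_a"] = "pa_" + out["record_id"].astype(str)
        out["plant_b"] = "pb_" + out["record_id"].astype(str)
    if "arena_id" not in out.columns:
        out["arena_id"] = out["record_id"]
    return out


def spearman_matrix(stats: pd.DataFrame, zone: int,
                    use_corrected: bool = True) -> pd.DataFrame:
    """Spearman rank correlations across records between whole-trial
    statistics within one zone.

    Constant statistics have undefined correlations and are reported as NaN.
    Needs at least 3 records.
    """
    val = "corrected" if use_corrected else "observed"
    sub = stats[(stats["zone"] == zone) & (stats["bin"] == -1)]
    wide = sub.pivot_table(index="record_id", columns="statistic",
                           values=val, aggfunc="first")
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    order = [s for s in CATALOGUE if s in wide.columns]
    wide = wide[order]
    rho = wide.corr(method="spearman")
    const = wide.nunique(dropna=True) <= 1
    rho.loc[const, :] = np.nan
    rho.loc[:, const] = np.nan
    return rho
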