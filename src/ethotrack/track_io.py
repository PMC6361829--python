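"""Reading, writing and validation of per-arena track exports.

A track is a fixed-rate stream of samples for one arena/subject.  Each sample
carries time since trial start (s), an (x, y) position in mm, an instantaneous
velocity in mm/s, the current zone (1, 2 or 3), and a detection flag; when the
tracker lost the subject the sample is "not detected" and carries no position,
velocity or zone.  The on-disk dialect is a small self-describing tab-separated
text format documented in ``TRACKFMT.md`` at the repository root.

Internally samples are stored as parallel NumPy arrays on :class:`TrackRecord`
(not one object per sample) because downstream segmentation iterates over
hundreds of thousands of samples per arena.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrackFormatError",
    "TrackValidationError",
    "TrackRecord",
    "VelocityHistogram",
    "read_track",
    "write_track",
    "derive_velocity",
    "velocity_histogram",
]

#: sentinel written for absent fields in the text dialect
MISSING = "-"

#: nominal tracker sample rate (samples/s)
DEFAULT_SAMPLE_RATE = 3.33

#: camera resolution used to convert pixel exports to mm (pixels per mm)
DEFAULT_PX_PER_MM = 20.0

HEADER_COLUMNS = ("t_s", "x_mm", "y_mm", "v_mm_s", "zone", "detected")


class TrackFormatError(ValueError):
    """Malformed track file (bad metadata, header or row)."""


class TrackValidationError(ValueError):
    """Structurally parseable but semantically invalid track data."""


@dataclass
class TrackRecord:
    """Time-ordered samples for one arena/subject.

    Attributes
    ----------
    arena_id, trial_id:
        Identifiers copied from the file metadata block.
    genotype_by_zone:
        Mapping of zone id (1, 2) to the genotype label of the leaf disc in
        that zone, parsed from the ``genotype`` metadata value ``"A$B"``.
    sample_rate:
        Nominal sample rate in samples/s.
    t, x, y, v:
        Float arrays, one entry per sample.  ``x``/``y``/``v`` are NaN for
        not-detected samples (and ``v`` may be NaN for detected samples when
        the exporter did not supply a velocity; see :func:`derive_velocity`).
    zone:
        int8 array; 1..3, or 0 when no zone applies (not detected).
    detected:
        Boolean array.
    """

    arena_id: str
    trial_id: str
    genotype_by_zone: dict[int, str]
    sample_rate: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    v: np.ndarray
    zone: np.ndarray
    detected: np.ndarray
    leaf_position_by_zone: dict[int, str] = field(default_factory=dict)
    extra_metadata: dict[str, str] = field(default_factory=dict)

    @property
    def record_id(self) -> str:
        return f"{self.trial_id}/{self.arena_id}"

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Trial span covered by the samples: n_samples / sample_rate."""
        return self.n_samples / self.sample_rate

    def validate(self) -> None:
        n = self.n_samples
        if n == 0:
            raise TrackValidationError("track has no samples")
        for name in ("x", "y", "v", "zone", "detected"):
            if getattr(self, name).shape != (n,):
                raise TrackValidationError(f"field {name!r} misaligned with t")
        if np.any(np.diff(self.t) <= 0):
            raise TrackValidationError("sample times are not strictly increasing")
        if self.t[0] < 0:
            raise TrackValidationError("negative start time")
        nd = ~self.detected
        if np.any(np.isfinite(self.x[nd])) or np.any(self.zone[nd] != 0):
            raise TrackValidationError(
                "not-detected samples must carry no position or zone")
        if np.any(self.v[self.detected] < 0):
            raise TrackValidationError("negative velocity")
        if set(self.genotype_by_zone) != {1, 2}:
            raise TrackValidationError(
                "genotype_by_zone must cover exactly zones 1 and 2")

    def copy(self) -> "TrackRecord":
        return replace(
            self,
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
            v=self.v.copy(), zone=self.zone.copy(),
            detected=self.detected.copy(),
            genotype_by_zone=dict(self.genotype_by_zone),
            leaf_position_by_zone=dict(self.leaf_position_by_zone),
            extra_metadata=dict(self.extra_metadata),
        )

    def equals(self, other: "TrackRecord") -> bool:
        """Field-for-field equality with NaN == NaN for data arrays."""
        if (self.arena_id, self.trial_id, self.genotype_by_zone) != (
                other.arena_id, other.trial_id, other.genotype_by_zone):
            return False
        if not math.isclose(self.sample_rate, other.sample_rate,
                            rel_tol=1e-9):
            return False
        if self.n_samples != other.n_samples:
            return False
        if not np.allclose(self.t, other.t, atol=1e-9):
            return False
        for name in ("x", "y", "v"):
            a, b = getattr(self, name), getattr(other, name)
            if not np.allclose(a, b, atol=1e-9, equal_nan=True):
                return False
        return (np.array_equal(self.zone, other.zone)
                and np.array_equal(self.detected, other.detected))


@dataclass
class VelocityHistogram:
    """Per-record velocity histogram used to pick the halting/moving threshold.

    The final bin is an overflow bin pooling all velocities >= ``v_max`` so
    that counts always sum to the number of detected samples with a velocity.
    """

    record_id: str
    bin_edges: np.ndarray  # len = n_bins + 1, strictly increasing
    counts: np.ndarray     # len = n_bins

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "count": self.counts,
        })


# ---------------------------------------------------------------------------
# parsing


def _parse_float(tok: str) -> float:
    if tok == MISSING or tok == "":
        return math.nan
    try:
        return float(tok)
    except ValueError:
        return math.nan


def read_track(path, *, px_per_mm: float | None = None,
               fill_gaps: bool = True) -> TrackRecord:
    """Read one per-arena track export.

    Parameters
    ----------
    path:
        Path to a UTF-8 text file in the dialect of ``TRACKFMT.md``.
    px_per_mm:
        If given, ``x``/``y``/``v`` in the file are taken to be in pixels
        (resp. pixels/s) and are divided by this factor on read.
    fill_gaps:
        Materialize missing rows (timestamp jumps larger than one sample
        interval) as not-detected samples at the nominal rate, so downstream
        code sees a single representation of tracking dropout.

    Rows whose position fields are non-numeric or carry the missing sentinel
    are normalized to not-detected samples.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float, float, int, bool]] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t", 1)
                if len(parts) != 2 or not parts[0].strip():
                    raise TrackFormatError(
                        f"{path}:{lineno}: malformed metadata line {line!r}")
                meta[parts[0].strip()] = parts[1].strip()
                continue
            toks = line.split("\t")
            if not header_seen:
                if tuple(toks) != HEADER_COLUMNS:
                    raise TrackFormatError(
                        f"{path}:{lineno}: expected column header "
                        f"{HEADER_COLUMNS}, got {tuple(toks)}")
                header_seen = True
                continue
            if len(toks) != 6:
                raise TrackFormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(toks)}")
            t = _parse_float(toks[0])
            if math.isnan(t):
                raise TrackFormatError(
                    f"{path}:{lineno}: non-numeric time {toks[0]!r}")
            x, y, v = (_parse_float(tok) for tok in toks[1:4])
            try:
                zone = 0 if toks[4] == MISSING else int(toks[4])
            except ValueError:
                raise TrackFormatError(
                    f"{path}:{lineno}: bad zone {toks[4]!r}") from None
            det = toks[5] == "1"
            if det and (math.isnan(x) or math.isnan(y)):
                # non-numeric position on a nominally detected row: treat the
                # sample as a tracking failure
                det = False
            if not det:
                x = y = v = math.nan
                zone = 0
            rows.append((t, x, y, v, zone, det))

    if not rows:
        raise TrackValidationError(f"{path}: no samples")
    for key in ("arena_id", "trial_id", "sample_rate_hz", "genotype"):
        if key not in meta:
            raise TrackFormatError(f"{path}: missing metadata key {key!r}")
    try:
        rate = float(meta["sample_rate_hz"])
    except ValueError:
        raise TrackFormatError(
            f"{path}: bad sample_rate_hz {meta['sample_rate_hz']!r}") from None
    if rate <= 0:
        raise TrackFormatError(f"{path}: sample_rate_hz must be positive")
    geno = meta["genotype"].split("$")
    if len(geno) != 2 or not all(g.strip() for g in geno):
        raise TrackFormatError(
            f"{path}: genotype value must be 'A$B', got {meta['genotype']!r}")

    arr = np.array([r[:4] for r in rows], dtype=float)
    t, x, y, v = arr.T
    zone = np.array([r[4] for r in rows], dtype=np.int8)
    detected = np.array([r[5] for r in rows], dtype=bool)
    if np.any(np.diff(t) <= 0):
        raise TrackValidationError(f"{path}: sample times not strictly increasing")

    if px_per_mm:
        x, y, v = x / px_per_mm, y / px_per_mm, v / px_per_mm

    if fill_gaps:
        t, x, y, v, zone, detected = _fill_gaps(t, x, y, v, zone, detected, rate)

    leaf_pos = {}
    if "leaf_position" in meta:
        parts = meta["leaf_position"].split("$")
        leaf_pos = {i + 1: p.strip() for i, p in enumerate(parts)}
    known = {"arena_id", "trial_id", "sample_rate_hz", "genotype",
             "leaf_position"}
    rec = TrackRecord(
        arena_id=meta["arena_id"],
        trial_id=meta["trial_id"],
        genotype_by_zone={1: geno[0].strip(), 2: geno[1].strip()},
        sample_rate=rate,
        t=t, x=x, y=y, v=v, zone=zone, detected=detected,
        leaf_position_by_zone=leaf_pos,
        extra_metadata={k: meta[k] for k in meta if k not in known},
    )
    rec.validate()
    return rec


def _fill_gaps(t, x, y, v, zone, detected, rate):
    """Insert not-detected samples where timestamps jump by > 1.5 intervals.

    The inserted samples sit on the nominal grid extrapolated from the sample
    before the gap, so the time axis (last t - first t) is unchanged.
    """
    dt = 1.0 / rate
    gaps = np.flatnonzero(np.diff(t) > 1.5 * dt)
    if gaps.size == 0:
        return t, x, y, v, zone, detected
    chunks_t, chunks_dat = [], []
    prev = 0
    for g in gaps:
        chunks_t.append(t[prev:g + 1])
        chunks_dat.append((x[prev:g + 1], y[prev:g + 1], v[prev:g + 1],
                           zone[prev:g + 1], detected[prev:g + 1]))
        n_missing = int(round((t[g + 1] - t[g]) / dt)) - 1
        n_missing = max(n_missing, 1)
        tt = t[g] + dt * np.arange(1, n_missing + 1)
        # keep strictly below the next real timestamp
        tt = tt[tt < t[g + 1] - 0.5 * dt]
        m = tt.size
        nanv = np.full(m, np.nan)
        chunks_t.append(tt)
        chunks_dat.append((nanv, nanv.copy(), nanv.copy(),
                           np.zeros(m, dtype=np.int8), np.zeros(m, dtype=bool)))
        prev = g + 1
    chunks_t.append(t[prev:])
    chunks_dat.append((x[prev:], y[prev:], v[prev:], zone[prev:],
                       detected[prev:]))
    t = np.concatenate(chunks_t)
    x = np.concatenate([c[0] for c in chunks_dat])
    y = np.concatenate([c[1] for c in chunks_dat])
    v = np.concatenate([c[2] for c in chunks_dat])
    zone = np.concatenate([c[3] for c in chunks_dat]).astype(np.int8)
    detected = np.concatenate([c[4] for c in chunks_dat])
    return t, x, y, v, zone, detected


# ---------------------------------------------------------------------------
# writing


def _fmt(val: float) -> str:
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return MISSING
    return format(val, ".6g")


def write_track(record: TrackRecord, path) -> None:
    """Write ``record`` in the text dialect; round-trip stable with
    :func:`read_track` (without unit conversion)."""
    if record.n_samples == 0:
        raise TrackValidationError("refusing to write a track with no samples")
    record.validate()
    buf = io.StringIO()
    buf.write(f"#arena_id\t{record.arena_id}\n")
    buf.write(f"#trial_id\t{record.trial_id}\n")
    buf.write(f"#sample_rate_hz\t{record.sample_rate:.6g}\n")
    buf.write("#genotype\t%s$%s\n" % (record.genotype_by_zone[1],
                                      record.genotype_by_zone[2]))
    if record.leaf_position_by_zone:
        vals = [record.leaf_position_by_zone.get(z, "") for z in (1, 2)]
        buf.write("#leaf_position\t%s\n" % "$".join(vals))
    for key, val in record.extra_metadata.items():
        buf.write(f"#{key}\t{val}\n")
    buf.write("\t".join(HEADER_COLUMNS) + "\n")
    zone_s = record.zone.astype(str)
    det = record.detected
    for i in range(record.n_samples):
        if det[i]:
            buf.write("%s\t%s\t%s\t%s\t%s\t1\n" % (
                format(record.t[i], ".6f"), _fmt(record.x[i]),
                _fmt(record.y[i]), _fmt(record.v[i]), zone_s[i]))
        else:
            buf.write("%s\t-\t-\t-\t-\t0\n" % format(record.t[i], ".6f"))
    tmp = os.fspath(path)
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# velocity


def derive_velocity(record: TrackRecord, *, overwrite: bool = False
                    ) -> TrackRecord:
    """Fill instantaneous velocity from positions.

    For each detected sample whose predecessor is also detected,
    ``v = |Δposition| * sample_rate``.  The first sample of a detected run
    takes the velocity of its successor; an isolated detected sample (both
    neighbours not detected) gets 0, since it carries no displacement
    evidence.  Existing finite velocities are preserved unless ``overwrite``.
    """
    rec = record.copy()
    det = rec.detected
    n = rec.n_samples
    v = np.full(n, np.nan)
    dx = np.diff(rec.x)
    dy = np.diff(rec.y)
    step = np.hypot(dx, dy) * rec.sample_rate  # step[i] = speed into sample i+1
    pair = det[1:] & det[:-1]
    v[1:][pair] = step[pair]
    # run starts: detected sample whose predecessor is not detected (or i=0)
    starts = det & ~np.concatenate(([False], det[:-1]))
    for i in np.flatnonzero(starts):
        if i + 1 < n and det[i + 1]:
            v[i] = step[i]       # successor's velocity
        else:
            v[i] = 0.0           # isolated sample
    if not overwrite:
        keep = np.isfinite(rec.v)
        v[keep] = rec.v[keep]
    rec.v = v
    return rec


def velocity_histogram(record: TrackRecord, bin_width: float = 0.0125,
                       v_max: float = 1.0) -> VelocityHistogram:
    """Histogram of detected-sample velocities with an overflow bin.

    The bimodal ("camel") shape of this histogram — a halting mode near zero
    and a moving mode well above it — is what guides the choice of the
    velocity threshold separating the two states; the dip between the modes
    is the natural threshold.
    """
    vs = record.v[record.detected]
    vs = vs[np.isfinite(vs)]
    if vs.size == 0:
        raise TrackValidationError("no detected samples with a velocity")
    edges = np.arange(0.0, v_max + bin_width * 0.5, bin_width)
    if edges[-1] < v_max:
        edges = np.append(edges, v_max)
    counts, _ = np.histogram(np.minimum(vs, v_max - 1e-12), bins=edges)
    # fold anything at/above v_max into the final (overflow) bin
    return VelocityHistogram(record_id=record.record_id,
                             bin_edges=edges, counts=counts)
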