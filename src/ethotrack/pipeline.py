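"""End-to-end pipeline: tracks -> events -> statistics -> preference models.

`run_pipeline` composes the stages in a fixed order — validate, segment,
event filters, record filters, statistics (whole-trial and hourly), zone
pairing, inference, report — writing TSV tables, plots and a markdown report
with the configuration hash and package version, so a run is reproducible
from its report plus inputs.  All stages are deterministic; only the
simulator consumes seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ethotrack import __version__
from ethotrack.track_io import TrackRecord, read_track
from ethotrack.segmentation import SegmentationConfig, segment_record
from ethotrack.filters import (EventFilterConfig, RecordFilterConfig,
                               apply_event_filters, apply_record_filters)
from ethotrack.stats import (StatisticConfig, TIMEBIN_SUBSET,
                             compute_statistics, choice_ratio_table,
                             spearman_matrix)
from ethotrack.inference import analyze_all_statistics

__all__ = ["PipelineConfig", "RunReport", "run_pipeline",
           "render_timecourse", "render_correlation"]

log = logging.getLogger("ethotrack")


@dataclass
class PipelineConfig:
    """Nested configuration of every stage; YAML round-trip stable."""

    input_paths: list[str] = field(default_factory=list)
    out_dir: str = "ethotrack_out"
    px_per_mm: float | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    event_filters: EventFilterConfig = field(default_factory=EventFilterConfig)
    record_filters: RecordFilterConfig = field(default_factory=RecordFilterConfig)
    statistics: StatisticConfig = field(default_factory=StatisticConfig)
    timebin_width: float = 3600.0
    model: str = "logit"
    include_trial_effect: bool = True
    correlation_zone: int = 2
    make_plots: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("segmentation", SegmentationConfig),
                         ("event_filters", EventFilterConfig),
                         ("record_filters", RecordFilterConfig),
                         ("statistics", StatisticConfig)):
            if key in d and isinstance(d[key], dict):
                kw = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in d[key].items()}
                d[key] = sub(**kw)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    n_records_in: int = 0
    n_records_kept: int = 0
    removed: dict[str, list[str]] = field(default_factory=dict)
    events_converted: dict[str, int] = field(default_factory=dict)
    output_files: list[str] = field(default_factory=list)
    results: pd.DataFrame | None = None


def _build_design(records: list[TrackRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "arena_id": r.arena_id,
            "trial_id": r.trial_id,
            "genotype_a": r.genotype_by_zone.get(1, ""),
            "genotype_b": r.genotype_by_zone.get(2, ""),
            "plant_a": r.extra_metadata.get("plant_a",
                                            f"pa_{r.record_id}"),
            "plant_b": r.extra_metadata.get("plant_b",
                                            f"pb_{r.record_id}"),
        })
    return pd.DataFrame(rows)


def process_records(records: list[TrackRecord],
                    seg: SegmentationConfig,
                    evf: EventFilterConfig,
                    rcf: RecordFilterConfig | None = None):
    """Segment, event-filter and record-filter a batch of records.

    Returns (filtered series list, record filter report or None,
    event conversion counts).
    """
    counts: dict[str, int] = {}
    raw_series = [segment_record(r, seg) for r in records]
    report = None
    if rcf is not None:
        report = apply_record_filters(raw_series, rcf)
        raw_series = [s for s in raw_series if s.record_id in report.kept]
    filtered = [apply_event_filters(s, evf, counts) for s in raw_series]
    return filtered, report, counts


def run_pipeline(config: PipelineConfig,
                 records: list[TrackRecord] | None = None,
                 design: pd.DataFrame | None = None) -> RunReport:
    """Execute the full pipeline.

    ``records`` (and optionally ``design``) may be passed directly — e.g.
    straight from the simulator — otherwise tracks are read from
    ``config.input_paths``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), version=__version__)

    if records is None:
        paths = [Path(p) for p in config.input_paths]
        if not paths:
            raise ValueError("no input tracks configured")
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(p)
        records = [read_track(p, px_per_mm=config.px_per_mm) for p in paths]
    if not records:
        raise ValueError("no input tracks")
    report.n_records_in = len(records)
    if design is None:
        design = _build_design(records)

    filtered, frep, counts = process_records(
        records, config.segmentation, config.event_filters,
        config.record_filters)
    report.removed = dict(frep.removed)
    report.events_converted = counts
    report.n_records_kept = len(filtered)
    log.info("records: %d in, %d kept; events converted: %s",
             report.n_records_in, report.n_records_kept, counts)
    if not filtered:
        raise ValueError("all records removed by record filters")

    events = pd.concat([s.to_frame() for s in filtered], ignore_index=True)
    _write(events, out / "events.tsv", report)
    frep.to_frame().to_csv(out / "filters.tsv", sep="\t", index=False)
    report.output_files.append(str(out / "filters.tsv"))

    whole = pd.concat(
        [compute_statistics(s, config.statistics) for s in filtered],
        ignore_index=True)
    binned_cfg = dataclasses.replace(config.statistics,
                                     bin_width=config.timebin_width)
    binned = pd.concat(
        [compute_statistics(s, binned_cfg) for s in filtered],
        ignore_index=True)
    stats_all = pd.concat([whole, binned], ignore_index=True)
    _write(stats_all, out / "stats.tsv", report)

    pairs = choice_ratio_table(stats_all, design)
    _write(pairs, out / "pairs.tsv", report)

    results = analyze_all_statistics(
        pairs, model=config.model,
        include_trial_effect=config.include_trial_effect)
    _write(results, out / "results.tsv", report)
    report.results = results

    rho = None
    if len(filtered) >= 3:
        rho = spearman_matrix(whole, zone=config.correlation_zone)
        rho.to_csv(out / "correlation.tsv", sep="\t")
        report.output_files.append(str(out / "correlation.tsv"))

    if config.make_plots:
        plots = out / "plots"
        plots.mkdir(exist_ok=True)
        tc = render_timecourse(binned, design, plots / "timecourse.png",
                               log_transform=config.statistics
                               .log_transform_for_averaging)
        report.output_files.extend(tc)
        if rho is not None:
            report.output_files.append(
                render_correlation(rho, plots / "correlation.png"))

    (out / "report.md").write_text(_report_md(config, report))
    report.output_files.append(str(out / "report.md"))
    return report


def _write(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    df.to_csv(path, sep="\t", index=False)
    report.output_files.append(str(path))


def _report_md(config: PipelineConfig, report: RunReport) -> str:
    lines = [
        "# ethotrack run report",
        "",
        f"- package version: {report.version}",
        f"- config hash: {report.config_hash}",
        f"- records in: {report.n_records_in}, kept: {report.n_records_kept}",
        f"- events converted by filters: {report.events_converted}",
        "",
        "## Removed records",
    ]
    if report.removed:
        for rid, crit in report.removed.items():
            lines.append(f"- {rid}: {', '.join(crit)}")
    else:
        lines.append("- none")
    lines += ["", "## Outputs"]
    lines += [f"- {f}" for f in report.output_files]
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# plots


def render_timecourse(binned_stats: pd.DataFrame, design: pd.DataFrame,
                      out_path, statistics=TIMEBIN_SUBSET,
                      log_transform: bool = True) -> list[str]:
    """Hourly time-course panels: per-genotype mean of (log-transformed)
    corrected values with normal-approximation 95% bands.

    Zone 1 carries genotype A, zone 2 genotype B; zeros are excluded from
    log averaging.  Bands are suppressed when fewer than 2 records remain.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = binned_stats[(binned_stats["bin"] >= 0)
                       & binned_stats["statistic"].isin(statistics)
                       & binned_stats["zone"].isin([1, 2])]
    geno = {1: design["genotype_a"].iloc[0] if len(design) else "zone 1",
            2: design["genotype_b"].iloc[0] if len(design) else "zone 2"}
    stats_present = [s for s in statistics
                     if s in set(sub["statistic"])]
    ncol = 2
    nrow = max(1, (len(stats_present) + ncol - 1) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 2.4 * nrow),
                             squeeze=False)
    for k, stat in enumerate(stats_present):
        ax = axes[k // ncol][k % ncol]
        for zone, color in ((1, "tab:green"), (2, "tab:blue")):
            d = sub[(sub["statistic"] == stat) & (sub["zone"] == zone)]
            vals = d["corrected"].to_numpy(dtype=float)
            if log_transform:
                vals = np.where(vals > 0, vals, np.nan)
                vals = np.log10(vals)
            d = d.assign(val=vals).dropna(subset=["val"])
            g = d.groupby("bin")["val"]
            mean, sd, cnt = g.mean(), g.std(), g.count()
            ax.plot(mean.index + 0.5, mean, color=color, label=geno[zone])
            band_ok = cnt >= 2
            if band_ok.any():
                half = 1.96 * sd[band_ok] / np.sqrt(cnt[band_ok])
                ax.fill_between(mean.index[band_ok] + 0.5,
                                (mean[band_ok] - half),
                                (mean[band_ok] + half),
                                color=color, alpha=0.25, linewidth=0)
        ax.set_title(stat, fontsize=8)
        ax.tick_params(labelsize=7)
        if k == 0:
            ax.legend(fontsize=7)
    for k in range(len(stats_present), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.supxlabel("time bin (h)", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return [str(out_path)]


def render_correlation(rho: pd.DataFrame, out_path) -> str:
    """Diverging heatmap of the Spearman matrix (red negative, blue
    positive); absent cells (constant statistics) render neutral."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 8))
    data = np.ma.masked_invalid(rho.to_numpy(dtype=float))
    cmap = plt.get_cmap("RdBu")
    cmap = cmap.copy()
    cmap.set_bad(color="0.9")
    im = ax.imshow(data, vmin=-1, vmax=1, cmap=cmap)
    ax.set_xticks(range(len(rho.columns)))
    ax.set_xticklabels(rho.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(rho.index)))
    ax.set_yticklabels(rho.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return str(out_path)
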