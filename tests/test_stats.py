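"""The statistic catalogue: closure, correction, binning, pairing."""

import numpy as np
import pandas as pd
import pytest

from ethotrack.stats import (StatisticConfig, CATALOGUE, TIMEBIN_SUBSET,
                             detection_fraction, compute_statistics,
                             choice_ratio_table, spearman_matrix)
from ethotrack.segmentation import SegmentationConfig, classify_samples, \
    build_events

from conftest import make_series, random_track


def stat(df, name, zone, b=-1, col="observed"):
    row = df[(df.statistic == name) & (df.zone == zone) & (df["bin"] == b)]
    assert len(row) == 1
    return float(row[col].iloc[0])


@pytest.fixture
def mixed_series():
    """One record: halts of 1, 3 and 12 s and moves with distinct mean
    velocities in zone 1; some zone-2 and not-detected time."""
    return make_series([
        ("halt", 1, 0, 1),            # short
        ("move", 1, 1, 11, 0.2),      # mean v 0.02 (slow)
        ("halt", 1, 11, 14),          # medium
        ("move", 1, 14, 24, 0.5),     # mean v 0.05 (medium speed)
        ("halt", 1, 24, 36),          # long
        ("move", 1, 36, 46, 1.0),     # mean v 0.1 (fast)
        ("halt", 2, 46, 66),
        ("nd", 0, 66, 100),
    ])


class TestCatalogue:
    def test_exactly_38_statistics(self):
        assert len(CATALOGUE) == 38
        assert len(TIMEBIN_SUBSET) == 14

    def test_every_statistic_emitted_per_zone(self, mixed_series):
        df = compute_statistics(mixed_series)
        for zone in (1, 2, 3):
            got = set(df[df.zone == zone].statistic)
            assert got == set(CATALOGUE)


class TestDetectionFraction:
    def test_fully_detected(self):
        s = make_series([("halt", 1, 0, 10), ("move", 1, 10, 20)])
        assert detection_fraction(s) == 1.0

    def test_ninety_percent(self):
        s = make_series([("halt", 1, 0, 90), ("nd", 0, 90, 100)])
        assert detection_fraction(s) == pytest.approx(0.9)

    def test_all_not_detected(self):
        s = make_series([("nd", 0, 0, 10)])
        assert detection_fraction(s) == 0.0

    def test_zone_specific(self, mixed_series):
        assert detection_fraction(mixed_series, zone=2) == \
            pytest.approx(20 / 100)

    def test_zero_length_bin_rejected(self, mixed_series):
        with pytest.raises(ValueError):
            detection_fraction(mixed_series, bin_interval=(5.0, 5.0))


class TestComputeStatistics:
    def test_duration_subcategory_binning(self, mixed_series):
        df = compute_statistics(mixed_series)
        assert stat(df, "halting_frequency_short", 1) == 1
        assert stat(df, "halting_frequency_medium", 1) == 1
        assert stat(df, "halting_frequency_long", 1) == 1
        assert stat(df, "halting_duration", 1) == pytest.approx(16.0)

    def test_velocity_subcategory_binning(self, mixed_series):
        df = compute_statistics(mixed_series)
        assert stat(df, "moving_frequency_slow", 1) == 1
        assert stat(df, "moving_frequency_medium_speed", 1) == 1
        assert stat(df, "moving_frequency_fast", 1) == 1

    def test_detection_correction_divides_by_overall_fraction(self):
        s = make_series([("halt", 1, 0, 1800), ("move", 1, 1800, 3240, 10.0),
                         ("nd", 0, 3240, 3600)])
        df = compute_statistics(s)
        assert stat(df, "halting_duration", 1) == pytest.approx(1800.0)
        assert stat(df, "halting_duration", 1, col="corrected") == \
            pytest.approx(1800.0 / 0.9)

    def test_full_detection_corrected_equals_observed(self, rng):
        rec = random_track(rng, max_len=400)
        rec.detected[:] = True
        rec.zone[rec.zone == 0] = 1
        rec.v[~np.isfinite(rec.v)] = 0.0
        s = build_events(rec, classify_samples(rec, SegmentationConfig()))
        assert not (s.state == 0).any()
        df = compute_statistics(s)
        both = df.dropna(subset=["observed", "corrected"])
        assert np.allclose(both.observed, both.corrected, rtol=1e-12)

    def test_frequencies_uncorrected_by_default(self):
        s = make_series([("halt", 1, 0, 50), ("nd", 0, 50, 100)])
        df = compute_statistics(s)
        assert stat(df, "halting_frequency", 1, col="corrected") == 1
        cfg = StatisticConfig(correct_frequencies=True)
        df2 = compute_statistics(s, cfg)
        assert stat(df2, "halting_frequency", 1, col="corrected") == \
            pytest.approx(2.0)

    def test_empty_cells_zero_totals_nan_averages(self):
        s = make_series([("halt", 1, 0, 10)])
        df = compute_statistics(s)
        assert stat(df, "moving_duration", 2) == 0.0
        assert np.isnan(stat(df, "moving_event_duration", 2))
        assert np.isnan(stat(df, "moving_to_halting", 2))

    def test_zero_detection_bin_corrected_absent(self):
        s = make_series([("nd", 0, 0, 10)])
        df = compute_statistics(s)
        needs_correction = df.statistic.map(
            lambda n: CATALOGUE[n][1] in ("total", "choice", "ratio"))
        assert df.loc[needs_correction, "corrected"].isna().all()
        # frequencies are uncorrected, so they keep their observed zeros
        freqs = df.statistic.map(lambda n: CATALOGUE[n][1] == "frequency")
        assert (df.loc[freqs, "corrected"] == 0).all()

    def test_ratio_consistency(self, mixed_series):
        df = compute_statistics(mixed_series)
        m_d = stat(df, "moving_to_detection", 1)
        h_d = stat(df, "halting_to_detection", 1)
        m_h = stat(df, "moving_to_halting", 1)
        assert m_h == pytest.approx(m_d / h_d)

    def test_choice_sums_to_overall_detection(self, rng):
        rec = random_track(rng, max_len=500)
        s = build_events(rec, classify_samples(rec, SegmentationConfig()))
        df = compute_statistics(s)
        total = sum(stat(df, "choice", z) for z in (1, 2, 3))
        assert total == pytest.approx(detection_fraction(s), rel=1e-9)


class TestBinClosure:
    @pytest.fixture
    def binned(self, rng):
        rec = random_track(rng, max_len=500)
        s = build_events(rec, classify_samples(rec, SegmentationConfig()))
        whole = compute_statistics(s, StatisticConfig(bin_width=0.0))
        hourly = compute_statistics(s, StatisticConfig(bin_width=20.0))
        return whole, hourly

    def test_binned_totals_sum_to_whole_trial(self, binned):
        whole, hourly = binned
        totals = [n for n, (_, kind) in CATALOGUE.items()
                  if kind in ("total", "frequency")]
        agg = (hourly[hourly.statistic.isin(totals)]
               .groupby(["zone", "statistic"])["observed"].sum())
        for (zone, name), val in agg.items():
            assert val == pytest.approx(stat(whole, name, zone),
                                        rel=1e-9, abs=1e-9), name

    def test_subcategory_closure_per_bin(self, binned):
        _, hourly = binned
        for b in hourly["bin"].unique():
            for zone in (1, 2, 3):
                f = lambda name: stat(hourly, name, zone, b)
                assert f("halting_duration") == pytest.approx(
                    f("halting_duration_short") + f("halting_duration_medium")
                    + f("halting_duration_long"), abs=1e-9)
                assert f("moving_frequency") == pytest.approx(
                    f("moving_frequency_slow")
                    + f("moving_frequency_medium_speed")
                    + f("moving_frequency_fast"), abs=1e-9)


class TestChoiceRatioTable:
    def test_symmetric_series_equal_pairs(self):
        ev1 = [("halt", 1, 0, 10), ("move", 1, 10, 20, 1.0),
               ("halt", 2, 20, 30), ("move", 2, 30, 40, 1.0)]
        s = make_series(ev1)
        df = compute_statistics(s)
        pairs = choice_ratio_table(df)
        sym = pairs.dropna(subset=["y_a", "y_b"])
        assert np.allclose(sym.y_a, sym.y_b)

    def test_cardinality(self, rng):
        frames = []
        for i in range(5):
            rec = random_track(rng, max_len=300)
            rec.zone[rec.zone == 0] = ((np.arange((rec.zone == 0).sum())
                                        % 3) + 1).astype(np.int8)
            s = build_events(rec, classify_samples(rec, SegmentationConfig()))
            s.record_id = f"T1/A{i:02d}"
            frames.append(compute_statistics(s))
        pairs = choice_ratio_table(pd.concat(frames, ignore_index=True))
        # totals and frequencies are defined for every record and zone, so
        # each yields one paired row per record
        always = [n for n, (_, kind) in CATALOGUE.items()
                  if kind in ("total", "frequency", "choice")]
        counts = (pairs[pairs.statistic.isin(always)]
                  .groupby("statistic")["record_id"].count())
        assert (counts == 5).all()

    def test_zero_zone_value_passes_through(self):
        s = make_series([("halt", 1, 0, 10), ("move", 1, 10, 20, 1.0)])
        pairs = choice_ratio_table(compute_statistics(s))
        row = pairs[pairs.statistic == "halting_duration"]
        assert row.y_a.iloc[0] == pytest.approx(10.0)
        assert row.y_b.iloc[0] == 0.0


class TestSpearman:
    def _stats_from(self, values: dict[str, np.ndarray]):
        """Fake long-format stats for n records with given per-statistic
        value vectors (zone 1, whole trial)."""
        rows = []
        n = len(next(iter(values.values())))
        for name, vec in values.items():
            for i in range(n):
                rows.append({"record_id": f"r{i}", "zone": 1, "bin": -1,
                             "statistic": name, "observed": vec[i],
                             "corrected": vec[i], "unit": "s"})
        return pd.DataFrame(rows)

    def test_self_and_negation(self, rng):
        a = rng.normal(size=30)
        df = self._stats_from({"choice": a, "average_velocity": -a,
                               "moving_distance": a + 1})
        rho = spearman_matrix(df, zone=1)
        assert rho.loc["choice", "choice"] == pytest.approx(1.0)
        assert rho.loc["choice", "average_velocity"] == pytest.approx(-1.0)
        assert rho.loc["choice", "moving_distance"] == pytest.approx(1.0)

    def test_independent_statistics_low_correlation(self, rng):
        df = self._stats_from({"choice": rng.normal(size=100),
                               "moving_distance": rng.normal(size=100)})
        rho = spearman_matrix(df, zone=1)
        assert abs(rho.loc["choice", "moving_distance"]) < 0.3

    def test_constant_statistic_absent(self, rng):
        df = self._stats_from({"choice": rng.normal(size=10),
                               "moving_distance": np.ones(10)})
        rho = spearman_matrix(df, zone=1)
        assert np.isnan(rho.loc["choice", "moving_distance"])

    def test_requires_three_records(self):
        df = self._stats_from({"choice": np.array([1.0, 2.0])})
        with pytest.raises(ValueError):
            spearman_matrix(df, zone=1)
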