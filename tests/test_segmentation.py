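"""State machine, event construction and halt recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethotrack.segmentation import (SegmentationConfig, MovementState,
                                    classify_samples, build_events,
                                    recover_halts, segment_record)

from conftest import make_record, make_series, random_track
from oracles import oracle_classify

H = int(MovementState.HALTING)
M = int(MovementState.MOVING)
ND = int(MovementState.NOT_DETECTED)


def classify(v, thr=0.05, n=2, detected=None, **kw):
    rec = make_record(v=v, detected=detected, rate=1.0)
    cfg = SegmentationConfig(v_threshold=thr, lookahead_n=n, **kw)
    return classify_samples(rec, cfg).tolist()


class TestClassifySamples:
    def test_all_still_and_detected_is_halting(self):
        assert classify([0, 0, 0, 0, 0, 0], thr=0.05, n=4) == [H] * 6

    def test_single_spike_suppressed(self):
        # one fast sample flanked by slow ones: start-moving fails because no
        # sample in the look-ahead window is above threshold
        assert classify([0, 0.1, 0, 0, 0, 0], thr=0.05, n=2) == [H] * 6

    def test_dip_bridged_by_remain_moving(self):
        out = classify([0.1, 0.02, 0.1, 0.1, 0, 0], thr=0.05, n=2)
        assert out == [M, M, M, M, H, H]

    def test_nondetect_velocity_counts_as_below_threshold(self):
        out = classify([0.1, 0.1, None, 0, 0, 0], thr=0.05, n=1,
                       detected=[1, 1, 0, 1, 1, 1])
        # the non-detected sample supplies no moving evidence and, coming
        # from a moving state, cannot start halting either
        assert out == [M, M, ND, H, H, H]

    def test_halting_bridges_short_dropout(self):
        out = classify([0, 0, None, 0, 0], thr=0.05, n=2,
                       detected=[1, 1, 0, 1, 1])
        assert out == [H] * 5

    def test_long_dropout_becomes_not_detected(self):
        out = classify([0, None, None, None, None, 0], thr=0.05, n=1,
                       detected=[1, 0, 0, 0, 0, 1])
        # remain-halting finds no detection within its 1-sample window
        assert out == [H, ND, ND, ND, ND, H]

    def test_empty_record_raises(self):
        rec = make_record(v=[0.1], rate=1.0)
        for name in ("t", "x", "y", "v", "zone", "detected"):
            setattr(rec, name, getattr(rec, name)[:0])
        with pytest.raises(ValueError):
            classify_samples(rec, SegmentationConfig())

    def test_lookahead_zero_start_impossible_by_default(self):
        # with an always-empty strictly-future window, start-moving can never
        # fire, so everything detected collapses to halting
        assert classify([0.3, 0.3, 0.3], thr=0.05, n=0) == [H, H, H]

    def test_lookahead_zero_with_empty_window_passing_is_thresholding(self):
        out = classify([0.3, 0.01, 0.3, 0.01], thr=0.05, n=0,
                       empty_window_passes=True)
        assert out == [M, H, M, H]

    @pytest.mark.parametrize("thr,n", [(0.025, 1), (0.05, 4), (0.1, 8),
                                       (0.05, 0)])
    def test_matches_literal_oracle(self, rng, thr, n):
        for _ in range(25):
            rec = random_track(rng, max_len=200)
            got = classify_samples(
                rec, SegmentationConfig(v_threshold=thr, lookahead_n=n))
            assert got.tolist() == oracle_classify(rec, thr, n)

    @given(st.integers(0, 2 ** 31 - 1), st.booleans())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_oracle_including_empty_window_variant(self, seed, ewp):
        rng = np.random.default_rng(seed)
        rec = random_track(rng, max_len=120)
        thr = float(rng.choice([0.0125, 0.05, 0.1]))
        n = int(rng.choice([0, 1, 2, 4, 8]))
        cfg = SegmentationConfig(v_threshold=thr, lookahead_n=n,
                                 empty_window_passes=ewp)
        got = classify_samples(rec, cfg)
        assert got.tolist() == oracle_classify(rec, thr, n,
                                               empty_window_passes=ewp)


class TestBuildEvents:
    def test_events_from_state_runs(self):
        rec = make_record(v=[0, 0, 0.1, 0.1, 0], rate=1.0)
        states = np.array([H, H, M, M, H], dtype=np.int8)
        s = build_events(rec, states)
        assert s.state.tolist() == [H, M, H]
        assert s.t_start.tolist() == [0.0, 2.0, 4.0]
        assert s.t_end.tolist() == [2.0, 4.0, 5.0]

    def test_zone_change_splits_moving_event(self):
        rec = make_record(v=[0.1] * 4, zone=[1, 1, 2, 2], rate=1.0)
        states = np.full(4, M, dtype=np.int8)
        s = build_events(rec, states)
        assert s.state.tolist() == [M, M]
        assert s.zone.tolist() == [1, 2]

    def test_all_not_detected_single_event(self):
        rec = make_record(v=[None] * 5, detected=[0] * 5, rate=1.0)
        states = np.full(5, ND, dtype=np.int8)
        s = build_events(rec, states)
        assert s.n_events == 1
        assert s.total_duration == pytest.approx(5.0)

    def test_moving_distance_is_path_length(self):
        rec = make_record(x=[0, 1, 3, 2], detected=[1] * 4, rate=1.0)
        rec.v[:] = 2.0
        s = build_events(rec, np.full(4, M, dtype=np.int8))
        # steps 1 + 2 + 1 within the single run
        assert s.distance[0] == pytest.approx(4.0)
        assert s.mean_velocity[0] == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        rec = make_record(v=[0, 0], rate=1.0)
        with pytest.raises(ValueError):
            build_events(rec, np.array([H], dtype=np.int8))

    def test_partition_of_timeline(self, rng):
        for _ in range(20):
            rec = random_track(rng, max_len=300)
            s = build_events(rec, classify_samples(rec, SegmentationConfig()))
            assert s.duration.sum() == pytest.approx(rec.duration, rel=1e-9)
            assert (s.t_end[:-1] == s.t_start[1:]).all()


class TestRecoverHalts:
    def _triplet(self, gap_dist, halt1_disp=0.2, zone2=1):
        """halt(Z1) / dropout / halt with controllable geometry."""
        s = make_series([("halt", 1, 0, 10), ("nd", 0, 10, 12),
                         ("halt", zone2, 12, 20)])
        s.sx[0], s.sy[0] = 0.0, 0.0
        s.ex[0], s.ey[0] = halt1_disp, 0.0
        s.sx[2], s.sy[2] = halt1_disp + gap_dist, 0.0
        s.ex[2], s.ey[2] = halt1_disp + gap_dist, 0.0
        return s

    def test_merge_within_radius(self):
        out = recover_halts(self._triplet(gap_dist=0.1))
        assert out.n_events == 1
        assert out.state.tolist() == [H]
        assert out.t_start[0] == 0 and out.t_end[0] == 20

    def test_no_merge_outside_radius(self):
        out = recover_halts(self._triplet(gap_dist=0.5, halt1_disp=0.2))
        assert out.n_events == 3
        assert out.state.tolist() == [H, ND, H]

    def test_no_merge_across_zones(self):
        out = recover_halts(self._triplet(gap_dist=0.1, zone2=2))
        assert out.n_events == 3

    def test_radius_floor_rescues_still_halt(self):
        # zero displacement in halt 1; the floor (one pixel) still allows a
        # merge with a nearby restart
        out = recover_halts(self._triplet(gap_dist=0.03, halt1_disp=0.0),
                            radius_floor=0.05)
        assert out.n_events == 1
        out = recover_halts(self._triplet(gap_dist=0.03, halt1_disp=0.0),
                            radius_floor=1e-9)
        assert out.n_events == 3

    def test_chained_merges_reach_fixpoint(self):
        s = make_series([("halt", 1, 0, 5), ("nd", 0, 5, 6),
                         ("halt", 1, 6, 10), ("nd", 0, 10, 11),
                         ("halt", 1, 11, 15)])
        for i in range(5):
            s.sx[i] = s.sy[i] = 0.0
            s.ex[i] = s.ey[i] = 0.0
        out = recover_halts(s, radius_floor=0.05)
        assert out.n_events == 1
        assert out.duration[0] == pytest.approx(15.0)

    def test_idempotent_and_monotone(self, rng):
        for _ in range(20):
            rec = random_track(rng, max_len=300)
            s = build_events(rec, classify_samples(rec, SegmentationConfig()))
            r1 = recover_halts(s)
            r2 = recover_halts(r1)
            assert r1.n_events == r2.n_events
            assert np.array_equal(r1.state, r2.state)
            assert np.allclose(r1.t_start, r2.t_start)
            nd_dur = lambda es: es.duration[es.state == ND].sum()
            mv_dur = lambda es: es.duration[es.state == M].sum()
            assert nd_dur(r1) <= nd_dur(s) + 1e-12
            assert mv_dur(r1) == pytest.approx(mv_dur(s), abs=1e-12)


class TestSegmentRecord:
    def test_recovery_reduces_not_detected_time(self):
        from ethotrack.simulate import BehaviorParams, simulate_track
        params = BehaviorParams(trial_length=600.0, dropout_rate=0.15,
                                dropout_in_halts=1.0)
        rec, _ = simulate_track(params, seed=3)
        on = segment_record(rec, SegmentationConfig(recover_halts=True))
        off = segment_record(rec, SegmentationConfig(recover_halts=False))
        nd = lambda es: es.duration[es.state == ND].sum()
        assert nd(on) < nd(off)
        assert on.duration.sum() == pytest.approx(off.duration.sum())
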