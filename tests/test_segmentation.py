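"""Tests for baseline estimation, change-point detection and level building."""

import itertools
import math

import numpy as np
import pytest

import blmpore as bp
from blmpore.segmentation import (
    EventSegment,
    Level,
    LevelSet,
    build_segments,
    level_histogram,
)

FS = 1000.0
TAU = 0.020


def brute_force_sse(z, n_changepoints, min_seg=2):
    """Exhaustive least-squares segmentation oracle for tiny series.

    Enumerates every placement of ``n_changepoints`` breakpoints and
    returns the minimal total within-segment squared error.
    """
    z = np.asarray(z, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(z)])
    cum2 = np.concatenate([[0.0], np.cumsum(z * z)])

    def sse(a, b):
        s, s2 = cum[b] - cum[a], cum2[b] - cum2[a]
        return s2 - s * s / (b - a)

    best = math.inf
    for bps in itertools.combinations(range(min_seg, z.size - min_seg + 1),
                                      n_changepoints):
        if any(b2 - b1 < min_seg for b1, b2 in zip(bps, bps[1:])):
            continue
        bounds = (0,) + bps + (z.size,)
        best = min(best, sum(sse(a, b) for a, b in zip(bounds, bounds[1:])))
    return best


def partition_sse(z, bps):
    bounds = np.concatenate([[0], bps, [len(z)]])
    return sum(
        float(np.sum((z[a:b] - z[a:b].mean()) ** 2))
        for a, b in zip(bounds[:-1], bounds[1:])
    )


class TestBaseline:
    def test_noisy_control_window_recovers_mean_and_sd(self, trace_factory):
        tr = trace_factory([(0.0, 30.0)], noise_sd_pS=2.0, baseline_pS=5.0, seed=1)
        mean, sd = bp.estimate_baseline(tr.conductance_pS(), FS, (0.0, 30.0))
        assert mean == pytest.approx(5.0, abs=0.2)
        assert sd == pytest.approx(2.0, abs=0.3)

    def test_noiseless_window_has_zero_spread(self, trace_factory):
        tr = trace_factory([(0.0, 5.0)], baseline_pS=10.0)
        mean, sd = bp.estimate_baseline(tr.conductance_pS(), FS, (1.0, 5.0))
        assert mean == pytest.approx(10.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_step_inside_window_warns(self, trace_factory):
        tr = trace_factory([(0.0, 3.0), (110.0, 3.0)], noise_sd_pS=2.0,
                           baseline_pS=5.0, seed=2)
        with pytest.warns(UserWarning, match="contains a conductance step"):
            bp.estimate_baseline(tr.conductance_pS(), FS, (0.0, 6.0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            bp.estimate_baseline(np.ones(100), FS, (1.0, 1.0))


class TestChangepointDetection:
    def test_constant_series_has_no_breakpoints(self):
        assert bp.detect_changepoints(np.full(2000, 50.0), FS).size == 0

    def test_single_noiseless_step_found_exactly_once(self, trace_factory):
        """One filtered 100 pS step yields one breakpoint at the step sample."""
        tr = trace_factory([(0.0, 1.0), (100.0, 1.0)])
        bps = bp.detect_changepoints(tr.conductance_pS(), FS)
        assert bps.size == 1
        assert abs(bps[0] - 1000) <= 3

    @pytest.mark.parametrize("amp", [25.0, 100.0, 900.0])
    def test_noiseless_localisation_is_amplitude_independent(self, amp,
                                                            trace_factory):
        tr = trace_factory([(0.0, 1.5), (amp, 1.5)])
        bps = bp.detect_changepoints(tr.conductance_pS(), FS)
        assert list(bps) == [1500]

    def test_rare_brief_closures_in_long_open_stretch(self, trace_factory):
        """A 600 s trace: opening plus two closures of 4 s and 6 s -> 5 steps."""
        seq = [(5.0, 100.0), (115.0, 100.0), (5.0, 4.0), (115.0, 196.0),
               (5.0, 6.0), (115.0, 194.0)]
        tr = trace_factory(seq, noise_sd_pS=2.0, seed=3)
        bps = bp.detect_changepoints(tr.conductance_pS(), FS)
        truth = np.cumsum([d for _, d in seq[:-1]]) * FS
        assert bps.size == 5
        assert all(np.abs(bps - t).min() <= 5 for t in truth)

    def test_no_false_positives_on_pure_noise(self, trace_factory):
        tr = trace_factory([(50.0, 60.0)], noise_sd_pS=6.0, seed=4)
        assert bp.detect_changepoints(tr.conductance_pS(), FS).size == 0

    def test_min_step_floor_suppresses_small_steps(self, trace_factory):
        tr = trace_factory([(0.0, 1.0), (10.0, 1.0)])
        assert bp.detect_changepoints(tr.conductance_pS(), FS,
                                      min_step_pS=20.0).size == 0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            bp.detect_changepoints(np.ones(1000), FS, min_step_pS=0.0)
        with pytest.raises(ValueError):
            bp.detect_changepoints(np.ones(10), FS)

    @pytest.mark.parametrize("n_cp", [1, 2, 3])
    def test_matches_brute_force_oracle_on_short_series(self, n_cp):
        """Detected partitions reach the exhaustive least-squares optimum."""
        rng = np.random.default_rng(100 + n_cp)
        for _ in range(5):
            bounds = np.sort(rng.choice(np.arange(30, 170), n_cp, replace=False))
            while np.any(np.diff(np.concatenate([[0], bounds, [200]])) < 30):
                bounds = np.sort(
                    rng.choice(np.arange(30, 170), n_cp, replace=False)
                )
            levels = rng.uniform(0, 400, n_cp + 1)
            while np.any(np.abs(np.diff(levels)) < 60):
                levels = rng.uniform(0, 400, n_cp + 1)
            z = np.repeat(levels, np.diff(np.concatenate([[0], bounds, [200]])))
            z = z + rng.normal(0, 4.0, z.size)
            bps = bp.detect_changepoints(
                z, FS, detect_window_s=0.012, filter_tau_s=None
            )
            assert bps.size == n_cp
            assert partition_sse(z, bps) <= 1.01 * brute_force_sse(z, n_cp)

    def test_idempotent_on_reconstructed_signal(self, trace_factory):
        seq = [(10.0, 1.0), (150.0, 0.8), (300.0, 1.2), (80.0, 1.0)]
        tr = trace_factory(seq, noise_sd_pS=3.0, seed=6)
        g = tr.conductance_pS()
        bps = bp.detect_changepoints(g, FS)
        segs = build_segments(g, FS, bps)
        recon = np.concatenate(
            [np.full(int(round(s.duration_s * FS)), s.mean_pS) for s in segs]
        )
        bps2 = bp.detect_changepoints(recon, FS, filter_tau_s=None)
        assert np.array_equal(bps, bps2)


class TestSegmentsAndLevels:
    def test_segment_means_unbiased_across_filter_ramp(self, trace_factory):
        tr = trace_factory([(10.0, 2.0), (200.0, 2.0)])
        g = tr.conductance_pS()
        segs = build_segments(g, FS, np.array([2000]))
        assert segs[0].mean_pS == pytest.approx(10.0, abs=0.1)
        assert segs[1].mean_pS == pytest.approx(200.0, abs=0.1)

    def test_short_events_flagged_not_deleted(self):
        segs = [
            EventSegment(0.0, 1.0, None, 5.0, 1.0),
            EventSegment(1.0, 1.050, None, 110.0, 1.0),   # 50 ms -> flagged
            EventSegment(1.050, 1.110, None, 5.0, 1.0),   # exactly 60 ms -> kept
        ]
        out = bp.filter_short_events(segs)
        assert [s.flag_short for s in out] == [False, True, False]
        assert len(out) == len(segs)

    def test_twelve_level_trace_recovered(self, trace_factory):
        """A multilevel trace with 12 well-separated levels is fully resolved."""
        means = [10.0 + 130.0 * i for i in range(12)]
        seq = [(m, 0.5) for m in means + means[-2::-1]]
        tr = trace_factory(seq, noise_sd_pS=6.0, seed=7)
        segments, levelset, _ = bp.segment_trace(tr)
        assert len(levelset) == 12
        for lv, m in zip(levelset.levels, means):
            assert lv.mean_pS == pytest.approx(m, abs=6.0)
        assert levelset.baseline.mean_pS == pytest.approx(10.0, abs=6.0)

    def test_single_segment_single_level(self):
        ls, segs = bp.cluster_levels([EventSegment(0.0, 1.0, None, 42.0, 1.0)])
        assert len(ls) == 1 and segs[0].level_id == 1

    def test_segments_within_tolerance_merge(self):
        segs = [
            EventSegment(0.0, 1.0, None, 100.0, 1.0),
            EventSegment(1.0, 2.0, None, 110.0, 1.0),
            EventSegment(2.0, 3.0, None, 200.0, 1.0),
        ]
        ls, out = bp.cluster_levels(segs, merge_tolerance_pS=20.0)
        assert len(ls) == 2
        assert ls.levels[0].mean_pS == pytest.approx(105.0)
        assert [s.level_id for s in out] == [1, 1, 2]

    def test_flagged_short_events_do_not_shape_levels(self):
        segs = [
            EventSegment(0.0, 10.0, None, 100.0, 1.0),
            EventSegment(10.0, 10.05, None, 150.0, 1.0, flag_short=True),
            EventSegment(10.05, 20.0, None, 102.0, 1.0),
        ]
        ls, out = bp.cluster_levels(segs, merge_tolerance_pS=20.0)
        assert len(ls) == 1
        # the flagged ramp fragment is assigned to the nearest real level
        assert out[1].level_id == 1
        assert ls.levels[0].mean_pS == pytest.approx(101.0, abs=0.1)

    def test_segmentation_partitions_the_trace(self, trace_factory):
        seq = [(10.0, 1.0), (150.0, 1.0), (10.0, 1.0)]
        tr = trace_factory(seq, noise_sd_pS=3.0, seed=8)
        segments, _, _ = bp.segment_trace(tr)
        assert segments[0].t_start_s == 0.0
        assert segments[-1].t_end_s == pytest.approx(tr.duration_s)
        for a, b in zip(segments, segments[1:]):
            assert b.t_start_s == pytest.approx(a.t_end_s)

    def test_levelset_invariants(self):
        with pytest.raises(ValueError):
            LevelSet(levels=[Level(1, 100.0, 1.0, 1.0), Level(2, 50.0, 1.0, 1.0)])


class TestPoreOccupancy:
    def test_two_similar_pores_counted(self):
        """Levels at baseline + n units resolve to n open pores."""
        ls = LevelSet(levels=[Level(1, 16.0, 2.0, 900.0),
                              Level(2, 148.0, 2.0, 600.0),
                              Level(3, 274.0, 2.0, 300.0)])
        occ = bp.infer_pore_occupancy(ls, unit_conductance_pS=130.0)
        assert [occ[i]["n_pores"] for i in (1, 2, 3)] == [0, 1, 2]
        assert not any(occ[i]["ambiguous"] for i in (1, 2, 3))

    def test_baseline_level_is_zero_pores(self):
        ls = LevelSet(levels=[Level(1, 16.0, 2.0, 900.0)])
        occ = bp.infer_pore_occupancy(ls, 130.0)
        assert occ[1]["n_pores"] == 0

    def test_half_unit_level_flagged_ambiguous(self):
        ls = LevelSet(levels=[Level(1, 0.0, 1.0, 10.0), Level(2, 65.0, 1.0, 10.0)])
        occ = bp.infer_pore_occupancy(ls, 130.0, tolerance_pS=30.0)
        assert occ[2]["ambiguous"]

    def test_invalid_unit_rejected(self):
        ls = LevelSet(levels=[Level(1, 0.0, 1.0, 1.0)])
        with pytest.raises(ValueError):
            bp.infer_pore_occupancy(ls, 0.0)


def test_level_histogram_covers_all_levels(trace_factory):
    tr = trace_factory([(10.0, 1.0), (150.0, 1.0)], noise_sd_pS=2.0, seed=9)
    _, levelset, _ = bp.segment_trace(tr)
    counts, edges = level_histogram(tr.conductance_pS(), levelset)
    assert counts.sum() == tr.n_samples
    assert edges[0] <= tr.conductance_pS().min()
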