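"""Tests for dwell statistics, opening kinetics and dose-response tables."""

import itertools
import math

import numpy as np
import pytest

import blmpore as bp
from blmpore.segmentation import EventSegment


def events_from_spans(spans):
    """spans: list of (level_id, duration_s) -> contiguous EventSegments."""
    out, t = [], 0.0
    for lid, d in spans:
        out.append(EventSegment(t, t + d, lid, float(100 * lid), 2.0))
        t += d
    return out


class TestDwellStatistics:
    def test_three_visits_average_like_the_worked_example(self):
        """Visits of 3.2, 2.6 and 2.9 s pool to a 2.9 s mean dwell."""
        spans = [(1, 5.0)]
        for d in (3.2, 2.6, 2.9):
            spans += [(2, d), (1, 5.0)]
        ds = bp.dwell_statistics(events_from_spans(spans), level_id=2)
        assert ds.n_visits == 3
        assert ds.mean_dwell_s == pytest.approx(2.9, abs=1e-9)
        # visit-to-visit spread is 0.3 s; the SE of the mean is 0.3/sqrt(3)
        assert ds.se_dwell_s == pytest.approx(0.3 / math.sqrt(3), abs=0.01)

    def test_single_visit_has_no_se(self):
        spans = [(1, 5.0), (2, 3.0), (1, 5.0)]
        ds = bp.dwell_statistics(events_from_spans(spans), 2)
        assert ds.n_visits == 1 and ds.se_dwell_s is None

    def test_censored_edge_visits_excluded(self):
        spans = [(2, 100.0), (1, 5.0), (2, 3.0), (1, 5.0), (2, 200.0)]
        ds = bp.dwell_statistics(events_from_spans(spans), 2)
        assert ds.n_visits == 1
        assert ds.mean_dwell_s == pytest.approx(3.0)

    def test_adjacent_same_level_segments_merge_into_one_visit(self):
        segs = events_from_spans([(1, 5.0), (2, 1.0), (2, 2.0), (1, 5.0)])
        ds = bp.dwell_statistics(segs, 2)
        assert ds.n_visits == 1
        assert ds.mean_dwell_s == pytest.approx(3.0)

    def test_short_flagged_interruption_does_not_split_a_visit(self):
        segs = events_from_spans([(1, 5.0), (2, 1.0), (3, 0.05), (2, 2.0), (1, 5.0)])
        segs[2] = EventSegment(segs[2].t_start_s, segs[2].t_end_s, 3, 300.0, 2.0,
                               flag_short=True)
        ds = bp.dwell_statistics(segs, 2)
        assert ds.n_visits == 1
        assert ds.mean_dwell_s == pytest.approx(3.0)

    def test_exponential_dwell_mean_recovered_within_clt_bounds(self):
        rng = np.random.default_rng(1)
        n = 10_000
        spans = []
        for d in rng.exponential(0.1, n):
            spans += [(1, 0.05), (2, d)]
        spans.append((1, 0.05))
        ds = bp.dwell_statistics(events_from_spans(spans), 2)
        assert abs(ds.mean_dwell_s - 0.1) < 3 * ds.se_dwell_s

    def test_no_visits_is_an_error(self):
        with pytest.raises(ValueError):
            bp.dwell_statistics(events_from_spans([(1, 5.0)]), 2)


class TestOpeningAndClosedTime:
    def test_eight_openings_in_100_minutes(self):
        """8 closed->open transitions over 100 min give 0.08 per minute."""
        spans = [(1, 60.0)]
        for _ in range(8):
            spans += [(2, 600.0), (1, 60.0)]
        spans[-1] = (1, 6000.0 - sum(d for _, d in spans[:-1]))
        events = events_from_spans(spans)
        assert bp.opening_frequency(events, 6000.0) == pytest.approx(0.08)

    def test_no_openings_is_zero(self):
        events = events_from_spans([(1, 100.0)])
        assert bp.opening_frequency(events, 100.0) == 0.0

    def test_poisson_rate_recovered(self):
        """CTMC openings at rate lambda are counted to within 3*sqrt(lam*T)/T."""
        lam = 0.05  # 1/s
        model = bp.build_two_state_model(
            1.2, barrier_open_kT=10.0, opening_rate_per_s=lam, nu=5e32
        )
        T = 20_000.0
        ev = bp.simulate_events(model, T, seed=21)
        segs = [
            EventSegment(t0, t1, 1 if sid == "closed" else 2,
                         0.0 if sid == "closed" else 940.0, 1.0)
            for sid, t0, t1 in ev.dwells
        ]
        est_per_s = bp.opening_frequency(segs, T) / 60.0
        # openings only occur while closed; compare against realised closed time
        closed_s = sum(s.duration_s for s in segs if s.level_id == 1)
        lam_eff = lam * closed_s / T
        assert abs(est_per_s - lam_eff) < 3 * math.sqrt(lam_eff * T) / T

    def test_closed_fraction_of_the_worked_example(self):
        """15 s at baseline over a 100 min observation is 0.25 %."""
        spans = [(1, 300.0), (2, 2000.0), (1, 7.0), (2, 2000.0), (1, 8.0),
                 (2, 1985.0)]
        events = events_from_spans(spans)
        assert bp.closed_fraction(events, (300.0, 6300.0)) == pytest.approx(0.25)

    def test_closed_fraction_window_defaults_to_after_first_opening(self):
        spans = [(1, 300.0), (2, 500.0), (1, 5.0), (2, 195.0)]
        assert bp.closed_fraction(events_from_spans(spans)) == pytest.approx(
            100 * 5.0 / 700.0
        )

    def test_always_open_and_always_closed_extremes(self):
        assert bp.closed_fraction(events_from_spans([(2, 100.0)])) == 0.0
        assert bp.closed_fraction(events_from_spans([(1, 100.0)])) == 100.0

    def test_open_plus_closed_fractions_partition_the_window(self):
        spans = [(1, 10.0), (2, 30.0), (1, 20.0), (2, 40.0)]
        events = events_from_spans(spans)
        w = (0.0, 100.0)
        closed = bp.closed_fraction(events, w)
        open_pct = 100.0 - closed
        t_open = sum(d for lid, d in spans if lid != 1)
        assert open_pct == pytest.approx(100 * t_open / 100.0)

    def test_time_translation_invariance(self):
        spans = [(1, 60.0), (2, 600.0), (1, 60.0), (2, 600.0), (1, 60.0)]
        ev1 = events_from_spans(spans)
        ev2 = events_from_spans([(1, 1000.0)] + spans)
        f1 = bp.opening_frequency(ev1, 1380.0)
        f2 = bp.opening_frequency(ev2, 2380.0)
        assert f1 * 1380 == pytest.approx(f2 * 2380)  # same count


class TestPerAddition:
    def test_known_interval_means_recovered_exactly(self, trace_factory):
        seq = [(5.0, 30.0), (120.0, 30.0), (260.0, 30.0)]
        tr = trace_factory(seq, noise_sd_pS=0.0)
        schedule = bp.AdditionSchedule.from_records(
            [{"time_s": 30.0, "chamber": "cis", "volume_uL": 10.0},
             {"time_s": 60.0, "chamber": "cis", "volume_uL": 10.0}]
        )
        df = bp.per_addition_conductance(tr, schedule, settling_s=5.0)
        assert df["volume_uL"].tolist() == [0.0, 10.0, 20.0]
        assert df["mean_pS"].iloc[1] == pytest.approx(120.0, abs=0.5)
        assert df["mean_pS"].iloc[2] == pytest.approx(260.0, abs=0.5)
        assert df["concentration_ug_per_mL"].iloc[2] == pytest.approx(8.0)

    def test_interval_shorter_than_settling_is_flagged(self, trace_factory):
        tr = trace_factory([(5.0, 20.0)])
        schedule = bp.AdditionSchedule.from_records(
            [{"time_s": 10.0, "chamber": "cis", "volume_uL": 10.0},
             {"time_s": 12.0, "chamber": "cis", "volume_uL": 10.0}]
        )
        df = bp.per_addition_conductance(tr, schedule, settling_s=5.0)
        assert bool(df["flagged"].iloc[1])
        assert math.isnan(df["mean_pS"].iloc[1])

    def test_membrane_spread_survives_aggregation(self):
        """Four membranes at {39, 43, 270, 1450} pS keep their ~40x spread."""
        import pandas as pd

        rows = []
        for i, g in enumerate([39.0, 43.0, 270.0, 1450.0]):
            rows.append({"volume_uL": 100.0, "concentration_ug_per_mL": 40.0,
                         "shell": "HSA", "particle_nm": 27.0,
                         "membrane_id": f"m{i}", "mean_pS": g, "se_pS": 5.0})
        agg = bp.aggregate_dose_response(pd.DataFrame(rows))
        assert agg["mean_pS"].iloc[0] == pytest.approx(np.mean([39, 43, 270, 1450]))
        assert agg["se_pS"].iloc[0] == pytest.approx(
            np.std([39, 43, 270, 1450], ddof=1) / 2
        )


class TestSignTest:
    def test_known_one_sided_values(self):
        assert bp.sign_test([1, 2, 3, 4, 5]) == pytest.approx(0.03125)
        assert bp.sign_test([1, -1]) == pytest.approx(0.75)

    def test_two_sided_doubles_the_smaller_tail(self):
        d = [1, 1, 1, -1]
        one = bp.sign_test(d, "greater")
        assert bp.sign_test(d, "two-sided") == pytest.approx(min(1.0, 2 * one))

    def test_zeros_dropped_and_all_zero_rejected(self):
        assert bp.sign_test([0, 0, 1, 1]) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            bp.sign_test([0.0, 0.0])

    @pytest.mark.parametrize("n", [1, 2, 5, 8, 12])
    def test_matches_exhaustive_enumeration(self, n):
        """P(X >= k) agrees with counting all 2^n sign patterns."""
        for k in range(n + 1):
            diffs = [1.0] * k + [-1.0] * (n - k)
            count = sum(
                1
                for signs in itertools.product([1, -1], repeat=n)
                if sum(s > 0 for s in signs) >= k
            )
            assert bp.sign_test(diffs) == pytest.approx(count / 2**n)
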