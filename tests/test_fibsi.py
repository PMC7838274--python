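"""Unit and property tests for the waveform-detection engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibsinet.fibsi import (
    ReferencePolyline,
    Trace,
    build_reference,
    detect_events,
    quantify_events,
    rdp_simplify,
    residual_trace,
    running_median,
)

from conftest import rdp_recursive_oracle


def make_trace(y, dt=1.0, cell="c"):
    y = np.asarray(y, dtype=float)
    return Trace(cell, np.arange(len(y)) * dt, y)


class TestRunningMedian:
    def test_constant_trace_is_unchanged(self):
        tr = make_trace(np.full(20, 7.0))
        assert np.allclose(running_median(tr, 5.0), 7.0)

    def test_shrinking_edge_windows_match_per_window_sort(self):
        tr = make_trace([1, 9, 1, 9, 1])
        # independent oracle: median over samples within +-1.5 of each time
        expected = [np.median([1, 9]), np.median([1, 9, 1]), np.median([9, 1, 9]),
                    np.median([1, 9, 1]), np.median([9, 1])]
        assert np.allclose(running_median(tr, 3.0), expected)

    def test_one_sample_window_is_identity(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(size=30))
        assert np.allclose(running_median(tr, 1.0), tr.y)

    def test_window_below_sample_interval_rejected(self):
        tr = make_trace(np.zeros(10))
        with pytest.raises(ValueError):
            running_median(tr, 0.5)

    def test_random_traces_match_brute_force(self):
        rng = np.random.default_rng(1)
        tr = make_trace(rng.normal(size=50))
        for window in (3.0, 7.0):
            got = running_median(tr, window)
            half = window / 2
            exp = [np.median(tr.y[np.abs(tr.t - t0) <= half + 1e-9]) for t0 in tr.t]
            assert np.allclose(got, exp)


class TestBuildReference:
    def test_flat_trace_reference_equals_trace(self, flat_trace):
        med = running_median(flat_trace, 5.0)
        ref = build_reference(flat_trace, med, side="below")
        assert np.allclose(ref(flat_trace.t), flat_trace.y)

    def test_triangular_bump_reference_is_baseline(self):
        y = np.zeros(41)
        y[18:23] = [5, 10, 15, 10, 5]
        tr = make_trace(y)
        med = running_median(tr, 5.0)
        ref = build_reference(tr, med, side="below")
        assert np.allclose(ref(tr.t), 0.0, atol=1e-12)

    def test_sawtooth_knots_at_trough_samples(self):
        # period-6 sawtooth: troughs at known indices
        t = np.arange(60.0)
        y = np.abs((t % 6) - 3)  # min 0 at t % 6 == 3
        tr = make_trace(y)
        med = running_median(tr, 7.0)
        ref = build_reference(tr, med, side="below")
        # brute-force local-minimum scan below the median
        troughs = [i for i in range(1, 59)
                   if y[i] < y[i - 1] and y[i] < y[i + 1] and y[i] < med[i]]
        interior = ref.knot_times[(ref.knot_times > 0) & (ref.knot_times < 59)]
        assert set(interior) == {float(i) for i in troughs}

    def test_above_side_mirrors_below(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=80)
        tr_pos = make_trace(y)
        tr_neg = make_trace(-y)
        med = running_median(tr_pos, 5.0)
        ref_b = build_reference(tr_pos, med, side="below")
        ref_a = build_reference(tr_neg, -med, side="above")
        assert np.allclose(ref_a(tr_pos.t), -ref_b(tr_pos.t))

    def test_degenerate_side_warns_and_returns_flat(self):
        y = np.zeros(10)
        y[5] = -1.0  # one dip; everything else at median
        tr = make_trace(y)
        med = np.zeros(10)
        with pytest.warns(RuntimeWarning):
            ref = build_reference(tr, med, side="above")
        assert np.allclose(ref(tr.t), 0.0)


class TestRdpSimplify:
    def test_collinear_points_keep_endpoints_only(self):
        pts = np.column_stack((np.arange(10.0), 2.0 * np.arange(10.0)))
        assert rdp_simplify(pts, 0.0).tolist() == [0, 9]

    def test_epsilon_above_max_deviation_keeps_endpoints_only(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack((np.arange(20.0), rng.normal(scale=0.1, size=20)))
        assert rdp_simplify(pts, 100.0).tolist() == [0, 19]

    def test_matches_recursive_oracle_on_random_polylines(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(2, 51)
            pts = np.column_stack((np.sort(rng.uniform(0, 10, n)),
                                   rng.uniform(-5, 5, n)))
            eps = rng.uniform(0, 2)
            assert rdp_simplify(pts, eps).tolist() == \
                rdp_recursive_oracle(pts, eps).tolist()

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.floats(0, 10))
    def test_dropped_points_stay_within_epsilon(self, ys, eps):
        pts = np.column_stack((np.arange(len(ys), dtype=float), ys))
        idx = rdp_simplify(pts, eps)
        assert idx[0] == 0 and idx[-1] == len(ys) - 1
        # every dropped point is within eps of its bracketing kept segment
        for a, b in zip(idx[:-1], idx[1:]):
            for i in range(a + 1, b):
                p0, p1, p = pts[a], pts[b], pts[i]
                d = p1 - p0
                dist = abs(d[0] * (p0[1] - p[1]) - (p0[0] - p[0]) * d[1]) / np.hypot(*d)
                assert dist <= eps + 1e-9


def rectangle_trace(h=10.0, w=4.0, dt=0.01, t_on=3.0, total=10.0):
    t = np.arange(0.0, total, dt)
    y = np.where((t >= t_on) & (t < t_on + w), h, 0.0)
    return Trace("rect", t, y)


def flat_reference(tr):
    return ReferencePolyline(np.array([tr.t[0], tr.t[-1]]), np.zeros(2))


class TestDetectAndQuantify:
    def test_zero_residual_gives_no_events(self, flat_trace):
        ref = ReferencePolyline(np.array([0.0, 49.0]), np.array([3.0, 3.0]))
        assert detect_events(flat_trace, ref, 0.5) == []

    def test_rectangular_pulse_metrics(self):
        tr = rectangle_trace()
        events = detect_events(tr, flat_reference(tr), 1.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude == pytest.approx(10.0)
        assert ev.auc == pytest.approx(40.0, rel=0.01)
        assert ev.duration == pytest.approx(4.0, rel=0.01)

    def test_subthreshold_pulse_rejected(self):
        tr = rectangle_trace(h=0.5)
        assert detect_events(tr, flat_reference(tr), 1.0) == []

    def test_symmetric_triangle_has_zero_peak_offset(self):
        y = np.concatenate([np.zeros(5), np.arange(0, 11.0), np.arange(9, -1, -1.0),
                            np.zeros(5)])
        tr = make_trace(y)
        ev = detect_events(tr, flat_reference(tr), 1.0)[0]
        assert ev.peak_offset == pytest.approx(0.0, abs=1e-9)
        assert ev.rise_time == pytest.approx(ev.duration / 2)

    def test_immediate_peak_ramp_has_zero_rise_time(self):
        y = np.concatenate([np.zeros(3), np.arange(10.0, 0.0, -1.0), np.zeros(3)])
        tr = make_trace(y)
        ev = detect_events(tr, flat_reference(tr), 1.0)[0]
        assert ev.rise_time == pytest.approx(1.0)  # one frame from zero boundary
        assert ev.peak_offset < 0

    def test_gamma_shaped_transient_matches_quadrature_oracle(self):
        from scipy.stats import gamma as gamma_dist

        dt = 0.001
        t = np.arange(0.0, 30.0, dt)
        shape, scale = 3.0, 1.5
        y = 50.0 * gamma_dist.pdf(t, shape, scale=scale) / \
            gamma_dist.pdf((shape - 1) * scale, shape, scale=scale)
        tr = Trace("g", t, y)
        ev = detect_events(tr, flat_reference(tr), 1.0)[0]
        # fine-grid quadrature oracle over the same event span
        mask = (t >= ev.t_start) & (t <= ev.t_end)
        oracle_auc = np.trapezoid(y[mask], t[mask])
        assert ev.amplitude == pytest.approx(50.0, rel=0.005)
        assert ev.auc == pytest.approx(oracle_auc, rel=0.005)

    def test_planted_transients_recovered_with_onset_accuracy(self):
        from fibsinet.synthetic import biexp_kernel

        rng = np.random.default_rng(5)
        t = np.arange(301.0)
        noise_sd = 0.5
        y = rng.normal(0, noise_sd, len(t))
        onsets = np.arange(10, 291, 28.0)[:10]
        kern = biexp_kernel(np.arange(40.0), 1.5, 6.0)
        for on in onsets:
            j = int(on)
            m = min(len(kern), len(t) - j)
            y[j:j + m] += 20.0 * kern[:m]  # SNR 40
        tr = Trace("p", t, y)
        med = running_median(tr, 5.0)
        ref = build_reference(tr, med, side="below")
        events = detect_events(tr, ref, 2 * noise_sd)
        big = [e for e in events if e.amplitude > 5 * noise_sd]
        assert len(big) == 10
        for e, on in zip(big, onsets):
            assert abs(e.t_start - on) <= 2.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        y = np.clip(rng.normal(0, 1, 200), 0, None)
        tr1, tr2 = make_trace(y), make_trace(5.0 * y)
        ev1 = detect_events(tr1, flat_reference(tr1), 0.5)
        ev2 = detect_events(tr2, flat_reference(tr2), 2.5)
        assert len(ev1) == len(ev2)
        for a, b in zip(ev1, ev2):
            assert (a.t_start, a.t_end) == (b.t_start, b.t_end)
            assert b.amplitude == pytest.approx(5 * a.amplitude)
            assert b.auc == pytest.approx(5 * a.auc)

    def test_time_shift_equivariance(self):
        rng = np.random.default_rng(7)
        y = np.clip(rng.normal(0, 1, 150), 0, None)
        t = np.arange(150.0)
        tr1 = Trace("a", t, y)
        tr2 = Trace("a", t + 37.0, y)
        ref1 = ReferencePolyline(np.array([t[0], t[-1]]), np.zeros(2))
        ref2 = ReferencePolyline(np.array([t[0] + 37, t[-1] + 37]), np.zeros(2))
        ev1 = detect_events(tr1, ref1, 0.5)
        ev2 = detect_events(tr2, ref2, 0.5)
        assert len(ev1) == len(ev2)
        for a, b in zip(ev1, ev2):
            assert b.t_peak == pytest.approx(a.t_peak + 37.0)
            assert b.duration == pytest.approx(a.duration)

    def test_events_disjoint_ordered_within_span(self, calcium_field):
        _, traces, _ = calcium_field
        for tr in traces[:3]:
            med = running_median(tr, 5.0)
            ref = build_reference(tr, med, side="below")
            events = detect_events(tr, ref, 1.0)
            for a, b in zip(events[:-1], events[1:]):
                assert a.t_end <= b.t_start + 1e-9
            for e in events:
                assert tr.t[0] <= e.t_start < e.t_end <= tr.t[-1]

    def test_boundary_event_flagged(self):
        y = np.concatenate([np.arange(10.0, 0, -1.0), np.zeros(20)])
        tr = make_trace(y)
        ev = detect_events(tr, flat_reference(tr), 1.0)[0]
        assert "boundary_truncated" in ev.flags

    def test_quantify_uses_raw_residual(self):
        tr = rectangle_trace(dt=0.5)
        runs = [(int(3.0 / 0.5), int(6.5 / 0.5))]
        evs = quantify_events(tr, flat_reference(tr), runs)
        assert evs[0].amplitude == pytest.approx(10.0)

    def test_residual_requires_spanning_reference(self):
        tr = rectangle_trace()
        short = ReferencePolyline(np.array([0.0, 5.0]), np.zeros(2))
        with pytest.raises(ValueError):
            residual_trace(tr, short)
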