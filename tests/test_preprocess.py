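"""Efficiency computation, masking, bleach detection, and response calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smfretkin.preprocess import (
    BleachCall,
    MissingInjectionError,
    classify_response,
    compute_efret,
    detect_bleach,
    fraction_percent,
    measure_delay,
)
from smfretkin.synth import (
    KineticScheme,
    SimConfig,
    StateSpec,
    default_scheme,
    render_trace,
    simulate_ctmc_path,
    simulate_experiment,
)
from smfretkin.trace_io import Trace


def flat_trace(e=0.47, n=200, total=100.0, **kw):
    return Trace(
        trace_id="t",
        donor=np.full(n, (1 - e) * total),
        acceptor=np.full(n, e * total),
        **kw,
    )


class TestComputeEfret:
    def test_proximity_ratio_arithmetic(self):
        t = Trace("t", donor=np.array([53.0, 10.0]), acceptor=np.array([47.0, 0.0]))
        e = compute_efret(t)
        assert e.E[0] == pytest.approx(0.47)
        assert e.E[1] == pytest.approx(0.0)

    def test_denominator_below_floor_masks_frame(self):
        t = flat_trace(total=100.0)
        t.donor[10] = 2.0
        t.acceptor[10] = 2.0  # total 4 < 10% of median total 100
        e = compute_efret(t)
        assert not e.valid[10] and np.isnan(e.E[10])
        assert e.valid[11]

    def test_direct_excitation_window_masked(self):
        t = flat_trace(direct_excitation_window=(50, 60))
        e = compute_efret(t)
        assert not e.valid[50:60].any()
        assert e.valid[:50].all() and e.valid[60:].all()

    def test_bleach_call_masks_tail(self):
        t = flat_trace(n=100)
        e = compute_efret(t, bleach=BleachCall(donor_bleach_frame=70))
        assert e.valid[:70].all() and not e.valid[70:].any()
        assert e.analysis_segments == [(0, 70)]

    def test_masking_is_monotone_under_bleach_calls(self):
        t = flat_trace(n=100, direct_excitation_window=(20, 30))
        base = compute_efret(t)
        more = compute_efret(t, bleach=BleachCall(acceptor_bleach_frame=60))
        assert not np.any(more.valid & ~base.valid)

    def test_fully_masked_trace_allowed(self):
        t = flat_trace(n=50)
        e = compute_efret(t, bleach=BleachCall(donor_bleach_frame=0))
        assert e.n_valid == 0 and e.analysis_segments == []

    def test_injection_splits_analysis_segments(self):
        t = flat_trace(n=100, injection_frame=40)
        e = compute_efret(t)
        assert e.analysis_segments == [(0, 40), (40, 100)]

    @given(scale=st.floats(1e-3, 1e3), e_level=st.floats(0.05, 0.95))
    def test_efficiency_is_scale_invariant(self, scale, e_level):
        t1 = flat_trace(e=e_level, n=10)
        t2 = Trace("t", donor=t1.donor * scale, acceptor=t1.acceptor * scale)
        np.testing.assert_allclose(
            compute_efret(t1).E, compute_efret(t2).E, rtol=1e-12
        )


class TestDetectBleach:
    @pytest.fixture(scope="class")
    @staticmethod
    def scheme():
        return KineticScheme(states=[StateSpec("A", 0.4)],
                             initial_distribution=np.array([1.0]))

    def render(self, scheme, rng, **kw):
        cfg = SimConfig(pre_scheme=scheme, n_traces=1, n_frames=400)
        path = simulate_ctmc_path(scheme, 20.0, rng)
        return render_trace(path, scheme, cfg, rng, **kw)

    def test_forced_donor_bleach_found_within_two_frames(self, scheme, rng):
        hits = []
        for _ in range(20):
            t = self.render(scheme, rng, donor_bleach_frame=200)
            call = detect_bleach(t)
            assert call.donor_bleach_frame is not None
            hits.append(call.donor_bleach_frame)
        assert np.all(np.abs(np.array(hits) - 200) <= 2)

    def test_clean_trace_yields_no_call(self, scheme, rng):
        for _ in range(10):
            call = detect_bleach(self.render(scheme, rng))
            assert call.donor_bleach_frame is None
            assert call.acceptor_bleach_frame is None

    def test_acceptor_bleach_detected_with_donor_rise(self, scheme, rng):
        for _ in range(10):
            t = self.render(scheme, rng, acceptor_bleach_frame=150)
            call = detect_bleach(t)
            assert call.donor_bleach_frame is None
            assert call.acceptor_bleach_frame is not None
            assert abs(call.acceptor_bleach_frame - 150) <= 2

    def test_short_trace_gives_no_call(self):
        t = flat_trace(n=5)
        call = detect_bleach(t, persistence=10)
        assert call == BleachCall()


class TestClassifyResponse:
    @pytest.fixture(scope="class")
    @staticmethod
    def folding_population():
        pre = default_scheme("Native")
        post = KineticScheme(states=[StateSpec("F", 0.47)],
                             initial_distribution=np.array([1.0]))
        cfg = SimConfig(pre_scheme=pre, post_scheme=post, injection_frame=120,
                        n_traces=150, n_frames=500, responder_fraction=0.62, seed=5)
        return simulate_experiment(cfg)

    def test_fold_calls_track_ground_truth(self, folding_population):
        ts, truths = folding_population
        calls = [classify_response(compute_efret(t)) for t in ts]
        agree = sum(
            (c.call == "fold") == bool(t.responder) for c, t in zip(calls, truths)
        )
        assert agree / len(ts) > 0.95

    def test_fold_fraction_recovers_responder_fraction_within_ci(self, folding_population):
        ts, _ = folding_population
        calls = [classify_response(compute_efret(t)) for t in ts]
        frac = sum(c.call == "fold" for c in calls) / len(calls)
        half = 1.96 * np.sqrt(0.62 * 0.38 / len(calls))
        assert abs(frac - 0.62) < half + 0.02

    def test_extension_with_delay_called_extend(self):
        pre = KineticScheme(states=[StateSpec("N", 0.24)],
                            initial_distribution=np.array([1.0]))
        post = KineticScheme(states=[StateSpec("E", 0.11)],
                             initial_distribution=np.array([1.0]))
        cfg = SimConfig(pre_scheme=pre, post_scheme=post, injection_frame=100,
                        n_traces=40, n_frames=900, responder_fraction=1.0,
                        delay_rate=0.2, seed=6)
        ts, truths = simulate_experiment(cfg)
        calls = [classify_response(compute_efret(t)) for t in ts]
        n_ext = sum(c.call == "extend" for c in calls)
        assert n_ext >= 0.9 * sum(bool(t.responder) for t in truths)
        with_delay = [c for c, t in zip(calls, truths)
                      if c.call == "extend" and t.delay_s and t.delay_s > 1.0]
        assert all(c.delay_s > 0 for c in with_delay)

    def test_static_population_mostly_static_calls(self):
        pre = default_scheme("Native")
        post = KineticScheme(states=[StateSpec("F", 0.47)],
                             initial_distribution=np.array([1.0]))
        cfg = SimConfig(pre_scheme=pre, post_scheme=post, injection_frame=80,
                        n_traces=100, n_frames=300, responder_fraction=0.0, seed=7)
        ts, _ = simulate_experiment(cfg)
        calls = [classify_response(compute_efret(t)) for t in ts]
        assert sum(c.call == "static" for c in calls) >= 95

    def test_dynamic_flag_from_switch_count(self):
        t = flat_trace(n=200, injection_frame=100)
        e = compute_efret(t)
        assert classify_response(e, n_post_switches=5).call == "dynamic"
        assert classify_response(e, n_post_switches=0).call == "static"

    def test_missing_injection_raises_informative_error(self):
        e = compute_efret(flat_trace(n=100))
        with pytest.raises(MissingInjectionError):
            classify_response(e)

    def test_masked_out_trace_rejected(self):
        t = flat_trace(n=100, injection_frame=50)
        e = compute_efret(t, bleach=BleachCall(donor_bleach_frame=55))
        assert classify_response(e).call == "rejected"


class TestMeasureDelay:
    def test_switch_at_injection_gives_zero_delay(self):
        n = 300
        e_vals = np.concatenate([np.full(100, 0.25), np.full(200, 0.47)])
        t = Trace("t", donor=(1 - e_vals) * 100, acceptor=e_vals * 100,
                  injection_frame=100)
        call = classify_response(compute_efret(t))
        assert call.call == "fold" and call.delay_s == 0.0

    def test_mean_measured_delay_matches_exponential_truth(self):
        pre = default_scheme("Native")
        post = KineticScheme(states=[StateSpec("E", 0.11)],
                             initial_distribution=np.array([1.0]))
        cfg = SimConfig(pre_scheme=pre, post_scheme=post, injection_frame=200,
                        n_traces=300, n_frames=1200, responder_fraction=1.0,
                        delay_rate=0.2, seed=6)
        ts, truths = simulate_experiment(cfg)
        meas, true = [], []
        for t, tr in zip(ts, truths):
            c = classify_response(compute_efret(t))
            if c.call == "extend" and c.delay_s is not None and np.isfinite(c.delay_s):
                meas.append(c.delay_s)
                true.append(tr.delay_s)
        assert len(meas) > 250
        assert abs(np.mean(meas) - 5.0) < 0.6
        assert abs(np.mean(meas) - np.mean(true)) < 0.3

    def test_delay_requires_fold_or_extend_call(self):
        e = compute_efret(flat_trace(n=100, injection_frame=50))
        with pytest.raises(ValueError, match="fold/extend"):
            measure_delay(e, "static")


class TestFractionPercent:
    @pytest.mark.parametrize(
        "n,total,expected",
        [(752, 1213, 62.0), (286, 609, 47.0), (549, 632, 87.0), (632, 1875, 34.0)],
    )
    def test_reported_population_percentages(self, n, total, expected):
        assert round(fraction_percent(n, total)) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fraction_percent(5, 0)
        with pytest.raises(ValueError):
            fraction_percent(-1, 10)
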