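"""Classifier tests against closed-form traces with analytically known labels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smadscreen as ss
from smadscreen.classify import Label
from smadscreen.synthetic import FixtureSpec, default_fixture_specs, make_trace


def trace_from(f, duration=36000.0, grid=60.0):
    t = np.arange(0.0, duration + 0.5 * grid, grid)
    return ss.ResponseTrace(t, f(t))


class TestFindExtrema:
    def test_monotone_trace_has_no_extrema(self):
        tr = trace_from(lambda t: t / 1000.0)
        assert ss.find_extrema(tr) == []

    def test_raised_cosine_maxima_positions_and_values(self):
        # y = 10*(1 - cos(2*pi*t/3600)): maxima of 20 at odd multiples of 1800 s
        tr = trace_from(lambda t: 10.0 * (1.0 - np.cos(2 * np.pi * t / 3600.0)))
        maxima = [e for e in ss.find_extrema(tr) if e.kind == "max"]
        assert len(maxima) == 10
        for i, e in enumerate(maxima):
            assert e.value == pytest.approx(20.0, abs=1e-9)
            assert e.time == pytest.approx((2 * i + 1) * 1800.0, abs=60.0)

    def test_damped_sinusoid_extrema_match_closed_form(self):
        spec = default_fixture_specs()["damped_sinusoid"]
        tr = make_trace(spec)
        for e in ss.find_extrema(tr):
            analytic = (spec.amplitude_pM * math.exp(-e.time / spec.tau_damp_s)
                        * (1.0 - math.cos(2 * math.pi * e.time / spec.period_s)))
            assert e.value == pytest.approx(analytic, rel=0.01, abs=1e-6)

    def test_plateau_merged_to_midpoint(self):
        t = np.arange(0, 601.0, 60.0)
        y = np.array([0, 1, 2, 2, 2, 1, 0, 1, 2, 3, 4.0])
        ext = ss.find_extrema(ss.ResponseTrace(t, y))
        kinds = [e.kind for e in ext]
        assert kinds == ["max", "min"]
        assert ext[0].time == pytest.approx(180.0)  # midpoint of the 2-plateau
        assert ext[0].value == 2.0

    def test_failed_trace_rejected(self):
        tr = ss.ResponseTrace(np.empty(0), np.empty(0), success=False)
        with pytest.raises(ValueError):
            ss.find_extrema(tr)


class TestClassify:
    def test_flat_zero_is_unresponsive(self, default_cfg):
        res = ss.classify(trace_from(lambda t: np.zeros_like(t)), default_cfg)
        assert res.label == Label.UNRESPONSIVE

    def test_saturating_exponential_is_sustained(self, default_cfg):
        # 20*(1-exp(-t/600)): 90% of peak at ~600*ln(10) = 1382 s, never decays
        res = ss.classify(trace_from(lambda t: 20.0 * (1 - np.exp(-t / 600.0))), default_cfg)
        assert res.label == Label.SUSTAINED
        assert res.Opeak == pytest.approx(20.0, rel=1e-6)
        assert res.t_peak90 == pytest.approx(600 * math.log(10), abs=60.0)

    def test_biexponential_pulse_is_transient(self, default_cfg):
        spec = default_fixture_specs()["transient_biexponential"]
        res = ss.classify(make_trace(spec), default_cfg)
        assert res.label == Label.TRANSIENT
        assert res.Opeak == pytest.approx(30.0, rel=0.01)
        assert res.Oend < 1.0

    def test_damped_sinusoid_is_sustained_oscillatory(self, default_cfg):
        # amplitude ratio of peaks 5 and 2 is exp(-3*5400/40000) = 0.67 >= 0.5
        res = ss.classify(make_trace(default_fixture_specs()["damped_sinusoid"]), default_cfg)
        assert res.label == Label.SUSTAINED_OSC
        ratio = res.amplitudes[3] / res.amplitudes[0]
        assert ratio == pytest.approx(math.exp(-3 * 5400 / 40000), rel=0.02)

    def test_fast_damping_flips_sublabel_to_dampened(self, default_cfg):
        spec = FixtureSpec("damped_sinusoid", amplitude_pM=40.0, period_s=5400.0,
                           tau_damp_s=8000.0)
        res = ss.classify(make_trace(spec), default_cfg)
        assert res.label == Label.DAMPENED_OSC

    def test_failed_trace_gets_failed_label(self, default_cfg):
        tr = ss.ResponseTrace(np.empty(0), np.empty(0), success=False)
        assert ss.classify(tr, default_cfg).label == Label.FAILED

    def test_short_trace_is_an_error(self, default_cfg):
        with pytest.raises(ValueError):
            ss.classify(trace_from(lambda t: t, duration=7200.0), default_cfg)

    def test_series_mode_uses_relative_threshold(self):
        # a 0.5 pM sustained shape: unresponsive at theta=10 pM, sustained in series mode
        tr = trace_from(lambda t: 0.5 * (1 - np.exp(-t / 600.0)))
        assert ss.classify(tr, ss.ClassifierConfig()).label == Label.UNRESPONSIVE
        assert ss.classify(tr, ss.ClassifierConfig().as_series()).label == Label.SUSTAINED

    def test_series_mode_floor_rejects_numerically_zero_traces(self):
        tr = trace_from(lambda t: 1e-4 * (1 - np.exp(-t / 600.0)))
        assert ss.classify(tr, ss.ClassifierConfig().as_series()).label == Label.UNRESPONSIVE


FAMILY_SHAPES = {
    "sustained_exponential": lambda t: 20.0 * (1 - np.exp(-t / 600.0)),
    "transient_biexponential": lambda t: 33.1 * (np.exp(-t / 900.0) - np.exp(-t / 150.0)),
    "damped_sinusoid": lambda t: 15.0 * np.exp(-t / 40000.0) * (1 - np.cos(2 * np.pi * t / 5400.0)),
    "flat": lambda t: np.full_like(t, 5.0),
}


class TestClassifierProperties:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           family=st.sampled_from(sorted(FAMILY_SHAPES)))
    def test_scale_equivariance(self, c, family):
        """Multiplying trace and theta by the same factor preserves the label."""
        tr = trace_from(FAMILY_SHAPES[family])
        base = ss.classify(tr, ss.ClassifierConfig(theta_pM=10.0)).label
        scaled = ss.classify(tr.scaled(c), ss.ClassifierConfig(theta_pM=10.0 * c)).label
        assert scaled == base

    @pytest.mark.parametrize("family", sorted(FAMILY_SHAPES))
    def test_raising_theta_never_creates_responsiveness(self, family):
        tr = trace_from(FAMILY_SHAPES[family])
        was_unresponsive = False
        for theta in (0.1, 1.0, 5.0, 10.0, 25.0, 100.0, 1000.0):
            label = ss.classify(tr, ss.ClassifierConfig(theta_pM=theta)).label
            if was_unresponsive:
                assert label == Label.UNRESPONSIVE
            was_unresponsive = label == Label.UNRESPONSIVE

    @pytest.mark.parametrize("stretch", [1.0, 2.0, 4.0])
    def test_time_stretch_preserves_sublabel_and_scales_period(self, stretch):
        period = 5400.0 * stretch
        tau = 40000.0 * stretch
        duration = max(36000.0, 8 * period)
        tr = trace_from(lambda t: 15.0 * np.exp(-t / tau)
                        * (1 - np.cos(2 * np.pi * t / period)), duration=duration)
        res = ss.classify(tr, ss.ClassifierConfig())
        assert res.label == Label.SUSTAINED_OSC
        assert res.period_s == pytest.approx(period, abs=120.0)

    def test_every_trace_gets_exactly_one_known_label(self):
        from smadscreen.classify import LABELS

        for family, f in FAMILY_SHAPES.items():
            res = ss.classify(trace_from(f), ss.ClassifierConfig())
            assert res.label in LABELS


class TestClassifyWithExtension:
    def test_non_oscillatory_identical_to_plain_classify(self, sustained_ps, default_cfg):
        plain = ss.classify(ss.simulate(sustained_ps), default_cfg)
        ext = ss.classify_with_extension(sustained_ps, cfg=default_cfg)
        assert ext.label == plain.label == Label.SUSTAINED
        assert ext.Opeak == pytest.approx(plain.Opeak, rel=1e-6)

    def test_slow_oscillation_extends_and_records_duration(self, default_cfg):
        # injectable simulator: a slowly damped 2 h-period oscillation whose
        # amplitudes stay above the floor well past the 10 h horizon
        def fake_simulate(params, totals, protocol, opts):
            t = np.arange(0.0, protocol.duration_s + 30.0, 60.0)
            y = 15.0 * np.exp(-t / 40000.0) * (1 - np.cos(2 * np.pi * t / 7200.0))
            return ss.ResponseTrace(t, y)

        res = ss.classify_with_extension(
            ss.make_parameter_fixtures()["sustained"], cfg=default_cfg,
            simulate_fn=fake_simulate)
        assert res.is_oscillatory
        assert res.duration_s > default_cfg.t_end_s      # extension happened
        assert res.period_s == pytest.approx(7200.0, abs=120.0)
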