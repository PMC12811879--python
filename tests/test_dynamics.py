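"""Winner-take-all competition dynamics: steps, clocks, and trial traces."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from rivalnorm.dynamics import (
    ChannelState,
    DynamicsParams,
    IntegrationError,
    ModelParams,
    adapt_step,
    apply_gain,
    recover_step,
    run_trial,
    wta_compare,
)
from rivalnorm.experiments import exp1_condition
from rivalnorm.stimulus import relabel_channels


def make_states():
    return (
        ChannelState("red", 1.0, 1.0, "dominant"),
        ChannelState("green", 0.5, 1.0, "suppressed"),
    )


class TestEulerSteps:
    def test_adapt_step_matches_exponential(self):
        out = adapt_step(1.0, 0.01, 2.5)
        assert out == pytest.approx(0.9960, abs=1e-4)
        assert out == pytest.approx(math.exp(-0.01 / 2.5), rel=1e-3)

    def test_adapt_step_infinite_tau_is_identity(self):
        assert adapt_step(0.7, 0.01, math.inf) == 0.7

    def test_repeated_adaptation_decreases_toward_zero(self):
        p = 1.0
        history = []
        for _ in range(100):
            p = adapt_step(p, 0.01, 2.5)
            history.append(p)
        assert all(b < a for a, b in zip(history, history[1:])) and history[-1] > 0

    def test_recover_step_matches_exponential(self):
        """The Euler increment dt/tau is first-order exact; the deviation
        from 1 - exp(-dt/tau) is far below 0.1% of the ceiling."""
        out = recover_step(0.0, 1.0, 0.01, 1.5)
        assert out == pytest.approx(0.006667, abs=1e-6)
        assert out == pytest.approx(1 - math.exp(-0.01 / 1.5), abs=1e-4)

    def test_recovery_fixed_point(self):
        assert recover_step(1.0, 1.0, 0.01, 1.5) == 1.0

    def test_recovery_reaches_ceiling_after_three_tau(self):
        p, tau, dt = 0.0, 1.5, 0.01
        for _ in range(int(3 * tau / dt)):
            p = recover_step(p, 1.0, dt, tau)
        assert p == pytest.approx(1 - math.exp(-3), rel=1e-3)
        assert abs(p - 1.0) < 0.051


class TestGainAssignment:
    def test_degenerate_bias_always_dominant(self):
        rng = np.random.default_rng(0)
        params = DynamicsParams(gain_bias=1.0)
        assert all(
            apply_gain(make_states(), params, rng) == "red" for _ in range(10_000)
        )

    def test_default_bias_frequency(self):
        rng = np.random.default_rng(1)
        params = DynamicsParams()
        n = 100_000
        hits = sum(apply_gain(make_states(), params, rng) == "red" for _ in range(n))
        se = math.sqrt(0.55 * 0.45 / n)
        assert abs(hits / n - 0.55) < 3 * se

    def test_unit_gain_changes_nothing(self):
        """g = 1 makes the assignment irrelevant to the comparison."""
        trace = run_trial(
            exp1_condition("gray"),
            ModelParams(dynamics=DynamicsParams(gain=1.0)),
            seed=3,
        )
        props = trace.dominance_proportions()
        assert props["red"] + props["green"] == pytest.approx(1.0)


class TestWtaCompare:
    def test_larger_value_wins(self):
        winner, value = wta_compare(0.80, 0.85, "red", ("red", "green"))
        assert winner == "green" and value == 0.85

    def test_exact_tie_retains_incumbent(self):
        winner, _ = wta_compare(0.5, 0.5, "red", ("red", "green"))
        assert winner == "red"

    def test_non_finite_raises(self):
        with pytest.raises(IntegrationError):
            wta_compare(float("nan"), 0.5, "red", ("red", "green"))


class TestRunTrial:
    def test_zero_noise_alternation_period_matches_root_finder(
        self, gray_bg, zero_noise_model
    ):
        """With noise off and the gain locked to the dominant percept, the
        alternation period is the crossing time of g*exp(-t/tau_D) with
        1 - exp(-t/tau_R), quantized to the sampling grid."""
        dyn = zero_noise_model.dynamics
        root = brentq(
            lambda t: dyn.gain * math.exp(-t / dyn.tau_d)
            - (1 - math.exp(-t / dyn.tau_r)),
            0.01,
            20.0,
        )
        trace = run_trial(gray_bg, zero_noise_model, seed=0)
        durations = [
            d
            for durs in trace.dominance_durations().values()
            for d in durs
        ]
        # interior episodes only (window edges truncate the first/last)
        interior = durations[1:-1]
        assert len(set(interior)) == 1
        period = interior[0]
        assert 0 <= period - root <= dyn.dt

    def test_label_symmetry_is_exact(self, green_bg, default_model):
        a = run_trial(green_bg, default_model, seed=11).dominance_proportions()
        b = run_trial(
            relabel_channels(green_bg), default_model, seed=11
        ).dominance_proportions()
        assert a["red"] == b["green"] and a["green"] == b["red"]

    def test_strengths_stay_nonnegative(self, green_bg, default_model):
        trace = run_trial(green_bg, default_model, seed=5)
        for arr in trace.strengths.values():
            assert np.min(arr) >= 0.0

    def test_proportions_partition_measured_time(self, gray_bg, default_model):
        props = run_trial(gray_bg, default_model, seed=7).dominance_proportions()
        assert props["red"] + props["green"] == pytest.approx(1.0)

    def test_same_seed_reproduces_trace(self, green_bg, default_model):
        a = run_trial(green_bg, default_model, seed=9, audit=True)
        b = run_trial(green_bg, default_model, seed=9, audit=True)
        assert np.array_equal(a.dominant, b.dominant)
        for lab in a.strengths:
            assert np.array_equal(a.strengths[lab], b.strengths[lab])
            assert np.array_equal(a.xi[lab], b.xi[lab])

    def test_no_switching_without_noise_gain_or_adaptation(self, gray_bg):
        """Equal drives, noise off, g = 1, adaptation off: the incumbent
        never loses."""
        from rivalnorm.normalization import NoiseParams

        model = ModelParams(
            noise=NoiseParams(lower=-1e-12, upper=1e-12),
            dynamics=DynamicsParams(gain=1.0, tau_d=1e9, tau_r=1e9),
        )
        trace = run_trial(gray_bg, model, seed=13)
        assert trace.switch_count() == 0

    def test_audit_records_bounded_noise(self, green_bg, default_model):
        trace = run_trial(green_bg, default_model, seed=15, audit=True)
        for lab, xs in trace.xi.items():
            assert np.all(np.abs(xs) <= default_model.noise.upper)

    def test_trace_frame_schema(self, green_bg, default_model):
        base = run_trial(green_bg, default_model, seed=17).to_frame()
        audit = run_trial(green_bg, default_model, seed=17, audit=True).to_frame(
            audit=True
        )
        assert list(base.columns) == ["time_s", "dominant_channel", "P_green", "P_red"]
        assert list(base.columns) == list(audit.columns[: len(base.columns)])
        assert {"xi_green", "xi_red", "gain_target"} <= set(audit.columns)
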