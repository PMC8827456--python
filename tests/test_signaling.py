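"""Calcium surrogate, activation integrals, Hill normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thrombosim import signaling as sig

AP = sig.ActivationParams()


class TestHillF:
    def test_zero_midpoint_saturation(self):
        assert sig.hill_F(0.0, AP) == pytest.approx(AP.alpha_min)
        assert sig.hill_F(AP.theta_50, AP) == pytest.approx(
            (AP.alpha_min + AP.alpha_max) / 2.0
        )
        assert sig.hill_F(1e6 * AP.theta_50, AP) == pytest.approx(
            AP.alpha_max, abs=1e-9
        )

    @given(st.floats(0, 1e9), st.floats(0, 1e9))
    def test_monotone_bounded(self, a, b):
        fa, fb = sig.hill_F(a, AP), sig.hill_F(b, AP)
        assert AP.alpha_min <= fa <= AP.alpha_max
        if a <= b:
            assert fa <= fb


class TestActivationIntegrals:
    def test_basal_trace_accumulates_nothing(self):
        st_ = sig.PlateletSignalState()
        for _ in range(100):
            sig.update_activation(st_, 100.0, 0.5, AP)
        assert st_.xi == 0.0
        assert not st_.release_triggered

    def test_constant_elevated_trace(self):
        # constant 200 nM for 10 s -> xi = (200 - 100) * 10 = 1000 nM s
        st_ = sig.PlateletSignalState(ca=200.0)
        for _ in range(20):
            sig.update_activation(st_, 200.0, 0.5, AP)
        assert st_.xi == pytest.approx(1000.0)

    def test_recent_window_fraction_of_total(self):
        # constant integrand: xi_dt / xi = window / t
        p = sig.ActivationParams(dt_window=30.0)
        st_ = sig.PlateletSignalState(ca=300.0)
        for _ in range(200):  # t = 100 s
            sig.update_activation(st_, 300.0, 0.5, p)
        assert st_.xi_dt / st_.xi == pytest.approx(30.0 / 100.0, rel=0.02)

    def test_release_latches_at_threshold(self):
        p = sig.ActivationParams(xi_crit=100.0)
        st_ = sig.PlateletSignalState(ca=300.0)
        while not st_.release_triggered:
            sig.update_activation(st_, 300.0, 0.5, p)
        t_rel = st_.t_release
        sig.update_activation(st_, 100.0, 0.5, p)
        assert st_.t_release == t_rel  # latched

    def test_subbasal_calcium_clipped(self):
        st_ = sig.PlateletSignalState(ca=50.0)
        sig.update_activation(st_, 40.0, 0.5, AP)
        assert st_.xi == 0.0

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            sig.update_activation(sig.PlateletSignalState(), -1.0, 0.5, AP)

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(3)
        trace = 100.0 + 200.0 * rng.random(40)
        st_ = sig.PlateletSignalState(ca=float(trace[0]))
        n_window = int(AP.dt_window / 0.5)
        xi = np.zeros(1)
        ring = np.zeros((1, n_window))
        prev = np.array([trace[0]])
        for step, ca in enumerate(trace[1:]):
            sig.update_activation(st_, float(ca), 0.5, AP)
            new = np.array([ca])
            xi, xi_dt = sig.accumulate_xi(xi, ring, step % n_window, prev, new, 0.5)
            prev = new
        assert xi[0] == pytest.approx(st_.xi)
        assert xi_dt[0] == pytest.approx(st_.xi_dt)


class TestDefaultCalciumModel:
    def test_basal_fixed_point(self):
        m = sig.default_calcium_model()
        trace = m.simulate([{} for _ in range(200)], 0.5)
        assert np.allclose(trace, 100.0)

    def test_saturating_iloprost_blocks_activation(self):
        m = sig.default_calcium_model()
        st_ = sig.PlateletSignalState()
        ca, aux = np.array([100.0]), m.initial_aux(1)
        exposure = {"collagen": 1.0, "ADP": 5000.0, "TXA2": 500.0,
                    "thrombin": 50.0, "iloprost": np.inf}
        for _ in range(600):  # 300 s of maximal agonist stimulation
            ca, aux = m.step(ca, aux, exposure, 0.5)
            sig.update_activation(st_, float(ca[0]), 0.5, AP)
        assert st_.xi == 0.0
        assert not st_.release_triggered

    def test_thrombin_slow_off_vs_adp(self):
        m = sig.default_calcium_model()

        def decay_time(exposure):
            ca, aux = np.array([100.0]), m.initial_aux(1)
            for _ in range(20):  # 10 s pulse
                ca, aux = m.step(ca, aux, exposure, 0.5)
            peak = float(ca[0]) - 100.0
            t = 0.0
            while float(ca[0]) - 100.0 > peak / np.e and t < 1000:
                ca, aux = m.step(ca, aux, {}, 0.5)
                t += 0.5
            return t

        assert decay_time({"thrombin": 100.0}) >= 5.0 * decay_time({"ADP": 10000.0})

    def test_collagen_thrombin_sustain_higher_xi_than_soluble(self):
        m = sig.default_calcium_model()
        ap = AP

        def total_xi(exposure, n=400):
            st_ = sig.PlateletSignalState()
            ca, aux = np.array([100.0]), m.initial_aux(1)
            for _ in range(n):
                ca, aux = m.step(ca, aux, exposure, 0.5)
                sig.update_activation(st_, float(ca[0]), 0.5, ap)
            return st_.xi

        core = total_xi({"collagen": 1.0, "thrombin": 10.0})
        shell = total_xi({"ADP": 2000.0, "TXA2": 100.0})
        assert core > shell

    def test_nonnegative_output(self):
        m = sig.default_calcium_model()
        ca, aux = np.array([0.0]), m.initial_aux(1)
        for _ in range(50):
            ca, aux = m.step(ca, aux, {"GSNO": 100.0}, 0.5)
            assert np.all(ca >= 0)
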