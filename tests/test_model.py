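"""Unit tests for the population equations: sigmoid, derivatives, LFP output."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nmprobe as nm
from nmprobe.model import N_STATE


class TestSigmoid:
    def test_half_activation_point(self, default_config):
        pp = default_config.params_1
        assert nm.sigmoid(pp.v0, pp) == pytest.approx(pp.e0, abs=1e-12)

    def test_saturation_limits(self, default_config):
        pp = default_config.params_1
        assert nm.sigmoid(1e3, pp) == pytest.approx(2 * pp.e0, abs=1e-9)
        assert nm.sigmoid(-1e3, pp) == pytest.approx(0.0, abs=1e-9)

    def test_value_at_zero_potential(self, default_config):
        # 5 / (1 + exp(0.56 * 6)) evaluated independently
        assert nm.sigmoid(0.0, default_config.params_1) == pytest.approx(0.167847, abs=1e-5)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, v1, v2):
        pp = nm.PopulationParams()
        s1, s2 = nm.sigmoid(v1, pp), nm.sigmoid(v2, pp)
        assert 0.0 < s1 < 2 * pp.e0
        if v2 - v1 > 1e-9:  # strict growth needs a representable gap
            assert s1 < s2

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            nm.sigmoid(np.nan)
        with pytest.raises(ValueError):
            nm.sigmoid(np.inf)


class TestDerivatives:
    def test_zero_state_values(self, default_config):
        """Hand-evaluated right-hand side at the origin with p = s = 0."""
        pp = default_config.params_1
        s0 = 2 * pp.e0 / (1 + np.exp(pp.r * pp.v0))  # S(0)
        dy = nm.derivatives(np.zeros(N_STATE), (0, 0), (0, 0), (0, 0), default_config)
        for off in (0, 10):
            # position derivatives are the (zero) velocities
            assert np.all(dy[[off, off + 1, off + 2, off + 3, off + 4]] == 0)
            assert dy[off + 5] == pytest.approx(pp.A * pp.a * s0)
            assert dy[off + 6] == pytest.approx(pp.A * pp.a * pp.C2 * s0)
            assert dy[off + 7] == pytest.approx(pp.B * pp.b * pp.C4 * s0)
            assert dy[off + 8] == pytest.approx(pp.G * pp.g * pp.C7 * s0)
            assert dy[off + 9] == pytest.approx(pp.B * pp.b * s0)

    def test_decoupled_populations_independent(self, rng):
        cfg = nm.CoupledModelConfig(K=0.0)
        y = rng.normal(0, 2, N_STATE)
        y2 = y.copy()
        y2[10:] = rng.normal(0, 2, 10)  # perturb only population 2
        d1 = nm.derivatives(y, (90, 90), (0, 0), (0, 0), cfg)
        d2 = nm.derivatives(y2, (90, 90), (0, 0), (0, 0), cfg)
        np.testing.assert_allclose(d1[:10], d2[:10], rtol=0, atol=0)

    def test_rejects_non_finite_state(self, default_config):
        y = np.zeros(N_STATE)
        y[3] = np.nan
        with pytest.raises(ValueError):
            nm.derivatives(y, (0, 0), (0, 0), (0, 0), default_config)

    def test_matches_independent_hand_coded_system(self, default_config, rng):
        """Each printed equation re-evaluated from scratch at random states."""
        cfg = default_config
        for _ in range(10):
            y = rng.normal(0, 5, N_STATE)
            p = rng.normal(90, 5, 2)
            s = rng.uniform(0, 200, 2)
            d = rng.normal(0, 5, 2)
            got = nm.derivatives(y, p, s, d, cfg)
            exp = np.empty(N_STATE)
            for i, pp in ((0, cfg.params_1), (1, cfg.params_2)):
                o = 10 * i
                S = lambda v: 2 * pp.e0 / (1 + np.exp(pp.r * (pp.v0 - v)))
                exp[o + 0] = y[o + 5]
                exp[o + 5] = (pp.A * pp.a * S(cfg.K * d[i] + y[o + 1] - y[o + 2] - y[o + 3])
                              - 2 * pp.a * y[o + 5] - pp.a ** 2 * y[o + 0])
                exp[o + 1] = y[o + 6]
                exp[o + 6] = (pp.A * pp.a * (s[i] + p[i] + pp.C2 * S(pp.C1 * y[o + 0]))
                              - 2 * pp.a * y[o + 6] - pp.a ** 2 * y[o + 1])
                exp[o + 2] = y[o + 7]
                exp[o + 7] = (pp.B * pp.b * pp.C4 * S(pp.C3 * y[o + 0])
                              - 2 * pp.b * y[o + 7] - pp.b ** 2 * y[o + 2])
                exp[o + 3] = y[o + 8]
                exp[o + 8] = (pp.G * pp.g * pp.C7 * S(pp.C5 * y[o + 0] - pp.C6 * y[o + 4])
                              - 2 * pp.g * y[o + 8] - pp.g ** 2 * y[o + 3])
                exp[o + 4] = y[o + 9]
                exp[o + 9] = (pp.B * pp.b * S(pp.C3 * y[o + 0])
                              - 2 * pp.b * y[o + 9] - pp.b ** 2 * y[o + 4])
            np.testing.assert_allclose(got, exp, rtol=1e-13)


class TestPspBlock:
    def test_impulse_response_closed_form(self):
        """Accurately integrating the block reproduces gain*rate*t*exp(-rate*t)."""
        from scipy.integrate import solve_ivp

        for gain, rate in ((4.0, 100.0), (40.0, 50.0), (20.0, 350.0)):
            t_eval = 0.00195 * np.arange(int(10 / rate / 0.00195))
            sol = solve_ivp(
                lambda t, y: nm.psp_block_rhs(y[0], y[1], 0.0, gain, rate),
                (0, t_eval[-1]), [0.0, gain * rate],  # impulse => velocity jumps to gain*rate
                t_eval=t_eval, rtol=1e-10, atol=1e-12)
            h = nm.psp_impulse_response(t_eval, gain, rate)
            rms = np.sqrt(np.mean((sol.y[0] - h) ** 2)) / h.max()
            assert rms < 1e-4

    def test_peak_location_and_height(self):
        t = np.linspace(0, 0.1, 100001)
        h = nm.psp_impulse_response(t, 4.0, 100.0)
        assert t[h.argmax()] == pytest.approx(0.01, abs=1e-4)   # 1/rate
        assert h.max() == pytest.approx(4.0 / np.e, rel=1e-6)


class TestLfpOutput:
    def test_zero_state(self, default_config):
        np.testing.assert_array_equal(
            nm.lfp_output(np.zeros(N_STATE), (0.0, 0.0), default_config), [0.0, 0.0])

    def test_psp_balance(self):
        cfg = nm.CoupledModelConfig(K=0.0)
        y = np.zeros(N_STATE)
        y[1], y[2], y[3] = 10.0, 3.0, 2.0
        assert nm.lfp_output(y, (0.0, 0.0), cfg)[0] == pytest.approx(5.0)

    def test_coupling_term_included_and_removable(self):
        y = np.zeros(N_STATE)
        cfg = nm.CoupledModelConfig(K=0.3)
        assert nm.lfp_output(y, (10.0, 0.0), cfg)[0] == pytest.approx(3.0)
        cfg_local = nm.CoupledModelConfig(K=0.3, lfp_includes_coupling=False)
        assert nm.lfp_output(y, (10.0, 0.0), cfg_local)[0] == 0.0


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [{"a": 0}, {"b": -1}, {"e0": 0}, {"r": -0.5}, {"C1": 0}])
    def test_population_params_rejects_nonpositive(self, kwargs):
        with pytest.raises(ValueError):
            nm.PopulationParams(**kwargs)

    def test_noise_and_coupling_invariants(self):
        with pytest.raises(ValueError):
            nm.NoiseSpec(sigma=-1.0)
        with pytest.raises(ValueError):
            nm.CoupledModelConfig(K=-0.1)
        with pytest.raises(ValueError):
            nm.CoupledModelConfig(tau_d=-0.01)
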