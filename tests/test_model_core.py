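"""Model core: sigmoid, synaptic kinetics, ODE system, RK4 integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

import gripalpha as ga
from gripalpha.model_core import _integrate


class TestModelParameters:
    def test_typical_alpha_values(self, typical):
        assert typical.Ge == 3.25
        assert typical.Gi == 22.0
        assert typical.omega_e == pytest.approx(1 / 0.0108)
        assert typical.omega_i == pytest.approx(50.0)
        assert typical.J == 135.0
        assert (typical.e0, typical.v0, typical.r) == (2.5, 6.0, 0.56)

    @pytest.mark.parametrize("J", [1.0, 135.0, 17.3])
    def test_connectivities_derive_from_J(self, J, typical):
        p = typical.replace(J=J)
        assert p.C1 == J
        assert p.C2 == 0.8 * J
        assert p.C3 == p.C4 == 0.25 * J

    @pytest.mark.parametrize("bad", [{"Ge": -1.0}, {"J": 0.0}, {"r": float("nan")}])
    def test_rejects_nonpositive_fields(self, bad):
        with pytest.raises(ValueError):
            ga.ModelParameters(**bad)


class TestSigmoid:
    def test_midpoint_gives_half_maximum(self, typical):
        # at v = v0 the logistic is exactly e0
        assert ga.sigmoid(6.0, typical) == 2.5

    def test_saturation_limits(self, typical):
        assert ga.sigmoid(-1e6, typical) == pytest.approx(0.0, abs=1e-12)
        assert ga.sigmoid(1e6, typical) == pytest.approx(5.0, abs=1e-12)

    def test_closed_form_value(self, typical):
        # frozen from arbitrary-precision evaluation of 5/(1+e^(0.56*(6-10)))
        assert ga.sigmoid(10.0, typical) == pytest.approx(
            4.5189222914465358, rel=1e-12
        )

    def test_rejects_nonfinite_potential(self, typical):
        with pytest.raises(ValueError):
            ga.sigmoid(float("nan"), typical)

    @settings(derandomize=True, max_examples=50)
    @given(
        v1=st.floats(-60, 60, allow_nan=False),
        v2=st.floats(-60, 60, allow_nan=False),
    )
    def test_monotone_and_bounded(self, v1, v2):
        p = ga.ModelParameters.typical_alpha()
        s1, s2 = ga.sigmoid(v1, p), ga.sigmoid(v2, p)
        assert 0.0 < s1 < 2 * p.e0
        if v2 - v1 > 1e-9:  # strictly increasing beyond float resolution
            assert s1 < s2
        elif v1 <= v2:
            assert s1 <= s2


class TestPspImpulse:
    def test_zero_at_origin_and_causal(self):
        assert ga.psp_impulse(0.0, 3.25, 100.0) == 0.0
        assert ga.psp_impulse(-0.5, 3.25, 100.0) == 0.0

    @pytest.mark.parametrize(
        "G,omega,expected_peak_t",
        [(3.25, 1 / 0.0108, 0.0108), (22.0, 50.0, 0.02)],
    )
    def test_peak_location_matches_time_constant(self, G, omega, expected_peak_t):
        # oracle: dense numeric grid maximization
        t = np.linspace(0, 0.2, 400_001)
        h = ga.psp_impulse(t, G, omega)
        t_num = t[np.argmax(h)]
        assert t_num == pytest.approx(expected_peak_t, abs=t[1] - t[0])
        assert 1 / omega == pytest.approx(expected_peak_t, abs=1e-6)

    def test_peak_value_is_gain_over_e(self):
        t = np.linspace(0, 0.2, 400_001)
        for omega in (50.0, 1 / 0.0108):
            peak = np.max(ga.psp_impulse(t, 3.25, omega))
            assert peak == pytest.approx(3.25 / np.e, rel=1e-6)

    @pytest.mark.parametrize("G,omega", [(3.25, 1 / 0.0108), (22.0, 50.0)])
    def test_integrates_to_gain_over_rate(self, G, omega):
        # total charge identity: integral of G*w*t*exp(-w t) over [0, inf) = G/w
        val, _ = integrate.quad(lambda t: ga.psp_impulse(t, G, omega), 0, np.inf)
        assert val == pytest.approx(G / omega, rel=1e-6)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            ga.psp_impulse(0.1, 3.25, 0.0)


class TestDerivatives:
    def test_origin_with_zero_drive(self, typical):
        d = ga.derivatives(np.zeros(6), 0.0, typical)
        s0 = 5.0 / (1.0 + np.exp(0.56 * 6.0))  # S(0), written out
        we, wi = 1 / 0.0108, 50.0
        assert np.allclose(d[:3], 0.0)
        assert d[3] == pytest.approx(3.25 * we * s0)
        assert d[4] == pytest.approx(3.25 * we * (0.8 * 135) * s0)
        assert d[5] == pytest.approx(22.0 * wi * (0.25 * 135) * s0)

    def test_origin_with_standard_drive(self, typical):
        d = ga.derivatives(np.zeros(6), 220.0, typical)
        s0 = 5.0 / (1.0 + np.exp(0.56 * 6.0))
        assert d[4] == pytest.approx((1 / 0.0108) * 3.25 * (220.0 + 0.8 * 135 * s0))

    def test_fixed_point_has_vanishing_derivative(self, typical):
        # oracle: reduce the equilibrium conditions (all derivatives zero)
        # to one scalar equation in u = y1 - y2 and solve it by bisection
        p_in = 220.0
        we, wi = typical.omega_e, typical.omega_i

        def residual(u):
            y0 = typical.Ge / we * ga.sigmoid(u, typical)
            y1 = typical.Ge / we * (
                p_in + typical.C2 * ga.sigmoid(typical.C1 * y0, typical)
            )
            y2 = typical.Gi / wi * typical.C4 * ga.sigmoid(
                typical.C3 * y0, typical
            )
            return (y1 - y2) - u

        u_star = optimize.brentq(residual, -50.0, 50.0, xtol=1e-13)
        y0 = typical.Ge / we * ga.sigmoid(u_star, typical)
        y1 = typical.Ge / we * (
            p_in + typical.C2 * ga.sigmoid(typical.C1 * y0, typical)
        )
        state = np.array([y0, y1, y1 - u_star, 0.0, 0.0, 0.0])
        assert np.max(np.abs(ga.derivatives(state, p_in, typical))) < 1e-6

    def test_accepts_state_vector_type(self, typical):
        d1 = ga.derivatives(ga.StateVector(), 0.0, typical)
        d2 = ga.derivatives(np.zeros(6), 0.0, typical)
        assert np.array_equal(d1, d2)

    def test_rejects_nonfinite_state(self, typical):
        with pytest.raises(ValueError):
            ga.derivatives(np.full(6, np.nan), 0.0, typical)


class TestRK4:
    def test_vanishing_step_returns_input(self, typical):
        state = np.array([1.0, 2.0, 0.5, -1.0, 0.3, 0.0])
        out = ga.rk4_step(state, 220.0, 1e-13, typical)
        assert np.allclose(out, state, atol=1e-7)

    def test_single_step_matches_damped_oscillator(self, typical, monkeypatch):
        # freeze the sigmoid so the y0 subsystem becomes the linear
        # critically damped oscillator y'' = Ge*w*c - 2w y' - w^2 y with
        # closed form y(t) = ys + (-ys - w*ys*t) e^{-wt}, ys = Ge*c/w
        c = 1.0
        monkeypatch.setattr(
            ga.model_core, "sigmoid", lambda v, params=None: c
        )
        w = typical.omega_e
        ys = typical.Ge * c / w
        dt = 1e-3
        out = ga.rk4_step(np.zeros(6), 0.0, dt, typical)
        exact = ys + (-ys - w * ys * dt) * np.exp(-w * dt)
        err = abs(out[0] - exact)
        assert err < 1e-7  # O(dt^5) local error at these scales
        # halving dt shrinks the local error by ~2^5
        out2 = ga.rk4_step(np.zeros(6), 0.0, dt / 2, typical)
        exact2 = ys + (-ys - w * ys * (dt / 2)) * np.exp(-w * dt / 2)
        assert abs(out2[0] - exact2) < err / 20

    def test_fourth_order_convergence(self, typical):
        # Richardson comparison on the full nonlinear system, constant drive
        def final_state(dt, T=0.25):
            y = np.zeros(6)
            for _ in range(round(T / dt)):
                y = ga.rk4_step(y, 220.0, dt, typical)
            return y

        dt = 2e-3
        y1, y2, y4 = final_state(dt), final_state(dt / 2), final_state(dt / 4)
        order = np.log2(
            np.linalg.norm(y1 - y2) / np.linalg.norm(y2 - y4)
        )
        assert 3.8 <= order <= 4.2

    def test_rejects_nonpositive_dt(self, typical):
        with pytest.raises(ValueError):
            ga.rk4_step(np.zeros(6), 220.0, 0.0, typical)

    def test_compiled_loop_agrees_with_python_step(self, typical):
        # the batch integrator and the public rk4_step must be the same map
        rng = np.random.default_rng(7)
        drive = rng.normal(220, 22, 50)
        dt = 1e-3
        y = np.zeros(6)
        for p in drive:
            y = ga.rk4_step(y, float(p), dt, typical)
        out = _integrate(drive, dt, typical)
        assert out[-1] == pytest.approx(y[1] - y[2], rel=1e-12)


class TestSimulate:
    def test_alpha_band_peak_with_typical_parameters(self, typical):
        cfg = ga.SimulationConfig(duration=10.0, burn_in=2.0)
        for seed in range(3):
            sig = ga.simulate(typical, ga.NoiseSpec(seed=seed), cfg)
            psd = ga.welch_psd(sig.samples, ga.WelchConfig())
            assert 8.0 <= ga.peak_frequency(psd, 1.0, 45.0) <= 12.0

    def test_length_and_finiteness(self, typical):
        cfg = ga.SimulationConfig(duration=3.5, burn_in=0.25)
        sig = ga.simulate(typical, ga.NoiseSpec(seed=1), cfg)
        assert sig.samples.size == round(3.5 * 1000)
        assert np.all(np.isfinite(sig.samples))

    def test_identical_seeds_bit_identical(self, typical):
        cfg = ga.SimulationConfig(duration=2.0, burn_in=0.5)
        a = ga.simulate(typical, ga.NoiseSpec(seed=42), cfg)
        b = ga.simulate(typical, ga.NoiseSpec(seed=42), cfg)
        assert np.array_equal(a.samples, b.samples)
        c = ga.simulate(typical, ga.NoiseSpec(seed=43), cfg)
        assert not np.array_equal(a.samples, c.samples)

    def test_deterministic_drive_reproducible(self, typical):
        # zero noise std: pure ODE response; the tail statistics must be
        # exactly reproducible run to run
        cfg = ga.SimulationConfig(duration=8.0, burn_in=0.0)
        noise = ga.NoiseSpec(mean=220.0, std=0.0, seed=0)
        a = ga.simulate(typical, noise, cfg)
        b = ga.simulate(typical, noise, cfg)
        tail = slice(-5000, None)
        assert np.var(a.samples[tail]) == np.var(b.samples[tail])
        assert np.all(np.isfinite(a.samples))

    def test_blowup_raises_with_diagnostics(self, typical):
        # dt far beyond the RK4 stability limit of the synaptic kinetics
        cfg = ga.SimulationConfig(fs=5.0, duration=40.0, burn_in=0.0)
        with pytest.raises(ga.IntegrationBlowUpError, match="step"):
            ga.simulate(typical, ga.NoiseSpec(seed=0), cfg)

    def test_ensemble_seeds_propagate(self, typical):
        cfg = ga.SimulationConfig(duration=1.0, burn_in=0.1)
        sigs = ga.simulate_ensemble(typical, cfg, seeds=[3, 4])
        assert [s.noise.seed for s in sigs] == [3, 4]
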