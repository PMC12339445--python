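"""Mean-field integration, transfer function, and hemodynamics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from dynfc.connectomes import StructuralConnectome
from dynfc.dmf import (
    HemodynamicParameters,
    ModelParameters,
    SimulationConfig,
    balloon_windkessel,
    compute_currents,
    integrate,
    transfer_function,
)

from conftest import random_connectome


def _isolated_connectome(n: int = 1) -> StructuralConnectome:
    return StructuralConnectome(weights=np.zeros((n, n)), lengths=np.zeros((n, n)))


class TestTransferFunction:
    def test_removable_singularity_is_inverse_saturation(self):
        for a, b, d in [(310.0, 125.0, 0.16), (615.0, 177.0, 0.087)]:
            assert transfer_function(b / a, a, b, d) == pytest.approx(1 / d, abs=1e-9)

    def test_linear_asymptote(self):
        a, b, d = 310.0, 125.0, 0.16
        u = 50.0 / d
        x = (u + b) / a
        assert transfer_function(x, a, b, d) == pytest.approx(u, rel=1e-6)

    def test_matches_high_precision_series_evaluation(self, rng):
        import sympy

        a, b, d = 310.0, 125.0, 0.16
        xs = np.concatenate(
            [rng.uniform(0, 1, 20), b / a + rng.uniform(-1e-7, 1e-7, 10)]
        )
        z = sympy.symbols("z")
        for x in xs:
            u = a * x - b
            expr = u * sympy.Pow(1 - sympy.exp(-sympy.Float(d * u, 50)), -1)
            expect = float(expr.evalf(50)) if abs(d * u) > 1e-30 else 1 / d
            assert transfer_function(x, a, b, d) == pytest.approx(expect, abs=1e-9)

    def test_nonnegative_everywhere(self, rng):
        x = rng.uniform(-5, 5, 200)
        out = transfer_function(x, 310.0, 125.0, 0.16)
        assert np.all(out >= 0)


class TestComputeCurrents:
    def test_zero_state_gives_external_input_only(self):
        sc = random_connectome(5, seed=1)
        p = ModelParameters()
        z = np.zeros(5)
        I_E, I_I = compute_currents(z, z, np.zeros((5, 5)), p, sc)
        np.testing.assert_allclose(I_E, p.w_E * p.I_0)
        np.testing.assert_allclose(I_I, p.w_I * p.I_0)

    def test_zero_coupling_decouples_regions(self, rng):
        sc = random_connectome(5, seed=2)
        p = ModelParameters(G=0.0)
        S_E, S_I = rng.random(5), rng.random(5)
        delayed = np.tile(S_E, (5, 1))
        I_E, _ = compute_currents(S_E, S_I, delayed, p, sc)
        expect = p.w_E * p.I_0 + p.w_p * p.J_N * S_E - p.J_i * S_I
        np.testing.assert_allclose(I_E, expect, atol=1e-14)

    def test_matches_triple_loop_oracle(self, rng):
        sc = random_connectome(5, seed=3)
        p = ModelParameters(G=1.7)
        S_E, S_I = rng.random(5), rng.random(5)
        delayed = rng.random((5, 5))
        I_E, I_I = compute_currents(S_E, S_I, delayed, p, sc)
        for i in range(5):
            acc = 0.0
            for j in range(5):
                acc += sc.weights[i, j] * delayed[i, j]
            expect_E = (
                p.w_E * p.I_0 + p.w_p * p.J_N * S_E[i] + p.G * p.J_N * acc
                - p.J_i * S_I[i]
            )
            expect_I = p.w_I * p.I_0 + p.J_N * S_E[i] - S_I[i]
            assert I_E[i] == pytest.approx(expect_E, abs=1e-12)
            assert I_I[i] == pytest.approx(expect_I, abs=1e-12)

    def test_regional_override_changes_only_that_region(self, rng):
        sc = random_connectome(5, seed=4)
        p = ModelParameters(G=2.0)
        S_E, S_I = rng.random(5), rng.random(5)
        delayed = np.tile(S_E, (5, 1))
        base, _ = compute_currents(S_E, S_I, delayed, p, sc)
        override = np.full(5, np.nan)
        override[2] = 0.0
        mod, _ = compute_currents(S_E, S_I, delayed, p, sc, regional_G_override=override)
        changed = base != mod
        assert changed[2] and not changed[[0, 1, 3, 4]].any()


def _fixed_point_oracle(p: ModelParameters) -> float:
    """Joint (S_E, S_I) fixed point of an isolated region by nested root-find."""

    def si_of(se):
        f = lambda si: p.tau_I * transfer_function(
            p.w_I * p.I_0 + p.J_N * se - si, p.a_I, p.b_I, p.d_I
        ) - si
        return brentq(f, 0.0, 5.0, xtol=1e-14)

    def dse(se):
        ie = p.w_E * p.I_0 + p.w_p * p.J_N * se - p.J_i * si_of(se)
        r = transfer_function(ie, p.a_E, p.b_E, p.d_E)
        return -se / p.tau_E + (1 - se) * p.gamma_E * r

    return brentq(dse, 1e-9, 1 - 1e-9, xtol=1e-14)


class TestIntegrate:
    def test_noise_free_single_region_reaches_fixed_point(self):
        p = ModelParameters(G=0.0, sigma=0.0)
        sc = _isolated_connectome(1)
        cfg = SimulationConfig(duration=60.0, burn_in=0.0, tr=0.5, seed=0)
        res = integrate(sc, p, cfg)
        expect = _fixed_point_oracle(p)
        assert res.S_E[-1, 0] == pytest.approx(expect, abs=1e-6)

    def test_same_seed_is_bit_identical(self, sc8):
        p = ModelParameters(G=1.0, sigma=0.02)
        cfg = SimulationConfig(duration=20.0, burn_in=2.0, tr=0.72, seed=5)
        a = integrate(sc8, p, cfg)
        b = integrate(sc8, p, cfg)
        np.testing.assert_array_equal(a.bold, b.bold)
        np.testing.assert_array_equal(a.S_E, b.S_E)

    def test_noise_free_is_seed_independent(self, sc8):
        p = ModelParameters(G=1.0, sigma=0.0)
        cfg = SimulationConfig(duration=5.0, burn_in=1.0, tr=0.5, seed=1)
        a = integrate(sc8, p, cfg)
        b = integrate(sc8, p, replace(cfg, seed=999))
        np.testing.assert_array_equal(a.S_E, b.S_E)

    def test_euler_first_order_convergence(self):
        # transient state error halves when dt halves (global order 1)
        sc = random_connectome(4, seed=6)
        p = ModelParameters(G=1.0, sigma=0.0)

        def terminal(dt):
            cfg = SimulationConfig(
                duration=0.3, burn_in=0.0, tr=0.3, dt=dt, seed=0,
                state_stride=int(round(0.3 / dt)),
            )
            return integrate(sc, p, cfg).S_E[-1]

        ref = terminal(7.5e-5)
        e1 = np.abs(terminal(3e-3) - ref).max()
        e2 = np.abs(terminal(1.5e-3) - ref).max()
        assert e1 / e2 == pytest.approx(2.0, rel=0.25)

    def test_gating_stays_in_unit_interval_under_strong_noise(self, sc8):
        p = ModelParameters(G=2.0, sigma=0.5)
        cfg = SimulationConfig(duration=10.0, burn_in=0.0, tr=0.5, seed=2, state_stride=1)
        res = integrate(sc8, p, cfg)
        assert res.S_E.min() >= 0 and res.S_E.max() <= 1
        assert res.S_I.min() >= 0 and res.S_I.max() <= 1

    def test_region_permutation_equivariance(self):
        sc = random_connectome(6, seed=7)
        p = ModelParameters(G=1.5, sigma=0.0)
        cfg = SimulationConfig(duration=8.0, burn_in=1.0, tr=0.5, seed=0)
        base = integrate(sc, p, cfg)
        perm = np.array([3, 1, 5, 0, 4, 2])
        sc_p = StructuralConnectome(
            weights=sc.weights[np.ix_(perm, perm)], lengths=sc.lengths[np.ix_(perm, perm)]
        )
        permuted = integrate(sc_p, p, cfg)
        np.testing.assert_allclose(permuted.S_E, base.S_E[:, perm], atol=1e-12)

    def test_noise_increments_scale_pathwise_with_sigma(self, sc8):
        cfg = SimulationConfig(duration=2.0, burn_in=0.0, tr=0.5, seed=9)
        a = integrate(sc8, ModelParameters(sigma=0.01), cfg, store_increments=True)
        b = integrate(sc8, ModelParameters(sigma=0.02), cfg, store_increments=True)
        np.testing.assert_allclose(b.noise_increments, 2.0 * a.noise_increments, rtol=1e-12)

    def test_delays_change_dynamics_but_stay_finite(self, sc8):
        p = ModelParameters(G=2.0, sigma=0.0)
        cfg = SimulationConfig(duration=6.0, burn_in=1.0, tr=0.5, seed=0)
        no_delay = integrate(sc8, p, cfg)
        delayed = integrate(sc8, p, replace(cfg, conduction_speed=1000.0))
        assert np.all(np.isfinite(delayed.S_E))
        assert not np.array_equal(no_delay.S_E, delayed.S_E)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(duration=5.0, burn_in=5.0)
        with pytest.raises(ValueError):
            SimulationConfig(tr=1e-5, dt=1e-3)


class TestBalloonWindkessel:
    def test_zero_input_gives_zero_bold(self):
        bold = balloon_windkessel(np.zeros((3000, 2)), dt=0.001, tr=0.5)
        np.testing.assert_allclose(bold, 0.0, atol=1e-12)

    def test_constant_input_matches_stiff_solver_steady_state(self):
        hemo = HemodynamicParameters()
        c = 0.3

        def rhs(t, y):
            s, f, v, q = y
            fv = v ** (1 / hemo.alpha)
            E = 1 - (1 - hemo.rho) ** (1 / f)
            return [
                c - hemo.kappa * s - hemo.gamma_f * (f - 1),
                s,
                (f - fv) / hemo.tau_h,
                (f * E / hemo.rho - fv * q / v) / hemo.tau_h,
            ]

        sol = solve_ivp(rhs, (0, 200), [0, 1, 1, 1], method="Radau", rtol=1e-10, atol=1e-12)
        s, f, v, q = sol.y[:, -1]
        expect = hemo.V0 * (
            hemo.k1 * (1 - q) + hemo.k2 * (1 - q / v) + hemo.k3 * (1 - v)
        )
        bold = balloon_windkessel(np.full((120_000, 1), c), hemo, dt=0.001, tr=1.0)
        assert bold[-1, 0] == pytest.approx(expect, abs=1e-5)

    def test_identical_inputs_give_identical_columns(self, rng):
        drive = rng.random((5000, 1)) * 0.1
        two = np.hstack([drive, drive])
        bold = balloon_windkessel(two, dt=0.001, tr=0.5)
        np.testing.assert_array_equal(bold[:, 0], bold[:, 1])

    def test_input_shorter_than_tr_rejected(self):
        with pytest.raises(ValueError):
            balloon_windkessel(np.zeros((10, 1)), dt=0.001, tr=0.72)
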