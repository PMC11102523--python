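"""Deterministic dynamics: advertising forcing, right-hand sides, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viralsir import (
    FractionState,
    ModelParams,
    ModelState,
    advertising_load,
    integrate,
    rhs_fractions,
    rhs_full,
    rhs_reduced,
)

from conftest import N_REF, random_theory_params


class TestAdvertisingLoad:
    @pytest.mark.parametrize(
        "gamma, N, I, expected",
        [
            (0.002, 10_000, 0, 20.0),  # gamma*N when nobody shares
            (0.002, 10_000, 10_000, 10.0),  # denominator doubles at I=N
            (0.0, 10_000, 123, 0.0),  # no advertising budget
        ],
    )
    def test_reference_values(self, gamma, N, I, expected):
        assert advertising_load(gamma, N, I) == pytest.approx(expected, rel=1e-12)

    @given(
        gamma=st.floats(1e-6, 1.0),
        N=st.floats(1.0, 1e9),
        frac=st.floats(0.0, 100.0),
        bump=st.floats(1e-6, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_strictly_decreasing_in_sharers(self, gamma, N, frac, bump):
        I = frac * N
        assert advertising_load(gamma, N, I + bump * N) < advertising_load(gamma, N, I)

    def test_rejects_invalid_domain(self):
        with pytest.raises(ValueError):
            advertising_load(0.01, -1.0, 0.0)
        with pytest.raises(ValueError):
            advertising_load(0.01, 100.0, -5.0)
        with pytest.raises(ValueError):
            advertising_load(-0.01, 100.0, 5.0)


class TestRightHandSides:
    def test_susceptible_growth_when_no_sharers(self, demo_params):
        # with I = 0 inflow minus advertising gives S' = (b - gamma) N > 0
        state = ModelState(S=N_REF, I=0.0, R=0.0, N=N_REF)
        dS, dI, dR = rhs_full(state, demo_params)
        assert dS == pytest.approx((demo_params.b - demo_params.gamma) * N_REF, rel=1e-12)
        assert dS > 0

    def test_component_sum_is_inflow(self, demo_params):
        rng = np.random.default_rng(7)
        for _ in range(20):
            S, I, R = rng.uniform(0, N_REF, 3)
            state = ModelState(S=S, I=I, R=R, N=N_REF)
            assert sum(rhs_full(state, demo_params)) == pytest.approx(
                demo_params.b * N_REF, rel=1e-12
            )

    def test_sharer_derivative_hand_value(self, demo_params):
        # beta1*I*S/N + gamma*N^2/(I+N) - alpha*I at S=9900, I=100:
        # 9.9 + 19.8019801980... - 3
        state = ModelState(S=9900.0, I=100.0, R=0.0, N=N_REF)
        _, dI, _ = rhs_full(state, demo_params)
        assert dI == pytest.approx(26.7019801980198, rel=1e-12)

    def test_sharer_derivative_matches_finite_difference(self, demo_params, demo_init):
        traj = integrate(demo_params, demo_init, t_end=0.02, output_grid=0.001)
        fd = (traj.I[1] - traj.I[0]) / (traj.times[1] - traj.times[0])
        state = ModelState(S=demo_init.S, I=demo_init.I, R=0.0, N=N_REF)
        assert fd == pytest.approx(rhs_full(state, demo_params)[1], rel=1e-3)

    def test_reduced_matches_full(self, demo_params):
        rng = np.random.default_rng(11)
        for _ in range(20):
            S, I, R = rng.uniform(0, N_REF, 3)
            full = rhs_full(ModelState(S=S, I=I, R=R, N=N_REF), demo_params)
            assert rhs_reduced(S, I, demo_params, N_REF) == pytest.approx(full[:2], rel=1e-14)

    def test_advertising_keeps_axis_repelling(self, demo_params):
        # on the S-axis (I=0) the sharer inflow is the finite advertising load gamma*N
        _, dI = rhs_reduced(5000.0, 0.0, demo_params, N_REF)
        assert dI == pytest.approx(demo_params.gamma * N_REF, rel=1e-12)
        assert dI > 0


class TestFractionSystem:
    def test_pure_susceptible_start(self, demo_params):
        ds, _, _ = rhs_fractions(FractionState(1.0, 0.0, 0.0), demo_params)
        assert ds == pytest.approx(-demo_params.gamma, rel=1e-12)

    def test_simplex_preserved(self, demo_params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s, i = rng.uniform(0, 1), 0.0
            i = rng.uniform(0, 1 - s)
            frac = FractionState(s, i, 1 - s - i)
            assert sum(rhs_fractions(frac, demo_params)) == pytest.approx(0.0, abs=1e-15)

    def test_matches_rescaled_full_system_minus_dilution(self, demo_params):
        # fraction rates = rhs_full(sN, iN, rN)/N minus the dilution b*(s, i, r)
        s, i, r = 0.5, 0.25, 0.25
        full = rhs_full(ModelState(s * N_REF, i * N_REF, r * N_REF, N_REF), demo_params)
        expected = tuple(f / N_REF - demo_params.b * x for f, x in zip(full, (s, i, r)))
        assert rhs_fractions(FractionState(s, i, r), demo_params) == pytest.approx(
            expected, rel=1e-12
        )


class TestIntegration:
    def test_pure_recovery_is_exponential(self):
        params = ModelParams(beta=1e-300, beta1=0.0, alpha=0.03, b=0.0, gamma=0.0)
        init = ModelState.initial(0.0, 100.0)
        traj = integrate(params, init, t_end=100.0, output_grid=1.0)
        expected = 100.0 * np.exp(-0.03 * traj.times)
        assert np.allclose(traj.I, expected, rtol=1e-8)

    def test_linear_first_integral_conserved(self, demo_params, demo_init):
        traj = integrate(demo_params, demo_init, t_end=200.0, output_grid=0.5)
        n0 = demo_init.S + demo_init.I + demo_init.R
        assert np.abs(traj.conservation_residual()).max() <= 1e-6 * n0

    def test_long_horizon_reaches_equilibrium(self, demo_params, demo_init):
        from viralsir import interior_equilibrium

        eq = interior_equilibrium(demo_params, N_REF)
        traj = integrate(demo_params, demo_init, t_end=2000.0, output_grid=10.0)
        assert abs(traj.S[-1] - eq.S_star) <= 1e-4 * N_REF
        assert abs(traj.I[-1] - eq.I_star) <= 1e-4 * N_REF

    def test_paths_stay_nonnegative(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = random_theory_params(rng)
            S0 = rng.uniform(0.1, 1.0) * N_REF
            I0 = rng.uniform(0.0, 0.5) * N_REF
            traj = integrate(params, ModelState.initial(S0, I0), t_end=300.0, output_grid=1.0)
            assert traj.S.min() >= 0 and traj.I.min() >= 0 and traj.R.min() >= 0

    def test_rejects_nonpositive_horizon(self, demo_params, demo_init):
        with pytest.raises(ValueError):
            integrate(demo_params, demo_init, t_end=0.0)


class TestModelParams:
    def test_requires_beta_above_beta1(self):
        with pytest.raises(ValueError):
            ModelParams(beta=0.1, beta1=0.4, alpha=0.03, b=0.02, gamma=0.002)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            ModelParams(beta=0.4, beta1=0.1, alpha=-0.03, b=0.02, gamma=0.002)

    def test_theory_regime_flag(self, demo_params):
        assert demo_params.theory_regime
        assert not demo_params.replace(b=0.05).theory_regime  # b > alpha
        assert not demo_params.replace(gamma=0.03).theory_regime  # gamma > b
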