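"""Unit and property tests for the two-sensor master-equation model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neqsense as nq
from neqsense.core import CYCLE_EDGES, STATES

from conftest import random_params


finite_params = st.builds(
    nq.SensorParams,
    beta=st.floats(0.0, 10.0),
    J=st.floats(-5.0, 5.0),
    t=st.floats(-8.0, 8.0),
)
signals = st.builds(
    nq.Signal,
    h1=st.floats(-4.0, 4.0),
    h2=st.floats(-4.0, 4.0),
)


class TestFreeEnergy:
    @pytest.mark.parametrize(
        "state, h, J, expected",
        [
            ((1, 1), (0.0, 0.0), 1.0, -1.0),
            ((1, -1), (1.0, 0.0), 0.0, -1.0),
            ((-1, -1), (1.0, 1.0), 2.0, 0.0),
        ],
    )
    def test_direct_values(self, state, h, J, expected):
        params = nq.SensorParams(beta=1.0, J=J)
        assert nq.free_energy_eq(state, nq.Signal(*h), params) == pytest.approx(expected)

    def test_drive_does_not_enter(self):
        sig = nq.Signal(0.3, -0.7)
        for state in STATES:
            assert nq.free_energy_eq(
                state, sig, nq.SensorParams(2.0, 1.0, 0.0)
            ) == nq.free_energy_eq(state, sig, nq.SensorParams(2.0, 1.0, 5.0))


class TestInversionRate:
    def test_all_params_zero_gives_unit_rates(self):
        params = nq.SensorParams(beta=0.0)
        sig = nq.Signal(0.0, 0.0)
        for state in STATES:
            for i in (1, 2):
                assert nq.inversion_rate(state, i, sig, params) == 1.0

    def test_equilibrium_rates_satisfy_detailed_balance_ratio(self):
        """rate(S->S^i)/rate(S^i->S) = exp(-beta (F_{S^i} - F_S)) at t = 0."""
        params = nq.SensorParams(beta=1.7, J=0.8)
        sig = nq.Signal(0.5, -0.3)
        for s1, s2 in STATES:
            for i in (1, 2):
                flipped = (-s1, s2) if i == 1 else (s1, -s2)
                ratio = nq.inversion_rate((s1, s2), i, sig, params) / nq.inversion_rate(
                    flipped, i, sig, params
                )
                dF = nq.free_energy_eq(flipped, sig, params) - nq.free_energy_eq(
                    (s1, s2), sig, params
                )
                assert ratio == pytest.approx(np.exp(-params.beta * dF))

    def test_cyclic_bias_factor(self):
        """The -- -> -+ move outpaces its reverse by exp(beta t) at h = J = 0."""
        params = nq.SensorParams(beta=1.0, J=0.0, t=1.0)
        sig = nq.Signal(0.0, 0.0)
        fwd = nq.inversion_rate((-1, -1), 2, sig, params)
        back = nq.inversion_rate((-1, 1), 2, sig, params)
        assert fwd / back == pytest.approx(np.exp(1.0))
        assert fwd == pytest.approx(np.exp(0.5))

    def test_invalid_sensor_index(self):
        with pytest.raises(ValueError):
            nq.inversion_rate((1, 1), 3, nq.Signal(0.0), nq.SensorParams(1.0))


class TestRateMatrix:
    def test_zero_params_structure(self):
        W = nq.build_rate_matrix(nq.Signal(0.0, 0.0), nq.SensorParams(0.0))
        assert np.allclose(np.diag(W), -2.0)
        # single-flip entries 1, double-flip entries 0
        assert W[2, 0] == 0.0 and W[0, 2] == 0.0
        assert W[3, 1] == 0.0 and W[1, 3] == 0.0
        assert W[1, 0] == 1.0 and W[3, 0] == 1.0

    @given(params=finite_params, signal=signals)
    @settings(max_examples=50, deadline=None)
    def test_generator_invariants(self, params, signal):
        W = nq.build_rate_matrix(signal, params)
        assert np.allclose(W.sum(axis=0), 0.0, atol=1e-12)
        off = W[~np.eye(4, dtype=bool)]
        assert np.all(off >= 0.0)
        assert W[2, 0] == 0.0 and W[0, 2] == 0.0
        assert W[3, 1] == 0.0 and W[1, 3] == 0.0


class TestSteadyState:
    def test_uniform_at_zero_params(self):
        W = nq.build_rate_matrix(nq.Signal(0.0, 0.0), nq.SensorParams(0.0))
        assert np.allclose(nq.steady_state_numeric(W), 0.25, atol=1e-12)

    def test_boltzmann_at_equilibrium(self):
        params = nq.SensorParams(beta=1.9, J=-0.8)
        sig = nq.Signal(0.6, -1.2)
        W = nq.build_rate_matrix(sig, params)
        p = nq.steady_state_numeric(W)
        F = np.array([nq.free_energy_eq(S, sig, params) for S in STATES])
        boltz = np.exp(-params.beta * F)
        boltz /= boltz.sum()
        assert np.allclose(p, boltz, atol=1e-12)

    def test_closed_form_matches_nullspace_at_spot_check(self):
        params = nq.SensorParams(beta=1.0, J=0.7, t=1.3)
        sig = nq.Signal(0.4, -0.2)
        pn = nq.steady_state_numeric(nq.build_rate_matrix(sig, params))
        pc = nq.steady_state_closed_form(sig, params)
        assert np.abs(pn - pc).max() < 1e-10

    @given(params=finite_params, signal=signals)
    @settings(max_examples=150, deadline=None)
    def test_closed_form_equals_nullspace(self, params, signal):
        """Oracle equivalence of the two independent steady-state routes."""
        pn = nq.steady_state_numeric(nq.build_rate_matrix(signal, params))
        pc = nq.steady_state_closed_form(signal, params)
        assert np.abs(pn - pc).max() < 1e-10
        assert pc.min() >= 0.0
        assert pc.sum() == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_refuses_biases(self):
        with pytest.raises(ValueError):
            nq.steady_state_closed_form(nq.Signal(0.0), nq.SensorParams(1.0, b1=0.5))

    def test_drive_correction_vanishes_as_t_to_zero(self):
        sig = nq.Signal(0.8, -0.4)
        p0 = nq.steady_state_closed_form(sig, nq.SensorParams(2.0, 1.0, 0.0))
        pb = nq.boltzmann_distribution(sig, nq.SensorParams(2.0, 1.0, 0.0))
        assert np.allclose(p0, pb, atol=1e-14)
        pt = nq.steady_state_closed_form(sig, nq.SensorParams(2.0, 1.0, 1e-8))
        assert np.abs(pt - p0).max() < 1e-7

    def test_exchange_symmetry(self):
        """Swapping h1<->h2 with t -> -t relabels states by s1<->s2."""
        params = nq.SensorParams(beta=2.3, J=-1.1, t=1.7)
        swapped = nq.SensorParams(beta=2.3, J=-1.1, t=-1.7)
        p = nq.steady_state_closed_form(nq.Signal(0.9, -0.5), params)
        q = nq.steady_state_closed_form(nq.Signal(-0.5, 0.9), swapped)
        # s1<->s2 maps (--, -+, ++, +-) to (--, +-, ++, -+)
        assert np.allclose(p, q[[0, 3, 2, 1]], atol=1e-12)

    def test_large_beta_is_stable(self):
        params = nq.SensorParams(beta=30.0, J=-2.0, t=3.0)
        sig = nq.Signal(0.5, 0.5)
        pc = nq.steady_state_closed_form(sig, params)
        pn = nq.steady_state_numeric(nq.build_rate_matrix(sig, params))
        assert np.isfinite(pc).all()
        assert np.abs(pn - pc).max() < 1e-10

    def test_reducible_chain_is_rejected(self):
        # two disconnected 2-state blocks
        W = np.array([
            [-1.0, 1.0, 0.0, 0.0],
            [1.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, -2.0, 2.0],
            [0.0, 0.0, 2.0, -2.0],
        ])
        with pytest.raises(ValueError):
            nq.steady_state_numeric(W)


class TestCycleObservables:
    def test_kolmogorov_ratio_values(self):
        assert nq.kolmogorov_ratio(nq.SensorParams(1.0, 2.0, 0.0)) == 1.0
        assert nq.kolmogorov_ratio(nq.SensorParams(1.0, 0.0, 1.0)) == pytest.approx(
            np.exp(4.0)
        )

    def test_kolmogorov_antisymmetry(self):
        r1 = nq.kolmogorov_ratio(nq.SensorParams(1.3, 0.5, 2.0))
        r2 = nq.kolmogorov_ratio(nq.SensorParams(1.3, 0.5, -2.0))
        assert r1 * r2 == pytest.approx(1.0)

    @given(params=finite_params, signal=signals)
    @settings(max_examples=50, deadline=None)
    def test_kolmogorov_ratio_matches_direct_rate_products(self, params, signal):
        """Analytic exp(4 beta (J12 - J21)) vs the actual product of rates."""
        log_ratio = 0.0
        for a, b in CYCLE_EDGES:
            sa, sb = STATES[a], STATES[b]
            sensor = 1 if sa[0] != sb[0] else 2
            log_ratio += np.log(nq.inversion_rate(sa, sensor, signal, params))
            log_ratio -= np.log(nq.inversion_rate(sb, sensor, signal, params))
        assert log_ratio == pytest.approx(
            np.log(nq.kolmogorov_ratio(params)), abs=1e-8
        )

    def test_current_zero_at_equilibrium(self):
        params = nq.SensorParams(beta=2.0, J=1.0)
        W = nq.build_rate_matrix(nq.Signal(0.7, -0.2), params)
        p = nq.steady_state_numeric(W)
        assert abs(nq.cycle_current(p, W)) < 1e-12

    @pytest.mark.parametrize("t", [2.0, -2.0])
    def test_current_sign_follows_drive(self, t):
        params = nq.SensorParams(beta=1.5, J=0.3, t=t)
        W = nq.build_rate_matrix(nq.Signal(0.2, 0.4), params)
        p = nq.steady_state_numeric(W)
        assert np.sign(nq.cycle_current(p, W)) == np.sign(t)

    def test_current_rejects_nonstationary_distribution(self):
        params = nq.SensorParams(beta=1.5, J=0.3, t=2.0)
        W = nq.build_rate_matrix(nq.Signal(0.2, 0.4), params)
        with pytest.raises(ValueError):
            nq.cycle_current(np.array([0.7, 0.1, 0.1, 0.1]), W)

    def test_dissipation_is_4t(self):
        assert nq.cycle_dissipation(nq.SensorParams(1.0, 0.0, 1.0)) == 4.0
        assert nq.cycle_dissipation(nq.SensorParams(1.0, 5.0, 0.0)) == 0.0

    def test_effective_free_energy_telescopes_to_minus_4t(self):
        """The equilibrium parts cancel around the loop for any signal."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            params = random_params(rng)
            if params.beta < 0.1:
                continue
            sig = nq.Signal(*rng.uniform(-3, 3, 2))
            drop = nq.cycle_free_energy_drop(sig, params)
            assert drop == pytest.approx(-4.0 * params.t, abs=1e-8)
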