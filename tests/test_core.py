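"""Neural-mass network dynamics: transfer function, currents, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eitune import (Connectome, CouplingWeights, DMFParams, DMFSimulator,
                    NetworkState, simulate, synaptic_currents, transfer_rate)
from eitune.core import SimulationError, integrate_step

P = DMFParams()


class TestTransferRate:
    def test_removable_singularity_limit(self):
        # at a*I = b the sigmoid's value is the limit 1/d
        assert transfer_rate(125.0 / 310.0, 310, 125, 0.16) == pytest.approx(
            1.0 / 0.16, rel=1e-9)

    def test_asymptotic_zero_rate(self):
        assert transfer_rate(-50.0, 310, 125, 0.16) == pytest.approx(0.0, abs=1e-12)

    def test_high_precision_oracle_value(self):
        # frozen 30-digit evaluation of (aI-b)/(1-exp(-d(aI-b))) at I=0.382
        assert transfer_rate(0.382, 310, 125, 0.16) == pytest.approx(
            3.52689491186803269678, rel=1e-12)

    def test_agrees_with_independent_evaluation_on_grid(self):
        # float128-style independent evaluation incl. the singular region
        I = np.concatenate([np.linspace(-0.5, 1.5, 401),
                            125.0 / 310.0 + np.linspace(-1e-6, 1e-6, 101)])
        ours = transfer_rate(I, 310, 125, 0.16)
        x = np.longdouble(310) * I.astype(np.longdouble) - 125
        with np.errstate(over="ignore", invalid="ignore"):
            ref = np.where(np.abs(x) < 1e-9, 1 / np.longdouble(0.16),
                           x / (1 - np.exp(-np.longdouble(0.16) * x)))
        assert np.max(np.abs(ours - ref.astype(float))
                      / np.maximum(np.abs(ref.astype(float)), 1e-30)) < 1e-10

    def test_continuous_and_nonnegative(self):
        I = np.linspace(-1, 2, 2001)
        r = transfer_rate(I, 310, 125, 0.16)
        assert np.all(r >= 0)
        assert np.max(np.abs(np.diff(r))) < 1.0  # no jumps on a fine grid

    def test_rejects_nonfinite_current(self):
        with pytest.raises(ValueError, match="finite"):
            transfer_rate(np.nan, 310, 125, 0.16)

    @given(a=st.floats(1.0, 1000.0), b=st.floats(0.0, 300.0),
           d=st.floats(0.01, 1.0), I=st.floats(-2.0, 2.0))
    @settings(max_examples=100, derandomize=True)
    def test_nonnegative_for_any_parameters(self, a, b, d, I):
        assert transfer_rate(I, a, b, d) >= 0.0


def _state(S_E, S_I, n):
    z = np.zeros(n)
    return NetworkState(np.asarray(S_E, float), np.asarray(S_I, float),
                        z, z, z, z)


class TestSynapticCurrents:
    def test_zero_state_gives_external_input_only(self):
        C = Connectome(np.zeros((3, 3)))
        W = CouplingWeights.default(3)
        I_E, I_I = synaptic_currents(_state(np.zeros(3), np.zeros(3), 3), P, C, W)
        assert np.allclose(I_E, P.W_E * P.I_0)
        assert np.allclose(I_I, P.W_I * P.I_0)

    def test_zero_lre_decouples_excitatory_input_from_connectome(self):
        rng = np.random.default_rng(0)
        C1 = rng.uniform(0, 1, (4, 4))
        np.fill_diagonal(C1, 0.0)
        C2 = 2.0 * C1
        W = CouplingWeights.default(4)
        W.w_LRE[:] = 0.0
        s = _state(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4), 4)
        I_E1, _ = synaptic_currents(s, P, Connectome(C1), W)
        I_E2, _ = synaptic_currents(s, P, Connectome(C2), W)
        assert np.allclose(I_E1, I_E2)

    def test_two_node_hand_value(self):
        # I_E_1 = 0.382 + 1.4*0.15*0.1 + 0.15*1*1*0.2 - 0 = 0.433 nA
        C = Connectome.two_node(1.0)
        W = CouplingWeights.default(2)
        s = _state([0.1, 0.2], [0.0, 0.0], 2)
        I_E, _ = synaptic_currents(s, P, C, W)
        assert I_E[0] == pytest.approx(0.433, abs=1e-12)

    def test_shape_mismatch_raises(self):
        C = Connectome(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="dimensions"):
            synaptic_currents(_state(np.zeros(2), np.zeros(2), 2), P, C,
                              CouplingWeights.default(3))


class TestIntegrateStep:
    def test_deterministic_fixed_point_is_stationary(self):
        # frozen 1-node fixed point from a scipy.brentq root-finding oracle
        S_E0, S_I0 = 0.164757207546, 0.039218448632
        C = Connectome(np.zeros((1, 1)))
        W = CouplingWeights.default(1)
        s = _state([S_E0], [S_I0], 1)
        s2 = integrate_step(s, P, C, W, dt=1.0)
        assert abs(s2.S_E[0] - S_E0) < 1e-6
        assert abs(s2.S_I[0] - S_I0) < 1e-6

    def test_gating_decays_with_tau_when_saturation_off(self):
        p = DMFParams(gamma_E=0.0, sigma=0.0)
        C = Connectome(np.zeros((1, 1)))
        W = CouplingWeights.default(1)
        s = _state([0.5], [0.0], 1)
        dt = 0.01
        for _ in range(1000):  # 10 ms
            s = integrate_step(s, p, C, W, dt=dt)
        assert s.S_E[0] == pytest.approx(0.5 * np.exp(-10.0 / p.tau_E), rel=1e-3)

    def test_same_noise_same_result(self):
        rng = np.random.default_rng(4)
        noise = (rng.standard_normal(2), rng.standard_normal(2))
        C = Connectome.two_node()
        W = CouplingWeights.default(2)
        s = _state([0.1, 0.2], [0.1, 0.1], 2)
        a = integrate_step(s, P, C, W, 1.0, noise)
        b = integrate_step(s, P, C, W, 1.0, noise)
        assert np.array_equal(a.S_E, b.S_E) and np.array_equal(a.S_I, b.S_I)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError, match="dt"):
            integrate_step(_state([0.1], [0.1], 1), P,
                           Connectome(np.zeros((1, 1))),
                           CouplingWeights.default(1), dt=0.0)


class TestSimulate:
    def test_same_seed_bitwise_identical_bold(self):
        C = Connectome(np.zeros((5, 5)))
        a = simulate(C, duration=10 * 720.0, seed=42)
        b = simulate(C, duration=10 * 720.0, seed=42)
        assert np.array_equal(a.bold, b.bold)
        assert not np.array_equal(
            a.bold, simulate(C, duration=10 * 720.0, seed=43).bold)

    def test_noiseless_run_settles_to_constant_tr_samples(self):
        p = DMFParams(sigma=0.0)
        res = simulate(Connectome.two_node(), p, duration=200 * 720.0, seed=0)
        tail = res.bold[:, -20:]
        assert np.max(np.abs(tail - tail[:, -1:])) < 1e-9

    def test_gating_stays_in_unit_interval(self):
        res = simulate(Connectome.two_node(), duration=120 * 720.0, seed=7)
        assert np.all(res.gating_E >= 0.0) and np.all(res.gating_E <= 1.0)

    def test_gating_variance_grows_with_noise_amplitude(self):
        C = Connectome(np.zeros((1, 1)))
        v = []
        for sigma in (0.002, 0.01, 0.05):
            res = simulate(C, DMFParams(sigma=sigma),
                           duration=400 * 720.0, seed=3)
            v.append(res.gating_E[0, 50:].var())
        assert v[0] < v[1] < v[2]

    def test_fic_drives_two_node_rates_to_target(self):
        sim = DMFSimulator(Connectome.two_node(), seed=1)
        sim.run(600_000, fic=True)                      # burn-in
        res = sim.run(600_000, fic=True)                # 10 min measurement
        rates = res.rates_E.mean(axis=1)
        assert np.all(np.abs(rates - 4.0) < 0.5)

    def test_duration_shorter_than_tr_rejected(self):
        with pytest.raises(ValueError):
            simulate(Connectome.two_node(), duration=100.0, tr=720.0)


class TestConnectomeInvariants:
    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError, match="nonnegative"):
            Connectome(np.array([[0.0, -1.0], [1.0, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            Connectome(np.eye(3))

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError, match="square"):
            Connectome(np.zeros((2, 3)))

    def test_weights_reject_negative(self):
        with pytest.raises(ValueError):
            CouplingWeights(-np.ones((2, 2)), np.zeros((2, 2)), np.ones(2))
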