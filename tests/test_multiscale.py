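"""Large-scale -> circuit coupling: drive extraction and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eitune import (Connectome, CouplingSpec, CouplingWeights, DMFParams,
                    DMFSimulator, SynthSpec, cohort_range, drive_from_gating,
                    gen_cohort, mean_fc, normalize_drive, region_drive)
from eitune.dm import DMParams
from eitune.multiscale import multiscale_dm

SPEC = CouplingSpec()


class TestRegionDrive:
    def test_zero_gating_zero_drive(self):
        C = Connectome.two_node()
        W = CouplingWeights.default(2)
        d = drive_from_gating(np.zeros(2), np.zeros(1), C, W, DMFParams(), 0)
        assert d == pytest.approx(0.0)

    def test_hand_evaluated_two_node_bracket(self):
        # w+*J*S_E + J*wLRE*C*S_E_j - J_i*S_I
        # = 1.4*0.15*0.1 + 0.15*1*1*0.2 - 1*0.05 = 0.001
        C = Connectome.two_node()
        W = CouplingWeights.default(2)
        d = drive_from_gating(np.array([0.1, 0.2]), np.array([0.05]),
                              C, W, DMFParams(), 0)
        assert d == pytest.approx(0.021 + 0.03 - 0.05, abs=1e-15)

    def test_zero_lre_row_reduces_to_local_terms(self):
        C = Connectome.two_node()
        W = CouplingWeights.default(2)
        W.w_LRE[:] = 0.0
        p = DMFParams()
        d = drive_from_gating(np.array([0.3, 0.9]), np.array([0.2]),
                              C, W, p, 0)
        assert d == pytest.approx(p.w_plus * p.J_NMDA * 0.3 - 0.2)

    def test_captured_drive_consistent_with_tr_averaged_currents(self):
        """The per-step captured drive equals I_E minus the external term,
        so its TR average must match the recorded TR-mean current."""
        sim = DMFSimulator(Connectome.two_node(), seed=3)
        res = sim.run(10 * 720.0, capture_drive_nodes=[0, 1])
        p = sim.params
        for k, node in enumerate((0, 1)):
            d = region_drive(res, node).reshape(res.n_tr, -1).mean(axis=1)
            assert np.allclose(d, res.currents_E[node] - p.W_E * p.I_0,
                               atol=1e-12)

    def test_missing_capture_instructs_user(self):
        sim = DMFSimulator(Connectome.two_node(), seed=3)
        res = sim.run(5 * 720.0)
        with pytest.raises(ValueError, match="capture_drive_nodes"):
            region_drive(res, 0)

    def test_uncaptured_node_reported(self):
        sim = DMFSimulator(Connectome.two_node(), seed=3)
        res = sim.run(5 * 720.0, capture_drive_nodes=[1])
        with pytest.raises(ValueError, match="node 0"):
            region_drive(res, 0)


class TestCohortRange:
    def test_linear_interpolation_percentile_convention(self):
        vals = np.arange(1.0, 101.0)
        a, b = cohort_range(vals, SPEC)
        assert a == pytest.approx(10.9)
        assert b == pytest.approx(90.1)

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohort_range([0.5, 0.5], SPEC)
        with pytest.raises(ValueError, match="at least 2"):
            cohort_range([0.5], SPEC)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(40)
        assert cohort_range(vals, SPEC) == cohort_range(rng.permutation(vals),
                                                        SPEC)


class TestNormalizeDrive:
    def test_source_bounds_map_to_target_bounds(self):
        out = normalize_drive(np.array([2.0, 5.0, 3.5]), 2.0, 5.0, SPEC)
        assert out[0] == pytest.approx(-0.006)
        assert out[1] == pytest.approx(0.001)
        assert out[2] == pytest.approx(-0.0025)

    def test_out_of_band_values_extrapolate_without_clipping(self):
        out = normalize_drive(np.array([1.0, 6.0]), 2.0, 5.0, SPEC)
        assert out[0] < -0.006
        assert out[1] > 0.001

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            normalize_drive(np.array([1.0]), 5.0, 2.0, SPEC)

    @given(a=st.floats(-1.0, 0.0), width=st.floats(0.1, 2.0),
           x=st.floats(-3.0, 3.0))
    @settings(max_examples=100, derandomize=True)
    def test_affine_and_invertible(self, a, width, x):
        b = a + width
        y = normalize_drive(np.array([x]), a, b, SPEC)[0]
        x_back = (y - SPEC.a_MJW) * (b - a) / (SPEC.b_MJW - SPEC.a_MJW) + a
        assert abs(x_back - x) < 1e-12


class TestCouplingSpecInvariants:
    def test_overlapping_region_lists_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            CouplingSpec(pfc_regions=(1, 2), ppc_regions=(2, 3))

    def test_inverted_target_band_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(a_MJW=0.01, b_MJW=-0.01)

    def test_node_outside_region_list_rejected(self):
        spec = CouplingSpec(pfc_regions=(1,), ppc_regions=(5,))
        with pytest.raises(ValueError, match="pfc_node"):
            multiscale_dm([], spec, pfc_node=2, ppc_node=5)


@pytest.fixture(scope="module")
def small_cohort():
    spec = SynthSpec(n_nodes=10, density=0.3, seed=2)
    return gen_cohort(10, spec, heterogeneity=2.8, seed=5,
                      shared_connectome=True, burn_in_ms=360_000,
                      duration_ms=900_000)


class TestMultiscaleDm:
    def test_identical_models_perform_alike(self, small_cohort):
        conn, _, W = small_cohort[5]
        # three copies of one model, distinguished only by drive seeds
        models = [(conn, W)] * 3
        res = multiscale_dm(models, CouplingSpec(), pfc_node=1, ppc_node=5,
                            n_trials=80, seed=3)
        pct = [r.percent_correct for r in res]
        assert max(pct) - min(pct) < 20.0  # Monte-Carlo band at n=80

    def test_seed_fixed_rerun_reproduces_bitwise(self, small_cohort):
        models = [(c, W) for (c, _, W) in small_cohort[:3]]
        a = multiscale_dm(models, CouplingSpec(), 1, 5, n_trials=30, seed=7)
        b = multiscale_dm(models, CouplingSpec(), 1, 5, n_trials=30, seed=7)
        assert all((x.percent_correct, x.mean_integration_time)
                   == (y.percent_correct, y.mean_integration_time)
                   for x, y in zip(a, b))

    def test_decision_time_increases_with_mean_fc_over_bins(self,
                                                            small_cohort):
        """Models with higher mean FC have lower, more synchronous drive
        and take longer to decide (binned rank correlation > 0)."""
        from scipy.stats import spearmanr
        mfc = np.array([mean_fc(t.rho_trg) for (_, t, _) in small_cohort])
        models = [(c, W) for (c, _, W) in small_cohort]
        res = multiscale_dm(models, CouplingSpec(), pfc_node=1, ppc_node=5,
                            p=DMParams(trial_max=8000.0), n_trials=150,
                            seed=9)
        tt = np.array([r.mean_integration_time for r in res])
        order = np.argsort(mfc)
        bins = np.array_split(order, 5)
        bfc = [mfc[b].mean() for b in bins]
        bt = [tt[b].mean() for b in bins]
        assert spearmanr(bfc, bt).statistic > 0.0
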