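import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsynergy.conditions import DOSE_GRID, NMType
from radsynergy.doseresponse import DoseResponseData, LL4Params, fit_ll4, ll4_predict
from radsynergy.synergy import (
    coefficient_distance,
    ir_impulse,
    null_distance_tolerance,
    simulate_ir_curve,
    synergy_call,
    synergy_heatmap,
    transfer_impulse,
)
from radsynergy.synthdata import default_generative_params, simulate_death_dataset

GRID = np.array(DOSE_GRID)

fractions = st.floats(0, 1, allow_nan=False)


def _call_from_world(synergy_coeff, seed, n_events=10_000, nm=NMType.TIO2,
                     timepoint=72.0):
    gp = default_generative_params(nm, timepoint, synergy_coeff)
    df = simulate_death_dataset(gp, GRID, nm_type=nm, timepoint_h=timepoint,
                                n_events=n_events, n_replicates=3, seed=seed)
    ni = df[~df.irradiated]
    ir = df[df.irradiated]
    return synergy_call(
        DoseResponseData(ir.dose_surface.to_numpy(), ir.mortality.to_numpy()),
        DoseResponseData(ni.dose_surface.to_numpy(), ni.mortality.to_numpy()),
        (float(ni[ni.dose_surface == 0].mortality.mean()),
         float(ir[ir.dose_surface == 0].mortality.mean())),
    )


class TestIrImpulse:
    def test_zero_baseline_returns_ir_control_mortality(self):
        assert ir_impulse(0.255, 0.0) == pytest.approx(0.255)

    def test_no_ir_effect(self):
        assert ir_impulse(0.3, 0.3) == 0.0

    def test_closed_form(self):
        assert ir_impulse(0.634, 0.1) == pytest.approx(0.5933, abs=5e-5)

    def test_protective_ir_rejected(self):
        with pytest.raises(ValueError):
            ir_impulse(0.1, 0.2)

    def test_saturated_baseline_rejected(self):
        with pytest.raises(ValueError):
            ir_impulse(1.0, 1.0)


class TestTransferImpulse:
    def test_worked_example(self):
        assert transfer_impulse(0.2795, 0.255) == pytest.approx(0.4632, abs=5e-5)

    def test_identity_cases(self):
        assert transfer_impulse(0.37, 0.0) == pytest.approx(0.37)
        assert transfer_impulse(0.0, 0.42) == pytest.approx(0.42)

    @given(p=fractions, q=fractions, r=fractions)
    @settings(max_examples=120, deadline=None)
    def test_commutative_associative_bounded_monotone(self, p, q, r):
        assert transfer_impulse(p, q) == pytest.approx(transfer_impulse(q, p))
        left = transfer_impulse(transfer_impulse(p, q), r)
        right = transfer_impulse(p, transfer_impulse(q, r))
        assert left == pytest.approx(right, abs=1e-12)
        assert 0.0 <= left <= 1.0
        assert transfer_impulse(min(p + 0.1, 1.0), q) >= transfer_impulse(p, q) - 1e-12


class TestSimulateIrCurve:
    def test_zero_impulse_is_identity(self):
        ni = DoseResponseData(GRID, np.linspace(0.05, 0.5, 6))
        sim = simulate_ir_curve(ni, 0.0)
        np.testing.assert_allclose(sim.responses, ni.responses)

    def test_saturated_curve_stays_saturated(self):
        ni = DoseResponseData(GRID, np.ones(6))
        np.testing.assert_allclose(simulate_ir_curve(ni, 0.3).responses, 1.0)

    def test_elementwise_arithmetic(self):
        ni = DoseResponseData([0.0, 6.0, 16.0, 64.0], [0.05, 0.1, 0.2, 0.2795])
        sim = simulate_ir_curve(ni, 0.255)
        np.testing.assert_allclose(
            sim.responses, 1 - (1 - ni.responses) * (1 - 0.255))
        assert sim.responses[0] == pytest.approx(0.29225)
        assert sim.responses[-1] == pytest.approx(0.4632275)


class TestCoefficientDistance:
    def test_identical_params_zero(self):
        p = LL4Params(0.1, 0.8, 20, 1.5)
        assert coefficient_distance(p, p) == 0.0

    def test_single_coordinate_difference(self):
        a = LL4Params(0.1, 0.7, 20, 1.5)
        b = LL4Params(0.1, 0.8, 20, 1.5)
        assert coefficient_distance(a, b) == pytest.approx(0.1)

    def test_symmetric_and_log_scaled_ed50(self):
        a = LL4Params(0.1, 0.8, 10, 1.5)
        b = LL4Params(0.1, 0.8, 100, 1.5)
        d = coefficient_distance(a, b)
        assert d == pytest.approx(np.log(10))
        assert d == coefficient_distance(b, a)

    def test_custom_scaling_divides_coordinates(self):
        a = LL4Params(0.1, 0.7, 20, 1.5)
        b = LL4Params(0.1, 0.8, 20, 1.5)
        assert coefficient_distance(a, b, scaling=np.array([1, 0.05, 1, 1])) == \
            pytest.approx(2.0)


class TestSynergyCall:
    def test_observed_equal_to_simulated_scores_zero(self):
        truth = LL4Params(0.05, 0.85, 30.0, 1.5)
        ni = DoseResponseData(GRID, ll4_predict(GRID, truth))
        q = 0.255
        obs = simulate_ir_curve(ni, q)
        res = synergy_call(obs, ni, (truth.lower, transfer_impulse(truth.lower, q)))
        assert res.distance == pytest.approx(0.0, abs=1e-4)
        assert res.sign == 0
        assert res.q_ir == pytest.approx(q)

    def test_synergy_world_called_positive(self):
        res = _call_from_world(synergy_coeff=0.8, seed=0)
        assert res.sign == 1
        assert res.signed_score > 0

    def test_mismatched_grids_rejected(self):
        ni = DoseResponseData(GRID, np.linspace(0.05, 0.5, 6))
        obs = DoseResponseData(GRID[:-1], np.linspace(0.1, 0.5, 5))
        with pytest.raises(ValueError):
            synergy_call(obs, ni, (0.05, 0.3))

    def test_per_dose_delta_sign_matches_direction(self):
        res = _call_from_world(synergy_coeff=0.8, seed=3)
        nonzero = [v for d, v in res.per_dose_delta.items() if d > 0]
        assert np.mean(nonzero) > 0


class TestHeatmap:
    def test_single_cell(self):
        res = _call_from_world(0.8, seed=1, n_events=4000)
        hm = synergy_heatmap({("TiO2", 72.0): res})
        assert hm.shape == (1, 1)
        assert hm.loc["TiO2", 72.0] == pytest.approx(res.signed_score)

    def test_synergy_only_at_one_timepoint_peaks_there(self):
        results = {}
        for t, syn in ((24.0, 0.0), (48.0, 1.5), (72.0, 0.0)):
            results[("TiO2", t)] = _call_from_world(syn, seed=11, n_events=20_000,
                                                    timepoint=t)
        hm = synergy_heatmap(results)
        scores = hm.loc["TiO2"].abs()
        assert scores.idxmax() == 48.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            synergy_heatmap({})


def test_null_distance_tolerance_is_percentile():
    d = np.arange(100, dtype=float)
    assert null_distance_tolerance(d, 95) == pytest.approx(np.percentile(d, 95))
    with pytest.raises(ValueError):
        null_distance_tolerance([1.0])


def test_null_world_distance_below_calibrated_tolerance():
    """A single null-world experiment at 1e5 events/well scores below the
    95th-percentile tolerance estimated from seeded null replicates."""
    null_distances = [_call_from_world(0.0, seed=s, n_events=100_000).distance
                      for s in range(25)]
    tol = null_distance_tolerance(null_distances, 95)
    probe = _call_from_world(0.0, seed=999, n_events=100_000)
    assert probe.distance <= tol * 1.5  # probe drawn from the same null
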