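import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsynergy.conditions import NMType, SampleCondition
from radsynergy.cytometry import classify_death
from radsynergy.doseresponse import LL4Params, ll4_predict
from radsynergy.synthdata import (
    TRUE_DIOC_THRESHOLD,
    TRUE_PI_THRESHOLD,
    CtParams,
    GenerativeParams,
    default_generative_params,
    render_nuclei_field,
    simulate_death_dataset,
    simulate_events,
    simulate_growth_images,
    simulate_pcr,
    subrng,
    true_mortality,
)


class TestTrueMortality:
    def test_unexposed_control_is_baseline_asymptote(self, tio2_gp):
        c = SampleCondition(NMType.NONE, 0.0, False, timepoint_h=72.0)
        assert true_mortality(c, tio2_gp) == pytest.approx(tio2_gp.nm_ll4.lower)

    def test_null_world_is_exact_independent_action(self, tio2_gp):
        c = SampleCondition(NMType.TIO2, 64.0, True, timepoint_h=72.0)
        p_nm = ll4_predict(64.0, tio2_gp.nm_ll4)
        expected = 1 - (1 - p_nm) * (1 - tio2_gp.ir_kill)
        assert true_mortality(c, tio2_gp) == pytest.approx(expected)

    def test_worked_single_agent_combination(self):
        # p_nm = 0.2795, ir_kill = 0.255, no interaction -> 0.4632
        gp = GenerativeParams(nm_ll4=LL4Params(0.2795, 0.2795, 10.0, 1.0),
                              ir_kill=0.255)
        c = SampleCondition(NMType.TIO2, 64.0, True, timepoint_h=72.0)
        assert true_mortality(c, gp) == pytest.approx(0.4632, abs=5e-5)

    @given(dose=st.floats(0, 64), ir_kill=st.floats(0, 1), syn=st.floats(0, 2))
    @settings(max_examples=100, deadline=None)
    def test_independent_action_invariant_when_synergy_zero(self, dose, ir_kill, syn):
        curve = LL4Params(0.05, 0.85, 30.0, 1.5)
        gp = GenerativeParams(nm_ll4=curve, ir_kill=ir_kill, synergy_coeff=0.0)
        nm = NMType.TIO2 if dose > 0 else NMType.NONE
        c = SampleCondition(nm, dose if dose > 0 else 0.0, True, timepoint_h=72.0)
        p_nm = ll4_predict(c.dose_surface, curve)
        assert true_mortality(c, gp) == pytest.approx(1 - (1 - p_nm) * (1 - ir_kill))
        # interaction can only increase mortality
        gp_syn = GenerativeParams(nm_ll4=curve, ir_kill=ir_kill, synergy_coeff=syn)
        assert true_mortality(c, gp_syn) >= true_mortality(c, gp) - 1e-12


class TestSimulateEvents:
    def test_no_nanomaterial_means_no_uptake_and_baseline_ssc(self, tio2_gp):
        c = SampleCondition(NMType.NONE, 0.0, False, timepoint_h=72.0)
        t = simulate_events(c, tio2_gp, 20_000, seed=3)
        assert t.truth["uptake_fraction"] == 0.0
        # baseline log-normal: median ssc ~ 100, far below the shifted mode
        assert np.median(t.data["ssc"]) == pytest.approx(100.0, rel=0.05)

    def test_zero_mortality_world_is_all_live(self):
        gp = GenerativeParams(nm_ll4=LL4Params(0.0, 0.0, 10.0, 1.0), ir_kill=0.0)
        c = SampleCondition(NMType.TIO2, 32.0, True, timepoint_h=72.0)
        t = simulate_events(c, gp, 5_000, seed=1)
        f = classify_death(t, TRUE_DIOC_THRESHOLD, TRUE_PI_THRESHOLD)
        assert f.live == 1.0 and f.mortality == 0.0

    def test_empirical_mortality_within_binomial_error(self, flat_mortality_gp):
        n = 100_000
        c = SampleCondition(NMType.TIO2, 16.0, False, timepoint_h=72.0)
        t = simulate_events(c, flat_mortality_gp, n, seed=11)
        frac_dying = (t.truth["n_apoptotic"] + t.truth["n_dead"]) / n
        assert abs(frac_dying - 0.3) < 3 * math.sqrt(0.3 * 0.7 / n)

    def test_deterministic_given_seed(self, tio2_gp):
        c = SampleCondition(NMType.TIO2, 16.0, True, timepoint_h=72.0)
        a = simulate_events(c, tio2_gp, 1000, seed=7)
        b = simulate_events(c, tio2_gp, 1000, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.truth == b.truth

    def test_invalid_inputs_rejected(self, tio2_gp):
        c = SampleCondition(NMType.TIO2, 16.0, False, timepoint_h=72.0)
        with pytest.raises(ValueError):
            simulate_events(c, tio2_gp, 0, seed=0)


class TestGrowthImages:
    def test_day_zero_expected_count_is_plating_count(self):
        gp = GenerativeParams(nm_ll4=LL4Params(0.0, 0.0, 10.0, 1.0), ir_kill=0.0)
        c = SampleCondition(NMType.NONE, 0.0, False)
        imgs = simulate_growth_images(c, 0, gp, n_fields=3, seed=5)
        for im in imgs:
            assert im.metadata["expected_count"] == pytest.approx(gp.plating_count)

    def test_total_mortality_drives_counts_to_zero(self):
        gp = GenerativeParams(nm_ll4=LL4Params(1.0, 1.0, 10.0, 1.0), ir_kill=0.0)
        c = SampleCondition(NMType.TIO2, 32.0, False)
        for day in (0, 2, 4):
            imgs = simulate_growth_images(c, day, gp, n_fields=2, seed=5)
            assert all(im.true_count == 0 for im in imgs)

    def test_rendered_field_bookkeeps_requested_count(self):
        img = render_nuclei_field(25, rng=np.random.default_rng(2))
        assert img.true_count == 25

    def test_overfull_field_raises(self):
        with pytest.raises(ValueError):
            render_nuclei_field(500, shape=(64, 64), rng=np.random.default_rng(0))


class TestPcr:
    def test_seeded_run_is_reproducible(self, tio2_gp):
        c = SampleCondition(NMType.TIO2, 32.0, True, timepoint_h=24.0)
        a = simulate_pcr(c, tio2_gp, seed=9)
        b = simulate_pcr(c, tio2_gp, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_stress_shift_gives_analytic_fold_change(self):
        # slope 2 with stress 0.5 lowers HMOX1 Ct by 1 cycle -> fold 2
        cp = CtParams(noise_sd=0.0, ir_weight=1.0, interaction=0.0)
        gp = GenerativeParams(nm_ll4=LL4Params(0.05, 0.85, 129.0, 1.3), ct_params=cp)
        ctrl = SampleCondition(NMType.NONE, 0.0, False, timepoint_h=24.0)
        trt = SampleCondition(NMType.TIO2, 32.0, False, timepoint_h=24.0)
        ct_ctrl = simulate_pcr(ctrl, gp, seed=0)
        ct_trt = simulate_pcr(trt, gp, seed=0)

        def mean_ct(df, gene):
            return df.loc[df["gene"] == gene, "ct"].mean()

        ddct = (mean_ct(ct_trt, "HMOX1") - mean_ct(ct_trt, "GAPDH")) - (
            mean_ct(ct_ctrl, "HMOX1") - mean_ct(ct_ctrl, "GAPDH"))
        assert 2.0 ** (-ddct) == pytest.approx(2.0)

    def test_defence_genes_flat_by_default(self, tio2_gp):
        trt = SampleCondition(NMType.TIO2, 64.0, True, timepoint_h=72.0)
        df = simulate_pcr(trt, tio2_gp, seed=4)
        cp = tio2_gp.ct_params
        for gene in ("NQO1", "TXNRD1"):
            assert df.loc[df["gene"] == gene, "ct"].mean() == pytest.approx(
                cp.baseline_ct[gene], abs=0.5)


def test_default_params_apoptotic_split_decays_with_time():
    splits = [default_generative_params(NMType.TIO2, t).apoptotic_split
              for t in (24.0, 48.0, 72.0, 168.0)]
    assert splits == sorted(splits, reverse=True)


def test_subrng_streams_are_independent_and_reproducible():
    a = subrng(1, 2, 3).random(5)
    b = subrng(1, 2, 3).random(5)
    c = subrng(1, 2, 4).random(5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_death_dataset_replicates_scatter_around_truth(tio2_gp):
    df = simulate_death_dataset(tio2_gp, [0, 6, 16, 32, 48, 64],
                                n_events=10_000, n_replicates=3, seed=2)
    assert len(df) == 36
    err = (df["mortality"] - df["true_mortality"]).abs()
    assert (err < 3 * np.sqrt(0.25 / 10_000) + 0.01).all()
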