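import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from edahab.errors import ParameterError
from edahab.synthetic import (
    CohortSpec,
    GroupSpec,
    Observer,
    ScrGenParams,
    generate_cohort,
    generate_eda_trace,
    kernel_peak_time,
    make_schedule,
    observer_response,
    scr_kernel,
)


class TestMakeSchedule:
    def test_single_trial_has_single_onset(self):
        s = make_schedule(1, 3, 20, 35, seed=7, start_s=10.0)
        assert s.onsets_s == (10.0,)

    def test_degenerate_jitter_gives_constant_gaps(self):
        s = make_schedule(15, 3, 25, 25, seed=0)
        assert np.allclose(np.diff(s.onsets_s), 28.0)

    def test_protocol_gaps_within_jitter_band(self):
        s = make_schedule(15, 3, 20, 35, seed=1)
        gaps = np.diff(s.onsets_s)
        assert s.n_trials == 15 and gaps.size == 14
        assert np.all(gaps >= 23.0) and np.all(gaps <= 38.0)

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 20))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_gap_bounds_hold_for_any_seed(self, seed, n):
        s = make_schedule(n, 3.0, 20.0, 35.0, seed=seed)
        gaps = np.diff(s.onsets_s)
        assert np.all(gaps >= 23.0) and np.all(gaps <= 38.0)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ParameterError):
            make_schedule(0, 3, 20, 35)
        with pytest.raises(ParameterError):
            make_schedule(5, 3, 35, 20)


class TestScrKernel:
    def test_starts_at_zero_peaks_at_one_then_decays(self):
        dt = 0.001
        k = scr_kernel(0.75, 2.0, dt)
        assert k[0] == 0.0
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert k[-1] < 1e-3

    def test_peak_time_matches_closed_form_and_dense_scan(self):
        # closed-form argmax of exp(-t/b) - exp(-t/a)
        t_star = kernel_peak_time(0.75, 2.0)
        assert t_star == pytest.approx(1.1779, abs=1e-3)
        dt = 0.001
        k = scr_kernel(0.75, 2.0, dt)
        assert np.argmax(k) * dt == pytest.approx(t_star, abs=2 * dt)

    def test_rise_must_be_faster_than_decay(self):
        with pytest.raises(ParameterError):
            scr_kernel(2.0, 0.75)


class TestGenerateEdaTrace:
    def test_no_events_is_exact_tonic_plus_drift(self):
        s = make_schedule(3, 3, 20, 35, seed=0)
        p = ScrGenParams(noise_sd_uS=0.0, drift_uS_per_s=0.01, response_prob=0.0)
        trace, truth = generate_eda_trace(s, p, rate_hz=100)
        expected = p.tonic_level_uS + p.drift_uS_per_s * trace.times_s()
        np.testing.assert_allclose(trace.values_uS, expected, atol=1e-12)
        assert not truth["emitted"].any()

    def test_trial_amplitudes_decay_geometrically(self, clean_params):
        from dataclasses import replace

        p = replace(clean_params, initial_amplitude_uS=0.5, decay_ratio=0.8)
        s = make_schedule(6, 3, 20, 35, seed=2)
        trace, truth = generate_eda_trace(s, p, rate_hz=100)
        assert truth["amplitude_uS"][4] == pytest.approx(0.5 * 0.8**4)
        # the raw trace maximum around trial 5 reflects that amplitude
        i0 = int(truth["onset_s"][4] * 100)
        i1 = i0 + 8 * 100
        local_max = trace.values_uS[i0:i1].max() - p.tonic_level_uS
        assert local_max == pytest.approx(0.5 * 0.8**4, rel=0.02)

    def test_equal_seeds_give_bitwise_equal_traces(self):
        s = make_schedule(5, 3, 20, 35, seed=3)
        p = ScrGenParams(seed=11)
        t1, g1 = generate_eda_trace(s, p, rate_hz=100)
        t2, g2 = generate_eda_trace(s, p, rate_hz=100)
        assert np.array_equal(t1.values_uS, t2.values_uS)
        assert g1.equals(g2)

    def test_total_too_short_rejected(self):
        s = make_schedule(5, 3, 20, 35, seed=3)
        with pytest.raises(ParameterError):
            generate_eda_trace(s, ScrGenParams(), rate_hz=100, total_s=s.onsets_s[-1] + 5)

    @pytest.mark.parametrize(
        "a0,r,expected",
        [(0.5, 0.73, 9), (0.5, 0.8, 13), (0.02, 0.9, 0), (0.5, 1.0, 15)],
    )
    def test_analytic_trials_to_habituation(self, a0, r, expected):
        p = ScrGenParams(initial_amplitude_uS=a0, decay_ratio=r)
        assert p.true_trials_to_habituation(0.03, 15) == expected


class TestObserver:
    def test_step_observer_is_inclusive_at_threshold(self):
        obs = Observer(true_threshold_db=15.0)
        assert observer_response(obs, 15.0) is True
        assert observer_response(obs, 10.0) is False

    def test_sigmoid_observer_is_at_chance_at_threshold(self):
        obs = Observer(true_threshold_db=20.0, slope_db=2.0, seed=42)
        yes = sum(observer_response(obs, 20.0) for _ in range(10_000))
        assert yes / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_rates_validated(self):
        with pytest.raises(ParameterError):
            Observer(10.0, lapse_rate=0.6)


class TestGenerateCohort:
    def test_identical_group_specs_give_null_effect(self):
        g = GroupSpec(n=1500, outcomes={"aasp_auditory": (30.0, 7.0)})
        spec = CohortSpec(groups={"ASD": g, "TD": g}, rank_corr_arousal_aasp=0.0)
        coh = generate_cohort(spec, seed=0)
        from edahab.stats import cohens_d

        d = cohens_d(
            coh.loc[coh.group == "ASD", "aasp_auditory"],
            coh.loc[coh.group == "TD", "aasp_auditory"],
        )
        assert abs(d) < 0.08

    def test_questionnaire_effect_size_matches_plugin_value(self):
        groups = {
            "ASD": GroupSpec(n=2000, outcomes={"aasp_auditory": (35.61, 8.1)}),
            "TD": GroupSpec(n=2000, outcomes={"aasp_auditory": (24.94, 6.0)}),
        }
        coh = generate_cohort(CohortSpec(groups=groups), seed=1)
        from edahab.stats import cohens_d

        d = cohens_d(
            coh.loc[coh.group == "ASD", "aasp_auditory"],
            coh.loc[coh.group == "TD", "aasp_auditory"],
        )
        assert d == pytest.approx(-1.49, abs=0.1)

    def test_target_rank_correlation_recovered_within_population(self):
        g = GroupSpec(
            n=2500,
            outcomes={"aasp_auditory": (30.0, 7.0), "arousal_tone": (4.5, 1.0)},
        )
        spec = CohortSpec(groups={"ASD": g, "TD": g}, rank_corr_arousal_aasp=0.61)
        coh = generate_cohort(spec, seed=2)
        rho = spearmanr(coh["arousal_tone"], coh["aasp_auditory"]).statistic
        assert rho == pytest.approx(0.61, abs=0.05)

    def test_rows_reproducible_from_master_seed(self):
        c1 = generate_cohort(seed=9)
        c2 = generate_cohort(seed=9)
        assert c1.equals(c2)

    def test_nonresponder_fraction_realised(self):
        g = GroupSpec(n=2000, outcomes={"aasp_auditory": (30, 7)}, nonresponder_frac=0.2)
        coh = generate_cohort(CohortSpec(groups={"ASD": g, "TD": g}), seed=3)
        frac = coh["true_nonresponder"].mean()
        assert frac == pytest.approx(0.2, abs=0.02)
        assert (coh.loc[coh.true_nonresponder, "scr_response_prob"] == 0).all()
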