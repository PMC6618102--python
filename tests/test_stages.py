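import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstcount import (
    GroundTruth,
    build_trial_schedule,
    draw_profiles,
    normalize_profile,
    run_correlation_stage,
    run_entrainment_stage,
    run_success_contrast_stage,
    simulate_behaviour,
    simulate_study,
    synthesize_epochs,
)
from burstcount.simulate import Study
from burstcount.stages import behavioural_profiles, equalise_success_sets


class TestNormalizeProfile:
    def test_basic_example(self):
        np.testing.assert_allclose(normalize_profile([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_normalized_input(self):
        v = np.array([0.0, 0.3, 0.7, 1.0])
        np.testing.assert_allclose(normalize_profile(v), v)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 100), st.floats(-50, 50))
    def test_affine_invariance(self, scale, shift):
        v = np.array([1.0, 2.5, 3.0, 7.0])
        np.testing.assert_allclose(normalize_profile(v * scale + shift),
                                   normalize_profile(v), atol=1e-9)

    def test_zero_range_raises(self):
        with pytest.raises(ValueError):
            normalize_profile([3.0, 3.0, 3.0])


class TestCorrelationStage:
    def test_missing_responses_rejected(self):
        sched = build_trial_schedule(2, 1, 8, 32, seed=0)
        with pytest.raises(ValueError):
            behavioural_profiles(sched)

    def test_single_participant_reduces_to_regression(self):
        study = simulate_study(GroundTruth(), n_participants=1, n_blocks=1,
                               base_reps=8, high_prev_reps=8, seed=21)
        res = run_correlation_stage(study)
        assert res.ancova.slope_df == (1, 10)

    def test_profiles_normalized_to_unit_span(self, coupled_study):
        res = run_correlation_stage(coupled_study)
        for df in (res.spectral_norm, res.behavioural_norm):
            np.testing.assert_allclose(df.min(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(df.max(axis=1), 1.0, atol=1e-12)

    def test_positive_coupling_recovered(self, coupled_study):
        res = run_correlation_stage(coupled_study)
        assert res.ancova.slope > 0.5
        assert res.ancova.slope_p < 0.001


class TestEntrainmentStage:
    def test_matched_exceeds_unmatched_with_gain(self, coupled_study):
        res = run_entrainment_stage(coupled_study, seed=3)
        assert res.matched_minus_unmatched().mean() > 0
        assert res.anova.f_main > 0

    def test_equalised_trial_counts(self, coupled_study):
        res = run_entrainment_stage(coupled_study, seed=4)
        counts = res.trial_counts
        assert (counts[10] == 16).all() and (counts[3] == 4).all()

    def test_outlier_participant_excluded_by_chauvenet(self):
        """One participant with a huge injected entrainment gain is
        flagged and removed before the ANOVA."""
        truth0 = GroundTruth.null(evoked_amplitude=0.0)
        big = GroundTruth.null(evoked_amplitude=0.0, entrainment_gain=12.0)
        sched = build_trial_schedule(10, 1, 4, 8, seed=31)
        profs = draw_profiles(truth0, 10, seed=31)
        sched = simulate_behaviour(sched, profs, truth0, seed=32)
        epochs = {}
        for p in range(10):
            tr = big if p == 0 else truth0
            epochs[p] = synthesize_epochs(sched[sched["participant"] == p],
                                          tr, profs[p], seed=100 + p)
        study = Study(schedule=sched, epochs=epochs, profiles=profs,
                      truth=truth0, seed=0)
        res = run_entrainment_stage(study, seed=5)
        assert 0 in res.excluded
        assert res.anova.n_participants == 10 - len(res.excluded)

    def test_deterministic_output(self, coupled_study):
        a = run_entrainment_stage(coupled_study, seed=6)
        b = run_entrainment_stage(coupled_study, seed=6)
        assert json.dumps(a.to_dict(), sort_keys=True) == \
            json.dumps(b.to_dict(), sort_keys=True)


class TestNullStudyCalibration:
    def test_no_effect_data_yields_nominal_error_rates(self):
        """With g = 0 and zero couplings the entrainment main effect and
        the correlation slope reject at their nominal rates."""
        truth = GroundTruth.null()
        ent_rej = corr_rej = 0
        n_studies = 60
        for i in range(n_studies):
            study = simulate_study(truth, n_participants=12, n_blocks=1,
                                   base_reps=4, high_prev_reps=8,
                                   seed=7_000 + i)
            ent_rej += run_entrainment_stage(study, seed=i).anova.p_main < 0.05
            corr_rej += run_correlation_stage(study).ancova.slope_p < 0.05
        # 95% binomial band around 0.05 for 60 draws is ~[0, 0.12]
        assert ent_rej / n_studies <= 0.15
        assert corr_rej / n_studies <= 0.15


class TestSuccessContrastStage:
    GRID = np.arange(60.0, 82.0, 3.0)

    def test_equal_n_invariant(self, rng):
        import pandas as pd
        trials = pd.DataFrame({"correct": rng.random(60) < 0.7})
        succ, fail = equalise_success_sets(trials, rng)
        assert len(succ) == len(fail) > 0
        assert not set(succ) & set(fail)

    def test_all_correct_participant_dropped(self, coupled_study):
        study = Study(schedule=coupled_study.schedule.copy(),
                      epochs=coupled_study.epochs,
                      profiles=coupled_study.profiles,
                      truth=coupled_study.truth, seed=0)
        mask = study.schedule["participant"] == 0
        study.schedule.loc[mask, "correct"] = True
        res = run_success_contrast_stage(study, seed=7, frequencies=self.GRID,
                                         n_permutations=50)
        assert 0 in res.dropped
        assert 0 not in res.trial_counts.index

    def test_maps_on_declared_grid_and_counts_equal(self, coupled_study):
        res = run_success_contrast_stage(coupled_study, seed=8,
                                         frequencies=self.GRID,
                                         n_permutations=50)
        nf, nt = res.amplitude_raw.stat_map.shape
        assert nf == self.GRID.size
        assert nt == res.times.size
        for name in ("amplitude_baselined", "plv_difference", "phase_angle"):
            assert getattr(res, name).stat_map.shape == (nf, nt)
        assert (res.trial_counts > 0).all()
        for cond in ("successful", "unsuccessful"):
            assert res.rayleigh[cond]["p"].shape == (nf, nt)

    def test_deterministic_output(self, coupled_study):
        kw = dict(seed=9, frequencies=self.GRID, n_permutations=50)
        a = run_success_contrast_stage(coupled_study, **kw)
        b = run_success_contrast_stage(coupled_study, **kw)
        assert json.dumps(a.to_dict(), sort_keys=True) == \
            json.dumps(b.to_dict(), sort_keys=True)
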