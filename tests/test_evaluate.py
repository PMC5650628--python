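import math

import numpy as np
import pytest

from seqcca.cca import train_filter_model
from seqcca.decode import DecodingResult, predict
from seqcca.evaluate import (
    component_similarity,
    decoding_accuracy,
    difference_wave,
    group_mean_similarity,
    leave_one_run_out_cv,
    leave_one_subject_out,
    online_simulation,
    permutation_chance,
    pooled_transfer_curve,
    select_pool,
    truncate_stimuli,
    wolpaw_itr,
)
from seqcca.simulate import eeg_preset, simulate_dataset


def fake_result(predicted, true):
    m = 12
    scores = np.zeros(m)
    scores[predicted] = 1.0
    return DecodingResult(
        scores=scores,
        ranking=np.argsort(-scores, kind="stable"),
        predicted=predicted,
        true_target=true,
    )


class TestAccuracy:
    def test_all_correct(self):
        assert decoding_accuracy([fake_result(3, 3)] * 5) == 1.0

    def test_eleven_of_twelve(self):
        results = [fake_result(i, i) for i in range(11)] + [fake_result(0, 1)]
        assert decoding_accuracy(results) == pytest.approx(11 / 12)

    def test_chance_over_random_predictions(self):
        rng = np.random.default_rng(0)
        results = [
            fake_result(int(rng.integers(12)), int(rng.integers(12)))
            for _ in range(10_000)
        ]
        assert decoding_accuracy(results) == pytest.approx(1 / 12, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            decoding_accuracy([])


class TestITR:
    def test_perfect_accuracy_closed_form(self):
        assert wolpaw_itr(1.0, 12, 10.0, 2.5) == pytest.approx(
            math.log2(12) * 60 / 12.5, abs=1e-12
        )

    def test_chance_gives_zero(self):
        assert wolpaw_itr(1 / 12, 12, 10.0, 2.5) == pytest.approx(0.0, abs=1e-12)

    def test_against_symbolic_oracle(self):
        import sympy

        P = sympy.Rational(911, 1000)
        N = 12
        B = (
            sympy.log(N, 2)
            + P * sympy.log(P, 2)
            + (1 - P) * sympy.log((1 - P) / (N - 1), 2)
        )
        expected = float(B * 60 / sympy.Rational(125, 10))
        assert wolpaw_itr(0.911, 12, 10.0, 2.5) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_above_chance(self):
        grid = np.linspace(1 / 12, 1.0, 25)
        vals = [wolpaw_itr(p, 12, 10.0, 2.5) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_degenerate_inputs(self):
        assert wolpaw_itr(0.0, 12, 10.0, 2.5) >= 0.0
        with pytest.raises(ValueError):
            wolpaw_itr(0.5, 1, 10.0)


class TestLeaveOneRunOut:
    def test_high_snr_accuracy(self, tiny_dataset):
        report = leave_one_run_out_cv(tiny_dataset.trials)
        assert report.da > 0.9

    def test_deterministic_and_order_invariant(self, tiny_dataset):
        r1 = leave_one_run_out_cv(tiny_dataset.trials)
        r2 = leave_one_run_out_cv(tiny_dataset.trials)
        r3 = leave_one_run_out_cv(tiny_dataset.trials[::-1])
        assert r1.da == r2.da == r3.da

    def test_zero_signal_is_at_chance(self):
        cfg = eeg_preset(
            n_objects=4, n_reps=3, n_channels=8, trials_per_run=8, n_runs=3,
            snr=0.0, seed=21,
        )
        ds = simulate_dataset(cfg)
        report = leave_one_run_out_cv(ds.trials)
        # 24 trials at chance 1/4: 99% binomial interval
        assert 0.02 <= report.da <= 0.5

    def test_needs_two_runs(self, tiny_dataset):
        one_run = [t for t in tiny_dataset.trials if t.run_id == 0]
        with pytest.raises(ValueError):
            leave_one_run_out_cv(one_run)


class TestOnline:
    def test_curve_and_first_trial_initial_model(self, tiny_dataset):
        from seqcca.cca import initial_filter_model

        trials = tiny_dataset.trials
        report = online_simulation(trials)
        assert len(report.curves["correct"]) == len(trials)
        first = predict(trials[0], initial_filter_model(trials[0].n_channels, 41))
        assert report.curves["correct"][0] == (first.predicted == trials[0].target)
        # learning: later accuracy beats the cold start on a high-SNR subject
        second_half = np.mean(report.curves["correct"][len(trials) // 2 :])
        assert second_half > 0.8

    def test_update_schedules_share_final_state(self, tiny_dataset):
        trials = tiny_dataset.trials
        m_all = train_filter_model(trials)
        m_again = train_filter_model(trials)
        np.testing.assert_allclose(m_all.W, m_again.W)


@pytest.fixture(scope="module")
def cohort():
    cfg = eeg_preset(
        n_objects=4, n_reps=3, n_channels=8, trials_per_run=8, n_runs=2,
        n_subjects=3, snr=1.2, subject_variability=0.1, seed=31,
    )
    return simulate_dataset(cfg)


class TestTransfer:
    def test_loso_shared_topography(self, cohort):
        report = leave_one_subject_out(cohort.by_subject())
        assert set(report.per_subject) == {0, 1, 2}
        assert report.da > 0.8

    def test_loso_layout_mismatch(self, cohort):
        from seqcca.preprocess import TrialData

        by = cohort.by_subject()
        tr = by[1][0]
        shrunk = TrialData(
            X=tr.X[:, :4], fs=tr.fs, schedule=tr.schedule, target=tr.target,
            run_id=tr.run_id, subject_id=tr.subject_id,
        )
        bad = {0: by[0], 1: [shrunk] + by[1][1:]}
        with pytest.raises(ValueError):
            leave_one_subject_out(bad)

    def test_single_heldout_trial(self, cohort):
        by = cohort.by_subject()
        small = {0: by[0], 1: by[1][:1]}
        report = leave_one_subject_out(small)
        assert 1 in report.per_subject

    def test_pool_selection_prefers_reliable_trials(self, cohort):
        by = cohort.by_subject()
        donor_model = train_filter_model(by[0])
        cands = by[1]
        pool = select_pool(cands, donor_model, n_pool=4)
        assert len(pool) == 4
        from seqcca.evaluate import trial_score

        chosen = {trial_score(t, donor_model) for t in pool}
        others = [trial_score(t, donor_model) for t in cands if trial_score(t, donor_model) not in chosen]
        assert min(chosen) >= max(others)

    def test_pooled_transfer_reaches_full_substitution(self, cohort):
        by = cohort.by_subject()
        donor_model = train_filter_model(by[0])
        pool = select_pool(by[0], donor_model, n_pool=6)
        report = pooled_transfer_curve(by[1], pool)
        assert report.curves["n_pool_used"][0] == 6
        assert report.curves["n_pool_used"][-1] == 0  # purely individual data
        assert report.da > 0.5


class TestPermutation:
    def test_single_permutation_valid(self, tiny_dataset):
        summary = permutation_chance(tiny_dataset.trials, n_perm=1, seed=0)
        assert summary["n_perm"] == 1
        assert summary["ci95"][0] == summary["ci95"][1] == summary["mean"]

    def test_relabeled_mean_near_chance(self):
        cfg = eeg_preset(
            n_objects=4, n_reps=3, n_channels=6, trials_per_run=8, n_runs=2,
            snr=0.0, seed=41,
        )
        ds = simulate_dataset(cfg)
        summary = permutation_chance(ds.trials, n_perm=30, seed=1)
        assert summary["mean"] == pytest.approx(0.25, abs=0.06)

    def test_real_signal_beats_permutation_bound(self, tiny_dataset):
        real = leave_one_run_out_cv(tiny_dataset.trials).da
        summary = permutation_chance(tiny_dataset.trials, n_perm=20, seed=2)
        assert real > summary["ci95"][1]


class TestTruncate:
    def test_full_reps_identity(self, eeg_dataset):
        tr = eeg_dataset.trials[0]
        assert truncate_stimuli(tr, 5) is tr

    def test_one_rep_geometry(self, eeg_dataset):
        tr = truncate_stimuli(eeg_dataset.trials[0], 1)
        assert tr.schedule.n_flashes == 12
        expected = round((11 / 6 + 0.8) * tr.fs)
        assert abs(tr.n_samples - expected) <= 1

    def test_accuracy_grows_with_repetitions(self, tiny_dataset):
        from seqcca.evaluate import truncate_dataset

        full = leave_one_run_out_cv(tiny_dataset.trials).da
        short = leave_one_run_out_cv(truncate_dataset(tiny_dataset.trials, 1)).da
        assert full >= short - 0.05

    def test_bad_reps(self, eeg_dataset):
        with pytest.raises(ValueError):
            truncate_stimuli(eeg_dataset.trials[0], 0)
        with pytest.raises(ValueError):
            truncate_stimuli(eeg_dataset.trials[0], 6)


class TestSimilarity:
    def test_identical_and_negated(self):
        s = np.sin(np.linspace(0, 3, 41))
        assert component_similarity(s, s) == pytest.approx(1.0)
        assert component_similarity(s, -s) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            component_similarity(np.ones(10), np.arange(10.0))

    def test_group_mean_back_transform(self):
        rs = [0.8, 0.9, 0.85]
        expected = np.tanh(np.mean(np.arctanh(rs)))
        assert group_mean_similarity(rs) == pytest.approx(expected)

    def test_consistency_across_synthetic_subjects(self):
        cfg = eeg_preset(
            n_objects=4, n_reps=3, n_channels=8, trials_per_run=8, n_runs=2,
            n_subjects=4, snr=1.2, subject_variability=0.0, seed=51,
        )
        ds = simulate_dataset(cfg)
        filters = [
            train_filter_model(trs).S[:, 0] for trs in ds.by_subject().values()
        ]
        rs = [
            abs(component_similarity(filters[0], f)) for f in filters[1:]
        ]
        assert min(rs) > 0.9


class TestDifferenceWave:
    def test_recovers_planted_template(self, eeg_dataset, trained_model):
        out = difference_wave(eeg_dataset.trials, model=trained_model)
        peak_t = out["times"][np.argmax(np.abs(out["difference"][:, 0]))]
        planted = eeg_dataset.subjects[0].latency
        fs = eeg_dataset.trials[0].fs
        assert abs(peak_t - planted) <= 2 / fs + 1e-9

    def test_common_oscillation_cancels(self):
        cfg = eeg_preset(
            n_objects=4, n_reps=3, n_channels=6, trials_per_run=8, n_runs=1,
            snr=0.0, ssvep_amp=2.0, noise_white=0.05, noise_pink=0.0, seed=61,
        )
        ds = simulate_dataset(cfg)
        out = difference_wave(ds.trials)
        single_cond = np.abs(out["ignored"]).max()
        diff = np.abs(out["difference"]).max()
        assert diff < 0.15 * single_cond

    def test_needs_labels(self, eeg_dataset):
        import dataclasses

        unlabeled = [dataclasses.replace(eeg_dataset.trials[0], target=None)]
        with pytest.raises(ValueError):
            difference_wave(unlabeled)
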