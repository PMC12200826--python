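"""Synthetic-cohort generator: schedule structure, agent behaviour,
hypnograms and EEG synthesis."""

import numpy as np
import pytest

from napinsight import simulate, spectral
from napinsight.simulate import (
    AgentParams,
    EEGSimParams,
    generate_task_schedule,
    simulate_agent_responses,
    simulate_cohort,
    simulate_eeg,
    simulate_hypnogram,
)

from conftest import single_channel_params


class TestTaskSchedule:
    def test_block_composition(self, schedule):
        trials = schedule.trials
        assert len(trials) == 900
        assert all(t.coherence == 1.0 for t in trials if t.block == 1)
        assert {t.coherence for t in trials if t.block == 2} <= {0.41, 0.59, 0.76}
        for block in range(3, 10):
            blk = [t.coherence for t in trials if t.block == block]
            counts = {c: blk.count(c) for c in set(blk)}
            assert counts == {0.05: 30, 0.23: 10, 0.41: 20, 0.59: 20, 0.76: 20}

    def test_phase_markers(self, schedule):
        for t in schedule.trials:
            assert t.colour_predictive == (t.trial_index >= 351)
            assert t.instructed == (t.block == 9)

    def test_colour_maps_to_diagonal_when_predictive(self, schedule):
        for t in schedule.trials:
            if t.colour_predictive:
                expected = "orange" if t.direction in ("NW", "SE") else "purple"
                assert t.colour == expected

    def test_seed_changes_order_not_composition(self):
        s1, s2 = generate_task_schedule(1), generate_task_schedule(2)
        for block in range(1, 10):
            c1 = sorted(t.coherence for t in s1.trials if t.block == block)
            c2 = sorted(t.coherence for t in s2.trials if t.block == block)
            assert c1 == c2
        assert [t.coherence for t in s1.trials] != [t.coherence for t in s2.trials]

    def test_determinism(self):
        a, b = generate_task_schedule(7), generate_task_schedule(7)
        assert [(t.coherence, t.direction, t.colour) for t in a.trials] == [
            (t.coherence, t.direction, t.colour) for t in b.trials
        ]


class TestAgent:
    def test_noiseless_ceiling(self, schedule):
        agent = AgentParams(is_insight=False, lapse=0.0)
        sess = simulate_agent_responses(schedule, agent, seed=0)
        block1 = [t for t in sess.trials if t.block == 1]
        assert all(t.correct for t in block1)  # p_motion(1.0)=1, lapse=0

    def test_step_limit_of_sigmoid(self, schedule):
        agent = AgentParams(is_insight=True, t_s_true=500, m_true=50.0, lapse=0.0)
        accs_pre, accs_post = [], []
        for seed in range(30):
            sess = simulate_agent_responses(schedule, agent, seed=seed)
            accs_pre.append(sess.accuracy(coherence=0.05, trial_range=(420, 495)))
            accs_post.append(sess.accuracy(coherence=0.05, trial_range=(505, 580)))
        assert np.nanmean(accs_pre) == pytest.approx(0.562, abs=0.05)
        assert np.nanmean(accs_post) == pytest.approx(0.97, abs=0.04)

    def test_low_coherence_calibration(self, schedule):
        # effective pre-switch accuracy at the noisiest level is ~56%
        agent = AgentParams(is_insight=False, lapse=0.03)
        n = correct = 0
        for seed in range(100):
            sess = simulate_agent_responses(schedule, agent, seed=seed)
            pre = [t.correct for t in sess.trials
                   if t.coherence == 0.05 and t.trial_index < 351]
            n += len(pre)
            correct += sum(pre)
        assert n >= 4000
        assert correct / n == pytest.approx(0.56, abs=0.02)

    def test_accuracy_monotone_in_coherence(self, schedule):
        agent = AgentParams(is_insight=False, lapse=0.02)
        by_level = {c: [] for c in (0.05, 0.23, 0.41, 0.59, 0.76)}
        for seed in range(10):
            sess = simulate_agent_responses(schedule, agent, seed=seed)
            for t in sess.trials:
                if t.block in range(3, 9) and t.coherence in by_level:
                    by_level[t.coherence].append(t.correct)
        means = [np.mean(by_level[c]) for c in sorted(by_level)]
        assert all(b > a - 0.02 for a, b in zip(means, means[1:]))

    def test_invalid_insight_switch_time(self, schedule):
        with pytest.raises(ValueError, match="351"):
            simulate_agent_responses(
                schedule, AgentParams(is_insight=True, t_s_true=100), seed=0
            )

    @pytest.mark.parametrize("bad", [{"lapse": 0.2}, {"p_colour": 0.3},
                                     {"m_true": -1.0}])
    def test_invalid_agent_params(self, bad):
        with pytest.raises(ValueError):
            AgentParams(is_insight=True, **bad)


class TestHypnogram:
    def test_wake_group_is_pure_wake(self):
        hyp = simulate_hypnogram("Wake", seed=0)
        assert hyp.epoch_labels == ["W"] * 40

    def test_min_n2_duration_knob(self):
        for seed in range(20):
            hyp = simulate_hypnogram("N2", seed=seed, min_n2_minutes=2.0)
            assert hyp.count("N2") >= 4

    @pytest.mark.parametrize("group", ["Wake", "N1", "N2"])
    def test_deepest_stage_matches_group(self, group):
        for seed in range(1000):
            hyp = simulate_hypnogram(group, seed=seed)
            assert hyp.group_label() == group
            assert len(hyp.epoch_labels) == 40

    def test_unknown_group(self):
        with pytest.raises(ValueError):
            simulate_hypnogram("REM", seed=0)


class TestEEG:
    def test_white_noise_limit(self, wake_hypnogram):
        rec = simulate_eeg(wake_hypnogram, single_channel_params(x=0.0), seed=11)
        spec = spectral.subject_spectra(rec)
        fit = spectral.fit_spectral_model(spec.frequencies, spec.row("F4"))
        assert abs(fit.exponent) < 0.05

    def test_determinism(self, wake_hypnogram):
        p = single_channel_params()
        a = simulate_eeg(wake_hypnogram, p, seed=5)
        b = simulate_eeg(wake_hypnogram, p, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_duration_and_units(self, wake_hypnogram):
        rec = simulate_eeg(wake_hypnogram, single_channel_params(), seed=1)
        assert rec.duration == pytest.approx(1200.0)
        assert np.all(np.isfinite(rec.samples))

    def test_nyquist_guard(self, wake_hypnogram):
        p = EEGSimParams(
            sampling_rate=60.0,
            channels={"F4": (0.4, 0.55)},
            stage_aperiodic={"W": (1.0, 1.0)},
            stage_peaks={"W": [(40.0, 0.5, 1.0)]},
        )
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_eeg(wake_hypnogram, p, seed=0)

    def test_stage_order_preserved_in_fits(self):
        # steeper generating exponent -> steeper fitted slope, every seed
        for seed in range(6):
            hyp = simulate.Hypnogram(["W"] * 40)
            slopes = {}
            for x in (1.37, 1.79):
                rec = simulate_eeg(hyp, single_channel_params(x=x), seed=seed)
                spec = spectral.subject_spectra(rec)
                slopes[x] = spectral.fit_spectral_model(
                    spec.frequencies, spec.row("F4")
                ).slope
            assert slopes[1.79] < slopes[1.37]


class TestCohort:
    def test_zero_rate_means_no_insight(self):
        cohort = simulate_cohort(
            seed=1, n_per_group={"N2": 3, "N1": 3, "Wake": 3},
            insight_rates={"N2": 0.0, "N1": 0.0, "Wake": 0.0}, with_eeg=False,
        )
        assert not any(s.truth["is_insight"] for s in cohort)

    def test_quota_mode_matches_expected_insight_count(self):
        cohort = simulate_cohort(seed=3, quota=True, with_eeg=False)
        assert sum(s.truth["is_insight"] for s in cohort) == 48
        by_group = {}
        for s in cohort:
            by_group.setdefault(s.group, []).append(s.truth["is_insight"])
        assert sum(by_group["N2"]) == 24
        assert sum(by_group["N1"]) == 14
        assert sum(by_group["Wake"]) == 10

    def test_counter_based_streams_are_stable_under_growth(self):
        small = simulate_cohort(
            seed=5, n_per_group={"N2": 2, "N1": 2, "Wake": 2}, with_eeg=False
        )
        large = simulate_cohort(
            seed=5, n_per_group={"N2": 4, "N1": 4, "Wake": 4}, with_eeg=False
        )
        by_id = {s.subject_id: s for s in large}
        for s in small:
            t = by_id[s.subject_id]
            assert s.truth["t_s_true"] == t.truth["t_s_true"]
            assert [x.correct for x in s.session.trials] == [
                x.correct for x in t.session.trials
            ]

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(seed=1, insight_rates={"N2": 1.5, "N1": 0, "Wake": 0})

    def test_mean_preserving_insight_coupling(self):
        cohort = simulate_cohort(
            seed=9, n_per_group={"N2": 40, "N1": 0, "Wake": 0},
            insight_rates={"N2": 0.5, "N1": 0, "Wake": 0},
            quota=True, with_eeg=False, slope_subject_sd=0.0,
            slope_insight_effect=0.25,
        )
        dx = np.array([s.truth["exponent_offset"] for s in cohort])
        ins = np.array([s.truth["is_insight"] for s in cohort])
        assert dx[ins].mean() - dx[~ins].mean() == pytest.approx(0.25)
        assert dx.mean() == pytest.approx(0.0, abs=1e-12)
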