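import numpy as np
import pytest

from ecochg.features import falling_edge_mask
from ecochg.processing import DEFAULT_HARMONIC_PAIRS, extract_series, inclusion_check
from ecochg.simulate import (
    CohortConfig,
    generate_cohort,
    generate_recording,
    generate_trajectory,
    render_waveforms,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"drop_depth": -0.1},
            {"drop_depth": 0.5, "drop_depth_max": 0.4},
            {"baseline_cm_range": (0.0, 5.0)},
            {"noise_sd": -1.0},
            {"drop_prob": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestTrajectories:
    CFG = CohortConfig(n_timepoints=60, seed=0)

    def test_no_drop_trajectory_never_drops_30_percent(self):
        rng = np.random.default_rng(3)
        lmax = self.CFG.drop_length[1]
        for _ in range(20):
            amp, intervals = generate_trajectory(self.CFG, rng, with_drop=False)
            assert intervals == ()
            assert (amp > 0).all()
            for t in range(1, amp.size):
                recent_max = amp[max(0, t - lmax) : t].max()
                assert amp[t] > (1 - self.CFG.drop_depth) * recent_max

    def test_injected_drop_depth_and_monotonicity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            amp, intervals = generate_trajectory(self.CFG, rng, with_drop=True)
            assert len(intervals) == 1
            a, b = intervals[0]
            onset = a - 1
            assert amp[b] <= (1 - self.CFG.drop_depth) * amp[onset] + 1e-12
            assert (np.diff(amp[onset : b + 1]) < 0).all()

    def test_fixed_seed_reproducible(self):
        a1, i1 = generate_trajectory(self.CFG, np.random.default_rng(9))
        a2, i2 = generate_trajectory(self.CFG, np.random.default_rng(9))
        np.testing.assert_array_equal(a1, a2)
        assert i1 == i2

    def test_half_depth_drop_arithmetic(self):
        cfg = CohortConfig(
            n_timepoints=60, drop_depth=0.5, drop_depth_max=0.5, seed=0
        )
        amp, ((a, b),) = generate_trajectory(cfg, np.random.default_rng(5), with_drop=True)
        assert amp[b] == pytest.approx(0.5 * amp[a - 1])


class TestRendering:
    def test_noiseless_round_trip_recovers_amplitudes(self):
        cfg = CohortConfig(n_timepoints=20, noise_sd=0.0, seed=0)
        rng = np.random.default_rng(1)
        cm = rng.uniform(2, 20, 5)
        ann = 0.2 * cm
        rec = render_waveforms(cm, ann, None, cfg, rng)
        series = extract_series(rec)
        for i, pair in enumerate(DEFAULT_HARMONIC_PAIRS):
            scale = cfg.harmonic_decay**i
            got_cm = np.array([m.cm_amp for m in series[pair]])
            got_ann = np.array([m.ann_amp for m in series[pair]])
            np.testing.assert_allclose(got_cm, cm * scale, atol=1e-9)
            np.testing.assert_allclose(got_ann, ann * scale, atol=1e-9)

    def test_zero_ann_fraction_gives_noise_only_sum(self):
        cfg = CohortConfig(n_timepoints=20, noise_sd=0.0, seed=0)
        rng = np.random.default_rng(1)
        rec = render_waveforms(np.array([5.0]), np.array([0.0]), None, cfg, rng)
        m = extract_series(rec)[(500.0, 1000.0)][0]
        assert m.ann_amp < 1e-12

    def test_ann_rendered_at_second_harmonic(self):
        cfg = CohortConfig(n_timepoints=20, noise_sd=0.0, harmonic_decay=0.0, seed=0)
        rng = np.random.default_rng(1)
        rec = render_waveforms(np.array([0.0]), np.array([2.0]), None, cfg, rng)
        m = extract_series(rec)[(500.0, 1000.0)][0]
        assert m.cm_amp < 1e-12 and m.ann_amp == pytest.approx(2.0, abs=1e-9)


class TestCohorts:
    def test_cohort_reproducible_and_sized(self):
        cfg = CohortConfig(n_patients=6, n_timepoints=30, seed=21)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        assert len(c1.recordings) == 6
        assert [r.patient_id for r in c1.recordings] == [r.patient_id for r in c2.recordings]
        for r1, r2 in zip(c1.recordings, c2.recordings):
            np.testing.assert_array_equal(r1.windows[0].rarefaction, r2.windows[0].rarefaction)

    def test_drop_patient_count_meets_probability(self):
        cfg = CohortConfig(n_patients=10, n_timepoints=30, drop_prob=0.3, seed=2)
        cohort = generate_cohort(cfg)
        assert len(cohort.drop_patients) == 3  # ceil(10 * 0.3)

    def test_single_patient_cohort(self):
        cfg = CohortConfig(n_patients=1, n_timepoints=30, drop_prob=1.0, seed=2)
        cohort = generate_cohort(cfg)
        assert len(cohort.recordings) == 1
        assert cohort.annotations["P000"].has_drop

    def test_annotated_drops_lie_on_falling_edges(self):
        cfg = CohortConfig(n_patients=6, n_timepoints=40, drop_prob=1.0, seed=13)
        cohort = generate_cohort(cfg)
        for rec in cohort.recordings:
            ms = extract_series(rec, DEFAULT_HARMONIC_PAIRS[:1])[(500.0, 1000.0)]
            amps = np.array([m.cm_amp for m in ms])
            falling = falling_edge_mask(amps)
            for a, b in cohort.annotations[rec.patient_id].intervals:
                assert falling[a : b + 1].all()

    def test_annotation_starts_after_reaction_delay(self):
        cfg = CohortConfig(n_patients=4, n_timepoints=40, drop_prob=1.0, seed=3)
        cohort = generate_cohort(cfg)
        for pid, gt in cohort.truth.items():
            (ga, gb) = gt.intervals[0]
            (aa, ab) = cohort.annotations[pid].intervals[0]
            assert aa == min(ga + cfg.reaction_delay, gb)
            assert ab == gb

    def test_low_amplitude_cohort_fails_inclusion(self):
        cfg = CohortConfig(
            n_patients=3, n_timepoints=20, baseline_cm_range=(0.1, 0.5), seed=4
        )
        cohort = generate_cohort(cfg)
        assert all(not inclusion_check(r)[0] for r in cohort.recordings)

    def test_normal_amplitude_cohort_passes_inclusion(self):
        cfg = CohortConfig(
            n_patients=3, n_timepoints=20, baseline_cm_range=(5.0, 6.0), seed=4
        )
        cohort = generate_cohort(cfg)
        assert all(inclusion_check(r)[0] for r in cohort.recordings)
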