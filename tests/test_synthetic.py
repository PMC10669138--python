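import numpy as np
import pytest
from scipy import stats as sps

from wormchrono import synthetic as syn


class TestTrueProfile:
    def test_all_amplitudes_zero_gives_constant_baseline(self):
        cfg = syn.PopulationConfig(gonad_amplitude=0, head_marker_amplitude=0, baseline=7.0)
        np.testing.assert_array_equal(syn.true_profile(50, cfg), np.full(50, 7.0))

    def test_no_gonad_bump_below_onset(self):
        cfg = syn.PopulationConfig()
        length = int(cfg.gonad_onset_length)  # at the threshold: still no bump
        prof = syn.true_profile(length, cfg)
        x = np.linspace(0, 1, length)
        head_only = cfg.baseline + cfg.head_marker_amplitude * np.exp(
            -0.5 * ((x - syn.HEAD_CENTER) / syn.HEAD_WIDTH) ** 2)
        np.testing.assert_allclose(prof, head_only, rtol=1e-12)

    def test_gonad_peak_position_at_default_center(self):
        cfg = syn.PopulationConfig()
        length = 400
        x = np.linspace(0, 1, length)
        head = cfg.head_marker_amplitude * np.exp(-0.5 * ((x - syn.HEAD_CENTER) / syn.HEAD_WIDTH) ** 2)
        residual = syn.true_profile(length, cfg) - head
        assert abs(int(np.argmax(residual)) - round(0.55 * (length - 1))) <= 1

    def test_gonad_signal_ramps_with_length(self):
        cfg = syn.PopulationConfig()
        peaks = [syn.true_profile(L, cfg).max() for L in (251, 270, 290, 310)]
        assert peaks == sorted(peaks)
        assert syn.gonad_growth_factor(int(cfg.gonad_onset_length + cfg.gonad_ramp_length), cfg) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            syn.true_profile(1, syn.PopulationConfig())


class TestSimulatePopulation:
    def test_empty_config_gives_empty_outputs(self):
        ds, truth = syn.simulate_population(syn.PopulationConfig(n_worms=0))
        assert len(ds) == 0 and truth.empty

    def test_seed_determinism(self):
        cfg = syn.PopulationConfig(n_worms=50, seed=9, bubble_rate=0.05, debris_rate=0.05)
        a, ta = syn.simulate_population(cfg)
        b, tb = syn.simulate_population(cfg)
        assert a == b
        assert ta.equals(tb)

    def test_noise_free_limit_reproduces_true_profile(self):
        cfg = syn.PopulationConfig(n_worms=20, seed=1, noise_sd=0.0, flip_probability=0.0)
        ds, truth = syn.simulate_population(cfg)
        for row in truth.itertuples():
            expected = syn.true_profile(row.true_length, cfg,
                                        gonad_amplitude=row.true_gonad_amplitude)
            np.testing.assert_array_equal(ds.profiles[row.event_id].samples, expected)

    def test_tof_matches_sample_count_and_ground_truth(self):
        cfg = syn.PopulationConfig(n_worms=30, seed=2)
        ds, truth = syn.simulate_population(cfg)
        tof = {e.event_id: e.tof for e in ds.events}
        for row in truth.itertuples():
            assert tof[row.event_id] == row.true_length
            assert len(ds.profiles[row.event_id]) == row.true_length

    def test_log_length_marginal_recovered(self):
        cfg = syn.PopulationConfig(n_worms=10_000, seed=5)
        ds, _ = syn.simulate_population(cfg)
        log_tof = np.log([e.tof for e in ds.events])
        se = cfg.length_log_sd / np.sqrt(cfg.n_worms)
        assert abs(log_tof.mean() - cfg.length_log_mean) < 3 * se + 1e-3

    def test_growth_delay_shifts_lengths_down(self):
        ctrl, _ = syn.simulate_population(syn.PopulationConfig.control(2000, seed=3))
        irr, _ = syn.simulate_population(syn.PopulationConfig.irradiated(2000, seed=4))
        assert np.median([e.tof for e in irr.events]) < np.median([e.tof for e in ctrl.events])

    def test_gonad_reduction_strictly_lowers_expected_green(self):
        # noise-free monotonicity of the effect model
        length = 400
        means = []
        for reduction in (1.0, 0.6, 0.3, 0.0):
            cfg = syn.PopulationConfig(noise_sd=0.0, gonad_reduction=reduction)
            means.append(syn.true_profile(
                length, cfg, gonad_amplitude=cfg.gonad_amplitude * reduction).max())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_flip_fraction_near_half(self):
        _, truth = syn.simulate_population(syn.PopulationConfig(n_worms=2000, seed=6))
        frac = truth.was_flipped.mean()
        assert 0.45 < frac < 0.55


class TestArtifacts:
    def test_rate_zero_leaves_dataset_unchanged(self):
        cfg = syn.PopulationConfig(n_worms=10, seed=0)
        ds, _ = syn.simulate_population(cfg)
        out, truth_rows = syn.inject_artifacts(ds, cfg)
        assert out == ds and truth_rows == []

    def test_debris_always_below_length_filter(self):
        cfg = syn.PopulationConfig(n_worms=200, seed=8, debris_rate=0.2)
        ds, truth = syn.simulate_population(cfg)
        debris = truth[truth.event_id.str.startswith("deb")]
        assert len(debris) > 0
        for eid in debris.event_id:
            assert len(ds.profiles[eid]) < 80

    def test_bubbles_exceed_ext_tof_threshold(self):
        cfg = syn.PopulationConfig(n_worms=200, seed=8, bubble_rate=0.2)
        ds, truth = syn.simulate_population(cfg)
        bubbles = {e.event_id: e for e in ds.events if e.event_id.startswith("bub")}
        assert len(bubbles) > 0
        for e in bubbles.values():
            assert e.tof < 30 and e.ext / e.tof > 10

    def test_artifact_count_within_binomial_interval(self):
        cfg = syn.PopulationConfig(n_worms=1000, seed=13, debris_rate=0.1)
        _, truth = syn.simulate_population(cfg)
        count = int(truth.is_artifact.sum())
        lo = sps.binom.ppf(0.005, 1000, 0.1)
        hi = sps.binom.ppf(0.995, 1000, 0.1)
        assert lo <= count <= hi

    def test_originals_untouched(self):
        cfg = syn.PopulationConfig(n_worms=50, seed=21, bubble_rate=0.1, debris_rate=0.1)
        base, _ = syn.simulate_population(syn.PopulationConfig(n_worms=50, seed=21))
        augmented, _ = syn.simulate_population(cfg)
        worm_ids = {e.event_id for e in base.events}
        assert {e.event_id for e in augmented.events if e.event_id.startswith("w")} == worm_ids
        for eid in worm_ids:
            assert augmented.profiles[eid] == base.profiles[eid]


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = syn.PopulationConfig.irradiated(123, seed=77, gonad_reduction=0.4)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert syn.PopulationConfig.from_yaml(tmp_path / "c.yaml") == cfg

    @pytest.mark.parametrize("kw", [
        {"flip_probability": 1.5}, {"n_worms": -1}, {"noise_sd": -0.1},
        {"gonad_center": 0.0}, {"agenesis_fraction": -0.2},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            syn.PopulationConfig(**kw)
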