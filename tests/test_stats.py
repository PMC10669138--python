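import numpy as np
import pytest

from wormchrono import pipeline as pl
from wormchrono import stats as ws
from wormchrono import synthetic as syn
from wormchrono.copas_io import ProfileRecord, PopulationDataset
from conftest import make_dataset


class TestLengthDistribution:
    def test_half_open_bins(self):
        ds = make_dataset({
            "a": (np.ones(5), 100.0, 50.0),
            "b": (np.ones(5), 150.0, 75.0),
            "c": (np.ones(5), 210.0, 105.0),
        })
        hist = ws.length_distribution(ds, 100.0)
        assert list(hist.edges) == [100.0, 200.0, 300.0]
        assert list(hist.counts) == [2, 1]

    def test_boundary_value_goes_right(self):
        ds = make_dataset({"a": (np.ones(5), 200.0, 10.0)})
        hist = ws.length_distribution(ds, 100.0)
        assert list(hist.edges) == [200.0, 300.0] and list(hist.counts) == [1]

    def test_empty_dataset(self):
        hist = ws.length_distribution(make_dataset({}), 25.0)
        assert hist.counts.size == 0

    def test_counts_conserved(self):
        ds, _ = syn.simulate_population(syn.PopulationConfig(n_worms=500, seed=1))
        hist = ws.length_distribution(ds, 25.0)
        assert hist.counts.sum() == len(ds)


class TestWormMeanFluorescence:
    def test_simple_mean(self):
        assert ws.worm_mean_fluorescence(np.array([2.0, 4.0, 6.0])) == 4.0

    def test_reversal_invariant(self):
        rng = np.random.default_rng(2)
        samples = rng.uniform(0, 9, 33)
        assert ws.worm_mean_fluorescence(samples) == ws.worm_mean_fluorescence(samples[::-1])

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            ws.worm_mean_fluorescence(np.array([]))


class TestGatedMeanFluorescence:
    def test_all_below_gate(self):
        ds = make_dataset({"a": (np.ones(5) * 3, 100.0, 50.0)})
        assert ws.gated_mean_fluorescence(ds, 200.0) == ws.GatedMean(0, None, None)

    def test_two_worm_hand_value(self):
        ds = make_dataset({
            "a": (np.full(4, 3.0), 100.0, 50.0),
            "b": (np.full(4, 5.0), 150.0, 75.0),
        })
        g = ws.gated_mean_fluorescence(ds, 0.0)
        assert g.n_gated == 2 and g.mean == 4.0
        assert g.sd == pytest.approx(np.sqrt(2.0))

    def test_gate_is_strict(self):
        ds = make_dataset({"a": (np.full(4, 3.0), 200.0, 10.0)})
        assert ws.gated_mean_fluorescence(ds, 200.0).n_gated == 0

    def test_order_invariance(self):
        ds, _ = syn.simulate_population(syn.PopulationConfig(n_worms=80, seed=3))
        reordered = PopulationDataset(ds.condition_label, list(reversed(ds.events)),
                                      ds.profiles, ds.metadata)
        assert ws.gated_mean_fluorescence(ds, 250.0) == ws.gated_mean_fluorescence(reordered, 250.0)


class TestComparePopulations:
    def test_self_comparison_identity(self):
        ds, _ = syn.simulate_population(syn.PopulationConfig(n_worms=120, seed=4))
        r = ws.compare_populations(ds, ds, tof_min=200.0)
        assert r.computable
        assert r.effect_ratio == pytest.approx(1.0)
        assert not r.growth_delayed and not r.fluorescence_reduced

    def test_halved_profiles_halve_ratio(self):
        ds, _ = syn.simulate_population(syn.PopulationConfig(n_worms=120, seed=5))
        halved = PopulationDataset(
            "halved", ds.events,
            {eid: ProfileRecord(eid, p.samples / 2) for eid, p in ds.profiles.items()},
            ds.metadata)
        r = ws.compare_populations(ds, halved, tof_min=200.0)
        assert r.effect_ratio == pytest.approx(0.5)
        assert r.fluorescence_reduced

    def test_scaling_both_groups_leaves_rank_p_and_ratio_unchanged(self):
        def scale(ds, c):
            return PopulationDataset(
                "scaled", ds.events,
                {eid: ProfileRecord(eid, p.samples * c) for eid, p in ds.profiles.items()},
                ds.metadata)

        a, _ = syn.simulate_population(syn.PopulationConfig(n_worms=100, seed=6))
        b, _ = syn.simulate_population(syn.PopulationConfig(n_worms=100, seed=7))
        r1 = ws.compare_populations(a, b, 200.0)
        r2 = ws.compare_populations(scale(a, 3.7), scale(b, 3.7), 200.0)
        assert r2.rank_test_p == pytest.approx(r1.rank_test_p)
        assert r2.effect_ratio == pytest.approx(r1.effect_ratio)

    def test_empty_gated_group_flagged(self):
        small, _ = syn.simulate_population(syn.PopulationConfig(n_worms=30, seed=8))
        r = ws.compare_populations(small, small, tof_min=1e9)
        assert not r.computable and r.effect_ratio is None

    def test_empty_dataset_rejected(self):
        ds, _ = syn.simulate_population(syn.PopulationConfig(n_worms=10, seed=9))
        with pytest.raises(ValueError):
            ws.compare_populations(ds, PopulationDataset("empty", [], {}, {}))

    def test_irradiation_direction_detected(self):
        control, irradiated = syn.paired_conditions(300, 300, seed=10)
        r = ws.compare_populations(control, irradiated, tof_min=200.0)
        assert r.growth_delayed and r.fluorescence_reduced
        assert r.rank_test_p < 0.01


class TestChronogramROI:
    def _chronogram(self, seed=11, n=150):
        ds, _ = syn.simulate_population(syn.PopulationConfig(n_worms=n, seed=seed))
        return pl.build_chronogram(ds).chronogram

    def test_full_window_is_overall_mean(self):
        chron = self._chronogram()
        roi = ws.chronogram_roi_signal(chron, (0.0, 1.0), 0.0)
        overall = np.concatenate([r.mean_profile for r in chron.rows]).mean()
        assert roi.mean == pytest.approx(overall)

    def test_gonad_window_brighter_than_complement(self):
        cfg = syn.PopulationConfig()
        chron = self._chronogram()
        roi = ws.chronogram_roi_signal(
            chron, (cfg.gonad_center - 0.1, cfg.gonad_center + 0.1), cfg.gonad_onset_length)
        head_side = ws.chronogram_roi_signal(chron, (0.30, 0.40), cfg.gonad_onset_length)
        assert roi.mean > head_side.mean

    def test_mirror_invariance(self):
        chron = self._chronogram()
        roi = ws.chronogram_roi_signal(chron, (0.45, 0.65), 250.0)
        roi_mirrored = ws.chronogram_roi_signal(chron.mirrored(), (0.45, 0.65), 250.0)
        assert roi.mean == pytest.approx(roi_mirrored.mean)

    def test_no_qualifying_cells(self):
        chron = self._chronogram()
        assert ws.chronogram_roi_signal(chron, (0.4, 0.6), 1e9) is None


def test_summarize_population_consistency():
    ds, _ = syn.simulate_population(syn.PopulationConfig(n_worms=200, seed=12))
    s = ws.summarize_population(ds, tof_min=200.0, bin_width=50.0)
    assert s.n_worms == len(ds)
    assert s.length_histogram.counts.sum() == s.n_worms
    assert s.gated_mean_fluorescence.n_gated <= s.n_worms
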