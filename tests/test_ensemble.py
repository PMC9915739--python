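"""Spatial maps, peak-position distributions, alternation selectivity."""
import numpy as np
import pytest

import mesoframe as mf
from mesoframe.ensemble import (
    SpatialActivityMap,
    alternation_selectivity,
    build_spatial_map,
    calibration_excess_bins,
    compare_peak_proportions,
    peak_position_distribution,
    selective_at_peak,
)


def map_from_tensor(per_trial, labels):
    return SpatialActivityMap(per_trial=np.asarray(per_trial, float),
                              trial_labels=list(labels))


def oracle_selectivity(d, k=2.0):
    """Direct enumeration of the per-position selectivity rule."""
    n, b = d.shape
    out = np.zeros((n, b), dtype=bool)
    for i in range(n):
        for j in range(b):
            others = np.delete(d[i], j)
            sd = np.std(others, ddof=1)
            if sd == 0:
                out[i, j] = abs(d[i, j]) > 0
            else:
                out[i, j] = abs(d[i, j]) > k * sd
    return out


class TestBuildSpatialMap:
    def test_single_bin_activity_maps_to_that_bin(self, short_session):
        s = short_session
        traj, trials, bins = s["traj"], s["trials"][:4], s["bins"][:4]
        dff = np.zeros((1, len(traj)))
        for trial, b in zip(trials, bins):
            frames = np.flatnonzero(b == 10) + trial.start_frame
            dff[0, frames] = 1.0
        ts = mf.TraceSet(dff=dff, frame_rate=30.0)
        amap = build_spatial_map(ts, trials, bins)
        mm = amap.mean_map[0]
        assert np.argmax(mm) == 9  # bin 10
        assert mm[9] == pytest.approx(1.0)
        off = np.delete(mm, 9)
        assert np.all(off == 0.0)

    def test_identical_trials_equal_mean_map(self):
        row = np.linspace(0, 1, 20)
        amap = map_from_tensor([[row], [row]], [None, True])
        assert np.allclose(amap.per_trial[0], amap.mean_map)

    def test_no_trials_rejected(self, short_session):
        ts = mf.TraceSet(dff=np.zeros((1, 100)), frame_rate=30.0)
        with pytest.raises(ValueError):
            build_spatial_map(ts, [], [])

    def test_tuned_population_recovery(self, long_session):
        """Peak bins recover ground-truth tuning for >= 95% of neurons."""
        s = long_session
        ts, truth = mf.simulate_trace_set(
            s["traj"],
            mf.TraceSimConfig(n_neurons=100, noise_sd=0.05, tuning_width=1.0,
                              peak_event_rate=2.0, seed=7),
        )
        amap = build_spatial_map(ts, s["trials"], s["bins"])
        peaks = peak_position_distribution(amap).peak_bins
        assert (peaks == np.array(truth.tuning_centers)).mean() >= 0.95


class TestPeakPositionDistribution:
    def test_all_neurons_at_one_bin(self):
        per_trial = np.zeros((2, 5, 20))
        per_trial[:, :, 9] = 1.0
        dist = peak_position_distribution(map_from_tensor(
            per_trial, [None, True]))
        assert dist.proportion[9] == 1.0
        assert dist.proportion.sum() == pytest.approx(1.0)
        assert np.all(dist.proportion[np.arange(20) != 9] == 0.0)

    def test_proportions_sum_to_one_and_cis_bounded(self, long_session):
        s = long_session
        ts, _ = mf.simulate_trace_set(
            s["traj"], mf.TraceSimConfig(n_neurons=50, seed=1))
        dist = peak_position_distribution(
            build_spatial_map(ts, s["trials"], s["bins"]))
        assert dist.proportion.sum() == pytest.approx(1.0)
        assert np.all((0 <= dist.ci_low) & (dist.ci_low <= dist.proportion))
        assert np.all((dist.proportion <= dist.ci_high) & (dist.ci_high <= 1))

    def test_invariant_to_per_neuron_rescaling(self):
        rng = np.random.default_rng(2)
        per_trial = rng.random((3, 8, 20))
        amap = map_from_tensor(per_trial, [None, True, False])
        base = peak_position_distribution(amap).peak_bins
        gains = rng.uniform(0.1, 10, 8)
        scaled = map_from_tensor(per_trial * gains[None, :, None],
                                 [None, True, False])
        assert np.array_equal(
            peak_position_distribution(scaled).peak_bins, base)

    def test_all_zero_neurons_excluded_and_counted(self):
        per_trial = np.zeros((2, 3, 20))
        per_trial[:, 0, 4] = 1.0
        dist = peak_position_distribution(
            map_from_tensor(per_trial, [None, True]))
        assert dist.n_neurons == 1
        assert dist.n_excluded == 2


class TestAlternationSelectivity:
    def _labels(self, n_alt=3, n_non=3):
        return [True] * n_alt + [False] * n_non

    def test_identical_label_means_are_never_selective(self):
        rng = np.random.default_rng(0)
        row = rng.random((4, 20))
        per_trial = np.stack([row, row, row, row])  # alt mean == nonalt mean
        sel = alternation_selectivity(
            map_from_tensor(per_trial, self._labels(2, 2)))
        assert not sel.selective.any()

    def test_single_position_difference_detected(self):
        rng = np.random.default_rng(1)
        base = np.zeros((1, 20)) + rng.normal(0, 1e-3, (1, 20))
        alt = base.copy()
        alt[0, 8] += 1.0  # bin 9
        per_trial = np.stack([alt, alt, base, base])
        sel = alternation_selectivity(
            map_from_tensor(per_trial, self._labels(2, 2)))
        assert sel.selective[0, 8]
        assert sel.selective[0].sum() == 1

    def test_requires_two_trials_per_label(self):
        per_trial = np.random.default_rng(0).random((3, 2, 20))
        with pytest.raises(ValueError):
            alternation_selectivity(
                map_from_tensor(per_trial, [True, True, False]))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        alt = rng.random((5, 10, 20))
        non = rng.random((5, 10, 20))
        amap = map_from_tensor(np.concatenate([alt, non]), self._labels(5, 5))
        sel = alternation_selectivity(amap)
        d = alt.mean(axis=0) - non.mean(axis=0)
        assert np.array_equal(sel.selective, oracle_selectivity(d))
        assert np.allclose(sel.difference, d)

    def test_selective_recovery_f1(self, long_session):
        """Gain-modulated neurons recovered with F1 >= 0.8."""
        s = long_session
        ts, truth = mf.simulate_trace_set(
            s["traj"],
            mf.TraceSimConfig(n_neurons=200, tuning_center=None,
                              frac_selective=0.2, selective_gain=2.0,
                              seed=42),
        )
        amap = build_spatial_map(ts, s["trials"], s["bins"])
        sel = alternation_selectivity(amap)
        peaks = peak_position_distribution(amap).peak_bins
        pred = selective_at_peak(sel, peaks)
        truth_mask = np.zeros(200, bool)
        truth_mask[truth.selective_neuron_ids] = True
        tp = (pred & truth_mask).sum()
        prec = tp / pred.sum()
        rec = tp / truth_mask.sum()
        assert 2 * prec * rec / (prec + rec) >= 0.8


class TestComparePeakProportions:
    def test_identical_groups_are_not_different(self):
        peaks = np.repeat(np.arange(1, 21), 10)
        res = compare_peak_proportions(peaks, peaks, center_bins=[8, 9, 10])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2_statistic(self):
        """50/100 vs 10/100 in the center: chi-square = 8000/210 = 38.1."""
        a = np.array([9] * 50 + [1] * 50)
        b = np.array([9] * 10 + [1] * 90)
        res = compare_peak_proportions(a, b, center_bins=[8, 9, 10])
        assert res.statistic == pytest.approx(8000.0 / 210.0)
        assert res.df == 1

    def test_doubling_counts_increases_statistic(self):
        a = np.array([9] * 30 + [1] * 70)
        b = np.array([9] * 15 + [1] * 85)
        r1 = compare_peak_proportions(a, b, center_bins=[9])
        r2 = compare_peak_proportions(np.tile(a, 2), np.tile(b, 2),
                                      center_bins=[9])
        assert r2.statistic == pytest.approx(2 * r1.statistic)

    def test_full_distribution_variant(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 21, 400)
        b = rng.integers(1, 21, 400)
        res = compare_peak_proportions(a, b, center_bins=[9],
                                       full_distribution=True)
        assert res.df == 19
        assert res.p_value > 0.01


class TestCalibration:
    def test_uniform_null_rarely_flags_bins(self):
        rng = np.random.default_rng(8)
        n_flagged = 0
        for _ in range(30):
            d = rng.normal(0, 1, (150, 20))
            sel = mf.SelectivityMap(
                selective=np.abs(d) > 2.0,  # exchangeable synthetic flags
                difference=d,
                proportion=(np.abs(d) > 2.0).mean(axis=0),
                ci_low=np.zeros(20), ci_high=np.ones(20),
                degenerate=np.zeros((150, 20), bool),
            )
            if len(calibration_excess_bins(sel)):
                n_flagged += 1
        assert n_flagged <= 4
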