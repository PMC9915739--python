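"""dF/F, annulus extraction, component selection, events, activity summaries."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mesoframe as mf
from mesoframe.calcium import _window_frames, moving_slope
from mesoframe.synthetic import simulate_event_traces, simulate_stim_response


def oracle_detect_events(trace, fs, stats, deriv_window=0.2, peak_k=3.0,
                         deriv_k=5.0):
    """Exhaustive-scan event oracle: explicit per-window polyfit slopes and a
    frame-by-frame walk over every derivative zero-crossing pair."""
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    w = int(round(deriv_window * fs))
    w = w + 1 if w % 2 == 0 else w
    half = (w - 1) // 2
    padded = np.concatenate([np.zeros(half), trace, np.zeros(half)])
    slope = np.empty(n)
    xs = np.arange(w, dtype=float)
    for i in range(n):
        slope[i] = np.polyfit(xs, padded[i:i + w], 1)[0]
    baseline = np.median(trace)
    events = []
    i = 0
    while i < n - 1:
        if slope[i] <= 0 and slope[i + 1] > 0:  # upward crossing at i
            start = i
            j = i + 1
            while j < n and slope[j] > 0:
                j += 1
            if j == n:
                break
            end = j  # first frame where the derivative has fallen <= 0
            if (slope[start + 1:end + 1].max() >= deriv_k * stats.sd_derivative
                    and (trace[end] - baseline) > peak_k * stats.sd_baseline):
                events.append((start, end))
            i = j
        else:
            i += 1
    merged = []
    for s, e in events:
        if merged and s - merged[-1][1] < 2:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class TestComputeDff:
    def test_hand_computed_example(self):
        ts = mf.compute_dff(np.array([[10.0, 10.0, 20.0, 10.0]]))
        assert np.allclose(ts.dff[0], [-0.2, -0.2, 0.6, -0.2])

    def test_constant_trace_is_all_zeros(self):
        ts = mf.compute_dff(np.full((2, 50), 7.0))
        assert np.all(ts.dff == 0.0)

    def test_doubling_f0_gives_unit_dff(self):
        raw = np.full((1, 100), 5.0)
        raw[0, 40] = 10.0
        ts = mf.compute_dff(raw, f0_mode="first_15s", frame_rate=2.0)
        assert ts.dff[0, 40] == pytest.approx(1.0)

    def test_nonpositive_f0_names_the_trace(self):
        raw = np.ones((3, 10))
        raw[1] = -1.0
        with pytest.raises(ValueError, match="1"):
            mf.compute_dff(raw)

    def test_gain_invariance_of_dff_and_activity_sd(self):
        rng = np.random.default_rng(0)
        raw = 100.0 + rng.normal(0, 5, (1, 600)).cumsum(axis=1) * 0 + \
            rng.normal(0, 5, (1, 600))
        a = mf.compute_dff(raw)
        b = mf.compute_dff(3.7 * raw)
        assert np.allclose(a.dff, b.dff)
        assert mf.activity_sd(a.dff[0]) == pytest.approx(
            mf.activity_sd(b.dff[0])
        )


class TestAnnulusExtraction:
    def _masks(self):
        soma = np.zeros((9, 9), bool)
        soma[3:6, 3:6] = True
        ann = np.zeros((9, 9), bool)
        ann[1:8, 1:8] = True
        ann[2:7, 2:7] = False
        return soma, ann

    def test_uniform_movie_gives_zero_trace(self):
        soma, ann = self._masks()
        movie = np.full((20, 9, 9), 3.0)
        assert np.allclose(mf.extract_trace_with_annulus(movie, soma, ann), 0.0)

    def test_constant_offset_recovered(self):
        soma, ann = self._masks()
        movie = np.full((10, 9, 9), 2.0)
        movie[:, soma] += 1.5
        trace = mf.extract_trace_with_annulus(movie, soma, ann)
        assert np.allclose(trace, 1.5)

    def test_overlapping_masks_rejected(self):
        soma, _ = self._masks()
        with pytest.raises(ValueError):
            mf.extract_trace_with_annulus(np.ones((5, 9, 9)), soma, soma)

    def test_flashing_cell_recovered_from_noisy_movie(self):
        rng = np.random.default_rng(4)
        soma, ann = self._masks()
        signal = 3.0 * np.clip(rng.normal(0, 1, 200), 0, None)
        movie = rng.normal(10.0, 0.5, (200, 9, 9))
        movie[:, soma] += signal[:, None]
        trace = mf.extract_trace_with_annulus(movie, soma, ann)
        assert np.corrcoef(trace, signal)[0, 1] > 0.99


class TestSelectComponents:
    def _component_set(self):
        rng = np.random.default_rng(0)
        n_px = 400
        frames = 800
        tc = np.vstack([
            rng.normal(0, 1, frames),  # symmetric -> rejected
            np.clip(rng.normal(0, 1, frames), 0, None) ** 2,  # skewed
            np.clip(rng.normal(0, 1, frames), 0, None) ** 2,  # skewed, vessel
        ])
        filt = np.zeros((3, n_px))
        filt[0, :20] = 1.0
        filt[1, 100:120] = 1.0
        filt[2, 200:220] = 1.0
        vessel = np.zeros(n_px, bool)
        vessel[210:220] = True  # half the top pixels of component 2
        return mf.ComponentSet(spatial_filters=filt, time_courses=tc,
                               vessel_mask=vessel)

    def test_skewness_and_vessel_rules(self):
        cs = self._component_set()
        assert cs.skewness[0] < 1 < cs.skewness[1]
        kept = mf.select_components(cs)
        assert kept.tolist() == [1]

    def test_no_vessel_mask_keeps_skewed_components(self):
        cs = self._component_set()
        cs.vessel_mask = None
        assert mf.select_components(cs).tolist() == [1, 2]


class TestDecomposeMovie:
    def test_recovers_sources_of_tiny_synthetic_movie(self):
        rng = np.random.default_rng(1)
        frames, n_px = 500, 64
        sources = np.clip(rng.normal(0, 1, (2, frames)), 0, None) ** 2
        mixing = np.zeros((n_px, 2))
        mixing[:20, 0] = 1.0
        mixing[40:60, 1] = 1.0
        movie = sources.T @ mixing.T + rng.normal(0, 0.05, (frames, n_px))
        cs = mf.decompose_movie(movie, n_components=2, seed=0)
        corr = np.abs(np.corrcoef(np.vstack([cs.time_courses, sources])))
        best = corr[:2, 2:].max(axis=1)
        assert np.all(best > 0.95)


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        stats = mf.BaselineStats(0.01, 0.001)
        assert mf.detect_events(np.zeros(300), 30.0, stats) == []

    def test_single_event_magnitude_recovered(self):
        """Injected amplitude recovered on average within 10%."""
        k = mf.calcium_kernel(0.1, 1.0, 30.0)
        rng = np.random.default_rng(7)
        mags, counts = [], []
        for _ in range(60):
            tr = np.zeros(600)
            tr[200:200 + len(k)] += 0.5 * k  # peak 10 x noise SD
            tr += rng.normal(0, 0.05, 600)
            ev = mf.detect_events(tr, 30.0,
                                  mf.estimate_baseline_stats(tr, 30.0))
            counts.append(len(ev))
            if ev:
                mags.append(ev[0].magnitude)
        assert np.mean(counts) == pytest.approx(1.0, abs=0.05)
        assert abs(np.mean(mags) - 0.5) / 0.5 < 0.10

    def test_subthreshold_event_rejected(self):
        """A 2-SD peak fails the 3-SD acceptance rule."""
        k = mf.calcium_kernel(0.1, 1.0, 30.0)
        tr = np.zeros(600)
        tr[200:200 + len(k)] += 0.1 * k
        stats = mf.BaselineStats(sd_baseline=0.05, sd_derivative=1e-4)
        assert mf.detect_events(tr, 30.0, stats) == []

    def test_offset_invariance(self):
        traces, _ = simulate_event_traces(3, duration_s=60, seed=5)
        for tr in traces:
            stats = mf.estimate_baseline_stats(tr, 30.0)
            a = mf.detect_events(tr, 30.0, stats)
            b = mf.detect_events(tr + 5.0, 30.0,
                                 mf.estimate_baseline_stats(tr + 5.0, 30.0))
            assert [(e.start_frame, e.end_frame) for e in a] == \
                [(e.start_frame, e.end_frame) for e in b]

    def test_matches_exhaustive_oracle_on_short_traces(self):
        traces, _ = simulate_event_traces(
            20, duration_s=6.0, rate_hz=0.2, min_separation_s=2.0, seed=13
        )
        for tr in traces:
            stats = mf.estimate_baseline_stats(tr, 30.0)
            got = [(e.start_frame, e.end_frame)
                   for e in mf.detect_events(tr, 30.0, stats)]
            assert got == oracle_detect_events(tr, 30.0, stats)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            mf.detect_events(np.zeros(100), 30.0, mf.BaselineStats(1, 1),
                             deriv_window=0.01)


class TestActivitySummaries:
    def test_constant_trace_sd_zero(self):
        assert mf.activity_sd(np.full(100, 3.0)) == 0.0

    def test_unit_square_wave_sd(self):
        wave = np.tile([-1.0, 1.0], 500)
        assert mf.activity_sd(wave) == pytest.approx(1.0, rel=1e-3)

    @given(st.floats(min_value=-10, max_value=10).filter(lambda c: c != 0))
    @settings(max_examples=25, derandomize=True)
    def test_scaling_scales_sd(self, c):
        rng = np.random.default_rng(0)
        tr = rng.normal(0, 1, 200)
        assert mf.activity_sd(c * tr) == pytest.approx(
            abs(c) * mf.activity_sd(tr), rel=1e-9
        )

    @pytest.mark.parametrize("sd1, sd2, expected",
                             [(1.0, 1.0, 0.0), (1.0, 1.5, 0.5), (2.0, 1.0, -0.5)])
    def test_activity_change(self, sd1, sd2, expected):
        assert mf.activity_change(sd1, sd2) == pytest.approx(expected)

    def test_activity_change_requires_positive_sd1(self):
        with pytest.raises(ValueError):
            mf.activity_change(0.0, 1.0)


class TestStimTimecourse:
    def test_noiseless_response_baseline_and_peak(self):
        trace, _ = simulate_stim_response(10, amplitude=0.5, noise_sd=0.0)
        tc = mf.stim_timecourse(trace.raw[None, :])
        onset = trace.onset_index
        assert np.allclose(tc.mean[:onset], 0.0, atol=1e-12)
        assert tc.mean.max() == pytest.approx(0.5)

    def test_identical_animals_have_zero_sem(self):
        trace, _ = simulate_stim_response(5, amplitude=0.3, noise_sd=0.0)
        tc = mf.stim_timecourse(np.vstack([trace.raw, trace.raw]))
        assert np.allclose(tc.sem, 0.0)

    def test_onset_beyond_series_rejected(self):
        with pytest.raises(ValueError):
            mf.stim_timecourse(np.ones((1, 10)), onset_s=20.0)
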