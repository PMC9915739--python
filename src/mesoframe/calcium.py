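"""Calcium trace processing: dF/F, component selection, events, activity summaries.

Implements the miniscope trace pipeline: per-trace dF/F0 against a session
mean (or the first 15 s for stimulation series), annulus background
subtraction around a soma, skewness/vessel-overlap component selection after
an ICA decomposition, rising-phase event detection from a windowed first
derivative, and standard-deviation activity summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TraceSet",
    "ComponentSet",
    "CalciumEvent",
    "BaselineStats",
    "compute_dff",
    "extract_trace_with_annulus",
    "decompose_movie",
    "select_components",
    "estimate_baseline_stats",
    "moving_slope",
    "detect_events",
    "activity_sd",
    "activity_change",
    "stim_timecourse",
]


@dataclass
class TraceSet:
    """Neurons x frames dF/F0 matrix with its sampling grid."""

    dff: np.ndarray
    frame_rate: float
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be a 2-D neurons x frames array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
        if self.frame_times is None:
            self.frame_times = np.arange(self.dff.shape[1]) / self.frame_rate
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("dff", data=self.dff)
            ds.attrs["frame_rate"] = self.frame_rate
            fh.create_dataset("frame_times", data=self.frame_times)

    @classmethod
    def from_hdf5(cls, path) -> "TraceSet":
        with h5py.File(path, "r") as fh:
            dff = fh["dff"][...]
            fr = float(fh["dff"].attrs["frame_rate"])
            times = fh["frame_times"][...] if "frame_times" in fh else None
        return cls(dff=dff, frame_rate=fr, frame_times=times)


@dataclass
class ComponentSet:
    """ICA components: spatial filters, time courses and selection inputs."""

    spatial_filters: np.ndarray  # components x pixels (or x H x W)
    time_courses: np.ndarray  # components x frames
    vessel_mask: Optional[np.ndarray] = None  # pixel mask, same pixel layout

    def __post_init__(self) -> None:
        if self.spatial_filters.shape[0] != self.time_courses.shape[0]:
            raise ValueError("spatial_filters and time_courses disagree on count")

    @property
    def skewness(self) -> np.ndarray:
        return sps.skew(self.time_courses, axis=1, bias=False)


@dataclass(frozen=True)
class CalciumEvent:
    """One rising-phase calcium event on a single trace."""

    neuron_id: int
    start_frame: int
    end_frame: int
    magnitude: float  # dF/F0 rise from start to end
    peak_value: float  # dF/F0 at the event end

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("event start must precede its end")
        if self.magnitude < 0:
            raise ValueError("event magnitude must be >= 0")


@dataclass(frozen=True)
class BaselineStats:
    """Baseline fluctuation scales used by the event detector.

    ``sd_baseline`` scales the 3-SD peak acceptance rule on the dF/F trace;
    ``sd_derivative`` scales the 5-SD rule on the windowed first derivative.
    Both are robust (1.4826 x MAD) estimates, which ignore sparse events.
    """

    sd_baseline: float
    sd_derivative: float
    method: str = "mad"

    def __post_init__(self) -> None:
        if self.sd_baseline < 0 or self.sd_derivative < 0:
            raise ValueError("baseline SDs must be >= 0")


def _mad_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def compute_dff(
    raw: np.ndarray,
    f0_mode: str = "session_mean",
    frame_rate: Optional[float] = None,
) -> TraceSet:
    """Convert raw fluorescence (neurons x frames) to dF/F0.

    ``f0_mode`` selects the baseline: "session_mean" uses each trace's mean
    over the whole recording; "first_15s" uses the mean of the first 15 s
    (stimulation-series convention; requires ``frame_rate``).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw fluorescence contains non-finite values")
    if f0_mode == "session_mean":
        f0 = raw.mean(axis=1)
        fr = frame_rate if frame_rate is not None else 30.0
    elif f0_mode == "first_15s":
        if frame_rate is None:
            raise ValueError("frame_rate is required for f0_mode='first_15s'")
        n0 = max(1, int(round(15.0 * frame_rate)))
        f0 = raw[:, :n0].mean(axis=1)
        fr = frame_rate
    else:
        raise ValueError(f"unknown f0_mode: {f0_mode!r}")
    bad = np.flatnonzero(f0 <= 0)
    if len(bad):
        raise ValueError(f"non-positive F0 for trace(s) {bad.tolist()}")
    dff = (raw - f0[:, None]) / f0[:, None]
    return TraceSet(dff=dff, frame_rate=fr)


def extract_trace_with_annulus(
    movie: np.ndarray, soma_mask: np.ndarray, annulus_mask: np.ndarray
) -> np.ndarray:
    """Soma trace with local background removed.

    Per frame: mean over the soma mask minus the median over a surrounding
    annulus ("doughnut") of background pixels.  Masks must be disjoint and
    nonempty.
    """
    soma_mask = np.asarray(soma_mask, dtype=bool)
    annulus_mask = np.asarray(annulus_mask, dtype=bool)
    if not soma_mask.any() or not annulus_mask.any():
        raise ValueError("soma and annulus masks must be nonempty")
    if (soma_mask & annulus_mask).any():
        raise ValueError("soma and annulus masks overlap")
    movie = np.asarray(movie, dtype=float)
    flat = movie.reshape(movie.shape[0], -1)
    soma = flat[:, soma_mask.ravel()].mean(axis=1)
    bg = np.median(flat[:, annulus_mask.ravel()], axis=1)
    return soma - bg


def decompose_movie(
    movie: np.ndarray, n_components: int, seed: int = 0
) -> ComponentSet:
    """Decompose a dF/F movie (frames x pixels) into independent components.

    A standard FastICA decomposition; spatial filters are rectified at zero
    and each component's sign is oriented so its time-course skewness is
    positive (calcium transients rise fast and decay slowly, so genuine
    components are positively skewed).
    """
    from sklearn.decomposition import FastICA

    movie = np.asarray(movie, dtype=float)
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=1000)
    time_courses = ica.fit_transform(movie).T  # components x frames
    filters = ica.mixing_.T  # components x pixels
    sk = sps.skew(time_courses, axis=1, bias=False)
    flip = np.where(sk < 0, -1.0, 1.0)
    time_courses = time_courses * flip[:, None]
    filters = np.clip(filters * flip[:, None], 0.0, None)
    return ComponentSet(spatial_filters=filters, time_courses=time_courses)


def select_components(
    cs: ComponentSet,
    skew_min: float = 1.0,
    vessel_overlap_max: float = 0.5,
    top_fraction: float = 0.05,
) -> np.ndarray:
    """Indices of accepted components.

    A component is kept when its time-course sample skewness is at least
    ``skew_min`` and the fraction of its strongest spatial-filter pixels
    (top ``top_fraction`` after rectification) falling inside the blood-vessel
    mask is below ``vessel_overlap_max``.
    """
    sk = cs.skewness
    keep = sk >= skew_min
    if cs.vessel_mask is not None:
        vessel = np.asarray(cs.vessel_mask, dtype=bool).ravel()
        filters = np.clip(
            cs.spatial_filters.reshape(cs.spatial_filters.shape[0], -1), 0.0, None
        )
        n_top = max(1, int(round(top_fraction * filters.shape[1])))
        for i in range(filters.shape[0]):
            top = np.argpartition(filters[i], -n_top)[-n_top:]
            overlap = vessel[top].mean()
            if overlap >= vessel_overlap_max:
                keep[i] = False
    return np.flatnonzero(keep)


def moving_slope(trace: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered least-squares slope of a trace over a moving window.

    Units: dF/F0 per frame.  Edges use zero-padding, which biases only the
    first and last half-windows.
    """
    if window_frames < 2:
        raise ValueError("derivative window must span at least 2 frames")
    offsets = np.arange(window_frames) - (window_frames - 1) / 2.0
    denom = float((offsets ** 2).sum())
    kern = offsets[::-1] / denom  # convolution flips the kernel
    return np.convolve(np.asarray(trace, dtype=float), kern, mode="same")


def _window_frames(deriv_window: float, fs: float) -> int:
    """Frame count for the derivative window, rounded up to odd.

    An odd count makes the least-squares slope exactly centered on a frame
    (an even window is centered between frames).
    """
    w = max(2, int(round(deriv_window * fs)))
    return w + 1 if w % 2 == 0 else w


def estimate_baseline_stats(
    trace: np.ndarray, fs: float, deriv_window: float = 0.2
) -> BaselineStats:
    """Robust baseline-fluctuation scales for the event detector."""
    trace = np.asarray(trace, dtype=float)
    w = _window_frames(deriv_window, fs)
    slope = moving_slope(trace, w)
    return BaselineStats(sd_baseline=_mad_sd(trace),
                         sd_derivative=_mad_sd(slope), method="mad")


def detect_events(
    trace: np.ndarray,
    fs: float,
    stats: Optional[BaselineStats] = None,
    deriv_window: float = 0.2,
    peak_k: float = 3.0,
    deriv_k: float = 5.0,
    neuron_id: int = 0,
    merge_gap_frames: int = 2,
) -> list[CalciumEvent]:
    """Detect rising-phase calcium events on one dF/F trace.

    A candidate starts at an upward zero-crossing of the windowed first
    derivative and ends at the following downward zero-crossing; it is a
    detection when the derivative exceeds ``deriv_k`` x sd_derivative within
    the rise and the baseline-referenced dF/F at the end exceeds ``peak_k``
    x sd_baseline.  The event magnitude is the dF/F rise from start to end.
    Events closer than ``merge_gap_frames`` are merged.  Results are
    invariant to adding a constant to the trace.
    """
    trace = np.asarray(trace, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if int(round(deriv_window * fs)) < 2:
        raise ValueError("derivative window shorter than 2 frames")
    w = _window_frames(deriv_window, fs)
    if stats is None:
        stats = estimate_baseline_stats(trace, fs, deriv_window)
    slope = moving_slope(trace, w)
    baseline = float(np.median(trace))

    pos = slope > 0
    ups = np.flatnonzero(~pos[:-1] & pos[1:])  # earlier frame of the tie
    downs = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1  # frame where it has fallen
    raw_events: list[tuple[int, int]] = []
    j = 0
    for u in ups:
        while j < len(downs) and downs[j] <= u:
            j += 1
        if j == len(downs):
            break
        d = int(downs[j])
        seg_max = slope[u + 1: d + 1].max() if d > u else -np.inf
        if seg_max < deriv_k * stats.sd_derivative:
            continue
        if (trace[d] - baseline) <= peak_k * stats.sd_baseline:
            continue
        raw_events.append((int(u), d))

    merged: list[tuple[int, int]] = []
    for s, e in raw_events:
        if merged and s - merged[-1][1] < merge_gap_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    return [
        CalciumEvent(
            neuron_id=neuron_id,
            start_frame=s,
            end_frame=e,
            magnitude=max(float(trace[e] - trace[s]), 0.0),
            peak_value=float(trace[e]),
        )
        for s, e in merged
    ]


def events_to_frame(events: Sequence[CalciumEvent], fs: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "neuron": [e.neuron_id for e in events],
            "start_s": [e.start_frame / fs for e in events],
            "end_s": [e.end_frame / fs for e in events],
            "start_frame": [e.start_frame for e in events],
            "end_frame": [e.end_frame for e in events],
            "magnitude": [e.magnitude for e in events],
            "peak": [e.peak_value for e in events],
        }
    )


def activity_sd(trace: np.ndarray) -> float:
    """Overall-activity summary: sample SD of a dF/F trace."""
    return float(np.std(np.asarray(trace, dtype=float), ddof=1))


def activity_change(sd1: float, sd2: float) -> float:
    """Relative activity change (SD2 - SD1) / SD1 (0.5 displays as 50%)."""
    if sd1 <= 0:
        raise ValueError("sd1 must be > 0")
    return (sd2 - sd1) / sd1


@dataclass
class StimTimecourse:
    """Baseline-referenced stimulation time course for one condition."""

    times: np.ndarray
    dff: np.ndarray  # series x frames
    mean: np.ndarray
    sem: np.ndarray


def stim_timecourse(
    series: np.ndarray,
    frame_dt: float = 0.351,
    f0_window_s: float = 15.0,
    onset_s: float = 20.0,
) -> StimTimecourse:
    """dF/F time course of stimulation-response series (one condition).

    ``series`` holds raw fluorescence, one row per animal.  F0 is each row's
    mean over the first ``f0_window_s`` seconds; the result carries per-frame
    mean and SEM across animals.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_frames = series.shape[1]
    if onset_s >= n_frames * frame_dt:
        raise ValueError("stimulus onset lies beyond the end of the series")
    n0 = max(1, int(round(f0_window_s / frame_dt)))
    f0 = series[:, :n0].mean(axis=1)
    if np.any(f0 <= 0):
        raise ValueError("non-positive F0 in stimulation series")
    dff = (series - f0[:, None]) / f0[:, None]
    n = series.shape[0]
    sem = dff.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(n_frames)
    return StimTimecourse(
        times=np.arange(n_frames) * frame_dt,
        dff=dff,
        mean=dff.mean(axis=0),
        sem=sem,
    )
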