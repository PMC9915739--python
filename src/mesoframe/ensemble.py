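"""Position-binned ensemble analysis: peak positions and alternation selectivity.

Each neuron's dF/F is averaged within 20 track bins per trial, then across
trials (all, alternating, non-alternating).  The population is summarized by
the proportion of neurons peaking in each bin (with Wilson 95% intervals)
and by the per-position alternation-selectivity rule: a neuron is selective
at a bin when the alternating/non-alternating activity difference there
exceeds k standard deviations of the differences at all other positions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .behavior import Trial
from .calcium import TraceSet

__all__ = [
    "SpatialActivityMap",
    "PeakDistribution",
    "SelectivityMap",
    "build_spatial_map",
    "peak_position_distribution",
    "alternation_selectivity",
    "selective_at_peak",
    "calibration_excess_bins",
    "compare_peak_proportions",
    "plot_raster",
]


@dataclass
class SpatialActivityMap:
    """Trial-resolved binned activity with alternation labels.

    ``per_trial`` is trials x neurons x n_bins; ``trial_labels`` holds True
    (alternating), False (non-alternating) or None (first trial, unlabeled).
    Mean maps are trial means over all / alternating / non-alternating
    trials.
    """

    per_trial: np.ndarray
    trial_labels: list[Optional[bool]]
    interpolated: np.ndarray = None  # trials x n_bins bool: bins with no frames

    def __post_init__(self) -> None:
        self.per_trial = np.asarray(self.per_trial, dtype=float)
        if self.per_trial.ndim != 3:
            raise ValueError("per_trial must be trials x neurons x bins")
        if len(self.trial_labels) != self.per_trial.shape[0]:
            raise ValueError("trial_labels length must match trial count")
        if self.interpolated is None:
            self.interpolated = np.zeros(
                (self.per_trial.shape[0], self.per_trial.shape[2]), dtype=bool
            )

    @property
    def n_bins(self) -> int:
        return self.per_trial.shape[2]

    @property
    def n_neurons(self) -> int:
        return self.per_trial.shape[1]

    @property
    def mean_map(self) -> np.ndarray:
        return self.per_trial.mean(axis=0)

    def _label_mean(self, want: bool) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.trial_labels) if lab is want]
        if not idx:
            raise ValueError(
                f"no {'alternating' if want else 'non-alternating'} trials"
            )
        return self.per_trial[idx].mean(axis=0)

    @property
    def mean_alt(self) -> np.ndarray:
        return self._label_mean(True)

    @property
    def mean_nonalt(self) -> np.ndarray:
        return self._label_mean(False)

    def n_labeled(self, want: bool) -> int:
        return sum(1 for lab in self.trial_labels if lab is want)


@dataclass
class PeakDistribution:
    """Proportion of neurons peaking in each bin, with Wilson 95% CIs."""

    proportion: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    counts: np.ndarray
    n_neurons: int
    peak_bins: np.ndarray  # 1-based peak bin per included neuron
    n_excluded: int  # all-zero neurons left out
    n_ties: int  # neurons whose argmax was tied (lowest bin kept)

    def to_frame(self) -> pd.DataFrame:
        bins = np.arange(1, len(self.proportion) + 1)
        return pd.DataFrame(
            {
                "bin": bins,
                "count": self.counts,
                "proportion": self.proportion,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class SelectivityMap:
    """Per-neuron, per-bin alternation-selectivity flags and bin proportions."""

    selective: np.ndarray  # neurons x bins bool
    difference: np.ndarray  # neurons x bins, mean_alt - mean_nonalt
    proportion: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    degenerate: np.ndarray  # neurons x bins where SD of other bins was 0

    @property
    def n_neurons(self) -> int:
        return self.selective.shape[0]

    def to_frame(self) -> pd.DataFrame:
        bins = np.arange(1, self.selective.shape[1] + 1)
        return pd.DataFrame(
            {
                "bin": bins,
                "count": self.selective.sum(axis=0),
                "proportion": self.proportion,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def build_spatial_map(
    traces: TraceSet,
    trials: Sequence[Trial],
    bins: Sequence[np.ndarray],
    n_bins: int = 20,
) -> SpatialActivityMap:
    """Average each neuron's dF/F within position bins, per trial.

    ``bins`` holds, for each trial, the 1-based bin index of every frame from
    the trial's start to its end (as produced by ``behavior.trial_bins``).
    Bins a trial never visited are linearly interpolated from neighboring
    bins and flagged in ``interpolated``.
    """
    if len(trials) == 0:
        raise ValueError("no trials to map")
    if len(trials) != len(bins):
        raise ValueError("trials and bins disagree in length")
    n_trials = len(trials)
    n_neurons = traces.n_neurons
    per_trial = np.zeros((n_trials, n_neurons, n_bins))
    interp_flags = np.zeros((n_trials, n_bins), dtype=bool)
    centers = np.arange(1, n_bins + 1, dtype=float)
    for t, (trial, b) in enumerate(zip(trials, bins)):
        sl = slice(trial.start_frame, trial.start_frame + len(b))
        seg = traces.dff[:, sl]
        for k in range(1, n_bins + 1):
            sel = b == k
            if sel.any():
                per_trial[t, :, k - 1] = seg[:, sel].mean(axis=1)
            else:
                interp_flags[t, k - 1] = True
        empty = interp_flags[t]
        if empty.any():
            filled = ~empty
            for nrn in range(n_neurons):
                per_trial[t, nrn, empty] = np.interp(
                    centers[empty], centers[filled], per_trial[t, nrn, filled]
                )
    labels = [trial.is_alternation for trial in trials]
    return SpatialActivityMap(per_trial=per_trial, trial_labels=labels,
                              interpolated=interp_flags)


def _wilson(counts: np.ndarray, n: int, alpha: float = 0.05):
    if n == 0:
        z = np.zeros_like(counts, dtype=float)
        return z, z
    low, high = proportion_confint(counts, n, alpha=alpha, method="wilson")
    return np.asarray(low, dtype=float), np.asarray(high, dtype=float)


def peak_position_distribution(
    amap: SpatialActivityMap, alpha: float = 0.05
) -> PeakDistribution:
    """Proportion of neurons with maximal mean activity at each bin.

    Per neuron the peak bin is the argmax of its trial-averaged map (ties
    resolved to the lowest bin and counted); all-zero neurons are excluded
    and counted.  Wilson score intervals at level ``1 - alpha``.
    """
    mm = amap.mean_map
    n_bins = amap.n_bins
    nonzero = ~np.all(mm == 0.0, axis=1)
    mm_use = mm[nonzero]
    peaks = np.argmax(mm_use, axis=1)
    maxvals = mm_use[np.arange(len(mm_use)), peaks]
    n_ties = int(np.sum((mm_use == maxvals[:, None]).sum(axis=1) > 1))
    counts = np.bincount(peaks, minlength=n_bins).astype(float)
    n = len(mm_use)
    prop = counts / n if n else counts
    lo, hi = _wilson(counts, n, alpha)
    return PeakDistribution(
        proportion=prop,
        ci_low=lo,
        ci_high=hi,
        counts=counts,
        n_neurons=n,
        peak_bins=peaks + 1,
        n_excluded=int(np.sum(~nonzero)),
        n_ties=n_ties,
    )


def alternation_selectivity(
    amap: SpatialActivityMap, k: float = 2.0, alpha: float = 0.05
) -> SelectivityMap:
    """Per-position alternation selectivity.

    d(b) = mean activity over alternating trials minus non-alternating
    trials.  A neuron is selective at bin b when |d(b)| exceeds ``k``
    standard deviations (ddof=1) of its differences at all other positions.
    Bins where that SD is zero are flagged degenerate and selective only if
    |d(b)| > 0.  Requires at least two trials of each label.
    """
    if amap.n_labeled(True) < 2 or amap.n_labeled(False) < 2:
        raise ValueError("need >= 2 alternating and >= 2 non-alternating trials")
    d = amap.mean_alt - amap.mean_nonalt  # neurons x bins
    n_bins = d.shape[1]
    m = n_bins - 1
    s1 = d.sum(axis=1, keepdims=True)
    s2 = (d ** 2).sum(axis=1, keepdims=True)
    mean_o = (s1 - d) / m
    var_o = np.clip(((s2 - d ** 2) - m * mean_o ** 2) / (m - 1), 0.0, None)
    sd_o = np.sqrt(var_o)
    degenerate = sd_o == 0.0
    selective = np.abs(d) > k * sd_o
    selective[degenerate] = np.abs(d[degenerate]) > 0.0
    counts = selective.sum(axis=0).astype(float)
    n = d.shape[0]
    lo, hi = _wilson(counts, n, alpha)
    return SelectivityMap(
        selective=selective,
        difference=d,
        proportion=counts / n,
        ci_low=lo,
        ci_high=hi,
        degenerate=degenerate,
    )


def selective_at_peak(sel: SelectivityMap, peak_bins: np.ndarray) -> np.ndarray:
    """Per-neuron selectivity summary: flagged at the neuron's peak bin.

    ``peak_bins`` are 1-based peak-activity bins (one per neuron, e.g. from
    ``peak_position_distribution``).  A neuron counts as alternation-
    selective when the per-position rule flags it at the position where it
    is most active -- the per-neuron reduction used when comparing recovered
    selective sets against ground truth.
    """
    peak_bins = np.asarray(peak_bins, dtype=int)
    if len(peak_bins) != sel.n_neurons:
        raise ValueError("peak_bins length must equal the neuron count")
    return sel.selective[np.arange(sel.n_neurons), peak_bins - 1]


def calibration_excess_bins(
    sel: SelectivityMap, familywise_alpha: float = 0.05
) -> np.ndarray:
    """Bins whose selective proportion exceeds its null upper bound.

    Under a null cohort the per-bin selective rate is exchangeable across
    bins (tuning centers are uniform), so each bin's count is compared with
    the binomial upper bound at the cohort's pooled rate.  The per-bin level
    is Sidak-adjusted so the familywise false-flag rate over all bins is
    ``familywise_alpha``: a calibrated analysis flags no bin in >= 95% of
    null cohorts.  Returns the 1-based indices of flagged bins.
    """
    counts = sel.selective.sum(axis=0)
    n = sel.n_neurons
    n_bins = sel.selective.shape[1]
    pooled = counts.sum() / (n * n_bins)
    alpha_bin = 1.0 - (1.0 - familywise_alpha) ** (1.0 / n_bins)
    ub = sps.binom.isf(alpha_bin, n, pooled)
    return np.flatnonzero(counts > ub) + 1


@dataclass
class ProportionComparison:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray
    low_expected: bool  # any expected cell below 5


def compare_peak_proportions(
    peaks_a: np.ndarray,
    peaks_b: np.ndarray,
    center_bins: Sequence[int],
    full_distribution: bool = False,
    n_bins: int = 20,
) -> ProportionComparison:
    """Chi-square comparison of two groups' peak-bin (or selectivity) counts.

    ``peaks_a``/``peaks_b`` are per-neuron 1-based bin assignments.  The
    default test is the 2x2 Pearson chi-square (no continuity correction) on
    neurons peaking within ``center_bins`` versus elsewhere; with
    ``full_distribution`` the 2 x n_bins distribution chi-square is used.
    A warning flag is set when any expected count falls below 5.
    """
    peaks_a = np.asarray(peaks_a, dtype=int)
    peaks_b = np.asarray(peaks_b, dtype=int)
    if full_distribution:
        table = np.vstack(
            [
                np.bincount(peaks_a - 1, minlength=n_bins),
                np.bincount(peaks_b - 1, minlength=n_bins),
            ]
        ).astype(float)
        table = table[:, table.sum(axis=0) > 0]
    else:
        center = set(int(b) for b in center_bins)
        in_a = np.isin(peaks_a, list(center)).sum()
        in_b = np.isin(peaks_b, list(center)).sum()
        table = np.array(
            [
                [in_a, len(peaks_a) - in_a],
                [in_b, len(peaks_b) - in_b],
            ],
            dtype=float,
        )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square table has a zero margin")
    stat, p, df, expected = sps.chi2_contingency(table, correction=False)
    low = bool(np.any(expected < 5))
    if low:
        warnings.warn("expected cell count below 5 in chi-square comparison")
    return ProportionComparison(statistic=float(stat), df=int(df),
                                p_value=float(p), table=table, low_expected=low)


def plot_raster(amap: SpatialActivityMap, path=None, sort: bool = True):
    """Temporal raster of per-neuron binned activity, peak-sorted.

    For display each neuron's row is normalized to its own maximum;
    statistics elsewhere always use unnormalized values.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mm = amap.mean_map.copy()
    scale = np.abs(mm).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    mm = mm / scale
    if sort:
        mm = mm[np.argsort(np.argmax(mm, axis=1))]
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(mm, aspect="auto", cmap="viridis",
                   extent=(0.5, amap.n_bins + 0.5, amap.n_neurons, 0))
    ax.set_xlabel("track bin (origin terminal -> destination terminal)")
    ax.set_ylabel("neuron (sorted by peak bin)")
    fig.colorbar(im, ax=ax, label="activity / own max")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
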