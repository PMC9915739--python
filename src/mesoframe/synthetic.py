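"""Synthetic data with known ground truth for every analysis stage.

Generators emulate the statistical structure the analyses assume:

* Y-maze sessions: a first-order Markov arm-entry process with a settable
  alternation probability, and a continuous body-center trajectory that
  visits arm terminals in the generated order (45 cm x 8 cm arms, 8-min
  sessions by default).
* 30-Hz dF/F trace sets with position-tuned, calcium-kernel-convolved events
  plus Gaussian noise, with an optional alternation-dependent gain on a
  subset of neurons.
* VTA-stimulation response series: 115 frames at 0.351 s/frame with response
  onset at 20 s.
* Two-channel section images with curvilinear axons and punctate boutons at
  known counts, lengths and densities, and labeled somata for cell counting.

Every generator takes a seed and is bit-reproducible; each returns a
:class:`GroundTruth` record listing exactly what was drawn.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import interpolate, signal
from scipy.ndimage import gaussian_filter

from .behavior import ArmEntry, ArmEntrySequence, Trajectory, detect_arm_entries, \
    segment_trials, trial_bins
from .calcium import TraceSet
from .errors import ConfigurationError
from .geometry import MazeGeometry
from .morphology import SectionImage

__all__ = [
    "BehaviorSimConfig",
    "TraceSimConfig",
    "ImageSimConfig",
    "GroundTruth",
    "StimTrace",
    "simulate_arm_entries",
    "simulate_trajectory",
    "simulate_trace_set",
    "simulate_event_traces",
    "simulate_stim_response",
    "simulate_morphology_image",
    "calcium_kernel",
    "write_ground_truth_json",
]

# per-operation RNG stream indices so that one seed yields independent,
# individually reproducible draws for each generator
_STREAM_ENTRIES = 0
_STREAM_TRAJECTORY = 1
_STREAM_TRACES = 2
_STREAM_IMAGE = 3
_STREAM_STIM = 4
_STREAM_EVENT_TRACES = 5


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Conditions for simulated Y-maze sessions.

    ``p_alternate`` is the probability that, on leaving an arm, the animal
    chooses the arm it has not just come from (0.5 = uniform random choice
    between the two available arms, the chance level of the task).
    """

    n_sessions: int = 1
    session_duration: float = 480.0  # s, the 8-min session
    arm_length: float = 45.0  # cm
    arm_width: float = 8.0  # cm
    p_alternate: float = 0.5
    mean_dwell: float = 2.0  # s spent at an arm terminal per visit
    speed: float = 10.0  # cm/s while traversing
    frame_rate: float = 30.0  # Hz of the position series
    n_entries: Optional[int] = None  # overrides the duration-derived count
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.p_alternate) or not 0.0 <= self.p_alternate <= 1.0:
            raise ConfigurationError("p_alternate must be a probability in [0, 1]")
        if self.session_duration <= 0:
            raise ConfigurationError("session_duration must be positive")
        if self.speed <= 0 or self.mean_dwell < 0 or self.frame_rate <= 0:
            raise ConfigurationError("speed/frame_rate must be > 0, mean_dwell >= 0")

    @property
    def geometry(self) -> MazeGeometry:
        return MazeGeometry(arm_length=self.arm_length, arm_width=self.arm_width)


@dataclass(frozen=True)
class TraceSimConfig:
    """Conditions for simulated dF/F trace sets.

    Tuning is a Gaussian event-rate profile over the 20 track bins, centered
    on ``tuning_center`` (None draws a uniform center per neuron).  A
    ``frac_selective`` subset of neurons has its event amplitudes multiplied
    by ``selective_gain`` on alternating trials.
    """

    n_neurons: int = 100
    frame_rate: float = 30.0
    n_bins: int = 20
    #: None = untuned (flat rate); "uniform" = centers drawn uniformly over
    #: bins; an int or per-neuron sequence fixes centers (0 = untuned neuron)
    tuning_center: Optional[object] = "uniform"
    tuning_width: float = 2.0  # bins
    event_amplitude: float = 0.5  # dF/F units
    peak_event_rate: float = 1.0  # Hz at the tuning center
    base_rate: float = 0.1  # off-field rate as a fraction of the peak
    kernel_rise: float = 0.1  # s
    kernel_decay: float = 1.0  # s
    noise_sd: float = 0.05  # dF/F units
    frac_selective: float = 0.0
    selective_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.frac_selective <= 1.0:
            raise ConfigurationError("frac_selective must lie in [0, 1]")
        if self.kernel_decay <= self.kernel_rise:
            raise ConfigurationError("kernel_decay must exceed kernel_rise")


@dataclass(frozen=True)
class ImageSimConfig:
    """Conditions for simulated two-channel section images.

    The red channel carries axons (and somata for the midbrain variant,
    ``n_cells`` > 0); the green channel carries boutons placed on axons at
    ``boutons_per_100um``.  ``curvature`` (radians of heading change per
    step) controls axon tortuosity; 0 draws straight axons.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # um / pixel
    n_axons: int = 5
    axon_intensity: float = 40.0  # a.u. above background
    axon_length_um: float = 250.0  # target length per axon
    boutons_per_100um: float = 5.0
    bouton_amplitude: float = 80.0  # a.u. peak above background
    bouton_sigma: float = 0.8  # um
    background_sd: float = 5.0  # a.u.
    background_level: float = 20.0  # a.u.
    n_cells: int = 0
    cell_intensity: float = 60.0
    cell_sigma: float = 5.0  # um
    curvature: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("axon_intensity", "boutons_per_100um", "bouton_amplitude",
                     "bouton_sigma", "background_sd", "cell_intensity"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.n_axons == 0 and self.boutons_per_100um > 0 and self.n_cells == 0:
            raise ConfigurationError(
                "bouton placement requested (boutons_per_100um > 0) with n_axons=0"
            )


@dataclass
class GroundTruth:
    """Exhaustive record of what a generator drew.

    Only the fields relevant to the generating operation are populated.
    """

    seed: Optional[int] = None
    entries: Optional[list[str]] = None
    entry_times: Optional[list[float]] = None
    trial_labels: Optional[list[Optional[bool]]] = None
    event_frames: Optional[list[list[int]]] = None  # per neuron
    event_amplitudes: Optional[list[list[float]]] = None  # per neuron
    tuning_centers: Optional[list[int]] = None
    selective_neuron_ids: Optional[list[int]] = None
    axon_polyline_lengths: Optional[list[float]] = None  # um
    axon_polylines: Optional[list[list[list[float]]]] = None  # (row, col) px
    bouton_coordinates: Optional[list[list[float]]] = None  # (row, col) px
    cell_coordinates: Optional[list[list[float]]] = None  # (row, col) px
    onset_index: Optional[int] = None
    response_peak: Optional[float] = None


def write_ground_truth_json(gt: GroundTruth, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump({k: v for k, v in asdict(gt).items() if v is not None},
                  fh, default=_default, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _derived_n_entries(cfg: BehaviorSimConfig) -> int:
    per_visit = cfg.mean_dwell + 2.0 * cfg.arm_length / cfg.speed
    return max(3, int(cfg.session_duration / per_visit) + 1)


def simulate_arm_entries(
    cfg: BehaviorSimConfig,
) -> tuple[list[str], GroundTruth]:
    """Generate an arm-entry sequence from a first-order Markov process.

    The first two entries are drawn uniformly without an immediate repeat;
    each subsequent entry is the new arm (neither the current one nor the one
    visited before it) with probability ``p_alternate`` and otherwise the
    previously visited arm.  The current arm is never repeated.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_ENTRIES])
    arms = cfg.geometry.arms
    n = cfg.n_entries if cfg.n_entries is not None else _derived_n_entries(cfg)
    seq: list[str] = []
    if n >= 1:
        seq.append(arms[int(rng.integers(len(arms)))])
    if n >= 2:
        others = [a for a in arms if a != seq[0]]
        seq.append(others[int(rng.integers(len(others)))])
    for _ in range(2, n):
        prev, cur = seq[-2], seq[-1]
        new = next(a for a in arms if a not in (prev, cur))
        seq.append(new if rng.random() < cfg.p_alternate else prev)
    labels: list[Optional[bool]] = [None] + [
        seq[k + 1] != seq[k - 1] for k in range(1, len(seq) - 1)
    ]
    gt = GroundTruth(seed=cfg.seed, entries=list(seq), trial_labels=labels)
    return seq, gt


def simulate_trajectory(
    entries: Sequence[str], cfg: BehaviorSimConfig
) -> Trajectory:
    """Continuous body-center trajectory visiting arm terminals in order.

    The animal dwells at each terminal (shifted-exponential dwell with mean
    ``mean_dwell`` and a 0.6 s floor -- a turn at a terminal takes at least
    that long) and travels terminal -> center -> terminal at constant
    ``speed``; positions are sampled at ``frame_rate``.
    """
    if len(entries) == 0:
        raise ConfigurationError("entries must be nonempty")
    rng = np.random.default_rng([cfg.seed, _STREAM_TRAJECTORY])
    geom = cfg.geometry
    dt_min = max(0.6, 2.0 / cfg.frame_rate)
    travel_t = geom.arm_length / cfg.speed

    t_way = [0.0]
    p_way = [geom.terminal(entries[0])]
    t = 0.0
    for k, arm in enumerate(entries):
        dwell = dt_min + rng.exponential(max(cfg.mean_dwell - dt_min, 1e-6)) \
            if cfg.mean_dwell > dt_min else dt_min
        t += dwell
        t_way.append(t)
        p_way.append(geom.terminal(arm))
        if k + 1 < len(entries):
            t += travel_t
            t_way.append(t)
            p_way.append(np.zeros(2))
            t += travel_t
            t_way.append(t)
            p_way.append(geom.terminal(entries[k + 1]))
    t_way = np.asarray(t_way)
    p_way = np.asarray(p_way)
    times = np.arange(0.0, t_way[-1], 1.0 / cfg.frame_rate)
    x = np.interp(times, t_way, p_way[:, 0])
    y = np.interp(times, t_way, p_way[:, 1])
    return Trajectory(time=times, x=x, y=y, geometry=geom)


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

def calcium_kernel(rise: float, decay: float, fs: float) -> np.ndarray:
    """Difference-of-exponentials calcium impulse response, peak-normalized.

    Approximates a GCaMP6s-like transient: k(t) = exp(-t/decay) - exp(-t/rise),
    sampled at ``fs`` and scaled so its maximum is exactly 1.
    """
    if decay <= rise:
        raise ConfigurationError("kernel_decay must exceed kernel_rise")
    t = np.arange(0.0, 6.0 * decay, 1.0 / fs)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def _tuning_centers(cfg: TraceSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-neuron tuning center (1..n_bins); 0 marks an untuned neuron."""
    tc = cfg.tuning_center
    if tc is None:
        return np.zeros(cfg.n_neurons, dtype=int)
    if isinstance(tc, str):
        if tc != "uniform":
            raise ConfigurationError(f"unknown tuning_center mode {tc!r}")
        return rng.integers(1, cfg.n_bins + 1, size=cfg.n_neurons)
    if np.isscalar(tc):
        return np.full(cfg.n_neurons, int(tc))
    tc = np.asarray(tc, dtype=int)
    if len(tc) != cfg.n_neurons:
        raise ConfigurationError("tuning_center sequence must have n_neurons entries")
    return tc


def _kernel_lag_frames(
    kernel: np.ndarray, tuning_width_bins: float, bin_dwell_frames: float
) -> int:
    """Frames by which the calcium kernel delays a tuned activity peak.

    The measured binned activity is the event-rate profile convolved in time
    with the (causal, slow-decaying) calcium kernel, so its peak lags the
    rate peak.  The lag is found numerically: a Gaussian rate bump of the
    configured width (in frames, via the typical frames-per-bin dwell) is
    convolved with the kernel and the argmax shift is measured.  The
    generator advances the rate profile by this many frames so that measured
    activity peaks at the nominal tuning bin.
    """
    w_frames = max(tuning_width_bins * bin_dwell_frames, 1.0)
    half = int(np.ceil(4 * w_frames))
    t = np.arange(-half, half + 1)
    bump = np.exp(-0.5 * (t / w_frames) ** 2)
    conv = np.convolve(bump, kernel, mode="full")
    return int(np.argmax(conv) - np.argmax(bump))


def simulate_trace_set(
    traj: Trajectory, cfg: TraceSimConfig
) -> tuple[TraceSet, GroundTruth]:
    """Simulate a position-tuned dF/F trace set on a trajectory's timebase.

    Per neuron, events fire as an inhomogeneous Bernoulli process whose rate
    is a Gaussian profile over track bins (plus an off-field base rate);
    amplitudes of selective neurons are multiplied by ``selective_gain``
    during alternating trials.  Impulses are convolved with the calcium
    kernel and i.i.d. Gaussian noise is added.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TRACES])
    n_frames = len(traj)
    fs = cfg.frame_rate
    entries = detect_arm_entries(traj)
    trials, _ = segment_trials(traj, entries)
    if not trials:
        raise ConfigurationError("trajectory must cover at least one trial")
    bins_per_trial = trial_bins(traj, trials, cfg.n_bins)

    frame_bin = np.zeros(n_frames, dtype=int)  # 0 = outside any trial
    frame_alt = np.zeros(n_frames, dtype=bool)
    for tr, b in zip(trials, bins_per_trial):
        frame_bin[tr.start_frame:tr.end_frame + 1] = b
        if tr.is_alternation:
            frame_alt[tr.start_frame:tr.end_frame + 1] = True

    centers = _tuning_centers(cfg, rng)
    selective = np.flatnonzero(rng.random(cfg.n_neurons) < cfg.frac_selective)
    is_sel = np.zeros(cfg.n_neurons, dtype=bool)
    is_sel[selective] = True

    kernel = calcium_kernel(cfg.kernel_rise, cfg.kernel_decay, fs)
    # advance the tuned rate profile so measured activity peaks at the
    # nominal tuning bin despite the kernel's temporal smear
    dwell = np.median([
        (tr.end_frame - tr.start_frame + 1) / cfg.n_bins for tr in trials
    ])
    lag = _kernel_lag_frames(kernel, cfg.tuning_width, dwell)
    bin_ahead = np.concatenate([frame_bin[lag:], np.zeros(lag, dtype=int)]) \
        if lag > 0 else frame_bin

    in_field_frame = bin_ahead > 0
    profile = np.empty((cfg.n_neurons, n_frames))
    profile[:] = cfg.base_rate
    tuned = centers > 0
    profile[~tuned] = 1.0  # untuned neurons: flat rate everywhere
    if tuned.any():
        d = bin_ahead[None, :] - centers[tuned, None]
        gauss = np.exp(-0.5 * (d / max(cfg.tuning_width, 1e-9)) ** 2)
        block = np.full((tuned.sum(), n_frames), cfg.base_rate)
        block[:, in_field_frame] = (
            cfg.base_rate + (1.0 - cfg.base_rate) * gauss[:, in_field_frame]
        )
        profile[tuned] = block
    rate = cfg.peak_event_rate * profile  # Hz
    p_event = np.clip(rate / fs, 0.0, 1.0)
    events = rng.random((cfg.n_neurons, n_frames)) < p_event

    amp = np.where(events, cfg.event_amplitude, 0.0)
    gain_mask = is_sel[:, None] & frame_alt[None, :]
    amp = np.where(events & gain_mask, amp * cfg.selective_gain, amp)

    dff = signal.fftconvolve(amp, kernel[None, :], axes=1)[:, :n_frames]
    if cfg.noise_sd > 0:
        dff = dff + rng.normal(0.0, cfg.noise_sd, size=dff.shape)

    gt = GroundTruth(
        seed=cfg.seed,
        event_frames=[np.flatnonzero(events[i]).tolist()
                      for i in range(cfg.n_neurons)],
        event_amplitudes=[amp[i, events[i]].tolist()
                          for i in range(cfg.n_neurons)],
        tuning_centers=centers.tolist(),
        selective_neuron_ids=selective.tolist(),
        trial_labels=[t.is_alternation for t in trials],
    )
    ts = TraceSet(dff=dff, frame_rate=fs, frame_times=traj.time.copy())
    return ts, gt


def simulate_event_traces(
    n_traces: int,
    duration_s: float = 480.0,
    fs: float = 30.0,
    amplitude_range: tuple[float, float] = (0.3, 0.6),
    rate_hz: float = 0.05,
    min_separation_s: float = 5.0,
    noise_sd: float = 0.05,
    kernel_rise: float = 0.1,
    kernel_decay: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate isolated calcium events on flat baselines (detector fixture).

    Events are placed uniformly in time with a minimum separation so each
    transient decays back to baseline before the next; amplitudes are drawn
    uniformly from ``amplitude_range``.  Used to validate event detection
    against exact ground truth.
    """
    rng = np.random.default_rng([seed, _STREAM_EVENT_TRACES])
    n_frames = int(round(duration_s * fs))
    kernel = calcium_kernel(kernel_rise, kernel_decay, fs)
    traces = np.zeros((n_traces, n_frames))
    ev_frames: list[list[int]] = []
    ev_amps: list[list[float]] = []
    margin = int(round(min_separation_s * fs))
    for i in range(n_traces):
        n_events = rng.poisson(rate_hz * duration_s)
        cand = np.sort(rng.integers(margin, n_frames - margin,
                                    size=max(n_events, 0)))
        keep: list[int] = []
        for f in cand:
            if not keep or f - keep[-1] >= margin:
                keep.append(int(f))
        amps = rng.uniform(*amplitude_range, size=len(keep))
        impulse = np.zeros(n_frames)
        impulse[keep] = amps
        traces[i] = signal.fftconvolve(impulse, kernel)[:n_frames]
        ev_frames.append(keep)
        ev_amps.append(amps.tolist())
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=traces.shape)
    gt = GroundTruth(seed=seed, event_frames=ev_frames, event_amplitudes=ev_amps)
    return traces, gt


# ---------------------------------------------------------------------------
# stimulation response
# ---------------------------------------------------------------------------

STIM_N_FRAMES = 115
STIM_FRAME_DT = 0.351  # s / frame
STIM_ONSET_S = 20.0

#: pulse count at which the response reaches the nominal amplitude
_STIM_REFERENCE_PULSES = 10
_STIM_PULSE_TAU = 5.0


@dataclass
class StimTrace:
    """One simulated stimulation-response series (raw fluorescence)."""

    times: np.ndarray
    raw: np.ndarray  # baseline_f * (1 + response + noise)
    response: np.ndarray  # noiseless dF/F response
    onset_index: int
    n_pulses: int


def stim_onset_index(frame_dt: float = STIM_FRAME_DT,
                     onset_s: float = STIM_ONSET_S) -> int:
    """Frame index nearest the stimulus onset (57 for 20 s at 0.351 s/frame)."""
    return int(round(onset_s / frame_dt))


def simulate_stim_response(
    n_pulses: int,
    amplitude: float = 0.5,
    decay: float = 8.0,
    noise_sd: float = 0.0,
    rise: float = 1.0,
    baseline_f: float = 1.0,
    seed: int = 0,
) -> tuple[StimTrace, GroundTruth]:
    """Simulate one 115-frame stimulation-response fluorescence series.

    The response begins at the frame nearest 20 s and follows a peak-
    normalized (1 - exp(-t/rise)) * exp(-t/decay) time course.  The peak
    scales monotonically and saturatingly with ``n_pulses``; at the 10-pulse
    reference condition the peak equals ``amplitude`` exactly.  The pre-onset
    dF/F mean is 0 in the noiseless case.
    """
    if n_pulses < 0:
        raise ConfigurationError("n_pulses must be >= 0")
    rng = np.random.default_rng([seed, _STREAM_STIM])
    times = np.arange(STIM_N_FRAMES) * STIM_FRAME_DT
    onset = stim_onset_index()
    sat = 1.0 - np.exp(-n_pulses / _STIM_PULSE_TAU)
    sat_ref = 1.0 - np.exp(-_STIM_REFERENCE_PULSES / _STIM_PULSE_TAU)
    peak = amplitude * sat / sat_ref
    response = np.zeros(STIM_N_FRAMES)
    tp = times[onset:] - times[onset]
    shape = (1.0 - np.exp(-tp / rise)) * np.exp(-tp / decay)
    if shape.max() > 0:
        shape = shape / shape.max()
    response[onset:] = peak * shape
    noise = rng.normal(0.0, noise_sd, STIM_N_FRAMES) if noise_sd > 0 else 0.0
    raw = baseline_f * (1.0 + response + noise)
    gt = GroundTruth(seed=seed, onset_index=onset, response_peak=float(peak))
    return StimTrace(times=times, raw=raw, response=response,
                     onset_index=onset, n_pulses=n_pulses), gt


# ---------------------------------------------------------------------------
# morphology images
# ---------------------------------------------------------------------------

def _axon_polyline(
    cfg: ImageSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One axon as a cubic-smoothed correlated random walk.

    Returns dense (row, col) points at ~0.25 px spacing and the polyline
    length in um.
    """
    h, w = cfg.image_shape
    margin = 8.0
    target_px = cfg.axon_length_um / cfg.pixel_size
    step = 6.0  # px between control points
    pos = np.array([rng.uniform(margin, h - margin),
                    rng.uniform(margin, w - margin)])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    length_px = 0.0
    while length_px < 1.35 * target_px:
        heading += rng.normal(0.0, cfg.curvature) if cfg.curvature > 0 else 0.0
        nxt = pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
        if not (margin <= nxt[0] <= h - margin and margin <= nxt[1] <= w - margin):
            break
        length_px += step
        pts.append(nxt)
    pts = np.asarray(pts)
    if len(pts) < 4:  # too short for a cubic spline; keep the raw segment
        dense = pts
    else:
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0.0)
        u = np.linspace(0.0, 1.0, int(20 * len(pts)))
        dense = np.column_stack(interpolate.splev(u, tck))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] > target_px:  # truncate at the target length
        stop = np.searchsorted(cum, target_px)
        dense = dense[: stop + 1]
        cum = cum[: stop + 1]
    return dense, float(cum[-1]) * cfg.pixel_size


def _splat(shape: tuple[int, int], coords: np.ndarray,
           mass: np.ndarray) -> np.ndarray:
    img = np.zeros(shape)
    rows = np.clip(np.round(coords[:, 0]).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(coords[:, 1]).astype(int), 0, shape[1] - 1)
    np.add.at(img, (rows, cols), mass)
    return img


def simulate_morphology_image(
    cfg: ImageSimConfig,
) -> tuple[SectionImage, GroundTruth]:
    """Simulate a two-channel section image with exact ground truth.

    Red: axons rendered along smoothed random-walk polylines (plus somata if
    ``n_cells`` > 0); green: Gaussian boutons centered on axon points at
    ``boutons_per_100um``, placed at regular arc-length spacing with a random
    phase.  Gaussian background noise is added to both channels.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_IMAGE])
    h, w = cfg.image_shape
    red = np.zeros((h, w))
    green = np.zeros((h, w))
    axon_lengths: list[float] = []
    axon_polylines: list[list[list[float]]] = []
    bouton_xy: list[list[float]] = []
    cell_xy: list[list[float]] = []

    axon_mask = np.zeros((h, w))
    for _ in range(cfg.n_axons):
        dense, length_um = _axon_polyline(cfg, rng)
        axon_lengths.append(length_um)
        keep = np.unique(np.r_[np.arange(0, len(dense), 10), len(dense) - 1])
        axon_polylines.append(dense[keep].tolist())
        rows = np.clip(np.round(dense[:, 0]).astype(int), 0, h - 1)
        cols = np.clip(np.round(dense[:, 1]).astype(int), 0, w - 1)
        axon_mask[rows, cols] = 1.0
        # boutons at regular arc-length spacing with random phase
        n_boutons = int(round(length_um * cfg.boutons_per_100um / 100.0))
        if n_boutons > 0:
            seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)]) * cfg.pixel_size
            spacing = length_um / n_boutons
            phase = rng.uniform(0.2, 0.8)
            s_targets = (np.arange(n_boutons) + phase) * spacing
            idx = np.searchsorted(cum, np.clip(s_targets, 0, cum[-1]))
            idx = np.clip(idx, 0, len(dense) - 1)
            for i in idx:
                bouton_xy.append([float(dense[i, 0]), float(dense[i, 1])])

    if cfg.n_axons > 0 and axon_mask.any():
        sm = gaussian_filter(axon_mask, sigma=1.0)
        red += sm / sm.max() * cfg.axon_intensity

    if bouton_xy:
        sig_px = cfg.bouton_sigma / cfg.pixel_size
        mass = cfg.bouton_amplitude * 2.0 * np.pi * sig_px ** 2
        delta = _splat((h, w), np.asarray(bouton_xy),
                       np.full(len(bouton_xy), mass))
        green += gaussian_filter(delta, sigma=sig_px)

    if cfg.n_cells > 0:
        sig_px = cfg.cell_sigma / cfg.pixel_size
        min_sep = 3.5 * sig_px  # above the detector's one-soma-radius merge
        margin = 3.0 * sig_px
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < cfg.n_cells and attempts < 20000:
            attempts += 1
            cand = np.array([rng.uniform(margin, h - margin),
                             rng.uniform(margin, w - margin)])
            if all(np.linalg.norm(cand - p) >= min_sep for p in placed):
                placed.append(cand)
        if len(placed) < cfg.n_cells:
            raise ConfigurationError(
                "could not place the requested somata with the required "
                "separation; reduce n_cells or enlarge the image"
            )
        mass = cfg.cell_intensity * 2.0 * np.pi * sig_px ** 2
        delta = _splat((h, w), np.asarray(placed), np.full(len(placed), mass))
        red += gaussian_filter(delta, sigma=sig_px)
        cell_xy = [[float(p[0]), float(p[1])] for p in placed]

    red += cfg.background_level + rng.normal(0.0, cfg.background_sd, (h, w))
    green += cfg.background_level + rng.normal(0.0, cfg.background_sd, (h, w))
    red = np.clip(red, 0.0, None)
    green = np.clip(green, 0.0, None)

    img = SectionImage(red=red, green=green, pixel_size=cfg.pixel_size,
                       roi_mask=np.ones((h, w), dtype=bool))
    gt = GroundTruth(
        seed=cfg.seed,
        axon_polyline_lengths=axon_lengths,
        axon_polylines=axon_polylines,
        bouton_coordinates=bouton_xy,
        cell_coordinates=cell_xy,
    )
    return img, gt
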