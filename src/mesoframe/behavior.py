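"""Y-maze behavior analysis: arm entries, alternation score, trials, position bins.

The spontaneous-alternation task scores the tendency of a mouse to visit the
least recently visited arm.  Entries are read off a tracked body-center
trajectory; alternation is the fraction of consecutive entry triplets with
three distinct arms; trials (terminal-to-terminal traversals) carry the
position binning used by the ensemble analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .geometry import MazeGeometry

__all__ = [
    "Trajectory",
    "ArmEntry",
    "ArmEntrySequence",
    "AlternationScore",
    "Trial",
    "detect_arm_entries",
    "score_alternation",
    "segment_trials",
    "bin_position",
    "trial_bins",
]


@dataclass
class Trajectory:
    """Timestamped 2-D maze positions with the maze geometry.

    ``time`` is strictly increasing (seconds); ``x``/``y`` are body-center
    coordinates in cm in the maze frame (center at the origin).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geometry: MazeGeometry = field(default_factory=MazeGeometry)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.time) == len(self.x) == len(self.y)):
            raise ValueError("time, x, y must have equal length")
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, arr in (("time", self.time), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in trajectory {name}")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def speed(self, smooth_s: float = 0.1) -> np.ndarray:
        """Instantaneous speed (cm/s), lightly smoothed."""
        if len(self) < 2:
            return np.zeros(len(self))
        vx = np.gradient(self.x, self.time)
        vy = np.gradient(self.y, self.time)
        sp = np.hypot(vx, vy)
        dt = float(np.median(np.diff(self.time)))
        win = max(1, int(round(smooth_s / dt)))
        return uniform_filter1d(sp, size=win, mode="nearest")

    def to_csv(self, path, arm_labels: Optional[Sequence[str]] = None) -> None:
        df = pd.DataFrame({"time_s": self.time, "x_cm": self.x, "y_cm": self.y})
        if arm_labels is not None:
            df["arm_label"] = list(arm_labels)
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, geometry: Optional[MazeGeometry] = None) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(),
            x=df["x_cm"].to_numpy(),
            y=df["y_cm"].to_numpy(),
            geometry=geometry or MazeGeometry(),
        )


@dataclass(frozen=True)
class ArmEntry:
    arm: str
    time: float
    frame: int


@dataclass
class ArmEntrySequence:
    """Ordered arm entries; no two consecutive entries share an arm."""

    entries: list[ArmEntry]

    def __post_init__(self) -> None:
        arms = self.arms
        if any(a == b for a, b in zip(arms, arms[1:])):
            raise ValueError("consecutive entries into the same arm are not allowed")

    @property
    def arms(self) -> list[str]:
        return [e.arm for e in self.entries]

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.entries])

    @property
    def frames(self) -> np.ndarray:
        return np.array([e.frame for e in self.entries], dtype=int)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"arm": self.arms, "time_s": self.times, "frame": self.frames}
        ).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "ArmEntrySequence":
        df = pd.read_csv(path)
        return cls(
            [
                ArmEntry(str(r.arm), float(r.time_s), int(r.frame))
                for r in df.itertuples()
            ]
        )


@dataclass(frozen=True)
class AlternationScore:
    """Alternation percentage over entry triplets.

    ``percent`` is 100 * (non-repeating triplets) / (total entries - 2) and is
    NaN when fewer than three entries were made (``insufficient`` is then
    True); such sessions are excluded from group means.
    """

    percent: float
    n_entries: int
    n_alternating: int
    n_triplets: int
    insufficient: bool


@dataclass(frozen=True)
class Trial:
    """One terminal-to-terminal traversal.

    ``is_alternation`` is True when the destination differs from the arm
    visited two entries before (the traversal completes a non-repeating
    triplet), False when it returns there, and None for the first trial of a
    session, where no such reference exists.
    """

    index: int
    origin: str
    destination: str
    start_time: float
    end_time: float
    start_frame: int
    end_frame: int
    is_alternation: Optional[bool]

    def __post_init__(self) -> None:
        if self.start_time >= self.end_time:
            raise ValueError("trial start must precede its end")
        if self.origin == self.destination:
            raise ValueError("trial origin and destination must differ")


def detect_arm_entries(
    traj: Trajectory, entry_fraction: float = 0.2
) -> ArmEntrySequence:
    """Detect arm entries from a trajectory.

    An entry into an arm is recorded when the tracked point penetrates beyond
    ``entry_fraction`` of the arm length from the center, for an arm other
    than the currently occupied one.  This operationalizes the all-four-paws
    entry rule with a body-center criterion.

    A trajectory that never leaves the center region yields an empty sequence.
    """
    if not 0 < entry_fraction < 1:
        raise ValueError("entry_fraction must lie strictly between 0 and 1")
    geom = traj.geometry
    if len(traj) == 0:
        return ArmEntrySequence([])
    proj = geom.arm_projections(traj.xy)
    thr = entry_fraction * geom.arm_length
    deep = proj > thr  # (n_frames, n_arms)
    entries: list[ArmEntry] = []
    current = -1
    # frames where any arm's deep flag switches on
    rises = np.flatnonzero(np.any(deep[1:] & ~deep[:-1], axis=1)) + 1
    if np.any(deep[0]):
        rises = np.concatenate([[0], rises])
    for f in rises:
        arm_idx = int(np.argmax(proj[f]))
        if not deep[f, arm_idx] or arm_idx == current:
            continue
        entries.append(ArmEntry(geom.arms[arm_idx], float(traj.time[f]), int(f)))
        current = arm_idx
    return ArmEntrySequence(entries)


def score_alternation(entries) -> AlternationScore:
    """Score spontaneous alternation over consecutive entry triplets.

    Counts triplets of consecutive entries with three distinct arms;
    percentage = 100 * count / (total entries - 2).  A uniform-random agent
    choosing between the two available arms scores 50% in expectation.
    """
    arms = entries.arms if isinstance(entries, ArmEntrySequence) else list(entries)
    n = len(arms)
    if n < 3:
        return AlternationScore(math.nan, n, 0, 0, True)
    n_alt = sum(
        1 for i in range(n - 2) if len({arms[i], arms[i + 1], arms[i + 2]}) == 3
    )
    return AlternationScore(100.0 * n_alt / (n - 2), n, n_alt, n - 2, False)


def _sustained_below(speed: np.ndarray, thr: float, n_sustain: int) -> np.ndarray:
    """Boolean mask: speed stays below thr for n_sustain frames starting here."""
    slow = speed < thr
    if n_sustain <= 1:
        return slow
    csum = np.concatenate([[0], np.cumsum(slow)])
    n = len(slow)
    out = np.zeros(n, dtype=bool)
    last = n - n_sustain
    if last >= 0:
        ok = (csum[n_sustain:] - csum[:-n_sustain]) == n_sustain
        out[: last + 1] = ok
    # near the end of the session accept a run to the last frame
    tail = np.flatnonzero(~slow)
    tail_start = tail[-1] + 1 if len(tail) else 0
    out[tail_start:] |= slow[tail_start:]
    return out


def segment_trials(
    traj: Trajectory,
    entries: ArmEntrySequence,
    stop_speed: float = 2.0,
    terminal_fraction: float = 0.9,
    sustain_s: float = 0.5,
) -> tuple[list[Trial], int]:
    """Segment a session into terminal-to-terminal trials.

    One trial spans each consecutive entry pair: it starts at the last frame
    the animal sits at the origin terminal below ``stop_speed`` (the moment it
    starts moving away) and ends at the first frame it has stopped (speed
    below ``stop_speed`` sustained for ``sustain_s``) at the destination
    terminal.  Traversals where the destination terminal is never reached are
    dropped; their count is returned alongside the trials.
    """
    geom = traj.geometry
    if len(entries) < 2:
        return [], 0
    speed = traj.speed()
    dt = float(np.median(np.diff(traj.time))) if len(traj) > 1 else 1.0
    n_sustain = max(1, int(round(sustain_s / dt)))
    stopped = _sustained_below(speed, stop_speed, n_sustain)
    slow = speed < stop_speed
    arm_idx, depth = geom.assign_arm(traj.xy)
    in_terminal = depth >= terminal_fraction * geom.arm_length

    frames = entries.frames
    arms = entries.arms
    arm_to_idx = {a: i for i, a in enumerate(geom.arms)}
    trials: list[Trial] = []
    n_aborted = 0
    for k in range(len(entries) - 1):
        origin, dest = arms[k], arms[k + 1]
        f0, f1 = frames[k], frames[k + 1]
        f2 = frames[k + 2] if k + 2 < len(entries) else len(traj)
        # departure from the origin terminal
        w1 = np.arange(f0, f1)
        at_origin = w1[
            in_terminal[w1] & (arm_idx[w1] == arm_to_idx[origin]) & slow[w1]
        ]
        if len(at_origin):
            start = int(at_origin[-1])
        else:  # never settled at the terminal: start at deepest origin point
            deep_o = w1[arm_idx[w1] == arm_to_idx[origin]]
            start = int(deep_o[np.argmax(depth[deep_o])]) if len(deep_o) else int(f0)
        # arrival at the destination terminal
        w2 = np.arange(f1, f2)
        at_dest = w2[
            in_terminal[w2] & (arm_idx[w2] == arm_to_idx[dest]) & stopped[w2]
        ]
        if not len(at_dest):
            n_aborted += 1
            continue
        end = int(at_dest[0])
        if end <= start:
            raise RuntimeError(
                f"trial segmentation invariant violated at entry {k}: "
                f"end frame {end} <= start frame {start}"
            )
        if trials and start < trials[-1].end_frame:
            raise RuntimeError(f"overlapping trials at entry {k}")
        is_alt = None if k == 0 else (arms[k + 1] != arms[k - 1])
        trials.append(
            Trial(
                index=len(trials),
                origin=origin,
                destination=dest,
                start_time=float(traj.time[start]),
                end_time=float(traj.time[end]),
                start_frame=start,
                end_frame=end,
                is_alternation=is_alt,
            )
        )
    return trials, n_aborted


def bin_position(trial: Trial, traj: Trajectory, n_bins: int = 20) -> np.ndarray:
    """Assign each trial frame to one of ``n_bins`` track-position bins.

    The terminal-to-terminal path is parameterized by a normalized coordinate
    u in [0, 1] (0 = origin terminal, 1 = destination terminal, 0.5 = maze
    center); u is cut into ``n_bins`` half-open equal intervals, with the top
    bin closed.  Bins are 1-based, so with 20 bins the maze center falls at
    the bin-10/11 boundary and maps to bin 11.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if trial.end_frame <= trial.start_frame:
        raise ValueError("zero-length trial")
    geom = traj.geometry
    sl = slice(trial.start_frame, trial.end_frame + 1)
    xy = traj.xy[sl]
    proj = geom.arm_projections(xy)
    i_o = geom.arms.index(trial.origin)
    i_d = geom.arms.index(trial.destination)
    p_o = np.clip(proj[:, i_o], 0.0, geom.arm_length)
    p_d = np.clip(proj[:, i_d], 0.0, geom.arm_length)
    L = geom.arm_length
    s = np.where(p_o >= p_d, L - p_o, L + p_d)
    u = s / (2.0 * L)
    bins = np.minimum((u * n_bins).astype(int), n_bins - 1) + 1
    return bins


def trial_bins(
    traj: Trajectory, trials: Sequence[Trial], n_bins: int = 20
) -> list[np.ndarray]:
    """Per-frame bin indices for every trial (convenience wrapper)."""
    return [bin_position(t, traj, n_bins) for t in trials]


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [t.index for t in trials],
            "origin": [t.origin for t in trials],
            "destination": [t.destination for t in trials],
            "start_s": [t.start_time for t in trials],
            "end_s": [t.end_time for t in trials],
            "start_frame": [t.start_frame for t in trials],
            "end_frame": [t.end_frame for t in trials],
            "is_alternation": [t.is_alternation for t in trials],
        }
    )
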