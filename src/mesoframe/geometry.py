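"""Y-maze geometry: three arms radiating from a common center.

The maze is modeled as three straight arms of equal length joined at the
origin, 120 degrees apart.  Positions are 2-D coordinates in centimeters;
each arm is identified by a letter and a unit axis pointing from the center
to the arm terminal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

DEFAULT_ARM_ANGLES: tuple[tuple[str, float], ...] = (
    ("A", 90.0),
    ("B", 210.0),
    ("C", 330.0),
)


@dataclass(frozen=True)
class MazeGeometry:
    """Geometry of a symmetric Y-maze.

    Parameters
    ----------
    arm_length : float
        Length of each arm from center to terminal, in cm.
    arm_width : float
        Width of each arm, in cm.
    arm_angles_deg : tuple of (str, float)
        Arm labels and the angle (degrees, counterclockwise from +x) of the
        axis pointing from the center toward each arm terminal.
    """

    arm_length: float = 45.0
    arm_width: float = 8.0
    arm_angles_deg: tuple[tuple[str, float], ...] = DEFAULT_ARM_ANGLES

    def __post_init__(self) -> None:
        if self.arm_length <= 0 or self.arm_width <= 0:
            raise ValueError("arm_length and arm_width must be positive")
        if len(self.arms) != len(set(self.arms)):
            raise ValueError("arm labels must be unique")

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.arm_angles_deg)

    @property
    def axes(self) -> np.ndarray:
        """Unit vectors (n_arms, 2) from center to each arm terminal."""
        ang = np.deg2rad([angle for _, angle in self.arm_angles_deg])
        return np.column_stack([np.cos(ang), np.sin(ang)])

    def terminal(self, arm: str) -> np.ndarray:
        """Coordinates of an arm's terminal."""
        i = self.arms.index(arm)
        return self.axes[i] * self.arm_length

    def arm_projections(self, xy: np.ndarray) -> np.ndarray:
        """Signed projection (n_frames, n_arms) of positions onto arm axes."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.axes.T

    def assign_arm(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest arm index and penetration depth (cm) for each position.

        A point is attributed to the arm with the largest positive projection;
        the depth is that projection, clipped at zero for points behind the
        center.
        """
        proj = self.arm_projections(xy)
        idx = np.argmax(proj, axis=1)
        depth = np.clip(proj[np.arange(len(idx)), idx], 0.0, None)
        return idx, depth

    def to_yaml(self, path) -> None:
        data = {
            "arm_length": float(self.arm_length),
            "arm_width": float(self.arm_width),
            "arm_angles_deg": {label: float(a) for label, a in self.arm_angles_deg},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "MazeGeometry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        angles = tuple(sorted(data["arm_angles_deg"].items()))
        return cls(
            arm_length=float(data["arm_length"]),
            arm_width=float(data["arm_width"]),
            arm_angles_deg=angles,
        )
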