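"""Coordinate frames and rotations shared by the simulator and the planners.

Conventions
-----------
* The **lab frame** is fixed: X along the X-ray beam, Y vertical (up),
  Z along the horizontal goniometer rotation axis.  On the on-axis
  microscope image the column index runs along +Z (to the right) and the
  row index runs along -Y (downwards).
* The **sample frame** rotates with the goniometer spindle about Z by the
  angle ``omega`` (degrees).  At ``omega = 0`` the two frames coincide.
  All sample-frame coordinates are in micrometres.
* The loop tip points toward -Z (left in the image); the pin stem points
  toward +Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LabFrame", "rot2d", "sample_to_lab", "lab_to_sample", "wrap_angle"]


def wrap_angle(omega: float, period: float = 360.0) -> float:
    """Reduce an angle in degrees to ``[0, period)``."""
    return float(np.mod(omega, period))


def rot2d(omega_deg: float) -> np.ndarray:
    """Rotation matrix about the Z axis acting on (x, y) pairs."""
    w = np.deg2rad(omega_deg)
    c, s = np.cos(w), np.sin(w)
    return np.array([[c, -s], [s, c]])


def sample_to_lab(points: np.ndarray, omega_deg: float) -> np.ndarray:
    """Map sample-frame points (..., 3) to the lab frame at ``omega_deg``."""
    p = np.asarray(points, dtype=float)
    out = np.empty_like(p)
    r = rot2d(omega_deg)
    out[..., 0] = r[0, 0] * p[..., 0] + r[0, 1] * p[..., 1]
    out[..., 1] = r[1, 0] * p[..., 0] + r[1, 1] * p[..., 1]
    out[..., 2] = p[..., 2]
    return out


def lab_to_sample(points: np.ndarray, omega_deg: float) -> np.ndarray:
    """Inverse of :func:`sample_to_lab`."""
    return sample_to_lab(points, -omega_deg)


@dataclass(frozen=True)
class LabFrame:
    """The fixed laboratory frame plus the current spindle angle.

    The three axes must form a right-handed orthonormal triad; ``omega``
    wraps modulo 360 degrees.
    """

    beam_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    vertical: tuple[float, float, float] = (0.0, 1.0, 0.0)
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    omega: float = 0.0

    def __post_init__(self) -> None:
        axes = np.array([self.beam_direction, self.vertical, self.rotation_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValueError("lab axes must be mutually orthogonal unit vectors")
        object.__setattr__(self, "omega", wrap_angle(self.omega))

    def rotated(self, delta_omega: float) -> "LabFrame":
        return LabFrame(
            self.beam_direction, self.vertical, self.rotation_axis,
            wrap_angle(self.omega + delta_omega),
        )
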