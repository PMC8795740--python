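"""Head-direction cell ring: feedforward velocity/heading encoding.

Each cell has a preferred angle on a ring; its signal is the current speed
times the cosine of the angle between its preferred direction and the current
heading. Signals are deliberately *not* rectified: cells opposing the heading
carry negative velocity modulation, which the downstream stripe plates
rectify through their own transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .trajectory import wrap_angle

__all__ = ["HeadDirectionRing", "RingReadout", "encode_velocity", "decode_ring"]


@dataclass(frozen=True)
class HeadDirectionRing:
    """Ring of head-direction cells with uniformly spaced preferred angles."""

    n_cells: int = 36

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("a head-direction ring needs at least 3 cells")

    @property
    def preferred_angles(self) -> np.ndarray:
        """Preferred angles theta_i, uniformly spaced on [0, 2*pi)."""
        return 2.0 * np.pi * np.arange(self.n_cells) / self.n_cells


class RingReadout(NamedTuple):
    speed: float
    heading: float
    heading_defined: bool


def encode_velocity(ring: HeadDirectionRing, speed: float, heading: float) -> np.ndarray:
    """Signed rate vector ``s_i = speed * cos(theta_i - heading)``."""
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return speed * np.cos(ring.preferred_angles - heading)


def decode_ring(ring: HeadDirectionRing, rates: np.ndarray) -> RingReadout:
    """Population-vector readout of (speed, heading) from ring signals.

    Exact inverse of :func:`encode_velocity` up to floating tolerance: the
    complex population vector of a cosine profile has argument equal to the
    heading and magnitude ``n_cells * speed / 2``. All-zero input leaves the
    heading undefined (flagged, heading reported as 0).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (ring.n_cells,):
        raise ValueError("rate vector length must match the ring size")
    z = np.sum(rates * np.exp(1j * ring.preferred_angles))
    speed = 2.0 * np.abs(z) / ring.n_cells
    if np.abs(z) < 1e-12 * (1.0 + np.max(np.abs(rates))):
        return RingReadout(0.0, 0.0, False)
    return RingReadout(float(speed), float(wrap_angle(np.angle(z))), True)
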