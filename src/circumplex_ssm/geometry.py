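"""Octant geometry of the interpersonal circumplex (IPC).

The IPC divides the two-dimensional space spanned by communion/affiliation
(x-axis) and agency/dominance (y-axis) into eight 45-degree octants. Each
octant carries a two-letter code and an angular midpoint, with LM (warm) at
0/360 degrees, PA (dominant) at 90, DE (cold) at 180 and HI (submissive)
at 270. All angles in this package are degrees, counterclockwise, reported
in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "OctantGeometry",
    "DEFAULT_GEOMETRY",
    "wrap_angle",
    "signed_angle_diff",
]

_DEFAULT_CODES = ("PA", "BC", "DE", "FG", "HI", "JK", "LM", "NO")
_DEFAULT_ANGLES = {
    "PA": 90.0,
    "BC": 135.0,
    "DE": 180.0,
    "FG": 225.0,
    "HI": 270.0,
    "JK": 315.0,
    "LM": 360.0,
    "NO": 45.0,
}


def wrap_angle(theta: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees into [0, 360)."""
    return np.asarray(theta) % 360.0 if isinstance(theta, np.ndarray) else float(theta) % 360.0


def signed_angle_diff(a: float | np.ndarray, b: float | np.ndarray) -> float | np.ndarray:
    """Signed circular difference a - b in degrees, in (-180, 180].

    The convention keeps +180 (exact opposition) positive so the result is
    single-valued.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if d.ndim == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class OctantGeometry:
    """The eight IPC octant codes and their angular midpoints in degrees.

    Invariants (checked at construction): exactly eight codes, angles
    distinct, equally spaced at 45 degrees on the circle, each in (0, 360].
    """

    codes: tuple[str, ...] = _DEFAULT_CODES
    angles: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ANGLES))

    def __post_init__(self) -> None:
        if len(self.codes) != 8:
            raise ValueError(f"expected 8 octant codes, got {len(self.codes)}")
        if set(self.codes) != set(self.angles):
            raise ValueError("codes and angle map must cover the same octants")
        vals = np.array([self.angles[c] for c in self.codes], dtype=float)
        if np.any(vals <= 0) or np.any(vals > 360):
            raise ValueError("octant angles must lie in (0, 360]")
        if len(np.unique(vals)) != 8:
            raise ValueError("octant angles must be distinct")
        gaps = np.sort(vals % 360.0)
        spacing = np.diff(np.concatenate([gaps, [gaps[0] + 360.0]]))
        if not np.allclose(spacing, 45.0):
            raise ValueError("octant angles must be equally spaced at 45 degrees")

    @property
    def angles_deg(self) -> np.ndarray:
        """Angular midpoints as an array ordered like ``codes``."""
        return np.array([self.angles[c] for c in self.codes], dtype=float)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)

    def octant_of(self, theta: float) -> str:
        """Code of the octant whose 45-degree sector contains ``theta``."""
        theta = wrap_angle(theta)
        diffs = np.abs(np.asarray(signed_angle_diff(theta, self.angles_deg)))
        return self.codes[int(np.argmin(diffs))]


DEFAULT_GEOMETRY = OctantGeometry()
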