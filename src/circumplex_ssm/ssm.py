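"""Structural summary method (SSM) for circumplex data.

An external scale's association with the circumplex is summarized by the
eight Pearson correlations between the scale and the octant scores (the
"interpersonal profile"). When the scale has prototypical interpersonal
content, the profile traces a cosine curve

    r_k ~= e + a * cos(theta_k - Theta)

whose parameters have a closed-form least-squares solution at equally
spaced octant angles theta_k:

    e = mean(r_k)                      (elevation)
    x = (2/8) * sum r_k cos(theta_k)   (communion vector component)
    y = (2/8) * sum r_k sin(theta_k)   (agency vector component)
    a = sqrt(x^2 + y^2)                (amplitude)
    Theta = atan2(y, x) mod 360        (angular displacement)
    R^2 = 1 - SS_res / SS_tot          (prototypicality)

The factor 2/8 makes (x, y) the cosine/sine regression coefficients, so the
closed form coincides with the general least-squares fit of
e + b1*cos(theta) + b2*sin(theta).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, OctantGeometry, signed_angle_diff

__all__ = [
    "CorrelationProfile",
    "SSMParams",
    "Cutoffs",
    "InterpretationRuling",
    "correlation_profile",
    "ssm_fit",
    "ssm_from_correlations",
    "polar_from_vectors",
    "apply_cutoffs",
]

#: amplitudes below this are treated as zero (angle undefined)
_AMPLITUDE_EPS = 1e-12


@dataclass
class CorrelationProfile:
    """Eight correlations of one external scale with the octant scores."""

    scale: str
    surface: str
    r: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if self.r.shape != (8,):
            raise ValueError("profile must hold exactly 8 correlations")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class SSMParams:
    """SSM parameters of one profile.

    ``theta`` is NaN when the profile is flat (amplitude 0); ``r2`` is NaN
    when the profile has zero variance (prototypicality undefined).
    """

    e: float
    x: float
    y: float
    a: float
    theta: float
    r2: float


@dataclass(frozen=True)
class Cutoffs:
    """Heuristic interpretation cut-offs for SSM parameters.

    Elevation and amplitude of at least |.10| count as elevated /
    differentiated; R^2 of at least .70 counts as an acceptable
    (prototypical) cosine fit; angles less than 22.5 degrees (half an
    octant) apart are not interpreted as meaningfully distinct.
    """

    elevation_min: float = 0.10
    amplitude_min: float = 0.10
    r2_min: float = 0.70
    angle_distinct_min: float = 22.5

    def __post_init__(self) -> None:
        for name in ("elevation_min", "amplitude_min", "r2_min", "angle_distinct_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class InterpretationRuling:
    """Gating flags for one profile under a set of cut-offs.

    ``differentiated`` and the angle are only reported when the profile is
    prototypical: a complex profile (low R^2) has no unified interpersonal
    theme, so its amplitude and angle are not interpretable regardless of
    magnitude.
    """

    elevated: bool
    prototypical: bool
    differentiated: bool
    angle_interpretable: bool


def correlation_profile(
    scale_scores: pd.Series,
    octant_scores: pd.DataFrame,
    geometry: OctantGeometry = DEFAULT_GEOMETRY,
    *,
    scale: str | None = None,
    surface: str = "",
) -> CorrelationProfile:
    """Pearson correlation of a scale with each octant, pairwise complete.

    Raises if the scale or an octant is constant on the complete pairs
    (the correlation would be undefined) or fewer than 3 complete pairs
    remain for an octant.
    """
    scale_name = scale or (scale_scores.name if scale_scores.name else "scale")
    octant_scores = octant_scores.loc[scale_scores.index, list(geometry.codes)]
    s = scale_scores.to_numpy(dtype=float)
    O = octant_scores.to_numpy(dtype=float)
    r = np.empty(8)
    n_pairs = np.empty(8, dtype=int)
    for k, code in enumerate(geometry.codes):
        o = O[:, k]
        mask = ~np.isnan(s) & ~np.isnan(o)
        n = int(mask.sum())
        n_pairs[k] = n
        if n < 3:
            raise ValueError(f"octant {code}: only {n} complete pairs (need >= 3)")
        sv, ov = s[mask], o[mask]
        if np.ptp(sv) == 0:
            raise ValueError(f"scale {scale_name!r} is constant; correlation undefined")
        if np.ptp(ov) == 0:
            raise ValueError(f"octant {code} is constant; correlation undefined")
        r[k] = np.corrcoef(sv, ov)[0, 1]
    return CorrelationProfile(scale=str(scale_name), surface=surface, r=r, n_pairs=n_pairs)


def ssm_from_correlations(r: np.ndarray, angles_deg: np.ndarray) -> SSMParams:
    """Closed-form SSM fit of a profile at the given (equally spaced) angles."""
    r = np.asarray(r, dtype=float)
    k = r.shape[-1]
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    e = float(np.mean(r))
    x = float(2.0 / k * np.sum(r * np.cos(rad)))
    y = float(2.0 / k * np.sum(r * np.sin(rad)))
    a = math.hypot(x, y)
    if a > _AMPLITUDE_EPS:
        theta = math.degrees(math.atan2(y, x)) % 360.0
        fitted = e + a * np.cos(rad - math.radians(theta))
    else:
        a = float(a)
        theta = float("nan")
        fitted = np.full(k, e)
    ss_tot = float(np.sum((r - e) ** 2))
    if ss_tot <= 1e-24:
        warnings.warn("flat profile: prototypicality (R^2) undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((r - fitted) ** 2)) / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
    return SSMParams(e=e, x=x, y=y, a=float(a), theta=theta, r2=r2)


def ssm_fit(profile: CorrelationProfile, geometry: OctantGeometry = DEFAULT_GEOMETRY) -> SSMParams:
    """SSM parameters of a correlation profile (see module docstring)."""
    return ssm_from_correlations(profile.r, geometry.angles_deg)


def polar_from_vectors(x: float, y: float) -> tuple[float, float]:
    """(amplitude, angle-in-degrees) from communion/agency components.

    The angle is NaN when the amplitude is zero.
    """
    a = math.hypot(x, y)
    if a <= _AMPLITUDE_EPS:
        return float(a), float("nan")
    return float(a), math.degrees(math.atan2(y, x)) % 360.0


def apply_cutoffs(params: SSMParams, cutoffs: Cutoffs = Cutoffs()) -> InterpretationRuling:
    """Interpretation gating of SSM parameters under heuristic cut-offs."""
    elevated = abs(params.e) >= cutoffs.elevation_min
    prototypical = bool(not math.isnan(params.r2) and params.r2 >= cutoffs.r2_min)
    differentiated = bool(prototypical and params.a >= cutoffs.amplitude_min)
    return InterpretationRuling(
        elevated=elevated,
        prototypical=prototypical,
        differentiated=differentiated,
        angle_interpretable=prototypical and differentiated,
    )


def angle_within(theta: float, low: float, high: float) -> bool:
    """Whether ``theta`` lies on the circular arc from ``low`` to ``high``
    (counterclockwise); used for octant-membership checks."""
    span = (high - low) % 360.0
    return (theta - low) % 360.0 <= span


def absolute_angle_distance(a: float, b: float) -> float:
    """Unsigned circular distance in degrees, in [0, 180]."""
    return abs(signed_angle_diff(a, b))
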