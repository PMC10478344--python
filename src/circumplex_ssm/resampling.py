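"""Bootstrap confidence intervals for SSM parameters and paired contrasts.

Case resampling: participants (rows) are drawn with replacement, scale and
octant scores jointly, and the SSM is refit on every resample. Percentile
intervals are reported for elevation, the two vector components and the
amplitude. The angular displacement is circular, so its interval is built
from the bootstrap deviations recentered on the point estimate: each
bootstrap angle is mapped to its signed circular deviation in
(-180, 180], percentiles of the deviations are taken, and the bounds are
the point estimate plus those percentiles (mod 360). This avoids the
wrap-around artifacts a naive percentile would produce for profiles
pointing near 0/360 degrees.

Contrasts between two scales measured on the same participants are paired:
both profiles are refit on the same resampled rows and the per-parameter
differences collected. Angle differences are taken on the circle and
signed into (-180, 180].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, OctantGeometry, signed_angle_diff
from .ssm import (
    Cutoffs,
    SSMParams,
    apply_cutoffs,
    correlation_profile,
    ssm_fit,
)

__all__ = [
    "BootstrapConfig",
    "SSMInterval",
    "ContrastResult",
    "bootstrap_ssm",
    "contrast_profiles",
]

_PARAMS = ("e", "x", "y", "a", "theta")


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling configuration: B resamples, CI level, RNG seed."""

    n_boot: int = 2000
    level: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")


@dataclass
class SSMInterval:
    """Point estimate plus percentile CI bounds per SSM parameter.

    ``lower``/``upper`` are keyed by parameter name (e, x, y, a, theta).
    The theta bounds live on the circle: lower may numerically exceed
    upper when the interval crosses 0/360.
    """

    point: SSMParams
    lower: dict[str, float]
    upper: dict[str, float]
    b_effective: int
    n: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class ContrastResult:
    """Paired bootstrap differences (scale_a minus scale_b) per parameter.

    ``delta['theta']`` is the signed circular angle difference in
    (-180, 180]. ``significant[p]`` flags CIs excluding zero.
    ``angle_status`` is 'ok' or 'excluded' — when either scale fails the
    prototypicality or amplitude cut-off on its point estimate, the
    angular contrast is computed but suppressed from interpretation.
    ``distinct_angle`` additionally requires |delta theta| of at least
    half an octant (22.5 degrees).
    """

    scale_pair: tuple[str, str]
    delta: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    boot_mean: dict[str, float]
    significant: dict[str, bool]
    angle_status: str
    distinct_angle: bool | None
    b_effective: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# batched internals
# ---------------------------------------------------------------------------


def _batched_profiles(
    scale: np.ndarray, octants: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation profiles of B row-resamples.

    scale: (n,), octants: (n, 8), idx: (B, n) row indices.
    Returns (r (B, 8), valid (B,)) where invalid rows had a degenerate
    (zero-variance or <3 complete pairs) correlation.
    """
    xs = scale[idx]  # (B, n)
    Ys = octants[idx]  # (B, n, 8)
    has_nan = np.isnan(xs).any() or np.isnan(Ys).any()
    if has_nan:
        w = (~np.isnan(xs))[:, :, None] & ~np.isnan(Ys)  # (B, n, 8)
        xs0 = np.where(np.isnan(xs), 0.0, xs)[:, :, None]
        Ys0 = np.where(np.isnan(Ys), 0.0, Ys)
        wf = w.astype(float)
        nw = wf.sum(axis=1)
        sx = (xs0 * wf).sum(axis=1)
        sy = (Ys0 * wf).sum(axis=1)
        sxx = (xs0 * xs0 * wf).sum(axis=1)
        syy = (Ys0 * Ys0 * wf).sum(axis=1)
        sxy = (xs0 * Ys0 * wf).sum(axis=1)
    else:
        n = xs.shape[1]
        nw = np.full((xs.shape[0], octants.shape[1]), float(n))
        sx = xs.sum(axis=1)[:, None] * np.ones((1, octants.shape[1]))
        sy = Ys.sum(axis=1)
        sxx = (xs * xs).sum(axis=1)[:, None] * np.ones((1, octants.shape[1]))
        syy = (Ys * Ys).sum(axis=1)
        sxy = np.einsum("bn,bnk->bk", xs, Ys)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / nw
        vx = sxx - sx**2 / nw
        vy = syy - sy**2 / nw
        r = cov / np.sqrt(vx * vy)
    enough = nw >= 3
    ok = enough & (vx > 1e-16) & (vy > 1e-16)
    valid = ok.all(axis=1)
    r = np.where(ok, r, np.nan)
    return r, valid


def _batched_ssm(r: np.ndarray, angles_deg: np.ndarray):
    """Vectorized closed-form SSM over profiles r of shape (B, k)."""
    k = r.shape[1]
    rad = np.deg2rad(angles_deg)
    e = r.mean(axis=1)
    x = 2.0 / k * (r * np.cos(rad)).sum(axis=1)
    y = 2.0 / k * (r * np.sin(rad)).sum(axis=1)
    a = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return e, x, y, a, theta


def _align(
    scale_scores: pd.Series, octant_scores: pd.DataFrame, geometry: OctantGeometry
) -> tuple[np.ndarray, np.ndarray]:
    if not scale_scores.index.equals(octant_scores.index):
        common = scale_scores.index.intersection(octant_scores.index)
        if len(common) == 0:
            raise ValueError("scale and octant tables share no participants")
        scale_scores = scale_scores.loc[common]
        octant_scores = octant_scores.loc[common]
    return (
        scale_scores.to_numpy(dtype=float),
        octant_scores[list(geometry.codes)].to_numpy(dtype=float),
    )


def _percentile_bounds(draws: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(draws, alpha)), float(np.quantile(draws, 1.0 - alpha))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def bootstrap_ssm(
    scale_scores: pd.Series,
    octant_scores: pd.DataFrame,
    geometry: OctantGeometry = DEFAULT_GEOMETRY,
    config: BootstrapConfig = BootstrapConfig(),
    *,
    resampler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
) -> SSMInterval:
    """Percentile bootstrap CI around the SSM parameters of one profile.

    ``resampler(rng, n_boot, n)`` may override how the (B, n) row-index
    matrix is drawn (the default draws rows with replacement); it exists
    for degenerate-resampling contracts in tests.
    """
    s, O = _align(scale_scores, octant_scores, geometry)
    n = s.shape[0]
    if n < 20:
        raise ValueError(f"refusing to bootstrap n={n} (< 20 participants)")
    point = ssm_fit(
        correlation_profile(
            pd.Series(s, name=scale_scores.name), pd.DataFrame(O, columns=list(geometry.codes)),
            geometry,
        ),
        geometry,
    )

    rng = np.random.default_rng(config.seed)
    if resampler is None:
        idx = rng.integers(0, n, size=(config.n_boot, n))
    else:
        idx = resampler(rng, config.n_boot, n)
    r, valid = _batched_profiles(s, O, idx)
    b_eff = int(valid.sum())
    warns: list[str] = []
    if b_eff < config.n_boot:
        r = r[valid]
    if b_eff < 0.9 * config.n_boot:
        msg = f"only {b_eff}/{config.n_boot} non-degenerate bootstrap resamples"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    if b_eff == 0:
        raise ValueError("all bootstrap resamples degenerate")

    e, x, y, a, theta = _batched_ssm(r, geometry.angles_deg)
    lower: dict[str, float] = {}
    upper: dict[str, float] = {}
    for name, draws in (("e", e), ("x", x), ("y", y), ("a", a)):
        lower[name], upper[name] = _percentile_bounds(draws, config.level)
    if math.isnan(point.theta):
        lower["theta"] = upper["theta"] = float("nan")
    else:
        dev = np.asarray(signed_angle_diff(theta, point.theta))
        lo, hi = _percentile_bounds(dev, config.level)
        # the recentered interval must contain the point estimate
        lo, hi = min(lo, 0.0), max(hi, 0.0)
        lower["theta"] = (point.theta + lo) % 360.0
        upper["theta"] = (point.theta + hi) % 360.0
    return SSMInterval(point=point, lower=lower, upper=upper,
                       b_effective=b_eff, n=n, warnings=warns)


def contrast_profiles(
    scale_a_scores: pd.Series,
    scale_b_scores: pd.Series,
    octant_scores: pd.DataFrame,
    geometry: OctantGeometry = DEFAULT_GEOMETRY,
    config: BootstrapConfig = BootstrapConfig(),
    *,
    cutoffs: Cutoffs | None = None,
    resampler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
) -> ContrastResult:
    """Paired bootstrap CI for SSM parameter differences of two scales.

    Both scales must be measured on the same participants; every resample
    refits both profiles on the same rows. When ``cutoffs`` is given and
    either scale fails the R^2 or amplitude cut-off on its point estimate,
    the angular contrast is computed but marked 'excluded'.
    """
    name_a = str(scale_a_scores.name or "a")
    name_b = str(scale_b_scores.name or "b")
    common = scale_a_scores.index.intersection(scale_b_scores.index).intersection(
        octant_scores.index
    )
    if len(common) == 0:
        raise ValueError("scales share no participants (paired design required)")
    sa = scale_a_scores.loc[common].to_numpy(dtype=float)
    sb = scale_b_scores.loc[common].to_numpy(dtype=float)
    O = octant_scores.loc[common, list(geometry.codes)].to_numpy(dtype=float)
    n = len(common)
    if n < 20:
        raise ValueError(f"refusing to bootstrap n={n} (< 20 participants)")

    cols = list(geometry.codes)
    point_a = ssm_fit(correlation_profile(pd.Series(sa, name=name_a),
                                          pd.DataFrame(O, columns=cols), geometry), geometry)
    point_b = ssm_fit(correlation_profile(pd.Series(sb, name=name_b),
                                          pd.DataFrame(O, columns=cols), geometry), geometry)

    angle_status = "ok"
    if cutoffs is not None:
        for p in (point_a, point_b):
            ruling = apply_cutoffs(p, cutoffs)
            if not ruling.angle_interpretable:
                angle_status = "excluded"

    delta = {
        "e": point_a.e - point_b.e,
        "x": point_a.x - point_b.x,
        "y": point_a.y - point_b.y,
        "a": point_a.a - point_b.a,
        "theta": signed_angle_diff(point_a.theta, point_b.theta)
        if not (math.isnan(point_a.theta) or math.isnan(point_b.theta))
        else float("nan"),
    }

    rng = np.random.default_rng(config.seed)
    if resampler is None:
        idx = rng.integers(0, n, size=(config.n_boot, n))
    else:
        idx = resampler(rng, config.n_boot, n)
    ra, va = _batched_profiles(sa, O, idx)
    rb, vb = _batched_profiles(sb, O, idx)
    valid = va & vb
    b_eff = int(valid.sum())
    warns: list[str] = []
    if b_eff < 0.9 * config.n_boot:
        msg = f"only {b_eff}/{config.n_boot} non-degenerate bootstrap resamples"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    if b_eff == 0:
        raise ValueError("all bootstrap resamples degenerate")
    ra, rb = ra[valid], rb[valid]
    ea, xa, ya, aa, ta = _batched_ssm(ra, geometry.angles_deg)
    eb, xb, yb, ab, tb = _batched_ssm(rb, geometry.angles_deg)

    draws = {
        "e": ea - eb,
        "x": xa - xb,
        "y": ya - yb,
        "a": aa - ab,
    }
    lower: dict[str, float] = {}
    upper: dict[str, float] = {}
    boot_mean: dict[str, float] = {}
    for name, d in draws.items():
        lower[name], upper[name] = _percentile_bounds(d, config.level)
        boot_mean[name] = float(np.mean(d))
    if math.isnan(delta["theta"]):
        lower["theta"] = upper["theta"] = boot_mean["theta"] = float("nan")
    else:
        dtheta = np.asarray(signed_angle_diff(ta, tb))
        dev = np.asarray(signed_angle_diff(dtheta, delta["theta"]))
        lo, hi = _percentile_bounds(dev, config.level)
        lo, hi = min(lo, 0.0), max(hi, 0.0)
        lower["theta"] = delta["theta"] + lo
        upper["theta"] = delta["theta"] + hi
        boot_mean["theta"] = delta["theta"] + float(np.mean(dev))

    significant = {
        p: bool(not math.isnan(lower[p]) and (lower[p] > 0.0 or upper[p] < 0.0))
        for p in _PARAMS
    }
    if angle_status == "excluded" or math.isnan(delta["theta"]):
        distinct: bool | None = None
    else:
        min_sep = (cutoffs or Cutoffs()).angle_distinct_min
        distinct = bool(significant["theta"] and abs(delta["theta"]) >= min_sep)
    return ContrastResult(
        scale_pair=(name_a, name_b),
        delta=delta,
        lower=lower,
        upper=upper,
        boot_mean=boot_mean,
        significant=significant,
        angle_status=angle_status,
        distinct_angle=distinct,
        b_effective=b_eff,
        warnings=warns,
    )
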