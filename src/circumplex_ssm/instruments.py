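"""Instrument scoring keys, protocol screening, scale/octant scoring.

Response data are plain pandas DataFrames: one row per participant (the
index holds unique participant ids), one column per item, integer-valued
responses with NaN marking blanks. They are read from delimited text with
a header row of item ids and the participant id in the first column.

Scoring keys are small structured config files (YAML), one per instrument,
listing item ids, scale membership, response bounds, the aggregation rule
(sum or mean) and — for circumplex instruments — the octant assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .geometry import DEFAULT_GEOMETRY, OctantGeometry

__all__ = [
    "ScoringKey",
    "ScreeningRules",
    "ExclusionLedger",
    "ScreeningResult",
    "read_responses",
    "write_responses",
    "screen_protocols",
    "score_scale",
    "score_octants",
    "omega_total",
    "ReliabilityResult",
]

#: minimum fraction of a scale's items a participant must answer for their
#: scale score to be computed (prorated); below this the score is missing.
PRORATE_MIN_ANSWERED = 0.8


# ---------------------------------------------------------------------------
# keys and response tables
# ---------------------------------------------------------------------------


@dataclass
class ScoringKey:
    """Scoring key for one instrument.

    ``scale_map`` maps each scale label to the ordered subset of
    ``item_ids`` that it aggregates; ``octant_map`` (circumplex instruments
    only) maps each of the eight octant codes to an equally sized item
    subset.
    """

    instrument: str
    item_ids: list[str]
    scale_map: dict[str, list[str]]
    response_min: int
    response_max: int
    aggregation: str = "mean"
    octant_map: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValueError("response_min must be < response_max")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        known = set(self.item_ids)
        covered: set[str] = set()
        for scale, items in self.scale_map.items():
            extra = set(items) - known
            if extra:
                raise ValueError(f"scale {scale!r} references unknown items {sorted(extra)}")
            covered |= set(items)
        if self.octant_map is not None:
            counts = {o: len(v) for o, v in self.octant_map.items()}
            if set(self.octant_map) != set(DEFAULT_GEOMETRY.codes):
                raise ValueError("octant_map must cover all 8 octants")
            if len(set(counts.values())) != 1:
                raise ValueError(f"octants must have equal item counts, got {counts}")
            for o, items in self.octant_map.items():
                extra = set(items) - known
                if extra:
                    raise ValueError(f"octant {o} references unknown items {sorted(extra)}")
                covered |= set(items)
        uncovered = known - covered
        if uncovered:
            raise ValueError(f"items belong to no scale: {sorted(uncovered)}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "instrument": self.instrument,
            "items": list(self.item_ids),
            "scales": {k: list(v) for k, v in self.scale_map.items()},
            "response_min": int(self.response_min),
            "response_max": int(self.response_max),
            "aggregation": self.aggregation,
        }
        if self.octant_map is not None:
            d["octants"] = {k: list(v) for k, v in self.octant_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringKey":
        return cls(
            instrument=d["instrument"],
            item_ids=list(d["items"]),
            scale_map={k: list(v) for k, v in d["scales"].items()},
            response_min=int(d["response_min"]),
            response_max=int(d["response_max"]),
            aggregation=d.get("aggregation", "mean"),
            octant_map={k: list(v) for k, v in d["octants"].items()} if "octants" in d else None,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringKey":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a delimited response table (first column = participant id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate participant ids: {dupes}")
    return df.astype(float)


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="participant_id")


def _check_bounds(values: pd.DataFrame, key: ScoringKey) -> None:
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < key.response_min) | (arr > key.response_max)
    if np.any(bad & ~np.isnan(arr)):
        rows, cols = np.where(bad & ~np.isnan(arr))
        item = values.columns[cols[0]]
        pid = values.index[rows[0]]
        raise ValueError(
            f"response out of bounds for instrument {key.instrument!r}: "
            f"participant {pid!r}, item {item!r}"
        )


# ---------------------------------------------------------------------------
# protocol screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningRules:
    """Protocol-validity screening rules.

    A participant is excluded iff their fraction of blank items is strictly
    greater than ``max_missing_fraction``, or their infrequency (careless
    responding) score exceeds ``norm_mean + cutoff * norm_sd`` of a
    normative sample, or they are manually flagged. Exclusions are
    attributed to the first rule that catches a participant, in that order,
    so the ledger counts are disjoint.
    """

    max_missing_fraction: float = 0.02
    infrequency_norm_mean: float = 0.0
    infrequency_norm_sd: float = 1.0
    infrequency_sd_cutoff: float = 2.5
    manual_exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing_fraction < 1):
            raise ValueError("max_missing_fraction must be in [0, 1)")
        if self.infrequency_sd_cutoff <= 0:
            raise ValueError("infrequency_sd_cutoff must be > 0")

    @property
    def infrequency_threshold(self) -> float:
        return self.infrequency_norm_mean + self.infrequency_sd_cutoff * self.infrequency_norm_sd


@dataclass
class ExclusionLedger:
    """Per-rule exclusion counts and per-participant reasons."""

    counts: dict[str, int]
    reasons: dict[str, str]

    @property
    def n_excluded(self) -> int:
        return len(self.reasons)


@dataclass
class ScreeningResult:
    retained: pd.DataFrame
    ledger: ExclusionLedger


def screen_protocols(
    responses: pd.DataFrame,
    validity_scores: pd.Series,
    rules: ScreeningRules,
) -> ScreeningResult:
    """Apply protocol screening and return retained rows plus a ledger.

    ``validity_scores`` holds per-participant infrequency totals, indexed
    like ``responses``. Rules are applied in the fixed order missingness →
    infrequency → manual flag; each excluded participant is attributed to
    the first rule that catches them.
    """
    if responses.shape[0] == 0 or responses.shape[1] == 0:
        raise ValueError("empty response matrix")
    unknown = set(rules.manual_exclusions) - set(responses.index)
    if unknown:
        raise ValueError(f"manual exclusions reference unknown participants: {sorted(unknown)}")
    missing_validity = responses.index.difference(validity_scores.index)
    if len(missing_validity):
        raise ValueError(
            f"validity scores missing for participants: {list(missing_validity[:5])}"
        )

    missing_frac = responses.isna().mean(axis=1)
    threshold = rules.infrequency_threshold
    manual = set(rules.manual_exclusions)

    reasons: dict[str, str] = {}
    for pid in responses.index:
        if missing_frac[pid] > rules.max_missing_fraction:
            reasons[pid] = "missingness"
        elif validity_scores[pid] > threshold:
            reasons[pid] = "infrequency"
        elif pid in manual:
            reasons[pid] = "manual"
    counts = {
        "missingness": sum(1 for r in reasons.values() if r == "missingness"),
        "infrequency": sum(1 for r in reasons.values() if r == "infrequency"),
        "manual": sum(1 for r in reasons.values() if r == "manual"),
    }
    retained = responses.loc[[p for p in responses.index if p not in reasons]]
    return ScreeningResult(retained=retained, ledger=ExclusionLedger(counts=counts, reasons=reasons))


# ---------------------------------------------------------------------------
# scale and octant scoring
# ---------------------------------------------------------------------------


def _aggregate(values: pd.DataFrame, aggregation: str) -> pd.Series:
    """Prorated aggregation of one scale's items.

    Sum scales return mean(answered) * n_items (the prorated sum); mean
    scales return mean(answered). Participants answering fewer than
    ``PRORATE_MIN_ANSWERED`` of the items get a missing score.
    """
    n_items = values.shape[1]
    answered = values.notna().sum(axis=1)
    mean = values.mean(axis=1)
    if aggregation == "sum":
        score = mean * n_items
    else:
        score = mean
    score[answered < PRORATE_MIN_ANSWERED * n_items] = np.nan
    return score


def score_scale(responses: pd.DataFrame, key: ScoringKey, scale: str) -> pd.Series:
    """Per-participant score on one scale of ``key``."""
    if scale not in key.scale_map:
        raise KeyError(f"unknown scale {scale!r} for instrument {key.instrument!r}")
    items = key.scale_map[scale]
    missing_cols = [i for i in items if i not in responses.columns]
    if missing_cols:
        raise ValueError(f"response table lacks items {missing_cols} of scale {scale!r}")
    values = responses[items]
    _check_bounds(values, key)
    if values.notna().sum(axis=1).eq(0).all():
        raise ValueError(f"all items missing for scale {scale!r}")
    out = _aggregate(values, key.aggregation)
    out.name = scale
    return out


def score_octants(
    responses: pd.DataFrame,
    key: ScoringKey,
    geometry: OctantGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Participant x 8 octant score table, columns in geometry order.

    Each octant is scored with the same aggregation and proration contract
    as :func:`score_scale`.
    """
    if key.octant_map is None:
        raise ValueError(f"instrument {key.instrument!r} has no octant map")
    missing = [o for o in geometry.codes if o not in key.octant_map]
    if missing:
        raise ValueError(f"octant map lacks octants {missing}")
    cols = {}
    for code in geometry.codes:
        values = responses[key.octant_map[code]]
        _check_bounds(values, key)
        cols[code] = _aggregate(values, key.aggregation)
    return pd.DataFrame(cols, index=responses.index)


# ---------------------------------------------------------------------------
# internal consistency: McDonald's omega-total
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityResult:
    """Single-factor reliability (McDonald's omega-total) for one scale."""

    scale: str
    omega_t: float
    loadings: np.ndarray
    uniquenesses: np.ndarray
    n_used: int
    estimator: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega_t <= 1.0):
            raise ValueError("omega_t outside [0, 1]")


def omega_from_loadings(loadings: np.ndarray, uniquenesses: np.ndarray) -> float:
    """omega_t = (sum lambda)^2 / ((sum lambda)^2 + sum psi)."""
    s = float(np.sum(loadings))
    psi = float(np.sum(np.clip(uniquenesses, 0.0, None)))
    return s * s / (s * s + psi)


def _ml_single_factor(S: np.ndarray, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood single-factor fit of a covariance matrix.

    Minimizes the normal-theory discrepancy log|Sigma| + tr(S Sigma^-1)
    over Sigma = lambda lambda' + diag(psi), with analytic gradients.
    Returns (loadings, uniquenesses, converged).
    """
    from scipy.optimize import minimize

    p = S.shape[0]
    diag = np.diag(S).copy()
    # principal-component start
    w, v = np.linalg.eigh(S)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
    psi0 = np.clip(diag - lam0**2, 1e-4 * diag, None)

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return theta[:p], np.exp(theta[p:])

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam, psi = unpack(theta)
        sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        inv = np.linalg.inv(sigma)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        f = logdet + float(np.trace(S @ inv))
        A = inv - inv @ S @ inv  # dF/dSigma
        grad_lam = 2.0 * A @ lam
        grad_logpsi = np.diag(A) * psi
        return f, np.concatenate([grad_lam, grad_logpsi])

    theta0 = np.concatenate([lam0, np.log(psi0)])
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    lam, psi = unpack(res.x)
    if np.sum(lam) < 0:
        lam = -lam
    return lam, psi, bool(res.success)


def _principal_axis(R: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Iterated principal-axis single-factor fit of a correlation matrix."""
    p = R.shape[0]
    h2 = 1.0 - 1.0 / np.clip(np.diag(np.linalg.pinv(R)), 1.0, None)  # SMC start
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        w, v = np.linalg.eigh(Rh)
        lam = v[:, -1] * np.sqrt(max(w[-1], 0.0))
        new_h2 = np.clip(lam**2, 0.0, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    if np.sum(lam) < 0:
        lam = -lam
    return lam, np.clip(1.0 - lam**2, 0.0, None)


def omega_total(
    item_scores: pd.DataFrame,
    scale: str | None = None,
    *,
    estimator: str = "minres",
) -> ReliabilityResult:
    """McDonald's omega-total for one scale's item responses.

    Fits a single-factor model to the Pearson correlations of complete
    rows. The default estimator is a minres-style iterated principal-axis
    fit, which matches only the off-diagonal structure: for mutually
    independent items it correctly drives the loadings (and omega) to
    zero, whereas a full-likelihood fit is non-identified there (a
    one-item "factor" reproduces a diagonal covariance exactly).
    ``estimator='ml'`` requests normal-theory maximum likelihood on the
    covariance matrix, with a principal-axis fallback on non-convergence.
    Requires at least 3 items and 50 complete rows.
    """
    name = scale or "scale"
    complete = item_scores.dropna()
    if item_scores.shape[1] < 3:
        raise ValueError(f"omega_t needs >= 3 items, got {item_scores.shape[1]}")
    if complete.shape[0] < 50:
        raise ValueError(f"omega_t needs >= 50 complete rows, got {complete.shape[0]}")
    X = complete.to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [complete.columns[i] for i in np.where(sds == 0)[0]]
        raise ValueError(f"constant items: {bad}")
    if estimator == "ml":
        S = np.cov(X, rowvar=False)
        lam, psi, ok = _ml_single_factor(S)
        used = "ml"
        if not ok:
            warnings.warn(
                f"ML single-factor fit did not converge for {name!r}; "
                "falling back to principal-axis estimation",
                stacklevel=2,
            )
            R = np.corrcoef(X, rowvar=False)
            lam, psi = _principal_axis(R)
            used = "minres"
    elif estimator == "minres":
        R = np.corrcoef(X, rowvar=False)
        lam, psi = _principal_axis(R)
        used = "minres"
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    omega = float(np.clip(omega_from_loadings(lam, psi), 0.0, 1.0))
    return ReliabilityResult(
        scale=name,
        omega_t=omega,
        loadings=lam,
        uniquenesses=psi,
        n_used=complete.shape[0],
        estimator=used,
    )
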