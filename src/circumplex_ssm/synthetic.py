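"""Synthetic participant data with prescribed circumplex structure.

The generator draws from a zero-mean, unit-variance multivariate normal
whose correlation matrix encodes (a) a circulant octant block,
corr(O_j, O_k) = c0 + c1 * cos(theta_j - theta_k), and (b) per-scale
target interpersonal profiles, corr(S, O_k) = e + a * cos(theta_k -
Theta). Both blocks arise from a common latent model — a general factor g
plus two circle factors (X, Y) — so the joint matrix is feasible by
construction whenever each scale's communalities fit: the scale loads
e/sqrt(c0) on g and a/sqrt(c1) on the circle factors. Scale-scale
correlations default to what this shared structure implies.

Optional post-processing emulates questionnaire data: Likert
discretization via normal quantile thresholds (equal category
probabilities by default, with a skew knob to mimic floor effects), MCAR
missingness, and a fraction of careless responders with random answers
and elevated infrequency (validity) scores.

:func:`make_study_fixture` packages a 929-protocol item-level roster
engineered so that protocol screening excludes exactly 31 participants
for missingness, 39 for infrequency and 3 by manual flag, leaving 856 —
with retained profiles following three archetypes: a cold detachment
scale near 184 degrees, a social-anxiety scale near 245 degrees, and a
psychoticism scale with a modest vindictive (147 degree) theme, each with
a roughly opposite, lower-amplitude profile on a second (sensitivities)
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import DEFAULT_GEOMETRY, OctantGeometry
from .instruments import ScoringKey, ScreeningRules

__all__ = [
    "ScaleTarget",
    "DiscretizeSpec",
    "SyntheticSpec",
    "SyntheticDataset",
    "StudyFixture",
    "InfeasibleSpecError",
    "build_target_correlation",
    "simulate_sample",
    "make_study_fixture",
    "FIXTURE_SEED",
]

#: recorded seed of the packaged study fixture
FIXTURE_SEED = 20230111

#: default octant structure constants: adjacent octants correlate ~.51,
#: orthogonal ~.30, opposite ~0 — a strict circumplex with a general factor
DEFAULT_OCTANT_BASE = 0.30
DEFAULT_COSINE_DECAY = 0.30


class InfeasibleSpecError(ValueError):
    """The requested correlation targets admit no valid joint matrix."""


@dataclass(frozen=True)
class ScaleTarget:
    """Target SSM profile (elevation, amplitude, angle) for one scale."""

    label: str
    e: float
    a: float
    theta: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 <= self.theta < 360):
            raise ValueError("theta must lie in [0, 360)")


@dataclass(frozen=True)
class DiscretizeSpec:
    """Likert discretization of unit-normal scores.

    Categories get equal probabilities by default; ``skew`` in [0, 1)
    shrinks upper-category probabilities geometrically (floor effect).
    """

    octant_levels: int | None = None
    octant_min: int = 0
    scale_levels: int | None = None
    scale_min: int = 0
    skew: float = 0.0


@dataclass
class SyntheticSpec:
    """Generator configuration for one circumplex surface plus m scales."""

    n: int = 856
    octant_base: float = DEFAULT_OCTANT_BASE
    cosine_decay: float = DEFAULT_COSINE_DECAY
    scales: Sequence[ScaleTarget] = field(default_factory=list)
    discretize: DiscretizeSpec | None = None
    missing_rate: float = 0.0
    infrequency_contamination: float = 0.0
    seed: int | None = None
    scale_scale: np.ndarray | None = None  # optional override, PSD-checked

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must be in [0, 0.5)")
        if not (0 <= self.infrequency_contamination < 1):
            raise ValueError("infrequency_contamination must be in [0, 1)")
        if self.octant_base < 0 or self.cosine_decay < 0:
            raise ValueError("octant structure constants must be >= 0")
        if self.octant_base + self.cosine_decay > 1 + 1e-12:
            raise ValueError("octant_base + cosine_decay must be <= 1")


@dataclass
class SyntheticDataset:
    """Simulated octant and scale scores with provenance."""

    octants: pd.DataFrame
    scales: pd.DataFrame
    validity: pd.Series | None
    careless_ids: list[str]
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# joint correlation matrix
# ---------------------------------------------------------------------------

_MAX_REPAIR_DISTORTION = 0.01


def build_target_correlation(
    spec: SyntheticSpec, geometry: OctantGeometry = DEFAULT_GEOMETRY
) -> tuple[list[str], np.ndarray]:
    """Joint (8 + m) correlation matrix implied by the spec.

    Raises :class:`InfeasibleSpecError` when a scale's profile cannot be
    embedded (communality above 1), or when positive-semidefinite repair
    of an overridden scale-scale block would move any target entry by
    more than .01.
    """
    angles = geometry.angles_rad
    c0, c1 = spec.octant_base, spec.cosine_decay
    k = 8
    m = len(spec.scales)
    labels = list(geometry.codes) + [s.label for s in spec.scales]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels between octants and scales")

    C = np.eye(k + m)
    # circulant octant block
    dtheta = angles[:, None] - angles[None, :]
    C[:k, :k] = c0 + c1 * np.cos(dtheta)
    np.fill_diagonal(C[:k, :k], 1.0)

    alphas = np.empty(m)
    gammas = np.empty(m)
    thetas = np.empty(m)
    for i, s in enumerate(spec.scales):
        if c0 == 0 and s.e != 0:
            raise InfeasibleSpecError(f"scale {s.label!r}: elevation needs octant_base > 0")
        if c1 == 0 and s.a != 0:
            raise InfeasibleSpecError(f"scale {s.label!r}: amplitude needs cosine_decay > 0")
        alphas[i] = s.e / np.sqrt(c0) if c0 > 0 else 0.0
        gammas[i] = s.a / np.sqrt(c1) if c1 > 0 else 0.0
        thetas[i] = np.deg2rad(s.theta)
        communality = alphas[i] ** 2 + gammas[i] ** 2
        if communality > 1 + 1e-12:
            raise InfeasibleSpecError(
                f"scale {s.label!r}: profile (e={s.e}, a={s.a}) implies latent "
                f"communality {communality:.3f} > 1 under octant structure "
                f"(c0={c0}, c1={c1})"
            )
        C[:k, k + i] = C[k + i, :k] = s.e + s.a * np.cos(angles - thetas[i])

    if spec.scale_scale is not None:
        ss = np.asarray(spec.scale_scale, dtype=float)
        if ss.shape != (m, m):
            raise ValueError("scale_scale override has wrong shape")
        C[k:, k:] = ss
        np.fill_diagonal(C[k:, k:], 1.0)
    else:
        # implied by the shared latent structure
        for i in range(m):
            for j in range(i + 1, m):
                rij = alphas[i] * alphas[j] + gammas[i] * gammas[j] * np.cos(
                    thetas[i] - thetas[j]
                )
                C[k + i, k + j] = C[k + j, k + i] = rij

    C = (C + C.T) / 2.0
    w = np.linalg.eigvalsh(C)
    if w[0] < -1e-10:
        # eigenvalue clipping + renormalization to unit diagonal
        w_full, v = np.linalg.eigh(C)
        repaired = (v * np.clip(w_full, 0.0, None)) @ v.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        dist = np.abs(repaired - C)
        if dist.max() > _MAX_REPAIR_DISTORTION:
            ii, jj = np.unravel_index(np.argmax(dist), dist.shape)
            offenders = [
                (labels[i], labels[j], float(dist[i, j]))
                for i, j in zip(*np.where(dist > _MAX_REPAIR_DISTORTION))
                if i < j
            ]
            raise InfeasibleSpecError(
                "requested correlation targets are infeasible; PSD repair "
                f"would distort entries by up to {dist[ii, jj]:.3f} > "
                f"{_MAX_REPAIR_DISTORTION}: {offenders[:10]}"
            )
        C = repaired
    return labels, C


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _likert_probs(levels: int, skew: float) -> np.ndarray:
    if not (0 <= skew < 1):
        raise ValueError("skew must be in [0, 1)")
    w = (1.0 - skew) ** np.arange(levels)
    return w / w.sum()


def likert_thresholds(levels: int, skew: float = 0.0) -> np.ndarray:
    """Normal quantile thresholds splitting N(0,1) into ``levels`` bins."""
    probs = _likert_probs(levels, skew)
    return norm.ppf(np.cumsum(probs)[:-1])


def _discretize(values: np.ndarray, levels: int, minimum: int, skew: float) -> np.ndarray:
    cuts = likert_thresholds(levels, skew)
    out = np.searchsorted(cuts, values).astype(float) + minimum
    out[np.isnan(values)] = np.nan
    return out


def simulate_sample(
    spec: SyntheticSpec, geometry: OctantGeometry = DEFAULT_GEOMETRY
) -> SyntheticDataset:
    """Draw a participant sample with the spec's target correlations.

    Fully seeded: the same spec and seed reproduce the same dataset.
    """
    labels, C = build_target_correlation(spec, geometry)
    rng = np.random.default_rng(spec.seed)
    w, v = np.linalg.eigh(C)
    A = v * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((spec.n, C.shape[0])) @ A.T

    k = 8
    ids = [f"S{i + 1:05d}" for i in range(spec.n)]
    octants = pd.DataFrame(Z[:, :k], columns=list(geometry.codes), index=ids)
    scales = pd.DataFrame(Z[:, k:], columns=labels[k:], index=ids)

    # careless responders: answers unrelated to the latent structure
    n_careless = int(round(spec.infrequency_contamination * spec.n))
    careless_pos = rng.choice(spec.n, size=n_careless, replace=False) if n_careless else np.array([], dtype=int)
    if n_careless:
        octants.iloc[careless_pos] = rng.standard_normal((n_careless, k))
        scales.iloc[careless_pos] = rng.standard_normal((n_careless, scales.shape[1]))

    if spec.discretize is not None:
        d = spec.discretize
        if d.octant_levels:
            octants = pd.DataFrame(
                _discretize(octants.to_numpy(), d.octant_levels, d.octant_min, d.skew),
                columns=octants.columns, index=ids,
            )
        if d.scale_levels:
            scales = pd.DataFrame(
                _discretize(scales.to_numpy(), d.scale_levels, d.scale_min, d.skew),
                columns=scales.columns, index=ids,
            )

    if spec.missing_rate > 0:
        mask_o = rng.random(octants.shape) < spec.missing_rate
        mask_s = rng.random(scales.shape) < spec.missing_rate
        octants = octants.mask(mask_o)
        scales = scales.mask(mask_s)

    # infrequency validity totals: 8 items scored 0-3, summed (range 0-24);
    # attentive responders endorse almost nothing, careless responders a lot
    validity = None
    if n_careless or spec.infrequency_contamination > 0:
        vals = rng.binomial(24, 0.0375, size=spec.n).astype(float)
        vals[careless_pos] = 4 + rng.binomial(20, 0.4, size=n_careless)
        validity = pd.Series(vals, index=ids, name="infrequency")

    return SyntheticDataset(
        octants=octants,
        scales=scales,
        validity=validity,
        careless_ids=[ids[i] for i in sorted(careless_pos.tolist())],
        spec=spec,
    )


# ---------------------------------------------------------------------------
# packaged study fixture
# ---------------------------------------------------------------------------

#: study-emulation conditions: two surfaces with the same circulant
#: structure, three external-scale archetypes with per-surface profiles
FIXTURE_SURFACES: dict[str, dict] = {
    "problems": {"prefix": "PRB", "items_per_octant": 4, "levels": 5, "minimum": 0},
    "sensitivities": {"prefix": "SNS", "items_per_octant": 8, "levels": 8, "minimum": 1},
}

FIXTURE_PROFILES: dict[str, dict[str, ScaleTarget]] = {
    "detachment": {
        "problems": ScaleTarget("detachment", 0.19, 0.28, 184.2),
        "sensitivities": ScaleTarget("detachment", -0.05, 0.21, 351.3),
    },
    "social_anxiety": {
        "problems": ScaleTarget("social_anxiety", 0.36, 0.25, 245.1),
        "sensitivities": ScaleTarget("social_anxiety", 0.05, 0.11, 33.2),
    },
    "psychoticism": {
        "problems": ScaleTarget("psychoticism", 0.25, 0.12, 147.4),
        "sensitivities": ScaleTarget("psychoticism", 0.09, 0.09, 340.7),
    },
}

_FIXTURE_ITEM_LOADING = 0.9
_FIXTURE_SCALE_ITEMS = 10
_N_RETAINED, _N_INCOMPLETE, _N_CARELESS, _N_MANUAL = 856, 31, 39, 3
_INFREQ_PROBS_ATTENTIVE = np.array([0.92, 0.05, 0.02, 0.01])
_INFREQ_NORM_MEAN, _INFREQ_NORM_SD = 0.9, 1.0  # threshold at 2.5 SD = 3.4


@dataclass
class StudyFixture:
    """Item-level 929-protocol roster with engineered screening outcome."""

    responses: pd.DataFrame
    keys: dict[str, ScoringKey]
    rules: ScreeningRules
    roster: pd.DataFrame
    seed: int
    expected_exclusions: dict[str, int]

    def config_dict(self, output_dir: str = "results", *, n_boot: int = 2000,
                    seed: int | None = None) -> dict:
        """Study configuration (plain dict, YAML-serializable) that scores,
        screens and profiles this fixture end to end."""
        return {
            "seed": int(self.seed if seed is None else seed),
            "responses": "responses.csv",
            "keys": {name: f"keys/{name}.yaml" for name in self.keys},
            "surfaces": [
                {"name": name, "instrument": name} for name in FIXTURE_SURFACES
            ],
            "scales": [
                {"name": label, "instrument": "stpp"} for label in FIXTURE_PROFILES
            ],
            "validity": {"instrument": "infrequency", "scale": "infrequency"},
            "screening": {
                "max_missing_fraction": self.rules.max_missing_fraction,
                "infrequency_norm_mean": self.rules.infrequency_norm_mean,
                "infrequency_norm_sd": self.rules.infrequency_norm_sd,
                "infrequency_sd_cutoff": self.rules.infrequency_sd_cutoff,
                "manual_exclusions": list(self.rules.manual_exclusions),
            },
            "cutoffs": {"elevation_min": 0.10, "amplitude_min": 0.10,
                        "r2_min": 0.70, "angle_distinct_min": 22.5},
            "bootstrap": {"n_boot": int(n_boot), "level": 0.95},
            "randall": {"mode": "exhaustive"},
            "contrast_pairs": [
                ["detachment", "social_anxiety"],
                ["detachment", "psychoticism"],
                ["social_anxiety", "psychoticism"],
            ],
            "output_dir": output_dir,
        }

    def write(self, outdir: str | Path, *, n_boot: int = 2000) -> Path:
        """Write responses, keys, roster and a study config; returns the
        config path."""
        import yaml

        outdir = Path(outdir)
        (outdir / "keys").mkdir(parents=True, exist_ok=True)
        self.responses.to_csv(outdir / "responses.csv", index_label="participant_id")
        self.roster.to_csv(outdir / "roster.csv", index=False)
        for name, key in self.keys.items():
            key.to_yaml(outdir / "keys" / f"{name}.yaml")
        cfg = self.config_dict(output_dir="results", n_boot=n_boot)
        path = outdir / "study.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        return path


def _items_from_latent(
    rng: np.random.Generator,
    latent: np.ndarray,
    n_items: int,
    levels: int,
    minimum: int,
) -> np.ndarray:
    lam = _FIXTURE_ITEM_LOADING
    noise = rng.standard_normal((latent.shape[0], n_items))
    cont = lam * latent[:, None] + np.sqrt(1 - lam**2) * noise
    return _discretize(cont, levels, minimum, skew=0.0)


def _draw_infrequency_items(
    rng: np.random.Generator, n: int, careless: np.ndarray
) -> np.ndarray:
    """8 infrequency items (0-3); attentive totals forced <= 3 and careless
    totals forced above the screening threshold by redraw."""
    items = np.empty((n, 8))
    att = ~careless
    items[att] = rng.choice(4, size=(att.sum(), 8), p=_INFREQ_PROBS_ATTENTIVE)
    items[careless] = rng.choice(4, size=(careless.sum(), 8))
    threshold = _INFREQ_NORM_MEAN + 2.5 * _INFREQ_NORM_SD
    for _ in range(1000):
        totals = items.sum(axis=1)
        bad_att = att & (totals > threshold)
        bad_car = careless & (totals <= threshold)
        if not bad_att.any() and not bad_car.any():
            return items
        if bad_att.any():
            items[bad_att] = rng.choice(4, size=(bad_att.sum(), 8), p=_INFREQ_PROBS_ATTENTIVE)
        if bad_car.any():
            items[bad_car] = rng.choice(4, size=(bad_car.sum(), 8))
    raise RuntimeError("infrequency redraw did not settle")  # pragma: no cover


def make_study_fixture(seed: int = FIXTURE_SEED) -> StudyFixture:
    """Build the packaged 929-protocol study fixture (see module docstring).

    Deterministic: regenerating with the recorded seed reproduces the
    fixture exactly.
    """
    rng = np.random.default_rng(seed)
    geometry = DEFAULT_GEOMETRY
    n = _N_RETAINED + _N_INCOMPLETE + _N_CARELESS + _N_MANUAL
    status = np.array(
        ["retained"] * _N_RETAINED + ["incomplete"] * _N_INCOMPLETE
        + ["careless"] * _N_CARELESS + ["manual"] * _N_MANUAL
    )

    c0, c1 = DEFAULT_OCTANT_BASE, DEFAULT_COSINE_DECAY
    angles = geometry.angles_rad

    # latent circle factors per surface, octant and scale latents
    octant_latents: dict[str, np.ndarray] = {}
    surface_factors: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for surface in FIXTURE_SURFACES:
        g = rng.standard_normal(n)
        X = rng.standard_normal(n)
        Y = rng.standard_normal(n)
        eps = rng.standard_normal((n, 8))
        octant_latents[surface] = (
            np.sqrt(c0) * g[:, None]
            + np.sqrt(c1) * (np.cos(angles) * X[:, None] + np.sin(angles) * Y[:, None])
            + np.sqrt(1 - c0 - c1) * eps
        )
        surface_factors[surface] = (g, X, Y)

    scale_latents: dict[str, np.ndarray] = {}
    for label, profiles in FIXTURE_PROFILES.items():
        total = np.zeros(n)
        communality = 0.0
        for surface, target in profiles.items():
            g, X, Y = surface_factors[surface]
            alpha = target.e / np.sqrt(c0)
            gamma = target.a / np.sqrt(c1)
            th = np.deg2rad(target.theta)
            total += alpha * g + gamma * (np.cos(th) * X + np.sin(th) * Y)
            communality += alpha**2 + gamma**2
        if communality > 1:
            raise InfeasibleSpecError(f"fixture scale {label!r} over-determined")
        total += np.sqrt(1 - communality) * rng.standard_normal(n)
        scale_latents[label] = total

    # item blocks
    blocks: list[pd.DataFrame] = []
    keys: dict[str, ScoringKey] = {}
    for surface, cfg in FIXTURE_SURFACES.items():
        octant_map: dict[str, list[str]] = {}
        cols: dict[str, np.ndarray] = {}
        for k_idx, code in enumerate(geometry.codes):
            items = _items_from_latent(
                rng, octant_latents[surface][:, k_idx], cfg["items_per_octant"],
                cfg["levels"], cfg["minimum"],
            )
            names = [f"{cfg['prefix']}_{code}_{i + 1}" for i in range(cfg["items_per_octant"])]
            octant_map[code] = names
            for j, name in enumerate(names):
                cols[name] = items[:, j]
        blocks.append(pd.DataFrame(cols))
        keys[surface] = ScoringKey(
            instrument=surface,
            item_ids=list(cols),
            scale_map={code: list(v) for code, v in octant_map.items()},
            response_min=cfg["minimum"],
            response_max=cfg["minimum"] + cfg["levels"] - 1,
            aggregation="mean",
            octant_map=octant_map,
        )

    scale_map: dict[str, list[str]] = {}
    cols = {}
    for label in FIXTURE_PROFILES:
        items = _items_from_latent(rng, scale_latents[label], _FIXTURE_SCALE_ITEMS, 5, 1)
        names = [f"{label[:3].upper()}_{i + 1}" for i in range(_FIXTURE_SCALE_ITEMS)]
        scale_map[label] = names
        for j, name in enumerate(names):
            cols[name] = items[:, j]
    blocks.append(pd.DataFrame(cols))
    keys["stpp"] = ScoringKey(
        instrument="stpp", item_ids=list(cols), scale_map=scale_map,
        response_min=1, response_max=5, aggregation="mean",
    )

    careless = status == "careless"
    inf_items = _draw_infrequency_items(rng, n, careless)
    inf_names = [f"INF_{i + 1}" for i in range(8)]
    blocks.append(pd.DataFrame(inf_items, columns=inf_names))
    keys["infrequency"] = ScoringKey(
        instrument="infrequency", item_ids=inf_names,
        scale_map={"infrequency": inf_names},
        response_min=0, response_max=3, aggregation="sum",
    )

    responses = pd.concat(blocks, axis=1)
    instrument_cols = [c for c in responses.columns if not c.startswith("INF_")]

    # careless responders answer the instruments at random too
    n_careless = int(careless.sum())
    for surface, cfg in FIXTURE_SURFACES.items():
        surf_cols = [c for c in responses.columns if c.startswith(FIXTURE_SURFACES[surface]["prefix"])]
        responses.loc[careless, surf_cols] = rng.integers(
            cfg["minimum"], cfg["minimum"] + cfg["levels"], size=(n_careless, len(surf_cols))
        ).astype(float)
    stpp_prefixes = tuple(label[:3].upper() + "_" for label in FIXTURE_PROFILES)
    stpp_cols = [c for c in responses.columns if c.startswith(stpp_prefixes)]
    responses.loc[careless, stpp_cols] = rng.integers(1, 6, size=(n_careless, len(stpp_cols))).astype(float)

    # blanks: retained/careless/manual participants leave at most 2 of the
    # 134 items blank (1.5% < 2%); incomplete protocols leave 8-27 blank
    arr = responses.to_numpy()
    n_items_total = responses.shape[1]
    for i in range(n):
        if status[i] == "incomplete":
            n_blank = int(rng.integers(8, 28))
        else:
            n_blank = int(rng.choice([0, 1, 2], p=[0.7, 0.2, 0.1]))
        if n_blank:
            which = rng.choice(len(instrument_cols), size=n_blank, replace=False)
            for w in which:
                arr[i, responses.columns.get_loc(instrument_cols[w])] = np.nan
    responses = pd.DataFrame(arr, columns=responses.columns)
    assert responses.shape[1] == n_items_total

    # shuffle participants and assign ids
    order = rng.permutation(n)
    responses = responses.iloc[order].reset_index(drop=True)
    status = status[order]
    ids = [f"P{i + 1:04d}" for i in range(n)]
    responses.index = pd.Index(ids, name="participant_id")

    roster = pd.DataFrame({"participant_id": ids, "status": status})
    manual_ids = [ids[i] for i in np.where(status == "manual")[0]]
    rules = ScreeningRules(
        max_missing_fraction=0.02,
        infrequency_norm_mean=_INFREQ_NORM_MEAN,
        infrequency_norm_sd=_INFREQ_NORM_SD,
        infrequency_sd_cutoff=2.5,
        manual_exclusions=manual_ids,
    )
    return StudyFixture(
        responses=responses,
        keys=keys,
        rules=rules,
        roster=roster,
        seed=seed,
        expected_exclusions={
            "missingness": _N_INCOMPLETE,
            "infrequency": _N_CARELESS,
            "manual": _N_MANUAL,
        },
    )
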