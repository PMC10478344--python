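"""Config-driven orchestration of the full construct-validation workflow.

Stages, in order: protocol screening → scale and octant scoring →
internal-consistency reliability → circumplex structure check (RANDALL)
per surface → SSM fit with bootstrap CIs per scale per surface →
interpretation gating → paired contrasts for declared scale pairs →
convergence calls → report. All randomness flows from the config seed;
re-running with the same inputs and seed reproduces the report byte for
byte.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .geometry import DEFAULT_GEOMETRY, OctantGeometry
from .instruments import (
    ExclusionLedger,
    ScoringKey,
    ScreeningRules,
    omega_total,
    read_responses,
    score_octants,
    score_scale,
    screen_protocols,
)
from .randall import RandallResult, randall_test
from .resampling import BootstrapConfig, ContrastResult, SSMInterval, bootstrap_ssm, contrast_profiles
from .ssm import Cutoffs, apply_cutoffs

logger = logging.getLogger("circumplex_ssm")

__all__ = [
    "StudyConfig",
    "StudyData",
    "StudyReport",
    "StageError",
    "run_study",
    "evaluate_convergence",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Declarative description of one study run (usually read from YAML)."""

    responses: str
    keys: dict[str, str]
    surfaces: list[dict]
    scales: list[dict]
    validity: dict | None = None
    screening: ScreeningRules = field(default_factory=ScreeningRules)
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    randall_mode: str = "exhaustive"
    contrast_pairs: list[tuple[str, str]] = field(default_factory=list)
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        scale_names = {s["name"] for s in self.scales}
        instruments = set(self.keys)
        for s in self.scales:
            if s["instrument"] not in instruments:
                raise ValueError(f"scale {s['name']!r} references undeclared instrument "
                                 f"{s['instrument']!r}")
        for surf in self.surfaces:
            if surf["instrument"] not in instruments:
                raise ValueError(f"surface {surf['name']!r} references undeclared "
                                 f"instrument {surf['instrument']!r}")
        for pair in self.contrast_pairs:
            for name in pair:
                if name not in scale_names:
                    raise ValueError(f"contrast pair references undeclared scale {name!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        screening = ScreeningRules(**d.get("screening", {}))
        cutoffs = Cutoffs(**d.get("cutoffs", {}))
        boot = d.get("bootstrap", {})
        seed = int(d.get("seed", 0))
        bootstrap = BootstrapConfig(
            n_boot=int(boot.get("n_boot", 2000)),
            level=float(boot.get("level", 0.95)),
        )
        return cls(
            responses=d["responses"],
            keys=dict(d["keys"]),
            surfaces=[dict(s) for s in d["surfaces"]],
            scales=[dict(s) for s in d["scales"]],
            validity=dict(d["validity"]) if d.get("validity") else None,
            screening=screening,
            cutoffs=cutoffs,
            bootstrap=bootstrap,
            randall_mode=d.get("randall", {}).get("mode", "exhaustive"),
            contrast_pairs=[tuple(p) for p in d.get("contrast_pairs", [])],
            output_dir=d.get("output_dir", "results"),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        base = Path(path).parent
        d = yaml.safe_load(Path(path).read_text())
        cfg = cls.from_dict(d)
        # resolve paths relative to the config file
        cfg.responses = str((base / cfg.responses))
        cfg.keys = {k: str(base / v) for k, v in cfg.keys.items()}
        return cfg


@dataclass
class StudyData:
    """In-memory study inputs (bypasses file loading, e.g. for fixtures)."""

    responses: pd.DataFrame
    keys: dict[str, ScoringKey]


@dataclass
class StudyReport:
    """All study outputs; serializable to a CSV set plus one JSON file."""

    exclusions: dict
    reliability: pd.DataFrame
    randall: dict[str, RandallResult]
    ssm: pd.DataFrame
    contrasts: pd.DataFrame
    convergence: pd.DataFrame
    plot_coords: pd.DataFrame
    n_retained: int
    seed: int

    def to_json_dict(self) -> dict:
        def clean(v):
            if isinstance(v, (np.bool_, bool)):
                return bool(v)
            if isinstance(v, (np.integer, int)):
                return int(v)
            if isinstance(v, (np.floating, float)):
                v = float(v)
                return None if math.isnan(v) else v
            return v

        def df_records(df: pd.DataFrame) -> list[dict]:
            return [{k: clean(v) for k, v in rec.items()}
                    for rec in df.to_dict(orient="records")]

        return {
            "seed": self.seed,
            "n_retained": self.n_retained,
            "exclusions": self.exclusions,
            "reliability": df_records(self.reliability),
            "randall": {
                surface: {
                    "n_predictions": r.n_predictions,
                    "n_met": r.n_met,
                    "n_violated": r.n_violated,
                    "n_tied": r.n_tied,
                    "correspondence_index": r.correspondence_index,
                    "p_value": r.p_value,
                    "exhaustive": r.exhaustive,
                }
                for surface, r in self.randall.items()
            },
            "ssm": df_records(self.ssm),
            "contrasts": df_records(self.contrasts),
            "convergence": df_records(self.convergence),
            "plot_coords": df_records(self.plot_coords),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [{"rule": k, "count": v} for k, v in self.exclusions["counts"].items()]
        ).to_csv(outdir / "exclusions.csv", index=False)
        self.reliability.to_csv(outdir / "reliability.csv", index=False)
        rows = []
        for surface, r in self.randall.items():
            rows.append({"surface": surface, "n_predictions": r.n_predictions,
                         "n_met": r.n_met, "n_violated": r.n_violated,
                         "n_tied": r.n_tied,
                         "correspondence_index": round(r.correspondence_index, 2),
                         "p_value": round(r.p_value, 4)})
        pd.DataFrame(rows).to_csv(outdir / "randall.csv", index=False)
        _round_ssm_table(self.ssm).to_csv(outdir / "ssm.csv", index=False)
        _round_contrast_table(self.contrasts).to_csv(outdir / "contrasts.csv", index=False)
        self.convergence.to_csv(outdir / "convergence.csv", index=False)
        self.plot_coords.to_csv(outdir / "plot_coords.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=1, sort_keys=True, allow_nan=False)
        )


def _round_cols(df: pd.DataFrame, decimals: Mapping[str, int]) -> pd.DataFrame:
    df = df.copy()
    for col, nd in decimals.items():
        if col in df.columns:
            df[col] = df[col].astype(float).round(nd)
    return df


def _round_ssm_table(df: pd.DataFrame) -> pd.DataFrame:
    # parameters to 2 decimals, angles to 1, R^2 to 3 (report convention)
    two = {c: 2 for c in df.columns if c.split("_")[0] in ("e", "x", "y", "a")}
    one = {c: 1 for c in df.columns if c.startswith("theta")}
    return _round_cols(df, {**two, **one, "r2": 3})


def _round_contrast_table(df: pd.DataFrame) -> pd.DataFrame:
    two = {c: 2 for c in df.columns if c.split("_")[0] in ("de", "dx", "dy", "da")}
    one = {c: 1 for c in df.columns if c.startswith("dtheta")}
    return _round_cols(df, {**two, **one})


def _child_seed(seed: int, stage: int, item: int) -> int:
    # deterministic, collision-free enough for the stage/item grid
    return int((seed * 1_000_003 + stage * 10_007 + item * 101 + 12345) % (2**31 - 1))


def evaluate_convergence(contrasts: list[ContrastResult]) -> pd.DataFrame:
    """Per-pair angular-convergence call.

    'convergent' when the angle-difference CI contains zero; 'distinct'
    when the CI excludes zero and the point difference is at least half an
    octant; 'statistically distinct but overlapping' when the CI excludes
    zero but the difference is smaller than that; 'excluded' when gating
    suppressed the angular contrast.
    """
    rows = []
    for c in contrasts:
        if c.angle_status != "ok" or math.isnan(c.delta["theta"]):
            call = "excluded"
        elif not c.significant["theta"]:
            call = "convergent"
        elif abs(c.delta["theta"]) >= 22.5:
            call = "distinct"
        else:
            call = "statistically distinct but overlapping"
        rows.append({"scale_a": c.scale_pair[0], "scale_b": c.scale_pair[1],
                     "call": call})
    return pd.DataFrame(rows, columns=["scale_a", "scale_b", "call"])


def run_study(
    config: StudyConfig,
    data: StudyData | None = None,
    geometry: OctantGeometry = DEFAULT_GEOMETRY,
) -> StudyReport:
    """Execute the full study workflow and return the report.

    ``data`` may supply in-memory inputs; otherwise the response table and
    keys are loaded from the paths in ``config``.
    """
    # ---- load ------------------------------------------------------------
    try:
        if data is None:
            responses = read_responses(config.responses)
            keys = {name: ScoringKey.from_yaml(path) for name, path in config.keys.items()}
        else:
            responses, keys = data.responses, data.keys
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", str(exc)) from exc

    # ---- screening -------------------------------------------------------
    try:
        if config.validity is not None:
            vkey = keys[config.validity["instrument"]]
            validity_scores = score_scale(responses, vkey, config.validity["scale"])
        else:
            validity_scores = pd.Series(0.0, index=responses.index)
        screening = screen_protocols(responses, validity_scores, config.screening)
        retained = screening.retained
        logger.info("screening: retained %d of %d protocols", len(retained), len(responses))
    except Exception as exc:  # noqa: BLE001
        raise StageError("screening", str(exc)) from exc

    # ---- scoring ---------------------------------------------------------
    try:
        scale_scores: dict[str, pd.Series] = {}
        for s in config.scales:
            key = keys[s["instrument"]]
            scale_scores[s["name"]] = score_scale(retained, key, s.get("scale", s["name"]))
        octant_scores: dict[str, pd.DataFrame] = {}
        for surf in config.surfaces:
            octant_scores[surf["name"]] = score_octants(retained, keys[surf["instrument"]], geometry)
    except Exception as exc:  # noqa: BLE001
        raise StageError("scoring", str(exc)) from exc

    # ---- reliability -----------------------------------------------------
    try:
        rel_rows = []
        for s in config.scales:
            key = keys[s["instrument"]]
            items = retained[key.scale_map[s.get("scale", s["name"])]].dropna()
            rel = omega_total(items, scale=s["name"])
            scores = scale_scores[s["name"]].dropna()
            rel_rows.append({
                "scale": s["name"], "n": int(scores.shape[0]),
                "mean": round(float(scores.mean()), 2),
                "sd": round(float(scores.std(ddof=1)), 2),
                "min": round(float(scores.min()), 2),
                "max": round(float(scores.max()), 2),
                "omega_t": round(rel.omega_t, 2),
                "estimator": rel.estimator,
            })
        reliability = pd.DataFrame(rel_rows)
    except Exception as exc:  # noqa: BLE001
        raise StageError("reliability", str(exc)) from exc

    # ---- circumplex structure check (RANDALL) ----------------------------
    try:
        randall_results: dict[str, RandallResult] = {}
        for i, surf in enumerate(config.surfaces):
            R = octant_scores[surf["name"]].corr().to_numpy()
            randall_results[surf["name"]] = randall_test(
                R, mode=config.randall_mode,
                seed=_child_seed(config.seed, 1, i),
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("randall", str(exc)) from exc

    # ---- SSM + bootstrap per scale per surface ---------------------------
    try:
        ssm_rows = []
        plot_rows = []
        intervals: dict[tuple[str, str], SSMInterval] = {}
        item = 0
        for surf in config.surfaces:
            for s in config.scales:
                cfg = BootstrapConfig(
                    n_boot=config.bootstrap.n_boot,
                    level=config.bootstrap.level,
                    seed=_child_seed(config.seed, 2, item),
                )
                item += 1
                ci = bootstrap_ssm(scale_scores[s["name"]], octant_scores[surf["name"]],
                                   geometry, cfg)
                intervals[(surf["name"], s["name"])] = ci
                ruling = apply_cutoffs(ci.point, config.cutoffs)
                ssm_rows.append({
                    "surface": surf["name"], "scale": s["name"],
                    "e": ci.point.e, "e_lo": ci.lower["e"], "e_hi": ci.upper["e"],
                    "x": ci.point.x, "x_lo": ci.lower["x"], "x_hi": ci.upper["x"],
                    "y": ci.point.y, "y_lo": ci.lower["y"], "y_hi": ci.upper["y"],
                    "a": ci.point.a, "a_lo": ci.lower["a"], "a_hi": ci.upper["a"],
                    "theta": ci.point.theta, "theta_lo": ci.lower["theta"],
                    "theta_hi": ci.upper["theta"],
                    "r2": ci.point.r2,
                    "elevated": ruling.elevated,
                    "prototypical": ruling.prototypical,
                    "differentiated": ruling.differentiated,
                    "angle_interpretable": ruling.angle_interpretable,
                    "b_effective": ci.b_effective,
                })
                plot_rows.append({
                    "surface": surf["name"], "scale": s["name"],
                    "theta_deg": ci.point.theta, "amplitude": ci.point.a,
                    "radial_lo": ci.lower["a"], "radial_hi": ci.upper["a"],
                    "angular_lo": ci.lower["theta"], "angular_hi": ci.upper["theta"],
                    "dashed": not ruling.prototypical,
                })
        ssm_table = pd.DataFrame(ssm_rows)
        plot_coords = pd.DataFrame(plot_rows)
    except Exception as exc:  # noqa: BLE001
        raise StageError("ssm", str(exc)) from exc

    # ---- contrasts -------------------------------------------------------
    try:
        contrast_rows = []
        contrast_objs: list[ContrastResult] = []
        item = 0
        for surf in config.surfaces:
            for pair in config.contrast_pairs:
                cfg = BootstrapConfig(
                    n_boot=config.bootstrap.n_boot,
                    level=config.bootstrap.level,
                    seed=_child_seed(config.seed, 3, item),
                )
                item += 1
                c = contrast_profiles(
                    scale_scores[pair[0]], scale_scores[pair[1]],
                    octant_scores[surf["name"]], geometry, cfg,
                    cutoffs=config.cutoffs,
                )
                contrast_objs.append(c)
                row: dict = {"surface": surf["name"],
                             "scale_a": pair[0], "scale_b": pair[1]}
                for short, p in (("de", "e"), ("dx", "x"), ("dy", "y"),
                                 ("da", "a"), ("dtheta", "theta")):
                    row[short] = c.delta[p]
                    row[f"{short}_lo"] = c.lower[p]
                    row[f"{short}_hi"] = c.upper[p]
                    row[f"{short}_boot_mean"] = c.boot_mean[p]
                    row[f"{short}_significant"] = c.significant[p]
                row["angle_status"] = c.angle_status
                row["distinct_angle"] = c.distinct_angle
                contrast_rows.append(row)
        contrasts = pd.DataFrame(contrast_rows)
        conv_rows = []
        idx = 0
        for surf in config.surfaces:
            n_pairs = len(config.contrast_pairs)
            block = evaluate_convergence(contrast_objs[idx: idx + n_pairs])
            block.insert(0, "surface", surf["name"])
            conv_rows.append(block)
            idx += n_pairs
        convergence = (
            pd.concat(conv_rows, ignore_index=True)
            if conv_rows else pd.DataFrame(columns=["surface", "scale_a", "scale_b", "call"])
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("contrast", str(exc)) from exc

    return StudyReport(
        exclusions={"counts": screening.ledger.counts,
                    "reasons": dict(sorted(screening.ledger.reasons.items()))},
        reliability=reliability,
        randall=randall_results,
        ssm=ssm_table,
        contrasts=contrasts,
        convergence=convergence,
        plot_coords=plot_coords,
        n_retained=int(retained.shape[0]),
        seed=config.seed,
    )
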