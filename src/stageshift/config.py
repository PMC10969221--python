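"""Configuration loading: YAML/JSON study definitions and packaged defaults."""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortSpec, FactorSpec
from .model import CoefficientSet, StageScale, coefficients_from_odds_ratios
from .scenarios import DesignSpec

__all__ = [
    "load_config",
    "cohort_spec_from_config",
    "coefficient_set_from_config",
    "stage_scale_from_config",
    "baseline_distribution",
    "scenario1_designs",
    "headline_shift_designs",
    "scenario2_designs",
    "scenario2_optimal",
    "policy_targets",
]


def load_config(path: str | Path | None = None) -> dict:
    """Load a study config; ``None`` loads the packaged defaults."""
    if path is None:
        text = resources.files("stageshift").joinpath("defaults.yaml").read_text()
        return yaml.safe_load(text)
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def cohort_spec_from_config(cfg: dict) -> CohortSpec:
    factors = []
    for name, block in cfg["factors"].items():
        if block["kind"] == "continuous":
            lo, hi = block.get("bounds", [None, None])
            factors.append(
                FactorSpec.continuous(
                    name,
                    mean=float(block["mean"]),
                    sd=float(block["sd"]),
                    lower_bound=-math.inf if lo is None else float(lo),
                    upper_bound=math.inf if hi is None else float(hi),
                )
            )
        else:
            factors.append(FactorSpec.binary(name, float(block["proportion"])))
    names = [f.name for f in factors]
    corr = np.eye(len(factors))
    for a, b, value in cfg.get("correlation") or []:
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = float(value)
    return CohortSpec(factors=tuple(factors), correlation=corr)


def coefficient_set_from_config(cfg: dict) -> CoefficientSet:
    ors = {name: float(block["or"]) for name, block in cfg["odds_ratios"].items()}
    scales = {
        name: float(block["unit_scale"])
        for name, block in cfg["odds_ratios"].items()
        if "unit_scale" in block
    }
    cis = {
        name: tuple(block["ci"])
        for name, block in cfg["odds_ratios"].items()
        if "ci" in block
    }
    per_cut = cfg.get("per_cut_odds_ratios") or {}
    return coefficients_from_odds_ratios(
        ors,
        unit_scale=scales,
        per_cut_odds_ratios=per_cut or None,
        sigma=float(cfg.get("model", {}).get("sigma", 0.0)),
        or_ci=cis,
    )


def stage_scale_from_config(cfg: dict) -> StageScale:
    return StageScale(levels=tuple(cfg["model"]["stages"]))


def baseline_distribution(cfg: dict) -> np.ndarray:
    return np.asarray(cfg["model"]["baseline_stage_distribution"], dtype=float)


def scenario1_designs(cfg: dict) -> list[DesignSpec]:
    return [
        DesignSpec(
            design_id=str(d["id"]),
            factor=d["factor"],
            grid=tuple(d["grid"]),
            baseline_value=float(d["baseline"]),
        )
        for d in cfg["scenario1"]["designs"]
    ]


def headline_shift_designs(cfg: dict) -> list[DesignSpec]:
    """Single-value designs at the headline shift amounts of each factor."""
    by_id = {str(d["id"]): d for d in cfg["scenario1"]["designs"]}
    out = []
    for design_id, value in cfg["scenario1"]["headline_shifts"].items():
        d = by_id[str(design_id)]
        out.append(
            DesignSpec(
                design_id=str(design_id),
                factor=d["factor"],
                grid=(float(value),),
                baseline_value=float(d["baseline"]),
            )
        )
    return out


def scenario2_designs(cfg: dict) -> list[DesignSpec]:
    """Cumulative designs: each pins earlier factors at their optimal values."""
    designs = []
    overrides: dict[str, float] = {}
    for d in cfg["scenario2"]["designs"]:
        designs.append(
            DesignSpec(
                design_id=str(d["id"]),
                factor=d["factor"],
                grid=tuple(d["grid"]),
                fixed_overrides=dict(overrides),
            )
        )
        overrides[d["factor"]] = float(d["optimal"])
    return designs


def scenario2_optimal(cfg: dict) -> dict[str, float]:
    return {str(d["id"]): float(d["optimal"]) for d in cfg["scenario2"]["designs"]}


def policy_targets(cfg: dict) -> dict[str, float]:
    return {k: float(v) for k, v in cfg["scenario3"]["targets"].items()}
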