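"""Scenario engine: paired baseline / counterfactual stage simulations.

Each scenario run simulates ``n_realizations`` independent cohorts of
``n_per_realization`` subjects, samples a stage for every subject, and
summarizes the per-realization stage proportions.  Counterfactual runs shift
one factor's population mean or prevalence (optionally on top of fixed
overrides from earlier steps of a cumulative sequence) and are compared to
the baseline realization by realization.

Under the default ``common_random_numbers`` pairing, realization r of every
arm reuses the random streams of baseline realization r — the same latent
normals and the same stage-assignment uniforms — so the stage-wise percent
changes are low-variance and sum to zero exactly within each realization.
``independent`` pairing gives every arm its own streams.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortSpec, sample_cohort, shift_spec
from .model import CoefficientSet, StageScale, category_probabilities, sample_stages
from .report import percentile_interval

__all__ = [
    "DesignSpec",
    "RunConfig",
    "ShiftResult",
    "run_baseline",
    "run_design",
    "run_cumulative",
    "run_policy_scenario",
    "cumulative_trajectory",
    "significant_designs",
]

# stream tags: keep every derived seed component a small non-negative int
_COHORT_STREAM = 0
_STAGE_STREAM = 1
_BASELINE_ARM = 0


@dataclass
class DesignSpec:
    """One factor sweep: which factor moves, over which grid, what is pinned."""

    design_id: str
    factor: str
    grid: tuple[float, ...]
    baseline_value: float | None = None
    fixed_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = tuple(float(g) for g in self.grid)
        if not self.grid:
            raise ValueError(f"design {self.design_id}: empty grid")


@dataclass(frozen=True)
class RunConfig:
    """Monte-Carlo layout: realizations, cohort size, seeding, pairing."""

    n_realizations: int = 20
    n_per_realization: int = 1000
    master_seed: int = 0
    pairing: str = "common_random_numbers"
    tail: float = 0.0225

    def __post_init__(self) -> None:
        if self.n_realizations < 2:
            raise ValueError("need at least 2 realizations")
        if self.n_per_realization < 1:
            raise ValueError("need at least 1 subject per realization")
        if self.pairing not in ("common_random_numbers", "independent"):
            raise ValueError(f"unknown pairing {self.pairing!r}")


@dataclass(eq=False)
class ShiftResult:
    """Per-realization stage proportions for one (design, grid value) cell."""

    design_id: str
    grid_value: float | None
    factor: str | None
    proportions: np.ndarray  # (n_realizations, J)
    percent_change: np.ndarray  # (n_realizations, J), vs. paired baseline, in points
    stage_labels: tuple[str, ...]
    median: np.ndarray = field(init=False)
    pi_lower: np.ndarray = field(init=False)
    pi_upper: np.ndarray = field(init=False)
    mean_percent_change: np.ndarray = field(init=False)
    tail: float = 0.0225

    def __post_init__(self) -> None:
        J = len(self.stage_labels)
        lo = np.empty(J)
        med = np.empty(J)
        hi = np.empty(J)
        for j in range(J):
            lo[j], med[j], hi[j] = percentile_interval(self.proportions[:, j], self.tail)
        self.pi_lower, self.median, self.pi_upper = lo, med, hi
        self.mean_percent_change = self.percent_change.mean(axis=0)


def _simulate_proportions(
    spec: CohortSpec,
    coeffs: CoefficientSet,
    cfg: RunConfig,
    scale: StageScale,
    arm: int,
) -> np.ndarray:
    """(n_realizations, J) stage proportions; arm selects the stream family."""
    J = scale.n_levels
    props = np.empty((cfg.n_realizations, J))
    for r in range(cfg.n_realizations):
        cohort = sample_cohort(
            spec, cfg.n_per_realization,
            (cfg.master_seed, arm, r, _COHORT_STREAM),
        )
        probs = category_probabilities(cohort, coeffs, scale)
        stages = sample_stages(probs, (cfg.master_seed, arm, r, _STAGE_STREAM))
        props[r] = np.bincount(stages, minlength=J) / cfg.n_per_realization
    return props


def _arm_index(cfg: RunConfig, arm_counter: int) -> int:
    return _BASELINE_ARM if cfg.pairing == "common_random_numbers" else arm_counter


def run_baseline(
    spec: CohortSpec,
    coeffs: CoefficientSet,
    cfg: RunConfig,
    scale: StageScale = StageScale(),
) -> ShiftResult:
    """Simulate the cohort at its observed factor values (zero percent change)."""
    props = _simulate_proportions(spec, coeffs, cfg, scale, _BASELINE_ARM)
    return ShiftResult(
        design_id="baseline",
        grid_value=None,
        factor=None,
        proportions=props,
        percent_change=np.zeros_like(props),
        stage_labels=scale.levels,
        tail=cfg.tail,
    )


def _apply_overrides(spec: CohortSpec, overrides: Mapping[str, float]) -> CohortSpec:
    for name, value in overrides.items():
        spec = shift_spec(spec, name, value)  # raises on unknown factor
    return spec


def run_design(
    design: DesignSpec,
    spec: CohortSpec,
    coeffs: CoefficientSet,
    cfg: RunConfig,
    baseline: ShiftResult | None = None,
    scale: StageScale = StageScale(),
    arm_offset: int = 1,
) -> list[ShiftResult]:
    """Sweep one design's grid against the baseline, one result per grid value.

    Percent change is 100 x (shifted proportion - baseline proportion),
    realization-matched; under common random numbers the paired streams make
    the identity shift exactly zero.
    """
    spec.index(design.factor)  # fail fast on unknown factor
    if baseline is None:
        baseline = run_baseline(spec, coeffs, cfg, scale)
    if baseline.proportions.shape[0] != cfg.n_realizations:
        raise ValueError("baseline realization count does not match RunConfig")
    pinned = _apply_overrides(spec, design.fixed_overrides)
    out: list[ShiftResult] = []
    for i, value in enumerate(design.grid):
        shifted = shift_spec(pinned, design.factor, value)
        arm = _arm_index(cfg, arm_offset + i)
        props = _simulate_proportions(shifted, coeffs, cfg, scale, arm)
        out.append(
            ShiftResult(
                design_id=design.design_id,
                grid_value=value,
                factor=design.factor,
                proportions=props,
                percent_change=100.0 * (props - baseline.proportions),
                stage_labels=scale.levels,
                tail=cfg.tail,
            )
        )
    return out


def run_cumulative(
    designs: Sequence[DesignSpec],
    spec: CohortSpec,
    coeffs: CoefficientSet,
    cfg: RunConfig,
    baseline: ShiftResult | None = None,
    scale: StageScale = StageScale(),
) -> list[ShiftResult]:
    """Run an ordered sequence of designs whose overrides pin earlier steps.

    Returns the flattened sweep results in design order; use
    :func:`cumulative_trajectory` to extract one endpoint per design.
    """
    if baseline is None:
        baseline = run_baseline(spec, coeffs, cfg, scale)
    out: list[ShiftResult] = []
    arm = 1
    for design in designs:
        out.extend(
            run_design(design, spec, coeffs, cfg, baseline=baseline, scale=scale,
                       arm_offset=arm)
        )
        arm += len(design.grid)
    return out


def cumulative_trajectory(
    results: Sequence[ShiftResult],
    optimal: Mapping[str, float],
) -> list[ShiftResult]:
    """Pick each design's result at its optimal grid value, in design order.

    ``optimal`` maps design_id -> the grid value at which the design is pinned
    in subsequent steps; the returned list is the cumulative trajectory whose
    stage-I proportion should be nondecreasing when every step is beneficial.
    """
    picked: dict[str, ShiftResult] = {}
    order: list[str] = []
    for res in results:
        if res.design_id in optimal and res.grid_value == optimal[res.design_id]:
            picked[res.design_id] = res
            if res.design_id not in order:
                order.append(res.design_id)
    missing = set(optimal) - set(picked)
    if missing:
        raise ValueError(f"no result at the optimal grid value for designs {sorted(missing)}")
    return [picked[d] for d in order]


def run_policy_scenario(
    spec: CohortSpec,
    coeffs: CoefficientSet,
    cfg: RunConfig,
    targets: Mapping[str, float] | None = None,
    scale: StageScale = StageScale(),
) -> list[ShiftResult]:
    """Cumulative run over a policy-relevant factor subset at fixed levels.

    ``targets`` maps factor name -> target mean/proportion, applied one at a
    time with earlier factors pinned (insertion order).  The default subset is
    the four policy factors: energy 1400 kcal/day, protein 85 g/day,
    mammogram 0.95, summer sun exposure 0.7.  An empty mapping returns just
    the baseline.
    """
    if targets is None:
        from .config import load_config, policy_targets

        targets = policy_targets(load_config())
    baseline = run_baseline(spec, coeffs, cfg, scale)
    if not targets:
        return [baseline]
    designs = []
    overrides: dict[str, float] = {}
    for i, (factor, value) in enumerate(targets.items()):
        designs.append(
            DesignSpec(
                design_id=f"policy-{i + 1}-{factor}",
                factor=factor,
                grid=(value,),
                fixed_overrides=dict(overrides),
            )
        )
        overrides[factor] = value
    return [baseline] + run_cumulative(designs, spec, coeffs, cfg,
                                       baseline=baseline, scale=scale)


def significant_designs(
    results: Sequence[ShiftResult],
    stage_index: int = 0,
    threshold: float = 0.5,
) -> list[str]:
    """Design ids whose shift moved the given stage by at least ``threshold``
    percentage points (the roster rule for promoting single-factor designs
    into a cumulative scenario)."""
    keep: list[str] = []
    for res in results:
        if res.design_id == "baseline":
            continue
        if res.mean_percent_change[stage_index] >= threshold and res.design_id not in keep:
            keep.append(res.design_id)
    return keep
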