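"""Proportional / partial-proportional odds stage-at-diagnosis model.

Stage at diagnosis is an ordered outcome (I, II, III+IV here; III and IV are
merged because stage IV is rare).  The model is a cumulative logit on the
exceedance probability

    P(Stage > j) = expit(alpha_j + x' beta [+ z' gamma_j] + eps),

where beta holds one log odds ratio per factor shared across cuts (the
proportional-odds part), gamma_j optionally gives selected factors a
cut-specific slope (the partial relaxation), and eps ~ N(0, sigma^2) is an
optional residual-heterogeneity term integrated out by Gauss-Hermite
quadrature.  A factor's odds ratio > 1 pushes diagnoses toward later stages;
OR < 1 is protective.

Published model intercepts are rarely reported alongside odds ratios, so
:func:`calibrate_intercepts` solves for the alpha_j that reproduce a target
baseline stage distribution over a large calibration cohort — each cut is a
one-dimensional monotone root-finding problem on the cumulative scale.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

from .cohort import CohortSample, CohortSpec, sample_cohort

__all__ = [
    "StageScale",
    "CoefficientSet",
    "StageProbabilities",
    "CalibrationError",
    "coefficients_from_odds_ratios",
    "linear_predictor",
    "exceedance_probability",
    "category_probabilities",
    "categories_from_exceedance",
    "sample_stages",
    "calibrate_intercepts",
]

ALPHA_BRACKET = 30.0  # calibration search interval for each intercept


class CalibrationError(RuntimeError):
    """Intercept calibration failed (unattainable or non-monotone target)."""


@dataclass(frozen=True)
class StageScale:
    """Ordered stage labels; default merges stages III and IV."""

    levels: tuple[str, ...] = ("I", "II", "III+IV")

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("need at least two stage levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("stage labels must be distinct")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def cut_count(self) -> int:
        return len(self.levels) - 1


@dataclass
class CoefficientSet:
    """Model coefficients on the log-odds scale.

    ``beta`` maps factor name -> log OR per *model unit*; ``unit_scale`` maps
    natural units to model units (e.g. 0.01 so a kcal/day intake enters per
    100 kcal/day).  Factors listed in ``gamma`` get a cut-specific log OR
    vector instead of the shared ``beta`` slope.  ``alpha`` holds one
    intercept per cut and is ``None`` until calibrated.
    """

    beta: dict[str, float]
    unit_scale: dict[str, float] = field(default_factory=dict)
    alpha: np.ndarray | None = None
    gamma: dict[str, np.ndarray] = field(default_factory=dict)
    sigma: float = 0.0
    or_ci: dict[str, tuple[float, float]] = field(default_factory=dict)  # metadata only

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if not np.all(np.isfinite(self.alpha)):
                raise ValueError("intercepts must be finite")
        self.gamma = {k: np.asarray(v, dtype=float) for k, v in self.gamma.items()}

    def scale(self, name: str) -> float:
        return self.unit_scale.get(name, 1.0)

    @property
    def cut_count(self) -> int:
        if self.alpha is None:
            raise CalibrationError("intercepts not calibrated yet")
        return len(self.alpha)

    def odds_ratio(self, name: str) -> float:
        """Proportional odds ratio per model unit (exp beta)."""
        return math.exp(self.beta[name])


def coefficients_from_odds_ratios(
    odds_ratios: Mapping[str, float],
    unit_scale: Mapping[str, float] | None = None,
    per_cut_odds_ratios: Mapping[str, Sequence[float]] | None = None,
    sigma: float = 0.0,
    or_ci: Mapping[str, tuple[float, float]] | None = None,
) -> CoefficientSet:
    """Convert printed odds ratios into log-odds coefficients.

    ``beta = ln(OR)`` per model unit; a factor given ``per_cut_odds_ratios``
    becomes non-proportional (its per-cut ``ln(OR_j)`` replaces the shared
    slope).  Intercepts are left unset pending calibration.
    """
    beta: dict[str, float] = {}
    for name, or_value in odds_ratios.items():
        if not or_value > 0:
            raise ValueError(f"{name}: odds ratio must be positive, got {or_value}")
        beta[name] = math.log(or_value)
    gamma: dict[str, np.ndarray] = {}
    if per_cut_odds_ratios:
        for name, ors in per_cut_odds_ratios.items():
            ors = np.asarray(ors, dtype=float)
            if np.any(ors <= 0):
                raise ValueError(f"{name}: odds ratios must be positive")
            gamma[name] = np.log(ors)
            beta[name] = 0.0  # cut-specific slopes replace the shared one
    return CoefficientSet(
        beta=beta,
        unit_scale=dict(unit_scale or {}),
        gamma=gamma,
        sigma=sigma,
        or_ci=dict(or_ci or {}),
    )


def _covariate_contributions(
    values: np.ndarray,
    names: Sequence[str],
    coeffs: CoefficientSet,
    cut_count: int,
) -> np.ndarray:
    """(n, cut_count) matrix of x'beta + z'gamma_j, excluding intercepts."""
    n = values.shape[0]
    shared = np.zeros(n)
    percut = np.zeros((n, cut_count))
    for col, name in enumerate(names):
        if name not in coeffs.beta and name not in coeffs.gamma:
            continue
        x = values[:, col] * coeffs.scale(name)
        if name in coeffs.gamma:
            g = coeffs.gamma[name]
            if len(g) != cut_count:
                raise ValueError(
                    f"{name}: gamma has {len(g)} entries, model has {cut_count} cuts"
                )
            percut += np.outer(x, g)
        else:
            shared += x * coeffs.beta[name]
    return shared[:, None] + percut


def linear_predictor(
    x: Sequence[float],
    names: Sequence[str],
    coeffs: CoefficientSet,
    j: int,
    eps: float = 0.0,
) -> float:
    """Single-subject linear predictor alpha_j + x'beta + z'gamma_j + eps."""
    values = np.asarray(x, dtype=float)[None, :]
    if values.shape[1] != len(names):
        raise ValueError(f"x has {values.shape[1]} entries for {len(names)} factors")
    cut_count = coeffs.cut_count
    contrib = _covariate_contributions(values, names, coeffs, cut_count)
    return float(coeffs.alpha[j] + contrib[0, j] + eps)


def exceedance_probability(eta, sigma: float = 0.0, n_nodes: int = 40):
    """P(Stage > j) given the linear predictor, marginal over eps.

    For sigma = 0 this is the plain logistic; for sigma > 0 the expectation
    E[expit(eta + sigma Z)], Z ~ N(0,1), is computed by Gauss-Hermite
    quadrature with ``n_nodes`` nodes.
    """
    eta = np.asarray(eta, dtype=float)
    if sigma == 0.0:
        out = expit(eta)
    else:
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        out = expit(eta[..., None] + math.sqrt(2.0) * sigma * nodes) @ weights
        out /= math.sqrt(math.pi)
    return float(out) if out.ndim == 0 else out


@dataclass(eq=False)
class StageProbabilities:
    """Per-subject stage category and exceedance probabilities."""

    category: np.ndarray  # (n, J)
    exceedance: np.ndarray  # (n, J-1)
    scale: StageScale = field(default_factory=StageScale)

    @property
    def n(self) -> int:
        return self.category.shape[0]


def categories_from_exceedance(
    exceedance: np.ndarray, scale: StageScale = StageScale()
) -> StageProbabilities:
    """Convert exceedance probabilities P(Stage > j) into category rows.

    P(1) = 1 - P(>1), P(j) = P(>j-1) - P(>j), P(J) = P(>J-1).  Raises when a
    row's exceedances increase in j (a negative category probability, possible
    under non-proportional gamma); callers must not silently clip.
    """
    exc = np.atleast_2d(np.asarray(exceedance, dtype=float))
    if exc.shape[1] != scale.cut_count:
        raise ValueError(f"expected {scale.cut_count} cuts, got {exc.shape[1]}")
    cat = np.empty((exc.shape[0], scale.n_levels))
    cat[:, 0] = 1.0 - exc[:, 0]
    if scale.cut_count > 1:
        cat[:, 1:-1] = exc[:, :-1] - exc[:, 1:]
    cat[:, -1] = exc[:, -1]
    bad = np.argwhere(cat < -1e-12)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"negative category probability for subject {i} at level index {j} "
            f"({cat[i, j]:.3g}): exceedance probabilities cross between cuts"
        )
    np.clip(cat, 0.0, None, out=cat)
    return StageProbabilities(category=cat, exceedance=exc, scale=scale)


def category_probabilities(
    sample: CohortSample,
    coeffs: CoefficientSet,
    scale: StageScale = StageScale(),
) -> StageProbabilities:
    """Stage probabilities for every subject of a cohort sample."""
    if coeffs.alpha is None:
        raise CalibrationError("intercepts not calibrated; run calibrate_intercepts")
    if len(coeffs.alpha) != scale.cut_count:
        raise ValueError(
            f"model has {len(coeffs.alpha)} intercepts for {scale.cut_count} cuts"
        )
    contrib = _covariate_contributions(sample.values, sample.names, coeffs,
                                       scale.cut_count)
    eta = coeffs.alpha[None, :] + contrib
    exc = exceedance_probability(eta, sigma=coeffs.sigma)
    return categories_from_exceedance(exc, scale)


def sample_stages(probs: StageProbabilities, seed) -> np.ndarray:
    """One categorical stage draw per subject (0-based level indices).

    A single uniform per subject is compared against the cumulative category
    probabilities, so paired runs that share the seed reuse the same uniforms
    (common random numbers).
    """
    seed_path = [int(s) for s in np.atleast_1d(seed)]
    rng = np.random.default_rng(np.random.SeedSequence(seed_path))
    cum = np.cumsum(probs.category, axis=1)
    cum[:, -1] = 1.0  # guard rounding at the top
    u = rng.random(probs.n)
    return (u[:, None] > cum).sum(axis=1)


def calibrate_intercepts(
    spec: CohortSpec,
    coeffs: CoefficientSet,
    target: Sequence[float],
    n_calib: int = 100_000,
    seed=0,
    scale: StageScale = StageScale(),
    tol: float = 1e-6,
) -> CoefficientSet:
    """Solve for intercepts reproducing a target baseline stage distribution.

    For each cut j the population-average exceedance over a calibration
    cohort of size ``n_calib`` is strictly increasing in alpha_j, so alpha_j
    is found by bracketed root-finding on [-30, 30] against the target
    cumulative proportion P(Stage > j).  Returns a copy of ``coeffs`` with
    ``alpha`` set; raises :class:`CalibrationError` if a target cumulative
    proportion is unattainable inside the bracket or the resulting average
    exceedances are non-monotone.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (scale.n_levels,):
        raise ValueError(f"target must have {scale.n_levels} entries")
    if np.any(target < 0) or abs(target.sum() - 1.0) > 1e-8:
        raise ValueError("target must be a probability distribution over stages")
    cum_targets = 1.0 - np.cumsum(target)[:-1]  # P(Stage > j) for each cut

    sample = sample_cohort(spec, n_calib, seed)
    contrib = _covariate_contributions(sample.values, sample.names, coeffs,
                                       scale.cut_count)
    alpha = np.empty(scale.cut_count)
    for j, c in enumerate(cum_targets):
        v = contrib[:, j]

        def gap(a: float) -> float:
            return float(np.mean(exceedance_probability(a + v, coeffs.sigma))) - c

        lo, hi = -ALPHA_BRACKET, ALPHA_BRACKET
        if gap(lo) > 0 or gap(hi) < 0:
            raise CalibrationError(
                f"cut {j}: cumulative target {c:.4g} unattainable within "
                f"alpha in [{lo}, {hi}]"
            )
        alpha[j] = optimize.brentq(gap, lo, hi, xtol=tol)

    mean_exc = [np.mean(exceedance_probability(alpha[j] + contrib[:, j], coeffs.sigma))
                for j in range(scale.cut_count)]
    if np.any(np.diff(mean_exc) > 1e-10):
        raise CalibrationError(
            f"calibrated average exceedances {mean_exc} are not decreasing in j"
        )
    out = dataclasses.replace(coeffs)
    out.alpha = alpha
    return out
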