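"""Synthetic cohort generation via a Gaussian copula.

A cohort is described by seven marginal factor distributions — two continuous
dietary intakes (truncated normal) and five binary lifestyle indicators
(Bernoulli) — plus a target matrix of pairwise correlations between the
*realized* variables.  Sampling draws a latent multivariate normal vector,
thresholds the binary coordinates at the quantile implied by each prevalence,
and location/scale-transforms the continuous coordinates, rejecting whole
rows whose continuous values fall outside their bounds so the continuous
block follows an exact truncated multivariate normal law.

The latent correlation matrix is solved so that the realized correlations hit
their targets: binary-binary entries via the Emrich-Piedmonte moment equation
(bivariate-normal orthant probability, root-found numerically), mixed
continuous-binary entries via the closed-form solution of the analogous
moment equation, continuous-continuous entries passed through (the truncation
mass is negligible for realistic dietary margins, > 2.5 SD from the bound).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FactorSpec",
    "CohortSpec",
    "CohortSample",
    "InfeasibleCorrelationError",
    "build_latent_correlation",
    "sample_cohort",
    "shift_spec",
]

#: smallest joint truncation mass for which rejection sampling is attempted
MIN_ACCEPTANCE_MASS = 1e-6


class InfeasibleCorrelationError(ValueError):
    """Target realized correlation lies outside the attainable range."""


@dataclass(frozen=True)
class FactorSpec:
    """Marginal distribution of a single lifestyle factor.

    Continuous factors carry ``mean``/``sd`` (natural units, e.g. kcal/day or
    g/day) and truncation bounds; binary factors carry a prevalence
    ``proportion`` in [0, 1].  Exactly the fields for the declared kind may
    be set.
    """

    name: str
    kind: str  # "continuous" | "binary"
    mean: float | None = None
    sd: float | None = None
    lower_bound: float | None = None
    upper_bound: float | None = None
    proportion: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: continuous factor needs mean and sd")
            if self.proportion is not None:
                raise ValueError(f"{self.name}: proportion is a binary-only field")
            if not self.sd > 0:
                raise ValueError(f"{self.name}: sd must be positive, got {self.sd}")
            lo = -math.inf if self.lower_bound is None else self.lower_bound
            hi = math.inf if self.upper_bound is None else self.upper_bound
            if not lo < hi:
                raise ValueError(f"{self.name}: bounds [{lo}, {hi}] are empty")
            object.__setattr__(self, "lower_bound", lo)
            object.__setattr__(self, "upper_bound", hi)
        elif self.kind == "binary":
            if self.proportion is None:
                raise ValueError(f"{self.name}: binary factor needs a proportion")
            if any(v is not None for v in (self.mean, self.sd, self.lower_bound, self.upper_bound)):
                raise ValueError(f"{self.name}: mean/sd/bounds are continuous-only fields")
            if not 0.0 <= self.proportion <= 1.0:
                raise ValueError(f"{self.name}: proportion {self.proportion} outside [0, 1]")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    @classmethod
    def continuous(
        cls,
        name: str,
        mean: float,
        sd: float,
        lower_bound: float = 0.0,
        upper_bound: float = math.inf,
    ) -> "FactorSpec":
        """Continuous factor; default bounds [0, +inf) — a physiological floor."""
        return cls(name, "continuous", mean=mean, sd=sd,
                   lower_bound=lower_bound, upper_bound=upper_bound)

    @classmethod
    def binary(cls, name: str, proportion: float) -> "FactorSpec":
        return cls(name, "binary", proportion=proportion)

    @property
    def in_bounds_mass(self) -> float:
        """Marginal probability that an untruncated draw respects the bounds."""
        if self.kind == "binary":
            return 1.0
        lo = (self.lower_bound - self.mean) / self.sd
        hi = (self.upper_bound - self.mean) / self.sd
        return float(stats.norm.cdf(hi) - stats.norm.cdf(lo))


@dataclass(eq=False)
class CohortSpec:
    """Ordered factor margins plus the target realized correlation matrix."""

    factors: tuple[FactorSpec, ...]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        k = len(self.factors)
        if self.correlation is None:
            self.correlation = np.eye(k)
        self.correlation = np.asarray(self.correlation, dtype=float)
        c = self.correlation
        if c.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}, got {c.shape}")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(c) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown factor {name!r}; known: {self.names}") from None

    def __getitem__(self, name: str) -> FactorSpec:
        return self.factors[self.index(name)]


@dataclass(eq=False)
class CohortSample:
    """Realized cohort: an n x k value matrix in CohortSpec column order."""

    values: np.ndarray
    names: tuple[str, ...]
    seed_path: tuple[int, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _binary_threshold(p: float) -> float:
    """Latent-normal cut above which the indicator is 1: P(Z > t) = p."""
    return float(stats.norm.isf(p))


def _orthant_probability(t1: float, t2: float, rho: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation rho."""
    if rho >= 1.0 - 1e-9:  # comonotone limit
        return float(stats.norm.sf(max(t1, t2)))
    if rho <= -1.0 + 1e-9:  # countermonotone limit
        return float(max(0.0, stats.norm.sf(t1) - stats.norm.cdf(t2)))
    cov = [[1.0, rho], [rho, 1.0]]
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)
        .cdf([-t1, -t2])
    )


def _binary_pair_latent(p1: float, p2: float, target: float,
                        pair: tuple[str, str]) -> float:
    """Latent correlation for a binary pair (Emrich-Piedmonte root solve).

    Solves P(Z1 > t1, Z2 > t2; rho) = p1*p2 + target * sqrt(p1 q1 p2 q2)
    for the latent rho, after checking the target against the Frechet-type
    attainable range for the given margins.
    """
    q1, q2 = 1.0 - p1, 1.0 - p2
    s = math.sqrt(p1 * q1 * p2 * q2)
    if s == 0.0:  # degenerate margin: only zero correlation is attainable
        if abs(target) > 1e-12:
            raise InfeasibleCorrelationError(
                f"{pair}: factor with degenerate proportion admits only correlation 0"
            )
        return 0.0
    r_max = (min(p1, p2) - p1 * p2) / s
    r_min = (max(0.0, p1 + p2 - 1.0) - p1 * p2) / s
    if not (r_min - 1e-9 <= target <= r_max + 1e-9):
        raise InfeasibleCorrelationError(
            f"{pair}: target correlation {target:.4g} outside attainable range "
            f"[{r_min:.4g}, {r_max:.4g}] for proportions ({p1:.4g}, {p2:.4g})"
        )
    if abs(target) < 1e-14:
        return 0.0
    target_p11 = p1 * p2 + target * s
    t1, t2 = _binary_threshold(p1), _binary_threshold(p2)
    lo, hi = -1.0 + 1e-10, 1.0 - 1e-10

    def gap(rho: float) -> float:
        return _orthant_probability(t1, t2, rho) - target_p11

    g_lo, g_hi = gap(lo), gap(hi)
    # targets at the attainable boundary: clamp to the near-singular copula
    if g_hi <= 0.0:
        return hi
    if g_lo >= 0.0:
        return lo
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def _mixed_pair_latent(p: float, target: float, pair: tuple[str, str]) -> float:
    """Latent correlation between a normal coordinate and a thresholded one.

    corr(Z, 1{Z' > t}) = rho * phi(t) / sqrt(p q), so the moment equation is
    linear in rho.  Continuous truncation is ignored here; for margins
    truncated > 2.5 SD from the mean the induced bias is under 1%.
    """
    q = 1.0 - p
    if p * q == 0.0:
        if abs(target) > 1e-12:
            raise InfeasibleCorrelationError(
                f"{pair}: factor with degenerate proportion admits only correlation 0"
            )
        return 0.0
    t = _binary_threshold(p)
    bound = float(stats.norm.pdf(t)) / math.sqrt(p * q)
    if abs(target) > bound + 1e-9:
        raise InfeasibleCorrelationError(
            f"{pair}: target correlation {target:.4g} outside attainable range "
            f"[{-bound:.4g}, {bound:.4g}] for proportion {p:.4g}"
        )
    return float(np.clip(target / bound, -1.0, 1.0))


def _nearest_correlation(m: np.ndarray) -> np.ndarray:
    """Project onto the positive semi-definite cone and restore unit diagonal."""
    w, v = np.linalg.eigh(m)
    if w.min() >= -1e-10:
        return m
    w = np.clip(w, 1e-12, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def build_latent_correlation(spec: CohortSpec) -> np.ndarray:
    """Latent-normal correlation matrix reproducing the spec's realized targets.

    Raises :class:`InfeasibleCorrelationError` naming the offending pair and
    its attainable range when a target cannot be met by any Gaussian copula
    with the given margins.
    """
    k = len(spec.factors)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            target = float(spec.correlation[i, j])
            fi, fj = spec.factors[i], spec.factors[j]
            pair = (fi.name, fj.name)
            if fi.kind == "binary" and fj.kind == "binary":
                rho = _binary_pair_latent(fi.proportion, fj.proportion, target, pair)
            elif fi.kind == "binary":
                rho = _mixed_pair_latent(fi.proportion, target, pair)
            elif fj.kind == "binary":
                rho = _mixed_pair_latent(fj.proportion, target, pair)
            else:
                rho = target
            latent[i, j] = latent[j, i] = rho
    return _nearest_correlation(latent)


def _as_seed_path(seed) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


def _latent_root(latent: np.ndarray) -> np.ndarray:
    """Square root of the latent correlation (Cholesky with eigen fallback)."""
    try:
        return np.linalg.cholesky(latent)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(latent)
        return v * np.sqrt(np.clip(w, 0.0, None))


def sample_cohort(spec: CohortSpec, n: int, seed) -> CohortSample:
    """Draw ``n`` subjects from the copula implied by ``spec``.

    ``seed`` is an integer or a tuple of integers (a seed path); the same
    (spec, n, seed) triple reproduces the sample bit for bit.  Rows whose
    continuous coordinates violate their bounds are redrawn, so the
    continuous block is an exact truncated multivariate normal.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mass = 1.0
    for f in spec.factors:
        mass *= f.in_bounds_mass
    if mass < MIN_ACCEPTANCE_MASS:
        raise ValueError(
            f"joint truncation mass ~{mass:.3g} below {MIN_ACCEPTANCE_MASS:g}; "
            "rejection sampling would not terminate"
        )
    seed_path = _as_seed_path(seed)
    rng = np.random.default_rng(np.random.SeedSequence(list(seed_path)))
    root = _latent_root(build_latent_correlation(spec))
    k = len(spec.factors)
    is_cont = np.array([f.kind == "continuous" for f in spec.factors])
    means = np.array([f.mean if f.kind == "continuous" else 0.0 for f in spec.factors])
    sds = np.array([f.sd if f.kind == "continuous" else 1.0 for f in spec.factors])
    los = np.array([f.lower_bound if f.kind == "continuous" else -math.inf
                    for f in spec.factors])
    his = np.array([f.upper_bound if f.kind == "continuous" else math.inf
                    for f in spec.factors])
    cuts = np.array([_binary_threshold(f.proportion) if f.kind == "binary" else 0.0
                     for f in spec.factors])

    values = np.empty((n, k))
    pending = np.arange(n)
    while pending.size:
        z = rng.standard_normal((pending.size, k)) @ root.T
        x = np.where(is_cont, means + sds * z, (z > cuts).astype(float))
        ok = np.all((x >= los) & (x <= his), axis=1)
        values[pending[ok]] = x[ok]
        pending = pending[~ok]
    return CohortSample(values=values, names=spec.names, seed_path=seed_path)


def shift_spec(spec: CohortSpec, factor: str, new_value: float) -> CohortSpec:
    """Copy of ``spec`` with one factor's mean (continuous) or proportion
    (binary) replaced; SDs, bounds and correlation targets are untouched."""
    idx = spec.index(factor)
    old = spec.factors[idx]
    if old.kind == "continuous":
        new = dataclasses.replace(old, mean=float(new_value))
    else:
        if not 0.0 <= new_value <= 1.0:
            raise ValueError(
                f"{factor}: proportion {new_value} outside [0, 1]"
            )
        new = dataclasses.replace(old, proportion=float(new_value))
    factors = list(spec.factors)
    factors[idx] = new
    return CohortSpec(factors=tuple(factors), correlation=spec.correlation.copy())
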