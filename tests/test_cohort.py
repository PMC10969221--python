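"""Cohort generator: copula construction, marginal/dependence recovery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from stageshift import (
    CohortSpec,
    FactorSpec,
    InfeasibleCorrelationError,
    build_latent_correlation,
    sample_cohort,
    shift_spec,
)
from stageshift.cohort import _binary_pair_latent, _mixed_pair_latent


def corr_matrix(k, pairs):
    m = np.eye(k)
    for i, j, v in pairs:
        m[i, j] = m[j, i] = v
    return m


def bivariate_orthant_dblquad(t1, t2, rho):
    """Independent oracle: P(Z1 > t1, Z2 > t2) by direct 2-D integration."""

    def pdf(y, x):
        return math.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * (1 - rho**2))) / (
            2 * math.pi * math.sqrt(1 - rho**2)
        )

    val, err = integrate.dblquad(pdf, t1, 9.0, t2, 9.0)
    assert err < 1e-7
    return val


class TestLatentCorrelation:
    def test_independent_targets_give_identity(self):
        spec = CohortSpec(
            factors=(
                FactorSpec.continuous("e", 1605, 576),
                FactorSpec.binary("m", 0.831),
                FactorSpec.binary("s", 0.504),
            )
        )
        assert np.array_equal(build_latent_correlation(spec), np.eye(3))

    def test_median_dichotomized_pair_closed_form(self):
        # two fair indicators with realized correlation r need latent
        # rho = sin(pi r / 2); r = 0.5 -> rho = sqrt(2)/2
        rho = _binary_pair_latent(0.5, 0.5, 0.5, ("a", "b"))
        assert rho == pytest.approx(math.sin(math.pi * 0.5 / 2), abs=1e-6)
        # and the solved rho reproduces the target cell probability under
        # independent numerical integration
        p11 = bivariate_orthant_dblquad(0.0, 0.0, rho)
        assert p11 == pytest.approx(0.25 + 0.5 * 0.25, abs=1e-6)

    def test_infeasible_binary_pair_raises_with_range(self):
        # margins 0.9/0.1: comonotone coupling caps the correlation at
        # (0.1 - 0.09)/0.09 = 1/9, so a 0.95 target is unattainable
        spec = CohortSpec(
            factors=(FactorSpec.binary("a", 0.9), FactorSpec.binary("b", 0.1)),
            correlation=corr_matrix(2, [(0, 1, 0.95)]),
        )
        with pytest.raises(InfeasibleCorrelationError, match="a.*b.*0.1111"):
            build_latent_correlation(spec)

    def test_binary_pair_boundary_target_clamps(self):
        # at the Frechet boundary the latent rho runs to +1; the solved value
        # must reproduce the boundary cell probability min(p1, p2) = 0.1
        rho = _binary_pair_latent(0.9, 0.1, 1.0 / 9.0, ("a", "b"))
        assert rho > 0.9
        from stageshift.cohort import _orthant_probability

        t1, t2 = stats.norm.isf(0.9), stats.norm.isf(0.1)
        assert _orthant_probability(t1, t2, rho) == pytest.approx(0.1, abs=1e-6)

    def test_mixed_pair_matches_moment_equation(self):
        # independent oracle: E[Z1 1{Z2 > t}] by 2-D integration
        p, target = 0.6, 0.25
        rho = _mixed_pair_latent(p, target, ("c", "b"))
        t = stats.norm.isf(p)

        def integrand(y, x):
            return x * math.exp(
                -(x * x - 2 * rho * x * y + y * y) / (2 * (1 - rho**2))
            ) / (2 * math.pi * math.sqrt(1 - rho**2))

        ez, _ = integrate.dblquad(integrand, -9.0, 9.0, t, 9.0)
        assert ez / math.sqrt(p * (1 - p)) == pytest.approx(target, abs=1e-6)

    def test_mixed_pair_infeasible_target(self):
        with pytest.raises(InfeasibleCorrelationError, match="attainable"):
            _mixed_pair_latent(0.95, 0.9, ("c", "b"))


class TestSampling:
    def test_marginal_recovery_pooled(self, cohort_spec):
        pooled = np.vstack(
            [sample_cohort(cohort_spec, 1000, (11, r)).values for r in range(20)]
        )
        names = cohort_spec.names
        n = pooled.shape[0]
        for f in cohort_spec.factors:
            col = pooled[:, names.index(f.name)]
            if f.kind == "continuous":
                se = col.std(ddof=1) / math.sqrt(n)
                assert abs(col.mean() - f.mean) < 3 * se
                assert abs(col.std(ddof=1) - f.sd) / f.sd < 0.03
                assert col.min() >= f.lower_bound
            else:
                assert set(np.unique(col)) <= {0.0, 1.0}
                se = math.sqrt(f.proportion * (1 - f.proportion) / n)
                assert abs(col.mean() - f.proportion) < 3 * se

    @pytest.mark.parametrize("target", [0.0, -0.2, 0.3, 0.5])
    def test_dependence_recovery(self, target):
        spec = CohortSpec(
            factors=(
                FactorSpec.continuous("e", 1605, 576),
                FactorSpec.continuous("p", 64, 25),
                FactorSpec.binary("m", 0.7),
                FactorSpec.binary("s", 0.4),
            ),
            correlation=corr_matrix(
                4, [(0, 1, target), (0, 2, target * 0.8), (2, 3, target)]
            ),
        )
        n = 40_000
        v = sample_cohort(spec, n, 5).values
        se = 3.0 / math.sqrt(n)  # conservative: SE(r) <= 1/sqrt(n) for |r| <= .5
        c = np.corrcoef(v, rowvar=False)
        assert abs(c[0, 1] - target) < 3 * se + 0.01  # truncation slack
        assert abs(c[0, 2] - target * 0.8) < 3 * se + 0.01
        assert abs(c[2, 3] - target) < 3 * se + 0.01

    def test_copula_cell_probabilities_match_integration(self):
        # realized joint cells of a binary pair vs. orthant probabilities
        # from independent 2-D numerical integration
        p1, p2, target = 0.7, 0.4, 0.3
        spec = CohortSpec(
            factors=(FactorSpec.binary("a", p1), FactorSpec.binary("b", p2)),
            correlation=corr_matrix(2, [(0, 1, target)]),
        )
        rho = build_latent_correlation(spec)[0, 1]
        t1, t2 = stats.norm.isf(p1), stats.norm.isf(p2)
        p11 = bivariate_orthant_dblquad(t1, t2, rho)
        expected = {
            (1, 1): p11,
            (1, 0): p1 - p11,
            (0, 1): p2 - p11,
            (0, 0): 1 - p1 - p2 + p11,
        }
        v = sample_cohort(spec, 4_000_000, 123).values
        for (a, b), prob in expected.items():
            emp = np.mean((v[:, 0] == a) & (v[:, 1] == b))
            assert abs(emp - prob) < 1e-3

    def test_determinism(self, cohort_spec):
        s1 = sample_cohort(cohort_spec, 500, (3, 4))
        s2 = sample_cohort(cohort_spec, 500, (3, 4))
        assert np.array_equal(s1.values, s2.values)
        assert s1.seed_path == (3, 4)
        s3 = sample_cohort(cohort_spec, 500, (3, 5))
        assert not np.array_equal(s1.values, s3.values)

    def test_degenerate_proportion_one(self):
        spec = CohortSpec(factors=(FactorSpec.binary("always", 1.0),))
        v = sample_cohort(spec, 200, 0).values
        assert np.all(v == 1.0)

    def test_truncation_mass_floor(self):
        spec = CohortSpec(
            factors=(FactorSpec.continuous("x", mean=-20.0, sd=1.0, lower_bound=0.0),)
        )
        with pytest.raises(ValueError, match="truncation mass"):
            sample_cohort(spec, 10, 0)

    def test_invalid_n(self, cohort_spec):
        with pytest.raises(ValueError, match="n must be"):
            sample_cohort(cohort_spec, 0, 0)

    @given(p=st.floats(0.05, 0.95), seed=st.integers(0, 2**20))
    def test_binary_columns_are_indicator_valued(self, p, seed):
        spec = CohortSpec(
            factors=(FactorSpec.binary("b", p), FactorSpec.continuous("c", 10, 2))
        )
        v = sample_cohort(spec, 50, seed).values
        assert set(np.unique(v[:, 0])) <= {0.0, 1.0}
        assert np.all(v[:, 1] >= 0.0)


class TestShiftSpec:
    def test_continuous_mean_replaced(self, cohort_spec):
        shifted = shift_spec(cohort_spec, "protein", 70)
        assert shifted["protein"].mean == 70
        assert shifted["protein"].sd == cohort_spec["protein"].sd
        assert shifted["energy"] == cohort_spec["energy"]
        assert np.array_equal(shifted.correlation, cohort_spec.correlation)

    def test_binary_proportion_replaced(self, cohort_spec):
        shifted = shift_spec(cohort_spec, "mammogram", 0.95)
        assert shifted["mammogram"].proportion == 0.95
        others = [n for n in cohort_spec.names if n != "mammogram"]
        for n in others:
            assert shifted[n] == cohort_spec[n]

    def test_identity_shift(self, cohort_spec):
        shifted = shift_spec(cohort_spec, "protein", cohort_spec["protein"].mean)
        assert shifted.factors == cohort_spec.factors

    def test_invalid_proportion_rejected(self, cohort_spec):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            shift_spec(cohort_spec, "mammogram", 1.2)

    def test_unknown_factor_rejected(self, cohort_spec):
        with pytest.raises(KeyError, match="unknown factor"):
            shift_spec(cohort_spec, "smoking", 0.5)


class TestSpecValidation:
    def test_factor_kind_fields_enforced(self):
        with pytest.raises(ValueError, match="needs mean and sd"):
            FactorSpec("x", "continuous")
        with pytest.raises(ValueError, match="binary-only"):
            FactorSpec("x", "continuous", mean=1, sd=1, proportion=0.5)
        with pytest.raises(ValueError, match="proportion"):
            FactorSpec.binary("x", 1.5)
        with pytest.raises(ValueError, match="sd"):
            FactorSpec.continuous("x", 1, -1)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CohortSpec(factors=(FactorSpec.binary("a", 0.5), FactorSpec.binary("a", 0.4)))

    def test_correlation_shape_and_diagonal(self):
        factors = (FactorSpec.binary("a", 0.5), FactorSpec.binary("b", 0.4))
        with pytest.raises(ValueError, match="unit diagonal"):
            CohortSpec(factors=factors, correlation=np.array([[2.0, 0], [0, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            CohortSpec(factors=factors, correlation=np.array([[1.0, 0.2], [0.1, 1.0]]))
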