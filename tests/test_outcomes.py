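"""Counts of significant SNPs and variance explained, vs independent oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from gwaspower import (
    GeneticArchitecture,
    apparent_variance_explained,
    corrected_variance_explained,
    expected_significant,
    gwas_outcomes,
    power_distribution,
    probability_interval,
    significance_threshold,
    variance_of_variance_explained,
    variance_significant,
    winners_curse_posterior,
)

PARAM_GRID = [
    GeneticArchitecture(h2=0.1, pi0=0.9, m=60_000),
    GeneticArchitecture(h2=0.4, pi0=0.99, m=60_000),
    GeneticArchitecture(h2=0.483, pi0=0.66, m=60_000),
    GeneticArchitecture(h2=0.089, pi0=0.85, m=60_000),
]


class TestSignificantCounts:
    def test_detected_causal_fraction_equals_mean_power(self, arch_moderate):
        n, alpha = 1e5, 5e-8
        _, e_c = expected_significant(arch_moderate, n, alpha)
        e_p = power_distribution(arch_moderate, n, alpha).mean
        assert e_c / arch_moderate.m1 == pytest.approx(e_p, rel=1e-12)

    def test_null_floor_at_tiny_sample_size(self):
        # with no power beyond the type-I rate, every SNP fires at ~alpha
        arch = GeneticArchitecture(h2=0.1, pi0=0.9, m=60_000)
        alpha = 5e-8
        e_s, e_c = expected_significant(arch, n=1, alpha=alpha)
        assert e_c == pytest.approx(arch.m1 * alpha, rel=1e-2)
        assert e_s == pytest.approx(arch.m * alpha, rel=1e-2)

    def test_pure_null_run_is_binomial(self):
        arch = GeneticArchitecture(h2=0.0, pi0=1.0, m=60_000)
        alpha = 1e-4
        e_s, e_c = expected_significant(arch, n=1e5, alpha=alpha)
        assert e_c == 0.0
        assert e_s == pytest.approx(arch.m * alpha, rel=1e-12)
        assert variance_significant(arch, 1e5, alpha) == pytest.approx(
            arch.m * alpha * (1 - alpha), rel=1e-12
        )

    def test_saturation_limit_large_n(self):
        # E(p) -> 1 up to the central grid cell (mass ~1e-3) whose midpoint
        # sits exactly at beta = 0 and contributes alpha forever
        arch = GeneticArchitecture(h2=0.4, pi0=0.99, m=60_000)
        alpha = 5e-8
        e_s, e_c = expected_significant(arch, n=1e12, alpha=alpha)
        assert e_c == pytest.approx(arch.m1, rel=2e-3)
        assert e_s == pytest.approx(arch.m1 + arch.m * arch.pi0 * alpha, rel=2e-3)

    def test_variance_nonnegative_and_below_binomial(self):
        for arch in PARAM_GRID:
            v = variance_significant(arch, 2e5, 5e-8)
            e_p = power_distribution(arch, 2e5, 5e-8).mean
            binom = arch.m * arch.pi0 * 5e-8 + arch.m1 * e_p * (1 - e_p)
            assert 0.0 <= v <= binom + 1e-9


class TestProbabilityInterval:
    def test_degenerate_and_floored(self):
        assert probability_interval(10.0, 0.0) == (10.0, 10.0)
        lo, hi = probability_interval(0.0, 4.0)
        assert lo == 0.0
        assert hi == pytest.approx(2 * stats.norm.isf(0.025), rel=1e-12)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            probability_interval(1.0, -0.5)


class TestWinnersCursePosterior:
    def test_zero_estimate_shrinks_to_zero_mean(self, arch_moderate):
        p_null, e_b, e_b2 = winners_curse_posterior(0.0, arch_moderate, 1e5)
        assert e_b == 0.0
        assert 0 < p_null < 1
        assert e_b2 > 0  # posterior spread survives at beta_hat = 0

    def test_flat_prior_limit_no_shrinkage(self):
        # pi0 = 0 and sigma2 >> 1/n: lambda -> 1
        arch = GeneticArchitecture(h2=1.0, pi0=0.0, m=10)
        n = 1e6
        bh = 0.3
        _, e_b, e_b2 = winners_curse_posterior(bh, arch, n)
        lam = arch.sigma2 / (arch.sigma2 + 1 / n)
        assert lam > 0.9999
        assert e_b == pytest.approx(bh, rel=1e-3)
        assert e_b2 == pytest.approx(bh**2 + lam / n, rel=1e-3)

    @pytest.mark.parametrize("beta_hat", [0.005, 0.01, 0.03])
    def test_against_quadrature_oracle(self, beta_hat):
        """Direct numeric posterior: prior density x N(bh | b, 1/n)."""
        arch = GeneticArchitecture(h2=0.3, pi0=0.95, m=20_000)
        n = 50_000
        s2, v0 = arch.sigma2, 1.0 / n

        def joint(b):
            return stats.norm.pdf(b, scale=np.sqrt(s2)) * stats.norm.pdf(
                beta_hat - b, scale=np.sqrt(v0)
            )

        hi = 12 * np.sqrt(s2)
        m0, _ = integrate.quad(joint, -hi, hi, limit=200)
        m2, _ = integrate.quad(lambda b: b * b * joint(b), -hi, hi, limit=200)
        null_lik = arch.pi0 * stats.norm.pdf(beta_hat, scale=np.sqrt(v0))
        marg = null_lik + (1 - arch.pi0) * m0
        expected_e_b2 = (1 - arch.pi0) * m2 / marg
        _, _, e_b2 = winners_curse_posterior(beta_hat, arch, n)
        assert e_b2 == pytest.approx(expected_e_b2, rel=1e-8)

    def test_shrinks_large_estimates(self, arch_moderate):
        n = 1e5
        bh = 10 * significance_threshold(n, 5e-8)
        _, _, e_b2 = winners_curse_posterior(bh, arch_moderate, n)
        assert e_b2 < bh**2


class TestVarianceExplained:
    def test_no_truncation_limit_recovers_total_variance(self, arch_moderate):
        n, alpha = 1e5, 1 - 1e-9
        ve = apparent_variance_explained(arch_moderate, n, alpha)
        total = arch_moderate.m * (1 / n + arch_moderate.h2 / arch_moderate.m)
        assert ve == pytest.approx(total, rel=1e-3)

    @pytest.mark.parametrize("arch", PARAM_GRID)
    @pytest.mark.parametrize("n", [5e4, 5e5])
    def test_corrected_never_exceeds_apparent(self, arch, n):
        app = apparent_variance_explained(arch, n, 5e-8)
        corr = corrected_variance_explained(arch, n, 5e-8)
        assert 0.0 <= corr <= app

    def test_corrected_against_quadrature_oracle(self):
        """Outer expectation of E(beta^2 | beta_hat) over the truncated
        estimate mixture, integrated numerically."""
        arch = GeneticArchitecture(h2=0.483, pi0=0.66, m=60_000)
        n, alpha = 693_529, 1e-8
        T = significance_threshold(n, alpha)
        v0 = 1.0 / n
        v1 = arch.sigma2 + v0

        def integrand(bh):
            _, _, e_b2 = winners_curse_posterior(bh, arch, n)
            mix = arch.pi0 * stats.norm.pdf(bh, scale=np.sqrt(v0)) + (
                1 - arch.pi0
            ) * stats.norm.pdf(bh, scale=np.sqrt(v1))
            return e_b2 * mix

        val, _ = integrate.quad(integrand, T, 20 * np.sqrt(v1), limit=400)
        oracle = 2 * arch.m * val  # both tails, times m
        assert corrected_variance_explained(arch, n, alpha) == pytest.approx(
            oracle, rel=1e-8
        )

    def test_heritability_recovered_at_large_n(self):
        arch = GeneticArchitecture(h2=0.4, pi0=0.99, m=60_000)
        alpha = 5e-8
        n = 1e10
        app = apparent_variance_explained(arch, n, alpha)
        corr = corrected_variance_explained(arch, n, alpha)
        noise_floor = arch.m * alpha / n  # null SNPs' inflation, negligible here
        assert app == pytest.approx(arch.h2, rel=1e-3)
        assert corr == pytest.approx(arch.h2, rel=1e-3)
        assert app - arch.h2 < 0.01 + noise_floor


@pytest.fixture(scope="module")
def mixture_sim():
    """Direct Monte-Carlo of the generative model: B trait realizations
    (causal set + effects) x R replicate GWAS estimate vectors each.

    Pooled means estimate the marginal expectations; within-realization
    variances estimate the sampling variance of a repeated GWAS of one
    fixed trait, which is what the analytic Var(S) describes.
    """
    rng = np.random.default_rng(7)
    arch = GeneticArchitecture(h2=0.4, pi0=0.9, m=2000)
    n, alpha = 2e4, 1e-5
    B, R = 60, 120
    T = significance_threshold(n, alpha)
    m1 = int(round(arch.m1))
    S = np.empty((B, R))
    VE = np.empty((B, R))
    for b in range(B):
        beta = np.zeros(arch.m)
        idx = rng.choice(arch.m, m1, replace=False)
        beta[idx] = rng.normal(0, arch.causal_sd, m1)
        bh = beta[None, :] + rng.normal(0, np.sqrt(1 / n), (R, arch.m))
        sig = np.abs(bh) > T
        S[b] = sig.sum(axis=1)
        VE[b] = np.where(sig, bh**2, 0.0).sum(axis=1)
    return arch, n, alpha, S, VE


class TestAgainstMixtureSimulation:
    def test_expected_count(self, mixture_sim):
        arch, n, alpha, S, VE = mixture_sim
        e_s, _ = expected_significant(arch, n, alpha)
        per_trait = S.mean(axis=1)
        se = per_trait.std(ddof=1) / np.sqrt(per_trait.size)
        assert e_s == pytest.approx(S.mean(), abs=3 * se)

    def test_count_variance_conditional_on_trait(self, mixture_sim):
        arch, n, alpha, S, VE = mixture_sim
        v = variance_significant(arch, n, alpha)
        within = S.var(axis=1, ddof=1).mean()
        assert 0.8 * v < within < 1.25 * v

    def test_apparent_ve_mean(self, mixture_sim):
        arch, n, alpha, S, VE = mixture_sim
        app = apparent_variance_explained(arch, n, alpha)
        per_trait = VE.mean(axis=1)
        se = per_trait.std(ddof=1) / np.sqrt(per_trait.size)
        assert app == pytest.approx(VE.mean(), abs=3 * se)

    def test_ve_variance_between_conditional_and_marginal(self, mixture_sim):
        """The law-of-total-variance Var(VE) treats significant contributions
        as i.i.d. redraws given S: it upper-bounds the fixed-trait sampling
        variance and lower-bounds the across-trait-realization variance."""
        arch, n, alpha, S, VE = mixture_sim
        var_ve, _ = variance_of_variance_explained(arch, n, alpha)
        within = VE.var(axis=1, ddof=1).mean()
        marginal = VE.reshape(-1).var(ddof=1)
        assert within < var_ve < marginal


class TestOutcomeSummary:
    def test_summary_consistent_with_parts(self, arch_moderate):
        n, alpha = 2e5, 5e-8
        s = gwas_outcomes(arch_moderate, n, alpha)
        e_s, e_c = expected_significant(arch_moderate, n, alpha)
        assert s.E_S == e_s and s.E_C == e_c
        assert s.PI_S[0] <= s.E_S <= s.PI_S[1]
        assert s.corrected_VE <= s.apparent_VE <= 1.0
        assert s.E_S >= arch_moderate.m * arch_moderate.pi0 * alpha
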