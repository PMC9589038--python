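"""Genetic architecture of a polygenic trait and scale transformations.

The model: a genome is summarised by ``m`` nearly independent SNPs (after LD
pruning/clumping).  A proportion ``pi0`` of them are null; the remaining
``m1 = m (1 - pi0)`` causal SNPs carry standardized (per-phenotypic-sd,
per-genotypic-sd) effects drawn from ``N(0, sigma2)`` with
``sigma2 = h2 / (m (1 - pi0))``, so that the causal effects jointly account
for the SNP heritability ``h2``.  Stacking the null point mass and the causal
normal gives the point-normal law

    beta ~ pi0 * delta_0 + (1 - pi0) * N(0, sigma2).

For disease traits analysed under the liability-threshold model, standardized
log-odds ratios ``gamma`` translate to liability-scale effects through the
prevalence-dependent factor ``K (1 - K) / phi(Phi^-1(K))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateArchitectureError",
    "GeneticArchitecture",
    "EffectSizeDistribution",
    "EstimateMixture",
    "LiabilityContext",
    "effect_size_distribution",
    "estimate_distribution",
    "liability_multiplier",
    "liability_effect_from_log_odds",
]

#: Default number of nearly independent SNPs genome-wide (European-ancestry
#: panels after clumping at conventional thresholds).
DEFAULT_M = 60_000


class DegenerateArchitectureError(ValueError):
    """Raised when pi0 = 1 leaves no causal SNP to carry the heritability."""


@dataclass(frozen=True)
class GeneticArchitecture:
    """Point-normal genetic architecture ``(h2, pi0, m)``.

    Parameters
    ----------
    h2 : float
        SNP heritability, the proportion of phenotypic (or liability)
        variance explained jointly by the ``m`` SNPs; in ``[0, 1]``.
    pi0 : float
        Proportion of null SNPs; in ``[0, 1]``.  ``pi0 = 0`` is the
        infinitesimal model.
    m : int, default 60_000
        Number of nearly independent SNPs.
    """

    h2: float
    pi0: float
    m: int = DEFAULT_M

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1], got {self.h2}")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")

    @property
    def m1(self) -> float:
        """Number of causal SNPs, ``m (1 - pi0)``."""
        return self.m * (1.0 - self.pi0)

    @property
    def sigma2(self) -> float:
        """Variance of a causal effect, ``h2 / (m (1 - pi0))``."""
        if self.pi0 >= 1.0:
            raise DegenerateArchitectureError(
                "pi0 = 1 leaves no causal SNPs; the causal effect variance "
                "h2 / (m (1 - pi0)) is undefined"
            )
        return self.h2 / self.m1

    @property
    def causal_sd(self) -> float:
        """Standard deviation of a causal effect."""
        return float(np.sqrt(self.sigma2))


@dataclass(frozen=True)
class EffectSizeDistribution:
    """Point-normal law of standardized effects across all SNPs.

    ``pi0`` of the mass sits in a point at zero; the rest is
    ``N(0, sigma2)``.
    """

    pi0: float
    sigma2: float

    @property
    def variance(self) -> float:
        """Unconditional second moment of beta, ``(1 - pi0) sigma2``."""
        return (1.0 - self.pi0) * self.sigma2

    def causal_pdf(self, beta):
        """Density of the causal (normal) component."""
        return stats.norm.pdf(beta, scale=np.sqrt(self.sigma2))

    def rvs(self, size: int, rng: np.random.Generator):
        """Draw effects from the mixture (exact zeros for null SNPs)."""
        causal = rng.random(size) >= self.pi0
        out = np.zeros(size)
        out[causal] = rng.normal(0.0, np.sqrt(self.sigma2), causal.sum())
        return out


def effect_size_distribution(arch: GeneticArchitecture) -> EffectSizeDistribution:
    """Point-normal effect-size distribution implied by an architecture.

    Raises
    ------
    DegenerateArchitectureError
        If ``pi0 = 1`` (no causal SNPs).
    """
    return EffectSizeDistribution(pi0=arch.pi0, sigma2=arch.sigma2)


@dataclass(frozen=True)
class EstimateMixture:
    """Marginal law of the effect estimate ``beta_hat`` across all SNPs.

    With sampling variance ``1/n`` around the true effect, marginalising the
    point-normal prior gives a two-component zero-mean normal mixture:
    weight ``pi0`` on ``N(0, 1/n)`` and ``1 - pi0`` on ``N(0, sigma2 + 1/n)``.
    """

    weights: tuple[float, float]
    variances: tuple[float, float]

    @property
    def variance(self) -> float:
        w, v = self.weights, self.variances
        return w[0] * v[0] + w[1] * v[1]

    def pdf(self, x):
        w, v = self.weights, self.variances
        return w[0] * stats.norm.pdf(x, scale=np.sqrt(v[0])) + w[1] * stats.norm.pdf(
            x, scale=np.sqrt(v[1])
        )

    def rvs(self, size: int, rng: np.random.Generator):
        w, v = self.weights, self.variances
        null = rng.random(size) < w[0]
        sd = np.where(null, np.sqrt(v[0]), np.sqrt(v[1]))
        return rng.normal(0.0, 1.0, size) * sd


def estimate_distribution(arch: GeneticArchitecture, n: float) -> EstimateMixture:
    """Mixture distribution of ``beta_hat`` at sample size ``n``.

    ``pi0 = 1`` collapses to the single null component ``N(0, 1/n)``.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if arch.pi0 >= 1.0:
        return EstimateMixture(weights=(1.0, 0.0), variances=(1.0 / n, 1.0 / n))
    return EstimateMixture(
        weights=(arch.pi0, 1.0 - arch.pi0),
        variances=(1.0 / n, arch.sigma2 + 1.0 / n),
    )


@dataclass(frozen=True)
class LiabilityContext:
    """Liability-threshold model context for a disease of prevalence ``K``."""

    K: float

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must lie in (0, 1), got {self.K}")

    #: Height of the standard normal density at the liability threshold.
    @property
    def z(self) -> float:
        return float(stats.norm.pdf(stats.norm.ppf(self.K)))

    @property
    def multiplier(self) -> float:
        """Log-odds to liability-scale conversion, ``K(1-K)/phi(Phi^-1(K))``."""
        return self.K * (1.0 - self.K) / self.z


def liability_multiplier(K: float) -> float:
    """Factor converting a standardized log-odds ratio to a liability effect."""
    return LiabilityContext(K).multiplier


def liability_effect_from_log_odds(gamma, K: float):
    """Approximate liability-scale effect for log-odds ratio ``gamma``.

    Linear and sign-preserving: ``beta ~= K(1-K)/phi(Phi^-1(K)) * gamma``.
    """
    return liability_multiplier(K) * np.asarray(gamma)
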