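"""Polygenic-score efficacy under the point-normal architecture.

A polygenic score built with weights ``beta_tilde_j`` is assessed by its
squared correlation with the true additive genetic value,

    r^2(G, G_tilde) = Cov^2(beta, beta_tilde) / (Var(beta) Var(beta_tilde)),

where the (co)variances are taken over the joint law of the true effect
``beta`` (point-normal) and its estimate ``beta_hat = beta + e``,
``e ~ N(0, 1/n)``.  Phenotype-scale accuracy is ``r^2 * h2``.

Three weighting rules are covered:

* OLSE — raw marginal estimates; closed form ``1 / (1 + m / (n h2))``,
  independent of polygenicity.
* p-value thresholding — ``beta_tilde = beta_hat 1{|beta_hat| > T}``;
  moments in closed truncated-normal form, with a bounded scalar search for
  the ``r^2``-maximizing threshold.
* Posterior-mean shrinkage — ``beta_tilde = E(beta | beta_hat)``; by the
  projection property ``r^2 = Var(beta_tilde) / Var(beta)``, evaluated by
  adaptive quadrature over the estimate mixture.

For binary traits the liability-scale ``r^2`` converts to an ROC AUC through
the liability-threshold model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, optimize, stats

from ._truncmoments import tail_m2
from .architecture import GeneticArchitecture
from .outcomes import winners_curse_posterior

__all__ = [
    "PGSAccuracy",
    "pgs_olse_r2",
    "pgs_threshold_r2",
    "optimize_threshold",
    "pgs_posterior_r2",
    "liability_r2_to_auc",
]


@dataclass(frozen=True)
class PGSAccuracy:
    """Efficacy of a polygenic score relative to the true genetic value."""

    method: str
    r2_genetic: float
    r2_phenotype: float
    threshold: Optional[float] = None
    equivalent_p: Optional[float] = None
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"method": self.method, "r2_genetic": self.r2_genetic,
             "r2_phenotype": self.r2_phenotype}
        if self.threshold is not None:
            d["threshold"] = self.threshold
            d["equivalent_p"] = self.equivalent_p
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def pgs_olse_r2(arch: GeneticArchitecture, n: float) -> PGSAccuracy:
    """Efficacy of the unshrunk marginal-estimate score.

    ``r^2(G_hat, G) = 1 / (1 + m / (n h2))``; zero when ``h2 = 0``.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    r2 = 0.0 if arch.h2 == 0.0 else 1.0 / (1.0 + arch.m / (n * arch.h2))
    return PGSAccuracy("olse", r2, r2 * arch.h2)


def _threshold_r2_value(arch: GeneticArchitecture, n: float, T: float) -> float:
    v0 = 1.0 / n
    v1 = arch.sigma2 + v0
    lam = arch.sigma2 / v1
    w1 = 1.0 - arch.pi0
    var_beta = arch.h2 / arch.m  # across all SNPs, nulls included
    # E[bh^2 1{|bh|>T}] per component; Cov(beta, beta_tilde) = lam * causal part
    m2_1 = tail_m2(v1, T)
    cov = w1 * lam * m2_1
    var_tilde = arch.pi0 * tail_m2(v0, T) + w1 * m2_1
    if var_tilde <= 0.0:
        return 0.0
    return cov * cov / (var_beta * var_tilde)


def pgs_threshold_r2(arch: GeneticArchitecture, n: float, threshold: float) -> PGSAccuracy:
    """Efficacy of hard thresholding at ``|beta_hat| > threshold``.

    ``threshold`` is on the beta_hat scale; ``threshold = 0`` keeps every SNP
    and reproduces the OLSE efficacy.  The equivalent two-sided p-value cutoff
    ``2 Q(threshold sqrt(n))`` is reported alongside.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    r2 = _threshold_r2_value(arch, n, threshold)
    return PGSAccuracy(
        "threshold",
        r2,
        r2 * arch.h2,
        threshold=threshold,
        equivalent_p=float(2.0 * stats.norm.sf(threshold * np.sqrt(n))),
    )


def optimize_threshold(arch: GeneticArchitecture, n: float) -> PGSAccuracy:
    """Threshold maximizing ``r^2(G, G_tilde)``, by bounded scalar search."""
    v1 = arch.sigma2 + 1.0 / n
    hi = 10.0 * np.sqrt(v1)
    res = optimize.minimize_scalar(
        lambda t: -_threshold_r2_value(arch, n, t),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    # the bounded search can sit in a flat region; keep whichever of
    # {optimum, no threshold} wins
    best_t, best_r2 = float(res.x), float(-res.fun)
    r2_zero = _threshold_r2_value(arch, n, 0.0)
    if r2_zero > best_r2:
        best_t, best_r2 = 0.0, r2_zero
    return PGSAccuracy(
        "threshold",
        best_r2,
        best_r2 * arch.h2,
        threshold=best_t,
        equivalent_p=float(2.0 * stats.norm.sf(best_t * np.sqrt(n))),
    )


def pgs_posterior_r2(arch: GeneticArchitecture, n: float, rel_tol: float = 1e-10) -> PGSAccuracy:
    """Efficacy of the posterior-mean (point-normal shrinkage) score.

    ``beta_tilde(bh) = E(beta | bh)``; since the posterior mean is the
    orthogonal projection of ``beta`` onto functions of ``bh``,
    ``Cov(beta, beta_tilde) = Var(beta_tilde)`` and

        r^2 = Var(beta_tilde) / Var(beta).

    ``Var(beta_tilde)`` is a one-dimensional integral over the estimate
    mixture, evaluated by adaptive quadrature (symmetric, so twice the
    positive half-line restricted to 20 mixture sd).
    """
    v0 = 1.0 / n
    v1 = arch.sigma2 + v0
    w0, w1 = arch.pi0, 1.0 - arch.pi0
    var_beta = arch.h2 / arch.m

    def integrand(bh):
        _, e_beta, _ = winners_curse_posterior(bh, arch, n)
        mix = w0 * stats.norm.pdf(bh, scale=np.sqrt(v0)) + w1 * stats.norm.pdf(
            bh, scale=np.sqrt(v1)
        )
        return e_beta**2 * mix

    hi = 20.0 * np.sqrt(v1)
    val, _ = integrate.quad(
        integrand, 0.0, hi, epsrel=rel_tol, epsabs=0.0, limit=400,
        points=[np.sqrt(v0), np.sqrt(v1)],
    )
    r2 = 2.0 * val / var_beta
    return PGSAccuracy("posterior", min(r2, 1.0), min(r2, 1.0) * arch.h2)


def liability_r2_to_auc(r2_liability: float, K: float, nodes: int = 200) -> float:
    """ROC AUC of a score explaining ``r2_liability`` of liability variance.

    Under the liability-threshold model with prevalence ``K``, cases are the
    upper liability tail at ``t = Phi^-1(1 - K)`` and the score ``G``
    satisfies ``L = G + e`` with ``Var(G) = r2``.  The AUC is the exact
    concordance probability

        AUC = P(G_case > G_control)
            = E[ Phi( a (L1 - L2) ) ],   a = sqrt(r2 / (2 (1 - r2))),

    with ``L1`` the case (upper-tail) and ``L2`` the control (lower-tail)
    truncated liabilities — using ``G = r2 L + u``, ``u`` independent noise.
    The double expectation is evaluated by Gauss-Legendre quadrature in
    probability space, which is exact up to quadrature error for every
    ``r2`` (including the limits ``r2 = 0 -> 0.5`` and ``r2 -> 1 -> 1``).
    """
    if not 0.0 <= r2_liability <= 1.0:
        raise ValueError(f"r2 must lie in [0, 1], got {r2_liability}")
    if not 0.0 < K < 1.0:
        raise ValueError(f"K must lie strictly in (0, 1), got {K}")
    r2 = r2_liability
    if r2 == 0.0:
        return 0.5
    if r2 == 1.0:
        return 1.0  # score equals liability: cases and controls separate
    x, wq = np.polynomial.legendre.leggauss(nodes)
    u = 0.5 * (x + 1.0)  # nodes on (0, 1)
    wq = 0.5 * wq
    L1 = stats.norm.ppf(1.0 - K * u)          # case liabilities, upper tail
    L2 = stats.norm.ppf((1.0 - K) * u)        # control liabilities, lower tail
    a = np.sqrt(r2 / (2.0 * (1.0 - r2)))
    inner = stats.norm.cdf(a * (L1[:, None] - L2[None, :]))
    return float(wq @ inner @ wq)
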