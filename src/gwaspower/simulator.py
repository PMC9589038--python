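"""Forward GWAS simulator on independent SNPs.

Validates the analytic machinery end to end: genotypes are drawn as
``Binomial(2, f)`` with ``f ~ Uniform(0.01, 0.5)`` and sample-standardized,
causal effects come from the architecture's point-normal law, and phenotypes
add Gaussian residual noise so the causal SNPs jointly explain ``h2``.
Association is the closed-form per-SNP regression on standardized data
(``beta_hat = x . y / n``, identical to simple OLS there), with the Wald
chi-square ``n beta_hat^2``.

Three sampling schemes:

* quantitative / random — SNP-chunked two-pass streaming with per-chunk RNG
  substreams, so results are bit-identical regardless of chunk size or
  whether chunks are cached or regenerated;
* quantitative / extreme — individuals kept only from the two phenotype
  tails; estimates are mapped back to the population scale through the
  selected-sample standard deviation;
* binary / case-control — liability thresholded at prevalence ``K``, cases
  oversampled to fraction ``w``, per-SNP logistic score test with a one-step
  log-odds estimate transformed to the liability scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .architecture import GeneticArchitecture, liability_multiplier
from .design import (
    CaseControlDesign,
    ExtremeSelectionDesign,
    equivalent_n,
    selected_trait_variance,
)
from .outcomes import OutcomeSummary, gwas_outcomes

__all__ = ["SimConfig", "SimResult", "simulate_replicate", "run_simulation", "run_validation"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated GWAS experiment."""

    arch: GeneticArchitecture
    n: int
    alpha: float = 5e-8
    trait: str = "quantitative"          # "quantitative" | "binary"
    K: Optional[float] = None            # prevalence, binary traits
    w: Optional[float] = None            # case fraction, binary traits
    selection: Optional[ExtremeSelectionDesign] = None
    replicates: int = 100
    seed: int = 0
    #: True re-runs the whole generative procedure each replicate (fresh causal
    #: set and effects); False replicates GWAS of one fixed trait, the regime
    #: under which the analytic Var(S) is the sampling variance.
    redraw_effects: bool = True
    chunk_snps: int = 2048
    cache_limit_bytes: int = 1 << 30

    def __post_init__(self):
        if self.trait not in ("quantitative", "binary"):
            raise ValueError(f"trait must be quantitative or binary, got {self.trait}")
        if self.trait == "binary" and (self.K is None or self.w is None):
            raise ValueError("binary traits need prevalence K and case fraction w")
        if self.trait == "binary" and self.selection is not None:
            raise ValueError("phenotype selection applies to quantitative traits only")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n < 4:
            raise ValueError("n must be >= 4")

    @property
    def equivalent_n(self) -> float:
        """Random-sample size with matching power (design-adjusted)."""
        if self.trait == "binary":
            return equivalent_n(CaseControlDesign(n=self.n, K=self.K, w=self.w))
        if self.selection is not None:
            # first-order scaling supported by the simulator itself
            return equivalent_n(self.selection, squared=False)
        return float(self.n)



def _draw_effects(arch, rng):
    """Causal set and point-normal effects for one trait realization."""
    m1 = int(round(arch.m1))
    beta = np.zeros(arch.m)
    causal_idx = rng.choice(arch.m, size=m1, replace=False)
    if m1:
        beta[causal_idx] = rng.normal(0.0, arch.causal_sd, size=m1)
    return beta, causal_idx


def _draw_genotypes(rng, f, n):
    """Standardized Binomial(2, f) genotypes, one uniform draw per entry."""
    u = rng.random((n, f.size), dtype=np.float32)
    x = (u < (2.0 * f - f * f)).astype(np.float32)
    x += u < f * f
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0.0] = 1.0  # monomorphic in sample: estimate is 0 anyway
    x -= mu
    x /= sd
    return x


def _chunk_starts(m, chunk):
    return list(range(0, m, chunk))


def _quantitative_replicate(cfg, rng, effects=None):
    arch, n, m = cfg.arch, cfg.n, cfg.arch.m
    beta, causal_idx = effects if effects is not None else _draw_effects(arch, rng)

    starts = _chunk_starts(m, cfg.chunk_snps)
    chunk_seeds = rng.bit_generator.seed_seq.spawn(len(starts))
    cache: list = []
    cache_bytes = 0
    use_cache = 4 * n * m <= cfg.cache_limit_bytes

    y = rng.normal(0.0, np.sqrt(1.0 - arch.h2), size=n).astype(np.float32)
    for ci, c0 in enumerate(starts):
        c = min(cfg.chunk_snps, m - c0)
        crng = np.random.default_rng(chunk_seeds[ci])
        f = crng.uniform(0.01, 0.5, size=c).astype(np.float32)
        x = _draw_genotypes(crng, f, n)
        y += x @ beta[c0 : c0 + c].astype(np.float32)
        if use_cache:
            cache.append(x)
            cache_bytes += x.nbytes

    ys = ((y - y.mean()) / y.std()).astype(np.float32)
    beta_hat = np.empty(m)
    for ci, c0 in enumerate(starts):
        c = min(cfg.chunk_snps, m - c0)
        if use_cache:
            x = cache[ci]
        else:  # regenerate from the same substream: identical genotypes
            crng = np.random.default_rng(chunk_seeds[ci])
            f = crng.uniform(0.01, 0.5, size=c).astype(np.float32)
            x = _draw_genotypes(crng, f, n)
        beta_hat[c0 : c0 + c] = (ys @ x).astype(np.float64) / n
    return beta_hat, causal_idx, beta


def _selected_replicate(cfg, rng, effects=None):
    """Extreme-phenotype sampling: keep tail individuals until quotas fill."""
    arch, sel = cfg.arch, cfg.selection
    m = arch.m
    beta, causal_idx = effects if effects is not None else _draw_effects(arch, rng)
    f = rng.uniform(0.01, 0.5, size=m).astype(np.float32)

    n_lo = int(round(cfg.n * sel.pl))
    n_hi = cfg.n - n_lo
    p_lo = stats.norm.cdf(sel.tl) if n_lo else np.inf
    p_hi = stats.norm.sf(sel.tu) if n_hi else np.inf
    xs, ys = [], []
    got_lo = got_hi = 0
    bf32 = beta.astype(np.float32)
    while got_lo < n_lo or got_hi < n_hi:
        need = max(
            (n_lo - got_lo) / max(p_lo, 1e-9) if got_lo < n_lo else 0.0,
            (n_hi - got_hi) / max(p_hi, 1e-9) if got_hi < n_hi else 0.0,
        )
        block = int(np.clip(1.4 * need + 100, 1000, 2_000_000))
        x = _draw_genotypes(rng, f, block)
        y = x @ bf32 + rng.normal(0.0, np.sqrt(1.0 - arch.h2), size=block).astype(np.float32)
        keep = np.zeros(block, dtype=bool)
        if got_lo < n_lo:
            lo = np.flatnonzero(y < sel.tl)[: n_lo - got_lo]
            keep[lo] = True
            got_lo += lo.size
        if got_hi < n_hi:
            hi = np.flatnonzero(y > sel.tu)[: n_hi - got_hi]
            keep[hi] = True
            got_hi += hi.size
        xs.append(x[keep])
        ys.append(y[keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    # restandardize genotypes within the selected sample; map the in-sample
    # slope back to the population trait scale via sd(Y_S)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0.0] = 1.0
    x = (x - mu) / sd
    ysd = y.std()
    ystd = ((y - y.mean()) / ysd).astype(np.float32)
    slope = (ystd @ x).astype(np.float64) / cfg.n
    # raw slope of y on x is ~ beta * Var(Y_S); divide by the analytic
    # selected variance to recover the population trait-scale effect
    beta_hat = slope * ysd / selected_trait_variance(sel)
    return beta_hat, causal_idx, beta


def _binary_replicate(cfg, rng, effects=None):
    """Case-control sampling under the liability-threshold model."""
    arch, K, w = cfg.arch, cfg.K, cfg.w
    m = arch.m
    beta, causal_idx = effects if effects is not None else _draw_effects(arch, rng)
    f = rng.uniform(0.01, 0.5, size=m).astype(np.float32)

    n_case = int(round(cfg.n * w))
    n_ctrl = cfg.n - n_case
    thresh = stats.norm.isf(K)
    xs, ys = [], []
    got_case = got_ctrl = 0
    bf32 = beta.astype(np.float32)
    while got_case < n_case or got_ctrl < n_ctrl:
        need = max(
            (n_case - got_case) / K if got_case < n_case else 0.0,
            (n_ctrl - got_ctrl) / (1.0 - K) if got_ctrl < n_ctrl else 0.0,
        )
        block = int(np.clip(1.4 * need + 100, 1000, 2_000_000))
        x = _draw_genotypes(rng, f, block)
        liab = x @ bf32 + rng.normal(0.0, np.sqrt(1.0 - arch.h2), size=block).astype(np.float32)
        is_case = liab > thresh
        keep = np.zeros(block, dtype=bool)
        if got_case < n_case:
            ci = np.flatnonzero(is_case)[: n_case - got_case]
            keep[ci] = True
            got_case += ci.size
        if got_ctrl < n_ctrl:
            cj = np.flatnonzero(~is_case)[: n_ctrl - got_ctrl]
            keep[cj] = True
            got_ctrl += cj.size
        xs.append(x[keep])
        ys.append(is_case[keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(np.float64)

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0.0] = 1.0
    x = (x - mu) / sd
    ybar = y.mean()
    # logistic score test: U = sum x (y - ybar), V = ybar (1 - ybar) sum x^2
    U = ((y - ybar) @ x).astype(np.float64)
    V = ybar * (1.0 - ybar) * cfg.n
    gamma_hat = U / V  # one-step standardized log-odds estimate
    chi2 = U * U / V
    beta_hat_liab = liability_multiplier(K) * gamma_hat
    return beta_hat_liab, causal_idx, beta, chi2


@dataclass
class SimResult:
    """Per-replicate counts and variance explained, with aggregates."""

    table: pd.DataFrame
    config: SimConfig

    @property
    def mean_S(self) -> float:
        return float(self.table["S_obs"].mean())

    @property
    def var_S(self) -> float:
        return float(self.table["S_obs"].var(ddof=1)) if len(self.table) > 1 else 0.0

    @property
    def mean_C(self) -> float:
        return float(self.table["C_obs"].mean())

    @property
    def mean_VE(self) -> float:
        return float(self.table["VE_obs"].mean())


def simulate_replicate(cfg: SimConfig, rng: np.random.Generator, effects=None) -> dict:
    """One simulated GWAS; returns S_obs, C_obs and apparent VE.

    ``effects`` optionally fixes the trait realization (beta, causal index
    array) across replicates.
    """
    crit = stats.chi2.isf(cfg.alpha, df=1)
    if cfg.trait == "binary":
        beta_hat, causal_idx, _, chi2 = _binary_replicate(cfg, rng, effects)
        sig = chi2 > crit
    else:
        if cfg.selection is not None:
            beta_hat, causal_idx, _ = _selected_replicate(cfg, rng, effects)
            n_eff = cfg.equivalent_n
        else:
            beta_hat, causal_idx, _ = _quantitative_replicate(cfg, rng, effects)
            n_eff = cfg.n
        sig = n_eff * beta_hat**2 > crit
    causal_mask = np.zeros(cfg.arch.m, dtype=bool)
    causal_mask[causal_idx] = True
    return {
        "S_obs": int(sig.sum()),
        "C_obs": int((sig & causal_mask).sum()),
        "VE_obs": float(np.sum(beta_hat[sig] ** 2)),
    }


def run_simulation(cfg: SimConfig) -> SimResult:
    """Run all replicates with index-derived substreams of ``cfg.seed``."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.replicates + 1)
    effects = None
    if not cfg.redraw_effects:
        effects = _draw_effects(cfg.arch, np.random.default_rng(children[-1]))
    rows = [
        simulate_replicate(cfg, np.random.default_rng(child), effects)
        for child in children[: cfg.replicates]
    ]
    return SimResult(table=pd.DataFrame(rows), config=cfg)


@dataclass(frozen=True)
class ValidationReport:
    """Empirical vs analytic outcome summary for a simulated experiment."""

    empirical_mean_S: float
    empirical_var_S: float
    empirical_mean_C: float
    empirical_mean_VE: float
    analytic: OutcomeSummary
    mean_S_covered: bool
    mean_VE_covered: bool
    seed: int

    def as_dict(self) -> dict:
        return {
            "empirical_mean_S": self.empirical_mean_S,
            "empirical_var_S": self.empirical_var_S,
            "empirical_mean_C": self.empirical_mean_C,
            "empirical_mean_VE": self.empirical_mean_VE,
            "analytic": self.analytic.as_dict(),
            "mean_S_covered": bool(self.mean_S_covered),
            "mean_VE_covered": bool(self.mean_VE_covered),
            "seed": self.seed,
        }


def run_validation(cfg: SimConfig) -> ValidationReport:
    """Simulate and compare against the analytic predictions.

    The analytic side is evaluated at the design's equivalent sample size, so
    the same report validates random, selected, and case-control sampling.
    Coverage flags record whether the analytic 95% probability intervals
    cover the empirical means.
    """
    if cfg.replicates < 30:
        raise ValueError("coverage statements need at least 30 replicates")
    res = run_simulation(cfg)
    summary = gwas_outcomes(cfg.arch, cfg.equivalent_n, cfg.alpha)
    return ValidationReport(
        empirical_mean_S=res.mean_S,
        empirical_var_S=res.var_S,
        empirical_mean_C=res.mean_C,
        empirical_mean_VE=res.mean_VE,
        analytic=summary,
        mean_S_covered=summary.PI_S[0] <= res.mean_S <= summary.PI_S[1],
        mean_VE_covered=summary.PI_VE[0] <= res.mean_VE <= summary.PI_VE[1],
        seed=cfg.seed,
    )
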