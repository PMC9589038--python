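"""Inverse problems: required sample size and consistent polygenicity range.

Both solvers run the forward power machinery inside a monotone root search.
Mean power depends on the sample size and architecture only through the
product ``n sigma2`` (and ``alpha``), so the sample-size search brackets on
``log n`` where ``E(p)`` is strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .architecture import GeneticArchitecture
from .outcomes import expected_significant, probability_interval, variance_significant
from .power import DEFAULT_GRID_POINTS, power_distribution

__all__ = ["SolveResult", "solve_n_for_detection", "solve_pi0_range"]

_LOG_N_LO, _LOG_N_HI = np.log(1.0), np.log(1e14)


@dataclass(frozen=True)
class SolveResult:
    """Outcome of an inverse solve: value, bracket, forward check, iterations."""

    solved_value: float
    bracket: tuple[float, float]
    achieved: float
    iterations: int


def solve_n_for_detection(
    arch: GeneticArchitecture,
    alpha: float = 5e-8,
    fraction: float = 0.5,
    grid_points: int = DEFAULT_GRID_POINTS,
    rel_tol: float = 1e-6,
) -> SolveResult:
    """Sample size at which mean power across causal SNPs reaches ``fraction``.

    Solves ``E(p)(n) = fraction`` by Brent root-finding on ``log n``
    (``E(p)`` is strictly increasing in ``n``).  The detection fraction is
    defined over causal SNPs only — ``E(C) = fraction * m1`` at the solution;
    false positives do not count as detections.

    Raises
    ------
    ValueError
        If ``fraction`` is outside ``(0, 1)`` or unreachable inside the
        search bracket ``n in [1, 1e14]``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    arch.sigma2  # fail fast on degenerate architectures

    evals = 0

    def gap(log_n: float) -> float:
        nonlocal evals
        evals += 1
        return power_distribution(arch, np.exp(log_n), alpha, grid_points).mean - fraction

    lo, hi = _LOG_N_LO, _LOG_N_HI
    if gap(lo) > 0.0 or gap(hi) < 0.0:
        raise ValueError(
            f"detection fraction {fraction} not bracketed for n in "
            f"[{np.exp(lo):.0f}, {np.exp(hi):.0e}]"
        )
    sol = optimize.brentq(gap, lo, hi, xtol=rel_tol / 10.0, rtol=8.9e-16)
    n_star = float(np.exp(sol))
    achieved = power_distribution(arch, n_star, alpha, grid_points).mean
    return SolveResult(
        solved_value=n_star,
        bracket=(float(np.exp(lo)), float(np.exp(hi))),
        achieved=achieved,
        iterations=evals,
    )


def _pi_interval_covers(pi0, m, h2, n, alpha, reported_S, grid_points, level):
    arch = GeneticArchitecture(h2=h2, pi0=pi0, m=m)
    e_s, _ = expected_significant(arch, n, alpha, grid_points)
    var_s = variance_significant(arch, n, alpha, grid_points)
    lo, hi = probability_interval(e_s, var_s, level)
    return lo <= reported_S <= hi


def solve_pi0_range(
    reported_S: float,
    m: int,
    h2: float,
    n: float,
    alpha: float = 5e-8,
    grid_points: int = DEFAULT_GRID_POINTS,
    level: float = 0.95,
    bracket: tuple[float, float] = (1e-4, 1.0 - 1e-4),
    coarse_step: float = 2e-3,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Range of ``pi0`` whose significant-count probability interval covers a
    reported discovery count.

    Scans a coarse ``pi0`` grid inside ``bracket`` for coverage of
    ``reported_S`` by the ``level`` probability interval of ``S``, then
    refines each edge of the covered region by bisection to ``tol``.

    Because ``E(S)`` is unimodal in ``pi0`` (the causal count falls while
    per-SNP power rises), a reported count below the peak can be consistent
    with two disjoint ``pi0`` ranges; in that case the search refuses to
    guess and asks for a narrower ``bracket``.

    Raises
    ------
    ValueError
        If ``reported_S < 1``; if no ``pi0`` in ``bracket`` covers the count
        (the error names the nearest boundary); or if the covered set inside
        ``bracket`` is not a single interval.
    """
    if reported_S < 1:
        raise ValueError(f"reported_S must be >= 1, got {reported_S}")
    b_lo, b_hi = bracket
    if not 0.0 < b_lo < b_hi < 1.0:
        raise ValueError(f"bracket must satisfy 0 < lo < hi < 1, got {bracket}")

    grid = np.arange(b_lo, b_hi + coarse_step / 2, coarse_step)
    grid = np.clip(grid, b_lo, b_hi)
    grid = grid[(grid > 0.0) & (grid < 1.0)]

    lo_arr = np.empty(grid.size)
    hi_arr = np.empty(grid.size)
    es_arr = np.empty(grid.size)
    for i, p in enumerate(grid):
        arch = GeneticArchitecture(h2=h2, pi0=p, m=m)
        e_s, _ = expected_significant(arch, n, alpha, grid_points)
        var_s = variance_significant(arch, n, alpha, grid_points)
        es_arr[i] = e_s
        lo_arr[i], hi_arr[i] = probability_interval(e_s, var_s, level)
    covered = (lo_arr <= reported_S) & (reported_S <= hi_arr)

    # seeds of coverage: covered grid points, plus E(S) = S crossings between
    # grid points (always covered, and able to mark windows narrower than the
    # grid step)
    seeds = [float(p) for p in grid[covered]]
    sign = np.sign(es_arr - reported_S)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):

        def gap(p):
            arch = GeneticArchitecture(h2=h2, pi0=p, m=m)
            e_s, _ = expected_significant(arch, n, alpha, grid_points)
            return e_s - reported_S

        seeds.append(float(optimize.brentq(gap, grid[i], grid[i + 1], xtol=tol / 10)))
    seeds.sort()

    if not seeds:
        mid = GeneticArchitecture(h2=h2, pi0=0.5 * (b_lo + b_hi), m=m)
        e_mid, _ = expected_significant(mid, n, alpha, grid_points)
        side = "pi0 -> 1" if e_mid < reported_S else "pi0 -> 0"
        raise ValueError(
            f"no pi0 in [{b_lo}, {b_hi}] yields a {level:.0%} interval "
            f"covering S = {reported_S}; nearest boundary: {side}"
        )

    def covers(p: float) -> bool:
        return _pi_interval_covers(p, m, h2, n, alpha, reported_S, grid_points, level)

    def refine(inside: float, outside: float) -> float:
        """Bisect the coverage boundary between a covered and uncovered pi0."""
        for _ in range(200):
            if abs(inside - outside) < tol:
                break
            mid = 0.5 * (inside + outside)
            if covers(mid):
                inside = mid
            else:
                outside = mid
        return inside

    # group seeds into contiguous coverage intervals: adjacent seeds belong
    # together when the midpoint between them is covered
    intervals: list[list[float]] = [[seeds[0], seeds[0]]]
    for s in seeds[1:]:
        if s - intervals[-1][1] <= coarse_step * 1.01 or covers(0.5 * (intervals[-1][1] + s)):
            intervals[-1][1] = s
        else:
            intervals.append([s, s])
    if len(intervals) > 1:
        raise ValueError(
            f"S = {reported_S} is consistent with multiple disjoint pi0 "
            f"ranges near {[tuple(iv) for iv in intervals]}; narrow `bracket` "
            "to select one"
        )

    left, right = intervals[0]
    pi_lo = b_lo if covers(b_lo) else refine(left, max(b_lo, left - coarse_step))
    pi_hi = b_hi if covers(b_hi) else refine(right, min(b_hi, right + coarse_step))
    return float(pi_lo), float(pi_hi)
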