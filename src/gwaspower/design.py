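"""Equivalent sample sizes for non-random study designs.

Power for a case-control, extreme-phenotype, or meta-analytic design is read
off the quantitative random-sample machinery by converting the design to the
*equivalent sample size* ``n*``: the random-sample size giving the same
sampling variance for the liability/trait-scale effect estimate.

Case-control at prevalence ``K`` with case fraction ``w``:

    n* = n * w (1 - w) phi^2(Phi^-1(K)) / (K^2 (1 - K)^2)

Extreme-phenotype selection keeps the two tails of the standardized trait
(below ``tl`` and above ``tu``, with sample fraction ``pl`` in the lower
tail); the selected trait variance ``Var(Y_S)`` follows from the law of total
variance over the two truncated-normal tails.  The published conversion is
``n* = n Var(Y_S)^2``; forward simulation of the selected-sample regression
supports the first-order result ``n* = n Var(Y_S)`` instead, so the exponent
is switchable (see ``equivalent_n_extreme`` and the methods note).

Meta-analysis: equivalent sizes add across component studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from scipy import stats

from ._truncmoments import lower_mean_var, upper_mean_var

__all__ = [
    "QuantitativeDesign",
    "CaseControlDesign",
    "ExtremeSelectionDesign",
    "MetaDesign",
    "case_control_rescale_factor",
    "equivalent_n_case_control",
    "selected_trait_variance",
    "equivalent_n_extreme",
    "equivalent_n_meta",
    "equivalent_n",
]


@dataclass(frozen=True)
class QuantitativeDesign:
    """Random population sample of a quantitative trait."""

    n: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class CaseControlDesign:
    """Case-control sample: total size ``n``, prevalence ``K``, case share ``w``."""

    n: float
    K: float
    w: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"K must lie strictly in (0, 1), got {self.K}")
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"w must lie strictly in (0, 1), got {self.w}")


@dataclass(frozen=True)
class ExtremeSelectionDesign:
    """Two-tail selection of a standardized trait.

    ``n`` subjects are recruited: a fraction ``pl`` from the lower tail
    ``Y < tl`` and ``1 - pl`` from the upper tail ``Y > tu``.
    """

    n: float
    tl: float
    tu: float
    pl: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.tl > self.tu:
            raise ValueError(f"tl must be <= tu, got tl={self.tl} > tu={self.tu}")
        if not 0.0 <= self.pl <= 1.0:
            raise ValueError(f"pl must lie in [0, 1], got {self.pl}")


Design = Union[QuantitativeDesign, CaseControlDesign, ExtremeSelectionDesign, "MetaDesign"]


@dataclass(frozen=True)
class MetaDesign:
    """Meta-analysis: a non-empty collection of component designs."""

    components: tuple

    def __post_init__(self):
        if len(self.components) == 0:
            raise ValueError("meta design needs at least one component study")


def case_control_rescale_factor(K: float, w: float) -> float:
    """Sample-size rescale factor ``w(1-w) phi^2(Phi^-1(K)) / (K(1-K))^2``.

    Maximized over ``w`` at a balanced design (``w = 0.5``) for any ``K``.
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"K must lie strictly in (0, 1), got {K}")
    if not 0.0 < w < 1.0:
        raise ValueError(f"w must lie strictly in (0, 1), got {w}")
    z = stats.norm.pdf(stats.norm.ppf(K))
    return w * (1.0 - w) * z * z / (K * (1.0 - K)) ** 2


def equivalent_n_case_control(d: CaseControlDesign) -> float:
    """Equivalent random-sample size of a case-control study."""
    return d.n * case_control_rescale_factor(d.K, d.w)


def selected_trait_variance(d: ExtremeSelectionDesign) -> float:
    """Variance of the trait in the two-tail selected sample.

    Law of total variance over the tail events ``A1 = {Y < tl}`` (sample
    probability ``pl``) and ``A2 = {Y > tu}``:

        Var(Y_S) = sum_i P_i Var(Y|A_i) + sum_i P_i (1 - P_i) E(Y|A_i)^2
                   - 2 P_1 P_2 E(Y|A_1) E(Y|A_2)
    """
    p1, p2 = d.pl, 1.0 - d.pl
    if p1 > 0.0:
        mu1, var1 = lower_mean_var(d.tl)  # raises on an empty tail
    else:
        mu1, var1 = 0.0, 0.0
    if p2 > 0.0:
        mu2, var2 = upper_mean_var(d.tu)
    else:
        mu2, var2 = 0.0, 0.0
    return (
        var1 * p1
        + var2 * p2
        + mu1 * mu1 * (1.0 - p1) * p1
        + mu2 * mu2 * (1.0 - p2) * p2
        - 2.0 * mu1 * mu2 * p1 * p2
    )


def equivalent_n_extreme(d: ExtremeSelectionDesign, *, squared: bool = True) -> float:
    """Equivalent random-sample size of an extreme-phenotype study.

    With ``squared=True`` (default) this is the published conversion
    ``n* = n Var(Y_S)^2``.  ``squared=False`` returns ``n* = n Var(Y_S)``,
    the scaling supported by forward simulation of the selected-sample
    regression (the noncentrality of the selected-sample Wald test is
    ``n beta^2 Var(Y_S)`` to first order in ``beta``).
    """
    v = selected_trait_variance(d)
    return d.n * (v * v if squared else v)


def equivalent_n_meta(md: MetaDesign, **kwargs) -> float:
    """Total equivalent sample size of a meta-analysis (sum of components)."""
    return float(sum(equivalent_n(c, **kwargs) for c in md.components))


def equivalent_n(design: Design, **kwargs) -> float:
    """Equivalent random-sample size of any supported design."""
    if isinstance(design, QuantitativeDesign):
        return float(design.n)
    if isinstance(design, CaseControlDesign):
        return equivalent_n_case_control(design)
    if isinstance(design, ExtremeSelectionDesign):
        return equivalent_n_extreme(design, **kwargs)
    if isinstance(design, MetaDesign):
        return equivalent_n_meta(design, **kwargs)
    raise TypeError(f"unsupported design type: {type(design).__name__}")
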