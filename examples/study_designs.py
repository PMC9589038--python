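"""Equivalent sample sizes for non-random study designs.

Every design maps to the random-quantitative-sample size n* giving the same
sampling variance for the liability/trait-scale effect estimate; the power
machinery is then run at n*.
"""

from gwaspower import (
    CaseControlDesign,
    ExtremeSelectionDesign,
    MetaDesign,
    QuantitativeDesign,
    equivalent_n,
    selected_trait_variance,
)

cc = CaseControlDesign(n=100_000, K=0.01, w=0.5)
print(f"balanced case-control, 1% prevalence, n = 100,000:")
print(f"  equivalent n* = {equivalent_n(cc):,.0f}")

ep = ExtremeSelectionDesign(n=10_000, tl=-1.645, tu=1.645, pl=0.5)
v = selected_trait_variance(ep)
print(f"two-tail 5% selection, n = 10,000 selected:")
print(f"  Var(Y_S) = {v:.3f}")
print(f"  published conversion  n* = n Var^2 = {equivalent_n(ep):,.0f}")
print(f"  first-order scaling   n* = n Var   = {equivalent_n(ep, squared=False):,.0f}")

meta = MetaDesign(components=(QuantitativeDesign(n=50_000), cc))
print(f"meta-analysis (quantitative 50,000 + the case-control study):")
print(f"  total equivalent n* = {equivalent_n(meta):,.0f}")

# Balanced case-control sampling of a rare disease is an extreme-liability
# design in disguise: oversampling cases to 50% makes each subject ~1.8x as
# informative as a random-sample subject here.  For the selected design,
# forward simulation supports the first-order n Var(Y_S) scaling (see
# docs/methods.md).
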