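"""Inverse solvers: required n, and the pi0 range consistent with a count.

First: sample sizes needed to detect 5%, 50% and 95% of causal SNPs for a
trait with h2 = 0.3 and 600 causal SNPs.  Then: the polygenicity range
consistent with an observed discovery count.
"""

from gwaspower import GeneticArchitecture, expected_significant, solve_n_for_detection, solve_pi0_range

arch = GeneticArchitecture(h2=0.3, pi0=0.99, m=60_000)
for fraction in (0.05, 0.5, 0.95):
    res = solve_n_for_detection(arch, alpha=5e-8, fraction=fraction)
    print(f"detect {fraction:4.0%} of causal SNPs: n = {res.solved_value:,.0f}")

# note the disproportionate growth: going from 50% to 95% detection costs
# two orders of magnitude more samples than going from 5% to 50%

m, h2, n, alpha = 60_000, 0.3, 500_000, 5e-8
observed = expected_significant(GeneticArchitecture(h2=h2, pi0=0.975, m=m), n, alpha)[0]
lo, hi = solve_pi0_range(round(observed), m, h2, n, alpha, bracket=(0.9, 0.999))
print(f"\nobserved {observed:.0f} significant SNPs at n = {n:,}:")
print(f"consistent pi0 range: [{lo:.4f}, {hi:.4f}] (generating value 0.975)")
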