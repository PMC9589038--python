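"""Distribution of statistical power across causal SNPs.

A trait with SNP heritability 0.4 spread over 600 causal SNPs (m = 60,000
nearly independent SNPs, 99% null) is studied at n = 100,000 with
genome-wide significance 5e-8.
"""

from gwaspower import GeneticArchitecture, power_cdf_curve, power_distribution

arch = GeneticArchitecture(h2=0.4, pi0=0.99, m=60_000)
pd = power_distribution(arch, n=1e5, alpha=5e-8)

print(f"mean power across causal SNPs  E(p)   = {pd.mean:.3f}")
print(f"variance of power              Var(p) = {pd.variance:.3f}")

levels, prop = power_cdf_curve(pd, levels=[0.1, 0.5, 0.9])
for lv, pr in zip(levels, prop):
    print(f"proportion of causal SNPs with power >= {lv:.1f}: {pr:.2f}")

# The large Var(p) relative to E(p)(1-E(p)) reflects the bimodal power
# density: most causal SNPs are either nearly undetectable or nearly
# certain to reach significance, with few in between.
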