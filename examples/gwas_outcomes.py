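"""Predicted GWAS outcomes for adult height.

Height: SNP heritability 0.483, 34% of 60,000 independent SNPs causal,
meta-analysis of n = 693,529, significance 1e-8.  Prints the expected
number of independent significant SNPs with its 95% probability interval,
and the phenotypic variance they explain before and after winner's-curse
correction.
"""

from gwaspower import GeneticArchitecture, gwas_outcomes

arch = GeneticArchitecture(h2=0.483, pi0=0.66, m=60_000)
s = gwas_outcomes(arch, n=693_529, alpha=1e-8)

print(f"expected significant SNPs  E(S) = {s.E_S:.2f}")
print(f"95% probability interval        = [{s.PI_S[0]:.2f}, {s.PI_S[1]:.2f}]")
print(f"expected detected causal   E(C) = {s.E_C:.2f}")
print(f"apparent variance explained     = {100 * s.apparent_VE:.2f}%")
print(f"corrected variance explained    = {100 * s.corrected_VE:.2f}%")

# The apparent figure sums squared estimates over significant SNPs and is
# inflated by winner's curse; the corrected figure replaces each squared
# estimate with its posterior second moment under the point-normal prior.
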