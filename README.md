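# gwaspower

Power, discovery, and polygenic-score predictions for genome-wide
association studies (GWAS) under a point-normal architecture of standardized
SNP effects.

Classical GWAS power calculators answer "what is the chance of detecting a
SNP with effect β?".  For a polygenic trait the more useful questions are
about the study as a whole: *how many* independent genome-wide significant
SNPs should a study of a given size expect, how much phenotypic variance
will they (appear to) explain, and how accurate will a polygenic score built
from the results be?  `gwaspower` answers these for study designers,
consortium analysts, and methodologists who want to sanity-check reported
GWAS yields against a trait's genetic architecture.

## Model

A genome is summarized by `m` nearly independent SNPs (after LD
pruning/clumping; default `m = 60,000`).  Standardized (per-sd) effects
follow a point-normal law

```
β ~ π₀·δ₀ + (1 − π₀)·N(0, σ²),   σ² = h² / (m(1 − π₀)),
```

so a fraction `π₀` of SNPs are null and the rest jointly explain the SNP
heritability `h²`.  With sampling variance `1/n`, the two-sided Wald test of
one SNP is a 1-df chi-square with noncentrality `nβ²`; integrating its power
over the causal effect distribution (grid discretization over ±10 causal sd)
gives the distribution of power across causal SNPs with mean `E(p)` and
variance `Var(p)`.  From these:

- **Discoveries** — `E(S) = m[π₀α + (1 − π₀)E(p)]` significant SNPs, with a
  Poisson-binomial variance and 95% probability interval; `E(C)` counts true
  causal detections.
- **Variance explained** — apparent (`Σ β̂²` over significant SNPs, inflated
  by winner's curse) and corrected, which replaces each `β̂²` by the
  posterior second moment `E(β²|β̂)` under the point-normal prior.
- **Designs** — case-control (prevalence `K`, case fraction `w`),
  extreme-phenotype selection, and meta-analyses map to an equivalent
  random-sample size `n*` and reuse the same machinery; binary traits are
  handled on the liability scale.
- **Polygenic scores** — efficacy `r²(G, G̃)` for raw marginal weights
  (`1/(1 + m/nh²)`), optimal p-value thresholding, and posterior-mean
  shrinkage, plus conversion of liability `r²` to ROC AUC.
- **Inverse solvers** — the `n` needed to detect a target fraction of causal
  SNPs, and the `π₀` range consistent with a reported discovery count.
- **Simulator** — forward simulation of independent-SNP GWAS (quantitative,
  case-control, extreme-selection sampling) that validates every formula.

## Worked example

Adult height: `h² = 0.483`, 34% of 60,000 independent SNPs causal, a
meta-analysis of `n = 693,529`, significance `α = 1e-8`:

```python
from gwaspower import GeneticArchitecture, gwas_outcomes

arch = GeneticArchitecture(h2=0.483, pi0=0.66, m=60_000)
s = gwas_outcomes(arch, n=693_529, alpha=1e-8)
```

Running `python examples/gwas_outcomes.py` prints:

```
expected significant SNPs  E(S) = 3462.72
95% probability interval        = [3405.46, 3519.98]
expected detected causal   E(C) = 3462.72
apparent variance explained     = 30.57%
corrected variance explained    = 27.63%
```

Read: a study this size should report ≈3.5k independent hits; they will
*appear* to explain ~31% of phenotypic variance, but after winner's-curse
shrinkage the honest figure is ~28% — still short of the full 48.3%
heritability, because thousands of small-effect causal SNPs remain below
threshold.  The same architecture says detecting 95% of causal SNPs would
need tens of millions of samples (`examples/required_sample_size.py`).

The CLI exposes the same computations:

```sh
gwaspower outcomes --h2 0.483 --pi0 0.66 --n 693529 --alpha 1e-8
gwaspower pgs --h2 0.5 --pi0 0.99 --n 1e5
gwaspower design --design cc --n 100000 --k 0.01 --w 0.5
```

Each `examples/*.py` script is a short narrative for one capability:
power distributions, study outcomes, design equivalences, polygenic scores,
inverse solvers, and simulator validation.

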