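# genopred

Genomic prediction and QTL mapping on simulated pedigree populations:
Bayesian whole-genome regression (BayesB, BayesCπ, and a joint
additive+dominance BayesCπ), GBLUP with additive/dominance/epistatic genomic
relationship matrices estimated by REML, marker-effect backsolving, and QTL
localization from 10-SNP window variances — all driven by a gene-dropping
population simulator with known ground truth, so every stage of the analysis
is verifiable end to end.

The package is aimed at quantitative geneticists who want a transparent,
tested reference implementation of the classic marker-based prediction
toolchain, and at anyone studying how these methods behave when the genetic
architecture contains non-additive components (imprinting, epistasis, linked
QTL in coupling or repulsion phase).

## Models

Phenotypes follow

```
y_i = μ + Σ_j (X_ij a_j + W_ij d_j) + e_i
```

where `X_ij ∈ {0,1,2}` is the allele dosage, `W_ij` indicates a heterozygote,
`a_j` is the additive effect (half the homozygote difference) and `d_j` the
dominance deviation.

**BayesB / BayesCπ** place spike-and-slab priors on SNP effects:
with probability π a SNP has no effect, otherwise a normal effect. BayesCπ
uses one common effect variance and samples π from its Beta full
conditional; BayesB fixes π (default 0.995) and gives each included SNP its
own scaled-inverse-χ² distributed variance, updated jointly with the
inclusion indicator by a Metropolis–Hastings step on the marginal
likelihood. The dominance variant runs interleaved single-site updates for
`a_j | d` and `d_j | a` with class-specific (π_a, π_d) and variances.

**GBLUP** fits animal genetic effects directly with
`G = M M′ / (2 Σ p_i(1−p_i))` (VanRaden method 1, `M` the 2p-centered dosage
matrix). Model G2 adds a dominance relationship from the 2pq-centered
heterozygote indicator; G3 adds an additive×additive epistatic relationship
(Hadamard square `G∘G` by default). Variance components come from AI-REML
with an EM warm start; allele substitution effects are backsolved as
`α = Z_c′ G⁻¹ â / (2 Σ p_i(1−p_i))`, which satisfies `Z_c α = â` exactly.

**QTL mapping** standardizes the variance of each sliding 10-SNP window's
GEBV contribution by the total GEBV variance; windows in the top `(1−π̂)`
quantile (BayesCπ), above a multiple of the median background (BayesB), or
SNPs with `|α|` above mean+4·SD (GBLUP) are flagged, merged, and reported at
the SNP with the largest per-SNP variance share.

**The simulator** builds a two-generation full-sib design (default 20 sires
× 10 dams/sire × 15 progeny, 3,220 individuals), drops founder haplotypes
(linkage equilibrium, MAF uniform on [0.1, 0.5]) through Haldane meioses
over 5 × 1-Morgan chromosomes with 1,998 evenly spaced SNPs, and places
8 QTL: one major additive, two linked additive pairs (coupling and
repulsion), one imprinted, one epistatic pair. Effects are rescaled so the
additive-TBV variance among progeny equals σ²_a = 26.35 exactly; residuals
are N(0, 61.49), giving h² = 0.3. Ten progeny per family are phenotyped;
the rest form the validation set.

## Worked example

```python
from genopred import pipeline

report = pipeline.run_all(pipeline.scaled_study_config(seed=1))
print(report.variance_table.to_string(index=False,
                                      float_format=lambda v: f"{v:.2f}"))
for m, a in report.accuracies.items():
    print(f"accuracy[{m}] = {a:.3f}")
```

which prints (desk-scale design: 1,000 phenotyped, 500 validation progeny,
1,000 SNPs, 12,000-iteration chains; a couple of minutes on one CPU):

```
      method  additive epistasis  dominance  residual  total   h2
      bayesB     29.06      None        NaN     59.57  88.63 0.33
    bayesCpi     30.12      None        NaN     58.44  88.55 0.34
bayesCpi-dom     28.78      None       1.20     58.36  88.34 0.34
          G1     28.37      None        NaN     59.06  87.43 0.32
          G2     21.48      None       8.15     56.27  85.90 0.25

accuracy[bayesB] = 0.984
accuracy[bayesCpi] = 0.982
accuracy[bayesCpi-dom] = 0.980
accuracy[G1] = 0.708
accuracy[G2] = 0.693
```

Reading the output: all methods recover the simulated heritability of 0.3 to
within sampling error of this single population realization; the dominance
models correctly find little dominance variance (none was simulated — the
G2 REML estimate is boundary noise, see `docs/methods.md`); and the
Bayesian methods predict validation breeding values far more accurately
than GBLUP here because the trait is controlled by 8 QTL, an architecture
the sparse mixture prior matches and the infinitesimal GBLUP prior does
not. GEBV from BayesB and BayesCπ correlate at 0.997. QTL calls land in
`report.calls`; all three methods localize the major QTL on chromosome 1.

A command-line interface mirrors the library
(`genopred simulate | bayes | gblup | map | run-all`), e.g.

```
genopred simulate --seed 3 --out-dir data/
genopred bayes --data-dir data/ --model bayesCpi --out-dir out/
genopred gblup --data-dir data/ --model G1 --out-dir out/
```

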