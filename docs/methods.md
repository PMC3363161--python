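# Methods

## The simulated population

The generator emulates a two-generation full-sib mating design: `n_sires`
founder sires, `n_dams_per_sire` founder dams nested within each sire, and
`n_progeny_per_dam` full-sib progeny per dam (defaults 20 × 10 × 15 → 3,220
individuals). Founder haplotypes are drawn in linkage equilibrium with
per-SNP allele frequencies uniform on [0.1, 0.5]; nothing else is assumed
about founder LD, so all linkage disequilibrium among progeny arises from
cosegregation in the single meiosis that separates them from the founders.
Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson(length in Morgans), crossover positions are uniform, the starting
strand is fair, and there is no interference. This model is deliberately
minimal — it is standard, and its end-to-end recombination fraction has the
closed form r = (1 − e^{−2L})/2 that the test suite checks empirically.

The marker panel is evenly spaced genome-wide (default 1,998 SNPs over
5 × 1 Morgan). QTL are map SNPs and remain on the analysis panel by default
(a custom architecture can place them anywhere), which makes detection
targets unambiguous.

### QTL architecture

The default architecture has 8 QTL, one per gene-action class the study
design exercises:

| chromosome | action | placement | effect (pre-calibration) |
|---|---|---|---|
| 1 | additive, major | mid-chromosome | 4 × minor |
| 2 | additive pair, coupling | 0.1 M apart around the middle | +1, +1 |
| 3 | additive pair, repulsion | 0.1 M apart | +1, −1 |
| 4 | imprinted (paternal) | mid-chromosome | 1 |
| 5 | additive×additive pair | 0.25 L and 0.75 L | interaction 1 |

Coupling vs repulsion is encoded by the signs of the two linked effects
(equal vs opposite); with founders in linkage equilibrium the parental
phase of any particular founder is random, so the sign convention is the
population-level meaning of the terms. Imprinting is modeled as expression
of the paternally inherited allele only (configurable): the locus
contributes `effect × (2u − 1)` with `u` the paternal allele. The
interaction term is `effect × (x_A − 1)(x_B − 1)` on centered dosages,
counted once per pair. The 4:1 major:minor ratio, the 0.1 M pair spacing
and the QTL placements are package defaults (reported in output headers);
only the counts and action classes of the architecture are fixed by the
study design.

`tbv_additive` is the dosage-linear (breeding-value) part of the genetic
value: additive QTL contribute in full; the imprinted locus contributes its
average effect `effect × (x − 2p)` (for a paternally expressed locus the
allele substitution effect equals the expression effect); each epistatic
member contributes `effect × (2p_partner − 1) × (x − 2p)`, the average
effect when the pair's genotypes are treated as independent at the
population frequencies. `tbv_total` adds the full imprinted and interaction
terms.

### Calibration and phenotypes

All QTL effects are rescaled by one common factor so that the empirical
variance of `tbv_additive` among progeny equals σ²_a (default 26.35)
*exactly* — every contribution is linear in the effects, so the rescale is
exact, and the tests assert it to 1e-9. Non-additive variance is whatever
the architecture implies (roughly 2–3 trait-variance units by default:
the orthogonal part of the imprinted locus and of the interaction term) and
is not separately calibrated. Residuals are i.i.d. N(0, σ²_e), default
61.49, so narrow-sense h² = 0.3 among progeny by construction. Ten progeny
per family (default) receive phenotypes; unphenotyped progeny are the
validation set.

What the generator does *not* emulate: ancestral LD beyond one generation
of cosegregation, selection, overlapping generations, sex chromosomes,
genotyping error or missingness. Passing tests therefore demonstrate
correctness of the estimators under a clean, strongly family-structured
design — not robustness to the messier LD patterns of real livestock data.

## Bayesian whole-genome regression

All samplers are single-site Gibbs on the model
`y = 1μ + X_c a + W_c d + e`, with dosage columns centered by 2p̂ and the
heterozygote indicator by its column mean (the intercept absorbs the
shifts; centering improves mixing and is variance-neutral). The residual
vector is maintained incrementally, giving O(nk) cost per iteration; the
inner loops are numba-compiled with a transposed (SNP-major) design matrix
for contiguous access.

Priors: effects are spike-and-slab; the slab variance carries a
scaled-inverse-χ² prior with ν = 4.2 (effects) and ν = 4 (residual).
Prior scales default to a weakly informative derivation from the data:
half the phenotypic variance assumed genetic, split over the expected
number of included SNPs, `S = genvar × (ν−2)/ν / ((1−π) Σ 2p_jq_j)`; the
residual scale analogously from the other half. π is fixed for BayesB
(default 0.995) and sampled for BayesCπ from
`π | δ ~ Beta(k − m + 1, m + 1)` (uniform prior; m = included SNPs). The
BayesB (indicator, locus-variance) pair is proposed from the prior and
accepted on the ratio of marginal likelihoods with the effect integrated
out — the cited mixture model does not pin down a unique sampler, and this
partially collapsed MH-within-Gibbs is simple and exactly testable against
enumeration on small instances. Chain defaults are 41,000 iterations,
1,000 burn-in, thinning 10; the desk-scale preset shortens this to
12,000/2,000/10, at which length the 1,000-phenotype runs are well mixed
(the acceptance checks pass with comfortable margins).

Reported genetic variance is the variance of the genomic values
(`Var_i(X_c a)`, and `Var_i(W_c d)` for the dominance class) across the
phenotyped individuals per retained sample, matching the "variance of GEBV
in the population" convention used for window variances — not the
marker-based `Σ 2pq E[a²]`. Zero-variance SNP columns are excluded with a
warning and their effects fixed at 0. Excluded SNPs carry effects exactly
0.0 in every retained sample, so posterior inclusion probabilities are
recovered as the fraction of nonzero retained effects.

GEBV are the linear combination of substitution effects. For the dominance
model the substitution effect is formed as `α_j = â_j + d̂_j(1 − 2p_j)` —
a declared convention (the classical substitution effect under
Hardy–Weinberg), since "linear combination of substitution effects" does
not by itself determine how â and d̂ combine.

## GBLUP, REML, backsolving

`G` is VanRaden method 1 with observed allele frequencies taken from the
full genotyped set; monomorphic SNPs contribute nothing. A diagonal ridge
of 1e-6 is added by default (logged) since `G` built with observed-frequency
centering is always singular (its rows sum to zero). The dominance
relationship uses heterozygote coding centered by 2pq and denominator
`Σ 2p_iq_i(1 − 2p_iq_i)`; the epistatic relationship defaults to the
Hadamard square `G∘G`, the standard additive×additive covariance, with the
literal matrix square available by flag.

REML maximizes the restricted likelihood of `V = Σ_c σ²_c K_c + σ²_e I`
over the phenotyped subset: 5 EM fixed-point iterations
(θ ← θ · y′PKPy / tr(PK)) to warm-start, then average-information updates
with step-halving; components driven negative are clamped to a floor of
1e-8 × Var(y) and flagged as boundary estimates, re-entering only while
their score points inward. Convergence is |Δ log-likelihood| < 1e-8
(default). The estimates were cross-checked against direct Nelder–Mead
maximization of the same restricted likelihood and against two-stage grid
search on small instances.

BLUP solutions use the equivalent variance form
`û_c = σ²_c K_c[:, obs] V⁻¹ (y − 1μ̂)` with the GLS intercept — identical
to Henderson's mixed-model equations when K is invertible (asserted in the
tests), while also handling singular K and yielding predictions for
unphenotyped individuals directly.

Backsolving uses `α = Z_c′ G⁻¹ â / (2 Σ p_i(1−p_i))`, the scaling that
makes `Z_c α = â` an exact identity (the common literature form with a
leading σ²_α instead of 1/denominator differs by the constant σ²_a;
relative magnitudes, hence QTL calls, are unaffected, and both scalings are
logged). `G⁻¹ â` is computed by least squares so a ridge-free singular `G`
is handled; the identity holds whenever `â` lies in the row space of `Z_c`,
which BLUP solutions do by construction.

## QTL calling

Window variances use sliding (per-SNP) 10-SNP windows within chromosomes;
the proportion is `Var_i(Σ_{j∈w} X_c,ij â_j) / Var_i(GEBV_i)`, computed
from posterior-mean effects by default, or as the posterior mean of the
per-sample ratio when retained samples are supplied. Thresholds:

* BayesCπ: windows in the top (1 − π̂) quantile of the proportion
  distribution;
* BayesB: windows above 10 × the median background proportion — a declared
  formalization of picking windows that stand clearly above background,
  which in the original workflow was a visual judgement;
* GBLUP: SNPs with |α| above mean(|α|) + 4·SD(|α|) — likewise a declared
  formalization of visually significant effects.

Overlapping/adjacent significant windows merge per chromosome; each merged
span is reported at the member SNP with the largest per-SNP variance share
(lowest index on ties, for determinism). Evaluation credits each true QTL
at most once, to the closest call within 0.05 Morgans (default).

`count_raw_signals` uses a *lower* matched threshold (mean + 2·SD of
|effect|, same rule for every method) than calling: calling reports
isolated peaks, while the raw-signal count characterizes how noisy a
method's effect profile is; at 4 SD the count is confounded by each
method's own SD. With the matched 2-SD rule the GBLUP profile shows several
times more raw signals than the sparse Bayesian profiles, the expected
noise ordering.

## Desk-scale study preset

`pipeline.scaled_study_config` halves the number of dams per sire
(→ 1,500 progeny; 1,000 phenotyped, 500 validation) and the panel
(1,000 SNPs), and shortens chains to 12,000 iterations. These sizes retain
the design's family structure and per-chromosome marker density while
keeping a full five-method run to a few minutes; parameter recovery at this
scale is tight (heritability to ±0.05 of the simulated 0.3 across seeds).

## Known limitations and numerical notes

* The G2 dominance variance estimate on a single realization is boundary
  noise: with no dominance simulated its REML distribution puts roughly
  half its mass exactly at zero and the rest in a half-normal whose scale,
  on this strongly full-sib design, is a non-trivial fraction of σ²_a
  (additive and dominance full-sib covariances, 0.5 and 0.25, are heavily
  confounded). The acceptance check therefore tests the *median* over
  replicate populations rather than one draw; single-realization estimates
  a few units above zero are expected and were verified to be exact
  restricted-likelihood optima, not convergence artifacts.
* The Bayesian additive model absorbs the non-dosage part of the imprinted
  and epistatic variance (≈2 trait units) into the residual, so residual
  estimates sit slightly above 61.49 on average — the same direction of
  bias the dominance-free models show on any architecture with non-additive
  action.
* Imprinted QTL are only partially detectable by dosage-based models: half
  the imprinted locus variance is invisible to any function of dosage.
* REML on n phenotyped individuals is O(n³) per iteration; the full
  3,220-individual design is practical (~seconds per iteration) but the
  desk-scale preset is used for routine runs.
* All randomness flows from explicit seeds (numpy `SeedSequence` for the
  simulator; one numba RNG per chain, with sequential sub-seeds per method
  in the pipeline); reruns are byte-identical, which the tests assert.
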