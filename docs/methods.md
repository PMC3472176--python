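# Methods

## The model family

`gvarpart` partitions the additive genetic variance of a quantitative trait
into a part traceable by a SNP panel and a residual polygenic part traceable
only through pedigree. All analyses are weighted single-trait mixed models
with a general mean as the only fixed effect:

1. `y = 1μ + Z a + e` — the classical animal model; `var(a) = A σ_a²`, with
   **A** the pedigree numerator relationship matrix (expected identity by
   descent, tabular method).
2. `y = 1μ + Z g + e` — the genomic model; `var(g) = G σ_g²`, with
   **G = (M − P)(M − P)′ / 2Σ p_j(1 − p_j)** the genomic relationship matrix
   built from centered allele counts (realized identity by state). The
   denominator puts G on the scale of A.
3. `y = 1μ + Z g + Z a + e` — both terms; σ_g²/(σ_g² + σ_a²) is the
   *genomic share* of total additive variance.
4. `y = 1μ + Z g_c + Z g_o + Z a + e` — one chromosome's markers give
   `G_c`, all remaining markers give `G_o`; run once per chromosome, the
   collected σ_c² partition genomic variance along the genome.

The residual is heterogeneous: `var(e) = D σ_e²` with `D_ii = 1/w_i` where
`w_i` is an effective-record weight. The phenotypes the package is designed
for are deregressed progeny proofs, which behave like progeny-group means:
a record backed by many effective daughters carries little residual
variance. We interpret "weights proportional to the effective number of
records" through the inverse, because residual variance must *shrink* with
information; the convention is config-exposed. The variance ratio reported
with each fit is `VR = Σ σ_r² / (Σ σ_r² + d̄ σ_e²)` with `d̄` the mean
diagonal of D — the heritability of the weighted record, not of the
underlying trait.

## REML engine

Estimation maximizes the restricted likelihood by average-information (AI)
updates with step halving and an EM fallback. Numerical choices:

* The likelihood is evaluated on error contrasts: all covariance structures
  are projected once onto the orthogonal complement of the mean column.
  Besides removing the fixed-effect determinant from every iteration, this
  is what makes the boundary region well conditioned — a sample-centered G
  has the ones vector as an exact null direction, so V itself becomes
  near-singular whenever σ_e² approaches its floor, while the contrast
  projection of V stays positive definite.
* Variances are constrained to ≥ 10⁻⁸·var(y). A component sitting on that
  floor whose score is negative is pinned there for the iteration
  (active-set treatment) instead of being allowed to crawl toward zero
  through ever-smaller EM steps.
* AI steps are accepted only if the restricted log-likelihood does not
  decrease (up to 10⁻¹⁰); otherwise the step is halved up to 12 times and
  finally replaced by an EM step, which cannot decrease the likelihood. The
  accepted trace is therefore non-decreasing.
* Convergence requires a relative log-likelihood change < 10⁻⁸ *and* a
  maximum relative parameter change < 10⁻⁶; the default iteration cap is
  200. Non-convergence returns the best iterate flagged
  `converged=False` rather than raising.
* Starting values split var(y) equally across all components.
* Standard errors come from the inverse AI matrix at the optimum. For a
  boundary component the SE is reported but has the usual one-sided caveat.
* Dense Cholesky algebra throughout; the intended scale is up to a few
  thousand records on one CPU. No sparse mixed-model-equation machinery is
  included, deliberately: the phenotyped subset is what REML needs, and A
  restricted to that subset is obtained by recursing over its ancestor
  closure.

σ_e² deserves a caveat: with one record per individual, the diagonal of G
(or A) competes with the residual, and only the spread of the weights
identifies σ_e² separately. With highly informative records (large `w`) the
residual is often estimated at its boundary with a large SE. This mirrors
the real situation with high-reliability bull proofs and is why VR, not
σ_e² itself, is the quantity reported.

## Marker QC

Markers are dropped when `min(p, 1−p) < 0.01` (strict inequality, so a
marker exactly at the threshold is kept), and when their genotype vector is
an *exact* affine function of an earlier retained marker in genome order —
this is an exact-collinearity filter (duplicates, complement-coded copies),
implemented by canonical hashing, not a correlation threshold. Only
pairwise affine dependence is removed; a marker that is a combination of
two or more others is kept. The QC report reconciles
`input = removed_MAF + removed_dependence + retained` and the pipeline logs
the accounting for every run.

Allele frequencies default to the observed sample frequencies of the
analyzed individuals (an external frequency vector can be supplied).
Missing genotypes are mean-imputed to `2p_j` before centering, so they
contribute nothing to the cross-product.

## Chromosome partition

`G_c` and `G_o` are each normalized by their own heterozygosity sum by
default; a flag switches both to the shared whole-genome denominator, which
changes only the scale of σ_c². Chromosome length is defined as the Mb span
between the first and last marker (1-based bp). Cross-chromosome covariance
of genomic effects is not modeled — the model-4 terms are independent — so
the sum of per-chromosome variances may fall short of the whole-genome
genomic variance; the shortfall is reported, not corrected. The model-3
σ_g² on the same data is the reference for that ratio.

## Panel-accuracy (beta) procedure

To ask how much additive variance a panel of N markers can explain, 2N
markers are sampled genome-wide and split at random; one half plays the
causal loci and yields `G_t`, the other yields `G_m`, each centered with
its own within-panel frequencies. After subtracting 1 from both diagonals
(removing their dominance), ordinary least squares of `G_t` elements on
`G_m` elements over all pairs j ≤ k gives an intercept α and slope β — the
expected proportion of additive variance a panel of that size explains.
Repeating over a grid of N traces the empirical β(N) curve; the default is
10 replicates per N with the SD reported, all seeds logged. A flag restricts
the regression to off-diagonal pairs as a sensitivity variant.
`G* = β(G_m − I) + I` rescales the off-diagonal structure so that a
genomic variance estimated with G* is inflated by ≈ 1/β relative to G_m —
exactly so when the identity component of G* is exchangeable with an iid
residual (homogeneous weights).

## The synthetic population

No suitable public dataset pairs dense bull genotypes with deregressed
proofs and deep pedigrees, so the package ships a generator that creates
the statistical structure the analysis assumes.

* **Pedigree**: founders alternate male/female; each later generation
  draws a fixed number of sires from the previous generation's males, each
  with a fixed number of offspring. Dams are unknown by default (a
  sire-heavy structure typical of dairy-bull pedigrees; unknown parents are
  treated as unrelated base-population founders) or can be drawn from the
  founder females.
* **Genotypes**: founder haplotypes are Bernoulli(p_j) under Hardy-Weinberg
  with p_j drawn from MAF ~ Uniform(0.05, 0.5) and random orientation;
  offspring receive one gamete per parent. Recombination uses the Haldane
  map — the source haplotype switches between adjacent markers with
  probability (1 − e^(−2d))/2 — which is the exact marker-level law of the
  Poisson crossover process with mean L per chromosome of length L Morgans.
  An unknown parent contributes a fresh base-population gamete. Defaults:
  29 autosomes of 1 Morgan, 180 markers each (both overridable per
  chromosome, e.g. to give longer chromosomes more markers).
* **QTL architecture**: 2000 additive QTL by default — a dense polygenic
  architecture, the standard assumption for production and fitness traits —
  with 10% placed on *hidden* loci that are gene-dropped through the same
  pedigree but excluded from the panel. Hidden loci are what create a
  genuine residual polygenic component: pedigree relationships track them,
  markers cannot. Effects are i.i.d. normal, each component centered on its
  founder expectation and rescaled so its realized variance among the
  final-generation cohort equals its target exactly (defaults
  σ_g² = 100, σ_polygenic² = 25, i.e. a genomic share of 0.8).
* **Phenotypes**: `y = μ + TBV + e`, `e ~ N(0, σ_e²/w)`, weights
  Uniform(20, 200) emulating large but heterogeneous progeny groups;
  σ_e² = 25. By default only the final-generation cohort is phenotyped —
  the analog of the genotyped, progeny-tested bull cohort, and the cohort
  in which the variance targets are defined; earlier generations supply
  pedigree depth. The variance targets are defined among that cohort
  deliberately: with sample-frequency centering the mean of G over the
  phenotyped set is zero, so the rescaled realized variance and the REML
  estimand coincide up to the mean diagonal of G (≈ 1).

Everything is reproducible bit-for-bit from the config seed; each stage
derives its generator from `(seed, stage)`.

What the generator does **not** emulate: linkage disequilibrium beyond what
the simulated pedigree itself creates (no long coalescent history, so
founder haplotypes are in linkage equilibrium), selection within the
breeding scheme, genotyping error, X-linked loci, or the national
evaluation machinery that produces real deregressed proofs. Passing tests
therefore demonstrate that the estimators recover the variance structure
they are defined for — not that any particular real population has that
structure. In particular, β(N) in the simulated population reflects
family-driven LD only, which is one of the three sources (causal markers,
population-level LD, family LD) operating in real cattle data.

## Problem sizes in the shipped experiments

The recovery experiments run at 1000 phenotyped individuals and ~5000
markers (20 replicate seeds), the chromosome-scan experiments at 500
phenotyped individuals on a 6-chromosome genome, and the β-curve at 300
individuals and 9000 markers with panels up to N = 4000 — sizes chosen so
the full suite runs comfortably on a single CPU while keeping the
estimators' standard errors small relative to the effects being checked.

## Known limitations

* Single-trait REML only; no multi-trait analysis, no Gibbs sampling, and
  no back-solving of individual breeding values.
* A-inverse (Henderson's rules), genetic groups and metafounders are out of
  scope; A is built densely for the ancestor closure of the analyzed set.
* The affine-dependence filter is pairwise and exact, as discussed above.
* The β procedure is empirical by design; no analytic prediction of β from
  effective population size or LD theory is attempted.
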