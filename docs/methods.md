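# Methods

## Model

`nestpath` implements a two-stage pathway association test for
sibship-structured (family) and unrelated samples.

### Stage 1: nested random-effects genotype model

For subject j in sibship i, the additive minor-allele count at SNP s of
gene g is

    w_ijgs | b_i, b_ij, b_ijg  ~  Binomial(2, π_ijgs)
    logit(π_ijgs) = α_s + x'_ij δ + b_i + b_ij + b_ijg

with independent normal random effects b_i ~ N(0, σ²_sib),
b_ij ~ N(0, σ²_subj), b_ijg ~ N(0, σ²_gene). The Binomial(2, ·) likelihood
assumes Hardy–Weinberg equilibrium. The nesting encodes two kinds of
genotype correlation: b_ij induces correlation among all SNPs of a
subject's pathway (between genes), b_ijg additional correlation among the
SNPs of one gene (within genes), and b_i the familial sharing among
siblings. For unrelated designs the sibship level is dropped
(`include_sibship_effect=False`); with singleton sibships the sibship and
subject variances are not separately identifiable and the package warns.

**Fixed effects.** Per-SNP intercepts are the default
(`intercept_mode="per_snp"`): pathway SNPs span minor allele frequencies
of orders of magnitude (rare variants below 0.03 alongside common ones),
which a shared intercept cannot represent. Per-gene or shared intercepts
are available for deliberately constrained fits. Genotype-model
covariates (e.g. Smoking, when a gene × smoking interaction is
anticipated in the phenotype model) enter as ordinary slopes.

**Estimation.** The marginal likelihood integrates over all random
effects. It is evaluated by the Laplace approximation at the joint
conditional mode, which is found by penalized iteratively reweighted
least squares (PIRLS) jointly over fixed effects and random-effect modes.
Because random effects never cross sibships, the Hessian of the penalized
problem is block-diagonal by sibship; each Newton step solves the small
dense per-sibship blocks (batched Cholesky) and one p × p Schur system
for the fixed effects. The profiled Laplace objective is then maximised
over the variance components on the log scale with Nelder–Mead
(derivative-free; at most 3 parameters). Random effects start at zero
and fixed effects at the logit of the observed allele frequencies, so
the fit is deterministic. Convergence: relative log-likelihood change
< 1e-8 and gradient max-norm < 1e-5, iteration cap 500 (outer) / 200
(inner). Variance components profiled below 1e-6 are clamped to exactly
0 and the modes re-solved on the reduced model, so boundary fits are
exact rather than approximate.

**Empirical Bayes summaries.** The EB estimate of b_ijg is its
conditional posterior mode at the fitted parameters (mode = mean of the
Laplace Gaussian approximation). One number per subject per gene, it
grows strictly with the subject's minor-allele count in that gene
(holding everything else fixed) — a model-based burden score. When
σ²_gene = 0 every EB entry is exactly 0 by construction. The exact
closed form of the EB estimator is deliberately not relied on: the
conditional mode is what mixed-model software computes, and it is the
quantity whose monotonicity and shrinkage properties the tests verify.

**Missing genotypes.** Missing cells are deleted from the likelihood
cell-wise; the subject (and its other cells) remain. A subject-gene pair
with no observed cells contributes exactly nothing to the marginal
likelihood — its prior and Laplace terms cancel — so no special-casing
is needed. No imputation is performed.

**Quadrature oracle.** `loglik_oracle` evaluates the same marginal
likelihood by nested adaptive Gauss–Hermite quadrature (each 1-D
integral centred at its mode, scaled by local curvature). It exists for
validation only and is capped at 8 random-effect dimensions per sibship.
On the packaged 2-sibship × 2-subject × 2-gene fixture the Laplace value
agrees with 15-node quadrature to 0.5%; quadrature itself is internally
converged to < 1e-6 between 10 and 15 nodes. The Laplace error is real
but small, and it cancels in the variance-component comparisons that
drive the EB summaries.

### Stage 2: phenotype models

Quantitative traits use a linear mixed model with a sibship random
intercept, y_ij = x'_ij β + Σ_g γ_g EB_ijg (+ interactions) + u_i + e_ij,
fitted by **ML** (not REML) so that the Wald covariance and any
likelihood comparisons are internally consistent; REML is available via
`PhenotypeModelSpec(reml=True)`. Binary traits use GEE with logit link,
exchangeable working correlation within sibships, estimated scale, and
robust sandwich covariance — a marginal model, chosen over a
mixed-effects logistic likelihood for robustness at the cost of some
efficiency. Both are computed by statsmodels (MixedLM, GEE) behind the
package's design/term bookkeeping. EB covariates enter unstandardized;
scaling changes γ's units, not the tests.

A gene whose EB column is constant (stage-1 gene variance at the
boundary 0) is inestimable in stage 2. Rather than failing, the package
drops the column, reports that gene with p = 1 (no evidence either way),
and keeps it in the pathway degrees of freedom — a conservative
completion of an otherwise undefined test. This matters for small or
null datasets where the boundary is reached with appreciable
probability.

### Tests

Pathway: W = γ̂' V̂⁻¹ γ̂ ~ χ²(G) under H₀: γ₁ = … = γ_G = 0, using the
model-based covariance for the linear mixed model and the sandwich for
GEE. (Whether the original family analyses used model-based or robust
covariance for the LMM is not determinable; model-based is the default
here and the choice is flagged in the API.) Gene-level tests are 1-df
Wald tests from the same joint fit — conditional on the other genes —
and interaction terms are tested separately, excluded from the pathway
null by default (`include_interactions=True` gives the (G+k)-df joint
test). Per-gene p-values are reported raw by default; an optional
Bonferroni adjustment over the tested genes is available
(`gene_tests(..., bonferroni=True)`). A singular Wald covariance raises
by default;
`singular="pseudo_inverse"` falls back to the pseudo-inverse with
effective-rank degrees of freedom and a warning.

The collapsed rare-variant test reassigns every SNP with MAF below a
threshold (default 0.05) to one pseudo-gene, refits stage 1, and tests
the single EB column (1 df). It can be more powerful when the signal is
spread thinly over many rare variants, but discards the gene structure,
so gene × environment interactions are unavailable in this mode and the
package refuses them explicitly.

## Simulator

The generator draws data from exactly the models above: random effects
from their normals, genotypes from Binomial(2, expit(·)) with per-SNP
MAF intercepts, then the trait from the stage-2 models using the *drawn*
b_ijg as the true gene scores with effects γ (the generative analogue of
the EB summary; this makes stage-2 recovery well-defined). Binary traits
are generated directly from the marginal logistic model, not through a
latent liability. Degenerate binary draws (all cases or all controls)
are resampled up to 10 times, then error.

Default study conditions: 600 singleton sibships; 3 genes × 4 SNPs with
MAFs (0.05, 0.1, 0.2, 0.4); σ²_sib = 0, σ²_subj = 0.3, σ²_gene = 0.5;
γ = 0 (null); quantitative trait with σ²_u = 0.2, σ²_e = 1;
Age ~ N(50, 10²) and Smoking ~ Bernoulli(0.25) as covariates (the
smoking prevalence matches typical adult cohorts; no canonical values
exist for these generators). Family scenarios set sibship sizes (fixed
or a distribution over 1–6) and may raise the MAFs to emulate the
enrichment of rare variants in families; ascertainment sampling is
deliberately not modelled.

Reproducibility: a single integer master seed; replicate r draws from
the independent counter-based stream `default_rng([seed, r+1])`, so the
replicate set is order-insensitive. Replicates whose fits fail to
converge are recorded and excluded from the rejection-rate denominator;
more than 20% failures aborts the study.

What the simulator does *not* emulate: linkage disequilibrium beyond the
random-effects correlation, ascertainment of extended pedigrees,
between-trait correlation, or relatedness beyond the sibship level
(cousin-level correlation is a documented non-goal). Passing
operating-characteristic tests therefore demonstrate correctness of the
procedure under its own assumptions, not robustness to real-data
violations of them.

## Verification strategy

* Exact reductions: all variance components fixed at 0 reproduces the
  independent binomial GLM (1e-6); all-singleton LMM equals OLS (1e-8);
  size-1-cluster GEE equals logistic ML with the HC0 sandwich (1e-6).
* The Laplace likelihood is checked against the independent quadrature
  oracle; the EB modes against 1-D grid search; the LMM ML fit against a
  brute-force profile-likelihood grid; the GEE working correlation
  against a hand-computed moment estimate.
* Operating characteristics: the null scenario's empirical type-I error
  at α = 0.05 over 200 replicates must fall inside the 95% binomial
  interval around 5%; power must be non-decreasing over an effect-size
  grid with paired seeds; the generative variance components (0.2, 0.3,
  0.5) must be recovered within ±50% in at least 80% of replicates at
  n = 2000.

Problem sizes in the test suite (600 subjects for size studies, 2000 for
recovery, 200/100 Monte-Carlo replicates) were chosen as the smallest
designs at which the binomial Monte-Carlo bounds are informative.

## Known limitations

* The Laplace approximation biases the likelihood slightly for
  Binomial(2, ·) data with few SNPs per gene; variance components are
  mildly attenuated in small samples (visible, within tolerance, in the
  recovery study). Quadrature-based production fitting is out of scope.
* With all-singleton data, σ²_sib and σ²_subj are confounded; only their
  sum is meaningful (the package warns and the unrelated reduction drops
  the sibship term).
* The GEE branch has no likelihood, hence no likelihood-ratio pathway
  test; only Wald tests are provided. Score tests are out of scope.
* No LD pruning, kinship estimation, imputation or phasing; pedigrees
  richer than sibships are collapsed to sibship labels on input.
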