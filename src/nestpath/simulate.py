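"""Generative model for sibship-structured pathway data, and Monte-Carlo
operating characteristics (type-I error / power) of the two-stage test.

Genotypes are drawn from the stage-1 model itself: for each sibship the
nested effects b_i, b_ij, b_ijg are drawn from their normal distributions
and each SNP's minor-allele count from Binomial(2, expit(logit(MAF_s) +
x' delta + b_i + b_ij + b_ijg)).  Phenotypes are generated from the
stage-2 models with the *drawn* gene effects b_ijg as the true gene
scores — the generative analogue of the EB summary — multiplied by the
effect vector gamma (all zeros = null scenario).  Quantitative traits add
a sibship effect u_i and residual e_ij; binary traits are Bernoulli with
a logistic mean (a direct marginal-logistic generator, not a latent
liability).

Family scenarios with enriched rare variants are emulated by giving the
family scenario higher MAFs, not by ascertainment sampling.

Reproducibility: one integer master seed; each replicate r uses the
independent stream ``default_rng([seed, r])``, so replicates do not
depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import DatasetBundle, GenotypeBlock, StudyFrame
from .exceptions import ConvergenceError, DataFormatError

__all__ = ["SimulationScenario", "OperatingCharacteristics",
           "simulate_dataset", "run_operating_characteristics"]


@dataclass
class SimulationScenario:
    """Study conditions for one simulated dataset.

    Defaults describe a null study of unrelated subjects: 600 singleton
    sibships, a 3-gene pathway with 4 SNPs per gene spanning rare to
    common frequencies, genotype variance components (0, 0.3, 0.5), a
    quantitative trait independent of the genotypes, and Age/Smoking as
    phenotype covariates.

    Parameters
    ----------
    n_sibships, sibship_sizes
        Number of sibships and their sizes: an int for fixed-size
        sibships or a ``{size: probability}`` mapping (sizes 1-6).
    n_genes, snps_per_gene, maf
        Pathway shape; ``maf`` is recycled across each gene's SNPs.
    var_sibship, var_subject, var_gene
        Genotype-model variance components (s2_sib, s2_subj, s2_gene).
    genotype_covariate_effects
        Logit-scale effects of covariates on the genotype model, e.g.
        ``{"Smoking": 0.2}``.
    gamma
        True gene-score effects on the trait, length ``n_genes``
        (all-zero = null scenario).
    trait_type, trait_name
        ``"quantitative"`` (default, trait ``Q``) or ``"binary"``.
    covariate_effects
        Trait-scale effects of Age and Smoking on the phenotype.
    interaction
        Optional ``(gene_index, covariate, effect)`` gene x environment
        term added to the trait model.
    var_u, var_e
        Sibship and residual variance of the quantitative trait.
    baseline_prevalence
        P(case) at covariate/pathway zero for the binary trait.
    age_mean, age_sd, smoking_prob
        Covariate generators: Age ~ Normal, Smoking ~ Bernoulli.
    """

    n_sibships: int = 600
    sibship_sizes: int | dict = 1
    n_genes: int = 3
    snps_per_gene: int = 4
    maf: tuple = (0.05, 0.1, 0.2, 0.4)
    var_sibship: float = 0.0
    var_subject: float = 0.3
    var_gene: float = 0.5
    genotype_covariate_effects: dict = field(default_factory=dict)
    gamma: tuple | None = None
    trait_type: str = "quantitative"
    trait_name: str = "Q"
    covariate_effects: dict = field(
        default_factory=lambda: {"Age": 0.01, "Smoking": 0.3})
    interaction: tuple | None = None
    var_u: float = 0.2
    var_e: float = 1.0
    baseline_prevalence: float = 0.3
    age_mean: float = 50.0
    age_sd: float = 10.0
    smoking_prob: float = 0.25

    def __post_init__(self):
        if self.gamma is None:
            self.gamma = tuple(0.0 for _ in range(self.n_genes))
        self.gamma = tuple(float(g) for g in self.gamma)
        if len(self.gamma) != self.n_genes:
            raise ValueError("gamma length must equal n_genes")
        mafs = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValueError("MAFs must lie in (0, 0.5]")
        self.maf = tuple(mafs)
        for v in (self.var_sibship, self.var_subject, self.var_gene,
                  self.var_u, self.var_e):
            if v < 0:
                raise ValueError("variances must be >= 0")
        if isinstance(self.sibship_sizes, dict):
            sizes = self.sibship_sizes
            if any(s < 1 for s in sizes):
                raise ValueError("sibship sizes must be >= 1")
            tot = sum(sizes.values())
            self.sibship_sizes = {int(s): p / tot for s, p in sizes.items()}
        elif self.sibship_sizes < 1:
            raise ValueError("sibship size must be >= 1")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    @property
    def snp_mafs(self) -> np.ndarray:
        base = np.resize(np.asarray(self.maf), self.snps_per_gene)
        return np.tile(base, self.n_genes)

    @property
    def is_family(self) -> bool:
        if isinstance(self.sibship_sizes, dict):
            return max(self.sibship_sizes) > 1
        return self.sibship_sizes > 1


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo rejection summary of the two-stage pathway test."""

    scenario: SimulationScenario
    n_replicates: int
    alpha: float
    rejection_rate_pathway: float
    gene_rejection_rates: pd.Series
    mc_se: float
    records: pd.DataFrame      # one row per replicate: stat, df, p, converged
    n_convergence_failures: int

    def summary(self) -> str:
        lines = [
            "Operating characteristics (two-stage pathway Wald test)",
            "=" * 55,
            f"replicates: {self.n_replicates}   alpha: {self.alpha}   "
            f"convergence failures: {self.n_convergence_failures}",
            f"pathway rejection rate: {self.rejection_rate_pathway:.4f} "
            f"(MC SE {self.mc_se:.4f})",
            "per-gene rejection rates:",
            self.gene_rejection_rates.to_string(float_format="%.4f"),
        ]
        return "\n".join(lines)


def _draw_sizes(scenario, rng) -> np.ndarray:
    if isinstance(scenario.sibship_sizes, dict):
        sizes = np.array(sorted(scenario.sibship_sizes))
        probs = np.array([scenario.sibship_sizes[s] for s in sizes])
        return rng.choice(sizes, size=scenario.n_sibships, p=probs)
    return np.full(scenario.n_sibships, int(scenario.sibship_sizes))


def simulate_dataset(scenario: SimulationScenario, seed: int,
                     _max_attempts: int = 10) -> DatasetBundle:
    """Draw one dataset under the scenario; byte-identical given a seed.

    The drawn per-subject gene effects (true gene scores) are stored in
    hidden StudyFrame columns ``_score_<gene>`` so simulation studies can
    compare EB recovery against the truth; I/O round trips keep them.
    """
    rng = np.random.default_rng([int(seed), 0x5e5])
    for attempt in range(_max_attempts):
        bundle = _simulate_once(scenario, rng)
        if bundle is not None:
            return bundle
        warnings.warn("degenerate trait draw (all cases or all controls); "
                      "resampling", stacklevel=2)
    raise DataFormatError(
        f"degenerate trait in {_max_attempts} attempts; "
        "check baseline_prevalence and effect sizes")


def _simulate_once(scenario, rng):
    sizes = _draw_sizes(scenario, rng)
    n = int(sizes.sum())
    G, S = scenario.n_genes, scenario.snps_per_gene
    sib_of = np.repeat(np.arange(scenario.n_sibships), sizes)

    age = rng.normal(scenario.age_mean, scenario.age_sd, size=n)
    smoking = rng.binomial(1, scenario.smoking_prob, size=n).astype(float)
    covars = {"Age": age, "Smoking": smoking}

    b_sib = rng.normal(0.0, np.sqrt(scenario.var_sibship),
                       size=scenario.n_sibships)[sib_of]
    b_subj = rng.normal(0.0, np.sqrt(scenario.var_subject), size=n)
    b_gene = rng.normal(0.0, np.sqrt(scenario.var_gene), size=(n, G))

    eta = logit(scenario.snp_mafs)[None, :].repeat(n, axis=0)
    for cov, eff in scenario.genotype_covariate_effects.items():
        eta += eff * covars[cov][:, None]
    eta += (b_sib + b_subj)[:, None]
    eta += np.repeat(b_gene, S, axis=1)
    w = rng.binomial(2, expit(eta)).astype(float)

    score = b_gene @ np.asarray(scenario.gamma)
    lin = score.copy()
    for cov, eff in scenario.covariate_effects.items():
        lin += eff * covars[cov]
    if scenario.interaction is not None:
        g_idx, cov, eff = scenario.interaction
        lin += eff * b_gene[:, int(g_idx)] * covars[cov]

    if scenario.trait_type == "quantitative":
        u = rng.normal(0.0, np.sqrt(scenario.var_u),
                       size=scenario.n_sibships)[sib_of]
        y = lin + u + rng.normal(0.0, np.sqrt(scenario.var_e), size=n)
    else:
        eta_y = logit(scenario.baseline_prevalence) + lin
        y = rng.binomial(1, expit(eta_y)).astype(float)
        if y.min() == y.max():
            return None

    subj_ids = [f"sub{k:05d}" for k in range(n)]
    table = pd.DataFrame({
        "sibship_id": [f"fam{f:05d}" for f in sib_of],
        "Age": age, "Smoking": smoking,
        scenario.trait_name: y,
    }, index=pd.Index(subj_ids, name="subject_id"))
    genes = [f"gene{g + 1}" for g in range(G)]
    for g_i, g in enumerate(genes):
        table[f"_score_{g}"] = b_gene[:, g_i]
    snp_ids = [f"{genes[g]}_snp{s + 1}" for g in range(G) for s in range(S)]
    gene_map = {sid: genes[g] for g in range(G) for s in range(S)
                for sid in [f"{genes[g]}_snp{s + 1}"]}
    block = GenotypeBlock(w, snp_ids, gene_map, minor_allele_coded=True)
    return DatasetBundle(StudyFrame(table), block,
                         provenance="simulate_dataset")


def _two_stage_pvalues(bundle, scenario, gene_spec=None, pheno_spec=None):
    """Run both stages on one dataset; return the full TestReport."""
    from .data import filter_monomorphic
    from .genemodel import GeneModelSpec, GenotypePathwayModel
    from .inference import full_report
    from .phenotype import PathwayPhenotypeModel, PhenotypeModelSpec

    bundle, _ = filter_monomorphic(bundle)
    if gene_spec is None:
        gene_spec = GeneModelSpec(
            include_sibship_effect=scenario.is_family,
            genotype_covariates=tuple(scenario.genotype_covariate_effects))
    gres = GenotypePathwayModel(bundle, gene_spec).fit()
    if pheno_spec is None:
        pheno_spec = PhenotypeModelSpec(
            scenario.trait_name, scenario.trait_type,
            covariates=("Age", "Smoking"))
    pres = PathwayPhenotypeModel(bundle.study, gres.empirical_bayes(),
                                 pheno_spec).fit()
    return full_report(pres)


def run_operating_characteristics(
        scenario: SimulationScenario, n_replicates: int, alpha: float,
        seed: int, gene_spec=None, pheno_spec=None,
        min_replicates: int = 50) -> OperatingCharacteristics:
    """Estimate the pathway test's rejection rate over simulated replicates.

    Each replicate simulates a dataset, runs stage 1, plugs the EB matrix
    into stage 2 and records the G-df pathway Wald p-value.  Replicates
    whose fits fail to converge are recorded and excluded from the
    denominator; more than 20% failures aborts.
    """
    if n_replicates < min_replicates:
        raise ValueError(
            f"need >= {min_replicates} replicates for a rate estimate")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    rows = []
    gene_rej = None
    for r in range(n_replicates):
        try:
            bundle = _simulate_replicate(scenario, seed, r)
            report = _two_stage_pvalues(bundle, scenario,
                                        gene_spec=gene_spec,
                                        pheno_spec=pheno_spec)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            rows.append({"replicate": r, "stat": np.nan, "df": np.nan,
                         "p": np.nan, "converged": False})
            continue
        rows.append({"replicate": r, "stat": report.pathway_stat,
                     "df": report.pathway_df, "p": report.pathway_p,
                     "converged": True})
        g = (report.gene_results["p"] < alpha).astype(float)
        gene_rej = g if gene_rej is None else gene_rej + g
    rec = pd.DataFrame(rows).set_index("replicate")
    n_fail = int((~rec["converged"]).sum())
    if n_fail > 0.2 * n_replicates:
        raise ConvergenceError(
            f"{n_fail}/{n_replicates} replicates failed to converge; "
            "scenario is numerically unstable")
    ok = rec["converged"]
    n_ok = int(ok.sum())
    rate = float((rec.loc[ok, "p"] < alpha).mean())
    mc_se = float(np.sqrt(rate * (1 - rate) / n_ok))
    gene_rates = (gene_rej / n_ok) if gene_rej is not None else pd.Series(
        dtype=float)
    return OperatingCharacteristics(
        scenario=scenario, n_replicates=n_replicates, alpha=alpha,
        rejection_rate_pathway=rate, gene_rejection_rates=gene_rates,
        mc_se=mc_se, records=rec, n_convergence_failures=n_fail)


def _simulate_replicate(scenario, seed, replicate):
    """Replicate r's dataset from the counter-based stream [seed, r+1]."""
    rng = np.random.default_rng([int(seed), replicate + 1])
    for _ in range(10):
        bundle = _simulate_once(scenario, rng)
        if bundle is not None:
            return bundle
    raise DataFormatError("degenerate trait in 10 attempts")
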