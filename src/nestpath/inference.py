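"""Wald tests for pathway, gene and gene x environment effects.

The pathway null H0: gamma_1 = ... = gamma_G = 0 (no gene summary carries
any phenotype signal) is tested with the quadratic form

    W = gamma_hat' V_hat^{-1} gamma_hat  ~  chi-square(G)  under H0,

where V_hat is the joint covariance of the gamma estimates — model-based
for the linear mixed model, robust sandwich for GEE.  Gene-level effects
are 1-df Wald tests of single coefficients from the same joint fit, i.e.
conditional on the EB summaries of the remaining genes; interactions are
tested the same way.  Interaction coefficients are excluded from the
pathway null by default and reported separately.

The collapsed rare-variant test refits stage 1 with every rare SNP
(MAF below a threshold) assigned to a single pseudo-gene, giving one EB
column and a 1-df pathway test; by construction it cannot carry per-gene
structure or gene x environment interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import DatasetBundle, GenotypeBlock
from .exceptions import DesignError, EmptyPathwayError

__all__ = ["TestReport", "pathway_wald", "gene_tests", "interaction_test",
           "collapsed_rare_test", "full_report"]


@dataclass
class TestReport:
    """Pathway, gene and interaction Wald results for one phenotype fit."""

    trait: str
    pathway_stat: float
    pathway_df: int
    pathway_p: float
    gene_results: pd.DataFrame          # index gene; estimate, se, stat, p
    interaction_results: pd.DataFrame   # index "gene:covariate"
    alpha: float = 0.05
    method_notes: str = ""
    warnings: tuple = ()

    def __post_init__(self):
        if self.pathway_stat < -1e-12:
            raise ValueError("negative Wald statistic")
        for p in [self.pathway_p, *self.gene_results["p"],
                  *self.interaction_results["p"]]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value outside [0, 1]: {p}")

    @property
    def reject_pathway(self) -> bool:
        return self.pathway_p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        """Table-style report: one row per gene, interaction and pathway."""
        rows = self.gene_results[["estimate", "se", "p"]].copy()
        inter = self.interaction_results[["estimate", "se", "p"]]
        rows = pd.concat([rows, inter])
        rows.loc["Pathway"] = [np.nan, np.nan, self.pathway_p]
        return rows

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "pathway": {"stat": self.pathway_stat, "df": self.pathway_df,
                        "p": self.pathway_p},
            "genes": self.gene_results.reset_index()
                        .to_dict(orient="records"),
            "interactions": self.interaction_results.reset_index()
                        .to_dict(orient="records"),
            "alpha": self.alpha,
            "method_notes": self.method_notes,
            "warnings": list(self.warnings),
        }


def _gamma_block(fit, gene_terms):
    """Split requested genes into estimable and degenerate (constant-EB).

    A gene whose EB column had no variation (stage-1 gene variance at the
    boundary 0) is inestimable: it contributes nothing to the Wald
    quadratic form but still counts toward the pathway degrees of freedom,
    which makes the test conservative rather than undefined.
    """
    degenerate_all = getattr(fit, "degenerate_genes", [])
    if gene_terms is None:
        genes = fit.gene_terms
        degenerate = list(degenerate_all)
    else:
        genes = [g for g in gene_terms if g not in degenerate_all]
        degenerate = [g for g in gene_terms if g in degenerate_all]
    missing = [g for g in genes if f"gene:{g}" not in fit.term_map]
    if missing:
        raise KeyError(f"gene terms not in fit: {missing}")
    cols = [fit.term_map[f"gene:{g}"] for g in genes]
    gamma = fit.params[cols].to_numpy()
    V = fit.cov_params.loc[cols, cols].to_numpy()
    return genes, degenerate, gamma, V


def pathway_wald(fit, gene_terms=None, include_interactions=False,
                 singular="error"):
    """G-df Wald test of the pathway null gamma_1 = ... = gamma_G = 0.

    Parameters
    ----------
    fit : PhenotypeResults
    gene_terms
        Genes to test jointly; default all gene terms in the fit.
    include_interactions
        Also put the interaction coefficients under the null (a (G+k)-df
        joint test); off by default — interactions are reported separately.
    singular : {"error", "pseudo_inverse"}
        What to do if the coefficient covariance block is singular.

    Returns
    -------
    (stat, df, p) — plus a warning flag in ``p``'s metadata when a
    pseudo-inverse with reduced degrees of freedom was used.
    """
    genes, degenerate, gamma, V = _gamma_block(fit, gene_terms)
    if include_interactions:
        cols = [fit.term_map[k] for k in fit.term_map
                if k.startswith("interaction:")]
        gcols = [fit.term_map[f"gene:{g}"] for g in genes] + cols
        gamma = fit.params[gcols].to_numpy()
        V = fit.cov_params.loc[gcols, gcols].to_numpy()
    df = len(gamma) + len(degenerate)
    if not len(gamma):
        return 0.0, df, 1.0
    cond = np.linalg.cond(V)
    if cond > 1e12:
        if singular == "error":
            raise DesignError(
                f"singular Wald covariance (cond={cond:.2e}); pass "
                "singular='pseudo_inverse' to test on the effective rank")
        Vinv = np.linalg.pinv(V, rcond=1e-12)
        df = int(np.linalg.matrix_rank(V, tol=None))
        warnings.warn(f"pseudo-inverse Wald with effective df={df}",
                      stacklevel=2)
    else:
        Vinv = np.linalg.inv(V)
    stat = float(gamma @ Vinv @ gamma)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def gene_tests(fit, gene_terms=None, bonferroni: bool = False) -> pd.DataFrame:
    """1-df Wald test per gene, conditional on the other genes' EB terms.

    Per-gene p-values are reported raw by default; ``bonferroni=True``
    adds a ``p_adjusted`` column (Bonferroni over the tested genes).
    Degenerate (constant-EB) genes appear with missing estimate/SE and
    p = 1: their column carries no evidence either way.
    """
    genes, degenerate, gamma, V = _gamma_block(fit, gene_terms)
    se = np.sqrt(np.diag(V))
    stat = (gamma / se) ** 2
    p = stats.chi2.sf(stat, 1)
    out = pd.DataFrame(
        {"estimate": gamma, "se": se, "stat": stat, "p": p},
        index=pd.Index(genes, name="gene"))
    for g in degenerate:
        out.loc[g] = [np.nan, np.nan, 0.0, 1.0]
    if bonferroni:
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p"].to_numpy(),
                                          method="bonferroni")[1]
    return out


def interaction_test(fit, term: tuple) -> pd.Series:
    """1-df Wald test of a (gene, covariate) interaction coefficient."""
    g, c = term
    key = f"interaction:{g}:{c}"
    if key not in fit.term_map:
        raise KeyError(f"no interaction term {g}:{c} in fit")
    est, se = fit.coef(key)
    stat = (est / se) ** 2
    return pd.Series({"estimate": est, "se": se, "stat": stat,
                      "p": float(stats.chi2.sf(stat, 1))},
                     name=f"{g}:{c}")


def full_report(fit, alpha: float = 0.05, gene_terms=None,
                singular="error") -> TestReport:
    """Assemble pathway, per-gene and interaction tests into a TestReport."""
    stat, df, p = pathway_wald(fit, gene_terms=gene_terms, singular=singular)
    genes = gene_tests(fit, gene_terms=gene_terms)
    inter = pd.DataFrame(
        [interaction_test(fit, t) for t in fit.interaction_terms],
        columns=["estimate", "se", "stat", "p"])
    inter.index = [f"{g}:{c}" for g, c in fit.interaction_terms]
    for g, c in getattr(fit, "degenerate_interactions", []):
        inter.loc[f"{g}:{c}"] = [np.nan, np.nan, 0.0, 1.0]
    inter.index.name = "interaction"
    notes = ("model-based covariance (linear mixed model)"
             if fit.kind == "lmm" else "robust sandwich covariance (GEE)")
    return TestReport(fit.spec.trait, stat, df, p, genes, inter,
                      alpha=alpha, method_notes=notes)


def collapsed_rare_test(bundle: DatasetBundle, pheno_spec,
                        gene_spec=None, maf_threshold: float = 0.05,
                        pseudo_gene: str = "RARE"):
    """One-df collapsed rare-variant pathway test.

    All SNPs with minor allele frequency below ``maf_threshold`` are
    assigned to a single pseudo-gene, stage 1 is refitted, and the single
    EB column is tested in the phenotype model (1 df).  Gene structure —
    and hence any gene x environment interaction — is unavailable here.

    Returns ``(report, gene_results, pheno_results)``.
    """
    from .genemodel import GeneModelSpec, GenotypePathwayModel
    from .phenotype import PathwayPhenotypeModel

    if pheno_spec.interactions:
        raise DesignError(
            "the collapsed rare-variant test has no per-gene structure; "
            "gene x environment interactions are unavailable")
    maf = bundle.genotypes.coded_allele_frequency()
    rare = maf < maf_threshold
    if not rare.any():
        raise EmptyPathwayError(
            f"no SNPs with MAF < {maf_threshold}")
    keep = [s for s, r in zip(bundle.genotypes.snp_ids, rare) if r]
    block = GenotypeBlock(
        bundle.genotypes.matrix[:, rare], keep,
        {s: pseudo_gene for s in keep},
        minor_allele_coded=bundle.genotypes.minor_allele_coded)
    collapsed = DatasetBundle(bundle.study, block,
                              bundle.provenance + "; collapsed rare variants")
    gspec = gene_spec or GeneModelSpec()
    gres = GenotypePathwayModel(collapsed, gspec).fit()
    pspec = replace(pheno_spec, gene_terms=(pseudo_gene,), interactions=())
    pres = PathwayPhenotypeModel(bundle.study, gres.empirical_bayes(),
                                 pspec).fit()
    report = full_report(pres)
    report.method_notes += f"; collapsed rare variants (MAF < {maf_threshold})"
    return report, gres, pres
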