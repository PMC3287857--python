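"""Stage 2: family-aware phenotype models with EB gene summaries.

For a quantitative trait y_ij (subject j, sibship i) the model is the
linear mixed model

    y_ij = x_ij' beta + sum_g gamma_g EB_ijg (+ interactions) + u_i + e_ij,

with a normal sibship random effect u_i and normal residual e_ij, fitted
by maximum likelihood (REML behind a flag).  For a binary trait the model
is marginal logistic,

    logit P(y_ij = 1) = x_ij' beta + sum_g gamma_g EB_ijg (+ interactions),

estimated by GEE with an exchangeable working correlation within sibships
and a robust (sandwich) covariance.  EB_ijg are the stage-1 empirical
Bayes gene summaries; a (gene, covariate) interaction term is the
elementwise product of the EB column and the covariate.

Fitting is delegated to statsmodels (MixedLM and GEE); this module owns
the design construction, the term bookkeeping used by the Wald tests, and
the result container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import StudyFrame
from .exceptions import (
    AlignmentError,
    ConvergenceError,
    DesignError,
    SeparationError,
)

__all__ = ["PhenotypeModelSpec", "PathwayPhenotypeModel", "PhenotypeResults",
           "build_design"]


@dataclass
class PhenotypeModelSpec:
    """Specification of a stage-2 phenotype model.

    Parameters
    ----------
    trait
        Name of the phenotype column in the StudyFrame.
    trait_type
        ``"quantitative"`` (linear mixed model) or ``"binary"`` (GEE).
    covariates
        Covariate column names (e.g. ``["Age", "Smoking"]``).
    gene_terms
        Gene labels whose EB columns enter with coefficients gamma_g;
        defaults to every column of the EB matrix.
    interactions
        (gene, covariate) pairs, e.g. ``[("KDR", "Smoking")]``; each gene
        must also appear in ``gene_terms``.
    reml
        Use REML instead of ML for the linear mixed model.
    """

    trait: str
    trait_type: str = "quantitative"
    covariates: tuple = ()
    gene_terms: tuple | None = None
    interactions: tuple = ()
    reml: bool = False

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        self.covariates = tuple(self.covariates)
        self.interactions = tuple((g, c) for g, c in self.interactions)
        if self.gene_terms is not None:
            self.gene_terms = tuple(self.gene_terms)


def _resolve_genes(spec: PhenotypeModelSpec, eb: pd.DataFrame) -> tuple:
    genes = spec.gene_terms if spec.gene_terms is not None \
        else tuple(eb.columns)
    missing = [g for g in genes if g not in eb.columns]
    if missing:
        raise DesignError(f"gene terms not in EB matrix: {missing}")
    for g, c in spec.interactions:
        if g not in genes:
            raise DesignError(
                f"interaction gene {g!r} must be among the gene terms")
    return genes


def build_design(study: StudyFrame, eb: pd.DataFrame,
                 spec: PhenotypeModelSpec) -> tuple[pd.DataFrame, dict]:
    """Assemble the stage-2 fixed-effects design and its term map.

    Returns ``(X, term_map)`` where ``X`` columns are Intercept,
    covariates, one ``EB_<gene>`` column per gene term, and one
    ``EB_<gene>:<covariate>`` product column per interaction; ``term_map``
    maps term keys (``"intercept"``, ``"covariate:Age"``, ``"gene:KDR"``,
    ``"interaction:KDR:Smoking"``) to column names.
    """
    if not np.array_equal(eb.index.to_numpy(), study.subject_ids):
        if set(eb.index) != set(study.subject_ids):
            raise AlignmentError("EB matrix subjects do not match StudyFrame")
        eb = eb.loc[study.subject_ids]
    genes = _resolve_genes(spec, eb)
    cols = {"Intercept": np.ones(study.n_subjects)}
    term_map = {"intercept": "Intercept"}
    for c in spec.covariates:
        cols[c] = study.column(c)
        term_map[f"covariate:{c}"] = c
    for g in genes:
        name = f"EB_{g}"
        cols[name] = eb[g].to_numpy(dtype=float)
        term_map[f"gene:{g}"] = name
    for g, c in spec.interactions:
        name = f"EB_{g}:{c}"
        cols[name] = eb[g].to_numpy(dtype=float) * study.column(c)
        term_map[f"interaction:{g}:{c}"] = name
    X = pd.DataFrame(cols, index=study.subject_ids)
    return X, term_map


class PathwayPhenotypeModel:
    """Stage-2 model: phenotype on EB gene summaries, sibship-clustered.

    Examples
    --------
    >>> spec = PhenotypeModelSpec("Q1", "quantitative",
    ...                           covariates=("Age", "Smoking"),
    ...                           interactions=(("KDR", "Smoking"),))
    >>> res = PathwayPhenotypeModel(study, eb, spec).fit()
    >>> res.pathway_wald()
    """

    def __init__(self, study: StudyFrame, eb: pd.DataFrame,
                 spec: PhenotypeModelSpec):
        self.study = study
        self.spec = spec
        X, term_map = build_design(study, eb, spec)
        # EB columns with no variation (gene variance at the boundary 0)
        # are inestimable: drop them from the design and report them as
        # carrying no evidence (p = 1) rather than failing the whole fit.
        self.degenerate_genes = []
        self.degenerate_interactions = []
        drop = []
        for key in list(term_map):
            col = term_map[key]
            if key.startswith(("gene:", "interaction:")) and \
                    np.ptp(X[col].to_numpy()) == 0.0:
                if key.startswith("gene:"):
                    self.degenerate_genes.append(key.split(":", 1)[1])
                else:
                    self.degenerate_interactions.append(
                        tuple(key.split(":")[1:3]))
                drop.append(col)
                del term_map[key]
        if drop:
            X = X.drop(columns=drop)
            warnings.warn(
                f"dropped constant EB terms (gene variance 0): {drop}",
                stacklevel=3)
        y = study.column(spec.trait)
        groups = pd.Series(study.sibship_ids, index=study.subject_ids)
        ok = ~np.isnan(y) & ~X.isna().any(axis=1).to_numpy()
        self.X = X.loc[ok]
        self.y = y[ok]
        self.groups = groups[ok]
        self.term_map = term_map
        if spec.trait_type == "binary":
            vals = np.unique(self.y)
            if not np.isin(vals, [0.0, 1.0]).all():
                raise DesignError(f"binary trait {spec.trait!r} not coded 0/1")
        if np.linalg.matrix_rank(self.X.to_numpy()) < self.X.shape[1]:
            raise DesignError("stage-2 design is rank deficient")
        self.n_clusters = self.groups.nunique()
        if self.n_clusters < 2:
            raise DesignError("need at least 2 sibship clusters")

    def fit(self) -> "PhenotypeResults":
        if self.spec.trait_type == "quantitative":
            return self._fit_lmm()
        return self._fit_gee()

    def _fit_lmm(self) -> "PhenotypeResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(self.y, self.X, groups=self.groups)
            try:
                fit = model.fit(reml=self.spec.reml)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"linear mixed model failed: {exc}") \
                    from exc
        k = self.X.shape[1]
        params = pd.Series(fit.fe_params, index=self.X.columns)
        cov = pd.DataFrame(np.asarray(fit.cov_params())[:k, :k],
                           index=self.X.columns, columns=self.X.columns)
        return PhenotypeResults(
            self, params, cov, kind="lmm",
            sibship_variance=float(np.asarray(fit.cov_re).ravel()[0]),
            residual_variance=float(fit.scale),
            working_correlation=None,
            converged=bool(fit.converged), llf=float(fit.llf),
            statsmodels_results=fit)

    def _fit_gee(self) -> "PhenotypeResults":
        if self.n_clusters < 10:
            warnings.warn(
                f"only {self.n_clusters} sibship clusters; GEE sandwich "
                "variances are unreliable below ~10 clusters", stacklevel=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(self.y, self.X, groups=self.groups,
                           family=sm.families.Binomial(),
                           cov_struct=sm.cov_struct.Exchangeable())
            fit = model.fit(maxiter=200, ctol=1e-8)
        eta = np.asarray(self.X @ fit.params)
        if np.abs(eta).max() > 30.0:
            raise SeparationError(
                "diverging linear predictor: quasi-complete separation")
        if not fit.converged:
            raise ConvergenceError("GEE did not converge", fit)
        params = pd.Series(np.asarray(fit.params), index=self.X.columns)
        cov = pd.DataFrame(np.asarray(fit.cov_params()),
                           index=self.X.columns, columns=self.X.columns)
        return PhenotypeResults(
            self, params, cov, kind="gee",
            sibship_variance=None, residual_variance=None,
            working_correlation=float(fit.cov_struct.dep_params),
            converged=True, llf=None, statsmodels_results=fit)


class PhenotypeResults:
    """Fitted stage-2 model.

    ``cov_params`` is model-based for the linear mixed model and the
    robust sandwich for GEE — the covariance the Wald pathway test uses.
    """

    def __init__(self, model, params, cov_params, kind, sibship_variance,
                 residual_variance, working_correlation, converged, llf,
                 statsmodels_results=None):
        self.model = model
        self.spec = model.spec
        self.term_map = dict(model.term_map)
        self.degenerate_genes = list(model.degenerate_genes)
        self.degenerate_interactions = list(model.degenerate_interactions)
        self.params = params
        self.cov_params = cov_params
        self.kind = kind
        self.sibship_variance = sibship_variance
        self.residual_variance = residual_variance
        self.working_correlation = working_correlation
        self.n_clusters = model.n_clusters
        self.nobs = len(model.y)
        self.converged = converged
        self.llf = llf
        self._sm = statsmodels_results

    @property
    def gene_terms(self) -> list[str]:
        return [k.split(":", 1)[1] for k in self.term_map
                if k.startswith("gene:")]

    @property
    def interaction_terms(self) -> list[tuple[str, str]]:
        return [tuple(k.split(":")[1:3]) for k in self.term_map
                if k.startswith("interaction:")]

    def coef(self, term_key: str) -> tuple[float, float]:
        """(estimate, SE) for a term-map key."""
        if term_key not in self.term_map:
            raise KeyError(f"no term {term_key!r} in fit")
        col = self.term_map[term_key]
        return (float(self.params[col]),
                float(np.sqrt(self.cov_params.loc[col, col])))

    # Wald tests live in nestpath.inference; thin conveniences here.
    def pathway_wald(self, **kw):
        from .inference import pathway_wald
        return pathway_wald(self, **kw)

    def gene_tests(self, **kw):
        from .inference import gene_tests
        return gene_tests(self, **kw)

    def interaction_test(self, term, **kw):
        from .inference import interaction_test
        return interaction_test(self, term, **kw)

    def summary(self) -> str:
        se = pd.Series(np.sqrt(np.diag(self.cov_params)),
                       index=self.params.index)
        tab = pd.DataFrame({"coef": self.params, "se": se,
                            "z": self.params / se})
        head = ("Linear mixed model (sibship random effect, "
                + ("REML" if self.spec.reml else "ML") + ")"
                if self.kind == "lmm"
                else "GEE logistic (exchangeable working correlation)")
        lines = [head, "=" * len(head),
                 f"trait: {self.spec.trait}   n={self.nobs}   "
                 f"clusters={self.n_clusters}"]
        if self.kind == "lmm":
            lines.append(f"sibship variance: {self.sibship_variance:.4f}   "
                         f"residual variance: {self.residual_variance:.4f}")
        else:
            lines.append(
                f"working correlation: {self.working_correlation:.4f}")
        lines += ["", tab.to_string(float_format="%.4f")]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "trait": self.spec.trait,
            "coefficients": self.params.to_dict(),
            "covariance": self.cov_params.to_numpy().tolist(),
            "term_map": self.term_map,
            "sibship_variance": self.sibship_variance,
            "residual_variance": self.residual_variance,
            "working_correlation": self.working_correlation,
            "n_clusters": self.n_clusters,
            "nobs": self.nobs,
            "converged": self.converged,
        }
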