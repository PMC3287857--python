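"""Stage 1: nested random-effects binomial model for pathway genotypes.

Under Hardy-Weinberg equilibrium the minor-allele count ``w_ijgs`` of
subject ``j`` in sibship ``i`` at SNP ``s`` of gene ``g`` is Binomial(2,
pi_ijgs) with

    logit(pi_ijgs) = alpha_s + x_ij' delta + b_i + b_ij + b_ijg,

where ``alpha_s`` are per-SNP intercepts (capturing heterogeneous minor
allele frequencies; per-gene or shared intercepts are available), ``x_ij``
are genotype-model covariates, and the nested normal random effects
``b_i ~ N(0, s2_sib)`` (sibship), ``b_ij ~ N(0, s2_subj)`` (subject:
pathway-wide burden) and ``b_ijg ~ N(0, s2_gene)`` (gene within subject)
induce the between- and within-gene genotype correlation.  For unrelated
subjects the sibship effect is omitted.

The marginal likelihood is evaluated by the Laplace approximation at the
joint conditional mode of the random effects, found by penalized
iteratively reweighted least squares (PIRLS) jointly with the fixed
effects; variance components are profiled out by direct optimisation on
the log scale.  The per-subject, per-gene empirical Bayes (EB) summaries
used by stage 2 are the conditional modes of ``b_ijg`` — one number per
gene summarising a subject's multi-SNP (rare-variant) burden.

Missing genotype cells are dropped from the likelihood cell-wise; the
subject and its remaining cells stay in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .data import DatasetBundle
from .exceptions import ConvergenceError, DesignError, EmptyPathwayError

__all__ = ["GeneModelSpec", "GenotypePathwayModel", "GeneModelResults",
           "COMPONENTS"]

#: variance-component names, outermost first
COMPONENTS = ("sibship", "subject", "gene")

_VAR_FLOOR = 1e-6  # variances profiled below this are reported as exactly 0


@dataclass
class GeneModelSpec:
    """Options for the genotype (stage-1) model.

    Parameters
    ----------
    include_sibship_effect
        Drop to analyse unrelated subjects (the model without ``b_i``).
    genotype_covariates
        Names of StudyFrame columns entering the genotype model (e.g.
        ``["Smoking"]`` when a gene x environment interaction is expected).
    intercept_mode
        ``"per_snp"`` (default; one intercept per SNP, required when minor
        allele frequencies differ across SNPs), ``"per_gene"`` or
        ``"shared"``.
    fix_variance
        Optional mapping from component name (``"sibship"``, ``"subject"``,
        ``"gene"``) to a fixed value; components fixed at 0 are removed
        from the model exactly.  Unlisted components are estimated.
    """

    include_sibship_effect: bool = True
    genotype_covariates: tuple = ()
    intercept_mode: str = "per_snp"
    fix_variance: dict | None = None
    variance_start: float = 0.2
    max_iter: int = 500
    inner_max_iter: int = 200
    grad_tol: float = 1e-5
    rel_tol: float = 1e-8

    def __post_init__(self):
        if self.intercept_mode not in ("per_snp", "per_gene", "shared"):
            raise ValueError(f"unknown intercept_mode {self.intercept_mode!r}")
        if self.grad_tol <= 0 or self.rel_tol <= 0:
            raise ValueError("tolerances must be positive")
        self.genotype_covariates = tuple(self.genotype_covariates)
        if self.fix_variance:
            bad = set(self.fix_variance) - set(COMPONENTS)
            if bad:
                raise ValueError(f"unknown variance components {sorted(bad)}")
            if any(v < 0 for v in self.fix_variance.values()):
                raise ValueError("fixed variances must be >= 0")


def _local_random_design(size: int, n_snps: int, gene_index: np.ndarray,
                         active: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Local random-effects design for one sibship of ``size`` subjects.

    Observations are laid out subject-major (subject 0's SNPs, subject
    1's SNPs, ...).  Columns are ordered sibship, then per subject the
    subject effect followed by its gene effects.  Returns (Z, comp) where
    ``comp[k]`` is the component index (0 sib, 1 subj, 2 gene) of column k.
    """
    n_genes = int(gene_index.max()) + 1 if len(gene_index) else 0
    cols, comp = [], []
    n_obs = size * n_snps
    if "sibship" in active:
        cols.append(np.ones(n_obs))
        comp.append(0)
    for j in range(size):
        rows = slice(j * n_snps, (j + 1) * n_snps)
        if "subject" in active:
            z = np.zeros(n_obs)
            z[rows] = 1.0
            cols.append(z)
            comp.append(1)
        if "gene" in active:
            for g in range(n_genes):
                z = np.zeros(n_obs)
                z[rows] = (gene_index == g).astype(float)
                cols.append(z)
                comp.append(2)
    if cols:
        return np.column_stack(cols), np.asarray(comp)
    return np.zeros((n_obs, 0)), np.zeros(0, dtype=int)


def _binom2_loglik(y, eta, mask):
    """Masked Binomial(2, expit(eta)) log-likelihood, incl. log C(2, y)."""
    ll = y * eta - 2.0 * np.logaddexp(0.0, eta) + np.log(2.0) * (y == 1.0)
    return float(np.sum(ll * mask))


class _Layout:
    """Batched per-sibship-size arrays for PIRLS."""

    def __init__(self, bundle: DatasetBundle, spec: GeneModelSpec):
        study, block = bundle.study, bundle.genotypes
        self.snp_ids = list(block.snp_ids)
        self.genes = block.genes
        self.gene_index = block.gene_index()
        self.n_snps = len(self.snp_ids)
        self.n_genes = len(self.genes)
        self.subject_ids = study.subject_ids

        # fixed-effect column names
        if spec.intercept_mode == "per_snp":
            self.coef_names = [f"snp:{s}" for s in self.snp_ids]
        elif spec.intercept_mode == "per_gene":
            self.coef_names = [f"gene:{g}" for g in self.genes]
        else:
            self.coef_names = ["intercept"]
        self.n_intercepts = len(self.coef_names)
        self.coef_names += list(spec.genotype_covariates)
        self.n_coef = len(self.coef_names)

        covars = np.column_stack(
            [study.column(c) for c in spec.genotype_covariates]
        ) if spec.genotype_covariates else np.zeros((study.n_subjects, 0))
        if np.isnan(covars).any():
            raise DesignError("missing values in genotype-model covariates")

        # per-observation intercept design for one subject's SNP rows
        if spec.intercept_mode == "per_snp":
            snp_design = np.eye(self.n_snps)
        elif spec.intercept_mode == "per_gene":
            snp_design = np.zeros((self.n_snps, self.n_genes))
            snp_design[np.arange(self.n_snps), self.gene_index] = 1.0
        else:
            snp_design = np.ones((self.n_snps, 1))

        sib = pd.Series(study.sibship_ids)
        members = sib.groupby(sib, sort=True).indices  # label -> row positions
        self.cluster_labels = list(members)
        by_size: dict[int, list] = {}
        for lab in self.cluster_labels:
            by_size.setdefault(len(members[lab]), []).append(lab)

        mat = block.matrix
        self.groups = []
        for size in sorted(by_size):
            labs = by_size[size]
            rows = np.array([members[l] for l in labs])  # (m, size)
            y = mat[rows].reshape(len(labs), size * self.n_snps)
            mask = (~np.isnan(y)).astype(float)
            y = np.nan_to_num(y)
            # X: intercept block tiled per subject + covariates repeated per SNP
            m = len(labs)
            X = np.zeros((m, size * self.n_snps, self.n_coef))
            for j in range(size):
                sl = slice(j * self.n_snps, (j + 1) * self.n_snps)
                X[:, sl, :self.n_intercepts] = snp_design
                if covars.shape[1]:
                    X[:, sl, self.n_intercepts:] = covars[rows[:, j]][:, None, :]
            self.groups.append({
                "size": size, "labels": labs, "rows": rows,
                "y": y, "mask": mask, "X": X,
            })
        self.n_obs = int(sum(g["mask"].sum() for g in self.groups))

    def random_designs(self, active: tuple):
        out = []
        for g in self.groups:
            Z, comp = _local_random_design(g["size"], self.n_snps,
                                           self.gene_index, active)
            out.append((Z, comp))
        return out


def _pirls(layout, designs, dinvs, beta, bs, spec, update_beta=True):
    """Joint Newton (PIRLS) for fixed effects and random-effect modes.

    ``dinvs`` holds, per sibship-size group, the prior precision of each
    local random-effect column.  Solves the penalized binomial problem by
    block elimination: the random-effects Hessian is block-diagonal by
    sibship, so each Newton step costs a batch of small dense Cholesky
    factorizations plus one p x p solve for the fixed effects.

    Returns (beta, bs, laplace_loglik, converged, n_iter).
    """
    groups = layout.groups

    def objective(beta, bs):
        total = 0.0
        for g, (Z, _), dinv, b in zip(groups, designs, dinvs, bs):
            eta = g["X"] @ beta + b @ Z.T
            total += _binom2_loglik(g["y"], eta, g["mask"])
            total -= 0.5 * float(np.sum(b * b * dinv))
        return total

    obj = objective(beta, bs)
    converged = False
    it = 0
    for it in range(1, spec.inner_max_iter + 1):
        A = np.zeros((layout.n_coef, layout.n_coef))
        grad_beta = np.zeros(layout.n_coef)
        chols, Bs, grads_b = [], [], []
        max_grad = 0.0
        for g, (Z, comp), dinv, b in zip(groups, designs, dinvs, bs):
            eta = g["X"] @ beta + b @ Z.T
            mu = 2.0 * expit(eta)
            w = (0.5 * mu * (2.0 - mu) + 1e-12) * g["mask"]
            r = (g["y"] - mu) * g["mask"]
            gb = r @ Z - b * dinv
            WZ = w[:, :, None] * Z              # (m, n_obs, q)
            C = np.matmul(Z.T, WZ)              # batched Z' W Z
            C[:, np.arange(len(comp)), np.arange(len(comp))] += dinv
            B = np.matmul(np.swapaxes(g["X"], 1, 2), WZ)  # (m, p, q)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError("indefinite random-effects Hessian",
                                       (beta, bs)) from exc
            chols.append(L)
            Bs.append(B)
            grads_b.append(gb)
            if update_beta:
                p = g["X"].shape[2]
                Xf = g["X"].reshape(-1, p)
                A += Xf.T @ (w.reshape(-1)[:, None] * Xf)
                grad_beta += Xf.T @ r.reshape(-1)
            if gb.size:
                max_grad = max(max_grad, float(np.abs(gb).max()))
        if update_beta:
            max_grad = max(max_grad, float(np.abs(grad_beta).max())
                           if grad_beta.size else 0.0)
        if max_grad < spec.grad_tol and it > 1:
            converged = True
            break

        if update_beta:
            # Schur complement over the fixed effects
            S = A.copy()
            rhs = grad_beta.copy()
            for L, B, gb in zip(chols, Bs, grads_b):
                if not L.shape[1]:
                    continue
                CinvBt = np.linalg.solve(
                    np.swapaxes(L, 1, 2),
                    np.linalg.solve(L, np.swapaxes(B, 1, 2)))
                S -= np.tensordot(B, CinvBt, axes=([0, 2], [0, 1]))
                Cinvg = np.linalg.solve(
                    np.swapaxes(L, 1, 2),
                    np.linalg.solve(L, gb[..., None]))[..., 0]
                rhs -= np.tensordot(B, Cinvg, axes=([0, 2], [0, 1]))
            try:
                dbeta = np.linalg.solve(S + 1e-10 * np.eye(len(S)), rhs)
            except np.linalg.LinAlgError as exc:
                raise DesignError("singular fixed-effects design") from exc
        else:
            dbeta = np.zeros(layout.n_coef)

        dbs = []
        for L, B, gb in zip(chols, Bs, grads_b):
            if not L.shape[1]:
                dbs.append(np.zeros_like(gb))
                continue
            rhs_b = gb - np.einsum("cps,p->cs", B, dbeta)
            db = np.linalg.solve(
                np.swapaxes(L, 1, 2), np.linalg.solve(L, rhs_b[..., None]))[..., 0]
            dbs.append(db)

        step = 1.0
        for _ in range(30):
            cand_beta = beta + step * dbeta
            cand_bs = [b + step * db for b, db in zip(bs, dbs)]
            cand_obj = objective(cand_beta, cand_bs)
            if cand_obj >= obj - 1e-12:
                break
            step *= 0.5
        else:
            converged = max_grad < 10 * spec.grad_tol
            break
        rel = abs(cand_obj - obj) / (abs(obj) + 1.0)
        beta, bs, obj = cand_beta, cand_bs, cand_obj
        if rel < spec.rel_tol and max_grad < 10 * spec.grad_tol:
            converged = True
            break

    # Laplace approximation at the mode: profile term -1/2 log|Z'WZ + D^-1|
    # plus the prior normalisation, which reduces to -1/2 sum log sigma2.
    ll = 0.0
    for g, (Z, comp), dinv, b in zip(groups, designs, dinvs, bs):
        eta = g["X"] @ beta + b @ Z.T
        ll += _binom2_loglik(g["y"], eta, g["mask"])
        if len(comp):
            mu = 2.0 * expit(eta)
            w = (0.5 * mu * (2.0 - mu) + 1e-12) * g["mask"]
            C = np.matmul(Z.T, w[:, :, None] * Z)
            C[:, np.arange(len(comp)), np.arange(len(comp))] += dinv
            L = np.linalg.cholesky(C)
            logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
            ll += -0.5 * float(np.sum(b * b * dinv))
            # prior normalisation, once per cluster: -1/2 sum log sigma2
            ll += 0.5 * len(b) * float(np.sum(np.log(dinv)))
            ll -= 0.5 * float(logdet)
    return beta, bs, ll, converged, it


class GenotypePathwayModel:
    """Stage-1 model: Binomial(2, pi) genotypes with nested random effects.

    Parameters
    ----------
    bundle
        Validated dataset (monomorphic SNPs must be filtered out first).
    spec
        Model options; defaults to estimating all applicable components.

    Examples
    --------
    >>> model = GenotypePathwayModel(bundle, GeneModelSpec(
    ...     include_sibship_effect=False, genotype_covariates=("Smoking",)))
    >>> res = model.fit()
    >>> eb = res.empirical_bayes()   # subjects x genes DataFrame
    """

    def __init__(self, bundle: DatasetBundle, spec: GeneModelSpec | None = None):
        self.bundle = bundle
        self.spec = spec or GeneModelSpec()
        if bundle.genotypes.n_snps == 0:
            raise EmptyPathwayError("no SNPs in bundle")
        mat = bundle.genotypes.matrix
        with np.errstate(invalid="ignore"):
            mono = np.nanmin(mat, axis=0) == np.nanmax(mat, axis=0)
        if np.any(mono | np.all(np.isnan(mat), axis=0)):
            raise DesignError(
                "monomorphic SNP columns present; run filter_monomorphic first")
        self.layout = _Layout(bundle, self.spec)
        sizes = [g["size"] for g in self.layout.groups]
        if self.spec.include_sibship_effect and max(sizes) == 1 and \
                self._is_free("sibship") and self._is_free("subject"):
            warnings.warn(
                "all sibships are singletons: sibship and subject variances "
                "are confounded; consider include_sibship_effect=False",
                stacklevel=2)

    def _is_free(self, comp: str) -> bool:
        fx = self.spec.fix_variance or {}
        if comp == "sibship" and not self.spec.include_sibship_effect:
            return False
        return comp not in fx

    def fit(self) -> "GeneModelResults":
        """Maximise the Laplace marginal likelihood; deterministic."""
        spec = self.spec
        fx = dict(spec.fix_variance or {})
        if not spec.include_sibship_effect:
            fx["sibship"] = 0.0
        free = [c for c in COMPONENTS if c not in fx]

        beta0 = self._initial_beta()
        state = {"beta": beta0, "bs": None, "active": None}

        def solve(variances):
            active = tuple(c for c in COMPONENTS if variances[c] > 0.0)
            designs = self.layout.random_designs(active)
            comp_var = np.array([max(variances[c], 1e-300) for c in COMPONENTS])
            dinvs = [1.0 / comp_var[comp] if len(comp) else np.zeros(0)
                     for (_, comp) in designs]
            if state["active"] == active and state["bs"] is not None:
                bs = state["bs"]
            else:
                bs = [np.zeros((len(g["labels"]), Z.shape[1]))
                      for g, (Z, _) in zip(self.layout.groups, designs)]
            beta, bs, ll, conv, n_it = _pirls(
                self.layout, designs, dinvs, state["beta"], bs, spec)
            state.update(beta=beta, bs=bs, active=active)
            return beta, bs, ll, conv, n_it, designs

        def objective(log_var):
            variances = dict(fx)
            for c, lv in zip(free, log_var):
                variances[c] = float(np.exp(np.clip(lv, -16.0, 5.0)))
            for c in COMPONENTS:
                variances.setdefault(c, 0.0)
            try:
                _, _, ll, conv, _, _ = solve(variances)
            except ConvergenceError:
                return 1e10
            return -ll if np.isfinite(ll) else 1e10

        n_outer = 0
        if free:
            x0 = np.full(len(free), np.log(spec.variance_start))
            opt = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7,
                         "maxfev": spec.max_iter * max(1, len(free))})
            n_outer = opt.nfev
            log_var = opt.x
            outer_ok = bool(opt.success)
        else:
            log_var = np.zeros(0)
            outer_ok = True

        variances = dict(fx)
        for c, lv in zip(free, log_var):
            v = float(np.exp(np.clip(lv, -16.0, 5.0)))
            variances[c] = 0.0 if v < _VAR_FLOOR else v
        for c in COMPONENTS:
            variances.setdefault(c, 0.0)

        state["active"] = None  # force clean final solve on the clamped set
        state["bs"] = None
        beta, bs, ll, conv, n_it, designs = solve(variances)
        if not conv:
            raise ConvergenceError(
                f"PIRLS did not converge in {spec.inner_max_iter} iterations",
                (beta, variances))
        return GeneModelResults(self, beta, bs, designs, variances, ll,
                                converged=conv and outer_ok,
                                n_iterations=n_outer + n_it)

    def _initial_beta(self) -> np.ndarray:
        block = self.bundle.genotypes
        freq = np.clip(block.coded_allele_frequency(), 1e-3, 1 - 1e-3)
        beta = np.zeros(self.layout.n_coef)
        if self.spec.intercept_mode == "per_snp":
            beta[:self.layout.n_intercepts] = np.log(freq / (1 - freq))
        else:
            mean_logit = float(np.mean(np.log(freq / (1 - freq))))
            beta[:self.layout.n_intercepts] = mean_logit
        return beta


class GeneModelResults:
    """Fitted stage-1 model.

    Attributes
    ----------
    params : pandas.Series
        Fixed effects on the logit scale (per-SNP intercepts and genotype
        covariate slopes).
    variance_components : pandas.Series
        ``sibship``, ``subject`` and ``gene`` variances (0 at the boundary
        or when excluded).
    llf : float
        Laplace-approximate marginal log-likelihood.
    """

    def __init__(self, model, beta, bs, designs, variances, llf,
                 converged, n_iterations):
        self.model = model
        layout = model.layout
        self.params = pd.Series(beta, index=layout.coef_names)
        self.variance_components = pd.Series(
            {c: variances[c] for c in COMPONENTS})
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iterations = int(n_iterations)
        self._unpack_modes(bs, designs)

    def _unpack_modes(self, bs, designs):
        layout = self.model.layout
        n = len(layout.subject_ids)
        eb = np.zeros((n, layout.n_genes))
        subj = np.zeros(n)
        sib = {}
        for g, (Z, comp), b in zip(layout.groups, designs, bs):
            size = g["size"]
            for c_i, lab in enumerate(g["labels"]):
                k = 0
                if len(comp) and comp[0] == 0:
                    sib[lab] = float(b[c_i, 0])
                    k = 1
                for j in range(size):
                    row = g["rows"][c_i, j]
                    if 1 in comp:
                        subj[row] = float(b[c_i, k])
                        k += 1
                    if 2 in comp:
                        eb[row] = b[c_i, k:k + layout.n_genes]
                        k += layout.n_genes
        self._eb = pd.DataFrame(eb, index=layout.subject_ids,
                                columns=layout.genes)
        self._subj_modes = pd.Series(subj, index=layout.subject_ids)
        self._sib_modes = {lab: sib.get(lab, 0.0)
                           for lab in layout.cluster_labels}

    # -- public API ---------------------------------------------------------

    def empirical_bayes(self) -> pd.DataFrame:
        """Subjects x genes EB matrix (conditional modes of ``b_ijg``)."""
        if not self.converged:
            raise ConvergenceError("fit did not converge; EB estimates "
                                   "are unreliable", self)
        return self._eb.copy()

    @property
    def eb_matrix(self) -> pd.DataFrame:
        return self.empirical_bayes()

    def conditional_modes(self, bundle: DatasetBundle | None = None
                          ) -> "GeneModelResults":
        """Re-solve the random-effect modes at the fitted parameters.

        ``bundle`` may hold modified genotypes for the same subjects and
        SNPs (e.g. to examine how the EB summary responds to an extra
        minor allele); fixed effects and variance components are held at
        their fitted values.
        """
        model = self.model
        if bundle is None:
            bundle = model.bundle
        layout = _Layout(bundle, model.spec)
        if layout.coef_names != model.layout.coef_names:
            raise DesignError("modified bundle changes the fixed design")
        variances = self.variance_components.to_dict()
        active = tuple(c for c in COMPONENTS if variances[c] > 0.0)
        designs = layout.random_designs(active)
        comp_var = np.array([max(variances[c], 1e-300) for c in COMPONENTS])
        dinvs = [1.0 / comp_var[comp] if len(comp) else np.zeros(0)
                 for (_, comp) in designs]
        bs = [np.zeros((len(g["labels"]), Z.shape[1]))
              for g, (Z, _) in zip(layout.groups, designs)]
        beta = self.params.to_numpy()
        beta, bs, ll, conv, n_it = _pirls(
            layout, designs, dinvs, beta, bs, model.spec, update_beta=False)
        shadow = object.__new__(GeneModelResults)
        shadow.model = type("_M", (), {"layout": layout,
                                       "spec": model.spec,
                                       "bundle": bundle})()
        shadow.params = self.params.copy()
        shadow.variance_components = self.variance_components.copy()
        shadow.llf = float(ll)
        shadow.converged = bool(conv)
        shadow.n_iterations = n_it
        shadow._unpack_modes(bs, designs)
        return shadow

    def predict_probability(self, subject_id: str, snp_id: str) -> float:
        """Plug-in genotype probability pi_ijgs at the conditional modes."""
        layout = self.model.layout
        try:
            row = int(np.where(layout.subject_ids == str(subject_id))[0][0])
        except IndexError:
            raise KeyError(f"unknown subject {subject_id!r}") from None
        try:
            s = layout.snp_ids.index(str(snp_id))
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None
        gene = layout.genes[layout.gene_index[s]]
        spec = self.model.spec
        if spec.intercept_mode == "per_snp":
            eta = self.params[f"snp:{snp_id}"]
        elif spec.intercept_mode == "per_gene":
            eta = self.params[f"gene:{gene}"]
        else:
            eta = self.params["intercept"]
        study = self.model.bundle.study
        for c in spec.genotype_covariates:
            eta += self.params[c] * study.column(c)[row]
        sib = study.sibship_ids[row]
        eta += self._sib_modes.get(sib, 0.0)
        eta += self._subj_modes.iloc[row]
        eta += self._eb.iloc[row][gene]
        return float(expit(eta))

    def summary(self) -> str:
        lines = ["Nested random-effects genotype model (Laplace)",
                 "=" * 47,
                 f"subjects: {len(self.model.layout.subject_ids)}   "
                 f"SNPs: {self.model.layout.n_snps}   "
                 f"genes: {self.model.layout.n_genes}",
                 f"log-likelihood: {self.llf:.4f}   "
                 f"converged: {self.converged}",
                 "",
                 "Variance components:",
                 self.variance_components.to_string(float_format="%.4f"),
                 "",
                 "Fixed effects (logit scale):",
                 self.params.to_string(float_format="%.4f")]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (EB matrix written separately)."""
        return {
            "fixed_effects": self.params.to_dict(),
            "variance_components": self.variance_components.to_dict(),
            "log_likelihood": self.llf,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "genes": list(self.model.layout.genes),
        }
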