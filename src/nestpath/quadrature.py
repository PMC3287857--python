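"""Exact-to-quadrature marginal likelihood for tiny genotype models.

Test oracle for the Laplace fit in :mod:`nestpath.genemodel`: the nested
random-effects integral is evaluated by adaptive Gauss-Hermite quadrature,
exploiting the hierarchy — given the sibship effect the subjects are
independent, and given the subject effect the genes are independent — so
only one-dimensional integrals are ever taken.  Each 1-D integral is
centred at the mode of its integrand and scaled by the local curvature
(standard adaptive GH), which makes 10-15 nodes ample.

Intended for fixtures only; the per-sibship random-effect dimension is
capped at 8.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, roots_hermite

from .exceptions import SizeError

__all__ = ["loglik_oracle"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_binom2(y, eta):
    return y * eta - 2.0 * np.logaddexp(0.0, eta) + np.log(2.0) * (y == 1.0)


def _agh_log_integral(log_f, sigma, n_points):
    """log of  integral  N(t; 0, sigma^2) * exp(log_f(t)) dt  by adaptive GH.

    ``log_f`` must accept a vector of evaluation points.
    """
    if sigma == 0.0:
        return float(log_f(np.zeros(1))[0])
    x, wgt = roots_hermite(n_points)

    def neg_log_integrand(t):
        return -(log_f(np.array([t]))[0]
                 - 0.5 * t * t / sigma ** 2 - np.log(sigma) - _LOG_SQRT_2PI)

    res = optimize.minimize_scalar(neg_log_integrand,
                                   bounds=(-12 * sigma, 12 * sigma),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    mu = float(res.x)
    h = 1e-4 * max(sigma, 1.0)
    curv = (neg_log_integrand(mu + h) - 2.0 * neg_log_integrand(mu)
            + neg_log_integrand(mu - h)) / h ** 2
    scale = 1.0 / np.sqrt(max(curv, 1e-8))
    t = mu + np.sqrt(2.0) * scale * x
    log_integrand = (log_f(t) - 0.5 * t * t / sigma ** 2
                     - np.log(sigma) - _LOG_SQRT_2PI)
    # int g(t) dt ~= sqrt(2)*scale * sum w_k exp(x_k^2) g(t_k)
    return float(logsumexp(log_integrand + x ** 2 + np.log(wgt))
                 + 0.5 * np.log(2.0) + np.log(scale))


def loglik_oracle(bundle, fixed_effects, variance_components,
                  spec=None, quadrature_points: int = 15) -> float:
    """Marginal log-likelihood of the stage-1 model by nested adaptive GH.

    Parameters
    ----------
    bundle : DatasetBundle
    fixed_effects : mapping or pandas.Series
        Coefficients named as in :class:`~nestpath.genemodel.GeneModelResults`
        (``snp:<id>`` / ``gene:<label>`` / ``intercept`` plus covariates).
    variance_components : mapping
        ``{"sibship": .., "subject": .., "gene": ..}``; zeros collapse the
        corresponding integral.
    spec : GeneModelSpec, optional
        Supplies intercept mode / covariates; defaults match GeneModelSpec.
    quadrature_points : int
        Nodes per one-dimensional integral.
    """
    from .genemodel import GeneModelSpec, _Layout  # deferred: avoid cycle

    spec = spec or GeneModelSpec()
    layout = _Layout(bundle, spec)
    beta = np.asarray([fixed_effects[c] for c in layout.coef_names], float)
    s2_sib = float(variance_components.get("sibship", 0.0))
    if not spec.include_sibship_effect:
        s2_sib = 0.0
    s2_subj = float(variance_components.get("subject", 0.0))
    s2_gene = float(variance_components.get("gene", 0.0))
    sig_sib, sig_subj, sig_gene = np.sqrt([s2_sib, s2_subj, s2_gene])

    gene_index = layout.gene_index
    n_genes = layout.n_genes
    total = 0.0
    for grp in layout.groups:
        size = grp["size"]
        dim = (s2_sib > 0) + size * ((s2_subj > 0) + n_genes * (s2_gene > 0))
        if dim > 8:
            raise SizeError(
                f"per-sibship random-effect dimension {dim} exceeds the "
                "oracle cap of 8")
        for c_i in range(len(grp["labels"])):
            offsets = grp["X"][c_i] @ beta          # (size * S,)
            y = grp["y"][c_i]
            mask = grp["mask"][c_i].astype(bool)

            def log_subject(j, shift_scalar_vec):
                """log of subject j's likelihood at sib+subj shifts (vector)."""
                sl = slice(j * layout.n_snps, (j + 1) * layout.n_snps)
                off = offsets[sl]
                yj = y[sl]
                mj = mask[sl]
                out = np.zeros(len(shift_scalar_vec))
                for k, shift in enumerate(shift_scalar_vec):
                    acc = 0.0
                    for g in range(n_genes):
                        sel = (gene_index == g) & mj
                        if not sel.any():
                            continue

                        def log_gene(t, sel=sel, off=off, yj=yj, shift=shift):
                            eta = off[sel][None, :] + shift + t[:, None]
                            return _log_binom2(yj[sel][None, :], eta).sum(axis=1)

                        acc += _agh_log_integral(log_gene, sig_gene,
                                                 quadrature_points)
                    out[k] = acc
                return out

            def log_subject_marginal(j, sib_vals):
                """Integrate subject j's likelihood over b_ij at each b_i."""
                out = np.zeros(len(sib_vals))
                for k, bi in enumerate(sib_vals):
                    def log_f(u, j=j, bi=bi):
                        return log_subject(j, bi + u)
                    out[k] = _agh_log_integral(log_f, sig_subj,
                                               quadrature_points)
                return out

            def log_cluster(sib_vals):
                return sum(log_subject_marginal(j, sib_vals)
                           for j in range(size))

            total += _agh_log_integral(log_cluster, sig_sib,
                                       quadrature_points)
    return float(total)
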