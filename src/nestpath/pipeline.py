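"""End-to-end orchestration: read -> filter -> stage 1 -> stage 2 -> tests.

A :class:`RunConfig` collects the file paths and analysis options; the
stage-1 fit is computed once and reused across traits (the pathway EB
summaries do not depend on the phenotype).  All artifacts are written
with the config hash that produced them, and a structured log records
versions, seeds and convergence diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .data import filter_monomorphic, read_dataset
from .exceptions import NestpathError
from .genemodel import GeneModelSpec, GenotypePathwayModel
from .inference import TestReport, full_report
from .phenotype import PathwayPhenotypeModel, PhenotypeModelSpec

__all__ = ["RunConfig", "run_pipeline", "render_report"]

logger = logging.getLogger("nestpath")


@dataclass
class RunConfig:
    """Configuration of a full two-stage analysis run."""

    genotypes: str
    pedigree: str
    phenotypes: str
    gene_map: str
    out_dir: str
    dialect: str = "tsv"
    trait: str = "Q"
    trait_type: str = "quantitative"
    covariates: tuple = ("Age", "Smoking")
    genotype_covariates: tuple = ()
    interactions: tuple = ()          # (gene, covariate) pairs
    include_sibship_effect: bool = True
    alpha: float = 0.05
    log_level: str = "INFO"
    seed: int = 0                     # for any stochastic step

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        self.genotype_covariates = tuple(self.genotype_covariates)
        self.interactions = tuple(tuple(t) for t in self.interactions)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat key: value (YAML) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise NestpathError(f"unknown config keys: {sorted(unknown)}")
        if "interactions" in raw:
            raw["interactions"] = [
                tuple(t.split(":")) if isinstance(t, str) else tuple(t)
                for t in raw["interactions"]]
        return cls(**raw)

    def validate(self) -> None:
        for key in ("genotypes", "pedigree", "phenotypes", "gene_map"):
            path = getattr(self, key)
            if not os.path.exists(path):
                raise NestpathError(f"{key} file not found: {path}")
        os.makedirs(self.out_dir, exist_ok=True)
        if not os.access(self.out_dir, os.W_OK):
            raise NestpathError(f"output directory not writable: "
                                f"{self.out_dir}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, gene_fit=None):
    """Execute the two-stage analysis; returns (gene_fit, pheno_fit, report).

    ``gene_fit`` may be a cached stage-1 result from a previous trait's
    run on the same data — the stage-1 model is phenotype-free.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    chash = config.hash()
    logger.info("nestpath %s  config %s", _version, chash)

    try:
        bundle = read_dataset(config.genotypes, config.pedigree,
                              config.phenotypes, config.gene_map,
                              dialect=config.dialect)
    except NestpathError as exc:
        raise type(exc)(f"[stage: read] {exc}") from exc
    bundle, removed = filter_monomorphic(bundle)
    logger.info("read %d subjects, %d SNPs (%d monomorphic removed)",
                bundle.n_subjects, bundle.genotypes.n_snps, len(removed))

    if gene_fit is None:
        gspec = GeneModelSpec(
            include_sibship_effect=config.include_sibship_effect,
            genotype_covariates=config.genotype_covariates)
        try:
            gene_fit = GenotypePathwayModel(bundle, gspec).fit()
        except NestpathError as exc:
            raise type(exc)(f"[stage: gene-model] {exc}") from exc
        logger.info("stage 1: llf=%.3f variances=%s",
                    gene_fit.llf, gene_fit.variance_components.to_dict())

    pspec = PhenotypeModelSpec(
        config.trait, config.trait_type, covariates=config.covariates,
        interactions=config.interactions)
    try:
        pheno_fit = PathwayPhenotypeModel(
            bundle.study, gene_fit.empirical_bayes(), pspec).fit()
        report = full_report(pheno_fit, alpha=config.alpha)
    except NestpathError as exc:
        raise type(exc)(f"[stage: phenotype] {exc}") from exc
    logger.info("stage 2: pathway W=%.3f df=%d p=%.3g",
                report.pathway_stat, report.pathway_df, report.pathway_p)

    _write_artifacts(config, chash, gene_fit, pheno_fit, report)
    return gene_fit, pheno_fit, report


def _write_artifacts(config, chash, gene_fit, pheno_fit, report):
    out = config.out_dir
    meta = {"nestpath_version": _version, "config_hash": chash,
            "seed": config.seed,
            "stage1_converged": gene_fit.converged,
            "stage2_converged": pheno_fit.converged}
    gd = gene_fit.to_dict()
    gd["config_hash"] = chash
    with open(os.path.join(out, "gene_model.json"), "w") as fh:
        json.dump(gd, fh, indent=1)
    eb = gene_fit.empirical_bayes()
    eb.index.name = f"subject_id (config {chash})"
    eb.to_csv(os.path.join(out, "eb_matrix.tsv"), sep="\t")
    pd_ = pheno_fit.to_dict()
    pd_["config_hash"] = chash
    with open(os.path.join(out, "phenotype_model.json"), "w") as fh:
        json.dump(pd_, fh, indent=1)
    rd = report.to_dict()
    rd["config_hash"] = chash
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(rd, fh, indent=1)
    with open(os.path.join(out, "report.tsv"), "w") as fh:
        fh.write(f"# config {chash}\n")
        fh.write(render_report(report, style="tsv"))
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _fmt_p(p: float) -> str:
    if np.isnan(p):
        return "NA"
    if p != 0.0 and p < 1e-4:
        exp = int(np.floor(np.log10(p)))
        mant = p / 10.0 ** exp
        return f"{mant:.1f} x 10^{exp}"
    return f"{p:.4g}"


def render_report(report: TestReport, style: str = "tsv") -> str:
    """Render a report as rows = genes, interactions, pathway.

    ``style`` is ``"tsv"`` or ``"markdown"``; p-values below 1e-4 are
    shown in scientific notation (``4.9 x 10^-10``).
    """
    frame = report.to_frame()
    rows = []
    for name, row in frame.iterrows():
        est = "" if np.isnan(row["estimate"]) else f"{row['estimate']:.4f}"
        se = "" if np.isnan(row["se"]) else f"{row['se']:.4f}"
        rows.append((str(name), est, se, _fmt_p(row["p"])))
    header = ("term", "estimate", "se", "p")
    if style == "tsv":
        lines = ["\t".join(header)]
        lines += ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if style == "markdown":
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join(["---"] * 4) + "|"]
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown style {style!r}")
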