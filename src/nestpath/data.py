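"""Study data model and I/O.

The package analyses a *pathway*: a set of G genes, gene g contributing
S_g SNPs, typed on subjects organised in sibships (clusters of siblings;
singleton sibships represent unrelated subjects).  Genotypes are additive
minor-allele counts in {0, 1, 2}; missing entries are kept as missing.

Three containers:

* :class:`StudyFrame` — one row per subject: sibship label, covariates
  and phenotypes.
* :class:`GenotypeBlock` — the subjects x SNPs genotype matrix plus the
  SNP -> gene map.
* :class:`DatasetBundle` — the two aligned, with provenance text.

Readers accept simple TSV, PLINK ``.raw``/``.fam``, and (optionally) VCF.
At read time every SNP column is oriented so that the coded allele is the
minor allele: columns whose coded-allele frequency exceeds 0.5 are flipped
``w -> 2 - w`` (ties at exactly 0.5 keep their original orientation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DataFormatError,
    EmptyPathwayError,
    MappingError,
)

__all__ = [
    "StudyFrame",
    "GenotypeBlock",
    "DatasetBundle",
    "read_dataset",
    "write_dataset",
    "filter_monomorphic",
    "orient_minor_allele",
]

_MISSING = "NA"


@dataclass
class StudyFrame:
    """Per-subject table: sibship membership, covariates, phenotypes.

    Parameters
    ----------
    subjects
        DataFrame indexed by unique string ``subject_id`` with a string
        column ``sibship_id`` plus any number of covariate / phenotype
        columns (numeric; binary phenotypes coded 0/1).
    """

    subjects: pd.DataFrame

    def __post_init__(self):
        df = self.subjects
        if "sibship_id" not in df.columns:
            raise DataFormatError("StudyFrame requires a 'sibship_id' column")
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()].tolist()
            raise DataFormatError(f"duplicate subject ids: {dup[:5]}")
        df.index = df.index.astype(str)
        df["sibship_id"] = df["sibship_id"].astype(str)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects.index.to_numpy()

    @property
    def sibship_ids(self) -> np.ndarray:
        return self.subjects["sibship_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def column(self, name: str) -> np.ndarray:
        if name not in self.subjects.columns:
            raise KeyError(f"no such column: {name!r}")
        return self.subjects[name].to_numpy(dtype=float)

    def check_binary(self, name: str) -> None:
        """Validate that a phenotype column is 0/1 (missing allowed)."""
        v = self.column(name)
        v = v[~np.isnan(v)]
        if not np.isin(v, [0.0, 1.0]).all():
            raise DataFormatError(f"phenotype {name!r} is not coded 0/1")


@dataclass
class GenotypeBlock:
    """Subjects x SNPs additive genotype matrix with a SNP -> gene map.

    ``matrix`` is float with NaN for missing; non-missing entries must be
    0, 1 or 2.  Row order is the bundle's subject order.
    """

    matrix: np.ndarray
    snp_ids: list[str]
    gene_of_snp: dict[str, str]
    minor_allele_coded: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.snp_ids = [str(s) for s in self.snp_ids]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.snp_ids):
            raise DataFormatError("genotype matrix shape does not match snp_ids")
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, [0.0, 1.0, 2.0]).all():
            bad = sorted(set(vals[~np.isin(vals, [0.0, 1.0, 2.0])]))
            raise DataFormatError(f"genotype codes outside {{0,1,2}}: {bad[:5]}")
        missing = [s for s in self.snp_ids if s not in self.gene_of_snp]
        if missing:
            raise MappingError(f"SNPs without gene assignment: {missing[:5]}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def genes(self) -> list[str]:
        """Gene labels in order of first appearance among the SNP columns."""
        seen: dict[str, None] = {}
        for s in self.snp_ids:
            seen.setdefault(self.gene_of_snp[s], None)
        return list(seen)

    def gene_index(self) -> np.ndarray:
        """Index of each SNP's gene within :attr:`genes`."""
        order = {g: i for i, g in enumerate(self.genes)}
        return np.array([order[self.gene_of_snp[s]] for s in self.snp_ids])

    def coded_allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of the coded allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0) / 2.0


@dataclass
class DatasetBundle:
    """A validated (StudyFrame, GenotypeBlock) pair."""

    study: StudyFrame
    genotypes: GenotypeBlock
    provenance: str = ""

    def __post_init__(self):
        if self.genotypes.matrix.shape[0] != self.study.n_subjects:
            raise AlignmentError(
                f"genotype rows ({self.genotypes.matrix.shape[0]}) != "
                f"subjects ({self.study.n_subjects})"
            )

    @property
    def n_subjects(self) -> int:
        return self.study.n_subjects


def orient_minor_allele(block: GenotypeBlock) -> tuple[GenotypeBlock, list[str]]:
    """Flip SNP columns coded on the major allele (frequency > 0.5).

    Ties at exactly 0.5 keep their original orientation.  Returns the
    oriented block and the list of flipped SNP ids.
    """
    freq = block.coded_allele_frequency()
    flip = freq > 0.5
    mat = block.matrix.copy()
    mat[:, flip] = 2.0 - mat[:, flip]
    flipped = [s for s, f in zip(block.snp_ids, flip) if f]
    return (
        replace(block, matrix=mat, minor_allele_coded=True),
        flipped,
    )


# ---------------------------------------------------------------------------
# readers


def _read_tsv_genotypes(path) -> tuple[pd.Index, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[_MISSING])
    df = df.set_index(df.columns[0])
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataFormatError(f"non-numeric genotype entry in {path}: {exc}") from exc
    return df.index.astype(str), mat, [str(c) for c in df.columns]


def _read_plink_raw(path) -> tuple[pd.Index, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str}, na_values=[_MISSING])
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    absent = [c for c in meta if c not in df.columns]
    if absent:
        raise DataFormatError(f"PLINK .raw missing columns {absent} in {path}")
    snp_cols = [c for c in df.columns if c not in meta]
    # .raw columns are named <snp>_<countedallele>; strip the allele suffix
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    mat = df[snp_cols].to_numpy(dtype=float)
    return pd.Index(df["IID"].astype(str)), mat, snp_ids


def _read_vcf(path) -> tuple[pd.Index, np.ndarray, list[str]]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise DataFormatError("VCF import requires cyvcf2") from exc
    vcf = VCF(str(path))
    subjects = pd.Index([str(s) for s in vcf.samples])
    cols, ids = [], []
    # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    dose = np.array([0.0, 1.0, np.nan, 2.0])
    for i, var in enumerate(vcf):
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        cols.append(dose[var.gt_types])
    if not cols:
        raise DataFormatError(f"no variants in {path}")
    return subjects, np.column_stack(cols), ids


def _read_pedigree(path) -> pd.DataFrame:
    """Read sibship assignment from a .fam file or a two-column TSV.

    PLINK ``.fam`` rows are FID IID PAT MAT SEX PHENO; any parent links are
    collapsed to the sibship label (FID).  A TSV must have a header with
    ``subject_id`` and ``sibship_id`` columns.
    """
    with open(path) as fh:
        first = fh.readline()
    if "subject_id" in first and "sibship_id" in first:
        ped = pd.read_csv(path, sep="\t", dtype=str)
        ped = ped[["subject_id", "sibship_id"]]
    else:
        fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        if fam.shape[1] < 2:
            raise DataFormatError(f"unrecognised pedigree format in {path}")
        ped = pd.DataFrame({"subject_id": fam[1], "sibship_id": fam[0]})
    if ped["subject_id"].duplicated().any():
        raise DataFormatError(f"duplicate subject ids in pedigree {path}")
    return ped.set_index("subject_id")


def _read_gene_map(path) -> dict[str, str]:
    gm = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "gene"}.issubset(gm.columns):
        raise MappingError(f"gene map {path} must have columns snp_id, gene")
    if gm["snp_id"].duplicated().any():
        dup = gm.loc[gm["snp_id"].duplicated(), "snp_id"].tolist()
        raise MappingError(f"SNP mapped to more than one gene: {dup[:5]}")
    return dict(zip(gm["snp_id"], gm["gene"]))


_GENOTYPE_READERS = {
    "tsv": _read_tsv_genotypes,
    "plink_raw": _read_plink_raw,
    "vcf": _read_vcf,
}


def read_dataset(
    genotype_path,
    pedigree_path,
    phenotype_path,
    gene_map_path,
    dialect: str = "tsv",
) -> DatasetBundle:
    """Read and validate a study dataset from its four component files.

    Subjects are taken in the order of the phenotype table; genotype and
    pedigree rows are aligned to that order.  Genotype columns are oriented
    to count minor alleles (flips recorded in ``provenance``).
    """
    if dialect not in _GENOTYPE_READERS:
        raise DataFormatError(f"unknown genotype dialect {dialect!r}")
    subjects_g, mat, snp_ids = _GENOTYPE_READERS[dialect](genotype_path)
    ped = _read_pedigree(pedigree_path)
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"subject_id": str},
                        na_values=[_MISSING], float_precision="round_trip")
    if "subject_id" not in pheno.columns:
        raise DataFormatError(f"phenotype table {phenotype_path} needs subject_id")
    pheno = pheno.set_index("subject_id")

    unknown = subjects_g.difference(pheno.index)
    if len(unknown):
        raise AlignmentError(
            f"subjects in genotype file absent from phenotype table: "
            f"{list(unknown)[:5]}"
        )
    missing_g = pheno.index.difference(subjects_g)
    if len(missing_g):
        raise AlignmentError(
            f"subjects without genotype rows: {list(missing_g)[:5]}"
        )
    missing_p = pheno.index.difference(ped.index)
    if len(missing_p):
        raise AlignmentError(f"subjects without pedigree rows: {list(missing_p)[:5]}")

    order = pheno.index
    row_of = {s: i for i, s in enumerate(subjects_g)}
    mat = mat[[row_of[s] for s in order]]

    gene_map = _read_gene_map(gene_map_path)
    unmapped = [s for s in snp_ids if s not in gene_map]
    if unmapped:
        raise MappingError(f"SNPs absent from gene map: {unmapped[:5]}")

    table = pheno.copy()
    table.insert(0, "sibship_id", ped.loc[order, "sibship_id"].to_numpy())
    study = StudyFrame(table)

    block = GenotypeBlock(mat, snp_ids, {s: gene_map[s] for s in snp_ids})
    block, flipped = orient_minor_allele(block)
    prov = f"read_dataset(dialect={dialect}, genotypes={os.fspath(genotype_path)})"
    if flipped:
        prov += f"; flipped to minor-allele coding: {','.join(flipped)}"
    return DatasetBundle(study, block, prov)


def filter_monomorphic(bundle: DatasetBundle) -> tuple[DatasetBundle, list[str]]:
    """Drop SNP columns that show no variation among non-missing calls.

    Genes left without SNPs disappear from the gene map.  Raises
    :class:`EmptyPathwayError` when nothing polymorphic remains.
    """
    mat = bundle.genotypes.matrix
    with np.errstate(invalid="ignore"):
        lo = np.nanmin(mat, axis=0)
        hi = np.nanmax(mat, axis=0)
    mono = (lo == hi) | np.isnan(lo)  # all-missing columns count as monomorphic
    keep = ~mono
    removed = [s for s, m in zip(bundle.genotypes.snp_ids, mono) if m]
    if not keep.any():
        raise EmptyPathwayError("every SNP is monomorphic; no pathway to analyse")
    kept_ids = [s for s, k in zip(bundle.genotypes.snp_ids, keep) if k]
    block = GenotypeBlock(
        mat[:, keep],
        kept_ids,
        {s: bundle.genotypes.gene_of_snp[s] for s in kept_ids},
        minor_allele_coded=bundle.genotypes.minor_allele_coded,
    )
    prov = bundle.provenance
    if removed:
        prov = (prov + "; " if prov else "") + \
            f"removed {len(removed)} monomorphic SNPs"
    return DatasetBundle(bundle.study, block, prov), removed


def _fmt(v) -> str:
    if pd.isna(v):
        return _MISSING
    if isinstance(v, (float, np.floating)):
        v = float(v)
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(v)  # shortest round-trip representation
    return str(v)


def write_dataset(bundle: DatasetBundle, out_prefix) -> dict[str, str]:
    """Write a bundle as four TSV files; inverse of :func:`read_dataset`.

    Returns a dict of the paths written (keys: genotypes, pedigree,
    phenotypes, gene_map).  ``read_dataset`` on the output reproduces the
    bundle exactly.
    """
    out_prefix = os.fspath(out_prefix)
    paths = {
        "genotypes": out_prefix + ".genotypes.tsv",
        "pedigree": out_prefix + ".pedigree.tsv",
        "phenotypes": out_prefix + ".phenotypes.tsv",
        "gene_map": out_prefix + ".genemap.tsv",
    }
    ids = bundle.study.subject_ids
    g = bundle.genotypes
    with open(paths["genotypes"], "w") as fh:
        fh.write("subject_id\t" + "\t".join(g.snp_ids) + "\n")
        for i, sid in enumerate(ids):
            row = "\t".join(_fmt(v) for v in g.matrix[i])
            fh.write(f"{sid}\t{row}\n")
    with open(paths["pedigree"], "w") as fh:
        fh.write("subject_id\tsibship_id\n")
        for sid, fid in zip(ids, bundle.study.sibship_ids):
            fh.write(f"{sid}\t{fid}\n")
    pheno_cols = [c for c in bundle.study.subjects.columns if c != "sibship_id"]
    with open(paths["phenotypes"], "w") as fh:
        fh.write("subject_id" + ("\t" if pheno_cols else "") + "\t".join(pheno_cols) + "\n")
        for sid in ids:
            vals = [_fmt(bundle.study.subjects.loc[sid, c]) for c in pheno_cols]
            fh.write(sid + ("\t" if vals else "") + "\t".join(vals) + "\n")
    with open(paths["gene_map"], "w") as fh:
        fh.write("snp_id\tgene\n")
        for s in g.snp_ids:
            fh.write(f"{s}\t{g.gene_of_snp[s]}\n")
    return paths
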