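import numpy as np
import pandas as pd
import pytest

from nestpath.data import DatasetBundle, GenotypeBlock, StudyFrame


def make_bundle(genotypes, gene_of_snp, sibships=None, snp_ids=None,
                phenotypes=None):
    """Build a validated bundle from plain arrays (test helper)."""
    genotypes = np.asarray(genotypes, dtype=float)
    n = genotypes.shape[0]
    if sibships is None:
        sibships = [f"f{i}" for i in range(n)]
    subject_ids = [f"s{i}" for i in range(n)]
    table = pd.DataFrame({"sibship_id": sibships},
                         index=pd.Index(subject_ids, name="subject_id"))
    if phenotypes:
        for k, v in phenotypes.items():
            table[k] = np.asarray(v, dtype=float)
    if snp_ids is None:
        snp_ids = list(gene_of_snp)
    block = GenotypeBlock(genotypes, snp_ids, dict(gene_of_snp))
    return DatasetBundle(StudyFrame(table), block, provenance="fixture")


@pytest.fixture
def tiny_nested_bundle():
    """2 sibships x 2 subjects x 2 genes x 2 SNPs each; fixed genotypes.

    Small enough for the adaptive-quadrature oracle (7 random-effect
    dimensions per sibship) yet polymorphic in every column.
    """
    genotypes = [
        [0, 1, 2, 0],
        [1, 0, 0, 1],
        [2, 2, 1, 0],
        [0, 0, 1, 1],
    ]
    gene_map = {"s1": "G1", "s2": "G1", "s3": "G2", "s4": "G2"}
    return make_bundle(genotypes, gene_map,
                       sibships=["f1", "f1", "f2", "f2"])


def random_polymorphic_bundle(rng, n_subjects=30, n_genes=2, snps_per_gene=3,
                              singleton=True, maf_range=(0.1, 0.4)):
    """Random fixture whose SNP columns are all guaranteed polymorphic."""
    S = n_genes * snps_per_gene
    while True:
        maf = rng.uniform(*maf_range, size=S)
        w = rng.binomial(2, maf, size=(n_subjects, S)).astype(float)
        if np.all(w.min(axis=0) < w.max(axis=0)):
            break
    gene_map = {f"g{g}_s{s}": f"G{g}" for g in range(n_genes)
                for s in range(snps_per_gene)}
    sibs = None if singleton else [f"f{i // 2}" for i in range(n_subjects)]
    return make_bundle(w, gene_map, sibships=sibs)
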