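import numpy as np
import pytest

from supervariant import preprocess, simulate
from supervariant.types import GenotypeMatrix, GeneModel, Phenotype, VariantRecord


def make_matrix(dosages, chrom="chr1", start_pos=100, step=10, sample_prefix="S"):
    """GenotypeMatrix from a plain 2-D array; positions spaced on one chromosome."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    variants = [
        VariantRecord(chrom=chrom, pos=start_pos + step * j, ref="A", alt="G")
        for j in range(p)
    ]
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        variants=variants,
        dosages=dosages,
    )


def make_phenotype(y, sample_prefix="S"):
    y = np.asarray(y)
    return Phenotype(sample_ids=[f"{sample_prefix}{i}" for i in range(len(y))], y=y)


@pytest.fixture(scope="session")
def setx_cohort():
    """One 103-sample cohort with a single signal gene shaped 380(135)."""
    cfg = simulate.SimConfig(seed=42)
    matrix, phen, models = simulate.simulate_cohort(cfg)
    return matrix, phen, models


@pytest.fixture(scope="session")
def setx_geneset(setx_cohort):
    matrix, phen, models = setx_cohort
    return preprocess.assign_to_genes(matrix, models)[0]


@pytest.fixture
def toy_gene_model():
    """Two-exon coding gene: exons [100,199] and [300,399], CDS 150..349."""
    return GeneModel(
        name="TOY", chrom="chr1", strand="+",
        tx_start=100, tx_end=399, cds_start=150, cds_end=349,
        exon_starts=[100, 300], exon_ends=[199, 399],
    )
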