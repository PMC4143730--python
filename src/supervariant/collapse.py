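"""Singleton detection, supervariant construction and region classification.

A *singleton* is a variant whose minor allele is observed exactly once
across all samples — a single heterozygote (a lone homozygote carries
two copies and is not a singleton).  Singleton status is decided over
cases and controls jointly, before any phenotype information enters,
which is what keeps the downstream permutation tests valid.

The gene's *supervariant* is the binary per-sample indicator of
carrying at least one of its singletons.  Region subsets (CDS / UTR /
intron) inherit the gene-level singleton list: a singleton of the gene
remains a singleton of the region subset even though the subset alone
would not certify it.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .types import (
    MISSING,
    GeneModel,
    GenotypeMatrix,
    GeneVariantSet,
    Phenotype,
    RegionClass,
    SuperVariant,
)


def _require_imputed(matrix: GenotypeMatrix, indices: np.ndarray) -> None:
    if (matrix.dosages[:, indices] == MISSING).any():
        raise ValueError("matrix contains missing genotypes; impute first")


def find_singletons(geneset: GeneVariantSet, matrix: GenotypeMatrix) -> np.ndarray:
    """Indices (into the matrix) of the gene's variants with minor-allele count 1."""
    idx = geneset.variant_indices
    _require_imputed(matrix, idx)
    d = matrix.dosages[:, idx].astype(np.int64)
    ac = d.sum(axis=0)
    mac = np.minimum(ac, 2 * matrix.n_samples - ac)
    return idx[mac == 1]


def build_supervariant(geneset: GeneVariantSet, matrix: GenotypeMatrix) -> SuperVariant:
    """Collapse the gene's singletons into one binary carrier indicator.

    ``x[i] = 1`` iff sample ``i`` has dosage >= 1 at one or more
    singletons; a gene with zero singletons yields an all-zero
    indicator flagged untestable via :attr:`SuperVariant.testable`.
    """
    singles = find_singletons(geneset, matrix)
    if singles.size == 0:
        x = np.zeros(matrix.n_samples, dtype=np.int8)
    else:
        x = (matrix.dosages[:, singles] >= 1).any(axis=1).astype(np.int8)
    return SuperVariant(gene=geneset.gene.name, x=x, n_singletons_used=int(singles.size))


def classify_region(pos: int, gene_model: GeneModel) -> RegionClass:
    """Classify an in-gene position as CDS, UTR or intron.

    CDS: inside an exon and inside the [cds_start, cds_end] interval;
    UTR: inside an exon but outside the CDS interval (both UTR sides and
    non-coding exons collapse here); intron: everything else in the
    transcript span.
    """
    if not gene_model.tx_start <= pos <= gene_model.tx_end:
        raise ValueError(
            f"position {pos} outside {gene_model.name} "
            f"[{gene_model.tx_start}, {gene_model.tx_end}]"
        )
    in_exon = any(
        s <= pos <= e for s, e in zip(gene_model.exon_starts, gene_model.exon_ends)
    )
    if not in_exon:
        return RegionClass.INTRON
    if gene_model.has_cds and gene_model.cds_start <= pos <= gene_model.cds_end:
        return RegionClass.CDS
    return RegionClass.UTR


def classify_variants(
    geneset: GeneVariantSet, matrix: GenotypeMatrix
) -> list[RegionClass]:
    """Region class of each variant in the gene set, in index order."""
    return [
        classify_region(matrix.variants[j].pos, geneset.gene)
        for j in geneset.variant_indices
    ]


def subset_by_region(
    geneset: GeneVariantSet,
    matrix: GenotypeMatrix,
    cls: RegionClass,
) -> GeneVariantSet:
    """Restrict a gene's variant set to one region class.

    Singleton status is *not* recomputed on the subset; callers pass
    the subset to :func:`build_supervariant`, which re-detects
    singletons against all samples — the gene-level status — so the
    region supervariant uses the region's share of the gene's
    singletons.  An empty subset is legal (untestable, not an error).
    """
    classes = classify_variants(geneset, matrix)
    keep = geneset.variant_indices[[k == cls for k in classes]]
    return GeneVariantSet(gene=geneset.gene, variant_indices=keep)


def write_supervariants_tsv(
    supervariants: list[SuperVariant],
    phenotype: Phenotype,
    path: str | Path,
) -> None:
    """Long-format export: gene, sample, carrier indicator."""
    with open(path, "w") as fh:
        fh.write("gene\tsample_id\tX\n")
        for sv in supervariants:
            for sid, xi in zip(phenotype.sample_ids, sv.x):
                fh.write(f"{sv.gene}\t{sid}\t{int(xi)}\n")


def write_supervariants_vcf(
    supervariants: list[SuperVariant],
    genesets: dict[str, GeneVariantSet],
    phenotype: Phenotype,
    path: str | Path,
) -> None:
    """Pseudo-VCF export: one line per gene, GT 0/1 for carriers.

    POS is the gene's transcript start; REF/ALT are placeholder alleles.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##source=supervariant collapse (one pseudo-variant per gene)\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(phenotype.sample_ids)
            + "\n"
        )
        for sv in supervariants:
            gene = genesets[sv.gene].gene
            gts = "\t".join("0/1" if xi else "0/0" for xi in sv.x)
            fh.write(
                f"{gene.chrom}\t{gene.tx_start}\t{sv.gene}_SUPER\tN\tA\t.\t.\t"
                f"NS={len(sv.x)}\tGT\t{gts}\n"
            )
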