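"""Input parsing, variant filtering, imputation and gene grouping.

The pipeline retains rare variants only: a variant survives filtering
when it is not on the known-site list (a dbSNP-style exclusion list),
its minor allele frequency among non-missing genotypes is at most 1%,
and its genotype missing rate is at most 5%.  Remaining missing
genotypes are resampled from the non-missing genotypes of the same
variant.  Variants are then grouped into genes by transcript span;
variants outside every transcript are dropped from analysis.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    FilterReport,
    GeneModel,
    GenotypeMatrix,
    GeneVariantSet,
    Phenotype,
    VariantRecord,
)

logger = logging.getLogger(__name__)

# cyvcf2 gt_types codes -> dosage
_GT_TYPE_TO_DOSAGE = {0: 0, 1: 1, 2: MISSING, 3: 2}


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF into a dosage matrix.

    Only bi-allelic SNVs are loaded; multi-allelic or non-SNV lines are
    skipped with a logged message.  ``./.`` becomes :data:`MISSING`.
    """
    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            logger.info(
                "skipping non-SNV/multi-allelic line %s:%d %s>%s",
                rec.CHROM, rec.POS, rec.REF, ",".join(rec.ALT),
            )
            continue
        variants.append(
            VariantRecord(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                var_id=rec.ID,
            )
        )
        rows.append(
            np.array([_GT_TYPE_TO_DOSAGE[t] for t in rec.gt_types], dtype=np.int8)
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNV lines", n_skipped)
    dosages = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a refFlat-style gene model table.

    Columns: geneName, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds (comma-separated).  All coordinates
    1-based inclusive (declared in the file's header comment); a
    non-coding transcript carries cdsStart > cdsEnd.
    """
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            exon_starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
            exon_ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
            if len(exon_starts) != int(f[7]):
                raise ValueError(f"{f[0]}: exonCount mismatch")
            models.append(
                GeneModel(
                    name=f[0], chrom=f[1], strand=f[2],
                    tx_start=int(f[3]), tx_end=int(f[4]),
                    cds_start=int(f[5]), cds_end=int(f[6]),
                    exon_starts=exon_starts, exon_ends=exon_ends,
                )
            )
    return models


def read_known_sites(path: str | Path) -> frozenset[str]:
    """Known-site exclusion list: one ``chrom:pos:ref:alt`` key or rsID per line."""
    keys = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                keys.add(line)
    return frozenset(keys)


def collapse_longitudinal_phenotype(table: pd.DataFrame) -> Phenotype:
    """Collapse longitudinal hypertension status to a binary trait.

    A sample is a case iff it was affected at any non-missing time
    point (columns ``HTN1..HTN4``).  Samples with all time points
    missing are excluded with a logged message.
    """
    htn_cols = [c for c in table.columns if c.upper().startswith("HTN")]
    if not htn_cols:
        raise ValueError("no HTN* longitudinal columns found")
    vals = table[htn_cols].to_numpy(dtype=float)
    all_missing = np.isnan(vals).all(axis=1)
    for sid in table.loc[all_missing, "sample_id"]:
        logger.warning("sample %s has no phenotype time point; excluded", sid)
    kept = table.loc[~all_missing]
    y = np.nanmax(kept[htn_cols].to_numpy(dtype=float), axis=1) == 1
    return Phenotype(sample_ids=list(kept["sample_id"]), y=y.astype(np.int8))


def read_phenotype(path: str | Path) -> Phenotype:
    """Read a phenotype TSV: ``sample_id`` plus either ``y`` or ``HTN1..HTN4``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "y" in df.columns:
        return Phenotype(sample_ids=list(df["sample_id"]), y=df["y"].to_numpy())
    return collapse_longitudinal_phenotype(df)


def compute_maf(matrix: GenotypeMatrix, variant_index: int) -> float:
    """Minor allele frequency at one variant over non-missing genotypes."""
    d = matrix.dosages[:, variant_index]
    obs = d[d != MISSING]
    if obs.size == 0:
        raise ValueError("all genotypes missing at variant")
    ac = int(obs.sum())
    n_alleles = 2 * obs.size
    return min(ac, n_alleles - ac) / n_alleles


def minor_allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Vectorized per-variant MAF (NaN where all genotypes are missing)."""
    d = matrix.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    ac = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = ac / (2.0 * n_obs)
        maf = np.minimum(freq, 1.0 - freq)
    return np.where(n_obs > 0, maf, np.nan)


def missing_rates(matrix: GenotypeMatrix) -> np.ndarray:
    if matrix.n_samples == 0:
        return np.zeros(matrix.n_variants)
    return (matrix.dosages == MISSING).mean(axis=0)


def filter_variants(
    matrix: GenotypeMatrix,
    known_keys: frozenset[str] = frozenset(),
    maf_max: float = 0.01,
    miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the known-site, MAF and missingness filters.

    Thresholds are strict on removal: a variant is removed when its MAF
    *exceeds* ``maf_max`` or its missing rate *exceeds* ``miss_max``
    (so MAF exactly 1% is retained).  MAF is computed over non-missing
    genotypes, before any imputation.  The report counts each removed
    variant once, at the first rule that removes it (known -> MAF ->
    missingness).
    """
    known = np.array(
        [
            v.key in known_keys or (v.var_id is not None and v.var_id in known_keys)
            for v in matrix.variants
        ],
        dtype=bool,
    )
    maf = minor_allele_frequencies(matrix)
    high_maf = np.nan_to_num(maf, nan=0.0) > maf_max
    high_miss = missing_rates(matrix) > miss_max
    removed_known = known
    removed_maf = ~known & high_maf
    removed_miss = ~known & ~high_maf & high_miss
    keep = ~(removed_known | removed_maf | removed_miss)
    report = FilterReport(
        n_input=matrix.n_variants,
        n_removed_known=int(removed_known.sum()),
        n_removed_maf=int(removed_maf.sum()),
        n_removed_missing=int(removed_miss.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "filter_variants: %d input, %d known, %d high-MAF, %d high-missing, %d retained",
        report.n_input, report.n_removed_known, report.n_removed_maf,
        report.n_removed_missing, report.n_retained,
    )
    return matrix.subset_variants(np.flatnonzero(keep)), report


def impute_missing(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Resample each missing genotype from the variant's non-missing genotypes.

    Draws are uniform with replacement and reproducible from ``seed``;
    non-missing entries are untouched.
    """
    rng = np.random.default_rng(seed)
    d = matrix.dosages.copy()
    for j in range(d.shape[1]):
        col = d[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        pool = col[~miss]
        if pool.size == 0:
            v = matrix.variants[j]
            raise ValueError(f"variant {v.key} has no non-missing genotype")
        col[miss] = rng.choice(pool, size=int(miss.sum()), replace=True)
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        variants=list(matrix.variants),
        dosages=d,
    )


def assign_to_genes(
    matrix: GenotypeMatrix, models: list[GeneModel]
) -> list[GeneVariantSet]:
    """Group variants into genes by transcript span.

    A variant joins every gene whose ``[tx_start, tx_end]`` interval
    (inclusive on both ends) contains its position on the matching
    chromosome; genes left with zero variants are dropped.
    """
    chroms = np.array([v.chrom for v in matrix.variants])
    pos = np.array([v.pos for v in matrix.variants], dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    out = []
    for m in models:
        mask = (chroms == m.chrom) & (pos >= m.tx_start) & (pos <= m.tx_end)
        idx = order[mask[order]]
        if idx.size:
            out.append(GeneVariantSet(gene=m, variant_indices=idx))
    return out


def harmonize_samples(
    matrix: GenotypeMatrix, phenotype: Phenotype
) -> tuple[GenotypeMatrix, Phenotype]:
    """Restrict to shared samples, ordered as in the phenotype table."""
    geno_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    shared = [s for s in phenotype.sample_ids if s in geno_index]
    dropped = (set(matrix.sample_ids) | set(phenotype.sample_ids)) - set(shared)
    if dropped:
        logger.warning("dropping %d samples absent from one input", len(dropped))
    keep_mask = np.array([s in geno_index for s in phenotype.sample_ids])
    phen = Phenotype(sample_ids=shared, y=phenotype.y[keep_mask])
    mat = matrix.subset_samples([geno_index[s] for s in shared])
    return mat, phen
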