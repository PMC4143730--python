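"""Core containers shared across the pipeline.

The substrate of every analysis is a samples x variants dosage matrix
(0/1/2 alternate-allele counts, -1 for missing), a binary phenotype
aligned to the same sample order, and transcript models that drive both
gene grouping and CDS/UTR/intron classification.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel for a missing genotype in a dosage matrix.
MISSING: int = -1


@dataclass(frozen=True)
class VariantRecord:
    """Identity of a bi-allelic SNV."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> str:
        """Canonical ``chrom:pos:ref:alt`` key used for known-site matching."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage table.

    ``dosages[i, j]`` is the alternate-allele count of sample ``i`` at
    variant ``j`` (0, 1, 2) or :data:`MISSING`.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[j] for j in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            dosages=self.dosages[idx, :].copy(),
        )


@dataclass
class Phenotype:
    """Binary case/control status (1 = case), aligned to a GenotypeMatrix."""

    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("phenotype length inconsistent with sample ids")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotype values must be 0/1")

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int((self.y == 0).sum())


@dataclass
class GeneModel:
    """Transcript model; all coordinates 1-based inclusive.

    Gene *length* is defined as ``tx_end - tx_start`` (the convention
    under which chr9:135,136,827-135,230,372 spans 93,545 bp).  A
    non-coding transcript is encoded with ``cds_start > cds_end``.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: list[int] = field(default_factory=list)
    exon_ends: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.name}: tx_start > tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.name}: exon start/end count mismatch")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s > e or s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.name}: exon [{s},{e}] outside transcript")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.name}: exons overlap or unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def has_cds(self) -> bool:
        return self.cds_start <= self.cds_end

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.tx_start <= pos <= self.tx_end


class RegionClass(enum.Enum):
    """Functional region of an in-gene position; the classes partition a gene."""

    CDS = "CDS"
    UTR = "UTR"
    INTRON = "INTRON"


@dataclass
class GeneVariantSet:
    """Variants of one matrix assigned to one gene (indices sorted by position)."""

    gene: GeneModel
    variant_indices: np.ndarray

    def __post_init__(self) -> None:
        self.variant_indices = np.asarray(self.variant_indices, dtype=int)
        if len(np.unique(self.variant_indices)) != len(self.variant_indices):
            raise ValueError("duplicate variant indices in gene set")

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


@dataclass
class SuperVariant:
    """Per-gene binary carrier indicator built from the gene's singletons.

    ``x[i] = 1`` iff sample ``i`` carries at least one singleton of the
    gene.  A gene with zero singletons yields an all-zero, untestable
    indicator.
    """

    gene: str
    x: np.ndarray
    n_singletons_used: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError("supervariant entries must be 0/1")

    @property
    def testable(self) -> bool:
        return self.n_singletons_used > 0 and bool(self.x.any())

    @property
    def n_carriers(self) -> int:
        return int(self.x.sum())


@dataclass
class FilterReport:
    """Partition of input variants over the filter rules (first rule wins)."""

    n_input: int
    n_removed_known: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_removed_known
            + self.n_removed_maf
            + self.n_removed_missing
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("filter report does not partition the input")


@dataclass
class TestResult:
    """Permutation test outcome with the '< 1/B' reporting convention."""

    statistic: float
    b: int  # number of permuted statistics >= observed
    B: int  # number of permutations
    method: str
    stage: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.b <= self.B:
            raise ValueError("need 0 <= b <= B")

    @property
    def p(self) -> float:
        """Point estimate b/B (0.0 encodes 'below resolution', see p_display)."""
        return self.b / self.B

    @property
    def p_conservative(self) -> float:
        """(b+1)/(B+1) upper-biased estimate."""
        return (self.b + 1) / (self.B + 1)

    @property
    def p_display(self) -> str:
        if self.b == 0:
            return f"<{1.0 / self.B:.1e}"
        return f"{self.p:.3g}"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control x carrier/non-carrier counts.

    ``a`` case carriers, ``b`` case non-carriers, ``c`` control
    carriers, ``d`` control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class PermutationPlan:
    """Two-step adaptive permutation schedule.

    All genes are screened with ``b1`` permutations; genes reaching an
    estimated p below ``alpha_promote`` for any method are re-tested
    with ``b2`` permutations for all methods.
    """

    b1: int = 1000
    alpha_promote: float = 1e-3
    b2: int = 10**6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b1 < 1 or self.b2 < self.b1:
            raise ValueError("need 1 <= b1 <= b2")
        if not 0.0 < self.alpha_promote < 1.0:
            raise ValueError("alpha_promote must be in (0, 1)")
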