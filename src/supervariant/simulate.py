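"""Synthetic case-control sequencing cohorts for the collapsing pipeline.

The generator emulates the statistical structure the analysis assumes:
a small unrelated cohort (default 64 cases / 39 controls), genes
carrying tens-to-hundreds of rare variants of which roughly a third
are singletons, and a configurable carrier-level odds ratio linking
singleton carriage in a signal gene to case status.

Sampling is retrospective (case-control): carrier status of the signal
gene's supervariant is drawn per sample with probability ``q1`` in
cases and ``q0`` in controls, where ``q1`` solves
``q1/(1-q1) = OR * q0/(1-q0)`` — the estimand is the carrier odds
ratio that the Fisher exact analysis reports.  In null genes each
singleton simply lands on a uniformly random sample, independent of
phenotype.  Singletons are always a single heterozygote; non-singleton
rare variants place 2..floor(0.01*2n) minor-allele copies uniformly
over chromosomes, keeping MAF <= 1%.

An optional two-subpopulation confounding mode gives subpopulation B
both an elevated case fraction and shifted allele frequencies: rare
carriers are drawn with subpopulation-weighted probabilities and
common-variant frequencies diverge by a Balding-Nichols model with
Fst equal to the same divergence parameter, so principal components
have real structure to find and the adjusted test something to fix.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import GeneModel, GenotypeMatrix, Phenotype, VariantRecord

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class GeneSpec:
    """Shape of one simulated gene.

    ``region_weights`` are (CDS, UTR, intron) placement weights for
    variant positions; the default mirrors a large, intron-dominated
    gene with a 14 : 6 : 360 split.
    """

    name: str
    n_variants: int
    n_singletons: int
    span_bp: int = 90_000
    n_exons: int = 10
    cds_len: int = 6_000
    utr_len: int = 1_000
    region_weights: tuple[float, float, float] = (14.0, 6.0, 360.0)
    is_signal: bool = False
    chrom: str | None = None

    def __post_init__(self) -> None:
        if self.n_variants < 1 or not 0 <= self.n_singletons <= self.n_variants:
            raise ValueError(f"{self.name}: need 0 <= n_singletons <= n_variants")
        if self.span_bp < self.cds_len + self.utr_len:
            raise ValueError(f"{self.name}: span shorter than exonic length")
        if self.n_exons < 1:
            raise ValueError(f"{self.name}: need >= 1 exon")
        if self.n_variants > self.span_bp:
            raise ValueError(f"{self.name}: more variants than positions")


def setx_like(name: str = "SETX", is_signal: bool = True) -> GeneSpec:
    """A gene shaped like the motivating example: 380 rare variants of
    which 135 are singletons, a 93,545 bp span, 26 exons and 8,034
    coding bases."""
    return GeneSpec(
        name=name, n_variants=380, n_singletons=135,
        span_bp=93_545, n_exons=26, cds_len=8_034, utr_len=1_000,
        region_weights=(14.0, 6.0, 360.0), is_signal=is_signal,
    )


@dataclass
class ConfoundingSpec:
    """Two-subpopulation confounding structure.

    Subpopulation B is both more affected (``case_fraction_b`` vs
    ``case_fraction_a``) and genetically diverged: ``divergence`` acts
    as the Balding-Nichols Fst for common variants and as the bias
    weight ``1 +/- divergence`` for placing rare-variant carriers.
    """

    subpop_b_fraction: float = 0.5
    case_fraction_a: float = 0.35
    case_fraction_b: float = 0.85
    divergence: float = 0.5

    def __post_init__(self) -> None:
        for name in ("subpop_b_fraction", "case_fraction_a", "case_fraction_b"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class SimConfig:
    """Full description of one simulated cohort."""

    n_cases: int = 64
    n_controls: int = 39
    genes: list[GeneSpec] = field(default_factory=lambda: [setx_like()])
    carrier_or: float = 8.8
    control_carrier_rate: float = 0.2
    confounding: ConfoundingSpec | None = None
    n_common_variants: int = 0
    common_maf_range: tuple[float, float] = (0.15, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not self.carrier_or > 0:
            raise ValueError("carrier_or must be positive")
        if not 0.0 < self.control_carrier_rate < 1.0:
            raise ValueError("control_carrier_rate must be in (0, 1)")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_carrier_rate(self) -> float:
        """q1 solving the carrier odds-ratio equation against q0."""
        q0 = self.control_carrier_rate
        odds1 = self.carrier_or * q0 / (1.0 - q0)
        return odds1 / (1.0 + odds1)


# ---------------------------------------------------------------------------
# gene model construction


def make_gene_model(spec: GeneSpec, chrom: str, tx_start: int) -> GeneModel:
    """Lay out a transcript for a GeneSpec: evenly spaced exons whose
    total length is cds_len + utr_len, CDS flanked by split UTRs."""
    exonic_total = spec.cds_len + spec.utr_len
    tx_end = tx_start + spec.span_bp  # length convention: end - start
    base = exonic_total // spec.n_exons
    lens = [base + (1 if i < exonic_total % spec.n_exons else 0) for i in range(spec.n_exons)]
    intron_total = (spec.span_bp + 1) - exonic_total
    n_gaps = max(spec.n_exons - 1, 1)
    gap = intron_total // n_gaps
    starts, ends = [], []
    cursor = tx_start
    for i, ln in enumerate(lens):
        if i == spec.n_exons - 1:
            cursor = tx_end - ln + 1  # pin last exon to the transcript end
        starts.append(cursor)
        ends.append(cursor + ln - 1)
        cursor += ln + gap
    if spec.cds_len > 0:
        utr5 = spec.utr_len // 2
        cds_start = _exonic_offset_to_genomic(starts, ends, utr5)
        cds_end = _exonic_offset_to_genomic(starts, ends, utr5 + spec.cds_len - 1)
    else:
        cds_start, cds_end = 1, 0  # non-coding
    return GeneModel(
        name=spec.name, chrom=chrom, strand="+",
        tx_start=tx_start, tx_end=tx_end,
        cds_start=cds_start, cds_end=cds_end,
        exon_starts=starts, exon_ends=ends,
    )


def _exonic_offset_to_genomic(starts: list[int], ends: list[int], offset: int) -> int:
    for s, e in zip(starts, ends):
        ln = e - s + 1
        if offset < ln:
            return s + offset
        offset -= ln
    raise ValueError("exonic offset beyond transcript")


def _region_positions(model: GeneModel) -> dict[str, np.ndarray]:
    """All genomic positions of the transcript split by region class."""
    pos = np.arange(model.tx_start, model.tx_end + 1)
    exonic = np.zeros(pos.size, dtype=bool)
    for s, e in zip(model.exon_starts, model.exon_ends):
        exonic[s - model.tx_start : e - model.tx_start + 1] = True
    cds = exonic & (pos >= model.cds_start) & (pos <= model.cds_end) if model.has_cds else np.zeros_like(exonic)
    return {
        "CDS": pos[cds],
        "UTR": pos[exonic & ~cds],
        "INTRON": pos[~exonic],
    }


# ---------------------------------------------------------------------------
# carrier designation


def designate_carriers(
    rng: np.random.Generator,
    y: np.ndarray,
    q1: float,
    q0: float,
    max_carriers: int | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Retrospective carrier draw: Bernoulli(q1) in cases, Bernoulli(q0)
    in controls, optionally tilted by per-sample ``weights`` (mean 1).

    Redraws until at least one carrier exists and the count fits under
    ``max_carriers`` (each carrier needs a singleton to carry); raises
    after repeated failure, which signals an infeasible configuration.
    """
    p = np.where(y == 1, q1, q0).astype(float)
    if weights is not None:
        p = np.clip(p * weights, 0.0, 1.0)
    for _ in range(1000):
        carriers = rng.random(len(y)) < p
        k = int(carriers.sum())
        if k >= 1 and (max_carriers is None or k <= max_carriers):
            return carriers
    raise ValueError(
        "could not designate carriers: singleton count incompatible with "
        "carrier rates (n_singletons too small for the configured rates?)"
    )


def _assign_singletons(
    rng: np.random.Generator, carriers: np.ndarray, n_singletons: int, n_samples: int
) -> np.ndarray:
    """Map each singleton to its carrier sample; every designated
    carrier receives at least one singleton.  Returns sample index per
    singleton."""
    idx = np.flatnonzero(carriers)
    owners = np.empty(n_singletons, dtype=int)
    owners[: idx.size] = rng.permutation(idx)
    if n_singletons > idx.size:
        owners[idx.size :] = rng.choice(idx, size=n_singletons - idx.size, replace=True)
    return rng.permutation(owners)


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    config: SimConfig, return_subpops: bool = False
) -> tuple[GenotypeMatrix, Phenotype, list[GeneModel]] | tuple[
    GenotypeMatrix, Phenotype, list[GeneModel], np.ndarray | None
]:
    """Draw one cohort; fully reproducible from ``config.seed``.

    Returns the dosage matrix (genes' rare variants plus any common
    background variants on their own chromosome), the phenotype and
    the gene models.  With ``return_subpops`` the per-sample
    subpopulation labels (0/1, or None without confounding) are
    appended for diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    max_mac = math.floor(0.01 * 2 * n)
    y = np.array([1] * config.n_cases + [0] * config.n_controls, dtype=np.int8)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    subpop = None
    rare_weights = None
    if config.confounding is not None:
        subpop = _draw_subpops(rng, y, config.confounding)
        d = config.confounding.divergence
        w = np.where(subpop == 1, 1.0 + d, 1.0 - d)
        rare_weights = w / w.mean()

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    models: list[GeneModel] = []
    cursor: dict[str, int] = {}
    for spec in config.genes:
        chrom = spec.chrom or "chr1"
        tx_start = cursor.get(chrom, 1_000)
        model = make_gene_model(spec, chrom, tx_start)
        cursor[chrom] = model.tx_end + 10_000
        models.append(model)
        pos = _draw_positions(rng, model, spec)
        is_single = np.zeros(spec.n_variants, dtype=bool)
        is_single[rng.choice(spec.n_variants, size=spec.n_singletons, replace=False)] = True

        geno = np.zeros((n, spec.n_variants), dtype=np.int8)
        if spec.n_singletons > 0:
            if spec.is_signal:
                # retrospective carrier draw fixes the supervariant's
                # case/control carrier probabilities at the configured OR
                carriers = designate_carriers(
                    rng, y,
                    config.case_carrier_rate, config.control_carrier_rate,
                    max_carriers=spec.n_singletons,
                )
                owners = _assign_singletons(rng, carriers, spec.n_singletons, n)
            else:
                # null gene: each singleton lands on a uniformly random
                # sample (subpopulation-weighted under confounding),
                # independent of phenotype
                p = None if rare_weights is None else rare_weights / rare_weights.sum()
                owners = rng.choice(n, size=spec.n_singletons, replace=True, p=p)
            geno[owners, np.flatnonzero(is_single)] = 1
        for j in np.flatnonzero(~is_single):
            if max_mac < 2:
                raise ValueError(
                    f"cohort of {n} samples cannot host non-singleton rare "
                    "variants with MAF <= 1%"
                )
            mac = int(rng.integers(2, max_mac + 1))
            geno[:, j] = _place_allele_copies(rng, n, mac, rare_weights)
        order = np.argsort(pos, kind="stable")
        for k in order:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            variants.append(VariantRecord(chrom=chrom, pos=int(pos[k]), ref=str(ref), alt=str(alt)))
        columns.append(geno[:, order])

    if config.n_common_variants > 0:
        common = _draw_common(rng, n, config, subpop)
        base_pos = 1_000
        for j in range(config.n_common_variants):
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            variants.append(
                VariantRecord(chrom="chr2", pos=base_pos + 100 * j, ref=str(ref), alt=str(alt))
            )
        columns.append(common)

    dosages = (
        np.concatenate(columns, axis=1)
        if columns
        else np.empty((n, 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)
    phen = Phenotype(sample_ids=sample_ids, y=y)
    if return_subpops:
        return matrix, phen, models, subpop
    return matrix, phen, models


def _draw_subpops(
    rng: np.random.Generator, y: np.ndarray, conf: ConfoundingSpec
) -> np.ndarray:
    """Subpopulation labels conditional on case status (Bayes over the
    population prior and per-subpopulation case fractions)."""
    pb, fa, fb = conf.subpop_b_fraction, conf.case_fraction_a, conf.case_fraction_b
    p_b_case = fb * pb / (fb * pb + fa * (1 - pb))
    p_b_ctrl = (1 - fb) * pb / ((1 - fb) * pb + (1 - fa) * (1 - pb))
    p = np.where(y == 1, p_b_case, p_b_ctrl)
    return (rng.random(len(y)) < p).astype(np.int8)


def _draw_positions(
    rng: np.random.Generator, model: GeneModel, spec: GeneSpec
) -> np.ndarray:
    """Sample distinct variant positions, region-stratified by the
    spec's CDS/UTR/intron weights (overflow spills into other regions)."""
    region_pos = _region_positions(model)
    names = ["CDS", "UTR", "INTRON"]
    weights = np.array(spec.region_weights, dtype=float)
    caps = np.array([region_pos[r].size for r in names])
    weights[caps == 0] = 0.0
    if weights.sum() == 0:
        weights = caps.astype(float)
    counts = rng.multinomial(spec.n_variants, weights / weights.sum())
    for _ in range(3):  # push overflow beyond a region's capacity elsewhere
        over = counts - caps
        if (over <= 0).all():
            break
        for i in np.flatnonzero(over > 0):
            excess, counts[i] = over[i], caps[i]
            room = np.flatnonzero(caps - counts > 0)
            for r in room:
                take = min(excess, caps[r] - counts[r])
                counts[r] += take
                excess -= take
    chosen = [
        rng.choice(region_pos[r], size=int(c), replace=False)
        for r, c in zip(names, counts)
        if c > 0
    ]
    return np.concatenate(chosen)


def _place_allele_copies(
    rng: np.random.Generator, n: int, mac: int, weights: np.ndarray | None
) -> np.ndarray:
    """Distribute ``mac`` minor-allele copies over 2n chromosomes
    (distinct copies, optionally subpopulation-weighted)."""
    p = None
    if weights is not None:
        p = np.repeat(weights, 2)
        p = p / p.sum()
    slots = rng.choice(2 * n, size=mac, replace=False, p=p)
    geno = np.zeros(n, dtype=np.int8)
    np.add.at(geno, slots // 2, 1)
    return geno


def _draw_common(
    rng: np.random.Generator, n: int, config: SimConfig, subpop: np.ndarray | None
) -> np.ndarray:
    """Common background variants; Balding-Nichols divergence between
    subpopulations when confounding is on."""
    lo, hi = config.common_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_common_variants)
    if subpop is not None and config.confounding.divergence > 0:
        fst = config.confounding.divergence
        shape = (1.0 - fst) / fst
        pa = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        pb = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        p_mat = np.where(subpop[:, None] == 1, pb[None, :], pa[None, :])
    else:
        p_mat = np.broadcast_to(p_anc[None, :], (n, config.n_common_variants))
    return rng.binomial(2, p_mat).astype(np.int8)


# ---------------------------------------------------------------------------
# serialization


def write_cohort(
    matrix: GenotypeMatrix,
    phenotype: Phenotype,
    models: list[GeneModel],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Serialize a cohort as VCF + refFlat-style gene models + phenotype
    TSV; files round-trip losslessly through the preprocess readers and
    are byte-identical for identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "genes": out / "genes.refflat.txt",
        "phenotype": out / "phenotype.tsv",
    }
    _write_vcf(matrix, paths["vcf"])
    _write_gene_models(models, paths["genes"])
    with open(paths["phenotype"], "w") as fh:
        fh.write("sample_id\ty\n")
        for sid, yi in zip(phenotype.sample_ids, phenotype.y):
            fh.write(f"{sid}\t{int(yi)}\n")
    return paths


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    chrom_max: dict[str, int] = {}
    for v in matrix.variants:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=supervariant simulate\n")
        for chrom, mx in sorted(chrom_max.items()):
            fh.write(f"##contig=<ID={chrom},length={mx + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids) + "\n"
        )
        for j, v in enumerate(matrix.variants):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in matrix.dosages[:, j])
            vid = v.var_id if v.var_id else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_gene_models(models: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# coords: 1-based inclusive; columns: geneName chrom strand "
            "txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds\n"
        )
        for m in models:
            fh.write(
                "\t".join([
                    m.name, m.chrom, m.strand,
                    str(m.tx_start), str(m.tx_end),
                    str(m.cds_start), str(m.cds_end),
                    str(m.n_exons),
                    ",".join(str(s) for s in m.exon_starts) + ",",
                    ",".join(str(e) for e in m.exon_ends) + ",",
                ]) + "\n"
            )
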