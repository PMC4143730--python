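"""Rare-variant association statistics, permutation engine, exact tests.

Three gene-level statistics are provided, all evaluated against a
permutation null (phenotype labels shuffled):

* **SSU / linear-kernel score** — ``S = U'U`` with marginal score
  vector ``U = F'(y - ybar)``; the quality-unweighted multivariate
  score test reduces to this (equivalently linear-kernel SKAT).
* **C-alpha** — binomial homogeneity of per-variant case allele
  counts: ``T = sum_i [(y_i - n_i p0)^2 - n_i p0 (1 - p0)]`` where
  ``n_i`` is the variant's total minor-allele count, ``y_i`` its count
  in cases and ``p0`` the case fraction of samples.
* **CMC** — variants collapsed into allele-frequency-bin carrier
  indicators, jointly compared between cases and controls with
  Hotelling's T^2 (pooled covariance, pseudo-inverse for rank
  deficiency).

For all three, large values indicate association; the permutation
p-value is ``b / B`` with exceedance counted as >= (ties count against
significance) and displayed ``< 1/B`` when no permutation reaches the
observed value.  A two-step schedule screens every gene cheaply and
confirms candidates with a deep permutation run.

The supervariant itself is tested with Fisher's exact test; the odds
ratio is the conditional MLE under the noncentral hypergeometric and
the 95% CI inverts the one-sided exact tests at 0.025 per side (the
convention of standard exact-test software).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import nchypergeom_fisher

from .collapse import build_supervariant, find_singletons
from .types import (
    ContingencyTable2x2,
    GenotypeMatrix,
    GeneVariantSet,
    PermutationPlan,
    Phenotype,
    SuperVariant,
    TestResult,
)

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ssu", "calpha", "cmc")
#: Default CMC allele-count bin edges: {count == 1} and {count >= 2}.
DEFAULT_CMC_EDGES = (1, 2)

# relative tolerance when counting permuted statistics >= observed; guards
# against float round-off breaking exact ties, which must count as exceedances
_TIE_RTOL = 1e-9


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Per-gene design matrix for the three permutation tests.

    After collapsing, the features are the dosages of the gene's
    non-singleton rare variants plus one binary supervariant column;
    ``allele_counts`` records each column's minor-allele count for CMC
    binning, with the supervariant assigned count 1 (it aggregates
    singletons).
    """

    values: np.ndarray  # n_samples x n_features, float64
    labels: list[str]
    allele_counts: np.ndarray
    is_super: np.ndarray
    n_dropped_constant: int = 0

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def testable(self) -> bool:
        return self.n_features > 0


def build_feature_matrix(
    geneset: GeneVariantSet,
    matrix: GenotypeMatrix,
    supervariant: SuperVariant | None = None,
    collapse_singletons: bool = True,
) -> FeatureMatrix:
    """Assemble the per-gene test features (collapsing precedes testing).

    With ``collapse_singletons`` the singleton columns are replaced by
    the gene's supervariant; without it all variant dosages enter
    as-is.  Constant (zero-variance) columns are dropped with a log
    entry; a matrix left with zero features is flagged untestable.
    """
    idx = geneset.variant_indices
    cols: list[np.ndarray] = []
    labels: list[str] = []
    acs: list[int] = []
    is_super: list[bool] = []
    if collapse_singletons:
        singles = set(find_singletons(geneset, matrix).tolist())
        keep = [j for j in idx if j not in singles]
    else:
        keep = list(idx)
    for j in keep:
        col = matrix.dosages[:, j].astype(np.float64)
        ac = int(col.sum())
        cols.append(col)
        labels.append(matrix.variants[j].key)
        acs.append(min(ac, 2 * matrix.n_samples - ac))
        is_super.append(False)
    if collapse_singletons:
        sv = supervariant if supervariant is not None else build_supervariant(geneset, matrix)
        if sv.n_singletons_used > 0:
            cols.append(sv.x.astype(np.float64))
            labels.append("SUPER")
            acs.append(1)
            is_super.append(True)
    if not cols:
        return FeatureMatrix(
            values=np.empty((matrix.n_samples, 0)),
            labels=[], allele_counts=np.empty(0, dtype=int),
            is_super=np.empty(0, dtype=bool),
        )
    values = np.column_stack(cols)
    variable = values.std(axis=0) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d constant feature(s)", geneset.gene.name, n_dropped
        )
    return FeatureMatrix(
        values=values[:, variable],
        labels=[l for l, v in zip(labels, variable) if v],
        allele_counts=np.asarray(acs)[variable],
        is_super=np.asarray(is_super)[variable],
        n_dropped_constant=n_dropped,
    )


# ---------------------------------------------------------------------------
# statistics


@dataclass
class CalphaInputs:
    """Sufficient statistics for the C-alpha homogeneity test."""

    n: np.ndarray  # per-variant total minor-allele count
    y: np.ndarray  # per-variant minor-allele count in cases
    p0: float  # expected case share, n_cases / n_samples

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        if ((self.y < 0) | (self.y > self.n)).any():
            raise ValueError("need 0 <= y_i <= n_i")


def calpha_statistic(inputs: CalphaInputs) -> float:
    """C-alpha statistic; its null expectation is zero by construction."""
    n, y, p0 = inputs.n, inputs.y, inputs.p0
    return float(((y - n * p0) ** 2 - n * p0 * (1.0 - p0)).sum())


def calpha_from_features(features: FeatureMatrix | np.ndarray, y: np.ndarray) -> float:
    """C-alpha computed from a feature matrix and binary phenotype."""
    F = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(y, dtype=np.float64)
    _check_two_classes(y)
    n = F.sum(axis=0)
    yc = y @ F
    return calpha_statistic(CalphaInputs(n=n, y=yc, p0=float(y.mean())))


def ssu_statistic(features: FeatureMatrix | np.ndarray, y: np.ndarray) -> float:
    """Sum of squared score components ``U'U`` with ``U = F'(y - ybar)``."""
    F = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(y, dtype=np.float64)
    _check_two_classes(y)
    u = F.T @ (y - y.mean())
    return float(u @ u)


def _check_two_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("phenotype is constant; both classes required")


def hotelling_t2(m: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Hotelling T^2 with pooled covariance and pseudo-inverse."""
    m = np.asarray(m, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_two_classes(y)
    n1 = int(y.sum())
    n2 = len(y) - n1
    if n1 + n2 < 3:
        raise ValueError("need at least 3 samples")
    m1 = m[y == 1].mean(axis=0)
    m2 = m[y == 0].mean(axis=0)
    c1 = np.cov(m[y == 1], rowvar=False, ddof=1) if n1 > 1 else np.zeros((m.shape[1],) * 2)
    c2 = np.cov(m[y == 0], rowvar=False, ddof=1) if n2 > 1 else np.zeros((m.shape[1],) * 2)
    c1 = np.atleast_2d(c1)
    c2 = np.atleast_2d(c2)
    pooled = ((n1 - 1) * c1 + (n2 - 1) * c2) / (n1 + n2 - 2)
    d = m1 - m2
    return float(n1 * n2 / (n1 + n2) * d @ np.linalg.pinv(pooled) @ d)


def cmc_bin_matrix(
    features: FeatureMatrix, edges: tuple[int, ...] = DEFAULT_CMC_EDGES
) -> np.ndarray:
    """Per-sample carrier indicators of allele-count bins.

    ``edges`` are ascending lower bounds; bin ``k`` collects features
    with allele count in ``[edges[k], edges[k+1])`` (last bin
    unbounded).  The supervariant column always joins the first bin
    (it stands for the singletons).  Empty bins are dropped.
    """
    if len(edges) < 1 or list(edges) != sorted(edges):
        raise ValueError("edges must be ascending and non-empty")
    ac = np.where(features.is_super, edges[0], features.allele_counts)
    bins = []
    for k, lo in enumerate(edges):
        hi = edges[k + 1] if k + 1 < len(edges) else np.inf
        member = (ac >= lo) & (ac < hi)
        if member.any():
            bins.append((features.values[:, member] >= 1).any(axis=1))
    if not bins:
        raise ValueError("no non-empty CMC bins")
    return np.column_stack(bins).astype(np.float64)


def cmc_hotelling(
    features: FeatureMatrix,
    y: np.ndarray,
    edges: tuple[int, ...] = DEFAULT_CMC_EDGES,
) -> float:
    """CMC statistic: Hotelling T^2 on frequency-bin carrier indicators."""
    return hotelling_t2(cmc_bin_matrix(features, edges), y)


# ---------------------------------------------------------------------------
# permutation engine


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def permuted_label_matrix(
    y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_perm`` independent uniform shuffles of ``y``, one per row."""
    return rng.permuted(np.tile(np.asarray(y, dtype=np.float64), (n_perm, 1)), axis=1)


def _batch_hotelling(yp: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Hotelling T^2 for each permuted label row (vectorized over rows)."""
    n, _k = m.shape
    n1 = yp[0].sum()  # permutation-invariant
    n2 = n - n1
    ym = yp @ m
    m1 = ym / n1
    m2 = (m.sum(axis=0) - ym) / n2
    # case + control second moments sum to M'M regardless of the labels,
    # so the pooled covariance needs only the per-permutation group means
    tw_mat = m.T @ m
    num = (
        tw_mat[None, :, :]
        - n1 * np.einsum("bi,bj->bij", m1, m1)
        - n2 * np.einsum("bi,bj->bij", m2, m2)
    )
    pooled = num / (n - 2)
    d = m1 - m2
    sd = np.linalg.pinv(pooled) @ d[:, :, None]
    return (n1 * n2 / n) * np.einsum("bi,bi->b", d, sd[:, :, 0])


def _batch_statistics(
    features: FeatureMatrix,
    yp: np.ndarray,
    methods: tuple[str, ...],
    edges: tuple[int, ...],
) -> dict[str, np.ndarray]:
    """All requested statistics on every permuted label row."""
    out: dict[str, np.ndarray] = {}
    f = features.values
    nvec = f.sum(axis=0)
    n = f.shape[0]
    p0 = yp[0].sum() / n
    if "ssu" in methods or "calpha" in methods:
        yc = yp @ f
        if "calpha" in methods:
            out["calpha"] = ((yc - nvec * p0) ** 2).sum(axis=1) - (
                nvec * p0 * (1.0 - p0)
            ).sum()
        if "ssu" in methods:
            u = yc - p0 * nvec
            out["ssu"] = (u * u).sum(axis=1)
    if "cmc" in methods:
        out["cmc"] = _batch_hotelling(yp, cmc_bin_matrix(features, edges))
    return out


def _count_exceedances(
    features: FeatureMatrix,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    methods: tuple[str, ...],
    edges: tuple[int, ...],
    chunk: int = 10_000,
) -> dict[str, TestResult]:
    """Observed statistics plus exceedance counts over ``n_perm`` shuffles.

    The observed values are computed through the identical vectorized
    path as the permuted ones so exact ties compare exactly; the same
    label shuffles serve every method.
    """
    y = np.asarray(y, dtype=np.float64)
    _check_two_classes(y)
    observed = {
        m: float(v[0]) for m, v in _batch_statistics(features, y[None, :], methods, edges).items()
    }
    counts = {m: 0 for m in methods}
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        yp = permuted_label_matrix(y, size, rng)
        stats = _batch_statistics(features, yp, methods, edges)
        for m in methods:
            thr = observed[m] - _TIE_RTOL * max(1.0, abs(observed[m]))
            counts[m] += int((stats[m] >= thr).sum())
        done += size
    return {
        m: TestResult(statistic=observed[m], b=counts[m], B=n_perm, method=m)
        for m in methods
    }


def permutation_pvalue(
    stat_fn,
    features: FeatureMatrix | np.ndarray,
    phenotype: Phenotype | np.ndarray,
    n_perm: int,
    seed: int,
) -> TestResult:
    """Permutation p-value of an arbitrary statistic ``stat_fn(features, y)``.

    Labels are shuffled uniformly at random ``n_perm`` times; ``b``
    counts permuted statistics >= the observed one (ties count against
    significance), and ``p = b / B`` with ``b = 0`` displayed
    ``< 1/B``.  Reproducible from ``seed``.
    """
    y = phenotype.y if isinstance(phenotype, Phenotype) else np.asarray(phenotype)
    y = y.astype(np.float64)
    _check_two_classes(y)
    rng = _rng(seed)
    observed = float(stat_fn(features, y))
    thr = observed - _TIE_RTOL * max(1.0, abs(observed))
    b = 0
    done = 0
    while done < n_perm:
        size = min(10_000, n_perm - done)
        yp = permuted_label_matrix(y, size, rng)
        b += sum(float(stat_fn(features, row)) >= thr for row in yp)
        done += size
    name = getattr(stat_fn, "__name__", "statistic")
    return TestResult(statistic=observed, b=b, B=n_perm, method=name)


def bonferroni_threshold(alpha: float, n_genes: int) -> float:
    """Family-wise gene-based significance threshold ``alpha / n_genes``."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def two_step_scan(
    genesets: list[GeneVariantSet],
    matrix: GenotypeMatrix,
    phenotype: Phenotype,
    plan: PermutationPlan,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    collapse_singletons: bool = True,
    cmc_edges: tuple[int, ...] = DEFAULT_CMC_EDGES,
    alpha: float = 0.05,
    threshold_denominator: int | None = None,
) -> pd.DataFrame:
    """Screen every gene at ``plan.b1`` permutations, confirm candidates.

    Genes with estimated p below ``plan.alpha_promote`` for at least
    one method are re-tested at ``plan.b2`` for all methods.  Each
    (gene, stage) pair draws its own seeded permutation stream, shared
    across the three methods so they see identical label shuffles.
    Genes whose final p falls below the Bonferroni threshold are
    flagged significant.
    """
    denom = threshold_denominator if threshold_denominator is not None else max(len(genesets), 1)
    threshold = bonferroni_threshold(alpha, denom)
    rows = []
    for gi, gs in enumerate(genesets):
        n_sing = len(find_singletons(gs, matrix))
        fm = build_feature_matrix(gs, matrix, collapse_singletons=collapse_singletons)
        base = {
            "gene": gs.gene.name,
            "chrom": gs.gene.chrom,
            "n_variants": gs.n_variants,
            "n_singletons": n_sing,
            "n_features": fm.n_features,
        }
        if not fm.testable:
            for m in methods:
                rows.append({**base, "method": m, "stage": 1, "statistic": np.nan,
                             "b": -1, "B": plan.b1, "p": np.nan, "p_display": "NA",
                             "promoted": False, "significant": False})
            continue
        stage1 = _count_exceedances(
            fm, phenotype.y, plan.b1, _rng(plan.seed, gi, 1), methods, cmc_edges
        )
        promoted = any(r.p < plan.alpha_promote for r in stage1.values())
        final = stage1
        if promoted and plan.b2 > plan.b1:
            final = _count_exceedances(
                fm, phenotype.y, plan.b2, _rng(plan.seed, gi, 2), methods, cmc_edges
            )
        for stage, results in ((1, stage1),) + (((2, final),) if final is not stage1 else ()):
            for m in methods:
                r = results[m]
                is_final = results is final
                rows.append({
                    **base, "method": m, "stage": stage, "statistic": r.statistic,
                    "b": r.b, "B": r.B, "p": r.p, "p_display": r.p_display,
                    "promoted": promoted,
                    "significant": bool(is_final and r.p < threshold),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact tests on the supervariant


@dataclass
class FisherExactResult:
    """Two-sided exact p with conditional-MLE odds ratio and exact 95% CI."""

    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    table: ContingencyTable2x2 | None = None


def supervariant_table(sv: SuperVariant, phenotype: Phenotype) -> ContingencyTable2x2:
    """Tally carriers of the supervariant by case status."""
    if len(sv.x) != len(phenotype.y):
        raise ValueError("supervariant and phenotype dimensions differ")
    x = sv.x.astype(bool)
    y = phenotype.y.astype(bool)
    return ContingencyTable2x2(
        a=int((x & y).sum()), b=int((~x & y).sum()),
        c=int((x & ~y).sum()), d=int((~x & ~y).sum()),
    )


def _support(total: int, n_success: int, n_draw: int) -> tuple[int, int]:
    return max(0, n_draw - (total - n_success)), min(n_draw, n_success)


def _cmle_odds_ratio(x: int, total: int, n_success: int, n_draw: int) -> float:
    """Conditional MLE: odds solving ``E[X | psi] = x`` (noncentral hypergeometric)."""
    lo, hi = _support(total, n_success, n_draw)
    if x == lo:
        return 0.0
    if x == hi:
        return math.inf

    def score(log_psi: float) -> float:
        return nchypergeom_fisher.mean(total, n_success, n_draw, math.exp(log_psi)) - x

    return math.exp(_expanding_brentq(score))


def _expanding_brentq(f, lo: float = -5.0, hi: float = 5.0) -> float:
    """Root of monotone ``f`` with bracket expansion on the log-odds axis."""
    flo, fhi = f(lo), f(hi)
    for _ in range(20):
        if flo * fhi <= 0:
            return brentq(f, lo, hi, xtol=1e-10)
        if abs(flo) < abs(fhi):
            lo -= 5.0
            flo = f(lo)
        else:
            hi += 5.0
            fhi = f(hi)
    raise RuntimeError("failed to bracket root for odds-ratio inversion")


def _exact_ci(
    x: int, total: int, n_success: int, n_draw: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact CI by inverting one-sided noncentral-hypergeometric tail tests."""
    alpha = (1.0 - level) / 2.0
    lo, hi = _support(total, n_success, n_draw)
    if x == lo:
        lower = 0.0
    else:
        lower = math.exp(_expanding_brentq(
            lambda t: nchypergeom_fisher.sf(x - 1, total, n_success, n_draw, math.exp(t)) - alpha
        ))
    if x == hi:
        upper = math.inf
    else:
        upper = math.exp(_expanding_brentq(
            lambda t: nchypergeom_fisher.cdf(x, total, n_success, n_draw, math.exp(t)) - alpha
        ))
    return lower, upper


def fisher_exact_2x2(table: ContingencyTable2x2, ci_level: float = 0.95) -> FisherExactResult:
    """Two-sided Fisher exact test with conditional-MLE OR and exact CI.

    The p-value sums hypergeometric probabilities not exceeding the
    observed table's probability (margins fixed); zero/infinite odds
    ratios for empty cells are returned as such.
    """
    if min(table.n_cases, table.n_controls) == 0 or min(
        table.a + table.c, table.b + table.d
    ) == 0:
        raise ValueError("Fisher exact test undefined for a zero margin")
    p = float(_scipy_fisher(table.as_array())[1])
    total = table.a + table.b + table.c + table.d
    n_success = table.a + table.c  # carriers
    n_draw = table.a + table.b  # cases
    or_cmle = _cmle_odds_ratio(table.a, total, n_success, n_draw)
    ci = _exact_ci(table.a, total, n_success, n_draw, ci_level)
    return FisherExactResult(p=p, odds_ratio=or_cmle, ci_low=ci[0], ci_high=ci[1], table=table)


def _rounds_to(value: float, target: float, sig: int = 2) -> bool:
    """True when ``value`` prints as ``target`` at ``sig`` significant figures."""
    if not math.isfinite(value):
        return False
    return float(f"{value:.{sig - 1}e}") == float(f"{target:.{sig - 1}e}")


def reconstruct_table(
    n_cases: int,
    n_controls: int,
    p_target: float,
    ci_target: tuple[float, float] | None = None,
    sig: int = 2,
    ci_rel_tol: float = 0.01,
) -> list[tuple[ContingencyTable2x2, FisherExactResult]]:
    """Recover candidate 2x2 tables behind printed exact-test summaries.

    Enumerates every carrier split ``(a, c)`` with the given margins and
    keeps tables whose two-sided Fisher p rounds to ``p_target`` at
    ``sig`` significant figures and (optionally) whose 95% CI bounds
    fall within ``ci_rel_tol`` relative of ``ci_target``.  CI matching
    is tolerant rather than digit-exact because printed CI bounds
    inherit the root-finding tolerance of whatever software produced
    them (commonly ~1e-4 on the reciprocal-odds scale, i.e. a few
    hundredths at an upper bound near 30).  Deterministic; an empty
    list means no table matches.
    """
    if not 0.0 < p_target <= 1.0:
        raise ValueError("p_target must be in (0, 1]")
    matches = []
    for a in range(n_cases + 1):
        for c in range(n_controls + 1):
            tab = ContingencyTable2x2(a=a, b=n_cases - a, c=c, d=n_controls - c)
            if a + c == 0 or tab.b + tab.d == 0:
                continue
            p = float(_scipy_fisher(tab.as_array())[1])
            if not _rounds_to(p, p_target, sig):
                continue
            res = fisher_exact_2x2(tab)
            if ci_target is not None:
                lo_t, hi_t = ci_target
                lo_ok = (
                    abs(res.ci_low - lo_t) <= ci_rel_tol * abs(lo_t)
                    if lo_t > 0 else res.ci_low <= ci_rel_tol
                )
                hi_ok = (
                    abs(res.ci_high - hi_t) <= ci_rel_tol * abs(hi_t)
                    if math.isfinite(hi_t) else math.isinf(res.ci_high)
                )
                if not (lo_ok and hi_ok):
                    continue
            matches.append((tab, res))
    return matches


# ---------------------------------------------------------------------------
# per-variant exact testing


def _fisher_p_carrier_split(cache: dict, a: int, k: int, n_cases: int, n_controls: int) -> float:
    key = (a, k)
    if key not in cache:
        tab = np.array([[a, n_cases - a], [k - a, n_controls - (k - a)]])
        cache[key] = float(_scipy_fisher(tab)[1])
    return cache[key]


def per_variant_fisher(
    geneset: GeneVariantSet,
    matrix: GenotypeMatrix,
    phenotype: Phenotype,
) -> tuple[float, np.ndarray]:
    """Fisher exact test of each variant individually (carrier dichotomy).

    Every variant is dichotomized to carrier (dosage >= 1) versus
    non-carrier and tested against case status; returns the minimum p
    and the per-variant p array (in gene-set index order).  Variants
    with identical carrier splits share one exact-test evaluation.
    """
    idx = geneset.variant_indices
    if idx.size == 0:
        return math.inf, np.empty(0)
    carrier = matrix.dosages[:, idx] >= 1
    y = phenotype.y.astype(bool)
    a_counts = carrier[y].sum(axis=0)
    k_counts = carrier.sum(axis=0)
    cache: dict = {}
    ps = np.array([
        _fisher_p_carrier_split(cache, int(a), int(k), phenotype.n_cases, phenotype.n_controls)
        for a, k in zip(a_counts, k_counts)
    ])
    return float(ps.min()), ps
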