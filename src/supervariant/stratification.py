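"""Population-stratification check: PCA covariates for the supervariant.

Confounding by ancestry is probed by computing principal components
from a random set of common variants (no missing genotypes, MAF above
0.1) and re-testing the supervariant in a logistic regression with the
top components as covariates.  If the supervariant signal survives
adjustment while the components themselves are not significant, the
association is unlikely to be an artifact of population structure.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .preprocess import minor_allele_frequencies, missing_rates
from .types import GenotypeMatrix, Phenotype, SuperVariant

logger = logging.getLogger(__name__)


@dataclass
class PCSet:
    """Principal-component scores (one row per sample)."""

    scores: np.ndarray  # n_samples x k
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class AdjustedTestResult:
    """Wald tests from the PC-adjusted logistic regression."""

    p_super: float
    beta_super: float
    p_pcs: np.ndarray
    separation: bool = False
    method: str = "mle"


def select_common_variants(
    matrix: GenotypeMatrix,
    maf_min: float = 0.1,
    n: int = 100_000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Uniform random draw (without replacement) of common variants.

    Eligible variants have no missing genotype and MAF strictly above
    ``maf_min``; if fewer than ``n`` qualify, all are returned with a
    warning.
    """
    maf = minor_allele_frequencies(matrix)
    eligible = np.flatnonzero(
        (missing_rates(matrix) == 0.0) & (np.nan_to_num(maf, nan=0.0) > maf_min)
    )
    if eligible.size == 0:
        raise ValueError(f"no variants with MAF > {maf_min} and zero missingness")
    if eligible.size < n:
        logger.warning(
            "only %d common variants eligible (requested %d); using all",
            eligible.size, n,
        )
        chosen = eligible
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(eligible, size=n, replace=False)
    return matrix.subset_variants(np.sort(chosen))


def pca_top_k(common: GenotypeMatrix, k: int = 10) -> PCSet:
    """Top-k principal components of z-scaled genotypes.

    Each variant column is centered and scaled to unit variance
    (zero-variance columns dropped); scores are the sample projections
    onto the leading eigenvectors of the covariance.  The sign of each
    component is fixed by making its largest-magnitude variant loading
    positive.
    """
    g = common.dosages.astype(np.float64)
    sd = g.std(axis=0)
    keep = sd > 0
    g = (g[:, keep] - g[:, keep].mean(axis=0)) / sd[keep]
    n = g.shape[0]
    rank = min(n - 1, g.shape[1])
    if k > rank:
        logger.warning("k=%d exceeds rank %d; reducing", k, rank)
        k = rank
    if k < 1:
        raise ValueError("no usable components")
    u, s, vt = np.linalg.svd(g, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| positive per component
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    total_var = (g ** 2).sum()
    return PCSet(scores=scores, explained_variance_ratio=s ** 2 / total_var)


def logistic_adjusted_test(
    supervariant: SuperVariant,
    phenotype: Phenotype,
    pcs: PCSet | None,
) -> AdjustedTestResult:
    """Logistic regression of case status on [supervariant, PC1..PCk].

    Per-coefficient Wald p-values are reported.  Perfect (or quasi-)
    separation is detected via non-convergence or exploding standard
    errors and handled by a Firth-penalized fit, labeled in the result.
    """
    k = 0 if pcs is None else pcs.k
    x = supervariant.x.astype(np.float64)[:, None]
    if k:
        x = np.column_stack([x, pcs.scores])
    design = sm.add_constant(x, prepend=True)
    y = phenotype.y.astype(np.float64)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        se = np.asarray(fit.bse)
        converged = bool(fit.mle_retvals.get("converged", True))
        if not converged or not np.isfinite(se).all() or se.max() > 50:
            raise np.linalg.LinAlgError("separation suspected")
        pvals = np.asarray(fit.pvalues)
        return AdjustedTestResult(
            p_super=float(pvals[1]), beta_super=float(fit.params[1]),
            p_pcs=pvals[2:], separation=False, method="mle",
        )
    except Exception:
        logger.warning("logistic MLE unstable (separation?); Firth fallback")
        beta, pvals = _firth_logistic(design, y)
        return AdjustedTestResult(
            p_super=float(pvals[1]), beta_super=float(beta[1]),
            p_pcs=pvals[2:], separation=True, method="firth",
        )


def _firth_logistic(
    x: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-penalized logistic fit; Wald p from the penalized
    information matrix.  Finite estimates exist even under separation."""
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = x.T @ (w[:, None] * x)
        cov = np.linalg.pinv(info)
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", x * np.sqrt(w)[:, None], cov, x * np.sqrt(w)[:, None])
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        if np.abs(step).max() > 5.0:
            step *= 5.0 / np.abs(step).max()
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.pinv(x.T @ (w[:, None] * x))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    return beta, 2.0 * norm.sf(np.abs(z))


def write_pc_scores(pcs: PCSet, phenotype: Phenotype, path: str | Path) -> None:
    df = pd.DataFrame(
        pcs.scores, columns=[f"PC{i + 1}" for i in range(pcs.k)]
    )
    df.insert(0, "sample_id", phenotype.sample_ids)
    df.to_csv(path, sep="\t", index=False)
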