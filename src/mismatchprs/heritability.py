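"""Heritability of acute rejection from genome-wide mismatch scores.

The genetic relationship between two transplant *pairs* is summarized by the
correlation of their mismatch profiles: each QC-passing SNP's mismatch column is
standardized and K = Z Z' / m is the mismatch relationship matrix (the analogue of
a GRM built on genotypes).  The proportion of phenotypic variance tied to K is
estimated by Haseman-Elston (HE) regression — regressing phenotypic cross-products
on the corresponding K entries — with a single-component REML estimator available
behind the same interface.  The binary rejection indicator is analyzed on the
observed (0/1) scale; fixed clinical covariates are regressed out first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .mismatch_qc import MismatchMatrix

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Heritability estimate on the observed scale.

    ``h2`` is reported raw (moment estimates may fall outside [0, 1];
    ``truncated`` flags whether clipping *would* apply, the estimate itself is
    never clipped).
    """

    h2: float
    se: float
    p_value: float
    method: str
    n_snps: int
    n_pairs: int

    @property
    def truncated(self) -> bool:
        return not (0.0 <= self.h2 <= 1.0)


def mismatch_relationship_matrix(
    mismatch: MismatchMatrix, snp_ids: list[str] | None = None
) -> tuple[np.ndarray, int]:
    """Pairs x pairs relationship matrix K = Z Z' / m from standardized mismatch.

    Zero-variance mismatch columns are dropped (with a logged count); missing
    scores are mean-imputed per SNP before standardization (they contribute 0).
    Returns (K, m) with m the number of SNPs actually used.  By construction the
    mean of diag(K) is exactly 1.
    """
    if snp_ids is None:
        scores = mismatch.scores
    else:
        wanted = set(snp_ids)
        cols = np.flatnonzero(np.isin(mismatch.snp_ids, list(wanted)))
        scores = mismatch.scores[:, cols]
    n, m_all = scores.shape
    if n < 2:
        raise ValueError("need at least 2 pairs")
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(scores, axis=0)
        sd = np.nanstd(scores, axis=0)
    keep = np.isfinite(sd) & (sd > 0)
    n_dropped = int(m_all - keep.sum())
    if n_dropped:
        logger.info("relationship matrix: dropped %d zero-variance mismatch columns", n_dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 SNPs with nonzero mismatch variance")
    Z = (scores[:, keep] - mu[keep]) / sd[keep]
    Z = np.nan_to_num(Z, nan=0.0)
    m = int(keep.sum())
    K = Z @ Z.T / m
    # restore exact unit diagonal mean lost to the biased (1/n) variance estimate
    K *= n / np.trace(K)
    return K, m


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, float)
    if covariates is None:
        return y - y.mean()
    X = np.column_stack([np.ones(y.size), np.asarray(covariates, float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def he_regression(
    K: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    n_snps: int | None = None,
    jackknife: bool = False,
) -> VarianceComponents:
    """Haseman-Elston regression of phenotype cross-products on kinship entries.

    The (covariate-residualized, centered) phenotype y is scaled by its variance;
    the slope of ``y_j y_k / var(y)`` on ``K_jk`` over all j < k estimates the
    observed-scale heritability.  The default SE comes from the OLS slope; a
    delete-one-pair jackknife SE is available (it is robust to the correlation
    between products sharing a pair).
    """
    K = np.asarray(K, float)
    n = K.shape[0]
    if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be a symmetric square matrix")
    y = np.asarray(phenotype, float)
    if y.std() == 0:
        raise ValueError("phenotype is constant")
    y = _residualize(y, covariates)
    y = y / y.std()

    iu, ju = np.triu_indices(n, k=1)
    x = K[iu, ju]
    if x.std() == 0:
        raise ValueError(
            "no variance among off-diagonal kinship entries; the relationship "
            "matrix carries no information (is it the identity?)"
        )
    prod = y[iu] * y[ju]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ prod) / sxx
    resid = prod - prod.mean() - slope * xc
    dof = x.size - 2
    se = float(np.sqrt(resid @ resid / dof / sxx))

    if jackknife:
        # delete-one-pair jackknife via per-pair sufficient-statistic updates
        se = _jackknife_se(K, y, slope)
    z = slope / se
    p = float(norm.sf(z))  # one-sided: alternative is positive heritability
    return VarianceComponents(
        h2=slope,
        se=se,
        p_value=p,
        method="he_regression",
        n_snps=n_snps if n_snps is not None else -1,
        n_pairs=n,
    )


def _jackknife_se(K: np.ndarray, y: np.ndarray, slope_full: float) -> float:
    """Delete-one-pair jackknife SE of the HE slope in O(n^2)."""
    n = K.shape[0]
    mask = ~np.eye(n, dtype=bool)
    x_all = K[np.triu_indices(n, 1)]
    p_all = np.outer(y, y)[np.triu_indices(n, 1)]
    N = x_all.size
    Sx, Sp = x_all.sum(), p_all.sum()
    Sxx, Sxp = float(x_all @ x_all), float(x_all @ p_all)
    # per-row contributions (each unordered pair counted once per member)
    rx = np.where(mask, K, 0.0).sum(axis=1)
    rp = (np.where(mask, np.outer(y, y), 0.0)).sum(axis=1)
    rxx = (np.where(mask, K**2, 0.0)).sum(axis=1)
    rxp = (np.where(mask, K * np.outer(y, y), 0.0)).sum(axis=1)
    slopes = np.empty(n)
    for i in range(n):
        Ni = N - (n - 1)
        sx, sp = Sx - rx[i], Sp - rp[i]
        sxx, sxp = Sxx - rxx[i], Sxp - rxp[i]
        denom = sxx - sx * sx / Ni
        slopes[i] = (sxp - sx * sp / Ni) / denom
    return float(np.sqrt((n - 1) / n * np.sum((slopes - slopes.mean()) ** 2)))


def reml_single_component(
    K: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    n_snps: int | None = None,
) -> VarianceComponents:
    """Single-component REML: y ~ N(0, sigma2 * (h2 K + (1-h2) I)).

    Works on the eigenbasis of K, profiling the total variance, and maximizes the
    restricted likelihood over h2 in [0, 1] by bounded scalar optimization.  The SE
    comes from the numerical curvature of the profile likelihood; the p-value from
    a half-half chi-square mixture LRT against h2 = 0 (the boundary null).
    """
    K = np.asarray(K, float)
    n = K.shape[0]
    y = _residualize(np.asarray(phenotype, float), covariates)
    vals, vecs = np.linalg.eigh(K)
    ystar = vecs.T @ y
    dof = n - 1  # intercept removed in residualization

    def nll(h2: float) -> float:
        d = h2 * vals + (1.0 - h2)
        d = np.maximum(d, 1e-10)
        sigma2 = float(np.sum(ystar**2 / d)) / dof
        return 0.5 * (np.sum(np.log(d)) + dof * np.log(sigma2) + dof)

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8})
    h2 = float(res.x)
    eps = 1e-4
    lo, hi = max(h2 - eps, 0.0), min(h2 + eps, 1.0)
    curv = (nll(lo) - 2 * nll(h2) + nll(hi)) / ((hi - lo) / 2) ** 2
    se = float(1.0 / np.sqrt(curv)) if curv > 0 else float("nan")
    lrt = 2.0 * (nll(0.0) - nll(h2))
    p = float(0.5 * chi2.sf(max(lrt, 0.0), df=1)) if h2 > 0 else 1.0
    return VarianceComponents(
        h2=h2,
        se=se,
        p_value=p,
        method="reml",
        n_snps=n_snps if n_snps is not None else -1,
        n_pairs=n,
    )


def estimate_heritability(
    mismatch: MismatchMatrix,
    phenotype: np.ndarray,
    snp_ids: list[str] | None = None,
    covariates: np.ndarray | None = None,
    method: str = "he_regression",
    jackknife: bool = False,
) -> VarianceComponents:
    """End-to-end: relationship matrix from mismatch scores, then HE or REML."""
    K, m = mismatch_relationship_matrix(mismatch, snp_ids)
    if method == "he_regression":
        return he_regression(K, phenotype, covariates, n_snps=m, jackknife=jackknife)
    if method == "reml":
        return reml_single_component(K, phenotype, covariates, n_snps=m)
    raise ValueError(f"unknown method {method!r}")


def write_grm(K: np.ndarray, n_snps: int, pair_ids, prefix: str) -> None:
    """Write K in GCTA GRM triplet text format (i, j, m, value) plus an id file."""
    with open(f"{prefix}.grm", "w") as fh:
        for i in range(K.shape[0]):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t{K[i, j]:.6f}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for pid in pair_ids:
            fh.write(f"{pid}\t{pid}\n")
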