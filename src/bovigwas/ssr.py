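"""Single SNP regression: per-SNP allele-count effect in an animal mixed model.

Model: y = 1 mu + x_j b_j + u + e, u ~ N(0, A sigma2_a), e ~ N(0, I sigma2_e),
with A the pedigree relationship matrix.  Variance components are estimated
once by REML on the null model (no SNP) through an eigendecomposition of A
and a one-dimensional profile likelihood over the variance ratio; the scan
then fits each SNP by generalized least squares with the covariance
structure held fixed and the residual scale re-estimated per SNP
(EMMAX/GRAMMAR-style).  P-values are two-sided Wald tests against a
standard normal reference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genio import GenotypeSet, PhenotypeTable
from .kinship import AMatrix, subset_amatrix

__all__ = [
    "VarianceComponents",
    "SsrResult",
    "MixedModelGWAS",
    "estimate_varcomp",
    "ssr_scan",
    "write_ssr",
    "read_ssr",
]


@dataclass
class VarianceComponents:
    """Null-model REML variance components; h2 = sigma2_a / (sigma2_a + sigma2_e)."""

    sigma2_a: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0


@dataclass
class SsrResult:
    """Per-SNP effect, standard error and Wald p-value from the scan."""

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n_used: int
    degenerate: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "effect": self.effect,
                "se": self.se,
                "p": self.p,
            }
        )


class MixedModelGWAS(BaseEstimator):
    """Scikit-learn style estimator for the mixed-model single-SNP scan.

    Parameters
    ----------
    max_ratio_log10 : bound for the REML search over log10(sigma2_a/sigma2_e).

    After ``fit(X, y, amatrix=...)`` (X: animals x SNPs dosage matrix), the
    fitted attributes are ``sigma2_a_``, ``sigma2_e_``, ``h2_``,
    ``effects_``, ``se_``, ``pvalues_`` and ``degenerate_``.  With no
    ``amatrix`` the model reduces to ordinary least squares per SNP.
    """

    def __init__(self, max_ratio_log10: float = 6.0):
        self.max_ratio_log10 = max_ratio_log10

    def fit(self, X, y, amatrix: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, m = X.shape
        if len(y) != n:
            raise ValueError("X and y have different numbers of animals")
        if n < 10:
            raise ValueError("need at least 10 animals")
        if np.ptp(y) == 0:
            raise ValueError("phenotype has zero variance")
        A = np.eye(n) if amatrix is None else np.asarray(amatrix, dtype=float)
        d, U = np.linalg.eigh(A)
        if d.min() < -1e-6 * max(1.0, d.max()):
            raise ValueError("relationship matrix is not positive semi-definite")
        d = np.clip(d, 0.0, None)
        self.sigma2_a_, self.sigma2_e_ = _reml_null(y, d, U, self.max_ratio_log10)
        self.h2_ = VarianceComponents(self.sigma2_a_, self.sigma2_e_).h2
        eff, se, p, degen = _gls_scan(X, y, d, U, self.sigma2_a_, self.sigma2_e_)
        self.effects_, self.se_, self.pvalues_, self.degenerate_ = eff, se, p, degen
        self.n_features_in_ = m
        return self


def _reml_null(y: np.ndarray, d: np.ndarray, U: np.ndarray, max_log10: float) -> tuple[float, float]:
    """REML of (sigma2_a, sigma2_e) for y = 1 mu + u + e via profile over the ratio."""
    n = len(y)
    ystar = U.T @ y
    tstar = U.T @ np.ones(n)

    def neg_restricted_ll(log10_lam: float) -> float:
        lam = 10.0 ** log10_lam  # sigma2_a / sigma2_e
        w = 1.0 / (lam * d + 1.0)
        stt = np.sum(w * tstar * tstar)
        sty = np.sum(w * tstar * ystar)
        mu = sty / stt
        resid = ystar - mu * tstar
        rss = np.sum(w * resid * resid)
        sigma2_e = rss / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2.0 * np.pi * sigma2_e)
            + (n - 1)
            - np.sum(np.log(w))
            + np.log(stt)
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-max_log10, max_log10), method="bounded",
        options={"xatol": 1e-8},
    )
    # compare against the boundary lam -> 0 (pure residual) explicitly
    best = res.x if res.fun <= neg_restricted_ll(-max_log10) else -max_log10
    lam = 10.0 ** best
    w = 1.0 / (lam * d + 1.0)
    stt = np.sum(w * tstar * tstar)
    mu = np.sum(w * tstar * ystar) / stt
    resid = ystar - mu * tstar
    sigma2_e = np.sum(w * resid * resid) / (n - 1)
    if best <= -max_log10 + 1e-9:
        lam = 0.0
    return lam * sigma2_e, sigma2_e


def _gls_scan(
    X: np.ndarray, y: np.ndarray, d: np.ndarray, U: np.ndarray,
    sigma2_a: float, sigma2_e: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n, m = X.shape
    w = 1.0 / (sigma2_a * d + sigma2_e)
    ystar = U.T @ y
    tstar = U.T @ np.ones(n)
    G = U.T @ X  # rotated dosages
    stt = np.sum(w * tstar * tstar)
    sty = np.sum(w * tstar * ystar)
    syy = np.sum(w * ystar * ystar)
    wg = w[:, None] * G
    sgg = np.einsum("ij,ij->j", G, wg)
    stg = tstar @ wg
    sgy = ystar @ wg
    det = stt * sgg - stg * stg
    degen = X.std(axis=0) == 0.0
    safe_det = np.where(det <= 0, np.nan, det)
    b = (stt * sgy - stg * sty) / safe_det
    mu = (sgg * sty - stg * sgy) / safe_det
    # weighted RSS per SNP, expanded algebraically
    rss = syy - 2.0 * (mu * sty + b * sgy) + mu * mu * stt + 2.0 * mu * b * stg + b * b * sgg
    scale = np.clip(rss, 0.0, None) / max(n - 2, 1)
    se = np.sqrt(scale * stt / safe_det)
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    degen |= ~np.isfinite(p)
    b = np.where(degen, 0.0, b)
    se = np.where(degen, np.nan, se)
    p = np.where(degen, 1.0, p)
    return b, se, np.clip(p, np.finfo(float).tiny, 1.0), degen


# ---------------------------------------------------------------------------
# module-level pipeline surface

def estimate_varcomp(y: PhenotypeTable, amatrix: AMatrix) -> VarianceComponents:
    """REML variance components of the null animal model for one trait."""
    traits = y.traits
    if len(traits) != 1:
        raise ValueError("estimate_varcomp expects a single-trait table")
    a_sub = subset_amatrix(amatrix, y.animals)
    est = MixedModelGWAS().fit(np.zeros((len(y.animals), 0)), y.y, amatrix=a_sub.values)
    return VarianceComponents(est.sigma2_a_, est.sigma2_e_)


def ssr_scan(
    genotypes: GenotypeSet,
    y: PhenotypeTable,
    amatrix: AMatrix,
    vc: VarianceComponents | None = None,
) -> SsrResult:
    """GLS scan of every SNP for one trait; missing calls mean-imputed."""
    gs = genotypes.take_animals(y.animals)
    a_sub = subset_amatrix(amatrix, y.animals)
    X = gs.dosage()
    est = MixedModelGWAS()
    if vc is not None:
        # reuse supplied variance components, skipping the REML step
        d, U = np.linalg.eigh(a_sub.values)
        d = np.clip(d, 0.0, None)
        eff, se, p, degen = _gls_scan(X, y.y, d, U, vc.sigma2_a, vc.sigma2_e)
    else:
        est.fit(X, y.y, amatrix=a_sub.values)
        eff, se, p, degen = est.effects_, est.se_, est.pvalues_, est.degenerate_
    return SsrResult(
        snp_ids=list(gs.snp_ids),
        chrom=gs.chrom,
        pos=gs.pos,
        effect=eff,
        se=se,
        p=p,
        n_used=gs.n_animals,
        degenerate=degen,
    )


def write_ssr(result: SsrResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def read_ssr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
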