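"""Storey-Tibshirani q-values and QTL calling by adjacent significant SNPs.

pi0, the proportion of true nulls, is estimated from the flat right tail of
the p-value histogram: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the
grid lambda = 0, 0.05, ..., 0.90, smoothed by a natural cubic smoother and
read off at lambda = 0.90.  q-values follow the step-up recursion
q_(i) = min(pi0 * m * p_(i) / i, q_(i+1)), so with pi0 = 1 they reduce to
Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeSet

__all__ = ["QvalueResult", "QtlCall", "estimate_pi0", "qvalues", "call_ssr_qtl", "write_qtl_bed"]


@dataclass
class QvalueResult:
    """Per-SNP p and q values, the pi0 estimate, and pSSR = #{q >= 0.05}/m."""

    p: np.ndarray
    q: np.ndarray
    pi0: float
    p_ssr: float


@dataclass
class QtlCall:
    """A genomic span called as one QTL, with its member SNPs and score."""

    chrom: str
    start: int
    end: int
    snp_ids: tuple[str, ...]
    source: str
    score: float
    occurrence_rate: int | None = None


def estimate_pi0(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    min_m_for_smoother: int = 100,
) -> float:
    """Smoother-based pi0 estimate; returns 1 for fewer than 100 p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m < min_m_for_smoother:
        return 1.0
    lam = np.arange(0.0, 0.901, 0.05) if lambdas is None else np.asarray(lambdas, float)
    raw = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    coeffs = np.polynomial.polynomial.polyfit(lam, raw, 3)
    smoothed = float(np.polynomial.polynomial.polyval(lam[-1], coeffs))
    return float(min(1.0, max(1.0 / m, smoothed)))


def qvalues(pvalues: np.ndarray, pi0: float | None = None) -> QvalueResult:
    """Step-up q-values at a given (or estimated) pi0."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = min(1.0, pi0 * p[order[-1]])
    q_sorted[-1] = running
    for i in range(m - 2, -1, -1):
        running = min(pi0 * m * p[order[i]] / (i + 1), running)
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return QvalueResult(p=p, q=q, pi0=float(pi0), p_ssr=float(np.mean(q >= 0.05)))


def call_ssr_qtl(
    qvalue_result: QvalueResult,
    snp_ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    alpha: float = 0.05,
) -> list[QtlCall]:
    """Merge maximal runs of map-adjacent SNPs with q < alpha into QTL.

    Runs never cross chromosome boundaries; the SNP map must already be
    sorted by chromosome and position (the pipeline's invariant order).
    """
    sig = qvalue_result.q < alpha
    calls: list[QtlCall] = []
    i, m = 0, len(snp_ids)
    while i < m:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and sig[j + 1] and chrom[j + 1] == chrom[i]:
            j += 1
        calls.append(
            QtlCall(
                chrom=str(chrom[i]),
                start=int(pos[i]),
                end=int(pos[j]),
                snp_ids=tuple(snp_ids[i : j + 1]),
                source="ssr",
                score=float(qvalue_result.q[i : j + 1].min()),
            )
        )
        i = j + 1
    return calls


def write_qvalues(
    result: QvalueResult, snp_ids: list[str], path: str | Path
) -> None:
    pd.DataFrame({"snp_id": snp_ids, "p": result.p, "q": result.q}).to_csv(
        path, sep="\t", index=False
    )


def write_qtl_bed(calls: list[QtlCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(calls):
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\tqtl{k}\t{c.score:.6g}\n")
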