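"""Multi-prior BayesB ensemble: occurrence rates and analysis selection.

Eleven analyses are run per trait, differing only in the prior association
probability 1 - pi: eight values log-uniformly spaced from 0.05 down to
6.25e-5, plus three derived from the single-SNP-regression scan (half of,
exactly, and double the proportion of SNPs that were NOT significant there,
applied to the associated proportion and capped at 0.5).  High-PP QTL
(window PP > 0.5) from different analyses are identified as the same QTL
when their member-SNP sets intersect (transitively); each QTL's occurrence
rate is the number of analyses in which a matching QTL appears, and the
analysis whose QTL have the highest average occurrence rate supplies the
final calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayesb import PosteriorProb
from .fdr import QtlCall

__all__ = [
    "PriorGrid",
    "EnsembleResult",
    "build_prior_grid",
    "call_high_pp_qtl",
    "occurrence_rates",
    "select_analysis",
]

FIXED_GRID_TOP = 0.05
FIXED_GRID_BOTTOM = 6.25e-5
FIXED_GRID_SIZE = 8


@dataclass
class PriorGrid:
    """Eleven 1 - pi values: the fixed grid plus three pSSR-derived priors."""

    values: list[float]

    def __post_init__(self) -> None:
        if len(self.values) != 11:
            raise ValueError("prior grid must hold exactly 11 values")
        if any(not (0.0 < v < 1.0) for v in self.values):
            raise ValueError("all priors must lie in (0, 1)")
        self.values = sorted(self.values, reverse=True)


@dataclass
class EnsembleResult:
    """Per-analysis prior, QTL calls and average occurrence rate."""

    priors: list[float]
    qtl_per_analysis: list[list[QtlCall]]
    average_rates: list[float] = field(default_factory=list)
    selected: int | None = None


def build_prior_grid(p_ssr: float) -> PriorGrid:
    """The paper-style 11-prior grid given pSSR from the SSR scan."""
    if not (0.0 < p_ssr < 1.0):
        raise ValueError("p_ssr must be in (0, 1)")
    fixed = list(np.geomspace(FIXED_GRID_TOP, FIXED_GRID_BOTTOM, FIXED_GRID_SIZE))
    assoc = 1.0 - p_ssr
    derived = [assoc / 2.0, assoc, min(2.0 * assoc, 0.5)]
    values = fixed + derived
    # resolve collisions by a half-step perturbation so the grid keeps 11 entries
    step = (np.log(FIXED_GRID_TOP) - np.log(FIXED_GRID_BOTTOM)) / (FIXED_GRID_SIZE - 1)
    seen: list[float] = []
    out: list[float] = []
    for v in values:
        while any(np.isclose(v, u, rtol=1e-12, atol=0) for u in seen):
            warnings.warn(f"prior grid collision at {v:g}; perturbing by a half grid step")
            v = min(v * np.exp(step / 2.0), 0.999999)
        seen.append(v)
        out.append(float(v))
    return PriorGrid(out)


def call_high_pp_qtl(
    pp: PosteriorProb,
    snp_ids: list[str],
    pos: np.ndarray,
    threshold: float = 0.5,
) -> list[QtlCall]:
    """Windows with PP strictly above threshold, overlaps merged per chromosome."""
    sig = np.nonzero(pp.window_pp > threshold)[0]
    calls: list[QtlCall] = []
    current: dict | None = None
    for w in sig:
        c = pp.window_chrom[w]
        first, last = int(pp.window_first[w]), int(pp.window_last[w])
        if current is not None and current["chrom"] == c and first <= current["last"]:
            current["last"] = max(current["last"], last)
            current["score"] = max(current["score"], float(pp.window_pp[w]))
        else:
            if current is not None:
                calls.append(_close(current, snp_ids, pos))
            current = {
                "chrom": c,
                "first": first,
                "last": last,
                "score": float(pp.window_pp[w]),
            }
    if current is not None:
        calls.append(_close(current, snp_ids, pos))
    return calls


def _close(span: dict, snp_ids: list[str], pos: np.ndarray) -> QtlCall:
    f, l = span["first"], span["last"]
    return QtlCall(
        chrom=str(span["chrom"]),
        start=int(pos[f]),
        end=int(pos[l]),
        snp_ids=tuple(snp_ids[f : l + 1]),
        source="bayesb",
        score=span["score"],
    )


def occurrence_rates(per_analysis_qtl: list[list[QtlCall]]) -> list[list[QtlCall]]:
    """Fill occurrence rates by transitive member-set matching across analyses.

    QTL whose member-SNP sets intersect (directly or through a chain of
    intersecting QTL) form one cluster; every QTL in a cluster receives the
    number of distinct analyses contributing to the cluster.
    """
    if not per_analysis_qtl:
        raise ValueError("need at least one analysis")
    items = [
        (ai, qi, set(q.snp_ids))
        for ai, qtls in enumerate(per_analysis_qtl)
        for qi, q in enumerate(qtls)
    ]
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    snp_owner: dict[str, int] = {}
    for k, (_, _, members) in enumerate(items):
        for s in members:
            if s in snp_owner:
                ra, rb = find(snp_owner[s]), find(k)
                if ra != rb:
                    parent[rb] = ra
            else:
                snp_owner[s] = k
    analyses_per_cluster: dict[int, set[int]] = {}
    for k, (ai, _, _) in enumerate(items):
        analyses_per_cluster.setdefault(find(k), set()).add(ai)
    out = [[QtlCall(**{**q.__dict__}) for q in qtls] for qtls in per_analysis_qtl]
    for k, (ai, qi, _) in enumerate(items):
        out[ai][qi].occurrence_rate = len(analyses_per_cluster[find(k)])
    return out


def select_analysis(ensemble: EnsembleResult) -> int:
    """Argmax of average occurrence rate; ties go to the larger 1 - pi.

    Fills ``ensemble.average_rates`` and ``ensemble.selected`` in place and
    returns the selected analysis index.
    """
    rated = occurrence_rates(ensemble.qtl_per_analysis)
    ensemble.qtl_per_analysis = rated
    if all(len(q) == 0 for q in rated):
        raise ValueError("no high PP QTL in any analysis")
    averages = []
    for qtls in rated:
        if qtls:
            averages.append(sum(q.occurrence_rate for q in qtls) / len(qtls))
        else:
            averages.append(0.0)
    ensemble.average_rates = averages
    best = max(averages)
    candidates = [i for i, a in enumerate(averages) if a == best]
    if len(candidates) > 1:
        warnings.warn("tied average occurrence rates; choosing the larger 1 - pi")
        candidates.sort(key=lambda i: -ensemble.priors[i])
    ensemble.selected = candidates[0]
    return ensemble.selected
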