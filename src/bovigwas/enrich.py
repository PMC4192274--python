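"""QTL -> nearby genes -> human orthologs -> pathway over-representation.

Bovine genes overlapping a 500 kb flank around any member SNP of a
significant QTL are mapped to human orthologs and tested for pathway
over-representation against a background of orthologs of all genes near
any analyzed SNP.  With no gene-length bias correction the sampling model
is the classical hypergeometric: p = P(X >= overlap) with population size
|background|, successes |pathway intersect background| and draws |hits|.
Raw p-values are reported (flag significance at p < alpha, no multiplicity
correction); an optional Benjamini-Hochberg column is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fdr import QtlCall
from .genio import GeneSet, OrthologMap, PathwayDB

__all__ = [
    "GeneHitSet",
    "PathwayResult",
    "genes_near_qtl",
    "genes_near_snps",
    "map_orthologs",
    "enrichment_test",
    "combined_trait_set",
    "results_to_frame",
]

DEFAULT_FLANK_BP = 500_000


@dataclass
class GeneHitSet:
    """Hit orthologs for one trait (or "combined") plus the shared background."""

    trait: str
    bovine_hits: frozenset[str]
    human_hits: frozenset[str]
    background: frozenset[str]
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        if not self.human_hits <= self.background:
            raise ValueError("hit orthologs must be a subset of the background")


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    overlap: int
    n_hits: int
    pathway_size: int
    background_size: int
    p: float
    overlap_genes: tuple[str, ...]
    significant: bool


def genes_near_snps(
    positions: dict[str, np.ndarray], genes: GeneSet, flank_bp: int = DEFAULT_FLANK_BP
) -> set[str]:
    """Bovine gene ids whose span overlaps [pos - flank, pos + flank] for any SNP.

    ``positions`` maps chromosome label -> sorted SNP bp positions.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    out: set[str] = set()
    for row in genes.df.itertuples(index=False):
        pos = positions.get(str(row.chrom))
        if pos is None or len(pos) == 0:
            continue
        # overlap iff some snp in [start - flank, end + flank]
        lo = np.searchsorted(pos, row.start - flank_bp, side="left")
        if lo < len(pos) and pos[lo] <= row.end + flank_bp:
            out.add(row.gene_id)
    return out


def genes_near_qtl(
    qtl: list[QtlCall],
    genes: GeneSet,
    snp_positions: dict[str, int],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> set[str]:
    """Bovine genes within the flank of any member SNP of any QTL.

    ``snp_positions`` maps snp_id -> bp position; flanks are measured from
    member SNP positions, not from QTL span ends.
    """
    per_chrom: dict[str, list[int]] = {}
    for q in qtl:
        for sid in q.snp_ids:
            per_chrom.setdefault(q.chrom, []).append(snp_positions[sid])
    arrays = {c: np.array(sorted(v), dtype=np.int64) for c, v in per_chrom.items()}
    return genes_near_snps(arrays, genes, flank_bp)


def map_orthologs(bovine_ids: set[str], ortholog_map: OrthologMap) -> tuple[set[str], int]:
    """Union of human orthologs; returns (human ids, count of unmapped bovine genes)."""
    human: set[str] = set()
    unmapped = 0
    for b in bovine_ids:
        hs = ortholog_map.mapping.get(b, frozenset())
        if hs:
            human |= hs
        else:
            unmapped += 1
    return human, unmapped


def build_hit_set(
    trait: str,
    qtl: list[QtlCall],
    genes: GeneSet,
    ortholog_map: OrthologMap,
    snp_positions: dict[str, int],
    all_positions: dict[str, np.ndarray],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> GeneHitSet:
    """Hit and background ortholog sets for one trait's QTL calls."""
    background_bovine = genes_near_snps(all_positions, genes, flank_bp)
    background, _ = map_orthologs(background_bovine, ortholog_map)
    bovine_hits = genes_near_qtl(qtl, genes, snp_positions, flank_bp) & background_bovine
    human_hits, unmapped = map_orthologs(bovine_hits, ortholog_map)
    return GeneHitSet(
        trait=trait,
        bovine_hits=frozenset(bovine_hits),
        human_hits=frozenset(human_hits & background),
        background=frozenset(background),
        n_unmapped=unmapped,
    )


def enrichment_test(
    hits: GeneHitSet, pathways: PathwayDB, alpha: float = 0.05
) -> list[PathwayResult]:
    """Hypergeometric upper-tail test of every pathway against the background."""
    background = hits.background
    if not background:
        raise ValueError("empty background gene set")
    n_bg = len(background)
    n_hits = len(hits.human_hits)
    results: list[PathwayResult] = []
    for pid, (name, genes) in pathways.pathways.items():
        in_bg = genes & background
        overlap = sorted(in_bg & hits.human_hits)
        k = len(overlap)
        K = len(in_bg)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K, n=n_hits)
        p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_hits)) if K else 1.0
        p = min(1.0, max(p, 0.0))
        results.append(
            PathwayResult(
                pathway_id=pid,
                name=name,
                overlap=k,
                n_hits=n_hits,
                pathway_size=K,
                background_size=n_bg,
                p=p,
                overlap_genes=tuple(overlap),
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results


def combined_trait_set(per_trait_hits: list[GeneHitSet]) -> GeneHitSet:
    """Union of per-trait hit sets over their (identical) shared background."""
    if not per_trait_hits:
        raise ValueError("need at least one trait hit set")
    background = per_trait_hits[0].background
    if any(h.background != background for h in per_trait_hits):
        raise ValueError("inconsistent backgrounds across traits")
    return GeneHitSet(
        trait="combined",
        bovine_hits=frozenset().union(*(h.bovine_hits for h in per_trait_hits)),
        human_hits=frozenset().union(*(h.human_hits for h in per_trait_hits)),
        background=background,
        n_unmapped=sum(h.n_unmapped for h in per_trait_hits),
    )


def results_to_frame(
    results: list[PathwayResult], trait: str, bh_column: bool = False
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "trait": trait,
            "pathway_id": [r.pathway_id for r in results],
            "pathway": [r.name for r in results],
            "overlap": [r.overlap for r in results],
            "pathway_size": [r.pathway_size for r in results],
            "p": [r.p for r in results],
            "candidate_genes": [",".join(r.overlap_genes) for r in results],
            "significant": [r.significant for r in results],
        }
    )
    if bh_column and len(df):
        from .fdr import qvalues

        # step-up q-values with pi0 = 1 are exactly Benjamini-Hochberg
        df["p_bh"] = qvalues(df["p"].to_numpy(), pi0=1.0).q
    return df


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
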