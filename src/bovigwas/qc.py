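"""SNP and animal quality control.

SNP filters, applied in order: unmapped/excluded-chromosome removal,
sire-progeny Mendelian consistency, minor allele frequency (< threshold
removed, boundary retained), and call rate (> threshold missing removed,
boundary retained).  Animal filtering discards records whose reliability,
after removing the parent-average contribution, falls below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import MISSING, GenotypeSet, Pedigree, PhenotypeTable

__all__ = [
    "QcReport",
    "filter_unmapped",
    "filter_mendelian",
    "filter_maf",
    "filter_callrate",
    "adjusted_reliability",
    "filter_animals",
    "run_snp_qc",
]

DEFAULT_EXCLUDED_CHROMS = frozenset({"X", "0", "unknown"})


@dataclass
class QcReport:
    """Ordered record of applied filters and what each removed."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, removed: list[str], **extra) -> None:
        self.stages.append({"filter": name, "removed": sorted(removed), "n_removed": len(removed), **extra})

    @property
    def total_removed(self) -> int:
        return sum(s["n_removed"] for s in self.stages)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "total_removed": self.total_removed}


def _drop(gs: GenotypeSet, remove_mask: np.ndarray) -> GenotypeSet:
    return gs.take_snps(np.nonzero(~remove_mask)[0])


def filter_unmapped(
    genotypes: GenotypeSet, excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS
) -> tuple[GenotypeSet, QcReport]:
    """Remove SNPs on excluded chromosomes (X/unplaced) or with position <= 0."""
    bad = np.array(
        [c in excluded_chroms or p <= 0 for c, p in zip(genotypes.chrom, genotypes.pos)]
    )
    report = QcReport()
    report.add("unmapped", [s for s, b in zip(genotypes.snp_ids, bad) if b])
    return _drop(genotypes, bad), report


def mendelian_violations(genotypes: GenotypeSet, pedigree: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP opposing-homozygote counts over genotyped sire-progeny pairs.

    Returns (violations, checkable pairs) per SNP; pairs with a missing call
    on either side are not checkable.  Only sire links are scored, matching
    a sire-genotyping design; dam links are scored identically when the dam
    is genotyped.
    """
    lookup = {a: i for i, a in enumerate(genotypes.animal_ids)}
    pairs = []
    for child, sire, dam in pedigree.records:
        if child not in lookup:
            continue
        for parent in (sire, dam):
            if parent is not None and parent in lookup:
                pairs.append((lookup[parent], lookup[child]))
    m = genotypes.n_snps
    viol = np.zeros(m, dtype=np.int64)
    checkable = np.zeros(m, dtype=np.int64)
    calls = genotypes.calls
    for pi, ci in pairs:
        p, c = calls[pi], calls[ci]
        ok = (p != MISSING) & (c != MISSING)
        checkable += ok
        viol += ok & (((p == 2) & (c == 0)) | ((p == 0) & (c == 2)))
    return viol, checkable


def filter_mendelian(
    genotypes: GenotypeSet, pedigree: Pedigree, max_error_rate: float = 0.0
) -> tuple[GenotypeSet, QcReport]:
    """Remove SNPs whose opposing-homozygote rate exceeds ``max_error_rate``.

    The default 0 removes a SNP on any violation (strictest reading of
    "inconsistent Mendelian inheritance").
    """
    viol, checkable = mendelian_violations(genotypes, pedigree)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(checkable > 0, viol / np.maximum(checkable, 1), 0.0)
    bad = rate > max_error_rate
    report = QcReport()
    report.add("mendelian", [s for s, b in zip(genotypes.snp_ids, bad) if b], max_error_rate=max_error_rate)
    return _drop(genotypes, bad), report


def filter_maf(genotypes: GenotypeSet, min_maf: float = 0.05) -> tuple[GenotypeSet, QcReport]:
    """Remove SNPs with minor allele frequency strictly below ``min_maf``.

    Frequency is computed over non-missing calls; all-missing SNPs are
    removed and reported separately.
    """
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    calls = genotypes.calls
    nonmiss = (calls != MISSING).sum(axis=0)
    alt = np.where(calls == MISSING, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(nonmiss > 0, alt / (2.0 * np.maximum(nonmiss, 1)), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    all_missing = nonmiss == 0
    low = ~all_missing & (maf < min_maf)
    report = QcReport()
    report.add("maf", [s for s, b in zip(genotypes.snp_ids, low) if b], min_maf=min_maf)
    report.add("all_missing", [s for s, b in zip(genotypes.snp_ids, all_missing) if b])
    return _drop(genotypes, low | all_missing), report


def filter_callrate(genotypes: GenotypeSet, max_missing: float = 0.05) -> tuple[GenotypeSet, QcReport]:
    """Remove SNPs with a missing-call fraction strictly greater than ``max_missing``."""
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    frac = (genotypes.calls == MISSING).mean(axis=0)
    bad = frac > max_missing
    report = QcReport()
    report.add("callrate", [s for s, b in zip(genotypes.snp_ids, bad) if b], max_missing=max_missing)
    return _drop(genotypes, bad), report


def run_snp_qc(
    genotypes: GenotypeSet,
    pedigree: Pedigree,
    excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
    mendel_max_error_rate: float = 0.0,
    min_maf: float = 0.05,
    max_missing: float = 0.05,
) -> tuple[GenotypeSet, QcReport]:
    """All SNP filters in order: position, Mendelian, MAF, call rate."""
    report = QcReport()
    gs, r = filter_unmapped(genotypes, excluded_chroms)
    report.stages += r.stages
    gs, r = filter_mendelian(gs, pedigree, mendel_max_error_rate)
    report.stages += r.stages
    gs, r = filter_maf(gs, min_maf)
    report.stages += r.stages
    gs, r = filter_callrate(gs, max_missing)
    report.stages += r.stages
    return gs, report


def adjusted_reliability(
    rel_animal: float, rel_sire: float | None, rel_dam: float | None
) -> float:
    """Reliability with the parent-average contribution removed.

    r2_PA = (r2_sire + r2_dam) / 4 with an unknown parent contributing 0;
    result = max(0, (r2 - r2_PA) / (1 - r2_PA)).  With both parents unknown
    the reliability is returned unchanged.
    """
    for v in (rel_animal, rel_sire, rel_dam):
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError("reliabilities must be in [0, 1]")
    if rel_sire is None and rel_dam is None:
        return rel_animal
    r2_pa = ((rel_sire or 0.0) + (rel_dam or 0.0)) / 4.0
    if r2_pa >= 1.0:
        raise ValueError("parent-average reliability of 1 is degenerate")
    return max(0.0, (rel_animal - r2_pa) / (1.0 - r2_pa))


def filter_animals(
    phenotypes: PhenotypeTable,
    pedigree: Pedigree,
    min_adj_rel: float = 0.70,
    parent_reliabilities: dict[str, float] | None = None,
) -> tuple[PhenotypeTable, QcReport]:
    """Per trait, drop animals whose adjusted reliability is < ``min_adj_rel``.

    Parent reliabilities are looked up per trait from the phenotype table
    itself, supplemented by ``parent_reliabilities`` for parents without a
    phenotype record; parents absent from both contribute nothing.
    """
    if not (0.0 <= min_adj_rel <= 1.0):
        raise ValueError("min_adj_rel must be in [0, 1]")
    parents = pedigree.parents
    extra = parent_reliabilities or {}
    keep_rows: list[int] = []
    removed: list[str] = []
    empty_traits: list[str] = []
    for trait in phenotypes.traits:
        sub = phenotypes.df[phenotypes.df["trait"] == trait]
        rel_of = dict(zip(sub["animal"], sub["reliability"]))
        kept_any = False
        for row in sub.itertuples():
            sire, dam = parents.get(row.animal, (None, None))
            r_s = rel_of.get(sire, extra.get(sire)) if sire is not None else None
            r_d = rel_of.get(dam, extra.get(dam)) if dam is not None else None
            adj = adjusted_reliability(row.reliability, r_s, r_d)
            if adj < min_adj_rel:
                removed.append(f"{row.animal}:{trait}")
            else:
                keep_rows.append(row.Index)
                kept_any = True
        if not kept_any:
            empty_traits.append(trait)
    report = QcReport()
    report.add("adjusted_reliability", removed, min_adj_rel=min_adj_rel, empty_traits=empty_traits)
    return PhenotypeTable(phenotypes.df.loc[keep_rows].reset_index(drop=True)), report
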