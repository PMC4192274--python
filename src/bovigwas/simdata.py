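"""Synthetic cattle GWAS data with the statistical structure the analysis assumes.

The generator produces, with no external downloads:

* a multi-generation pedigree (discrete generations, random matings);
* SNP-chip style genotypes: founder haplotypes with a chosen MAF spectrum
  and first-order-Markov local LD, dropped through the pedigree under
  Mendelian transmission with recombination (one expected crossover per
  chromosome), then corrupted with genotyping errors and missing calls;
* a sparse set of QTL whose per-locus effect variances follow a scaled
  inverse chi-squared law (defaults nu=4.234, S=0.0429, the BayesB prior);
* pseudo-phenotypes built as de-regressed proofs: genetic value = QTL sum +
  pedigree polygenic term, observed with noise variance
  sigma_g^2 * (1 - r^2) / r^2 governed by a per-animal reliability r^2;
* gene annotations, a one-to-many bovine-to-human ortholog map, and random
  pathway gene sets including one "spiked" pathway enriched near true QTL.

The true genetic values and QTL positions are returned solely so tests can
score recovery; analysis modules never read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import (
    MISSING,
    GeneSet,
    GenotypeSet,
    OrthologMap,
    PathwayDB,
    Pedigree,
    PhenotypeTable,
    write_genes_bed,
    write_genotypes,
    write_gmt,
    write_orthologs,
    write_pedigree,
    write_phenotypes,
)
from .kinship import AMatrix, subset_amatrix

__all__ = [
    "SimConfig",
    "TrueEffects",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_qtl_effects",
    "simulate_phenotypes",
    "simulate_annotations",
    "simulate_dataset",
    "sample_scaled_inv_chi2",
]


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    Defaults emulate a desk-scale version of a 50k-chip dairy-sire design:
    moderate LD, a handful of QTL against a polygenic background, and
    reliabilities in the 0.70-0.99 range typical of progeny-tested sires.
    """

    n_founders: int = 60
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_chromosomes: int = 5
    snps_per_chromosome: int = 400
    chromosome_length_bp: int = 100_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.6
    n_qtl: int = 10
    qtl_nu: float = 4.234
    qtl_s: float = 0.0429
    h2_polygenic: float = 0.3
    rel_low: float = 0.70
    rel_high: float = 0.99
    mendel_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not (0.0 <= self.rel_low <= self.rel_high <= 1.0):
            raise ValueError("require 0 <= rel_low <= rel_high <= 1")
        for name in ("mendel_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.h2_polygenic < 1.0):
            raise ValueError("h2_polygenic must be in [0, 1)")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ValueError("n_qtl exceeds the total SNP count")
        if self.n_generations < 0 or self.n_founders < 1:
            raise ValueError("need n_founders >= 1 and n_generations >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulation stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class TrueEffects:
    """Planted QTL: index set, full-length effect vector, per-QTL variances."""

    snp_indices: np.ndarray
    effects: np.ndarray
    variances: np.ndarray = field(default=None)  # type: ignore[assignment]


def sample_scaled_inv_chi2(
    rng: np.random.Generator, nu: float, s: float, size: int | tuple[int, ...] = 1
) -> np.ndarray:
    """Draws from the scaled inverse chi-squared(nu, S): nu*S / chi2(nu).

    Mean is nu*S/(nu-2) for nu > 2.
    """
    return nu * s / rng.chisquare(nu, size=size)


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation pedigree: founders, then random sire x dam matings.

    Each generation forms ``n_founders // 2`` matings by drawing a distinct
    sire and dam from the previous generation; each mating produces
    ``offspring_per_mating`` offspring.
    """
    if cfg.n_generations >= 1 and cfg.n_founders < 2:
        raise ValueError("at least two founders are needed to form a mating")
    rng = cfg.rng(1)
    records: list[tuple[str, str | None, str | None]] = []
    previous = [f"G0_{i:04d}" for i in range(cfg.n_founders)]
    records.extend((a, None, None) for a in previous)
    for g in range(1, cfg.n_generations + 1):
        current: list[str] = []
        n_matings = max(1, cfg.n_founders // 2)
        for m in range(n_matings):
            sire, dam = rng.choice(len(previous), size=2, replace=False)
            for k in range(cfg.offspring_per_mating):
                child = f"G{g}_{m:04d}_{k}"
                records.append((child, previous[sire], previous[dam]))
                current.append(child)
        previous = current
    return Pedigree(records)


# ---------------------------------------------------------------------------
# genotypes

def _founder_haplotype(rng: np.random.Generator, freqs: np.ndarray, rho: float) -> np.ndarray:
    """One founder haplotype: Markov chain of Bernoulli alleles.

    Adjacent markers k-1, k have allelic correlation ``rho``:
    P(z_k = 1 | z_{k-1}) = p_k + rho * sqrt(p_k q_k / (p_{k-1} q_{k-1}))
                                 * (z_{k-1} - p_{k-1}), clipped to [0, 1].
    """
    m = len(freqs)
    z = np.empty(m, dtype=np.int8)
    u = rng.random(m)
    z[0] = u[0] < freqs[0]
    sd = np.sqrt(freqs * (1.0 - freqs))
    for k in range(1, m):
        p = freqs[k] + rho * (sd[k] / sd[k - 1]) * (z[k - 1] - freqs[k - 1])
        z[k] = u[k] < min(1.0, max(0.0, p))
    return z


def _meiosis(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chrom_slices: list[slice],
    recomb: list[np.ndarray],
) -> np.ndarray:
    """One gamete: random start haplotype per chromosome, crossovers between markers."""
    gamete = np.empty_like(hap_a)
    for sl, r in zip(chrom_slices, recomb):
        m = sl.stop - sl.start
        cross = rng.random(m - 1) < r if m > 1 else np.empty(0, dtype=bool)
        which = np.empty(m, dtype=np.int8)
        which[0] = rng.integers(2)
        for k in range(1, m):
            which[k] = which[k - 1] ^ cross[k - 1]
        seg_a, seg_b = hap_a[sl], hap_b[sl]
        gamete[sl] = np.where(which == 0, seg_a, seg_b)
    return gamete


def simulate_genotypes(pedigree: Pedigree, cfg: SimConfig) -> GenotypeSet:
    """Gene-drop founder haplotypes through the pedigree, then corrupt calls."""
    rng = cfg.rng(2)
    m_total = cfg.n_chromosomes * cfg.snps_per_chromosome
    chrom_labels: list[str] = []
    snp_ids: list[str] = []
    pos = np.empty(m_total, dtype=np.int64)
    freqs = np.empty(m_total)
    chrom_slices: list[slice] = []
    recomb: list[np.ndarray] = []
    for c in range(cfg.n_chromosomes):
        sl = slice(c * cfg.snps_per_chromosome, (c + 1) * cfg.snps_per_chromosome)
        chrom_slices.append(sl)
        p = np.sort(
            rng.choice(cfg.chromosome_length_bp, size=cfg.snps_per_chromosome, replace=False) + 1
        )
        pos[sl] = p
        # one expected crossover per chromosome, proportional to bp interval
        recomb.append(np.diff(p) / cfg.chromosome_length_bp)
        freqs[sl] = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.snps_per_chromosome)
        chrom_labels.extend([str(c + 1)] * cfg.snps_per_chromosome)
        snp_ids.extend(f"c{c + 1}s{k:05d}" for k in range(cfg.snps_per_chromosome))

    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for animal in pedigree.topological_order():
        sire, dam = pedigree.parents[animal]
        gametes = []
        for parent in (sire, dam):
            if parent is None:
                hap = np.concatenate(
                    [_founder_haplotype(rng, freqs[sl], cfg.ld_rho) for sl in chrom_slices]
                )
            else:
                hap = _meiosis(rng, *haplos[parent], chrom_slices, recomb)
            gametes.append(hap)
        haplos[animal] = (gametes[0], gametes[1])

    animal_ids = pedigree.animals
    calls = np.empty((len(animal_ids), m_total), dtype=np.int8)
    for i, a in enumerate(animal_ids):
        calls[i] = haplos[a][0] + haplos[a][1]

    if cfg.mendel_error_rate > 0:
        hit = rng.random(calls.shape) < cfg.mendel_error_rate
        calls[hit] = rng.integers(0, 3, size=int(hit.sum()), dtype=np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    return GenotypeSet(animal_ids, snp_ids, calls, np.array(chrom_labels, dtype=object), pos)


# ---------------------------------------------------------------------------
# QTL effects and phenotypes

def simulate_qtl_effects(
    genotypes: GenotypeSet, cfg: SimConfig, seed: int | None = None
) -> TrueEffects:
    """Pick QTL uniformly; effects ~ N(0, v) with v ~ scaled-inv-chi2(nu, S)."""
    m = genotypes.n_snps
    if cfg.n_qtl > m:
        raise ValueError(f"n_qtl={cfg.n_qtl} exceeds SNP count {m}")
    rng = np.random.default_rng([cfg.seed, 3]) if seed is None else np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    variances = sample_scaled_inv_chi2(rng, cfg.qtl_nu, cfg.qtl_s, size=cfg.n_qtl)
    effects = np.zeros(m)
    effects[idx] = rng.standard_normal(cfg.n_qtl) * np.sqrt(variances)
    return TrueEffects(idx, effects, variances)


def simulate_phenotypes(
    genotypes: GenotypeSet,
    effects: TrueEffects,
    amatrix: AMatrix,
    cfg: SimConfig,
    trait: str = "trait",
    seed: int | None = None,
) -> PhenotypeTable:
    """De-regressed-proof style pseudo-phenotypes.

    g = X a + u with u ~ MVN(0, A * sigma2_poly), sigma2_poly chosen so the
    polygenic share of genetic variance equals ``h2_polygenic``; then
    y = g + eps with Var(eps) = sigma2_g (1 - r2) / r2 and r2 ~ U(rel_low,
    rel_high).  The realised genetic value g is stored as ``true_g`` for
    recovery tests only.
    """
    rng = np.random.default_rng([cfg.seed, 4]) if seed is None else np.random.default_rng(seed)
    a_sub = subset_amatrix(amatrix, genotypes.animal_ids)
    x = genotypes.dosage()
    qtl_part = x @ effects.effects
    var_qtl = float(np.var(qtl_part))
    h2 = cfg.h2_polygenic
    if h2 <= 0.0:
        sigma2_poly = 0.0
    elif var_qtl > 0.0:
        sigma2_poly = var_qtl * h2 / (1.0 - h2)
    else:
        sigma2_poly = h2  # no QTL: polygenic variance on a unit scale
    if sigma2_poly > 0.0:
        cov = a_sub.values * sigma2_poly
        try:
            chol = np.linalg.cholesky(cov + 1e-10 * sigma2_poly * np.eye(a_sub.n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("relationship matrix is singular beyond jitter") from exc
        u = chol @ rng.standard_normal(a_sub.n)
    else:
        u = np.zeros(a_sub.n)
    g = qtl_part + u
    sigma2_g = float(np.var(g))
    rel = rng.uniform(cfg.rel_low, cfg.rel_high, size=len(g))
    noise_sd = np.sqrt(sigma2_g * (1.0 - rel) / rel)
    y = g + rng.standard_normal(len(g)) * noise_sd
    df = pd.DataFrame(
        {
            "animal": genotypes.animal_ids,
            "trait": trait,
            "drp": y,
            "reliability": rel,
            "true_g": g,
        }
    )
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# annotations

def simulate_annotations(
    genotypes: GenotypeSet,
    effects: TrueEffects,
    cfg: SimConfig,
    n_genes_per_chrom: int = 40,
    ortholog_probs: tuple[float, float, float] = (0.2, 0.6, 0.2),
    n_pathways: int = 20,
    pathway_size: tuple[int, int] = (10, 200),
    spike_fraction: float = 0.9,
    spike_size: int = 25,
    flank_bp: int = 500_000,
    seed: int | None = None,
) -> tuple[GeneSet, OrthologMap, PathwayDB]:
    """Genes, orthologs and pathways, with one pathway spiked near true QTL.

    Genes are non-overlapping intervals (one per equal-width slot along each
    chromosome); each bovine gene maps to 0, 1 or 2 human ids with
    ``ortholog_probs``; pathways are random human-gene sets plus one spiked
    pathway drawing ``spike_fraction`` of its members from orthologs of
    bovine genes within ``flank_bp`` of a true QTL SNP.
    """
    rng = np.random.default_rng([cfg.seed, 5]) if seed is None else np.random.default_rng(seed)
    chroms = list(dict.fromkeys(genotypes.chrom))
    rows = []
    if n_genes_per_chrom > 0:
        slot = cfg.chromosome_length_bp // n_genes_per_chrom
        for c in chroms:
            for k in range(n_genes_per_chrom):
                length = int(rng.integers(5_000, min(50_000, max(5_001, slot // 2))))
                start = k * slot + int(rng.integers(1, max(2, slot - length)))
                rows.append((f"BT_{c}_{k:04d}", c, start, start + length - 1))
    genes = GeneSet(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))
    if len(genes) == 0:
        return genes, OrthologMap({}), PathwayDB({})

    mapping: dict[str, frozenset[str]] = {}
    counter = 0
    for gid in genes.df["gene_id"]:
        k = int(rng.choice(3, p=np.asarray(ortholog_probs) / np.sum(ortholog_probs)))
        hs = []
        for _ in range(k):
            hs.append(f"HS_{counter:05d}")
            counter += 1
        mapping[gid] = frozenset(hs)
    orthologs = OrthologMap(mapping)
    universe = sorted(set().union(*mapping.values())) if counter else []

    # orthologs of genes within the flank of any true QTL SNP
    near: set[str] = set()
    qtl_pos = genotypes.pos[effects.snp_indices]
    qtl_chrom = genotypes.chrom[effects.snp_indices]
    for r in genes.df.itertuples(index=False):
        on_chrom = qtl_pos[qtl_chrom == r.chrom]
        if np.any((r.start <= on_chrom + flank_bp) & (r.end >= on_chrom - flank_bp)):
            near |= mapping[r.gene_id]
    far = sorted(set(universe) - near)

    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = pathway_size
    hi = min(hi, len(universe))
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        pathways[f"pw{p:03d}"] = (f"random pathway {p}", frozenset(members))
    if universe:
        target_near = int(round(spike_fraction * spike_size))
        n_near = min(target_near, len(near))
        n_far = min(spike_size - target_near, len(far))
        spiked = set(rng.choice(sorted(near), size=n_near, replace=False)) if n_near else set()
        if n_far:
            spiked |= set(rng.choice(far, size=n_far, replace=False))
        if spiked:
            pathways["pw_spiked"] = ("pathway spiked near true QTL", frozenset(spiked))
    return genes, orthologs, PathwayDB(pathways)


# ---------------------------------------------------------------------------
# one-call dataset writer

def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full dataset and write every pipeline input file to ``out_dir``."""
    from .kinship import build_amatrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    eff = simulate_qtl_effects(geno, cfg)
    amat = build_amatrix(ped)
    pheno = simulate_phenotypes(geno, eff, amat, cfg)
    genes, orth, pathways = simulate_annotations(geno, eff, cfg)
    note = f"seed={cfg.seed}"
    paths = {
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "pedigree": out / "pedigree.csv",
        "pheno": out / "phenotypes.tsv",
        "genes": out / "genes.bed",
        "orthologs": out / "orthologs.tsv",
        "gmt": out / "pathways.gmt",
        "truth": out / "true_qtl.tsv",
    }
    write_genotypes(geno, paths["ped"], paths["map"], tool_note=note)
    write_pedigree(ped, paths["pedigree"], tool_note=note)
    write_phenotypes(pheno, paths["pheno"], tool_note=note)
    write_genes_bed(genes, paths["genes"], tool_note=note)
    write_orthologs(orth, paths["orthologs"], tool_note=note)
    write_gmt(pathways, paths["gmt"], tool_note=note)
    truth = pd.DataFrame(
        {
            "snp_id": [geno.snp_ids[i] for i in eff.snp_indices],
            "chrom": geno.chrom[eff.snp_indices],
            "pos": geno.pos[eff.snp_indices],
            "effect": eff.effects[eff.snp_indices],
        }
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
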