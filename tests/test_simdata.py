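"""The synthetic-data generator: transmission, LD, effect law, phenotype model."""

from __future__ import annotations

import numpy as np
import pytest

from bovigwas.genio import MISSING
from bovigwas.kinship import build_amatrix
from bovigwas.qc import mendelian_violations
from bovigwas.simdata import (
    SimConfig,
    TrueEffects,
    sample_scaled_inv_chi2,
    simulate_annotations,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_qtl_effects,
)


def test_smallest_pedigree_is_a_trio():
    cfg = SimConfig(n_founders=2, n_generations=1, offspring_per_mating=1, seed=1)
    ped = simulate_pedigree(cfg)
    assert len(ped.records) == 3
    child, sire, dam = ped.records[-1]
    assert {sire, dam} == set(ped.founders())


def test_zero_generations_gives_founders_only():
    cfg = SimConfig(n_founders=7, n_generations=0, seed=1)
    ped = simulate_pedigree(cfg)
    assert ped.founders() == ped.animals and len(ped.animals) == 7


def test_single_founder_cannot_mate():
    with pytest.raises(ValueError, match="two founders"):
        simulate_pedigree(SimConfig(n_founders=1, n_generations=1))


def test_parents_precede_children_topologically():
    cfg = SimConfig(n_founders=10, n_generations=3, seed=5)
    ped = simulate_pedigree(cfg)
    order = {a: i for i, a in enumerate(ped.topological_order())}
    for child, sire, dam in ped.records:
        if sire is not None:
            assert order[sire] < order[child] and order[dam] < order[child]


def test_clean_transmission_has_no_opposing_homozygotes(small_pedigree, small_genotypes):
    """With zero error and missing rates the trio check finds no violations."""
    viol, checkable = mendelian_violations(small_genotypes, small_pedigree)
    assert checkable.sum() > 0
    assert viol.sum() == 0


def test_ld_rho_zero_gives_uncorrelated_adjacent_markers():
    cfg = SimConfig(
        n_founders=5000, n_generations=0, n_chromosomes=1, snps_per_chromosome=12,
        ld_rho=0.0, maf_low=0.2, maf_high=0.4, seed=3,
    )
    geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
    # founders' genotypes = sum of two iid haplotypes; genotype correlation
    # equals the haplotype allelic correlation
    g = geno.calls.astype(float)
    for k in range(geno.n_snps - 1):
        r = np.corrcoef(g[:, k], g[:, k + 1])[0, 1]
        assert abs(r) < 0.1


def test_ld_rho_positive_correlates_adjacent_markers():
    cfg = SimConfig(
        n_founders=3000, n_generations=0, n_chromosomes=1, snps_per_chromosome=10,
        ld_rho=0.7, maf_low=0.3, maf_high=0.4, seed=4,
    )
    geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
    g = geno.calls.astype(float)
    rs = [np.corrcoef(g[:, k], g[:, k + 1])[0, 1] for k in range(geno.n_snps - 1)]
    assert np.mean(rs) == pytest.approx(0.7, abs=0.08)


def test_fixed_maf_half_within_binomial_bounds():
    cfg = SimConfig(
        n_founders=2000, n_generations=0, n_chromosomes=1, snps_per_chromosome=20,
        maf_low=0.5, maf_high=0.5, ld_rho=0.0, seed=9,
    )
    geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
    freq = geno.calls.mean(axis=0) / 2.0
    n_haplo = 2 * geno.n_animals
    bound = 3.0 * np.sqrt(0.25 / n_haplo)
    assert (np.abs(freq - 0.5) < bound).mean() > 0.9


def test_gene_dropping_preserves_frequency_in_expectation():
    cfg = SimConfig(n_founders=100, n_generations=3, offspring_per_mating=3,
                    n_chromosomes=2, snps_per_chromosome=100, seed=21)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    founders = set(ped.founders())
    is_founder = np.array([a in founders for a in geno.animal_ids])
    f0 = geno.calls[is_founder].mean(axis=0) / 2.0
    f_last = geno.calls[~is_founder].mean(axis=0) / 2.0
    drift = f_last - f0
    # mean drift over SNPs ~ 0 within 4 SD of its estimator
    assert abs(drift.mean()) < 4.0 * drift.std() / np.sqrt(len(drift))


def test_corruption_rates_and_missingness():
    cfg = SimConfig(n_founders=200, n_generations=1, n_chromosomes=1,
                    snps_per_chromosome=100, missing_rate=0.1, seed=2)
    geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
    miss = (geno.calls == MISSING).mean()
    assert miss == pytest.approx(0.1, abs=0.02)


def test_qtl_effects_zero_and_full():
    cfg0 = SimConfig(n_qtl=0, seed=1)
    geno = simulate_genotypes(simulate_pedigree(SimConfig(n_founders=4, n_generations=0,
                              n_chromosomes=1, snps_per_chromosome=20, seed=1)),
                              SimConfig(n_founders=4, n_generations=0, n_chromosomes=1,
                                        snps_per_chromosome=20, seed=1))
    eff0 = simulate_qtl_effects(geno, SimConfig(n_qtl=0, n_chromosomes=1,
                                                snps_per_chromosome=20, seed=1))
    assert not eff0.effects.any()
    eff_all = simulate_qtl_effects(geno, SimConfig(n_qtl=20, n_chromosomes=1,
                                                   snps_per_chromosome=20, seed=1))
    assert (eff_all.effects != 0).all()
    with pytest.raises(ValueError):
        simulate_qtl_effects(geno, SimConfig(n_qtl=21, n_chromosomes=1,
                                             snps_per_chromosome=21, seed=1))


def test_scaled_inv_chi2_moment():
    """Sample mean of the variance law matches nu*S/(nu-2)."""
    rng = np.random.default_rng(8)
    nu, s = 4.234, 0.0429
    draws = sample_scaled_inv_chi2(rng, nu, s, size=10_000)
    expected = nu * s / (nu - 2.0)
    se = draws.std() / np.sqrt(len(draws))
    assert draws.mean() == pytest.approx(expected, abs=4 * se)


def test_perfect_reliability_gives_exact_genetic_values(small_genotypes, small_amatrix):
    cfg = SimConfig(rel_low=1.0, rel_high=1.0, h2_polygenic=0.3, n_qtl=2,
                    n_chromosomes=2, snps_per_chromosome=50, seed=6)
    eff = simulate_qtl_effects(small_genotypes, cfg)
    tab = simulate_phenotypes(small_genotypes, eff, small_amatrix, cfg)
    np.testing.assert_allclose(tab.df["drp"], tab.df["true_g"], atol=1e-12)


def test_no_genetics_gives_zero_phenotype(small_genotypes, small_amatrix):
    cfg = SimConfig(n_qtl=0, h2_polygenic=0.0, n_chromosomes=2,
                    snps_per_chromosome=50, seed=6)
    eff = TrueEffects(np.array([], dtype=int), np.zeros(small_genotypes.n_snps))
    tab = simulate_phenotypes(small_genotypes, eff, small_amatrix, cfg)
    assert np.allclose(tab.df["true_g"], 0.0)
    assert np.var(tab.df["drp"]) == pytest.approx(0.0, abs=1e-20)


def test_phenotype_regression_on_genetic_value_is_unbiased():
    cfg = SimConfig(n_founders=250, n_generations=2, offspring_per_mating=3,
                    n_chromosomes=2, snps_per_chromosome=100, n_qtl=5,
                    h2_polygenic=0.3, seed=17)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    eff = simulate_qtl_effects(geno, cfg)
    amat = build_amatrix(ped)
    tab = simulate_phenotypes(geno, eff, amat, cfg)
    g = tab.df["true_g"].to_numpy()
    y = tab.df["drp"].to_numpy()
    slope = np.cov(y, g)[0, 1] / np.var(g)
    assert 0.9 <= slope <= 1.1


def test_annotation_structure_and_spike(small_genotypes):
    cfg = SimConfig(n_chromosomes=2, snps_per_chromosome=50,
                    chromosome_length_bp=50_000_000, n_qtl=2, seed=11)
    eff = simulate_qtl_effects(small_genotypes, cfg)
    genes, orth, pathways = simulate_annotations(
        small_genotypes, eff, cfg, n_genes_per_chrom=30, spike_fraction=1.0
    )
    # genes non-overlapping within chromosome
    for c in genes.df["chrom"].unique():
        sub = genes.df[genes.df["chrom"] == c].sort_values("start")
        assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()
    # spiked members all lie near a true QTL (spike fraction 1)
    spiked = pathways.pathways["pw_spiked"][1]
    near = set()
    qtl_pos = small_genotypes.pos[eff.snp_indices]
    qtl_chrom = small_genotypes.chrom[eff.snp_indices]
    for r in genes.df.itertuples(index=False):
        on = qtl_pos[qtl_chrom == r.chrom]
        if np.any((r.start <= on + 500_000) & (r.end >= on - 500_000)):
            near |= set(orth.mapping[r.gene_id])
    assert spiked <= near


def test_ortholog_multiplicity_proportions():
    cfg = SimConfig(n_chromosomes=5, snps_per_chromosome=20,
                    chromosome_length_bp=50_000_000, n_qtl=1, seed=12)
    ped = simulate_pedigree(SimConfig(n_founders=4, n_generations=0, n_chromosomes=5,
                                      snps_per_chromosome=20, seed=12))
    geno = simulate_genotypes(ped, cfg)
    eff = simulate_qtl_effects(geno, cfg)
    probs = (0.2, 0.6, 0.2)
    genes, orth, _ = simulate_annotations(geno, eff, cfg, n_genes_per_chrom=220,
                                          ortholog_probs=probs)
    counts = np.bincount([len(v) for v in orth.mapping.values()], minlength=3)
    total = counts.sum()
    for k, p in enumerate(probs):
        se = np.sqrt(p * (1 - p) / total)
        assert counts[k] / total == pytest.approx(p, abs=4 * se)


def test_zero_genes_requested_gives_empty_annotation(small_genotypes):
    cfg = SimConfig(n_chromosomes=2, snps_per_chromosome=50, n_qtl=2, seed=1)
    eff = simulate_qtl_effects(small_genotypes, cfg)
    genes, orth, pathways = simulate_annotations(small_genotypes, eff, cfg,
                                                 n_genes_per_chrom=0)
    assert len(genes) == 0 and len(pathways) == 0


def test_dataset_bit_reproducible(tmp_path):
    cfg = SimConfig(n_founders=10, n_generations=1, n_chromosomes=1,
                    snps_per_chromosome=30, n_qtl=2, seed=33)
    p1 = simulate_dataset(cfg, tmp_path / "a")
    p2 = simulate_dataset(cfg, tmp_path / "b")
    for key in p1:
        assert p1[key].read_text() == p2[key].read_text()
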