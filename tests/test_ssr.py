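"""Mixed-model single-SNP scan: OLS reduction, invariances, REML recovery."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from bovigwas.genio import GenotypeSet
from bovigwas.kinship import build_amatrix
from bovigwas.simdata import SimConfig, simulate_genotypes, simulate_pedigree
from bovigwas.ssr import MixedModelGWAS, VarianceComponents, estimate_varcomp, ssr_scan

from conftest import make_phenotypes


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Plain least squares of y on [1, x] with normal-theory Wald p."""
    Z = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    sigma2 = resid @ resid / (len(y) - 2)
    cov = sigma2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(cov[1, 1])
    z = beta[1] / se
    return beta[1], se, 2 * stats.norm.sf(abs(z))


def random_geno(rng, n, m):
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    return GenotypeSet([f"a{i}" for i in range(n)], [f"s{j}" for j in range(m)],
                       calls, np.array(["1"] * m, dtype=object),
                       np.arange(1, m + 1) * 1000)


def test_identity_a_zero_sigma_a_reduces_to_ols():
    """With A = I and sigma2_a = 0 the GLS scan is exactly OLS."""
    rng = np.random.default_rng(0)
    n, m = 200, 50
    gs = random_geno(rng, n, m)
    y = rng.standard_normal(n)
    amat = build_amatrix(
        __import__("bovigwas.genio", fromlist=["Pedigree"]).Pedigree(
            [(f"a{i}", None, None) for i in range(n)]
        )
    )
    tab = make_phenotypes(gs.animal_ids, y)
    vc = VarianceComponents(sigma2_a=0.0, sigma2_e=1.0)
    res = ssr_scan(gs, tab, amat, vc)
    for j in range(m):
        b, se, p = ols_oracle(gs.calls[:, j].astype(float), y)
        assert abs(np.log10(res.p[j]) - np.log10(p)) < 1e-8
        assert res.effect[j] == pytest.approx(b, abs=1e-10)


def test_constant_snp_flagged_degenerate():
    rng = np.random.default_rng(1)
    n = 50
    gs = random_geno(rng, n, 3)
    calls = gs.calls.copy()
    calls[:, 1] = 1
    gs = GenotypeSet(gs.animal_ids, gs.snp_ids, calls, gs.chrom, gs.pos)
    tab = make_phenotypes(gs.animal_ids, rng.standard_normal(n))
    est = MixedModelGWAS().fit(gs.dosage(), tab.y)
    assert est.degenerate_[1]
    assert est.pvalues_[1] == 1.0 and est.effects_[1] == 0.0


def test_scan_invariant_to_animal_reordering(small_genotypes, small_amatrix):
    rng = np.random.default_rng(2)
    n = small_genotypes.n_animals
    y = rng.standard_normal(n)
    tab = make_phenotypes(small_genotypes.animal_ids, y)
    vc = VarianceComponents(sigma2_a=0.4, sigma2_e=0.6)
    res1 = ssr_scan(small_genotypes, tab, small_amatrix, vc)
    perm = rng.permutation(n)
    ids_p = [small_genotypes.animal_ids[i] for i in perm]
    tab_p = make_phenotypes(ids_p, y[perm])
    res2 = ssr_scan(small_genotypes, tab_p, small_amatrix, vc)
    np.testing.assert_allclose(res1.effect, res2.effect, atol=1e-8)
    np.testing.assert_allclose(res1.p, res2.p, atol=1e-8)
    # full path (REML refit) agrees up to eigendecomposition noise
    full1 = ssr_scan(small_genotypes, tab, small_amatrix)
    full2 = ssr_scan(small_genotypes, tab_p, small_amatrix)
    np.testing.assert_allclose(full1.p, full2.p, atol=1e-5)


def test_allele_recoding_flips_sign_keeps_p(small_genotypes, small_amatrix):
    rng = np.random.default_rng(3)
    y = rng.standard_normal(small_genotypes.n_animals)
    tab = make_phenotypes(small_genotypes.animal_ids, y)
    res1 = ssr_scan(small_genotypes, tab, small_amatrix)
    flipped = GenotypeSet(
        small_genotypes.animal_ids, small_genotypes.snp_ids,
        2 - small_genotypes.calls, small_genotypes.chrom, small_genotypes.pos,
    )
    res2 = ssr_scan(flipped, tab, small_amatrix)
    np.testing.assert_allclose(res2.effect, -res1.effect, atol=1e-10)
    np.testing.assert_allclose(res2.p, res1.p, atol=1e-10)


@pytest.fixture(scope="module")
def reml_pedigree():
    cfg = SimConfig(n_founders=160, n_generations=2, offspring_per_mating=3,
                    n_chromosomes=1, snps_per_chromosome=10, seed=13)
    ped = simulate_pedigree(cfg)
    return ped, build_amatrix(ped)


def test_reml_detects_no_heritability(reml_pedigree):
    ped, amat = reml_pedigree
    rng = np.random.default_rng(4)
    ids = amat.animal_ids
    tab = make_phenotypes(ids, rng.standard_normal(len(ids)))
    vc = estimate_varcomp(tab, amat)
    assert vc.h2 < 0.1


def test_reml_detects_pure_genetic_signal(reml_pedigree):
    ped, amat = reml_pedigree
    rng = np.random.default_rng(5)
    chol = np.linalg.cholesky(amat.values + 1e-9 * np.eye(amat.n))
    u = chol @ rng.standard_normal(amat.n)
    tab = make_phenotypes(amat.animal_ids, u)
    vc = estimate_varcomp(tab, amat)
    assert vc.h2 > 0.9


def test_constant_phenotype_rejected(reml_pedigree):
    _, amat = reml_pedigree
    tab = make_phenotypes(amat.animal_ids, np.zeros(amat.n))
    with pytest.raises(ValueError, match="zero variance"):
        estimate_varcomp(tab, amat)


def test_large_effect_qtl_is_scan_minimum():
    """A 1-SD causal SNP attains the minimum p in >= 95% of replicates."""
    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        rng = np.random.default_rng(100 + seed)
        n, m = 500, 80
        gs = random_geno(rng, n, m)
        x = gs.calls[:, 40].astype(float)
        noise = rng.standard_normal(n)
        beta = noise.std() / x.std()  # effect = 1 phenotypic SD of noise
        y = x * beta + noise
        tab = make_phenotypes(gs.animal_ids, y)
        est = MixedModelGWAS().fit(gs.dosage(), tab.y)
        hits += est.pvalues_.argmin() == 40
    assert hits >= int(0.95 * n_rep)


def test_estimator_sklearn_contract():
    est = MixedModelGWAS(max_ratio_log10=5.0)
    assert est.get_params() == {"max_ratio_log10": 5.0}
    est.set_params(max_ratio_log10=6.0)
    rng = np.random.default_rng(0)
    X = rng.integers(0, 3, size=(30, 4)).astype(float)
    est.fit(X, rng.standard_normal(30))
    assert est.effects_.shape == (4,)
    assert est.n_features_in_ == 4
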