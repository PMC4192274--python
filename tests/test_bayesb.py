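"""BayesB sampler: determinism, exchangeability, recovery, PP definitions."""

from __future__ import annotations

import numpy as np
import pytest

from bovigwas.bayesb import (
    BayesB,
    BayesBConfig,
    ChainSamples,
    compute_pp,
    load_chain,
    run_bayesb,
    save_chain,
    _run_chain,
)

from conftest import make_phenotypes


def make_chain(delta, effects=None, chrom=None, pos=None, loglik=None):
    delta = np.asarray(delta, dtype=np.uint8)
    r, m = delta.shape
    effects = np.asarray(effects, float) if effects is not None else delta.astype(float)
    cfg = BayesBConfig(one_minus_pi=0.05, n_iterations=r, thin=1)
    return ChainSamples(
        effects=effects,
        delta=delta,
        sigma2_e=np.ones(r),
        mu=np.zeros(r),
        loglik=np.asarray(loglik, float) if loglik is not None else np.zeros(r),
        snp_ids=[f"s{j}" for j in range(m)],
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 100),
        config=cfg,
    )


def test_config_validation():
    with pytest.raises(ValueError):
        BayesBConfig(one_minus_pi=0.0)
    with pytest.raises(ValueError):
        BayesBConfig(n_iterations=10, thin=20)


def test_vanishing_prior_keeps_all_effects_zero(small_genotypes):
    """With 1 - pi ~ 1e-12 the exclusion state dominates every locus."""
    rng = np.random.default_rng(0)
    tab = make_phenotypes(small_genotypes.animal_ids,
                          rng.standard_normal(small_genotypes.n_animals))
    cfg = BayesBConfig(one_minus_pi=1e-12, n_iterations=200, thin=10, seed=5)
    chain = run_bayesb(small_genotypes, tab, cfg)
    assert not chain.delta.any()
    assert not chain.effects.any()


def test_strong_single_snp_recovered():
    """One 5-SD SNP among 50 reaches PP > 0.9."""
    rng = np.random.default_rng(1)
    n, m = 200, 50
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    noise = rng.standard_normal(n)
    j = 17
    y = X[:, j] * (5.0 * noise.std() / X[:, j].std()) + noise
    est = BayesB(one_minus_pi=0.05, n_iterations=20_000, thin=100, seed=2)
    est.fit(X, y)
    assert est.pp_[j] > 0.9
    # the fitted predictor tracks the phenotype
    assert np.corrcoef(est.predict(X), y)[0, 1] > 0.9


def test_identical_seed_gives_bit_identical_chain(small_genotypes):
    rng = np.random.default_rng(3)
    tab = make_phenotypes(small_genotypes.animal_ids,
                          rng.standard_normal(small_genotypes.n_animals))
    cfg = BayesBConfig(one_minus_pi=0.02, n_iterations=300, thin=10, seed=9)
    c1 = run_bayesb(small_genotypes, tab, cfg)
    c2 = run_bayesb(small_genotypes, tab, cfg)
    for field in ("effects", "delta", "sigma2_e", "mu", "loglik"):
        np.testing.assert_array_equal(getattr(c1, field), getattr(c2, field))


def test_snp_permutation_permutes_results_identically():
    """Counter-based per-locus streams make the chain column-exchangeable."""
    rng = np.random.default_rng(4)
    n, m = 80, 30
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    y = rng.standard_normal(n)
    ids = [f"s{j:03d}" for j in range(m)]
    chrom = np.array(["1"] * m, dtype=object)
    pos = np.arange(1, m + 1, dtype=np.int64)
    cfg = BayesBConfig(one_minus_pi=0.05, n_iterations=200, thin=5, seed=10)
    c1 = _run_chain(X, y, ids, chrom, pos, cfg)
    perm = rng.permutation(m)
    c2 = _run_chain(X[:, perm], y, [ids[j] for j in perm], chrom[perm], pos[perm], cfg)
    np.testing.assert_array_equal(c1.effects[:, perm], c2.effects)
    np.testing.assert_array_equal(c1.loglik, c2.loglik)


def test_prior_calibration_under_null():
    """Posterior mean count of included SNPs stays near m(1 - pi) on null data."""
    rng = np.random.default_rng(5)
    n, m = 150, 100
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    y = rng.standard_normal(n)
    one_minus_pi = 0.05
    est = BayesB(one_minus_pi=one_minus_pi, n_iterations=4000, thin=20, seed=6)
    est.fit(X, y)
    burn = est.chain_.n_records // 2
    mean_count = est.chain_.delta[burn:].sum(axis=1).mean()
    expected = m * one_minus_pi
    assert expected / 3.0 <= mean_count <= expected * 3.0


def test_pp_definition_and_windows():
    # SNP included in 6 of 10 records -> PP 0.6
    delta = np.zeros((10, 3), dtype=np.uint8)
    delta[:6, 0] = 1
    # two SNPs included in disjoint record sets of sizes 3 and 4 -> window PP 0.7
    delta[:3, 1] = 1
    delta[3:7, 2] = 1
    chain = make_chain(delta)
    pp = compute_pp(chain, burn_in=0, window=2)
    assert pp.snp_pp[0] == pytest.approx(0.6)
    # window covering SNPs 1 and 2
    w = [i for i in range(len(pp.window_pp))
         if pp.window_first[i] == 1 and pp.window_last[i] == 2]
    assert pp.window_pp[w[0]] == pytest.approx(0.7)


def test_window_one_equals_per_snp_pp():
    rng = np.random.default_rng(6)
    delta = (rng.random((20, 8)) < 0.3).astype(np.uint8)
    chain = make_chain(delta)
    pp = compute_pp(chain, burn_in=4, window=1)
    np.testing.assert_allclose(pp.window_pp, pp.snp_pp)


def test_window_pp_dominates_member_pp():
    rng = np.random.default_rng(7)
    delta = (rng.random((30, 12)) < 0.2).astype(np.uint8)
    chain = make_chain(delta, chrom=["1"] * 7 + ["2"] * 5)
    pp = compute_pp(chain, burn_in=0, window=5)
    for i in range(len(pp.window_pp)):
        members = slice(pp.window_first[i], pp.window_last[i] + 1)
        assert pp.window_pp[i] >= pp.snp_pp[members].max() - 1e-15


def test_windows_never_cross_chromosomes():
    delta = np.zeros((5, 10), dtype=np.uint8)
    chain = make_chain(delta, chrom=["1"] * 6 + ["2"] * 4)
    pp = compute_pp(chain, burn_in=0, window=5)
    for i in range(len(pp.window_pp)):
        assert chain.chrom[pp.window_first[i]] == chain.chrom[pp.window_last[i]]
    # chromosome 2 has fewer SNPs than the window: one whole-chromosome window
    on_2 = [i for i in range(len(pp.window_pp)) if pp.window_chrom[i] == "2"]
    assert len(on_2) == 1


def test_burn_in_bounds_checked():
    chain = make_chain(np.zeros((5, 2), dtype=np.uint8))
    with pytest.raises(ValueError):
        compute_pp(chain, burn_in=5)


def test_delta_effect_consistency_enforced():
    with pytest.raises(ValueError):
        make_chain(np.zeros((3, 2), dtype=np.uint8), effects=np.ones((3, 2)))


def test_chain_hdf5_roundtrip(tmp_path, small_genotypes):
    rng = np.random.default_rng(8)
    tab = make_phenotypes(small_genotypes.animal_ids,
                          rng.standard_normal(small_genotypes.n_animals))
    cfg = BayesBConfig(one_minus_pi=0.02, n_iterations=100, thin=10, seed=1)
    chain = run_bayesb(small_genotypes, tab, cfg)
    save_chain(chain, tmp_path / "c.h5")
    back = load_chain(tmp_path / "c.h5")
    np.testing.assert_array_equal(back.effects, chain.effects)
    np.testing.assert_array_equal(back.delta, chain.delta)
    assert back.snp_ids == chain.snp_ids
    assert back.config == chain.config


def test_estimator_sklearn_contract():
    est = BayesB(one_minus_pi=0.02, n_iterations=100, thin=10, seed=3)
    params = est.get_params()
    assert params["one_minus_pi"] == 0.02 and params["nu"] == 4.234
    rng = np.random.default_rng(9)
    X = rng.integers(0, 3, size=(30, 5)).astype(float)
    est.fit(X, rng.standard_normal(30))
    assert est.coef_.shape == (5,)
    assert est.predict(X).shape == (30,)
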