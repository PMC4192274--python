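"""BayesB: Bayesian mixture-model regression over all SNPs simultaneously.

Model: y = 1 mu + sum_j x_j a_j + e.  Each SNP effect is zero with prior
probability pi and otherwise N(0, sigma2_j) with sigma2_j drawn from a
scaled inverse chi-squared(nu, S) prior (defaults nu=4.234, S=0.0429).
Per sweep the sampler runs, for every locus, a joint Metropolis-Hastings
update of (delta_j, sigma2_j) with the effect integrated out of the
likelihood (the zero-effect state has no conjugate update), proposing from
the prior; included effects, the intercept and the residual variance are
then Gibbs-updated from their full conditionals.  Every thin-th sweep is
recorded together with the summed absolute per-observation Gaussian
log-density.

Posterior probabilities (PP) of association are the fraction of post
burn-in records in which a SNP - or, for sliding windows of adjacent SNPs,
at least one member SNP - has a non-zero effect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._kernels import bayesb_chain
from .genio import GenotypeSet, PhenotypeTable

__all__ = [
    "BayesBConfig",
    "ChainSamples",
    "PosteriorProb",
    "BayesB",
    "run_bayesb",
    "compute_pp",
    "save_chain",
    "load_chain",
]


@dataclass
class BayesBConfig:
    """Sampler settings; defaults follow the cattle-GWAS convention."""

    one_minus_pi: float = 0.01
    nu: float = 4.234
    s: float = 0.0429
    n_iterations: int = 200_000
    thin: int = 500
    mh_inner: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.one_minus_pi < 1.0):
            raise ValueError("one_minus_pi must be in (0, 1)")
        if self.thin < 1 or self.n_iterations < self.thin:
            raise ValueError("need thin >= 1 and n_iterations >= thin")
        if self.mh_inner < 1:
            raise ValueError("mh_inner must be >= 1")


@dataclass
class ChainSamples:
    """Thinned MCMC draws plus the SNP map they refer to."""

    effects: np.ndarray      # (records, m)
    delta: np.ndarray        # (records, m) uint8 inclusion indicators
    sigma2_e: np.ndarray     # (records,)
    mu: np.ndarray           # (records,)
    loglik: np.ndarray       # (records,) summed absolute log-likelihood
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    config: BayesBConfig

    def __post_init__(self) -> None:
        if ((self.delta == 0) & (self.effects != 0.0)).any():
            raise ValueError("delta = 0 requires a zero recorded effect")

    @property
    def n_records(self) -> int:
        return self.effects.shape[0]


@dataclass
class PosteriorProb:
    """Per-SNP and sliding-window posterior probabilities of association."""

    snp_pp: np.ndarray
    window_chrom: np.ndarray     # per window
    window_first: np.ndarray     # index of first member SNP
    window_last: np.ndarray      # index of last member SNP (inclusive)
    window_pp: np.ndarray
    burn_in: int


class BayesB(RegressorMixin, BaseEstimator):
    """Scikit-learn style BayesB estimator.

    ``fit(X, y)`` runs the MCMC chain on an animals x SNPs dosage matrix.
    Fitted attributes: ``chain_`` (thinned draws), ``coef_`` (posterior
    mean effects over post burn-in records), ``intercept_``, ``pp_``
    (per-SNP posterior probabilities).  ``predict`` returns genomic values
    ``intercept_ + X @ coef_``.
    """

    def __init__(
        self,
        one_minus_pi: float = 0.01,
        nu: float = 4.234,
        s: float = 0.0429,
        n_iterations: int = 20_000,
        thin: int = 100,
        mh_inner: int = 10,
        burn_in_fraction: float = 0.5,
        seed: int = 0,
    ):
        self.one_minus_pi = one_minus_pi
        self.nu = nu
        self.s = s
        self.n_iterations = n_iterations
        self.thin = thin
        self.mh_inner = mh_inner
        self.burn_in_fraction = burn_in_fraction
        self.seed = seed

    def fit(self, X, y, snp_ids: list[str] | None = None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least two animals")
        if len(y) != n:
            raise ValueError("X and y disagree on the number of animals")
        cfg = BayesBConfig(
            one_minus_pi=self.one_minus_pi, nu=self.nu, s=self.s,
            n_iterations=self.n_iterations, thin=self.thin,
            mh_inner=self.mh_inner, seed=self.seed,
        )
        ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(m)]
        chrom = np.array(["1"] * m, dtype=object)
        pos = np.arange(1, m + 1, dtype=np.int64)
        self.chain_ = _run_chain(X, y, ids, chrom, pos, cfg)
        burn = int(self.burn_in_fraction * self.chain_.n_records)
        kept_a = self.chain_.effects[burn:]
        self.coef_ = kept_a.mean(axis=0)
        self.intercept_ = float(self.chain_.mu[burn:].mean())
        self.pp_ = self.chain_.delta[burn:].mean(axis=0)
        self.n_features_in_ = m
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self.intercept_ + X @ self.coef_


def _locus_keys(snp_ids: list[str]) -> np.ndarray:
    keys = np.empty(len(snp_ids), dtype=np.uint64)
    for j, sid in enumerate(snp_ids):
        digest = hashlib.blake2b(sid.encode(), digest_size=8).digest()
        keys[j] = np.uint64(int.from_bytes(digest, "little"))
    return keys


def _run_chain(
    X: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    cfg: BayesBConfig,
) -> ChainSamples:
    n, m = X.shape
    keys = _locus_keys(snp_ids)
    # canonical visit order: by locus key, so chains are invariant to column order
    schedule = np.argsort(keys, kind="stable").astype(np.int64)
    records = cfg.n_iterations // cfg.thin
    rec_a = np.zeros((records, m))
    rec_delta = np.zeros((records, m), dtype=np.uint8)
    rec_sigma2e = np.zeros(records)
    rec_mu = np.zeros(records)
    rec_loglik = np.zeros(records)
    status = bayesb_chain(
        np.ascontiguousarray(X.T),
        y,
        keys,
        schedule,
        float(cfg.one_minus_pi),
        float(cfg.nu),
        float(cfg.s),
        int(cfg.n_iterations),
        int(cfg.thin),
        int(cfg.mh_inner),
        np.uint64(cfg.seed),
        rec_a,
        rec_delta,
        rec_sigma2e,
        rec_mu,
        rec_loglik,
    )
    if status != 0:
        raise FloatingPointError(
            "BayesB chain diverged: non-finite residual variance; "
            f"last recorded sigma2_e values: {rec_sigma2e[max(0, records - 5):]}"
        )
    return ChainSamples(
        effects=rec_a, delta=rec_delta, sigma2_e=rec_sigma2e, mu=rec_mu,
        loglik=rec_loglik, snp_ids=list(snp_ids), chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64), config=cfg,
    )


def run_bayesb(genotypes: GenotypeSet, y: PhenotypeTable, cfg: BayesBConfig) -> ChainSamples:
    """Run one BayesB chain on a genotype set for a single-trait phenotype table."""
    gs = genotypes.take_animals(y.animals)
    X = gs.dosage()
    return _run_chain(X, y.y, gs.snp_ids, gs.chrom, gs.pos, cfg)


def compute_pp(chain: ChainSamples, burn_in: int, window: int = 5) -> PosteriorProb:
    """Per-SNP and sliding-window posterior probabilities after burn-in.

    Windows cover ``window`` map-adjacent SNPs, slide by one SNP and never
    cross a chromosome boundary; a chromosome with fewer SNPs than the
    window width contributes a single whole-chromosome window.  A window's
    PP is the fraction of records in which at least one member is included,
    hence always >= the maximum member-SNP PP.
    """
    if burn_in >= chain.n_records:
        raise ValueError("burn_in must be smaller than the record count")
    if window < 1:
        raise ValueError("window must be >= 1")
    kept = chain.delta[burn_in:]
    snp_pp = kept.mean(axis=0)
    w_chrom: list[str] = []
    w_first: list[int] = []
    w_last: list[int] = []
    w_pp: list[float] = []
    for c in dict.fromkeys(chain.chrom):
        idx = np.nonzero(chain.chrom == c)[0]
        span = min(window, len(idx))
        for start in range(len(idx) - span + 1):
            members = idx[start : start + span]
            any_in = kept[:, members].any(axis=1)
            w_chrom.append(str(c))
            w_first.append(int(members[0]))
            w_last.append(int(members[-1]))
            w_pp.append(float(any_in.mean()))
    return PosteriorProb(
        snp_pp=snp_pp,
        window_chrom=np.array(w_chrom, dtype=object),
        window_first=np.array(w_first, dtype=np.int64),
        window_last=np.array(w_last, dtype=np.int64),
        window_pp=np.array(w_pp),
        burn_in=burn_in,
    )


# ---------------------------------------------------------------------------
# chain archive (HDF5)

def save_chain(chain: ChainSamples, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(chain.config))
        f.create_dataset("effects", data=chain.effects, compression="gzip")
        f.create_dataset("delta", data=chain.delta, compression="gzip")
        f.create_dataset("sigma2_e", data=chain.sigma2_e)
        f.create_dataset("mu", data=chain.mu)
        f.create_dataset("loglik", data=chain.loglik)
        f.create_dataset("snp_ids", data=np.array(chain.snp_ids, dtype="S"))
        f.create_dataset("chrom", data=np.array([str(c) for c in chain.chrom], dtype="S"))
        f.create_dataset("pos", data=chain.pos)


def load_chain(path: str | Path) -> ChainSamples:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = BayesBConfig(**json.loads(f.attrs["config"]))
        return ChainSamples(
            effects=f["effects"][:],
            delta=f["delta"][:],
            sigma2_e=f["sigma2_e"][:],
            mu=f["mu"][:],
            loglik=f["loglik"][:],
            snp_ids=[s.decode() for s in f["snp_ids"][:]],
            chrom=np.array([s.decode() for s in f["chrom"][:]], dtype=object),
            pos=f["pos"][:],
            config=cfg,
        )
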