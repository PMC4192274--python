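"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bovigwas.genio import GenotypeSet, Pedigree, PhenotypeTable
from bovigwas.kinship import build_amatrix
from bovigwas.simdata import SimConfig, simulate_genotypes, simulate_pedigree


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_founders=40,
        n_generations=2,
        offspring_per_mating=2,
        n_chromosomes=2,
        snps_per_chromosome=50,
        chromosome_length_bp=50_000_000,
        n_qtl=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pedigree(small_cfg) -> Pedigree:
    return simulate_pedigree(small_cfg)


@pytest.fixture(scope="session")
def small_genotypes(small_cfg, small_pedigree) -> GenotypeSet:
    return simulate_genotypes(small_pedigree, small_cfg)


@pytest.fixture(scope="session")
def small_amatrix(small_pedigree):
    return build_amatrix(small_pedigree)


@pytest.fixture()
def trio_pedigree() -> Pedigree:
    return Pedigree([("S", None, None), ("D", None, None), ("C", "S", "D")])


def make_phenotypes(animal_ids, y, reliability=0.9, trait="t") -> PhenotypeTable:
    rel = np.full(len(animal_ids), reliability) if np.isscalar(reliability) else reliability
    return PhenotypeTable(
        pd.DataFrame({"animal": animal_ids, "trait": trait, "drp": y, "reliability": rel})
    )
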