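"""Pedigree additive (numerator) relationship matrix.

The A matrix gives the expected proportion of genome shared identically by
descent between animals, twice the kinship coefficient.  It is built by the
tabular (recursive) method over a topologically sorted pedigree, which
handles inbreeding implicitly: a_kk = 1 + 0.5 * a_sd and
a_jk = 0.5 * (a_js + a_jd) with unknown parents contributing zero.
Dense storage; intended scale is a few thousand animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genio import Pedigree

__all__ = ["AMatrix", "build_amatrix", "subset_amatrix", "write_amatrix", "read_amatrix"]


@dataclass
class AMatrix:
    """Symmetric additive relationship matrix with its animal-id ordering."""

    animal_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match animal id list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("A matrix must be symmetric")
        diag = np.diag(self.values)
        if ((diag < 1.0 - 1e-9) | (diag > 2.0 + 1e-9)).any():
            raise ValueError("A diagonal outside [1, 2]")

    @property
    def n(self) -> int:
        return len(self.animal_ids)


def build_amatrix(pedigree: Pedigree) -> AMatrix:
    """Tabular-method A over the pedigree's topological order."""
    order = pedigree.topological_order()
    idx = {a: i for i, a in enumerate(order)}
    parents = pedigree.parents
    n = len(order)
    a = np.zeros((n, n))
    for k, animal in enumerate(order):
        s, d = parents[animal]
        si = idx[s] if s is not None and s in idx else None
        di = idx[d] if d is not None and d in idx else None
        a[k, k] = 1.0 + (0.5 * a[si, di] if si is not None and di is not None else 0.0)
        for j in range(k):
            v = 0.0
            if si is not None:
                v += 0.5 * a[j, si]
            if di is not None:
                v += 0.5 * a[j, di]
            a[k, j] = a[j, k] = v
    return AMatrix(order, a)


def subset_amatrix(amatrix: AMatrix, animal_ids: Sequence[str]) -> AMatrix:
    """Principal submatrix of A in the requested animal order."""
    lookup = {a: i for i, a in enumerate(amatrix.animal_ids)}
    missing = [a for a in animal_ids if a not in lookup]
    if missing:
        raise KeyError(f"animals not in A matrix: {missing[:5]}")
    sel = np.array([lookup[a] for a in animal_ids], dtype=np.intp)
    return AMatrix(list(animal_ids), amatrix.values[np.ix_(sel, sel)])


def write_amatrix(amatrix: AMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(amatrix.animal_ids) + "\n")
        for aid, row in zip(amatrix.animal_ids, amatrix.values):
            fh.write(aid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_amatrix(path: str | Path) -> AMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
    return AMatrix(header, np.array(rows, dtype=float))
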