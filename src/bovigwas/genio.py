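"""Readers, writers and validated in-memory containers for the pipeline's file formats.

Formats handled: PED/MAP genotype pairs (whitespace PED, MAP columns
``chrom snp_id 0 bp``), pedigree CSV (``animal,sire,dam`` with ``0`` =
unknown), phenotype TSV (``animal trait drp reliability [true_g]``),
gene BED (0-based half-open on disk, 1-based inclusive in memory),
two-column ortholog TSV, and GMT pathway sets.

Genotype calls are stored as the count (0/1/2) of the lexicographically
smaller allele at each biallelic site; ``-1`` marks a missing call.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeSet",
    "Pedigree",
    "PhenotypeTable",
    "GeneSet",
    "OrthologMap",
    "PathwayDB",
    "ParseError",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_genes_bed",
    "write_genes_bed",
    "read_orthologs",
    "write_orthologs",
    "read_gmt",
    "write_gmt",
]

#: sentinel for a missing genotype call
MISSING: int = -1

_HEADER_PREFIX = "#"


class ParseError(ValueError):
    """A file violated its format contract; the message names the offending record."""


def _comment(tool_note: str | None) -> str:
    from . import __version__

    note = f" {tool_note}" if tool_note else ""
    return f"{_HEADER_PREFIX} bovigwas v{__version__}{note}\n"


# ---------------------------------------------------------------------------
# GenotypeSet


@dataclass
class GenotypeSet:
    """Animals x SNPs call matrix plus the SNP map.

    Parameters
    ----------
    animal_ids : ordered animal identifiers (rows).
    snp_ids : ordered SNP identifiers (columns, in map order).
    calls : int8 matrix of allele counts in {0, 1, 2}, ``-1`` missing.
    chrom : per-SNP chromosome label.
    pos : per-SNP 1-based bp position, strictly increasing within a chromosome.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.calls.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"call matrix {self.calls.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("SNP map length does not match the SNP id list")
        if len(set(self.snp_ids)) != m:
            raise ParseError("duplicated SNP ids in map")
        if len(set(self.animal_ids)) != n:
            raise ParseError("duplicated animal ids")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ParseError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeSet":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeSet(
            animal_ids=list(self.animal_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            calls=self.calls[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
        )

    def take_animals(self, ids: Sequence[str]) -> "GenotypeSet":
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([lookup[a] for a in ids], dtype=np.intp)
        return GenotypeSet(list(ids), list(self.snp_ids), self.calls[idx], self.chrom, self.pos)

    def dosage(self) -> np.ndarray:
        """Float copy of the call matrix with missing calls mean-imputed per SNP."""
        x = self.calls.astype(np.float64)
        x[x == MISSING] = np.nan
        col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(x))
        x[nan_r, nan_c] = col_mean[nan_c]
        return x


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    """Parent links: one record per animal, ``None`` for an unknown parent."""

    records: list[tuple[str, str | None, str | None]]
    _order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ParseError("duplicated animal ids in pedigree")
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        # Kahn's algorithm over parent -> child edges; raises on a cycle.
        parents = {a: [p for p in (s, d) if p is not None] for a, s, d in self.records}
        known = set(parents)
        indeg = {a: sum(p in known for p in ps) for a, ps in parents.items()}
        children: dict[str, list[str]] = {a: [] for a in parents}
        for a, ps in parents.items():
            for p in ps:
                if p in known:
                    children[p].append(a)
        queue = sorted(a for a, d in indeg.items() if d == 0)
        out: list[str] = []
        while queue:
            a = queue.pop()
            out.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != len(parents):
            raise ParseError("cycle detected in pedigree")
        return out

    @property
    def animals(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        return {a: (s, d) for a, s, d in self.records}

    def topological_order(self) -> list[str]:
        """Animal ids ordered so every known parent precedes its offspring."""
        return list(self._order)

    def founders(self) -> list[str]:
        return [a for a, s, d in self.records if s is None and d is None]


# ---------------------------------------------------------------------------
# PhenotypeTable


@dataclass
class PhenotypeTable:
    """Per animal-trait de-regressed PTA records.

    Columns: ``animal``, ``trait``, ``drp``, ``reliability`` and optionally
    ``true_g`` (simulation oracle only; never read by analysis code).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "trait", "drp", "reliability"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        rel = self.df["reliability"].to_numpy(dtype=float)
        if ((rel < 0) | (rel > 1)).any():
            raise ParseError("reliability outside [0, 1]")
        if self.df.duplicated(["animal", "trait"]).any():
            raise ParseError("duplicate animal-trait records")
        self.df = self.df.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.df["trait"]))

    def for_trait(self, trait: str) -> "PhenotypeTable":
        return PhenotypeTable(self.df[self.df["trait"] == trait].reset_index(drop=True))

    @property
    def animals(self) -> list[str]:
        return list(self.df["animal"])

    @property
    def y(self) -> np.ndarray:
        return self.df["drp"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# GeneSet / OrthologMap / PathwayDB


@dataclass
class GeneSet:
    """Gene spans, 1-based inclusive; columns gene_id, chrom, start, end."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        if required - set(self.df.columns):
            raise ValueError("gene table requires gene_id, chrom, start, end")
        if (self.df["start"] > self.df["end"]).any():
            raise ParseError("gene with start > end")
        if self.df["gene_id"].duplicated().any():
            raise ParseError("duplicated gene ids")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class OrthologMap:
    """Bovine gene id -> set of human ortholog ids (possibly empty per gene)."""

    mapping: dict[str, frozenset[str]]

    def orthologs_of(self, bovine_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for b in bovine_ids:
            out |= self.mapping.get(b, frozenset())
        return out


@dataclass
class PathwayDB:
    """Pathway id -> (name, human gene id set); sets must be non-empty."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ParseError(f"pathway {pid} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)


# ---------------------------------------------------------------------------
# PED/MAP

def read_genotypes(ped_path: str | Path, map_path: str | Path) -> GenotypeSet:
    """Read a PED/MAP pair, collapsing allele pairs to 0/1/2 counts.

    The counted allele at each SNP is the lexicographically smaller of the
    two observed alleles; ``0 0`` is missing.  A site with more than two
    distinct non-missing alleles is rejected.
    """
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    for ln, line in enumerate(_data_lines(map_path), start=1):
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
        chrom.append(parts[0])
        snp_ids.append(parts[1])
        pos.append(int(parts[3]))
    m = len(snp_ids)

    animal_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(_data_lines(ped_path), start=1):
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}:{ln}: ragged PED row ({len(parts)} fields, expected {6 + 2 * m})"
            )
        animal_ids.append(parts[1])
        allele_rows.append([(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)])

    calls = np.full((len(animal_ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        observed = {a for row in allele_rows for a in row[j] if a != "0"}
        if len(observed) > 2:
            raise ParseError(f"SNP {snp_ids[j]}: more than two alleles observed: {sorted(observed)}")
        counted = min(observed) if observed else None
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == counted) + (a2 == counted)
    return GenotypeSet(animal_ids, snp_ids, calls, np.array(chrom, dtype=object), np.array(pos))


def write_genotypes(
    gs: GenotypeSet,
    ped_path: str | Path,
    map_path: str | Path,
    alleles: tuple[str, str] = ("A", "B"),
    tool_note: str | None = None,
) -> None:
    """Write a PED/MAP pair; count-``alleles[0]`` must sort before ``alleles[1]``."""
    lo, hi = alleles
    if not lo < hi:
        raise ValueError("counted allele must sort lexicographically first")
    pair = {2: f"{lo} {lo}", 1: f"{lo} {hi}", 0: f"{hi} {hi}", MISSING: "0 0"}
    with open(map_path, "w") as fh:
        fh.write(_comment(tool_note))
        for sid, c, p in zip(gs.snp_ids, gs.chrom, gs.pos):
            fh.write(f"{c}\t{sid}\t0\t{p}\n")
    with open(ped_path, "w") as fh:
        fh.write(_comment(tool_note))
        for i, aid in enumerate(gs.animal_ids):
            geno = " ".join(pair[int(g)] for g in gs.calls[i])
            fh.write(f"FAM {aid} 0 0 0 -9 {geno}\n")


def _data_lines(path: str | Path) -> Iterable[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(_HEADER_PREFIX):
                continue
            yield line


# ---------------------------------------------------------------------------
# pedigree CSV

def read_pedigree(path: str | Path) -> Pedigree:
    records: list[tuple[str, str | None, str | None]] = []
    for ln, line in enumerate(_data_lines(path), start=1):
        parts = [p.strip() for p in line.split(",")]
        if parts[0].lower() == "animal":  # header row
            continue
        if len(parts) != 3:
            raise ParseError(f"{path}:{ln}: expected animal,sire,dam")
        a, s, d = parts
        records.append((a, None if s == "0" else s, None if d == "0" else d))
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path, tool_note: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(tool_note))
        fh.write("animal,sire,dam\n")
        for a, s, d in ped.records:
            fh.write(f"{a},{s or 0},{d or 0}\n")


# ---------------------------------------------------------------------------
# phenotype TSV

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    text = "\n".join(_data_lines(path))
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"animal": str, "trait": str})
    return PhenotypeTable(df)


def write_phenotypes(tab: PhenotypeTable, path: str | Path, tool_note: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(tool_note))
        tab.df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED genes

def read_genes_bed(path: str | Path) -> GeneSet:
    """Read genes from BED (0-based half-open); stored 1-based inclusive."""
    rows = []
    for ln, line in enumerate(_data_lines(path), start=1):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln}: BED needs chrom,start,end,name")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if end <= start:
            raise ParseError(f"{path}:{ln}: empty or inverted interval")
        rows.append((name, chrom, start + 1, end))
    return GeneSet(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))


def write_genes_bed(genes: GeneSet, path: str | Path, tool_note: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(tool_note))
        for r in genes.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\n")


# ---------------------------------------------------------------------------
# orthologs

def read_orthologs(path: str | Path) -> OrthologMap:
    mapping: dict[str, set[str]] = {}
    for ln, line in enumerate(_data_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{ln}: expected two tab-separated columns")
        bovine, human = parts[0].strip(), parts[1].strip()
        if bovine.lower() == "bovine_gene":
            continue
        mapping.setdefault(bovine, set())
        if human:  # empty second column = no ortholog
            mapping[bovine].add(human)
    return OrthologMap({b: frozenset(h) for b, h in mapping.items()})


def write_orthologs(om: OrthologMap, path: str | Path, tool_note: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(tool_note))
        fh.write("bovine_gene\thuman_gene\n")
        for b in sorted(om.mapping):
            hs = sorted(om.mapping[b])
            if not hs:
                fh.write(f"{b}\t\n")
            for h in hs:
                fh.write(f"{b}\t{h}\n")


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> PathwayDB:
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for ln, line in enumerate(_data_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: GMT line needs id, description and >= 1 gene")
        pid, desc, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
        if not genes:
            raise ParseError(f"{path}:{ln}: pathway {pid} has no genes")
        pathways[pid] = (desc, genes)
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path: str | Path, tool_note: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(tool_note))
        for pid in sorted(db.pathways):
            name, genes = db.pathways[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")
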