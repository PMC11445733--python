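"""Core in-memory containers shared by every stage of the pipeline.

Genotypes are held as an individuals x markers dosage matrix coded 0/1/2
(copies of the designated minor allele) with ``MISSING`` (-1) as the
unobserved sentinel.  The marker map is the single source of truth for
marker order; the pedigree defines families for Mendelian checks, phasing
and gene-drop simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for an unobserved genotype in a dosage matrix.
MISSING: int = -1

_LEGAL_DOSAGES = frozenset({-1, 0, 1, 2})


class MarkerMap:
    """Per-marker chromosome, physical and genetic position, and alleles.

    Backed by a :class:`pandas.DataFrame` with columns
    ``marker, chrom, bp, cm, allele_a, allele_b``, sorted by
    ``(chrom, bp)``.  ``allele_a`` is the counted (minor) allele.
    """

    COLUMNS = ("marker", "chrom", "bp", "cm", "allele_a", "allele_b")

    def __init__(self, table: pd.DataFrame):
        missing_cols = set(self.COLUMNS) - set(table.columns)
        if missing_cols:
            raise ValueError(f"marker map missing columns: {sorted(missing_cols)}")
        tab = table.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        tab["chrom"] = tab["chrom"].astype(int)
        tab["bp"] = tab["bp"].astype(int)
        tab["cm"] = tab["cm"].astype(float)
        if tab["marker"].duplicated().any():
            raise ValueError("marker ids must be unique")
        order = np.lexsort((tab["bp"].to_numpy(), tab["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(tab))):
            raise ValueError("marker map must be sorted by (chrom, bp)")
        for _, grp in tab.groupby("chrom", sort=False):
            cm = grp["cm"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise ValueError("cm positions must be non-decreasing within a chromosome")
        self.table = tab
        self._index = pd.Index(tab["marker"])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chrom"].unique().tolist())

    def positions(self, marker_ids: Sequence[str]) -> np.ndarray:
        """Integer row positions of ``marker_ids`` in map order."""
        pos = self._index.get_indexer(list(marker_ids))
        if (pos < 0).any():
            bad = [m for m, p in zip(marker_ids, pos) if p < 0]
            raise KeyError(f"markers not in map: {bad[:5]}")
        return pos

    def chrom_slice(self, chrom: int) -> np.ndarray:
        """Row positions of all markers on ``chrom`` in map order."""
        return np.flatnonzero(self.table["chrom"].to_numpy() == chrom)

    def subset(self, marker_ids: Sequence[str]) -> "MarkerMap":
        pos = np.sort(self.positions(marker_ids))
        return MarkerMap(self.table.iloc[pos])

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, MarkerMap) and self.table.equals(other.table)


class Pedigree:
    """Individual/sire/dam/family records.

    Unknown parents are ``None``.  Invariants: acyclic, every named parent
    of a non-founder appears as an individual, founders have both parents
    unknown (a record with exactly one known parent is rejected — the
    generator never emits one and it simplifies the trio logic downstream;
    readers may still treat absent parents as unknown).
    """

    def __init__(self, records: pd.DataFrame):
        tab = records.loc[:, ["individual", "sire", "dam", "family"]].reset_index(drop=True).copy()
        tab = tab.where(pd.notna(tab), None)
        tab.loc[tab["sire"].isin(["0", 0]), "sire"] = None
        tab.loc[tab["dam"].isin(["0", 0]), "dam"] = None
        if tab["individual"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        ids = set(tab["individual"])
        parents: dict[str, tuple] = {}
        for row in tab.itertuples(index=False):
            for p in (row.sire, row.dam):
                if p is not None and p not in ids:
                    raise ValueError(f"parent {p!r} of {row.individual!r} not in pedigree")
            parents[row.individual] = (row.sire, row.dam)
        self._check_acyclic(parents)
        self.table = tab
        self._parents = parents

    @staticmethod
    def _check_acyclic(parents: Mapping[str, tuple]) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in parents:
            if start in state:
                continue
            stack = [(start, iter([p for p in parents[start] if p is not None]))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if state.get(nxt) == 0:
                        raise ValueError(f"pedigree cycle involving {nxt!r}")
                    if nxt not in state:
                        state[nxt] = 0
                        stack.append((nxt, iter([p for p in parents[nxt] if p is not None])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "Pedigree":
        return cls(pd.DataFrame(records, columns=["individual", "sire", "dam", "family"]))

    @property
    def individuals(self) -> np.ndarray:
        return self.table["individual"].to_numpy()

    @property
    def founders(self) -> list[str]:
        return [i for i, (s, d) in self._parents.items() if s is None and d is None]

    @property
    def families(self) -> list[str]:
        fams = self.table.loc[self.table["family"].notna(), "family"]
        return sorted(fams.unique().tolist())

    def parents_of(self, individual: str) -> tuple:
        return self._parents.get(individual, (None, None))

    def topological_order(self) -> list[str]:
        """Individuals ordered so every parent precedes its offspring."""
        order: list[str] = []
        done: set[str] = set()

        def visit(node: str) -> None:
            if node in done:
                return
            for p in self._parents.get(node, (None, None)):
                if p is not None:
                    visit(p)
            done.add(node)
            order.append(node)

        for ind in self.table["individual"]:
            visit(ind)
        return order

    def __len__(self) -> int:
        return len(self.table)


class GenotypeMatrix:
    """Individuals x markers minor-allele dosage matrix with MISSING = -1."""

    def __init__(self, dosages: np.ndarray, individuals: Sequence[str], markers: Sequence[str]):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        if dosages.shape != (len(individuals), len(markers)):
            raise ValueError(
                f"shape {dosages.shape} does not match {len(individuals)} individuals "
                f"x {len(markers)} markers"
            )
        bad = set(np.unique(dosages)) - _LEGAL_DOSAGES
        if bad:
            raise ValueError(f"illegal dosage values: {sorted(bad)}")
        self.dosages = dosages
        self.individuals = np.asarray(individuals, dtype=object)
        self.markers = np.asarray(markers, dtype=object)
        self._ind_index = pd.Index(self.individuals)
        self._marker_index = pd.Index(self.markers)
        if self._ind_index.has_duplicates or self._marker_index.has_duplicates:
            raise ValueError("individual and marker ids must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.individuals, self.markers)

    def individual_positions(self, ids: Sequence[str]) -> np.ndarray:
        pos = self._ind_index.get_indexer(list(ids))
        if (pos < 0).any():
            bad = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"individuals not in matrix: {bad[:5]}")
        return pos

    def marker_positions(self, ids: Sequence[str]) -> np.ndarray:
        pos = self._marker_index.get_indexer(list(ids))
        if (pos < 0).any():
            bad = [m for m, p in zip(ids, pos) if p < 0]
            raise KeyError(f"markers not in matrix: {bad[:5]}")
        return pos

    def has_individual(self, ind: str) -> bool:
        return ind in self._ind_index

    def row(self, ind: str) -> np.ndarray:
        return self.dosages[self._ind_index.get_loc(ind)]

    def subset(self, individuals: Sequence[str] | None = None,
               markers: Sequence[str] | None = None) -> "GenotypeMatrix":
        rows = (self.individual_positions(individuals)
                if individuals is not None else np.arange(self.n_individuals))
        cols = (self.marker_positions(markers)
                if markers is not None else np.arange(self.n_markers))
        return GenotypeMatrix(self.dosages[np.ix_(rows, cols)],
                              self.individuals[rows], self.markers[cols])

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele over non-missing calls.

        All-missing markers yield ``nan``.
        """
        obs = self.dosages != MISSING
        counts = np.where(obs, self.dosages, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.individuals, columns=self.markers)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (np.array_equal(self.dosages, other.dosages)
                and np.array_equal(self.individuals, other.individuals)
                and np.array_equal(self.markers, other.markers))


@dataclass
class DatasetBundle:
    """A genotype matrix with its marker map, pedigree and provenance."""

    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    pedigree: Pedigree | None = None
    population_labels: pd.Series | None = None  # index = individual id
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.array_equal(self.genotypes.markers, self.marker_map.markers):
            raise ValueError("genotype marker order must match the marker map")
        if self.pedigree is not None:
            geno_ids = set(self.genotypes.individuals)
            ped_ids = set(self.pedigree.individuals)
            if not geno_ids <= ped_ids:
                missing = sorted(geno_ids - ped_ids)
                raise ValueError(f"genotyped individuals absent from pedigree: {missing[:5]}")
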