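"""Genotype tables, baseline registries, and the delimited-text dialect.

The on-disk dialect mirrors widely used mixed-stock analysis inputs: a
block of leading metadata columns (``sample_type``, ``repunit``,
``collection``, ``indiv``, plus any extras such as ``sex`` or
``brood_year``) followed by two integer allele columns per locus named
``<locus>`` and ``<locus>_1``. Missing genotypes are encoded as empty
fields or ``0``.

Internally a genotype is stored as the dosage of the locus's second
allele code: 0, 1 or 2, with :data:`MISSING` (``-1``) for no-calls.
Allele pairs are unordered, so dosage loses no information for
biallelic loci.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import LocusPanel

MISSING: int = -1

_META_ORDER = ["sample_type", "repunit", "collection", "indiv"]


class GenotypeFileError(ValueError):
    """Raised for malformed genotype files."""


@dataclass
class GenotypeTable:
    """Individuals-by-loci genotype matrix with group labels.

    ``groups`` hold the population for baseline/broodstock tables and the
    fishery stratum for mixture tables. ``meta`` carries any extra
    per-individual metadata columns found in the source file (sex,
    brood year, ...), aligned with ``ids``.
    """

    ids: np.ndarray
    groups: np.ndarray
    loci: list[str]
    geno: np.ndarray  # (n, L) int8 dosage of second allele; MISSING = -1
    meta: pd.DataFrame | None = None
    sample_type: str = "mixture"
    repunits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.loci = [str(l) for l in self.loci]
        n, L = self.geno.shape if self.geno.ndim == 2 else (len(self.ids), 0)
        if self.geno.ndim != 2:
            self.geno = self.geno.reshape(n, L)
        if len(self.ids) != n or len(self.groups) != n:
            raise ValueError("ids, groups and geno must agree on n individuals")
        if len(self.loci) != self.geno.shape[1]:
            raise ValueError("loci and geno must agree on n loci")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids must be unique within a table")
        bad = (self.geno < MISSING) | (self.geno > 2)
        if bad.any():
            raise ValueError("genotype dosages must be in {0,1,2} or MISSING")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_per_individual(self) -> np.ndarray:
        return (self.geno == MISSING).sum(axis=1)

    def take(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            self.ids[idx],
            self.groups[idx],
            list(self.loci),
            self.geno[idx],
            self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None,
            self.sample_type,
            self.repunits[idx] if self.repunits is not None else None,
        )

    def select_loci(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeTable(
            self.ids,
            self.groups,
            [self.loci[i] for i in keep],
            self.geno[:, keep],
            self.meta,
            self.sample_type,
            self.repunits,
        )

    def row(self, individual_id: str) -> np.ndarray:
        where = np.flatnonzero(self.ids == individual_id)
        if len(where) != 1:
            raise KeyError(individual_id)
        return self.geno[where[0]]

    @staticmethod
    def concat(tables: list["GenotypeTable"]) -> "GenotypeTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        loci = tables[0].loci
        for t in tables[1:]:
            if t.loci != loci:
                raise ValueError("tables must share an identical locus list")
        metas = [t.meta for t in tables]
        meta = (
            pd.concat(metas, ignore_index=True)
            if all(m is not None for m in metas)
            else None
        )
        return GenotypeTable(
            np.concatenate([t.ids for t in tables]),
            np.concatenate([t.groups for t in tables]),
            list(loci),
            np.concatenate([t.geno for t in tables], axis=0),
            meta,
            tables[0].sample_type,
        )


def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_genotypes(path, panel: LocusPanel) -> GenotypeTable:
    """Read a delimited genotype file against ``panel``.

    Two columns per locus (``<locus>``, ``<locus>_1``); leading columns
    are metadata. Raises :class:`GenotypeFileError` for unknown loci,
    allele codes outside the panel, or half-called genotypes.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    cols = list(df.columns)

    known = set(panel.locus_ids)
    first_locus_col = None
    for i, c in enumerate(cols):
        base = c[:-2] if c.endswith("_1") else c
        if base in known:
            first_locus_col = i
            break
    if first_locus_col is None:
        raise GenotypeFileError(f"{path}: no panel locus columns found")
    meta_cols = cols[:first_locus_col]
    locus_cols = cols[first_locus_col:]
    if "indiv" not in meta_cols:
        raise GenotypeFileError(f"{path}: required metadata column 'indiv' missing")

    if len(locus_cols) % 2 != 0:
        raise GenotypeFileError(f"{path}: odd number of allele columns")
    loci: list[str] = []
    for j in range(0, len(locus_cols), 2):
        a, b = locus_cols[j], locus_cols[j + 1]
        if b != f"{a}_1":
            raise GenotypeFileError(f"{path}: expected column '{a}_1' after '{a}', got '{b}'")
        if a not in known:
            raise GenotypeFileError(f"{path}: unknown locus {a!r} not in panel")
        loci.append(a)

    n = len(df)
    L = len(loci)
    geno = np.full((n, L), MISSING, dtype=np.int8)
    code_index = {l: i for i, l in enumerate(panel.locus_ids)}
    for j, locus in enumerate(loci):
        codes = panel.allele_codes[code_index[locus]]
        a = _parse_allele_column(df[locus], path, locus)
        b = _parse_allele_column(df[f"{locus}_1"], path, locus)
        miss_a, miss_b = a == 0, b == 0
        if (miss_a != miss_b).any():
            row = int(np.argmax(miss_a != miss_b))
            raise GenotypeFileError(
                f"{path}: half-called genotype at locus {locus!r}, row {row + 2}"
            )
        called = ~miss_a
        for arr in (a, b):
            bad = called & ~np.isin(arr, codes)
            if bad.any():
                row = int(np.argmax(bad))
                raise GenotypeFileError(
                    f"{path}: allele {arr[row]} at locus {locus!r} (row {row + 2}) "
                    f"not in panel codes {tuple(codes)}"
                )
        dosage = (a == codes[1]).astype(np.int8) + (b == codes[1]).astype(np.int8)
        geno[called, j] = dosage[called]

    ids = df["indiv"].to_numpy(dtype=object)
    groups = (
        df["collection"].to_numpy(dtype=object)
        if "collection" in meta_cols
        else np.array([""] * n, dtype=object)
    )
    repunits = df["repunit"].to_numpy(dtype=object) if "repunit" in meta_cols else None
    sample_type = df["sample_type"].iloc[0] if ("sample_type" in meta_cols and n) else "mixture"
    extra_cols = [c for c in meta_cols if c not in _META_ORDER]
    meta = df[extra_cols].copy() if extra_cols else None
    return GenotypeTable(ids, groups, loci, geno, meta, str(sample_type), repunits)


def _parse_allele_column(col: pd.Series, path, locus: str) -> np.ndarray:
    raw = col.to_numpy(dtype=object)
    out = np.zeros(len(raw), dtype=np.int64)
    for i, v in enumerate(raw):
        s = str(v).strip()
        if s in ("", "NA", "0"):
            continue
        try:
            out[i] = int(s)
        except ValueError as exc:
            raise GenotypeFileError(
                f"{path}: malformed allele {v!r} at locus {locus!r}, row {i + 2}"
            ) from exc
    return out


def write_genotypes(table: GenotypeTable, path, panel: LocusPanel) -> None:
    """Write ``table`` in the two-column-per-locus dialect."""
    code_index = {l: i for i, l in enumerate(panel.locus_ids)}
    n = table.n_individuals
    data: dict[str, object] = {
        "sample_type": [table.sample_type] * n,
        "repunit": table.repunits if table.repunits is not None else [""] * n,
        "collection": table.groups,
        "indiv": table.ids,
    }
    if table.meta is not None:
        for c in table.meta.columns:
            data[c] = table.meta[c].to_numpy()
    for j, locus in enumerate(table.loci):
        codes = panel.allele_codes[code_index[locus]]
        g = table.geno[:, j]
        a = np.where(g == MISSING, "", np.where(g >= 1, codes[1], codes[0]).astype(str))
        b = np.where(g == MISSING, "", np.where(g == 2, codes[1], codes[0]).astype(str))
        data[locus] = a
        data[f"{locus}_1"] = b
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


@dataclass(frozen=True)
class BaselineRegistry:
    """Population -> conservation unit / region / country mapping."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"population", "cu", "region", "country"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"registry needs columns {sorted(required)}")
        if self.table["population"].duplicated().any():
            dups = self.table.loc[self.table["population"].duplicated(), "population"]
            raise ValueError(f"duplicate populations in registry: {list(dups)}")

    @property
    def populations(self) -> list[str]:
        return list(self.table["population"])

    def unit_of(self, level: str) -> dict[str, str]:
        if level == "population":
            return {p: p for p in self.populations}
        if level not in ("cu", "region", "country"):
            raise ValueError(f"unknown roll-up level {level!r}")
        return dict(zip(self.table["population"], self.table[level]))

    def membership(self, populations: list[str], level: str):
        """Indicator matrix (n_pops, n_units) and the ordered unit names.

        Roll-up is a partition: each population maps to exactly one unit.
        """
        mapping = self.unit_of(level)
        missing = [p for p in populations if p not in mapping]
        if missing:
            raise KeyError(f"populations absent from registry: {missing}")
        units = sorted({mapping[p] for p in populations})
        uidx = {u: i for i, u in enumerate(units)}
        M = np.zeros((len(populations), len(units)))
        for i, p in enumerate(populations):
            M[i, uidx[mapping[p]]] = 1.0
        return M, units

    @classmethod
    def from_csv(cls, path) -> "BaselineRegistry":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def qc_filter(table: GenotypeTable, max_missing: int = 120):
    """Drop individuals with more than ``max_missing`` missing genotypes.

    The threshold is strict: an individual with exactly ``max_missing``
    no-calls is retained. Returns ``(filtered_table, excluded_ids)``.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    miss = table.missing_per_individual()
    keep = miss <= max_missing
    excluded = list(table.ids[~keep])
    return table.take(np.flatnonzero(keep)), excluded


def drop_non_analytic(table: GenotypeTable, panel: LocusPanel) -> GenotypeTable:
    """Restrict ``table`` to the panel's analytic loci, order preserved."""
    flag = dict(zip(panel.locus_ids, panel.is_analytic))
    unknown = [l for l in table.loci if l not in flag]
    if unknown:
        raise ValueError(f"table loci not in panel: {unknown}")
    keep = np.array([flag[l] for l in table.loci], dtype=bool)
    if not keep.any():
        raise ValueError("no analytic loci present in table")
    return table.select_loci(keep)


@dataclass
class AlleleFrequencies:
    """Per-population, per-locus frequency of each locus's second allele."""

    populations: list[str]
    loci: list[str]
    values: np.ndarray  # (P, L) in (0, 1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.populations), len(self.loci)):
            raise ValueError("values shape must be (n_populations, n_loci)")

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)

    def for_population(self, population: str) -> np.ndarray:
        return self.values[self.pop_index(population)]

    def select_loci(self, loci: list[str]) -> "AlleleFrequencies":
        idx = [self.loci.index(l) for l in loci]
        return AlleleFrequencies(list(self.populations), list(loci), self.values[:, idx])

    @classmethod
    def from_csv(cls, path) -> "AlleleFrequencies":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.populations, columns=self.loci).to_csv(path)
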