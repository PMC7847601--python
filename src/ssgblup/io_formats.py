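"""Readers and writers for the external text formats the pipeline touches.

PLINK PED/MAP genotype text files, delimited pedigree files (animal, sire,
dam[, year_class]) and delimited phenotype tables (animal_id, traits,
hatch_year, harvest_group, family).  All writers emit the same dialect the
readers accept, so write(read(x)) round-trips after whitespace
normalisation.

Dosage convention: for each SNP the "A1" allele is, by default, the first
allele of the first non-missing call (PLINK-like); the dosage is the count
of A1 copies, missing call ("0 0") -> nan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "MarkerMap",
    "RawGenotypes",
    "PhenotypeTable",
    "ParseError",
    "read_plink_ped_map",
    "write_plink_ped_map",
    "dosage_matrix",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
]

MISSING_ALLELE = "0"
_ALLELE_ALPHABET = {"A", "C", "G", "T", "1", "2", MISSING_ALLELE}


class ParseError(ValueError):
    """Malformed input file; the message names the offending row."""


@dataclass
class MarkerMap:
    """SNP ids with chromosome and 1-based bp position, in file order."""

    snp_id: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        m = len(self.snp_id)
        if self.chromosome.shape != (m,) or self.position_bp.shape != (m,):
            raise ValueError("marker map columns must have equal length")
        if len(set(self.snp_id)) != m:
            raise ValueError("duplicate SNP ids in marker map")
        if (self.position_bp < 0).any():
            raise ValueError("position_bp must be >= 0")
        for c in np.unique(self.chromosome):
            pos = np.sort(self.position_bp[self.chromosome == c])
            if len(pos) > 1 and (np.diff(pos) == 0).any():
                raise ValueError(f"tied bp positions on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def position_morgan(self, cm_per_mb: float = 1.0) -> np.ndarray:
        """Map positions in Morgans under a uniform cM/Mb conversion."""
        return self.position_bp / 1e6 * cm_per_mb / 100.0

    def subset(self, snp_ids: Sequence[str]) -> "MarkerMap":
        index = {s: j for j, s in enumerate(self.snp_id)}
        cols = [index[s] for s in snp_ids]
        return MarkerMap(
            snp_id=[self.snp_id[j] for j in cols],
            chromosome=self.chromosome[cols],
            position_bp=self.position_bp[cols],
        )

    def sorted_within_chromosome(self) -> "MarkerMap":
        order = np.lexsort((self.position_bp, self.chromosome.astype(str)))
        return MarkerMap(
            snp_id=[self.snp_id[j] for j in order],
            chromosome=self.chromosome[order],
            position_bp=self.position_bp[order],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )


@dataclass
class RawGenotypes:
    """One PED row: animal id plus per-SNP allele pairs ('0' = missing)."""

    animal_id: str
    family_id: str
    sire_id: str
    dam_id: str
    sex: str
    phenotype: str
    calls: list[tuple[str, str]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.calls:
            if a not in _ALLELE_ALPHABET or b not in _ALLELE_ALPHABET:
                raise ParseError(
                    f"animal {self.animal_id!r}: allele outside "
                    f"{{A,C,G,T,1,2,0}}: {(a, b)!r}"
                )


def read_plink_ped_map(ped_path, map_path) -> tuple[list[RawGenotypes], MarkerMap]:
    """Parse PLINK text PED/MAP into raw allele calls plus a marker map.

    PED rows carry 6 leading columns (family, animal, sire, dam, sex,
    phenotype) followed by two alleles per MAP SNP; a column-count mismatch
    or duplicate animal id raises :class:`ParseError` naming the row.
    """
    map_rows = []
    for k, line in enumerate(_read_lines(map_path)):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{map_path}: MAP row {k + 1} has {len(parts)} columns")
        chrom, snp, _cm, bp = parts[:4]
        map_rows.append((snp, chrom, int(bp)))
    mmap = MarkerMap(
        snp_id=[r[0] for r in map_rows],
        chromosome=np.array([r[1] for r in map_rows]),
        position_bp=np.array([r[2] for r in map_rows]),
    )
    m = mmap.n_snps
    records: list[RawGenotypes] = []
    seen: set[str] = set()
    for k, line in enumerate(_read_lines(ped_path)):
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}: PED row {k + 1} has {len(parts) - 6} allele "
                f"columns, expected {2 * m} for {m} MAP SNPs"
            )
        fam, animal, sire, dam, sex, pheno = parts[:6]
        if animal in seen:
            raise ParseError(f"{ped_path}: duplicate animal id {animal!r} (row {k + 1})")
        seen.add(animal)
        alleles = parts[6:]
        calls = list(zip(alleles[0::2], alleles[1::2]))
        records.append(
            RawGenotypes(
                animal_id=animal,
                family_id=fam,
                sire_id=sire,
                dam_id=dam,
                sex=sex,
                phenotype=pheno,
                calls=calls,
            )
        )
    return records, mmap


def write_plink_ped_map(records: Sequence[RawGenotypes], mmap: MarkerMap, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for j in range(mmap.n_snps):
            fh.write(
                f"{mmap.chromosome[j]} {mmap.snp_id[j]} 0 {mmap.position_bp[j]}\n"
            )
    with open(ped_path, "w") as fh:
        for r in records:
            if len(r.calls) != mmap.n_snps:
                raise ValueError(
                    f"animal {r.animal_id!r} has {len(r.calls)} calls for "
                    f"{mmap.n_snps} SNPs"
                )
            allele_cols = " ".join(f"{a} {b}" for a, b in r.calls)
            fh.write(
                f"{r.family_id} {r.animal_id} {r.sire_id} {r.dam_id} "
                f"{r.sex} {r.phenotype} {allele_cols}\n"
            )


def dosage_matrix(
    records: Sequence[RawGenotypes],
    mmap: MarkerMap,
    a1: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Convert raw allele calls to A1-allele dosages.

    The counted allele per SNP defaults to the first allele of the first
    non-missing call, overridable per SNP id through ``a1``.
    """
    n, m = len(records), mmap.n_snps
    allele1 = np.empty((n, m), dtype="U1")
    allele2 = np.empty((n, m), dtype="U1")
    for i, r in enumerate(records):
        if len(r.calls) != m:
            raise ParseError(
                f"animal {r.animal_id!r} has {len(r.calls)} calls for {m} SNPs"
            )
        allele1[i] = [c[0] for c in r.calls]
        allele2[i] = [c[1] for c in r.calls]
    dos = np.full((n, m), np.nan)
    for j in range(m):
        snp = mmap.snp_id[j]
        non_missing = allele1[:, j] != MISSING_ALLELE
        if a1 and snp in a1:
            ref = a1[snp]
        elif non_missing.any():
            ref = allele1[non_missing, j][0]
        else:
            continue  # fully missing SNP stays all-nan
        d = (allele1[:, j] == ref).astype(float) + (allele2[:, j] == ref).astype(float)
        d[~non_missing] = np.nan
        dos[:, j] = d
    return GenotypeMatrix(
        animal_ids=[r.animal_id for r in records],
        snp_ids=list(mmap.snp_id),
        dosages=dos,
    )


# ----------------------------------------------------------------------
# pedigree files


def read_pedigree(path) -> Pedigree:
    """Delimited animal/sire/dam[/year_class] text -> topologically ordered
    Pedigree.  Unknown parent = 0; undefined parents become founders with a
    warning; cycles raise."""
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: pedigree needs >= 3 columns, got {df.shape[1]}")
    cols = [c.lower() for c in df.columns.astype(str)]
    df.columns = cols
    recs = []
    has_yc = df.shape[1] > 3
    for row in df.itertuples(index=False):
        rec = (str(row[0]), str(row[1]), str(row[2]))
        if has_yc:
            rec = rec + (row[3],)
        recs.append(rec)
    return Pedigree.from_records(recs)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(ped.records(), columns=["animal", "sire", "dam"])
    if ped.year_class is not None:
        df["year_class"] = ped.year_class
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# phenotype files

RESERVED_PHENO_COLS = ("animal_id", "hatch_year", "harvest_group", "family")


@dataclass
class PhenotypeTable:
    """Trait values plus fixed-effect levels and full-sib family labels.

    ``data`` holds one row per animal with columns ``animal_id``, one column
    per trait (float, nan = missing record, kept not dropped), ``hatch_year``,
    ``harvest_group`` and ``family``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for c in RESERVED_PHENO_COLS:
            if c not in self.data.columns:
                raise ValueError(f"phenotype table missing column {c!r}")
        if self.data["animal_id"].duplicated().any():
            dup = self.data["animal_id"][self.data["animal_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicated animal_id {dup!r} in phenotype table")
        self.data = self.data.reset_index(drop=True)
        self.data["animal_id"] = self.data["animal_id"].astype(str)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_PHENO_COLS]

    @property
    def animal_ids(self) -> list[str]:
        return self.data["animal_id"].tolist()

    def n_missing(self, trait: str) -> int:
        return int(self.data[trait].isna().sum())

    def phenotyped_ids(self, trait: str) -> list[str]:
        return self.data.loc[self.data[trait].notna(), "animal_id"].tolist()


def read_phenotypes(path) -> PhenotypeTable:
    """Delimited phenotype table; non-numeric trait cells raise with the row
    index, missing values ('NA' or empty) are kept as nan."""
    df = _read_table(path)
    df.columns = [str(c) for c in df.columns]
    if "animal_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "animal_id"})
    trait_cols = [c for c in df.columns if c not in RESERVED_PHENO_COLS]
    for c in trait_cols:
        parsed = pd.to_numeric(df[c].replace({"NA": np.nan, "": np.nan}), errors="coerce")
        bad = parsed.isna() & df[c].notna() & ~df[c].astype(str).isin(["NA", "nan", ""])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {df[c].iloc[i]!r} in trait column "
                f"{c!r}, row {i + 1}"
            )
        df[c] = parsed
    return PhenotypeTable(data=df)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    df = table.data.copy()
    ordered = ["animal_id"] + table.traits + ["hatch_year", "harvest_group", "family"]
    # canonical 12-significant-digit dialect so write(read(x)) is stable
    df[ordered].to_csv(path, index=False, na_rep="NA", float_format="%.12g")


# ----------------------------------------------------------------------


def _read_lines(path) -> list[str]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return [ln for ln in p.read_text().splitlines() if ln.strip()]


def _read_table(path) -> pd.DataFrame:
    """Comma/tab/whitespace auto-sniffed delimited table with header."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    first = p.read_text().splitlines()[0] if p.read_text() else ""
    if "," in first:
        return pd.read_csv(p, dtype=str).pipe(_strip_cells)
    if "\t" in first:
        return pd.read_csv(p, sep="\t", dtype=str).pipe(_strip_cells)
    return pd.read_csv(p, sep=r"\s+", dtype=str).pipe(_strip_cells)


def _strip_cells(df: pd.DataFrame) -> pd.DataFrame:
    return df.apply(lambda s: s.str.strip() if s.dtype == object else s)
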