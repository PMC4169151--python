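"""Shared data containers and plain-text file formats.

Genotypes travel as TSV dosage matrices rather than VCF: the analysis
consumes 0/1/2 allele counts (or real-valued parent-of-origin codes in the
linkage dialect), not calls with quality.  Missing cells are written "NA".
SNP map positions are 1-based bp; interval (BED-like) outputs are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.nan

#: genotype matrix dialects
DIALECTS = ("raw", "gwas", "linkage")


class FormatError(ValueError):
    """A file violated the TSV genotype/map/phenotype format contract."""


@dataclass(frozen=True)
class SnpMap:
    """Ordered SNP metadata shared by all genotype matrices.

    SNPs are sorted by (chromosome, position); positions are 1-based bp and
    unique within a chromosome.  Chromosome blocks are contiguous, in order
    of first appearance.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos_bp", np.asarray(self.pos_bp, dtype=np.int64))
        if not (len(self.snp_id) == len(self.chrom) == len(self.pos_bp)):
            raise FormatError("snp_id, chrom and pos_bp must have equal length")
        seen = {}
        prev = None
        for i, c in enumerate(self.chrom):
            if c != prev:
                if c in seen:
                    raise FormatError(f"chromosome {c!r} appears in non-contiguous blocks")
                seen[c] = i
                prev = c
            elif self.pos_bp[i] <= self.pos_bp[i - 1]:
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c!r} "
                    f"at {self.snp_id[i]!r}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def __len__(self) -> int:
        return self.n_snps

    @property
    def chromosomes(self) -> list:
        out = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, keep: np.ndarray) -> "SnpMap":
        keep = np.asarray(keep)
        return SnpMap(self.snp_id[keep], self.chrom[keep], self.pos_bp[keep])

    @classmethod
    def from_positions(cls, positions: dict) -> "SnpMap":
        """Build from ``{chrom: array of 1-based bp positions}``."""
        ids, chroms, pos = [], [], []
        for c, p in positions.items():
            p = np.asarray(p, dtype=np.int64)
            ids.extend(f"S{c}_{x}" for x in p)
            chroms.extend([str(c)] * len(p))
            pos.extend(p.tolist())
        return cls(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(pos))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "chrom": self.chrom, "pos_bp": self.pos_bp}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpMap":
        return cls(
            df["snp_id"].to_numpy(dtype=object),
            df["chrom"].astype(str).to_numpy(dtype=object),
            df["pos_bp"].to_numpy(dtype=np.int64),
        )


@dataclass
class GenotypeMatrix:
    """Lines x SNPs coded genotypes with family labels.

    ``codes`` is float64; missing cells are NaN.  ``dialect`` distinguishes
    raw/GWAS integer allele counts from real-valued parent-of-origin codes.
    """

    codes: np.ndarray
    line_id: np.ndarray
    family: np.ndarray
    snp_map: SnpMap
    dialect: str = "raw"

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.float64)
        self.line_id = np.asarray(self.line_id, dtype=object)
        self.family = np.asarray(self.family, dtype=object)
        if self.codes.ndim != 2:
            raise FormatError("codes must be 2-D (lines x SNPs)")
        n, m = self.codes.shape
        if len(self.line_id) != n or len(self.family) != n:
            raise FormatError("line_id/family length does not match codes rows")
        if m != self.snp_map.n_snps:
            raise FormatError("codes columns do not match SNP map")
        if self.dialect not in DIALECTS:
            raise FormatError(f"unknown dialect {self.dialect!r}")
        uniq, counts = np.unique(self.line_id.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise FormatError(f"duplicated line id {dup!r}")

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def families(self) -> list:
        out = []
        for f in self.family:
            if f not in out:
                out.append(f)
        return out

    def family_rows(self, fam) -> np.ndarray:
        return np.flatnonzero(self.family == fam)

    def subset_lines(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.codes[rows], self.line_id[rows], self.family[rows],
            self.snp_map, self.dialect,
        )

    def subset_snps(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.codes[:, keep], self.line_id, self.family,
            self.snp_map.subset(keep), self.dialect,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.codes.copy(), self.line_id.copy(), self.family.copy(),
            self.snp_map, self.dialect,
        )


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------

def _snp_column_names(snp_map: SnpMap) -> list:
    return [f"{c}_{p}" for c, p in zip(snp_map.chrom, snp_map.pos_bp)]


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """Write a genotype matrix: ``line_id  family  <chrom>_<pos> ...``.

    The first line records the dialect as ``#dialect: <name>``.
    """
    path = Path(path)
    cols = _snp_column_names(gm.snp_map)
    df = pd.DataFrame(gm.codes, columns=cols)
    df.insert(0, "family", gm.family)
    df.insert(0, "line_id", gm.line_id)
    with open(path, "w") as fh:
        fh.write(f"#dialect: {gm.dialect}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_genotype_tsv(path, snp_map: SnpMap | None = None) -> GenotypeMatrix:
    """Read a genotype TSV; validates codes and (optionally) the SNP map."""
    path = Path(path)
    dialect = "raw"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#dialect:"):
            dialect = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"], dtype={"line_id": str, "family": str})
    if df.columns[0] != "line_id" or df.columns[1] != "family":
        raise FormatError(f"{path}: first columns must be line_id, family")
    snp_cols = list(df.columns[2:])
    chroms, pos = [], []
    for name in snp_cols:
        c, _, p = name.rpartition("_")
        if not c or not p.isdigit():
            raise FormatError(f"{path}: malformed SNP column name {name!r}")
        chroms.append(c)
        pos.append(int(p))
    if snp_map is not None:
        if list(snp_map.chrom) != chroms or list(snp_map.pos_bp) != pos:
            raise FormatError(f"{path}: SNP columns do not match the supplied map")
        smap = snp_map
    else:
        smap = SnpMap(np.array(snp_cols, dtype=object),
                      np.array(chroms, dtype=object), np.array(pos))
    codes = df[snp_cols].to_numpy(dtype=np.float64)
    if dialect in ("raw", "gwas"):
        bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    else:
        bad = ~np.isnan(codes) & ((codes < 0) | (codes > 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid code {codes[i, j]!r} at line {df['line_id'].iloc[i]!r}, "
            f"SNP {snp_cols[j]!r}"
        )
    return GenotypeMatrix(
        codes, df["line_id"].to_numpy(dtype=object),
        df["family"].to_numpy(dtype=object), smap, dialect,
    )


def write_snp_map_tsv(snp_map: SnpMap, path) -> None:
    snp_map.to_frame().to_csv(path, sep="\t", index=False)


def read_snp_map_tsv(path) -> SnpMap:
    return SnpMap.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_phenotype_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"line_id": str, "family": str})
    for col in df.columns:
        if col.endswith("_censored"):
            df[col] = df[col].astype(bool)
        elif col not in ("line_id", "family"):
            df[col] = df[col].astype(np.float64)
    return df


def write_mask_bed(regions, path) -> None:
    """Write per-family non-segregating regions as BED-like TSV.

    ``regions`` is an iterable of ``(chrom, start, end, family)`` with
    0-based half-open coordinates.
    """
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "family"])
    df.to_csv(path, sep="\t", index=False)


def read_mask_bed(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "family": str})
    return [tuple(r) for r in df.itertuples(index=False)]
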