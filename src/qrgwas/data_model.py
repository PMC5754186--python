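"""Core domain containers and file I/O for genotypes, SNP maps and phenotypes.

The package works on three plain-text inputs:

* a *wide* genotype CSV — first column the genotype (cultivar) id, one
  column per SNP holding allele dosages 0/1/2 (count of the alternate
  allele; heterozygote = 1) with blanks/``NA`` for missing calls;
* a SNP map TSV — ``snp_id``, ``chromosome`` (e.g. ``Pv01`` … ``Pv11``),
  ``position_bp`` — either as a separate file or embedded in the genotype
  CSV as two extra rows labelled ``#chrom`` and ``#pos``;
* a *long* phenotype CSV — ``genotype``, ``environment``, ``block``, then
  one column per trait, one row per field plot.

Positions are stored in base pairs and displayed in Mb (2 decimals).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "GenotypeMatrix",
    "PhenotypeRecords",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "impute_missing",
    "drop_unusable_snps",
]

#: chromosome labels of the Phaseolus vulgaris reference genome
PV_CHROMOSOMES = tuple(f"Pv{i:02d}" for i in range(1, 12))

_VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclasses.dataclass(frozen=True)
class SnpMap:
    """Genomic coordinates for a panel of SNPs.

    Parameters
    ----------
    snp_id : array of str
        Unique marker identifiers.
    chromosome : array of str
        Chromosome label per marker (e.g. ``"Pv01"``).
    position_bp : array of int
        Physical position in base pairs, non-negative.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        sid = np.asarray(self.snp_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(sid) == len(chrom) == len(pos)):
            raise ValueError("snp_id, chromosome and position_bp must have equal length")
        if len(np.unique(sid)) != len(sid):
            dup = pd.Series(sid)[pd.Series(sid).duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id in map: {dup!r}")
        if (pos < 0).any():
            raise ValueError("position_bp must be non-negative")
        object.__setattr__(self, "snp_id", sid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def position_mb(self) -> np.ndarray:
        """Positions in megabases (display convention: 2 decimals)."""
        return self.position_bp / 1e6

    def subset(self, idx: np.ndarray) -> "SnpMap":
        return SnpMap(self.snp_id[idx], self.chromosome[idx], self.position_bp[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "chromosome": self.chromosome, "position_bp": self.position_bp}
        )


@dataclasses.dataclass(frozen=True)
class GenotypeMatrix:
    """Allele-dosage matrix (genotypes x SNPs) with its SNP map.

    ``dosages`` is float with ``NaN`` marking missing calls; after
    :func:`impute_missing` entries are real-valued in ``[0, 2]``.
    """

    genotype_ids: tuple
    dosages: np.ndarray
    snp_map: SnpMap

    def __post_init__(self) -> None:
        ids = tuple(str(g) for g in self.genotype_ids)
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for g in ids:
                if g in seen:
                    dup = g
                    break
                seen.add(g)
            raise ValueError(f"duplicate genotype id: {dup!r}")
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if d.shape[0] != len(ids):
            raise ValueError("row count does not match number of genotype ids")
        if d.shape[1] != len(self.snp_map):
            raise ValueError("column count does not match SNP map length")
        if len(ids) < 2:
            raise ValueError("need at least 2 genotypes")
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(d) & ((d < 0) | (d > 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage out of range at genotype {ids[i]!r}, SNP "
                f"{self.snp_map.snp_id[j]!r}: {d[i, j]}"
            )
        object.__setattr__(self, "genotype_ids", ids)
        object.__setattr__(self, "dosages", d)

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=list(self.genotype_ids), columns=list(self.snp_map.snp_id)
        )


@dataclasses.dataclass(frozen=True)
class PhenotypeRecords:
    """Long-format plot-level observations.

    One row per (genotype, environment, block, trait); blocks are nested
    within environments (block ``1`` in env ``E1`` is a different plot
    grouping from block ``1`` in env ``E2``).
    """

    data: pd.DataFrame  # columns: genotype, environment, block, trait, value

    REQUIRED = ("genotype", "environment", "block", "trait", "value")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing phenotype columns: {missing}")
        df = df.copy()
        for c in ("genotype", "environment", "block", "trait"):
            df[c] = df[c].astype(str)
        if not pd.api.types.is_numeric_dtype(df["value"]):
            bad = df.loc[pd.to_numeric(df["value"], errors="coerce").isna(), "value"]
            if len(bad):
                raise ValueError(f"non-numeric trait value: {bad.iloc[0]!r}")
            df["value"] = pd.to_numeric(df["value"])
        key = ["genotype", "environment", "block", "trait"]
        dup = df.duplicated(subset=key)
        if dup.any():
            row = df.loc[dup, key].iloc[0].tolist()
            raise ValueError(f"duplicated plot record for {tuple(row)}")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    @property
    def genotypes(self) -> list:
        return sorted(self.data["genotype"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present (have {self.traits})")
        return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers


def _validate_dosage_frame(df: pd.DataFrame) -> np.ndarray:
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # entries that were non-numeric text become NaN; distinguish from declared NA
    raw_na = df.isna().to_numpy()
    coerced = np.isnan(vals) & ~raw_na
    if coerced.any():
        i, j = np.argwhere(coerced)[0]
        raise ValueError(
            f"non-numeric dosage at genotype {df.index[i]!r}, SNP {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    finite = np.isfinite(vals)
    ok = ~finite | np.isin(vals, _VALID_DOSAGES)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"dosage not in {{0,1,2}} at genotype {df.index[i]!r}, SNP "
            f"{df.columns[j]!r}: {vals[i, j]}"
        )
    return vals


def read_genotypes(path, map_path=None, dialect: str = "wide_csv") -> GenotypeMatrix:
    """Read a wide genotype CSV (and its SNP map) into a :class:`GenotypeMatrix`.

    The map is taken from ``map_path`` (3-column TSV: snp_id, chromosome,
    position_bp) when given; otherwise the CSV must embed it as two extra
    rows whose first-column labels are ``#chrom`` and ``#pos``.

    Missing calls may be blank or ``NA``; they are flagged as ``NaN``,
    never silently imputed.
    """
    if dialect != "wide_csv":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=object)
    df.index = df.index.astype(str)

    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", dtype={0: str, 1: str, 2: np.int64})
        mp.columns = ["snp_id", "chromosome", "position_bp"]
        if list(mp["snp_id"]) != list(df.columns):
            raise ValueError("SNP ids in map file do not match genotype CSV columns")
        snp_map = SnpMap(mp["snp_id"].to_numpy(object), mp["chromosome"].to_numpy(object),
                         mp["position_bp"].to_numpy())
    else:
        if not {"#chrom", "#pos"}.issubset(df.index):
            raise ValueError(
                "no map_path given and genotype CSV has no embedded '#chrom'/'#pos' rows"
            )
        chrom = df.loc["#chrom"].to_numpy(object)
        pos = df.loc["#pos"].astype(np.int64).to_numpy()
        df = df.drop(index=["#chrom", "#pos"])
        snp_map = SnpMap(np.asarray(df.columns, dtype=object), chrom, pos)

    dosages = _validate_dosage_frame(df)
    return GenotypeMatrix(tuple(df.index), dosages, snp_map)


def write_genotypes(g: GenotypeMatrix, path, map_path=None) -> None:
    """Write a genotype matrix back to the wide-CSV dialect (round-trip safe)."""
    frame = g.to_frame()
    out = frame.copy()
    # keep integral dosages as integers in text form
    def _fmt(v):
        if np.isnan(v):
            return ""
        return str(int(v)) if float(v).is_integer() else repr(float(v))
    out = out.map(_fmt)
    if map_path is None:
        header = pd.DataFrame(
            [g.snp_map.chromosome, g.snp_map.position_bp.astype(str)],
            index=["#chrom", "#pos"], columns=frame.columns,
        )
        out = pd.concat([header, out])
    else:
        g.snp_map.to_frame().to_csv(map_path, sep="\t", index=False)
    out.index.name = "genotype"
    out.to_csv(path)


def read_phenotypes(path) -> PhenotypeRecords:
    """Read a long phenotype CSV (genotype, environment, block, trait columns...).

    Every column after the three id columns is treated as a trait and the
    table is melted to one row per plot x trait.
    """
    df = pd.read_csv(path, dtype=object)
    idcols = ["genotype", "environment", "block"]
    missing = [c for c in idcols if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns {missing}")
    traits = [c for c in df.columns if c not in idcols]
    if not traits:
        raise ValueError("phenotype file has no trait columns")
    long = df.melt(id_vars=idcols, value_vars=traits, var_name="trait", value_name="value")
    long = long.dropna(subset=["value"])
    return PhenotypeRecords(long)


def write_phenotypes(records: PhenotypeRecords, path) -> None:
    wide = (
        records.data.pivot_table(
            index=["genotype", "environment", "block"],
            columns="trait", values="value", aggfunc="first",
        )
        .reset_index()
    )
    wide.columns.name = None
    wide.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cleaning


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by its SNP's mean over observed genotypes.

    Deterministic and column-local; non-missing entries are never touched.
    A SNP with no observed calls is an error.
    """
    d = g.dosages
    if not np.isnan(d).any():
        return g
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        bad = list(g.snp_map.snp_id[all_missing])
        raise ValueError(f"SNP(s) with all calls missing: {bad}")
    col_means = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_means[None, :], d)
    return GenotypeMatrix(g.genotype_ids, filled, g.snp_map)


def drop_unusable_snps(g: GenotypeMatrix):
    """Drop monomorphic (constant-dosage) SNPs.

    A constant column makes the per-SNP design singular, so such markers
    carry no association information. Returns the filtered matrix and the
    list of removed snp_ids (column order otherwise preserved).
    """
    if np.isnan(g.dosages).any():
        raise ValueError("impute_missing must be applied before drop_unusable_snps")
    constant = np.ptp(g.dosages, axis=0) == 0
    removed = [str(s) for s in g.snp_map.snp_id[constant]]
    if not removed:
        return g, removed
    keep = ~constant
    filtered = GenotypeMatrix.__new__(GenotypeMatrix)
    # bypass the n>=2-SNP style checks only for the empty-matrix boundary case
    object.__setattr__(filtered, "genotype_ids", g.genotype_ids)
    object.__setattr__(filtered, "dosages", g.dosages[:, keep])
    object.__setattr__(filtered, "snp_map", g.snp_map.subset(keep))
    return filtered, removed
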