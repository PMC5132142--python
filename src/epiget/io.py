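"""Reading and writing genotype / phenotype tables.

Two genotype dialects are accepted:

* a delimited (tab or comma) matrix with a header row of marker names and
  one row per subject; an optional leading subject-id column and an optional
  phenotype column (named on read) are split off;
* the PLINK ``.raw`` additive dialect, auto-detected by its
  ``FID IID PAT MAT SEX PHENOTYPE`` prefix columns (whitespace-delimited);
  the prefix is split off, ``IID`` becomes the subject id and ``PHENOTYPE``
  (1/2 or 0/1 coded) becomes the phenotype when present.

Values must be complete 0/1/2 allele counts; missingness is an error here —
impute or drop upstream.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import BinaryPhenotype, GenotypeMatrix
from .exceptions import InvalidInputError

__all__ = ["read_genotypes", "read_phenotype", "PLINK_RAW_PREFIX"]

PLINK_RAW_PREFIX = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _sniff_raw(path: Path) -> bool:
    with open(path) as fh:
        head = fh.readline().split()
    return tuple(head[:6]) == PLINK_RAW_PREFIX


def _binary_phenotype(series: pd.Series) -> BinaryPhenotype:
    vals = pd.to_numeric(series)
    uniq = sorted(set(vals.dropna().unique()))
    if uniq == [1, 2]:  # PLINK case/control coding: 1=control, 2=case
        vals = vals - 1
    elif not set(uniq) <= {0, 1}:
        raise InvalidInputError(
            f"phenotype must be coded 0/1 (or PLINK 1/2), found {uniq}")
    if vals.isna().any():
        raise InvalidInputError("phenotype contains missing values")
    return BinaryPhenotype(values=vals.to_numpy(dtype=int))


def read_genotypes(path, phenotype_column: str | None = None,
                   ) -> tuple[GenotypeMatrix, BinaryPhenotype | None]:
    """Read a genotype table; returns (genotypes, phenotype-or-None).

    ``phenotype_column`` names a column to split off as the binary phenotype
    (implied for the ``.raw`` dialect, where it is ``PHENOTYPE``).
    """
    path = Path(path)
    if _sniff_raw(path):
        df = pd.read_csv(path, sep=r"\s+")
        pheno = None
        if df["PHENOTYPE"].notna().all() and df["PHENOTYPE"].nunique() > 1:
            pheno = _binary_phenotype(df["PHENOTYPE"])
        subject_ids = tuple(df["IID"].astype(str))
        markers = df.drop(columns=list(PLINK_RAW_PREFIX))
        g = GenotypeMatrix(values=markers.to_numpy(),
                           marker_ids=tuple(markers.columns),
                           subject_ids=subject_ids)
        return g, pheno

    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    pheno = None
    if phenotype_column is not None:
        if phenotype_column not in df.columns:
            raise InvalidInputError(
                f"phenotype column {phenotype_column!r} not in file")
        pheno = _binary_phenotype(df[phenotype_column])
        df = df.drop(columns=[phenotype_column])
    # a non-numeric first column is treated as subject ids
    subject_ids = None
    first_col = df.columns[0]
    if df[first_col].dtype == object:
        subject_ids = tuple(df[first_col].astype(str))
        df = df.drop(columns=[first_col])
    g = GenotypeMatrix(values=df.to_numpy(), marker_ids=tuple(df.columns),
                       subject_ids=subject_ids)
    return g, pheno


def read_phenotype(path, g: GenotypeMatrix) -> BinaryPhenotype:
    """Read a two-column (subject_id, 0/1) phenotype file aligned to ``g``."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, header=None if first.strip()[0].isdigit()
                     else 0)
    df.columns = ["subject_id", "phenotype"]
    lookup = dict(zip(df["subject_id"].astype(str), df["phenotype"]))
    missing = [s for s in g.subject_ids if s not in lookup]
    if missing:
        raise InvalidInputError(
            f"{len(missing)} subject(s) missing from phenotype file, "
            f"first: {missing[0]!r}")
    return _binary_phenotype(pd.Series([lookup[s] for s in g.subject_ids]))


def write_genotypes_tsv(g: GenotypeMatrix, y: BinaryPhenotype | None,
                        path) -> None:
    df = g.to_dataframe()
    df.insert(0, "subject_id", list(g.subject_ids))
    if y is not None:
        df["phenotype"] = y.values
    df.to_csv(path, sep="\t", index=False)
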