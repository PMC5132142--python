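"""Core in-memory containers: genotypes, phenotypes, covariates, partitioned
correlation matrices.

Genotypes are additively coded allele counts (0/1/2) held as a small integer
matrix with marker and subject identifiers, convertible to/from a pandas
DataFrame.  Missing values are not represented: missingness must be resolved
upstream (the package's own QC stance is that imputation choices belong to
the caller).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, PartitionTooSmallError

__all__ = [
    "GenotypeMatrix",
    "BinaryPhenotype",
    "CovariateMatrix",
    "PartitionedCorrelations",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x p additive-coded marker matrix.

    Parameters
    ----------
    values : ndarray of int
        Allele counts in {0, 1, 2}; rows are subjects, columns markers.
    marker_ids : sequence of str, optional
        Defaults to ``snp1..snpP``.
    subject_ids : sequence of str, optional
        Defaults to ``s1..sN``.
    """

    values: np.ndarray
    marker_ids: tuple = None
    subject_ids: tuple = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise InvalidInputError("genotype values must be a 2-d matrix")
        if not np.issubdtype(v.dtype, np.integer):
            f = np.asarray(v, dtype=float)
            if not np.all(f == np.round(f)):
                raise InvalidInputError("genotype values must be integers 0/1/2")
            v = f.astype(np.int8)
        if v.size and (v.min() < 0 or v.max() > 2):
            raise InvalidInputError("genotype values must lie in {0, 1, 2}")
        n, p = v.shape
        if n < 4 or p < 2:
            raise InvalidInputError(f"need n >= 4 subjects and p >= 2 markers, got {n} x {p}")
        mids = tuple(self.marker_ids) if self.marker_ids is not None else tuple(
            f"snp{j + 1}" for j in range(p))
        sids = tuple(self.subject_ids) if self.subject_ids is not None else tuple(
            f"s{i + 1}" for i in range(n))
        if len(mids) != p:
            raise InvalidInputError("marker_ids length does not match column count")
        if len(sids) != n:
            raise InvalidInputError("subject_ids length does not match row count")
        object.__setattr__(self, "values", np.ascontiguousarray(v, dtype=np.int8))
        object.__setattr__(self, "marker_ids", mids)
        object.__setattr__(self, "subject_ids", sids)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(values=df.to_numpy(),
                   marker_ids=tuple(map(str, df.columns)),
                   subject_ids=tuple(map(str, df.index)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.subject_ids),
                            columns=list(self.marker_ids))


@dataclass(frozen=True)
class BinaryPhenotype:
    """n-vector of case (1) / control (0) indicators."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, [0, 1])):
            raise InvalidInputError("phenotype values must be 0/1")
        v = v.astype(np.int8)
        if v.ndim != 1:
            raise InvalidInputError("phenotype must be a 1-d vector")
        d = int(v.sum())
        if d == 0 or d == v.size:
            raise InvalidInputError("phenotype must contain both cases and controls")
        object.__setattr__(self, "values", v)

    @property
    def d(self) -> int:
        """Number of cases."""
        return int(self.values.sum())

    @property
    def n(self) -> int:
        return self.values.size

    def case_mask(self) -> np.ndarray:
        return self.values == 1


@dataclass(frozen=True)
class CovariateMatrix:
    """n x k real covariate matrix (k may be 0)."""

    values: np.ndarray
    covariate_ids: tuple = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise InvalidInputError("covariates must form a 2-d matrix")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("covariates must be finite")
        ids = tuple(self.covariate_ids) if self.covariate_ids is not None else tuple(
            f"c{j + 1}" for j in range(v.shape[1]))
        if len(ids) != v.shape[1]:
            raise InvalidInputError("covariate_ids length mismatch")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "covariate_ids", ids)

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def empty(cls, n: int) -> "CovariateMatrix":
        return cls(values=np.empty((n, 0)), covariate_ids=())


@dataclass(frozen=True)
class PartitionedCorrelations:
    """The pair of within-class marker correlation matrices (S1, S0).

    ``s_case`` is estimated from the d case rows, ``s_control`` from the
    n - d control rows; when ``partial`` is True both are partial correlations
    given the covariates.  These are the sample estimates of the within-class
    population LD structure whose equality the global test examines.
    """

    s_case: np.ndarray
    s_control: np.ndarray
    d: int
    n: int
    partial: bool = False
    marker_ids: tuple = field(default=None)

    def __post_init__(self):
        s1 = np.asarray(self.s_case, dtype=float)
        s0 = np.asarray(self.s_control, dtype=float)
        for name, s in (("s_case", s1), ("s_control", s0)):
            if s.ndim != 2 or s.shape[0] != s.shape[1]:
                raise InvalidInputError(f"{name} must be square")
            if not np.allclose(s, s.T, atol=1e-10):
                raise InvalidInputError(f"{name} must be symmetric")
            if not np.allclose(np.diag(s), 1.0, atol=1e-8):
                raise InvalidInputError(f"{name} must have unit diagonal")
            if np.nanmax(np.abs(s)) > 1.0 + 1e-8:
                raise InvalidInputError(f"{name} entries must lie in [-1, 1]")
        if s1.shape != s0.shape:
            raise InvalidInputError("matrix shapes differ")
        if not (2 <= self.d <= self.n - 2):
            raise PartitionTooSmallError(
                f"need at least 2 cases and 2 controls, got d={self.d}, n={self.n}")
        object.__setattr__(self, "s_case", s1)
        object.__setattr__(self, "s_control", s0)
        if self.marker_ids is not None:
            object.__setattr__(self, "marker_ids", tuple(self.marker_ids))

    @property
    def p(self) -> int:
        return self.s_case.shape[0]
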