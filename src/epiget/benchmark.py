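"""Two-stage benchmark global interaction test.

A per-pair p-value is computed for every ordered marker pair by the
case-only trend test: among cases, regress Ga on [1, C, Gb] by least squares
and Wald-test the Gb slope against zero (t reference with d - k - 2 degrees
of freedom).  The p(p-1)/2 pair p-values are then combined by Fisher's
method into a single global p-value.

The case-only construction is powerful but assumes the markers are
uncorrelated in the source population; when they are not, the pair p-values
are anticonservative and mutually dependent and the combined test can reject
essentially always.  This failure mode is deliberate — the method is the
comparison baseline for the global epistasis test, which does not share it.

With no covariates the Wald t for the slope equals the Pearson-correlation
t-statistic of the pair among cases, t = r sqrt((d-2)/(1-r^2)), and is
symmetric in the pair; the vectorized global path exploits this.  The slope
estimate itself does depend on which marker is the response (the lower-index
marker, by convention here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BinaryPhenotype, CovariateMatrix, GenotypeMatrix
from .exceptions import InvalidInputError, SingularFitError

__all__ = [
    "PairwisePValues",
    "case_only_trend_test",
    "fisher_combine",
    "benchmark_global_test",
    "CaseOnlyGlobalTest",
    "CaseOnlyResults",
]

#: Underflow floor applied to per-pair p-values before taking logs.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class PairwisePValues:
    """Per-pair interaction p-values (i < j by column order)."""

    pairs: tuple
    p_values: np.ndarray

    def __post_init__(self):
        pv = np.asarray(self.p_values, dtype=float)
        if len(self.pairs) != pv.size:
            raise InvalidInputError("pairs and p_values length mismatch")
        if pv.size and (not np.all(np.isfinite(pv)) or pv.min() <= 0 or pv.max() > 1):
            raise InvalidInputError("p-values must be finite and in (0, 1]")
        object.__setattr__(self, "pairs", tuple(self.pairs))
        object.__setattr__(self, "p_values", pv)


def case_only_trend_test(ga, gb, y: BinaryPhenotype,
                         c: CovariateMatrix | None = None) -> float:
    """Two-sided p-value for the case-only trend regression of ga on gb.

    Fits E(Ga | Y=1, Gb, C) = b0 + sum_i bCi Ci + bGb Gb on the case rows and
    Wald-tests bGb = 0 using the t distribution with d - k - 2 df.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    mask = y.case_mask()
    k = c.k if c is not None else 0
    d = int(mask.sum())
    if d < k + 3:
        raise InvalidInputError(f"need at least k+3 = {k + 3} cases, got {d}")
    cols = [np.ones(d)]
    if k:
        cols.append(c.values[mask])
    cols.append(gb[mask, None] if gb.ndim == 1 else gb[mask])
    design = np.column_stack(cols)
    resp = ga[mask]
    q = design.shape[1]
    if np.linalg.matrix_rank(design) < q:
        raise SingularFitError("collinear case-only design (is Gb constant "
                               "among cases?)")
    coef, _, _, _ = np.linalg.lstsq(design, resp, rcond=None)
    resid = resp - design @ coef
    dof = d - q
    s2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(s2 * xtx_inv[-1, -1])
    if se == 0.0:  # perfect fit: slope t-statistic diverges
        return 0.0
    t = coef[-1] / se
    return float(2.0 * stats.t.sf(abs(t), dof))


def fisher_combine(pvals) -> float:
    """Fisher's method: X = -2 sum log p_i referred to chi-square(2m).

    Zero/underflowed inputs are floored at 1e-300 with a warning; inputs
    above 1 are invalid.
    """
    if isinstance(pvals, PairwisePValues):
        pv = pvals.p_values
    else:
        pv = np.asarray(pvals, dtype=float)
    if pv.size < 1:
        raise InvalidInputError("need at least one p-value")
    if np.any(pv > 1.0) or not np.all(np.isfinite(pv)):
        raise InvalidInputError("p-values must be finite and at most 1")
    if np.any(pv <= 0.0):
        warnings.warn("flooring non-positive p-value(s) at 1e-300 before "
                      "Fisher combination", stacklevel=2)
        pv = np.maximum(pv, P_FLOOR)
    x = -2.0 * np.log(pv).sum()
    return float(stats.chi2.sf(x, 2 * pv.size))


def _pairwise_case_pvalues(g: GenotypeMatrix, y: BinaryPhenotype,
                           c: CovariateMatrix | None) -> PairwisePValues:
    """All p(p-1)/2 case-only trend p-values, vectorized.

    The Wald t for the trend slope equals the (partial) correlation t among
    cases, so one correlation matrix yields every pair's p-value at once.
    """
    from .core import _residualize

    mask = y.case_mask()
    x = np.asarray(g.values[mask], dtype=float)
    k = c.k if c is not None else 0
    d = x.shape[0]
    if d < k + 3:
        raise InvalidInputError(f"need at least k+3 = {k + 3} cases, got {d}")
    x = _residualize(x, c.values[mask] if k else None)
    sd = x.std(axis=0)
    if np.any(sd == 0.0):
        j = int(np.flatnonzero(sd == 0.0)[0])
        raise SingularFitError(
            f"marker {g.marker_ids[j]!r} has zero variance among cases")
    z = x / sd
    r = (z.T @ z) / d
    dof = d - k - 2
    iu = np.triu_indices(g.n_markers, k=1)
    rv = np.clip(r[iu], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt(dof / np.maximum(1.0 - rv ** 2, 1e-300))
    pv = 2.0 * stats.t.sf(np.abs(t), dof)
    pv = np.maximum(pv, P_FLOOR)
    pairs = tuple(zip(iu[0].tolist(), iu[1].tolist()))
    return PairwisePValues(pairs=pairs, p_values=pv)


@dataclass(frozen=True)
class CaseOnlyResults:
    """Results of the benchmark two-stage global test."""

    pvalue: float
    pairwise: PairwisePValues
    n_markers: int
    n_cases: int

    def pair_table(self) -> pd.DataFrame:
        i, j = zip(*self.pairwise.pairs) if self.pairwise.pairs else ((), ())
        return pd.DataFrame({"i": i, "j": j, "p_value": self.pairwise.p_values})

    def summary(self) -> str:
        m = len(self.pairwise.pairs)
        lines = [
            "Case-only trend + Fisher global interaction test (benchmark)",
            "=" * 60,
            f"markers (p):         {self.n_markers}",
            f"cases (d):           {self.n_cases}",
            f"pairs combined (m):  {m}",
            f"min pair p-value:    {self.pairwise.p_values.min():.4g}",
            f"global p-value:      {self.pvalue:.4g}",
            "=" * 60,
            "Valid only when markers are uncorrelated in the population;",
            "correlated markers inflate the type I error dramatically.",
        ]
        return "\n".join(lines)


class CaseOnlyGlobalTest:
    """Model object for the benchmark two-stage global interaction test."""

    def __init__(self, genotypes, phenotype, covariates=None):
        if isinstance(genotypes, pd.DataFrame):
            genotypes = GenotypeMatrix.from_dataframe(genotypes)
        elif not isinstance(genotypes, GenotypeMatrix):
            genotypes = GenotypeMatrix(values=np.asarray(genotypes))
        if not isinstance(phenotype, BinaryPhenotype):
            phenotype = BinaryPhenotype(values=np.asarray(phenotype))
        if covariates is not None and not isinstance(covariates, CovariateMatrix):
            covariates = CovariateMatrix(values=np.asarray(covariates, dtype=float))
        self.genotypes = genotypes
        self.phenotype = phenotype
        self.covariates = covariates

    def fit(self) -> CaseOnlyResults:
        pw = _pairwise_case_pvalues(self.genotypes, self.phenotype,
                                    self.covariates)
        return CaseOnlyResults(pvalue=fisher_combine(pw), pairwise=pw,
                               n_markers=self.genotypes.n_markers,
                               n_cases=self.phenotype.d)


def benchmark_global_test(genotypes, phenotype, covariates=None) -> float:
    """Global benchmark p-value (functional form)."""
    return CaseOnlyGlobalTest(genotypes, phenotype, covariates).fit().pvalue
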