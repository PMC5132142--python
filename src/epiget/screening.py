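"""Marker screening by marginal association, and BH false-discovery-rate
utilities.

For genome-scale panels the global interaction test needs a reduced marker
set (the Tracy-Widom approximation degrades as n/p falls).  The screening
filter ranks markers by the Wald p-value of the marker coefficient in a
one-marker regression of the phenotype on [1, C, G] — logistic for a binary
phenotype, linear for a continuous one — and keeps the k best.  Marginal
association is asymptotically independent of interaction statistics under
the null of no interaction, which is what makes it a legitimate screening
statistic; this module asserts only the operational contract, not that
asymptotic claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .datatypes import BinaryPhenotype, CovariateMatrix, GenotypeMatrix
from .exceptions import InvalidInputError

__all__ = ["FilterResult", "marginal_filter", "bh_fdr"]


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the marginal-association screen.

    ``marginal_p`` is aligned with the input marker order; ``kept_ids`` are
    the ``threshold_rank`` markers with the smallest p-values, ties broken
    by input marker order (stable, deterministic).
    """

    kept_ids: tuple
    marginal_p: np.ndarray
    threshold_rank: int
    marker_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "kept_ids", tuple(self.kept_ids))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        object.__setattr__(self, "marginal_p",
                           np.asarray(self.marginal_p, dtype=float))

    def kept_indices(self) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        return np.array([lookup[m] for m in self.kept_ids], dtype=int)

    def apply(self, g: GenotypeMatrix) -> GenotypeMatrix:
        """Subset a genotype matrix to the kept markers (in kept order)."""
        idx = self.kept_indices()
        return GenotypeMatrix(values=g.values[:, idx],
                              marker_ids=self.kept_ids,
                              subject_ids=g.subject_ids)


def _marker_pvalue_logistic(yv, design):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, design).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return None
        if not res.mle_retvals.get("converged", False):
            return None
        return float(res.pvalues[-1])


def _marker_pvalue_linear(yv, design):
    res = sm.OLS(yv, design).fit()
    return float(res.pvalues[-1])


def marginal_filter(g: GenotypeMatrix, y, c: CovariateMatrix | None = None,
                    k: int = 100) -> FilterResult:
    """Keep the k markers most marginally associated with the phenotype.

    ``y`` may be a :class:`BinaryPhenotype` (or 0/1 vector), screened by
    logistic regression, or any other numeric vector, screened by linear
    regression.  Covariates, when given, enter every per-marker fit.
    Non-convergent logistic fits (e.g. complete separation) are assigned
    p = 1 with a warning — conservative, and keeps the screen total.
    """
    if k < 1:
        raise InvalidInputError("k must be at least 1")
    if isinstance(y, BinaryPhenotype):
        yv, binary = y.values.astype(float), True
    else:
        yv = np.asarray(y, dtype=float)
        binary = np.all(np.isin(np.unique(yv), [0.0, 1.0]))
    if yv.size != g.n_subjects:
        raise InvalidInputError("phenotype length does not match genotype rows")
    base = [np.ones(g.n_subjects)]
    if c is not None and c.k:
        base.append(c.values)
    base = np.column_stack(base)

    pvals = np.ones(g.n_markers)
    fit = _marker_pvalue_logistic if binary else _marker_pvalue_linear
    for j in range(g.n_markers):
        design = np.column_stack([base, g.values[:, j].astype(float)])
        pv = fit(yv, design)
        if pv is None:
            warnings.warn(
                f"logistic fit for marker {g.marker_ids[j]!r} did not "
                "converge (separation?); assigning p = 1", stacklevel=2)
            pv = 1.0
        pvals[j] = pv

    k_eff = min(k, g.n_markers)
    # stable mergesort => ties at the k-th rank resolve by input marker order
    order = np.argsort(pvals, kind="stable")[:k_eff]
    return FilterResult(kept_ids=tuple(g.marker_ids[j] for j in order),
                        marginal_p=pvals, threshold_rank=k_eff,
                        marker_ids=g.marker_ids)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with the running-minimum
    (monotone) correction, as returned by statsmodels' ``fdr_bh``."""
    pv = np.asarray(pvals, dtype=float)
    if pv.size == 0:
        return pv.copy()
    if not np.all(np.isfinite(pv)) or pv.min() < 0.0 or pv.max() > 1.0:
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(pv, method="fdr_bh")[1]
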