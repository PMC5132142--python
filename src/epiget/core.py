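"""The global epistasis test (GET).

The test compares the within-case and within-control sample correlation
matrices of a set of additively coded markers.  Under the global null of no
gene-gene interaction the two population correlation matrices are equal, so
the largest eigenvalue ("greatest root") of

    (d S1 + (n - d) S0)^{-1} d S1

behaves like the greatest root of a Jacobi (double Wishart) ensemble.
Johnstone's result gives the null approximation

    T = (logit(lambda1) - mu(p, n1, n2)) / sigma(p, n1, n2)  ->  F1,

the Tracy-Widom law of order 1, where the numerator sample (the cases,
d observations) takes the n2 role and the controls the n1 role, and the
p-value is the F1 upper-tail probability of T.

A single significant result indicates that *some* pair of markers has
case/control correlation (LD) structure that differs — it does not identify
which pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .datatypes import (BinaryPhenotype, CovariateMatrix, GenotypeMatrix,
                        PartitionedCorrelations)
from .exceptions import (AngleDomainError, DegenerateMarkerError,
                         InvalidInputError, NumericalRankError,
                         PartitionTooSmallError)
from .tracy_widom import tw1_sf

__all__ = [
    "partitioned_correlations",
    "greatest_root",
    "centering_and_scaling",
    "global_epistasis_test",
    "GlobalEpistasisTest",
    "GETResults",
]

#: lambda1 is clamped into [EPS, 1 - EPS] before the logit transform.
EPS = 1e-12


def _residualize(x: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
    """Mean-center x columnwise, or residualize on [1, cov] when covariates
    are present (partition-specific least squares)."""
    x = np.asarray(x, dtype=float)
    if cov is not None and cov.shape[1] > 0:
        design = np.column_stack([np.ones(x.shape[0]), cov])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        return x - design @ coef
    return x - x.mean(axis=0)


def _correlate(x: np.ndarray) -> np.ndarray:
    """Pearson correlation of the columns of an already-centered matrix."""
    z = x / x.std(axis=0)
    corr = (z.T @ z) / x.shape[0]
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def partitioned_correlations(g: GenotypeMatrix, y: BinaryPhenotype,
                             c: CovariateMatrix | None = None,
                             drop_degenerate: bool = False,
                             ) -> PartitionedCorrelations:
    """Within-case and within-control marker correlation matrices.

    With covariates, each marker is residualized on [1, C] by least squares
    within each partition and the residuals are correlated, giving partial
    correlation matrices (no degrees-of-freedom correction for k is applied).

    Raises :class:`DegenerateMarkerError` if a marker is constant within a
    partition, unless ``drop_degenerate`` is set, in which case the marker is
    dropped from *both* matrices with a warning (note this changes p and
    hence the null centering).
    """
    if y.n != g.n_subjects:
        raise InvalidInputError("phenotype length does not match genotype rows")
    if c is not None and c.values.shape[0] != g.n_subjects:
        raise InvalidInputError("covariate rows do not match genotype rows")
    d, n = y.d, y.n
    if d < 2 or n - d < 2:
        raise PartitionTooSmallError(f"d={d}, n-d={n - d}; need at least 2 of each")
    mask = y.case_mask()
    cov1 = c.values[mask] if c is not None and c.k else None
    cov0 = c.values[~mask] if c is not None and c.k else None
    partial = cov1 is not None

    x1 = _residualize(g.values[mask], cov1)
    x0 = _residualize(g.values[~mask], cov0)
    sd1, sd0 = x1.std(axis=0), x0.std(axis=0)
    bad1, bad0 = sd1 == 0.0, sd0 == 0.0
    if bad1.any() or bad0.any():
        if not drop_degenerate:
            if bad1.any():
                raise DegenerateMarkerError(
                    g.marker_ids[int(np.flatnonzero(bad1)[0])], "cases")
            raise DegenerateMarkerError(
                g.marker_ids[int(np.flatnonzero(bad0)[0])], "controls")
        bad = bad1 | bad0
        warnings.warn(
            f"dropping {int(bad.sum())} zero-variance marker(s): "
            f"{[g.marker_ids[j] for j in np.flatnonzero(bad)]}", stacklevel=2)
        keep = np.flatnonzero(~bad)
        if keep.size < 2:
            raise DegenerateMarkerError(
                g.marker_ids[0], "both partitions (fewer than 2 usable markers)")
        x1, x0 = x1[:, keep], x0[:, keep]
    else:
        keep = np.arange(g.n_markers)
    return PartitionedCorrelations(
        s_case=_correlate(x1), s_control=_correlate(x0), d=d, n=n,
        partial=partial, marker_ids=tuple(g.marker_ids[j] for j in keep))


def greatest_root(pc: PartitionedCorrelations) -> float:
    """Largest eigenvalue of (d S1 + (n-d) S0)^{-1} d S1, in (0, 1).

    The case-weighted matrix sits in the numerator: the greatest root probes
    the direction in marker space where the case correlation structure most
    exceeds the pooled structure, which is where phenotype-dependent
    selection concentrates interaction signal in a case-control design.
    (The complementary control-weighted root is 1 minus the *smallest* root
    of this pencil; with d = n - d the two have the same null law but they
    are not the same test.)

    Solved as the symmetric generalized eigenproblem
    d S1 v = lambda (d S1 + (n-d) S0) v via Cholesky reduction, never by
    explicit inversion — numerically stabler for near-singular sums.
    """
    a = pc.d * pc.s_case
    b = (pc.n - pc.d) * pc.s_control
    try:
        p = pc.p
        lam = scipy.linalg.eigh(a, a + b, subset_by_index=(p - 1, p - 1),
                                eigvals_only=True)[0]
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise NumericalRankError(
            "weighted correlation sum d*S1 + (n-d)*S0 is numerically singular; "
            "consider filtering collinear/duplicated markers") from exc
    return float(min(max(lam, EPS), 1.0 - EPS))


def centering_and_scaling(p: int, n1: int, n2: int) -> tuple[float, float]:
    """Johnstone's centering mu and scaling sigma for logit(lambda1).

    With s = n1 + n2 - 1 and angles gamma, phi defined by

        sin^2(gamma/2) = (min(p, n2) - 1/2) / s
        sin^2(phi/2)   = (max(p, n2) - 1/2) / s

    the centering is mu = 2 log tan((phi + gamma)/2) and the scaling obeys
    sigma^3 = 16 / s^2 / (sin^2(phi + gamma) sin(phi) sin(gamma)).

    Note the asymmetry: the roles of n1 and n2 are not exchangeable (they
    coincide when n1 = n2).  The test maps n1 = d (cases), n2 = n - d.
    """
    if min(p, n1, n2) < 2:
        raise InvalidInputError("p, n1, n2 must each be at least 2")
    s = n1 + n2 - 1
    hi = (max(p, n2) - 0.5) / s
    lo = (min(p, n2) - 0.5) / s
    if hi >= 1.0:
        raise AngleDomainError(
            f"(max(p, n2) - 0.5)/(n1 + n2 - 1) = {hi:.4f} >= 1: p={p} is too "
            f"large relative to the sample sizes (n1={n1}, n2={n2})")
    gamma = 2.0 * np.arcsin(np.sqrt(lo))
    phi = 2.0 * np.arcsin(np.sqrt(hi))
    total = phi + gamma
    if total >= np.pi:
        raise AngleDomainError(
            f"phi + gamma = {total:.4f} >= pi: centering undefined for p={p}, "
            f"n1={n1}, n2={n2}")
    mu = 2.0 * np.log(np.tan(total / 2.0))
    sigma3 = (16.0 / s ** 2) / (np.sin(total) ** 2 * np.sin(phi) * np.sin(gamma))
    return float(mu), float(np.cbrt(sigma3))


@dataclass(frozen=True)
class GETResults:
    """Results of a fitted global epistasis test.

    Attributes mirror the statistic chain: ``lambda1`` (greatest root),
    ``mu``/``sigma`` (null centering and scaling), ``statistic``
    (the Tracy-Widom-scale statistic T) and ``pvalue`` = 1 - F1(T).
    """

    lambda1: float
    mu: float
    sigma: float
    statistic: float
    pvalue: float
    n_markers: int
    n_cases: int
    n_controls: int
    partial: bool = False

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "lambda1": self.lambda1, "mu": self.mu, "sigma": self.sigma,
            "T": self.statistic, "p_value": self.pvalue,
            "p": self.n_markers, "d": self.n_cases, "n": self.n,
        }])

    def summary(self) -> str:
        adj = "partial (covariate-adjusted) " if self.partial else ""
        lines = [
            "Global Epistasis Test (greatest root / Tracy-Widom order 1)",
            "=" * 59,
            f"markers (p):            {self.n_markers}",
            f"cases / controls:       {self.n_cases} / {self.n_controls}",
            f"correlation matrices:   {adj}Pearson, partitioned by phenotype",
            f"greatest root lambda1:  {self.lambda1:.6f}",
            f"centering mu:           {self.mu:.6f}",
            f"scaling sigma:          {self.sigma:.6f}",
            f"statistic T:            {self.statistic:.6f}",
            f"p-value (1 - F1(T)):    {self.pvalue:.4g}",
            "=" * 59,
            "H0: case and control marker correlation (LD) matrices are equal;",
            "rejection indicates some interacting marker pair, not which one.",
        ]
        return "\n".join(lines)


class GlobalEpistasisTest:
    """Model object for the global epistasis test.

    Parameters
    ----------
    genotypes : GenotypeMatrix or array-like / DataFrame of 0/1/2
    phenotype : BinaryPhenotype or array-like of 0/1
    covariates : CovariateMatrix or array-like, optional
        If given, partial correlations given the covariates are used.
    drop_degenerate : bool
        Drop markers that are constant within a phenotype class instead of
        raising (changes p, logged as a warning).

    Examples
    --------
    >>> res = GlobalEpistasisTest(g, y).fit()
    >>> res.pvalue
    """

    def __init__(self, genotypes, phenotype, covariates=None,
                 drop_degenerate: bool = False):
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
        self.drop_degenerate = drop_degenerate

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotype: str,
                       covariates: list[str] | None = None, **kwargs
                       ) -> "GlobalEpistasisTest":
        """Build from a single tidy DataFrame naming the phenotype column."""
        covariates = list(covariates or [])
        marker_cols = [c for c in df.columns if c != phenotype and c not in covariates]
        g = GenotypeMatrix.from_dataframe(df[marker_cols])
        y = BinaryPhenotype(values=df[phenotype].to_numpy())
        c = (CovariateMatrix(values=df[covariates].to_numpy(dtype=float),
                             covariate_ids=tuple(covariates))
             if covariates else None)
        return cls(g, y, c, **kwargs)

    def fit(self) -> GETResults:
        g, y = self.genotypes, self.phenotype
        d, n = y.d, y.n
        if n / g.n_markers < 5:
            warnings.warn(
                f"n/p = {n / g.n_markers:.2f} < 5: the Tracy-Widom null "
                "approximation degrades in this regime", stacklevel=2)
        if g.n_markers > min(d, n - d):
            warnings.warn(
                f"p = {g.n_markers} exceeds min(d, n-d) = {min(d, n - d)}; "
                "results may be unreliable", stacklevel=2)
        pc = partitioned_correlations(g, y, self.covariates,
                                      drop_degenerate=self.drop_degenerate)
        lam = greatest_root(pc)
        # the case matrix (d observations) is the numerator sample, so it
        # takes the n2 role in the centering/scaling formulas
        mu, sigma = centering_and_scaling(pc.p, n - d, d)
        t = (np.log(lam / (1.0 - lam)) - mu) / sigma
        return GETResults(lambda1=lam, mu=mu, sigma=sigma, statistic=float(t),
                          pvalue=float(tw1_sf(t)), n_markers=pc.p,
                          n_cases=d, n_controls=n - d, partial=pc.partial)


def global_epistasis_test(genotypes, phenotype, covariates=None,
                          drop_degenerate: bool = False) -> GETResults:
    """Functional one-shot form of :class:`GlobalEpistasisTest`."""
    return GlobalEpistasisTest(genotypes, phenotype, covariates,
                               drop_degenerate=drop_degenerate).fit()
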