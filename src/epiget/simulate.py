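"""Genotype / phenotype simulators.

Genotypes are additively coded SNPs: each marker is Binomial(2, MAF) under
Hardy-Weinberg equilibrium, and cross-marker dependence is induced by a
Gaussian copula with exchangeable latent correlation rho (latent z-scores
share a single common factor, are mapped through the standard normal CDF,
then through the Binomial(2, MAF) quantile function).  A latent rho of 0.1
yields a genotype Pearson correlation of ~0.1 for intermediate MAFs.

Binary phenotypes follow a logistic model on the additive codes with
optional marginal terms and pairwise product (interaction) terms:

    logit P(Y=1 | G) = beta0 + sum_i beta_i G_i + sum_(i,j) beta_ij G_i G_j.

Case-control designs are emulated the way cohort-to-case-control sampling
works: a large pool of subjects is generated (adaptively, in blocks of
``block_factor * n`` up to ``cap_factor * n``), and the requested numbers of
cases and controls are drawn uniformly without replacement within class.

A configurable disease-architecture generator composes known risk SNPs,
environmental exposures (as covariates), unassociated null SNPs and optional
G x G terms, all mutually independent, for more realistic risk models.

All entry points are deterministic given a seed (or Generator / SeedSequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr

from .datatypes import BinaryPhenotype, CovariateMatrix, GenotypeMatrix
from .exceptions import InsufficientCasesError, InvalidInputError

__all__ = [
    "GenotypeModel",
    "SimulationModel",
    "DiseaseArchitecture",
    "simulate_genotypes",
    "simulate_phenotype",
    "subsample_case_control",
    "simulate_case_control",
    "simulate_disease",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenotypeModel:
    """Marginal and dependence structure of a panel of p SNPs.

    ``maf`` is either a fixed allele frequency in (0, 1) applied to every
    marker, or a (low, high) range from which each data set draws one
    frequency per SNP uniformly (fresh per data set).  ``rho`` is the
    exchangeable latent copula correlation in [0, 1).
    """

    p: int
    maf: float | tuple = 0.25
    rho: float = 0.0

    def __post_init__(self):
        if self.p < 1:
            raise InvalidInputError("p must be at least 1")
        if not (0.0 <= self.rho < 1.0):
            raise InvalidInputError("rho must lie in [0, 1)")
        m = self.maf
        if isinstance(m, (tuple, list)):
            lo, hi = float(m[0]), float(m[1])
            if not (0.0 < lo <= hi < 1.0):
                raise InvalidInputError("maf range must satisfy 0 < lo <= hi < 1")
            object.__setattr__(self, "maf", (lo, hi))
        else:
            if not (0.0 < float(m) < 1.0):
                raise InvalidInputError("maf must lie in (0, 1)")
            object.__setattr__(self, "maf", float(m))

    def sample_mafs(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.maf, tuple):
            return rng.uniform(self.maf[0], self.maf[1], size=self.p)
        return np.full(self.p, self.maf)


@dataclass(frozen=True)
class SimulationModel:
    """Logistic phenotype model on additive genotype codes.

    ``marginal`` maps 0-based marker column -> log-odds coefficient;
    ``interactions`` lists ((i, j), log-odds coefficient) product terms.
    """

    beta0: float
    marginal: dict = field(default_factory=dict)
    interactions: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.beta0):
            raise InvalidInputError("beta0 must be finite")
        marg = {int(k): float(v) for k, v in dict(self.marginal).items()}
        if marg and not all(np.isfinite(list(marg.values()))):
            raise InvalidInputError("marginal coefficients must be finite")
        inter = []
        seen = set()
        for (i, j), coef in self.interactions:
            i, j, coef = int(i), int(j), float(coef)
            if i == j:
                raise InvalidInputError(f"interaction pair ({i}, {j}) is degenerate")
            if not np.isfinite(coef):
                raise InvalidInputError("interaction coefficients must be finite")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise InvalidInputError(f"duplicate interaction pair {key}")
            seen.add(key)
            inter.append(((i, j), coef))
        object.__setattr__(self, "marginal", marg)
        object.__setattr__(self, "interactions", tuple(inter))

    def max_marker_index(self) -> int:
        idx = [-1]
        idx.extend(self.marginal.keys())
        idx.extend(i for (i, j), _ in self.interactions for i in (i, j))
        return max(idx)

    def linear_predictor(self, gvalues: np.ndarray) -> np.ndarray:
        g = gvalues
        eta = np.full(g.shape[0], float(self.beta0))
        for j, coef in self.marginal.items():
            eta += coef * g[:, j]
        for (i, j), coef in self.interactions:
            eta += coef * (g[:, i] * g[:, j]).astype(float)
        return eta


def _genotype_block(mafs: np.ndarray, rho: float, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """n x p additive genotype block under the exchangeable Gaussian copula."""
    p = mafs.size
    if rho > 0.0:
        z = (np.sqrt(rho) * rng.standard_normal((n, 1))
             + np.sqrt(1.0 - rho) * rng.standard_normal((n, p)))
        u = ndtr(z)
    else:
        u = rng.random((n, p))
    # Binomial(2, maf) quantile function evaluated by its two CDF thresholds
    t0 = (1.0 - mafs) ** 2          # P(G = 0)
    t1 = 1.0 - mafs ** 2            # P(G <= 1)
    return ((u > t0).view(np.int8) + (u > t1).view(np.int8))


def simulate_genotypes(model: GenotypeModel, n: int, seed=None) -> GenotypeMatrix:
    """Draw an n x p genotype matrix from the copula model.

    MAFs are drawn once for the data set (when ``model.maf`` is a range) and
    shared by all n rows.
    """
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    rng = _rng(seed)
    mafs = model.sample_mafs(rng)
    return GenotypeMatrix(values=_genotype_block(mafs, model.rho, n, rng))


def simulate_phenotype(g: GenotypeMatrix, model: SimulationModel,
                       seed=None) -> BinaryPhenotype:
    """Bernoulli phenotype with success probability expit(linear predictor).

    Raises if the draw is degenerate (all cases or all controls) since a
    one-class phenotype cannot enter any downstream test; use
    :func:`simulate_case_control` for rare-outcome designs.
    """
    if model.max_marker_index() >= g.n_markers:
        raise InvalidInputError("model references a marker index beyond p")
    rng = _rng(seed)
    prob = expit(model.linear_predictor(g.values))
    return BinaryPhenotype(values=(rng.random(g.n_subjects) < prob).astype(np.int8))


def subsample_case_control(g: GenotypeMatrix, y: BinaryPhenotype,
                           n_cases: int, n_controls: int, seed=None
                           ) -> tuple[GenotypeMatrix, BinaryPhenotype]:
    """Uniform without-replacement subsample within each phenotype class.

    The output row order is randomized (cases are not stacked first).
    """
    rng = _rng(seed)
    case_idx = np.flatnonzero(y.values == 1)
    ctrl_idx = np.flatnonzero(y.values == 0)
    if case_idx.size < n_cases or ctrl_idx.size < n_controls:
        raise InsufficientCasesError(n_cases, case_idx.size, n_controls,
                                     ctrl_idx.size, y.n, y.d / y.n)
    take = np.concatenate([rng.choice(case_idx, n_cases, replace=False),
                           rng.choice(ctrl_idx, n_controls, replace=False)])
    yvals = np.concatenate([np.ones(n_cases, np.int8),
                            np.zeros(n_controls, np.int8)])
    order = rng.permutation(take.size)
    sub = GenotypeMatrix(values=g.values[take[order]],
                         marker_ids=g.marker_ids)
    return sub, BinaryPhenotype(values=yvals[order])


def simulate_case_control(genotype_model: GenotypeModel,
                          phenotype_model: SimulationModel,
                          n_cases: int, n_controls: int, seed=None,
                          block_factor: int = 10, cap_factor: int = 100
                          ) -> tuple[GenotypeMatrix, BinaryPhenotype]:
    """Pool-then-subsample case-control draw.

    Subjects are generated in blocks of ``block_factor * (n_cases +
    n_controls)`` (one shared MAF draw for the whole data set) until both
    class quotas are met or the pool reaches ``cap_factor * n`` subjects;
    rows are then subsampled uniformly within class and shuffled.
    """
    if n_cases < 1 or n_controls < 1:
        raise InvalidInputError("need at least one case and one control")
    if phenotype_model.max_marker_index() >= genotype_model.p:
        raise InvalidInputError("model references a marker index beyond p")
    rng = _rng(seed)
    n = n_cases + n_controls
    block, cap = block_factor * n, cap_factor * n
    mafs = genotype_model.sample_mafs(rng)
    case_rows, ctrl_rows = [], []
    got_cases = got_ctrls = pool = 0
    while pool < cap and (got_cases < n_cases or got_ctrls < n_controls):
        b = min(block, cap - pool)
        gblk = _genotype_block(mafs, genotype_model.rho, b, rng)
        prob = expit(phenotype_model.linear_predictor(gblk))
        yblk = rng.random(b) < prob
        case_rows.append(gblk[yblk])
        ctrl_rows.append(gblk[~yblk])
        got_cases += int(yblk.sum())
        got_ctrls += b - int(yblk.sum())
        pool += b
    if got_cases < n_cases or got_ctrls < n_controls:
        raise InsufficientCasesError(n_cases, got_cases, n_controls, got_ctrls,
                                     pool, got_cases / pool)
    cases = np.concatenate(case_rows)
    ctrls = np.concatenate(ctrl_rows)
    keep = np.concatenate([
        cases[rng.choice(got_cases, n_cases, replace=False)],
        ctrls[rng.choice(got_ctrls, n_controls, replace=False)]])
    yvals = np.concatenate([np.ones(n_cases, np.int8),
                            np.zeros(n_controls, np.int8)])
    order = rng.permutation(n)
    return (GenotypeMatrix(values=keep[order]),
            BinaryPhenotype(values=yvals[order]))


@dataclass(frozen=True)
class DiseaseArchitecture:
    """Configurable disease risk architecture.

    ``risk_snps`` is a list of (maf, odds_ratio); ``exposures`` a list of
    (spec, odds_ratio) where spec is either a prevalence in (0, 1) for a
    binary exposure or a ("normal", mean, sd) tuple for a continuous one;
    ``null_snps`` unassociated SNPs get MAFs from ``null_maf`` (value or
    range); ``gxg`` lists ((i, j), log_odds) product terms over risk-SNP
    indices.  All components are generated mutually independently.
    """

    intercept: float
    risk_snps: tuple = ()
    exposures: tuple = ()
    null_snps: int = 0
    null_maf: float | tuple = (0.05, 0.95)
    gxg: tuple = ()

    def __post_init__(self):
        rs = tuple((float(m), float(orr)) for m, orr in self.risk_snps)
        if any(not (0 < m < 1) or orr <= 0 for m, orr in rs):
            raise InvalidInputError("risk SNPs need maf in (0,1), odds ratio > 0")
        ex = tuple(self.exposures)
        if any(orr <= 0 for _, orr in ex):
            raise InvalidInputError("exposure odds ratios must be > 0")
        gxg = tuple(((int(i), int(j)), float(b)) for (i, j), b in self.gxg)
        nr = len(rs)
        if any(i == j or not (0 <= i < nr) or not (0 <= j < nr)
               for (i, j), _ in gxg):
            raise InvalidInputError("gxg pairs must index distinct risk SNPs")
        object.__setattr__(self, "risk_snps", rs)
        object.__setattr__(self, "exposures", ex)
        object.__setattr__(self, "gxg", gxg)
        if self.null_snps < 0:
            raise InvalidInputError("null_snps must be non-negative")


def _draw_exposures(arch: DiseaseArchitecture, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    cols = []
    for spec, _ in arch.exposures:
        if isinstance(spec, (tuple, list)):
            tag, mean, sd = spec
            if tag != "normal":
                raise InvalidInputError(f"unknown exposure distribution {tag!r}")
            cols.append(rng.normal(float(mean), float(sd), size=n))
        else:
            prev = float(spec)
            if not (0.0 < prev < 1.0):
                raise InvalidInputError("exposure prevalence must be in (0, 1)")
            cols.append((rng.random(n) < prev).astype(float))
    return np.column_stack(cols) if cols else np.empty((n, 0))


def simulate_disease(arch: DiseaseArchitecture, n_cases: int, n_controls: int,
                     seed=None, block_factor: int = 10, cap_factor: int = 100
                     ) -> tuple[GenotypeMatrix, CovariateMatrix, BinaryPhenotype]:
    """Case-control data from a disease architecture.

    Risk SNPs, exposures and null SNPs are independent; the outcome follows
    the logistic model with log-odds contributions log(OR) per allele copy /
    exposure unit plus any G x G product terms.  Pool-then-subsample as in
    :func:`simulate_case_control`.
    """
    if n_cases < 1 or n_controls < 1:
        raise InvalidInputError("need at least one case and one control")
    rng = _rng(seed)
    n = n_cases + n_controls
    block, cap = block_factor * n, cap_factor * n
    nr = len(arch.risk_snps)
    risk_mafs = np.array([m for m, _ in arch.risk_snps])
    risk_logor = np.array([np.log(orr) for _, orr in arch.risk_snps])
    exp_logor = np.array([np.log(orr) for _, orr in arch.exposures])
    null_model = (GenotypeModel(p=arch.null_snps, maf=arch.null_maf)
                  if arch.null_snps else None)
    null_mafs = (null_model.sample_mafs(rng) if null_model is not None
                 else np.empty(0))

    g_case, g_ctrl, c_case, c_ctrl = [], [], [], []
    got_cases = got_ctrls = pool = 0
    while pool < cap and (got_cases < n_cases or got_ctrls < n_controls):
        b = min(block, cap - pool)
        grisk = (_genotype_block(risk_mafs, 0.0, b, rng) if nr
                 else np.empty((b, 0), np.int8))
        expo = _draw_exposures(arch, b, rng)
        gnull = (_genotype_block(null_mafs, 0.0, b, rng) if arch.null_snps
                 else np.empty((b, 0), np.int8))
        eta = arch.intercept + grisk @ risk_logor + expo @ exp_logor
        for (i, j), coef in arch.gxg:
            eta = eta + coef * (grisk[:, i] * grisk[:, j]).astype(float)
        yblk = rng.random(b) < expit(eta)
        gall = np.concatenate([grisk, gnull], axis=1)
        g_case.append(gall[yblk]); c_case.append(expo[yblk])
        g_ctrl.append(gall[~yblk]); c_ctrl.append(expo[~yblk])
        got_cases += int(yblk.sum())
        got_ctrls += b - int(yblk.sum())
        pool += b
    if got_cases < n_cases or got_ctrls < n_controls:
        raise InsufficientCasesError(n_cases, got_cases, n_controls, got_ctrls,
                                     pool, got_cases / pool)
    gc, gt = np.concatenate(g_case), np.concatenate(g_ctrl)
    cc, ct = np.concatenate(c_case), np.concatenate(c_ctrl)
    pick1 = rng.choice(got_cases, n_cases, replace=False)
    pick0 = rng.choice(got_ctrls, n_controls, replace=False)
    gkeep = np.concatenate([gc[pick1], gt[pick0]])
    ckeep = np.concatenate([cc[pick1], ct[pick0]])
    yvals = np.concatenate([np.ones(n_cases, np.int8),
                            np.zeros(n_controls, np.int8)])
    order = rng.permutation(n)
    marker_ids = tuple([f"risk{i + 1}" for i in range(nr)]
                       + [f"null{i + 1}" for i in range(arch.null_snps)])
    return (GenotypeMatrix(values=gkeep[order], marker_ids=marker_ids),
            CovariateMatrix(values=ckeep[order],
                            covariate_ids=tuple(f"e{i + 1}" for i in
                                                range(len(arch.exposures)))),
            BinaryPhenotype(values=yvals[order]))
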