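"""Simulation-study harness: type-I error and power grids, the worked
correlation-contrast example, and the Tracy-Widom calibration check.

Every cell of a grid runs ``reps`` independent replicates; each replicate
draws a case-control data set from the pool-then-subsample simulator, runs
the global epistasis test and (where requested) the two-stage benchmark,
and counts p-values below alpha.  Rates are reported with binomial
Monte-Carlo standard errors sqrt(r (1 - r) / reps).

Reproducibility: the replicate RNG stream is
``SeedSequence(master_seed, spawn_key=(cell_index, rep_index, attempt))``,
so a report is bit-identical for a fixed (grid, reps, master seed)
regardless of execution order or parallelism.  A replicate that fails for a
degenerate draw (e.g. a constant marker at small n) is regenerated with the
next attempt number up to 3 tries, then recorded as a failure and excluded
from the rate denominator.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import benchmark_global_test
from .core import global_epistasis_test, partitioned_correlations
from .exceptions import EpigetError, InvalidInputError
from .simulate import GenotypeModel, SimulationModel, simulate_case_control
from .tracy_widom import tw1_cdf, tw1_quantile

__all__ = [
    "ExperimentCell",
    "ExperimentReport",
    "type1_designs",
    "power_designs",
    "run_cells",
    "run_type1_grid",
    "run_power_grid",
    "run_table1_demo",
    "run_calibration",
    "Table1Report",
    "CalibrationReport",
]

_LOG_OR_MARGINAL = float(np.log(1.15))
_LOG_OR_INTERACTION = float(np.log(2.0))
_N_GRID = (250, 500, 1000, 2000, 4000)
_N_PAIRS = 5


@dataclass(frozen=True)
class ExperimentCell:
    """One design cell of a simulation grid with its Monte-Carlo tallies."""

    design: dict
    replicates: int
    alpha: float
    rejections_get: int
    rejections_benchmark: int
    failures: int
    seed: int
    cell_index: int

    @property
    def completed(self) -> int:
        return self.replicates - self.failures

    @property
    def rate_get(self) -> float:
        return (self.rejections_get / self.completed if self.completed
                else float("nan"))

    @property
    def rate_benchmark(self) -> float:
        return (self.rejections_benchmark / self.completed if self.completed
                else float("nan"))

    def mc_se(self, rate: float) -> float:
        if not self.completed:
            return float("nan")
        return float(np.sqrt(rate * (1.0 - rate) / self.completed))


@dataclass(frozen=True)
class ExperimentReport:
    """Machine-readable result of a grid run (the table twin)."""

    name: str
    master_seed: int
    alpha: float
    cells: tuple

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = dict(c.design)
            row.update(replicates=c.replicates, failures=c.failures,
                       rate_get=c.rate_get, se_get=c.mc_se(c.rate_get),
                       rate_benchmark=c.rate_benchmark,
                       se_benchmark=c.mc_se(c.rate_benchmark))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "name": self.name, "master_seed": self.master_seed,
            "alpha": self.alpha,
            "cells": [
                {"design": c.design, "replicates": c.replicates,
                 "failures": c.failures,
                 "rejections_get": c.rejections_get,
                 "rejections_benchmark": c.rejections_benchmark,
                 "rate_get": c.rate_get,
                 "se_get": c.mc_se(c.rate_get),
                 "rate_benchmark": c.rate_benchmark,
                 "se_benchmark": c.mc_se(c.rate_benchmark),
                 "cell_index": c.cell_index}
                for c in self.cells],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def type1_designs(p: int = 50) -> list[dict]:
    """The 20 null design cells: {marginal, no marginal} x rho {0, 0.1} x n.

    Marginal cells use beta0 = -2 with log(1.15) effects on the first ten
    SNPs; no-marginal cells use beta0 = -5 with no effects.  No interactions.
    """
    designs = []
    idx = 0
    for marginal in (True, False):
        for rho in (0.0, 0.1):
            for n in _N_GRID:
                designs.append({
                    "cell_index": idx, "model": "null",
                    "n": n, "p": p, "rho": rho,
                    "maf": (0.25, 0.75),
                    "beta0": -2.0 if marginal else -5.0,
                    "marginal": ({j: _LOG_OR_MARGINAL for j in range(10)}
                                 if marginal else {}),
                    "has_marginal": marginal,
                    "interaction_coef": None, "eligible": None,
                })
                idx += 1
    return designs


def power_designs(p: int = 50) -> list[dict]:
    """The 15 power cells: models 1-3 x n, independent SNPs (rho = 0).

    Model 1: beta0 = -3, marginal log(1.15) on SNPs 1-10, five interaction
    pairs drawn from those main-effect SNPs at log(2).
    Model 2: as model 1 but pairs drawn from the non-main-effect SNPs 11..p.
    Model 3: beta0 = -1, no marginal effects, pairs drawn from all SNPs.
    Pairs are redrawn fresh each replicate from the replicate's seed stream.
    """
    eligibility = {
        1: list(range(10)),
        2: list(range(10, p)),
        3: list(range(p)),
    }
    designs = []
    idx = 0
    for model in (1, 2, 3):
        beta0 = -3.0 if model in (1, 2) else -1.0
        marginal = ({j: _LOG_OR_MARGINAL for j in range(10)}
                    if model in (1, 2) else {})
        for n in _N_GRID:
            designs.append({
                "cell_index": idx, "model": model,
                "n": n, "p": p, "rho": 0.0,
                "maf": (0.25, 0.75),
                "beta0": beta0, "marginal": marginal,
                "has_marginal": bool(marginal),
                "interaction_coef": _LOG_OR_INTERACTION,
                "eligible": eligibility[model],
            })
            idx += 1
    return designs


def _replicate_rng(master_seed: int, cell_index: int, rep: int,
                   attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed,
                               spawn_key=(cell_index, rep, attempt)))


def _grid_replicate(design: dict, rng: np.random.Generator,
                    run_benchmark: bool) -> tuple[float, float]:
    """One simulated data set -> (GET p-value, benchmark p-value)."""
    gm = GenotypeModel(p=design["p"], maf=design["maf"], rho=design["rho"])
    interactions = ()
    if design["interaction_coef"] is not None:
        pairs = list(itertools.combinations(design["eligible"], 2))
        pick = rng.choice(len(pairs), size=_N_PAIRS, replace=False)
        interactions = tuple((pairs[t], design["interaction_coef"])
                             for t in sorted(pick))
    pm = SimulationModel(beta0=design["beta0"], marginal=design["marginal"],
                         interactions=interactions)
    n = design["n"]
    g, y = simulate_case_control(gm, pm, n // 2, n - n // 2, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_get = global_epistasis_test(g, y).pvalue
        p_bench = benchmark_global_test(g, y) if run_benchmark else np.nan
    return p_get, p_bench


def _run_cell(design: dict, reps: int, master_seed: int, alpha: float,
              run_benchmark: bool) -> ExperimentCell:
    rej_get = rej_bench = failures = 0
    ci = design["cell_index"]
    for rep in range(reps):
        for attempt in range(3):
            rng = _replicate_rng(master_seed, ci, rep, attempt)
            try:
                p_get, p_bench = _grid_replicate(design, rng, run_benchmark)
                break
            except EpigetError:
                continue
        else:
            failures += 1
            continue
        rej_get += p_get < alpha
        if run_benchmark:
            rej_bench += p_bench < alpha
    return ExperimentCell(design=design, replicates=reps, alpha=alpha,
                          rejections_get=rej_get,
                          rejections_benchmark=rej_bench,
                          failures=failures, seed=master_seed, cell_index=ci)


def run_cells(designs: list[dict], reps: int = 1000, seed: int = 0,
              alpha: float = 0.05, jobs: int = 1, run_benchmark: bool = True,
              name: str = "grid") -> ExperimentReport:
    """Run an arbitrary list of design cells (the grid workhorse)."""
    if reps < 1:
        raise InvalidInputError("reps must be at least 1")
    if jobs > 1:
        from joblib import Parallel, delayed
        cells = Parallel(n_jobs=jobs)(
            delayed(_run_cell)(d, reps, seed, alpha, run_benchmark)
            for d in designs)
    else:
        cells = [_run_cell(d, reps, seed, alpha, run_benchmark)
                 for d in designs]
    return ExperimentReport(name=name, master_seed=seed, alpha=alpha,
                            cells=tuple(cells))


def run_type1_grid(reps: int = 1000, seed: int = 0, alpha: float = 0.05,
                   jobs: int = 1) -> ExperimentReport:
    """All 20 null cells; GET should be conservative everywhere, the
    benchmark catastrophically inflated whenever rho > 0."""
    return run_cells(type1_designs(), reps=reps, seed=seed, alpha=alpha,
                     jobs=jobs, name="type1")


def run_power_grid(reps: int = 1000, seed: int = 0, alpha: float = 0.05,
                   jobs: int = 1) -> ExperimentReport:
    """All 15 power cells (models 1-3 x sample sizes)."""
    return run_cells(power_designs(), reps=reps, seed=seed, alpha=alpha,
                     jobs=jobs, name="power")


# ---------------------------------------------------------------------------
# Worked example: averaged partitioned correlations for a five-SNP panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Report:
    """Averaged within-case / within-control correlation matrices for the
    five-SNP interaction demonstration."""

    mean_s_case: np.ndarray
    mean_s_control: np.ndarray
    replicates: int
    seed: int
    interacting_pair: tuple = (0, 1)

    @property
    def gap_interacting(self) -> float:
        i, j = self.interacting_pair
        return float(abs(self.mean_s_case[i, j] - self.mean_s_control[i, j]))

    @property
    def gap_background(self) -> float:
        p = self.mean_s_case.shape[0]
        i0, j0 = self.interacting_pair
        gaps = [abs(self.mean_s_case[i, j] - self.mean_s_control[i, j])
                for i in range(p) for j in range(i + 1, p)
                if (i, j) != (i0, j0)]
        return float(np.mean(gaps))

    def summary(self) -> str:
        with np.printoptions(precision=2, suppress=True):
            return "\n".join([
                f"Averaged correlation matrices over {self.replicates} "
                "replicates (five SNPs, interaction between SNPs 1 and 2)",
                "mean S1 (cases):", str(np.round(self.mean_s_case, 2)),
                "mean S0 (controls):", str(np.round(self.mean_s_control, 2)),
                f"interacting-pair gap |S1[1,2] - S0[1,2]| = "
                f"{self.gap_interacting:.3f}",
                f"background mean gap                     = "
                f"{self.gap_background:.3f}",
            ])


def run_table1_demo(reps: int = 20, seed: int = 0) -> Table1Report:
    """Average partitioned correlation matrices over ``reps`` five-SNP data
    sets (MAF 0.25, copula rho 0.1, logistic model with marginal log(1.5)
    effects on SNPs 1-2 and a log(3) interaction between them; 500 cases and
    500 controls subsampled from a larger pool each replicate)."""
    if reps < 1:
        raise InvalidInputError("reps must be at least 1")
    gm = GenotypeModel(p=5, maf=0.25, rho=0.1)
    pm = SimulationModel(beta0=-1.0,
                         marginal={0: float(np.log(1.5)), 1: float(np.log(1.5))},
                         interactions=(((0, 1), float(np.log(3.0))),))
    acc1 = np.zeros((5, 5))
    acc0 = np.zeros((5, 5))
    for rep in range(reps):
        rng = _replicate_rng(seed, 0, rep)
        g, y = simulate_case_control(gm, pm, 500, 500, rng)
        pc = partitioned_correlations(g, y)
        acc1 += pc.s_case
        acc0 += pc.s_control
    return Table1Report(mean_s_case=acc1 / reps, mean_s_control=acc0 / reps,
                        replicates=reps, seed=seed)


# ---------------------------------------------------------------------------
# Null calibration of the statistic against the Tracy-Widom law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationReport:
    """Empirical distribution of the statistic T on null data vs F1.

    One collection has no genetic effects at all; the other adds marginal
    (but still no interaction) effects for the first five SNPs, probing
    whether marginal structure alone can distort the null.  ``tail_rate``
    is the empirical P(T > F1^{-1}(0.95)); conservative behaviour means it
    sits at or below 0.05.
    """

    t_stats: dict = field(repr=False)
    n: int = 500
    p: int = 100
    seed: int = 0

    @property
    def replicates(self) -> int:
        return len(next(iter(self.t_stats.values())))

    def tail_rate(self, collection: str, level: float = 0.95) -> float:
        t = self.t_stats[collection]
        return float(np.mean(t > tw1_quantile(level)))

    def tail_mc_se(self, level: float = 0.95) -> float:
        a = 1.0 - level
        return float(np.sqrt(a * (1.0 - a) / self.replicates))

    def ks_distance(self, collection: str) -> float:
        return float(stats.kstest(self.t_stats[collection], tw1_cdf).statistic)

    def signed_tail_deviation(self, collection: str, level: float = 0.95) -> float:
        """Empirical tail rate minus nominal; negative = conservative."""
        return self.tail_rate(collection, level) - (1.0 - level)

    def summary(self) -> str:
        lines = [f"Null calibration of T against Tracy-Widom order 1 "
                 f"(n={self.n}, p={self.p}, {self.replicates} replicates)"]
        for name in self.t_stats:
            lines.append(
                f"  {name:>10}: tail rate at F1 0.95-quantile = "
                f"{self.tail_rate(name):.4f} (nominal 0.05, MC-SE "
                f"{self.tail_mc_se():.4f}), KS = {self.ks_distance(name):.4f}")
        return "\n".join(lines)


def run_calibration(reps: int = 2500, n: int = 500, p: int = 100,
                    seed: int = 0) -> CalibrationReport:
    """Simulate two collections of null data sets (independent SNPs, MAF
    0.25, balanced case/control subsample) and record the statistic T.

    Collection "none": no genetic effects (intercept -1).  Collection
    "marginal": log(1.5) marginal effects on the first five SNPs, still no
    interactions.  Under a well-calibrated null both empirical T
    distributions match F1, with any deviation conservative.
    """
    if reps < 1:
        raise InvalidInputError("reps must be at least 1 (empty report)")
    gm = GenotypeModel(p=p, maf=0.25, rho=0.0)
    models = {
        "none": SimulationModel(beta0=-1.0),
        "marginal": SimulationModel(
            beta0=-1.0, marginal={j: float(np.log(1.5)) for j in range(5)}),
    }
    t_stats = {}
    for ci, (name, pm) in enumerate(models.items()):
        ts = np.empty(reps)
        for rep in range(reps):
            rng = _replicate_rng(seed, ci, rep)
            g, y = simulate_case_control(gm, pm, n // 2, n - n // 2, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ts[rep] = global_epistasis_test(g, y).statistic
        t_stats[name] = ts
    return CalibrationReport(t_stats=t_stats, n=n, p=p, seed=seed)
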