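"""Tracy-Widom law of order 1 (F1).

F1 is the limiting distribution of the (centered, scaled) largest eigenvalue
of real Wishart-type random matrices (the orthogonal ensemble, beta = 1) and
is the null reference distribution for the global epistasis test statistic.

The distribution is represented by a precomputed table of CDF values on a
dense grid, shipped with the package as a plain two-column text resource and
interpolated with a monotone (PCHIP) cubic.  The table itself is generated by
numerically solving the Painleve II equation

    q'' = x q + 2 q^3,   q(x) ~ Ai(x) as x -> +infinity

for the Hastings-McLeod solution as a two-point boundary value problem, and
evaluating the determinantal formula

    F1(s) = exp( -1/2 * int_s^inf [ q(x) + (x - s) q(x)^2 ] dx ).

Outside the tabulated grid the tail mass is below 1e-8 and the CDF is clamped
to 0 / 1; p-values simply saturate there.

Only order 1 is implemented; orders 2 and 4 (unitary/symplectic ensembles)
are out of scope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

from .exceptions import InvalidInputError

__all__ = [
    "TW1Table",
    "tw1_cdf",
    "tw1_sf",
    "tw1_quantile",
    "build_tw1_table",
    "default_table",
]

_TABLE_RESOURCE = "tw1_cdf.tsv"

#: Default grid used when (re)building the shipped table.
GRID_MIN = -13.0
GRID_MAX = 8.0
GRID_STEP = 0.01


@dataclass(frozen=True)
class TW1Table:
    """Tabulated F1 CDF with monotone interpolation.

    Attributes
    ----------
    grid : ndarray
        Ordered abscissae on the statistic scale.
    cdf_values : ndarray
        F1 evaluated at ``grid``; strictly increasing, in [0, 1].
    construction_method : str
        ``"painleve_ode"`` for a freshly integrated table,
        ``"shipped_table"`` when loaded from the packaged resource.
    """

    grid: np.ndarray
    cdf_values: np.ndarray
    construction_method: str = "shipped_table"
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)
    _inv: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        cdf = np.asarray(self.cdf_values, dtype=float)
        if grid.ndim != 1 or grid.shape != cdf.shape or grid.size < 4:
            raise InvalidInputError("grid and cdf_values must be matching 1-d arrays")
        if np.any(np.diff(grid) <= 0) or np.any(np.diff(cdf) <= 0):
            raise InvalidInputError("grid and cdf_values must be strictly increasing")
        if cdf[0] >= 1e-6 or cdf[-1] <= 1.0 - 1e-6:
            raise InvalidInputError("table does not cover both tails to 1e-6")
        if grid[0] > -10.0 or grid[-1] < 6.0:
            raise InvalidInputError("grid must span at least [-10, 6]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "cdf_values", cdf)
        # PCHIP preserves monotonicity of the data, so the interpolated CDF
        # cannot overshoot [0, 1] between knots.
        object.__setattr__(self, "_interp", PchipInterpolator(grid, cdf, extrapolate=False))
        object.__setattr__(self, "_inv", PchipInterpolator(cdf, grid, extrapolate=False))

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise InvalidInputError("t must be finite")
        out = self._interp(t)
        out = np.where(t < self.grid[0], 0.0, out)
        out = np.where(t > self.grid[-1], 1.0, out)
        return out if out.ndim else float(out)

    def sf(self, t):
        return 1.0 - self.cdf(t)

    def quantile(self, q):
        q = np.asarray(q, dtype=float)
        if not np.all((q > 0.0) & (q < 1.0)):
            raise InvalidInputError("q must lie strictly inside (0, 1)")
        lo, hi = self.cdf_values[0], self.cdf_values[-1]
        qc = np.clip(q, lo, hi)
        out = self._inv(qc)
        return out if out.ndim else float(out)


def _load_default() -> TW1Table:
    text = resources.files(__package__).joinpath("data", _TABLE_RESOURCE).read_text()
    data = np.loadtxt(io.StringIO(text))
    return TW1Table(grid=data[:, 0], cdf_values=data[:, 1],
                    construction_method="shipped_table")


_DEFAULT: TW1Table | None = None


def default_table() -> TW1Table:
    """The packaged F1 table (loaded lazily, cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_default()
    return _DEFAULT


def tw1_cdf(t):
    """F1(t), the Tracy-Widom order-1 CDF; clamps to 0/1 outside the table."""
    return default_table().cdf(t)


def tw1_sf(t):
    """1 - F1(t); the upper-tail probability used as the GET p-value."""
    return default_table().sf(t)


def tw1_quantile(q):
    """Inverse of F1 for q in (0, 1), accurate to ~1e-6 on the statistic scale."""
    return default_table().quantile(q)


# ----------------------------------------------------------------------------
# Table construction (developer path; exposed via `epiget tw-table`)
# ----------------------------------------------------------------------------

def _hastings_mcleod(x_left: float, x_right: float):
    """Solve Painleve II for the Hastings-McLeod solution on [x_left, x_right].

    Returns the solve_bvp solution object; q matches Ai on the right and the
    q(x) ~ sqrt(-x/2) parabolic asymptote on the left.
    """
    from scipy.integrate import solve_bvp
    from scipy.special import airy

    def rhs(x, y):
        return np.vstack([y[1], x * y[0] + 2.0 * y[0] ** 3])

    q_left = np.sqrt(-x_left / 2.0) * (1.0 + 1.0 / (8.0 * x_left ** 3))
    ai_right = airy(x_right)[0]

    def bc(ya, yb):
        return np.array([ya[0] - q_left, yb[0] - ai_right])

    x0 = np.linspace(x_left, x_right, 801)
    q0 = np.where(x0 < 0.0, np.sqrt(np.maximum(-x0, 0.0) / 2.0),
                  airy(np.minimum(x0, x_right))[0])
    sol = solve_bvp(rhs, bc, x0, np.vstack([q0, np.gradient(q0, x0)]),
                    tol=1e-12, max_nodes=200_000)
    if sol.status != 0:
        raise RuntimeError(f"Painleve II BVP failed to converge: {sol.message}")
    return sol


def build_tw1_table(grid_min: float = GRID_MIN, grid_max: float = GRID_MAX,
                    step: float = GRID_STEP) -> TW1Table:
    """Regenerate the F1 table from scratch by Painleve II integration.

    The cumulative integrals in the determinantal formula are evaluated by
    spline antiderivatives on a grid ten times finer than the output grid;
    the Airy tail beyond ``grid_max`` is added by quadrature.
    """
    from scipy.integrate import quad
    from scipy.interpolate import CubicSpline
    from scipy.special import airy

    sol = _hastings_mcleod(grid_min, grid_max)
    fine = np.arange(grid_min, grid_max + 1e-12, step / 10.0)
    q = sol.sol(fine)[0]

    def cumulative_from_right(values):
        anti = CubicSpline(fine, values).antiderivative()
        return anti(grid_max) - anti(fine)

    J = cumulative_from_right(q)              # int_s q
    R = cumulative_from_right(q * q)          # int_s q^2
    W = cumulative_from_right(fine * q * q)   # int_s x q^2
    J += quad(lambda t: airy(t)[0], grid_max, np.inf)[0]
    R += quad(lambda t: airy(t)[0] ** 2, grid_max, np.inf)[0]
    W += quad(lambda t: t * airy(t)[0] ** 2, grid_max, np.inf)[0]

    log_f1 = -0.5 * (J + W - fine * R)
    keep = slice(0, fine.size, 10)
    return TW1Table(grid=fine[keep], cdf_values=np.exp(log_f1[keep]),
                    construction_method="painleve_ode")


def write_table(table: TW1Table, path) -> None:
    """Write a table as the two-column text format the package ships."""
    with open(path, "w") as fh:
        fh.write("# Tracy-Widom order 1 CDF table: t\tF1(t)\n")
        for t, c in zip(table.grid, table.cdf_values):
            fh.write(f"{t:.2f}\t{c:.10e}\n")
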