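"""Theta-logistic state process, shape solver and backwards K-solution.

The population state follows a density-dependent surplus-production
recursion with multiplicative lognormal process error.  The shape of the
density dependence is parameterized by the depletion level at which
production peaks, mapped one-to-one to the theta-logistic exponent.
Carrying capacity is not assigned a prior directly; instead a recent
abundance is drawn and the capacity back-solved so the trajectory passes
through it (the "backwards" parameterization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ProductionParams",
    "Trajectory",
    "InfeasibleDraw",
    "START_YEAR",
    "EQUILIBRIUM_END",
    "LAST_CATCH_YEAR",
    "END_YEAR",
    "haplotype_floor",
    "shape_from_pmsy",
    "pmsy_from_shape",
    "surplus_production",
    "step_median",
    "project",
    "project_many",
    "solve_k_backwards",
    "solve_k_many",
]

START_YEAR = 1648
#: Last year of the pre-exploitation block with the median pinned at K.
EQUILIBRIUM_END = 1677
LAST_CATCH_YEAR = 1973
END_YEAR = 2030

#: Default minimum-abundance floor: unique mtDNA haplotype count times the
#: recommended 3x correction for males and non-contributing individuals.
DEFAULT_N_C = 72.0


def haplotype_floor(n_haplotypes: int = 24, correction: float = 3.0) -> float:
    """Minimum-abundance constraint implied by a haplotype count."""
    if n_haplotypes < 0 or correction < 0:
        raise ValueError("haplotype count and correction must be non-negative")
    return float(n_haplotypes * correction)


class InfeasibleDraw(RuntimeError):
    """The requested recent abundance is unreachable for any capacity."""


@dataclass
class ProductionParams:
    """Parameters of the stochastic theta-logistic production model."""

    r_max: float
    k: float
    p_msy: float = 0.6
    sigma2: float = 0.0
    n_c: float = DEFAULT_N_C
    z: float = field(init=False)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("carrying capacity must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.n_c < 0:
            raise ValueError("n_c must be non-negative")
        self.z = shape_from_pmsy(self.p_msy)


@dataclass
class Trajectory:
    """Yearly median and realized abundances with derived depletion."""

    years: np.ndarray
    n_tilde: np.ndarray
    n: np.ndarray
    k: float

    @property
    def depletion(self) -> np.ndarray:
        return self.n / self.k

    def at(self, year: int) -> float:
        """Realized abundance in a given year."""
        return float(self.n[int(year) - int(self.years[0])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "n_tilde": self.n_tilde,
                "n": self.n,
                "depletion": self.depletion,
            }
        )


def shape_from_pmsy(p_msy: float, tol: float = 1e-10) -> float:
    """Solve (1+z)^(-1/z) = p_msy for the theta-logistic exponent z > 0.

    p_msy = 0.5 is the ordinary logistic (z = 1); values must exceed the
    z -> 0 limit exp(-1).
    """
    lo_limit = float(np.exp(-1.0))
    if not lo_limit < p_msy < 1.0:
        raise ValueError(
            f"p_msy must lie in (e^-1, 1) ~ ({lo_limit:.4f}, 1), got {p_msy}"
        )

    def g(z: float) -> float:
        return -np.log1p(z) / z - np.log(p_msy)

    lo, hi = 1e-9, 1.0
    while g(hi) <= 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"no bracket found for p_msy={p_msy}")
    return float(brentq(g, lo, hi, xtol=tol))


def pmsy_from_shape(z: float) -> float:
    """Depletion at maximum production for a given exponent (inverse map)."""
    if z <= 0:
        raise ValueError("z must be positive")
    return float((1.0 + z) ** (-1.0 / z))


def surplus_production(n: float | np.ndarray, params: ProductionParams):
    """Net annual production r_max * n * (1 - (n/K)^z)."""
    n = np.asarray(n, dtype=float)
    out = params.r_max * n * (1.0 - (n / params.k) ** params.z)
    return float(out) if out.ndim == 0 else out


def step_median(n_y: float, c_eff_y: float, params: ProductionParams) -> float:
    """One deterministic state transition with the minimum-abundance floor."""
    return max(params.n_c, n_y + surplus_production(n_y, params) - c_eff_y)


def _catch_array(catches, years: np.ndarray) -> np.ndarray:
    """Effective catches aligned to the model years, zero-filled outside."""
    c = np.zeros(years.size)
    if catches is None:
        return c
    if isinstance(catches, pd.Series):
        yrs = catches.index.to_numpy()
        vals = catches.to_numpy(dtype=float)
    else:
        arr = np.asarray(catches, dtype=float)
        if arr.size != years.size:
            raise ValueError("raw catch array must span the model years")
        return arr
    inside = (yrs >= years[0]) & (yrs <= years[-1])
    c[yrs[inside] - years[0]] = vals[inside]
    if np.any(c[years > LAST_CATCH_YEAR] != 0):
        raise ValueError(f"catches must be zero after {LAST_CATCH_YEAR}")
    return c


def project(
    params: ProductionParams,
    catches=None,
    deviates: np.ndarray | None = None,
    start: int = START_YEAR,
    end: int = END_YEAR,
) -> Trajectory:
    """Run the state process over ``start..end``.

    The median abundance is pinned at K through the pre-exploitation block
    (start..1677) and follows the floored production recursion afterwards;
    the realized abundance multiplies each median by exp(sigma * eps_y).
    Passing ``deviates=None`` (or zeros) gives the deterministic skeleton.
    """
    years = np.arange(start, end + 1)
    eps = np.zeros(years.size) if deviates is None else np.asarray(deviates, float)
    if eps.size != years.size:
        raise ValueError("deviate vector must span start..end")
    c = _catch_array(catches, years)
    n_mat = project_many(
        k=np.array([params.k]),
        r_max=np.array([params.r_max]),
        z=np.array([params.z]),
        sigma=np.array([np.sqrt(params.sigma2)]),
        n_c=np.array([params.n_c]),
        c_eff=c[None, :],
        eps=eps[None, :],
        years=years,
        return_median=True,
    )
    n, n_tilde = n_mat
    traj = Trajectory(years=years, n_tilde=n_tilde[0], n=n[0], k=params.k)
    if not np.all(np.isfinite(traj.n)):
        bad = years[~np.isfinite(traj.n)][0]
        raise FloatingPointError(f"non-finite abundance at year {bad}")
    return traj


def project_many(
    k: np.ndarray,
    r_max: np.ndarray,
    z: np.ndarray,
    sigma: np.ndarray,
    n_c: np.ndarray,
    c_eff: np.ndarray,
    eps: np.ndarray,
    years: np.ndarray,
    return_median: bool = False,
    stop_index: int | None = None,
):
    """Vectorized projection of many parameter draws at once.

    All parameter arrays have shape (ndraw,), ``c_eff`` and ``eps`` shape
    (ndraw, nyears).  Returns realized abundances (ndraw, nyears); with
    ``return_median`` also the medians.  ``stop_index`` truncates the
    recursion (used by the bisection solver, which only needs the state up
    to the anchor year).
    """
    ndraw, nyears = eps.shape
    last = nyears - 1 if stop_index is None else stop_index
    eq_end = min(EQUILIBRIUM_END - int(years[0]), last)
    noise = np.exp(sigma[:, None] * eps)
    n = np.empty((ndraw, last + 1))
    n_tilde = np.empty((ndraw, last + 1)) if return_median else None

    n[:, : eq_end + 1] = k[:, None] * noise[:, : eq_end + 1]
    if return_median:
        n_tilde[:, : eq_end + 1] = k[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(eq_end, last):
            cur = n[:, i]
            ratio = cur / k
            growth = cur + r_max * cur * (1.0 - ratio**z) - c_eff[:, i]
            med = np.maximum(n_c, growth)
            if return_median:
                n_tilde[:, i + 1] = med
            n[:, i + 1] = med * noise[:, i + 1]
    if return_median:
        return n, n_tilde
    return n


def solve_k_many(
    r_max: np.ndarray,
    z: np.ndarray,
    sigma: np.ndarray,
    n_c: np.ndarray,
    c_eff: np.ndarray,
    eps: np.ndarray,
    n_recent: np.ndarray,
    anchor_index: int,
    years: np.ndarray,
    k_hi: float = 1e7,
    rel_tol: float = 1e-8,
):
    """Bisect K per draw so the realized abundance at the anchor year equals
    the drawn recent abundance, holding the deviate vector fixed.

    Returns (k, feasible) where infeasible draws (anchor abundance below
    target even at the upper bracket) get k = nan and feasible = False.
    """
    ndraw = eps.shape[0]

    def anchor_n(kv: np.ndarray) -> np.ndarray:
        n = project_many(
            kv, r_max, z, sigma, n_c, c_eff, eps, years, stop_index=anchor_index
        )
        return n[:, anchor_index]

    lo = np.maximum(n_c, 1.0)
    hi = np.full(ndraw, k_hi)
    feasible = anchor_n(hi) >= n_recent
    # terminal abundance already above target at the smallest admissible K:
    # clamp to the lower bracket (only possible with extreme noise draws)
    n_iter = int(np.ceil(np.log2(k_hi / rel_tol / 1.0))) + 10
    for _ in range(min(n_iter, 80)):
        mid = 0.5 * (lo + hi)
        too_low = anchor_n(mid) < n_recent
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.all((hi - lo) <= rel_tol * hi):
            break
    k = 0.5 * (lo + hi)
    k = np.where(feasible, k, np.nan)
    return k, feasible


def solve_k_backwards(
    r_max: float,
    p_msy: float,
    sigma2: float,
    n_c: float,
    n_recent: float,
    catches=None,
    deviates: np.ndarray | None = None,
    anchor_year: int = 2019,
    start: int = START_YEAR,
    end: int = END_YEAR,
) -> tuple[float, Trajectory]:
    """Back-solve carrying capacity for a single draw and attach the
    trajectory projected with it.

    Raises :class:`InfeasibleDraw` when no capacity in the bracket reaches
    the requested recent abundance.
    """
    years = np.arange(start, end + 1)
    eps = np.zeros(years.size) if deviates is None else np.asarray(deviates, float)
    c = _catch_array(catches, years)
    zshape = shape_from_pmsy(p_msy)
    anchor_index = int(anchor_year) - start
    k, feasible = solve_k_many(
        r_max=np.array([r_max]),
        z=np.array([zshape]),
        sigma=np.array([np.sqrt(sigma2)]),
        n_c=np.array([n_c]),
        c_eff=c[None, :],
        eps=eps[None, :],
        n_recent=np.array([n_recent]),
        anchor_index=anchor_index,
        years=years,
    )
    if not feasible[0]:
        raise InfeasibleDraw(
            f"n_recent={n_recent} unreachable at anchor year {anchor_year}"
        )
    params = ProductionParams(
        r_max=r_max, k=float(k[0]), p_msy=p_msy, sigma2=sigma2, n_c=n_c
    )
    traj = project(params, catches=c, deviates=eps, start=start, end=end)
    return float(k[0]), traj
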