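"""Seasonal daily-count model and the accumulated-arrivals index.

Daily whale counts in the monitored strip are modelled with a
negative-binomial regression (log link) on year, day-of-year and
day-of-year squared.  Because individual whales stay only part of the
season, occupancy cannot simply be summed over days; the per-year total
number of arrivals is recovered by deconvolving the predicted occupancy
curve with the residence-time distribution:

    A_x = W_x + sum_{k=1..x} p_k A_{x-k},   A_0 = 0

where p_k is the probability that a whale remains exactly k days.
Uncertainty in the per-year index is propagated by resampling regression
coefficients from their asymptotic normal distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import norm

import statsmodels.formula.api as smf

__all__ = [
    "DailyCountModel",
    "ResidenceDistribution",
    "AccumulatedIndex",
    "DailyModelFitError",
    "fit_daily_model",
    "discretize_residence",
    "accumulate",
    "accumulation_operator",
    "index_covariance",
    "read_flight_counts",
    "write_index",
]

#: First day-of-year on which whales may be present; occupancy is forced
#: to zero for days 1..SEASON_START-1.
SEASON_START = 100
#: Last day with possible new arrivals; the index value is A at this day.
HORIZON = 320


class DailyModelFitError(RuntimeError):
    """Raised when the negative-binomial fit does not converge."""


@dataclass
class DailyCountModel:
    """Fitted daily-count model (negative binomial, log link).

    Coefficients are stored in an internally standardized day scale
    (``z = (day - day_center) / day_scale``) for numerical stability; all
    predictions go through :meth:`predict_daily`, which undoes the mapping.
    """

    params: pd.Series
    cov: pd.DataFrame
    alpha: float
    years: np.ndarray
    day_center: float
    day_scale: float
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def design_matrix(self, year: int, days: np.ndarray) -> np.ndarray:
        """Design row-block matching ``params`` for one year over ``days``."""
        days = np.asarray(days, dtype=float)
        z = (days - self.day_center) / self.day_scale
        X = np.zeros((days.size, len(self.params)))
        names = list(self.params.index)
        X[:, names.index("Intercept")] = 1.0
        dummy = f"C(year)[T.{int(year)}]"
        if dummy in names:
            X[:, names.index(dummy)] = 1.0
        elif int(year) != int(self.years[0]):
            raise ValueError(f"year {year} not in fitted model")
        X[:, names.index("day_z")] = z
        X[:, names.index("day_z2")] = z * z
        return X

    def predict_daily(
        self, year: int, days: np.ndarray, params: np.ndarray | None = None
    ) -> np.ndarray:
        """Predicted mean count per day, clamped to 0 before the season."""
        days = np.asarray(days)
        beta = self.params.to_numpy() if params is None else np.asarray(params)
        eta = self.design_matrix(year, days) @ beta
        w = np.exp(eta)
        return np.where(days < SEASON_START, 0.0, w)


@dataclass(frozen=True)
class ResidenceDistribution:
    """Discretized residence-time law: p[k-1] = P(stay exactly k days)."""

    mu: float
    sd: float
    p: np.ndarray

    @property
    def horizon(self) -> int:
        return self.p.size


@dataclass
class AccumulatedIndex:
    """Per-year arrivals index with log-scale covariance."""

    years: np.ndarray
    a: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.a = np.asarray(self.a, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.years.size
        if self.a.shape != (n,) or self.sigma.shape != (n, n):
            raise ValueError("index dimensions do not agree")
        if np.any(self.a <= 0):
            raise ValueError("index values must be positive")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")


def fit_daily_model(counts: pd.DataFrame, seed: int = 0) -> DailyCountModel:
    """Fit the negative-binomial daily-count regression.

    ``counts`` needs columns ``year``, ``julian_day``, ``count``.  Year
    enters as a categorical factor, day-of-year as a standardized linear
    plus quadratic term.  Returns the MLE with asymptotic coefficient
    covariance (mean-model block only; dispersion uncertainty excluded).
    """
    df = counts[["year", "julian_day", "count"]].copy()
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(df["count"], np.round(df["count"])):
        raise ValueError("counts must be integers")
    per_year = df.groupby("year")["julian_day"].nunique()
    if (per_year < 2).any():
        raise ValueError("need at least 2 distinct survey days per year")

    center = float(df["julian_day"].mean())
    scale = float(df["julian_day"].std() or 1.0)
    df["day_z"] = (df["julian_day"] - center) / scale
    df["day_z2"] = df["day_z"] ** 2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.negativebinomial(
                "count ~ C(year) + day_z + day_z2", data=df
            ).fit(disp=0, maxiter=500)
        except Exception as exc:  # pragma: no cover - optimizer internals
            raise DailyModelFitError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False):
        raise DailyModelFitError(
            f"negative-binomial fit did not converge: {fit.mle_retvals}"
        )

    params = fit.params.drop("alpha")
    cov = fit.cov_params().drop("alpha", axis=0).drop("alpha", axis=1)
    return DailyCountModel(
        params=params,
        cov=cov,
        alpha=float(fit.params["alpha"]),
        years=np.sort(df["year"].unique()),
        day_center=center,
        day_scale=scale,
        meta={"loglike": float(fit.llf), "nobs": int(fit.nobs), "seed": seed},
    )


def discretize_residence(
    mu: float, sd: float, horizon: int = HORIZON
) -> ResidenceDistribution:
    """Discretize a normal residence-time law onto integer days 1..horizon.

    Uses continuity-corrected CDF differences renormalized to sum to one.
    ``sd = 0`` degenerates to a point mass at ``round(mu)``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    k = np.arange(1, horizon + 1)
    if sd == 0:
        p = np.zeros(horizon)
        j = int(np.clip(round(mu), 1, horizon))
        p[j - 1] = 1.0
        return ResidenceDistribution(mu=mu, sd=sd, p=p)
    if horizon < mu - 6 * sd:
        warnings.warn(
            f"horizon {horizon} truncates nearly all residence mass "
            f"(mu={mu}, sd={sd})",
            stacklevel=2,
        )
    p = norm.cdf((k + 0.5 - mu) / sd) - norm.cdf((k - 0.5 - mu) / sd)
    total = p.sum()
    if total <= 0:
        raise ValueError("no residence mass within horizon")
    return ResidenceDistribution(mu=mu, sd=sd, p=p / total)


def accumulate(W: np.ndarray, p: ResidenceDistribution) -> tuple[np.ndarray, float]:
    """Run the accumulation recursion for one season.

    ``W[t-1]`` is the occupancy on day t (t = 1..horizon).  Returns the
    per-day accumulated arrivals A (same indexing) and the season total
    A at the final day.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("occupancy W must be non-negative")
    n = W.size
    pk = p.p
    A = np.zeros(n)
    for x in range(n):
        # A_x = W_x + sum_{k=1..x} p_k A_{x-k}; array index is day-1
        kmax = min(x, pk.size)
        conv = float(pk[:kmax] @ A[x - 1 :: -1][:kmax]) if kmax else 0.0
        A[x] = W[x] + conv
    return A, float(A[-1])


def accumulation_operator(p: ResidenceDistribution, n: int = HORIZON) -> np.ndarray:
    """Matrix M with A = M @ W, i.e. the inverse of (I - P) where P is the
    strictly-lower-triangular Toeplitz convolution with p.

    Used to batch the recursion over many simulated occupancy curves.
    """
    T = np.eye(n)
    for k in range(1, n):
        if k <= p.p.size:
            idx = np.arange(k, n)
            T[idx, idx - k] = -p.p[k - 1]
    return scipy.linalg.solve_triangular(T, np.eye(n), lower=True)


def index_covariance(
    model: DailyCountModel,
    p: ResidenceDistribution,
    n_rep: int = 2000,
    seed: int = 0,
) -> AccumulatedIndex:
    """Point index A_y per survey year plus simulated log-scale covariance.

    Coefficient vectors are drawn from the fit's asymptotic multivariate
    normal; for each draw and year the occupancy curve is rebuilt and the
    accumulation recursion applied.  The covariance of log A across draws
    is returned together with the point index from the point coefficients.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be at least 100")
    cov = model.cov.to_numpy()
    if not np.all(np.isfinite(cov)):
        raise ValueError("coefficient covariance contains non-finite values")
    eigvals = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise ValueError("coefficient covariance is not positive semi-definite")

    days = np.arange(1, HORIZON + 1)
    m_last = accumulation_operator(p, HORIZON)[-1, :]

    a_point = np.empty(model.years.size)
    for i, y in enumerate(model.years):
        a_point[i] = m_last @ model.predict_daily(y, days)

    rng = np.random.default_rng(seed)
    betas = rng.multivariate_normal(
        model.params.to_numpy(), cov, size=n_rep, method="svd"
    )
    log_a = np.empty((n_rep, model.years.size))
    clamp = days < SEASON_START
    for i, y in enumerate(model.years):
        X = model.design_matrix(int(y), days)
        w = np.exp(betas @ X.T)  # (n_rep, ndays)
        w[:, clamp] = 0.0
        log_a[:, i] = np.log(w @ m_last)
    sigma = np.cov(log_a, rowvar=False)
    sigma = np.atleast_2d((sigma + sigma.T) / 2)
    return AccumulatedIndex(
        years=model.years,
        a=a_point,
        sigma=sigma,
        meta={"seed": seed, "n_rep": n_rep},
    )


def read_flight_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"year", "julian_day", "count"}
    if not expected.issubset(df.columns):
        raise ValueError(f"flight counts CSV must have columns {sorted(expected)}")
    return df


def write_index(index: AccumulatedIndex, out_prefix: str) -> None:
    """Write `year,A` CSV, the sigma matrix CSV and a JSON metadata sidecar."""
    pd.DataFrame({"year": index.years, "A": index.a}).to_csv(
        f"{out_prefix}_index.csv", index=False
    )
    pd.DataFrame(index.sigma, index=index.years, columns=index.years).to_csv(
        f"{out_prefix}_sigma.csv"
    )
    with open(f"{out_prefix}_meta.json", "w") as fh:
        json.dump(index.meta, fh, indent=2)
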