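"""Priors, likelihood components and the sampling-importance-resampling
posterior engine.

The sampler draws every parameter from its prior, fixes a per-draw vector
of process deviates, back-solves carrying capacity so the trajectory hits
the drawn recent abundance, and weights each draw by the product of the
relative-index likelihood (with catchability integrated out analytically)
and the absolute-abundance likelihood.  Resampling with replacement
proportional to weight gives the posterior sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, norm

from . import production_model as pm
from .catch_series import slr_vector

__all__ = [
    "Uniform",
    "Normal",
    "LogNormal",
    "TruncatedLogNormal",
    "Fixed",
    "PriorSet",
    "DataBundle",
    "Posterior",
    "base_priors",
    "distribution_from_dict",
    "analytic_q",
    "loglik_index",
    "loglik_absolute",
    "sample_priors",
    "importance_resample",
    "run_sir",
    "posterior_q_draws",
    "post_model_pre_data",
    "ABSOLUTE_ESTIMATE",
    "ABSOLUTE_SE",
    "ABSOLUTE_YEAR",
]

ABSOLUTE_ESTIMATE = 4245.0
ABSOLUTE_SE = 245.0
ABSOLUTE_YEAR = 2010


# ---------------------------------------------------------------------------
# distribution specs

@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)


@dataclass(frozen=True)
class LogNormal:
    """meanlog/sdlog parameterization (log of the draw is normal)."""

    meanlog: float
    sdlog: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(self.meanlog, self.sdlog, size=n))


@dataclass(frozen=True)
class TruncatedLogNormal:
    meanlog: float
    sdlog: float
    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            cand = np.exp(rng.normal(self.meanlog, self.sdlog, size=max(n, 1000)))
            cand = cand[(cand >= self.low) & (cand <= self.high)]
            take = min(cand.size, n - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
        return out


@dataclass(frozen=True)
class Fixed:
    value: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.value)


_DIST_TAGS = {
    "uniform": Uniform,
    "normal": Normal,
    "lognormal": LogNormal,
    "truncated-lognormal": TruncatedLogNormal,
    "fixed": Fixed,
}


def distribution_from_dict(spec: dict):
    """Build a distribution from a tagged dict, e.g.
    ``{"dist": "uniform", "low": 0, "high": 0.11}``."""
    spec = dict(spec)
    tag = spec.pop("dist", None)
    if tag not in _DIST_TAGS:
        raise ValueError(f"unknown distribution tag {tag!r}")
    try:
        return _DIST_TAGS[tag](**spec)
    except TypeError as exc:
        raise ValueError(f"malformed {tag} spec {spec}: {exc}") from exc


@dataclass(frozen=True)
class PriorSet:
    """Joint prior for the estimable parameters (base case defaults)."""

    r_max: object = Uniform(0.0, 0.11)
    n_recent: object = Uniform(100.0, 10_000.0)
    p_msy: object = Uniform(0.5, 0.8)
    sigma2: object = Uniform(6.5e-5, 6.5e-4)
    slr1: object = Normal(1.6, 0.04)
    slr2: object = Normal(1.09, 0.04)
    pi: object = Uniform(0.0, 1.0)
    tau2: object = Fixed(0.0)
    beta: object = Fixed(0.0)

    PARAMS = ("r_max", "n_recent", "p_msy", "sigma2", "slr1", "slr2", "pi", "tau2", "beta")

    def with_overrides(self, **overrides) -> "PriorSet":
        unknown = set(overrides) - set(self.PARAMS)
        if unknown:
            raise ValueError(f"unknown prior keys {sorted(unknown)}")
        return replace(self, **overrides)


def base_priors() -> PriorSet:
    return PriorSet()


def sample_priors(spec: PriorSet, n_draws: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """i.i.d. joint prior draws, one column per parameter."""
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return pd.DataFrame(
        {name: getattr(spec, name).sample(n_draws, rng) for name in PriorSet.PARAMS}
    )


# ---------------------------------------------------------------------------
# likelihood components

def _check_sigma(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("sigma must be symmetric")
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() <= 0:
        raise ValueError("sigma must be positive definite")
    return sigma


def analytic_q(A: np.ndarray, N: np.ndarray, sigma: np.ndarray, beta: float = 0.0) -> float:
    """Catchability maximizing the multivariate lognormal index likelihood.

    The GLS estimate of log q: (1' Sigma^-1 r) / (1' Sigma^-1 1) with
    residuals r = log(A / N^(1+beta)), exponentiated.
    """
    A = np.asarray(A, float)
    N = np.asarray(N, float)
    if np.any(A <= 0) or np.any(N <= 0):
        raise ValueError("A and N must be positive")
    sigma = _check_sigma(sigma)
    sinv = np.linalg.inv(sigma)
    r = np.log(A) - (1.0 + beta) * np.log(N)
    ones = np.ones_like(r)
    return float(np.exp((ones @ sinv @ r) / (ones @ sinv @ ones)))


def loglik_index(
    A: np.ndarray,
    N: np.ndarray,
    sigma: np.ndarray,
    beta: float = 0.0,
    tau2: float = 0.0,
) -> float:
    """Multivariate normal log-density of log A around log(q_hat N^(1+beta)).

    ``tau2`` adds white observation variance to the diagonal (time-varying
    catchability scenario).
    """
    sigma = _check_sigma(np.asarray(sigma, float) + tau2 * np.eye(len(A)))
    qhat = analytic_q(A, N, sigma, beta)
    mean = np.log(qhat) + (1.0 + beta) * np.log(np.asarray(N, float))
    return float(multivariate_normal(mean=mean, cov=sigma).logpdf(np.log(A)))


def absolute_obs_variance(estimate: float = ABSOLUTE_ESTIMATE, se: float = ABSOLUTE_SE) -> float:
    """Lognormal variance implied by the survey CV: log(1 + (se/est)^2)."""
    return float(np.log1p((se / estimate) ** 2))


def loglik_absolute(
    n_2010: float, estimate: float = ABSOLUTE_ESTIMATE, se: float = ABSOLUTE_SE
) -> float:
    """Lognormal log-density of the absolute estimate centred on log n."""
    if n_2010 <= 0:
        raise ValueError("abundance must be positive")
    tau0 = np.sqrt(absolute_obs_variance(estimate, se))
    return float(norm(loc=np.log(n_2010), scale=tau0).logpdf(np.log(estimate)))


# ---------------------------------------------------------------------------
# data bundle and posterior containers

@dataclass
class DataBundle:
    """Everything the likelihood needs: catch bounds, index, absolute datum."""

    catch_bounds: pd.DataFrame  # year, c_min, c_max
    index_years: np.ndarray
    index_a: np.ndarray
    index_sigma: np.ndarray
    absolute_estimate: float = ABSOLUTE_ESTIMATE
    absolute_se: float = ABSOLUTE_SE
    absolute_year: int = ABSOLUTE_YEAR

    def __post_init__(self) -> None:
        self.index_years = np.asarray(self.index_years, int)
        self.index_a = np.asarray(self.index_a, float)
        self.index_sigma = _check_sigma(self.index_sigma)


@dataclass
class Posterior:
    """Resampled SIR posterior with per-draw derived quantities."""

    draws: pd.DataFrame
    trajectories: np.ndarray  # (n_out, nyears) realized abundances
    years: np.ndarray
    log_marginal: float
    n_unique: int
    n_importance: int
    feasible_fraction: float
    scenario_id: str = "base"
    meta: dict = field(default_factory=dict)

    def summary_row(self, col: str) -> dict:
        x = self.draws[col].to_numpy()
        qs = np.percentile(x, [2.5, 25, 50, 75, 97.5])
        return {
            "mean": float(np.mean(x)),
            "median": float(qs[2]),
            "2.5%": float(qs[0]),
            "25%": float(qs[1]),
            "75%": float(qs[3]),
            "97.5%": float(qs[4]),
        }


# ---------------------------------------------------------------------------
# SIR engine

def importance_resample(
    log_weights: np.ndarray, n_out: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices resampled with replacement proportional to exp(log_weights).

    Draws with -inf log-weight are never selected.  Invariant to adding a
    constant to all log-weights.
    """
    lw = np.asarray(log_weights, float)
    finite = np.isfinite(lw)
    if not finite.any():
        raise RuntimeError("all importance weights are zero")
    w = np.zeros(lw.size)
    w[finite] = np.exp(lw[finite] - lw[finite].max())
    return rng.choice(lw.size, size=n_out, replace=True, p=w / w.sum())


def _effective_catch_matrix(
    bounds: pd.DataFrame, pi: np.ndarray, slr1: np.ndarray, slr2: np.ndarray, years: np.ndarray
) -> np.ndarray:
    """Per-draw effective removals over the full model year range."""
    c_min = np.zeros(years.size)
    c_max = np.zeros(years.size)
    yrs = bounds["year"].to_numpy()
    inside = (yrs >= years[0]) & (yrs <= pm.LAST_CATCH_YEAR)
    pos = yrs[inside] - years[0]
    c_min[pos] = bounds["c_min"].to_numpy()[inside]
    c_max[pos] = bounds["c_max"].to_numpy()[inside]
    landed = c_min[None, :] + pi[:, None] * (c_max - c_min)[None, :]
    return landed * slr_vector(years, slr1, slr2)


def _index_loglik_vectorized(
    logA: np.ndarray,
    logN: np.ndarray,
    sigma: np.ndarray,
    beta: np.ndarray,
    tau2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood and analytic log-catchability for many draws at once.

    ``logN`` has shape (ndraw, nyears); ``beta``/``tau2`` shape (ndraw,).
    Per-draw covariance is sigma + tau2*I, handled through the
    eigendecomposition of sigma so no per-draw matrix solves are needed.
    """
    eigval, Q = np.linalg.eigh(sigma)
    if eigval.min() <= 0:
        raise ValueError("sigma must be positive definite")
    lam = eigval[None, :] + tau2[:, None]  # (ndraw, ny)
    if np.any(lam <= 0):
        raise ValueError("negative observation variance")
    r = logA[None, :] - (1.0 + beta)[:, None] * logN  # residuals before q
    r_t = r @ Q  # rotate into eigenbasis
    ones_t = (np.ones(sigma.shape[0]) @ Q)[None, :]
    denom = (ones_t**2 / lam).sum(axis=1)
    logq = (ones_t * r_t / lam).sum(axis=1) / denom
    resid_t = r_t - logq[:, None] * ones_t
    quad = (resid_t**2 / lam).sum(axis=1)
    logdet = np.log(lam).sum(axis=1)
    ny = sigma.shape[0]
    ll = -0.5 * (quad + logdet + ny * np.log(2.0 * np.pi))
    return ll, logq


def _run_draws(
    spec: PriorSet,
    data: DataBundle,
    n_importance: int,
    rng: np.random.Generator,
    anchor_year: int,
    n_c: float,
    use_likelihood: bool,
):
    """Shared machinery: prior draws, backwards solve, per-draw log-weights."""
    years = np.arange(pm.START_YEAR, pm.END_YEAR + 1)
    draws = sample_priors(spec, n_importance, rng)
    eps = rng.standard_normal((n_importance, years.size))
    c_eff = _effective_catch_matrix(
        data.catch_bounds,
        draws["pi"].to_numpy(),
        draws["slr1"].to_numpy(),
        draws["slr2"].to_numpy(),
        years,
    )
    z = np.array([pm.shape_from_pmsy(p) for p in draws["p_msy"]])
    sigma_proc = np.sqrt(draws["sigma2"].to_numpy())
    anchor_index = anchor_year - pm.START_YEAR
    k, feasible = pm.solve_k_many(
        r_max=draws["r_max"].to_numpy(),
        z=z,
        sigma=sigma_proc,
        n_c=np.full(n_importance, n_c),
        c_eff=c_eff,
        eps=eps,
        n_recent=draws["n_recent"].to_numpy(),
        anchor_index=anchor_index,
        years=years,
    )
    k_safe = np.where(feasible, k, 1.0)
    n = pm.project_many(
        k_safe,
        draws["r_max"].to_numpy(),
        z,
        sigma_proc,
        np.full(n_importance, n_c),
        c_eff,
        eps,
        years,
    )
    draws["z"] = z
    draws["k"] = k

    loglik = np.zeros(n_importance)
    logq = np.full(n_importance, np.nan)
    if use_likelihood:
        survey_idx = data.index_years - pm.START_YEAR
        with np.errstate(divide="ignore", invalid="ignore"):
            logN = np.log(n[:, survey_idx])
        bad = ~np.all(np.isfinite(logN), axis=1)
        logN[bad] = 0.0  # placeholder; these draws get -inf weight below
        feasible = feasible & ~bad
        ll_idx, logq = _index_loglik_vectorized(
            np.log(data.index_a),
            logN,
            data.index_sigma,
            draws["beta"].to_numpy(),
            draws["tau2"].to_numpy(),
        )
        tau0 = np.sqrt(absolute_obs_variance(data.absolute_estimate, data.absolute_se))
        n_abs = n[:, data.absolute_year - pm.START_YEAR]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_abs = norm.logpdf(np.log(data.absolute_estimate), np.log(n_abs), tau0)
        loglik = ll_idx + ll_abs
    loglik = np.where(feasible & np.isfinite(loglik), loglik, -np.inf)
    draws["loglik"] = loglik
    draws["log_q_hat"] = logq
    return draws, n, years, feasible


def _derive_columns(draws: pd.DataFrame, n: np.ndarray, years: np.ndarray) -> pd.DataFrame:
    """Attach trajectory-derived quantities (per draw)."""
    lo = pm.EQUILIBRIUM_END + 1 - pm.START_YEAR
    hi = 2019 - pm.START_YEAR
    n_min = n[:, lo : hi + 1].min(axis=1)
    out = draws.copy()
    out["q_hat"] = np.exp(draws["log_q_hat"])
    out["n_min"] = n_min
    out["n_2021"] = n[:, 2021 - pm.START_YEAR]
    out["n_2030"] = n[:, 2030 - pm.START_YEAR]
    out["p_min"] = n_min / draws["k"]
    out["p_2021"] = out["n_2021"] / draws["k"]
    out["p_2030"] = out["n_2030"] / draws["k"]
    return out


def run_sir(
    spec: PriorSet,
    data: DataBundle,
    n_importance: int = 200_000,
    n_out: int = 20_000,
    seed: int = 0,
    anchor_year: int = 2019,
    n_c: float = pm.DEFAULT_N_C,
    scenario_id: str = "base",
) -> Posterior:
    """Sampling-importance-resampling posterior for one model configuration.

    Importance draws come from the joint prior (with a fixed process-deviate
    vector each); weights are exp(index + absolute log-likelihood), zero for
    draws whose backwards solve is infeasible.  ``n_out`` draws are then
    resampled with replacement.  The log marginal likelihood (log mean raw
    weight) is recorded for Bayes-factor comparison.
    """
    rng = np.random.default_rng(seed)
    draws, n, years, feasible = _run_draws(
        spec, data, n_importance, rng, anchor_year, n_c, use_likelihood=True
    )
    loglik = draws["loglik"].to_numpy()
    idx = importance_resample(loglik, n_out, rng)
    log_marginal = float(logsumexp(loglik[np.isfinite(loglik)]) - np.log(n_importance))
    resampled = _derive_columns(draws.iloc[idx].reset_index(drop=True), n[idx], years)
    return Posterior(
        draws=resampled,
        trajectories=n[idx],
        years=years,
        log_marginal=log_marginal,
        n_unique=int(np.unique(idx).size),
        n_importance=n_importance,
        feasible_fraction=float(np.mean(feasible)),
        scenario_id=scenario_id,
        meta={"seed": seed, "anchor_year": anchor_year, "n_c": n_c, "n_out": n_out},
    )


def post_model_pre_data(
    spec: PriorSet,
    catch_bounds: pd.DataFrame,
    n_draws: int = 20_000,
    seed: int = 0,
    anchor_year: int = 2019,
    n_c: float = pm.DEFAULT_N_C,
) -> Posterior:
    """Distribution induced by the priors and catch feasibility alone.

    Every feasible backwards solve gets weight one; the abundance data do
    not enter.  With zero catches this is exactly the prior.
    """
    rng = np.random.default_rng(seed)
    dummy = DataBundle(
        catch_bounds=catch_bounds,
        index_years=np.array([2010]),
        index_a=np.array([1.0]),
        index_sigma=np.array([[1.0]]),
    )
    draws, n, years, feasible = _run_draws(
        spec, dummy, n_draws, rng, anchor_year, n_c, use_likelihood=False
    )
    lw = np.where(feasible, 0.0, -np.inf)
    idx = importance_resample(lw, n_draws, rng)
    resampled = _derive_columns(draws.iloc[idx].reset_index(drop=True), n[idx], years)
    return Posterior(
        draws=resampled,
        trajectories=n[idx],
        years=years,
        log_marginal=float(np.log(np.mean(feasible))),
        n_unique=int(np.unique(idx).size),
        n_importance=n_draws,
        feasible_fraction=float(np.mean(feasible)),
        scenario_id="post-model-pre-data",
        meta={"seed": seed, "anchor_year": anchor_year, "n_c": n_c},
    )


def posterior_q_draws(
    posterior: Posterior,
    A: np.ndarray,
    sigma: np.ndarray,
    beta_col: str = "beta",
    seed: int = 0,
) -> np.ndarray:
    """Sample catchability per posterior draw.

    With the improper uniform prior on log q, the conditional posterior of
    log q given a draw's trajectory is normal with mean log q_hat and
    variance 1 / (1' Sigma^-1 1); a zero-variance sigma limit returns
    q_hat exactly.
    """
    if len(posterior.draws) == 0:
        raise ValueError("posterior is empty")
    sigma = np.asarray(sigma, float)
    sinv = np.linalg.inv(sigma)
    var = 1.0 / float(np.ones(len(A)) @ sinv @ np.ones(len(A)))
    rng = np.random.default_rng(seed)
    log_qhat = posterior.draws["log_q_hat"].to_numpy()
    tau2 = posterior.draws["tau2"].to_numpy() if "tau2" in posterior.draws else 0.0
    if np.any(np.asarray(tau2) > 0):
        # per-draw variance when extra diagonal observation error is present
        var_d = np.empty(log_qhat.size)
        for i, t2 in enumerate(np.atleast_1d(tau2)):
            sinv_i = np.linalg.inv(sigma + t2 * np.eye(len(A)))
            var_d[i] = 1.0 / float(np.ones(len(A)) @ sinv_i @ np.ones(len(A)))
        var = var_d
    return np.exp(log_qhat + np.sqrt(var) * rng.standard_normal(log_qhat.size))


def write_posterior(posterior: Posterior, out_prefix: str) -> None:
    """CSV of resampled draws plus JSON run metadata."""
    posterior.draws.to_csv(f"{out_prefix}_draws.csv", index=False)
    meta = {
        "scenario_id": posterior.scenario_id,
        "log_marginal": posterior.log_marginal,
        "n_unique": posterior.n_unique,
        "n_importance": posterior.n_importance,
        "feasible_fraction": posterior.feasible_fraction,
        **posterior.meta,
    }
    with open(f"{out_prefix}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
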