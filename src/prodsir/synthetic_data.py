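"""Synthetic assessment datasets with the statistical structure the
pipeline assumes, plus the age-structured simulation that sets the
process-error prior bounds.

Every generator is a pure function of its seed and parameters.  The
survey generator keeps exact arrival/departure books, so the conservation
identity E_t - S_t = W_t - W_{t-1} holds by construction and can serve as
an oracle for the index deconvolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from . import production_model as pm
from .catch_series import SlrFactors, effective_catches
from .survey_index import HORIZON, SEASON_START, ResidenceDistribution, discretize_residence

__all__ = [
    "VitalRates",
    "TruthBundle",
    "AssessmentDataset",
    "generate_catch_history",
    "generate_survey_counts",
    "generate_absolute_estimate",
    "sigma2_bound_from_age_structure",
    "generate_assessment_dataset",
    "DEFAULT_SURVEY_YEARS",
]

DEFAULT_SURVEY_YEARS = tuple([1999, 2000] + list(range(2005, 2020)))


@dataclass(frozen=True)
class VitalRates:
    """Published vital rates driving the process-error bound simulation."""

    calf_mortality: float = 0.179
    adult_mortality: float = 0.026
    annual_increase: float = 1.065
    age_first_pregnancy: float = 7.58
    calf_survival_deviate_sd: float = 0.097
    adult_logit_survival_deviate_sd: float = 0.19423

    def __post_init__(self) -> None:
        if not (0 < self.calf_mortality < 1 and 0 < self.adult_mortality < 1):
            raise ValueError("mortalities must lie in (0, 1)")
        if self.age_first_pregnancy <= 1:
            raise ValueError("age at first pregnancy must exceed 1")


def generate_catch_history(
    peak_year: int = 1780,
    peak_height: float = 330.0,
    peak_width: float = 40.0,
    plateau_height: float = 0.0,
    modern_pulse_height: float = 1000.0,
    spread: float = 1.0,
    first_year: int = 1670,
    last_year: int = 1973,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-bound annual catch series with an 18th-century peak, an
    optional low sustained 19th-century plateau and a short modern pulse
    in the early 1960s.

    The low series is a smoothed multi-bump shape with multiplicative
    lognormal roughness; the high series multiplies it by (1 + spread*u_y)
    with u_y ~ U(0, 2), so ``spread = 0`` collapses the bounds.
    """
    if peak_height < 0 or modern_pulse_height < 0 or spread < 0 or plateau_height < 0:
        raise ValueError("heights and spread must be non-negative")
    rng = np.random.default_rng(seed)
    years = np.arange(first_year, last_year + 1)
    shape = peak_height * np.exp(-0.5 * ((years - peak_year) / peak_width) ** 2)
    shape = shape + plateau_height * np.exp(-0.5 * ((years - 1870) / 55.0) ** 2)
    shape = shape + modern_pulse_height * np.exp(-0.5 * ((years - 1962) / 2.0) ** 2)
    rough = np.exp(rng.normal(0.0, noise_cv, size=years.size))
    c_min = shape * rough
    c_max = c_min * (1.0 + spread * rng.uniform(0.0, 2.0, size=years.size))
    return pd.DataFrame({"year": years, "c_min": c_min, "c_max": c_max})


def _arrival_day_probs(mu_day: float, sd_day: float) -> np.ndarray:
    """Discretized truncated-normal day-of-arrival law on the open season."""
    days = np.arange(SEASON_START, HORIZON + 1)
    p = norm.cdf((days + 0.5 - mu_day) / sd_day) - norm.cdf((days - 0.5 - mu_day) / sd_day)
    total = p.sum()
    if total <= 0:
        raise ValueError("arrival law has no mass inside the season")
    return p / total


def generate_survey_counts(
    abundances: dict[int, float],
    q: float,
    residence: ResidenceDistribution | None = None,
    arrival_mu: float = 185.0,
    arrival_sd: float = 35.0,
    dispersion: float = 0.1,
    flight_days: dict[int, list[int]] | list[int] | None = None,
    beta: float = 0.0,
    seed: int = 0,
    return_ledger: bool = False,
):
    """Simulate per-flight whale counts from true abundances.

    ``q * N_y^(1+beta)`` whales arrive during the season of year y (days
    drawn from a truncated-normal timing law, never before the season
    opens); each stays a number of days drawn from the residence law.
    Flight-day counts are negative-binomial around the true occupancy
    (``dispersion`` is the NB2 alpha; 0 means Poisson).
    """
    if q < 0 or q > 1:
        raise ValueError("q must lie in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    residence = residence or discretize_residence(60.0, 8.66)
    rng = np.random.default_rng(seed)
    day_probs = _arrival_day_probs(arrival_mu, arrival_sd)
    if flight_days is None:
        flight_days = list(range(130, 311, 30))
    rows = []
    ledgers = {}
    for year, n_true in sorted(abundances.items()):
        total = rng.poisson(q * float(n_true) ** (1.0 + beta))
        arrivals = rng.multinomial(total, day_probs)
        E = np.zeros(HORIZON + 1)
        S = np.zeros(HORIZON + 1)
        E[SEASON_START : HORIZON + 1] = arrivals
        for t in np.nonzero(E)[0]:
            stays = rng.choice(
                np.arange(1, residence.horizon + 1),
                size=int(E[t]),
                p=residence.p,
            )
            depart = t + stays
            depart = depart[depart <= HORIZON]
            np.add.at(S, depart, 1)
        W = np.cumsum(E - S)
        days = flight_days[year] if isinstance(flight_days, dict) else flight_days
        for d in days:
            m = W[d]
            if dispersion > 0 and m > 0:
                lam = rng.gamma(1.0 / dispersion, dispersion * m)
            else:
                lam = m
            rows.append((year, int(d), int(rng.poisson(lam))))
        if return_ledger:
            ledgers[year] = {"E": E.copy(), "S": S.copy(), "W": W.copy()}
    counts = pd.DataFrame(rows, columns=["year", "julian_day", "count"])
    return (counts, ledgers) if return_ledger else counts


def generate_absolute_estimate(
    n_true: float, cv: float = 0.058, seed: int = 0
) -> tuple[float, float]:
    """Noisy absolute abundance estimate: lognormal draw around the truth
    with the stated CV; the reported SE is estimate * cv."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if n_true <= 0:
        raise ValueError("n_true must be positive")
    rng = np.random.default_rng(seed)
    sdlog = np.sqrt(np.log1p(cv**2))
    estimate = float(n_true * np.exp(rng.normal(0.0, sdlog)))
    return estimate, estimate * cv


def _tuned_leslie(v: VitalRates, target_lambda: float = 1.0) -> tuple[np.ndarray, int, float]:
    """Female Leslie matrix with fecundity tuned so the dominant
    eigenvalue equals ``target_lambda``; plus-group at twice the age at
    first pregnancy."""
    s0 = 1.0 - v.calf_mortality
    sa = 1.0 - v.adult_mortality
    m = int(round(2 * v.age_first_pregnancy))  # plus-group age
    am = int(round(v.age_first_pregnancy))

    def build(f: float) -> np.ndarray:
        M = np.zeros((m + 1, m + 1))
        M[0, am:] = f
        M[1, 0] = s0
        for a in range(1, m):
            M[a + 1, a] = sa
        M[m, m] = sa  # plus group self-loop
        return M

    def lam(f: float) -> float:
        return float(np.max(np.real(np.linalg.eigvals(build(f)))))

    f_star = brentq(lambda f: lam(f) - target_lambda, 1e-4, 2.0)
    return build(f_star), am, f_star


def sigma2_bound_from_age_structure(
    v: VitalRates = VitalRates(),
    years: int = 2000,
    n_rep: int = 4,
    seed: int = 0,
    burn_in: int = 200,
) -> float:
    """Stationary variance of annual log-total-abundance innovations for a
    female age-structured population at equilibrium with annual survival
    deviates.

    Fecundity is tuned so the deterministic growth rate is one (the
    population sits at equilibrium); calf survival then receives additive
    normal deviates and adult survival logit-scale deviates each year.
    Returns the variance of the detrended one-step change in log total
    abundance, averaged over replicates.  The process-error prior uses
    this value as its lower bound and (by default) ten times it as the
    upper bound.
    """
    if years < burn_in:
        raise ValueError("years must be at least the burn-in length")
    M, am, f_star = _tuned_leslie(v, target_lambda=1.0)
    m = M.shape[0] - 1
    s0 = 1.0 - v.calf_mortality
    sa = 1.0 - v.adult_mortality
    rng = np.random.default_rng(seed)
    variances = []
    for _ in range(n_rep):
        # deterministic stable age structure as the starting state
        eigval, eigvec = np.linalg.eig(M)
        w = np.real(eigvec[:, np.argmax(np.real(eigval))])
        n = 1000.0 * w / w.sum()
        log_tot = np.empty(years)
        for t in range(years):
            s0_t = float(np.clip(s0 + rng.normal(0.0, v.calf_survival_deviate_sd), 0.0, 1.0))
            sa_t = float(expit(logit(sa) + rng.normal(0.0, v.adult_logit_survival_deviate_sd)))
            births = f_star * n[am:].sum()
            new = np.empty_like(n)
            new[0] = births
            new[1] = s0_t * n[0]
            new[2:m] = sa_t * n[1 : m - 1]
            new[m] = sa_t * (n[m - 1] + n[m])
            n = new
            log_tot[t] = np.log(n.sum())
        d = np.diff(log_tot[burn_in:])
        if not np.all(np.isfinite(d)):
            raise RuntimeError("age-structured simulation left stationarity")
        variances.append(np.var(d - d.mean()))
    return float(np.mean(variances))


@dataclass
class TruthBundle:
    """True parameter values behind a synthetic assessment dataset."""

    r_max: float = 0.03
    k: float = 6_000.0
    p_msy: float = 0.6
    sigma2: float = 2.0e-4
    n_c: float = 72.0
    pi: float = 0.5
    slr1: float = 1.6
    slr2: float = 1.09
    q: float = 0.35
    beta: float = 0.0
    residence_mu: float = 60.0
    residence_sd: float = 8.66
    dispersion: float = 0.05
    arrival_mu: float = 185.0
    arrival_sd: float = 35.0
    absolute_cv: float = 0.058
    catch_peak_year: int = 1780
    catch_peak_height: float = 60.0
    catch_peak_width: float = 30.0
    catch_plateau_height: float = 5.0
    catch_pulse_height: float = 40.0
    catch_spread: float = 1.0
    survey_years: tuple = DEFAULT_SURVEY_YEARS
    flights_per_year: int = 7
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.r_max <= 0.11:
            raise ValueError("r_max outside the base prior support")
        if not 0.5 <= self.p_msy <= 0.8:
            raise ValueError("p_msy outside the base prior support")
        if not 0 <= self.pi <= 1:
            raise ValueError("pi outside [0, 1]")
        if not 6.5e-5 <= self.sigma2 <= 6.5e-4:
            raise ValueError("sigma2 outside the base prior support")


@dataclass
class AssessmentDataset:
    """A complete synthetic data bundle plus the recorded truth."""

    catch_bounds: pd.DataFrame
    flight_counts: pd.DataFrame
    absolute_estimate: float
    absolute_se: float
    truth: TruthBundle
    trajectory: pm.Trajectory
    deviates: np.ndarray = field(repr=False, default=None)

    def write(self, out_prefix: str) -> None:
        self.catch_bounds.to_csv(f"{out_prefix}_catch_bounds.csv", index=False)
        self.flight_counts.to_csv(f"{out_prefix}_flight_counts.csv", index=False)
        sidecar = asdict(self.truth)
        sidecar["survey_years"] = list(self.truth.survey_years)
        sidecar["absolute_estimate"] = self.absolute_estimate
        sidecar["absolute_se"] = self.absolute_se
        with open(f"{out_prefix}_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def generate_assessment_dataset(truth: TruthBundle = TruthBundle()) -> AssessmentDataset:
    """Forward-simulate a full assessment dataset from known parameters.

    Catch bounds, flight counts and the absolute estimate are all driven
    by child seeds of ``truth.seed``, so the bundle is bit-reproducible.
    """
    truth.validate()
    seeds = np.random.SeedSequence(truth.seed).spawn(4)
    catch_seed, dev_seed, survey_seed, abs_seed = (s.generate_state(1)[0] for s in seeds)

    bounds = generate_catch_history(
        peak_year=truth.catch_peak_year,
        peak_height=truth.catch_peak_height,
        peak_width=truth.catch_peak_width,
        plateau_height=truth.catch_plateau_height,
        modern_pulse_height=truth.catch_pulse_height,
        spread=truth.catch_spread,
        seed=catch_seed,
    )
    c_eff = effective_catches(
        bounds, pi=truth.pi, f=SlrFactors(truth.slr1, truth.slr2)
    )
    years = np.arange(pm.START_YEAR, pm.END_YEAR + 1)
    rng = np.random.default_rng(dev_seed)
    eps = rng.standard_normal(years.size)
    params = pm.ProductionParams(
        r_max=truth.r_max,
        k=truth.k,
        p_msy=truth.p_msy,
        sigma2=truth.sigma2,
        n_c=truth.n_c,
    )
    traj = pm.project(params, catches=c_eff, deviates=eps)

    residence = discretize_residence(truth.residence_mu, truth.residence_sd)
    abund = {y: traj.at(y) for y in truth.survey_years}
    flight_schedule = np.linspace(125, 315, truth.flights_per_year).astype(int).tolist()
    counts = generate_survey_counts(
        abund,
        q=truth.q,
        residence=residence,
        arrival_mu=truth.arrival_mu,
        arrival_sd=truth.arrival_sd,
        dispersion=truth.dispersion,
        flight_days=flight_schedule,
        beta=truth.beta,
        seed=survey_seed,
    )
    estimate, se = generate_absolute_estimate(
        traj.at(2010), cv=truth.absolute_cv, seed=abs_seed
    )
    return AssessmentDataset(
        catch_bounds=bounds,
        flight_counts=counts,
        absolute_estimate=estimate,
        absolute_se=se,
        truth=truth,
        trajectory=traj,
        deviates=eps,
    )
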