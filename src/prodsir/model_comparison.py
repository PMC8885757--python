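"""Scenario harness, Bayes-factor model averaging and posterior checks.

The 15 model configurations (base case plus 14 sensitivity variants) are
data, shipped as YAML files under ``prodsir/configs``; a single driver
launches any of them.  Marginal likelihoods from the SIR runs give Bayes
factors and posterior model probabilities, which in turn drive the pooled
(model-averaged) posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import production_model as pm
from .inference import (
    DataBundle,
    Posterior,
    PriorSet,
    Fixed,
    distribution_from_dict,
    run_sir,
)

__all__ = [
    "ScenarioConfig",
    "ModelRun",
    "AveragedPosterior",
    "load_scenario",
    "list_scenarios",
    "run_scenario",
    "bayes_factors",
    "model_average",
    "posterior_predictive_check",
    "summarize",
]

_CATCH_SWITCHES = ("both", "low-only", "high-only", "no-slr")
_SCENARIO_KEYS = {
    "id",
    "description",
    "anchor_year",
    "n_c",
    "catch_series",
    "include_in_average",
    "priors",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One named prior/data configuration."""

    id: str
    description: str = ""
    anchor_year: int = 2019
    n_c: float = pm.DEFAULT_N_C
    catch_series: str = "both"
    include_in_average: bool = True
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.catch_series not in _CATCH_SWITCHES:
            raise ValueError(
                f"catch_series must be one of {_CATCH_SWITCHES}, got {self.catch_series}"
            )
        if self.anchor_year not in (2019, 2004):
            raise ValueError("anchor_year must be 2019 or 2004")

    def build_priors(self, base: PriorSet | None = None) -> PriorSet:
        """Apply the catch-series switch and explicit prior overrides."""
        spec = base or PriorSet()
        overrides = {k: distribution_from_dict(v) for k, v in self.priors.items()}
        if self.catch_series == "low-only":
            overrides.setdefault("pi", Fixed(0.0))
        elif self.catch_series == "high-only":
            overrides.setdefault("pi", Fixed(1.0))
        elif self.catch_series == "no-slr":
            overrides.setdefault("slr1", Fixed(1.0))
            overrides.setdefault("slr2", Fixed(1.0))
        return spec.with_overrides(**overrides)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        unknown = set(raw) - _SCENARIO_KEYS
        if unknown:
            raise ValueError(f"unknown scenario keys {sorted(unknown)}")
        return cls(**raw)


def list_scenarios() -> list[str]:
    files = resources.files("prodsir.configs")
    return sorted(
        p.name.removesuffix(".yaml") for p in files.iterdir() if p.name.endswith(".yaml")
    )


def load_scenario(name_or_path: str) -> ScenarioConfig:
    """Load a shipped scenario by id (e.g. ``scen3``) or a YAML file path."""
    files = resources.files("prodsir.configs")
    candidate = files / f"{name_or_path}.yaml"
    if candidate.is_file():
        raw = yaml.safe_load(candidate.read_text())
    else:
        with open(name_or_path) as fh:
            raw = yaml.safe_load(fh)
    return ScenarioConfig.from_dict(raw)


@dataclass
class ModelRun:
    """A completed SIR run for one scenario."""

    config: ScenarioConfig
    posterior: Posterior

    @property
    def log_marginal(self) -> float:
        return self.posterior.log_marginal


def run_scenario(
    config: ScenarioConfig,
    data: DataBundle,
    n_importance: int = 200_000,
    n_out: int = 20_000,
    seed: int = 0,
) -> ModelRun:
    posterior = run_sir(
        spec=config.build_priors(),
        data=data,
        n_importance=n_importance,
        n_out=n_out,
        seed=seed,
        anchor_year=config.anchor_year,
        n_c=config.n_c,
        scenario_id=config.id,
    )
    return ModelRun(config=config, posterior=posterior)


def bayes_factors(runs: list[ModelRun]) -> pd.DataFrame:
    """Posterior model probabilities under equal prior model weight.

    Returns a frame with log-marginal, Bayes factor against the best model
    and normalized probability per scenario.  Runs with non-finite marginal
    likelihood are excluded with a warning.
    """
    rows = []
    for run in runs:
        lm = run.log_marginal
        if not np.isfinite(lm):
            warnings.warn(f"excluding {run.config.id}: non-finite marginal", stacklevel=2)
            continue
        rows.append((run.config.id, lm))
    if not rows:
        raise ValueError("no runs with finite marginal likelihood")
    df = pd.DataFrame(rows, columns=["scenario", "log_marginal"])
    best = df["log_marginal"].max()
    df["bayes_factor_vs_best"] = np.exp(df["log_marginal"] - best)
    df["probability"] = df["bayes_factor_vs_best"] / df["bayes_factor_vs_best"].sum()
    return df.set_index("scenario")


@dataclass
class AveragedPosterior:
    """Pooled draws sampled across models by posterior model probability."""

    draws: pd.DataFrame
    trajectories: np.ndarray
    years: np.ndarray
    allocation: dict
    meta: dict = field(default_factory=dict)

    def summary_row(self, col: str) -> dict:
        return Posterior.summary_row(self, col)  # same draw layout


def model_average(
    runs: list[ModelRun],
    probabilities: pd.DataFrame | None = None,
    n_out: int = 20_000,
    seed: int = 0,
) -> AveragedPosterior:
    """Bayesian model averaging over the runs flagged for inclusion.

    Draw counts are allocated multinomially by model probability
    (renormalized over included models), then draws are resampled
    uniformly with replacement within each model's posterior.
    """
    included = [r for r in runs if r.config.include_in_average]
    if not included:
        raise ValueError("no runs are flagged for inclusion in model averaging")
    if probabilities is None:
        probabilities = bayes_factors(included)
    probs = np.array(
        [probabilities.loc[r.config.id, "probability"] for r in included], dtype=float
    )
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_out, probs)
    pieces, traj_pieces, allocation = [], [], {}
    for run, cnt in zip(included, counts):
        allocation[run.config.id] = int(cnt)
        if cnt == 0:
            continue
        take = rng.integers(0, len(run.posterior.draws), size=cnt)
        piece = run.posterior.draws.iloc[take].reset_index(drop=True)
        piece["scenario"] = run.config.id
        pieces.append(piece)
        traj_pieces.append(run.posterior.trajectories[take])
    draws = pd.concat(pieces, ignore_index=True)
    return AveragedPosterior(
        draws=draws,
        trajectories=np.vstack(traj_pieces),
        years=included[0].posterior.years,
        allocation=allocation,
        meta={"seed": seed, "n_out": n_out},
    )


def posterior_predictive_check(
    posterior: Posterior | AveragedPosterior,
    sigma: np.ndarray,
    a_obs: np.ndarray,
    index_years: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate index vectors per posterior draw and compare with
    the observations.

    Returns per-survey-year predictive quantiles (2.5/25/50/75/97.5%) and
    flags for whether the observed value falls inside the 25-75% and
    2.5-97.5% bands.
    """
    sigma = np.asarray(sigma, float)
    index_years = np.asarray(index_years, int)
    a_obs = np.asarray(a_obs, float)
    rng = np.random.default_rng(seed)
    year0 = int(posterior.years[0])
    n_surv = posterior.trajectories[:, index_years - year0]
    beta = posterior.draws["beta"].to_numpy()
    tau2 = posterior.draws["tau2"].to_numpy()
    log_mean = posterior.draws["log_q_hat"].to_numpy()[:, None] + (
        1.0 + beta
    )[:, None] * np.log(n_surv)
    eigval, Q = np.linalg.eigh(sigma)
    root = np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal(log_mean.shape)
    noise = (z * root[None, :]) @ Q.T
    if np.any(tau2 > 0):
        noise = noise + np.sqrt(tau2)[:, None] * rng.standard_normal(log_mean.shape)
    a_rep = np.exp(log_mean + noise)
    qs = np.percentile(a_rep, [2.5, 25, 50, 75, 97.5], axis=0)
    return pd.DataFrame(
        {
            "year": index_years,
            "observed": a_obs,
            "q2.5": qs[0],
            "q25": qs[1],
            "q50": qs[2],
            "q75": qs[3],
            "q97.5": qs[4],
            "in_50": (a_obs >= qs[1]) & (a_obs <= qs[3]),
            "in_95": (a_obs >= qs[0]) & (a_obs <= qs[4]),
        }
    )


_SUMMARY_COLUMNS = (
    "r_max",
    "k",
    "p_msy",
    "sigma",
    "n_min",
    "n_2021",
    "n_2030",
    "p_min",
    "p_2021",
    "p_2030",
)


def summarize(posterior: Posterior | AveragedPosterior) -> pd.DataFrame:
    """Posterior mean, median and 50%/95% credible bounds per key quantity.

    Derived quantities are summarized per draw (e.g. depletion is the
    summary of the per-draw ratio, never a ratio of summaries).
    """
    draws = posterior.draws
    if len(draws) == 0:
        raise ValueError("empty posterior")
    work = draws.copy()
    work["sigma"] = np.sqrt(work["sigma2"])
    rows = {}
    for col in _SUMMARY_COLUMNS:
        x = work[col].to_numpy()
        qs = np.percentile(x, [2.5, 25, 50, 75, 97.5])
        rows[col] = {
            "mean": np.mean(x),
            "median": qs[2],
            "2.5%": qs[0],
            "25%": qs[1],
            "75%": qs[3],
            "97.5%": qs[4],
        }
    return pd.DataFrame(rows).T
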