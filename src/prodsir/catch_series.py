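"""Construction of the effective annual removals series.

Landed-whale counts come as per-year (minimum, maximum) bounds.  A single
time-invariant mixing parameter ``pi`` interpolates between the two bound
series, and era-specific struck-and-lost multipliers inflate the landings
for whales fatally struck but never recovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OilQuantity",
    "AnnualCatchBounds",
    "SlrFactors",
    "oil_to_whales",
    "slr_factor",
    "slr_vector",
    "effective_catches",
    "read_catch_bounds",
    "write_effective_catches",
    "PRE_MODERN_ERA",
    "MODERN_ERA",
]

#: Inclusive year ranges over which each struck-and-lost factor applies.
PRE_MODERN_ERA = (1771, 1850)
MODERN_ERA = (1851, 1973)

_BARRELS_PER_UNIT = {"barrel": 1.0, "tun": 8.0, "cask": 6.5}


@dataclass(frozen=True)
class OilQuantity:
    """A quantity of whale oil in one of the historical units."""

    amount: float
    unit: str

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"oil amount must be non-negative, got {self.amount}")
        if self.unit not in _BARRELS_PER_UNIT:
            raise ValueError(
                f"unknown oil unit {self.unit!r}; expected one of "
                f"{sorted(_BARRELS_PER_UNIT)}"
            )


@dataclass(frozen=True)
class AnnualCatchBounds:
    """Per-year lower/upper bound on the number of whales landed."""

    year: int
    c_min: float
    c_max: float

    def __post_init__(self) -> None:
        if self.c_min < 0 or self.c_max < 0:
            raise ValueError(f"catch bounds must be non-negative in year {self.year}")
        if self.c_min > self.c_max:
            raise ValueError(
                f"c_min > c_max in year {self.year}: {self.c_min} > {self.c_max}"
            )


@dataclass(frozen=True)
class SlrFactors:
    """Struck-and-lost multipliers for the pre-modern and modern eras."""

    slr1: float = 1.6
    slr2: float = 1.09


def oil_to_whales(q: OilQuantity, barrels_per_whale: float = 60.0) -> float:
    """Convert an oil quantity to (fractional) whale equivalents.

    One whale yields ``barrels_per_whale`` barrels; a tun is 8 barrels and
    a cask 6.5.  No rounding is applied.
    """
    if barrels_per_whale <= 0:
        raise ValueError("barrels_per_whale must be positive")
    return q.amount * _BARRELS_PER_UNIT[q.unit] / barrels_per_whale


def slr_factor(year: int, f: SlrFactors) -> float:
    """Struck-and-lost multiplier applying in a given calendar year.

    1.0 outside the two whaling eras, ``slr1`` for 1771-1850 and ``slr2``
    for 1851-1973 (both ranges inclusive).
    """
    if PRE_MODERN_ERA[0] <= year <= PRE_MODERN_ERA[1]:
        return f.slr1
    if MODERN_ERA[0] <= year <= MODERN_ERA[1]:
        return f.slr2
    return 1.0


def slr_vector(years: np.ndarray, slr1: float | np.ndarray, slr2: float | np.ndarray) -> np.ndarray:
    """Vectorized era multiplier; broadcasts draw-wise slr values over years.

    ``slr1``/``slr2`` may be scalars or arrays of shape (ndraw,); the result
    has shape (nyears,) or (ndraw, nyears) accordingly.
    """
    years = np.asarray(years)
    in1 = (years >= PRE_MODERN_ERA[0]) & (years <= PRE_MODERN_ERA[1])
    in2 = (years >= MODERN_ERA[0]) & (years <= MODERN_ERA[1])
    slr1 = np.asarray(slr1, dtype=float)
    slr2 = np.asarray(slr2, dtype=float)
    if slr1.ndim == 0 and slr2.ndim == 0:
        out = np.ones(years.shape, dtype=float)
        out[in1] = slr1
        out[in2] = slr2
        return out
    s1 = np.atleast_1d(slr1)[:, None]
    s2 = np.atleast_1d(slr2)[:, None]
    out = np.ones((s1.shape[0], years.size), dtype=float)
    out = np.where(in1[None, :], s1, out)
    out = np.where(in2[None, :], s2, out)
    return out


def _as_bounds_frame(bounds: Iterable[AnnualCatchBounds] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(bounds, pd.DataFrame):
        df = bounds[["year", "c_min", "c_max"]].copy()
    else:
        df = pd.DataFrame(
            [(b.year, b.c_min, b.c_max) for b in bounds],
            columns=["year", "c_min", "c_max"],
        )
    if (df["c_min"] > df["c_max"]).any():
        bad = df.loc[df["c_min"] > df["c_max"], "year"].tolist()
        raise ValueError(f"c_min > c_max in year(s) {bad}")
    if df["year"].duplicated().any():
        raise ValueError("duplicated years in catch bounds")
    return df.sort_values("year").reset_index(drop=True)


def effective_catches(
    bounds: Sequence[AnnualCatchBounds] | pd.DataFrame,
    pi: float,
    f: SlrFactors = SlrFactors(),
    last_catch_year: int = 1973,
) -> pd.Series:
    """Effective annual removals C_y * SLR_y as a year-indexed series.

    Per year the landed catch is ``c_min + pi * (c_max - c_min)``, then
    multiplied by the era struck-and-lost factor.  Years missing from the
    record inside [first catch year, ``last_catch_year``] are filled with
    zero so the state model sees a complete series.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    df = _as_bounds_frame(bounds)
    first = int(df["year"].min())
    years = np.arange(first, last_catch_year + 1)
    landed = np.zeros(years.size)
    idx = df["year"].to_numpy() - first
    keep = (df["year"].to_numpy() >= first) & (df["year"].to_numpy() <= last_catch_year)
    interp = df["c_min"].to_numpy() + pi * (df["c_max"].to_numpy() - df["c_min"].to_numpy())
    landed[idx[keep]] = interp[keep]
    eff = landed * slr_vector(years, f.slr1, f.slr2)
    return pd.Series(eff, index=pd.Index(years, name="year"), name="catch_effective")


def read_catch_bounds(path) -> pd.DataFrame:
    """Read a `year,c_min,c_max` CSV into a validated bounds frame."""
    df = pd.read_csv(path)
    expected = {"year", "c_min", "c_max"}
    if not expected.issubset(df.columns):
        raise ValueError(f"catch bounds CSV must have columns {sorted(expected)}")
    return _as_bounds_frame(df)


def write_effective_catches(series: pd.Series, path) -> None:
    series.rename("catch_effective").to_csv(path, header=True)
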