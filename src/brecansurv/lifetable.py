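"""Population life tables: the expected (background) hazard and survival.

A life table stores the annual all-cause mortality hazard of the general
population indexed by integer age, calendar year and sex.  The expected
hazard of a patient t years after diagnosis is the table rate at attained
age ``floor(age_dx + t)`` and year ``floor(year_dx + t)`` (piecewise
constant within integer cells); the expected survival is
``ES(T) = exp(-Lambda_P(T))`` with the cumulative hazard integrated
exactly over the step function.  Lookups past the table edges clamp to the
nearest boundary, which registries routinely need when predicting beyond
the last tabulated age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def prob_to_rate(q):
    """Annual death probability q -> constant annual hazard rate -ln(1-q)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("annual probabilities must lie in [0, 1)")
    return -np.log1p(-q)


def rate_to_prob(rate):
    """Inverse of :func:`prob_to_rate`."""
    return -np.expm1(-np.asarray(rate, dtype=float))


@dataclass
class LifeTable:
    """Annual mortality hazard rates on a rectangular (age, year, sex) grid."""

    ages: np.ndarray            # sorted integer ages
    years: np.ndarray           # sorted integer calendar years
    rates: dict[str, np.ndarray]  # sex -> (n_ages, n_years) hazard rates
    n_clamped: int = 0          # out-of-range lookups served by clamping

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        for sex, r in self.rates.items():
            r = np.asarray(r, dtype=float)
            if r.shape != (len(self.ages), len(self.years)):
                raise ValueError(f"rate grid for {sex!r} is not rectangular")
            if np.any(r < 0) or not np.all(np.isfinite(r)):
                raise ValueError(f"negative or non-finite rates for sex {sex!r}")
            self.rates[sex] = r

    def rate_at(self, age: float, year: float, sex: str = "female") -> float:
        """Hazard at integer (floored) age and year, clamped to the grid."""
        if sex not in self.rates:
            raise KeyError(f"sex {sex!r} not in life table")
        ai = int(np.floor(age))
        yi = int(np.floor(year))
        ci = np.clip(ai, self.ages[0], self.ages[-1])
        cj = np.clip(yi, self.years[0], self.years[-1])
        if ci != ai or cj != yi:
            self.n_clamped += 1
        i = np.searchsorted(self.ages, ci)
        j = np.searchsorted(self.years, cj)
        return float(self.rates[sex][i, j])


@dataclass
class ExpectedCurve:
    """Expected-survival curve: ES = exp(-cumulative population hazard)."""

    grid: np.ndarray
    ES: np.ndarray
    cum_hazard: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.ES = np.asarray(self.ES, dtype=float)
        self.cum_hazard = np.asarray(self.cum_hazard, dtype=float)


def read_lifetable(path, value_kind: str = "rate") -> LifeTable:
    """Read a long-format CSV (age, year, sex, value) into a LifeTable.

    ``value_kind`` is ``"rate"`` (stored as given) or
    ``"annual_probability"`` (converted via -ln(1-q)).
    """
    if value_kind not in ("rate", "annual_probability"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    df = pd.read_csv(path)
    required = {"age", "year", "sex", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"life table must have columns {sorted(required)}")
    if df.duplicated(subset=["age", "year", "sex"]).any():
        raise ValueError("duplicate (age, year, sex) entries in life table")
    vals = df["value"].to_numpy(dtype=float)
    if value_kind == "annual_probability":
        vals = prob_to_rate(vals)
    elif np.any(vals < 0):
        raise ValueError("negative rates in life table")
    df = df.assign(rate=vals)
    ages = np.sort(df["age"].unique())
    years = np.sort(df["year"].unique())
    rates = {}
    for sex, sub in df.groupby("sex"):
        pivot = sub.pivot(index="age", columns="year", values="rate")
        if pivot.shape != (len(ages), len(years)) or pivot.isna().any().any():
            raise ValueError(f"life table grid for sex {sex!r} is not rectangular")
        rates[str(sex)] = pivot.reindex(index=ages, columns=years).to_numpy()
    return LifeTable(ages=ages, years=years, rates=rates)


def make_synthetic_lifetable(
    r0: float,
    g: float,
    ages=range(0, 110),
    years=range(2000, 2036),
    sexes=("female", "male"),
) -> LifeTable:
    """Gompertz fixture table: rate(a, y) = r0 * exp(g * a), year-constant.

    r0 = 0 yields the degenerate zero-mortality table used to validate
    estimators in the excess-only regime.
    """
    if r0 < 0 or g < 0:
        raise ValueError("require r0 >= 0 and g >= 0")
    ages = np.asarray(list(ages), dtype=int)
    years = np.asarray(list(years), dtype=int)
    col = r0 * np.exp(g * ages)
    grid = np.repeat(col[:, None], len(years), axis=1)
    return LifeTable(ages=ages, years=years, rates={s: grid.copy() for s in sexes})


def expected_hazard(table: LifeTable, patient, t: float) -> float:
    """Population hazard for `patient` at time t after diagnosis."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return table.rate_at(patient.age_dx + t, patient.year_dx + t, patient.sex)


def hazard_segments(
    table: LifeTable, age_dx: float, year_dx: float, sex: str, t_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints and per-segment rates of the step hazard on [0, t_max].

    Returns ``(bounds, rates)`` with ``bounds`` of length m+1 and ``rates``
    of length m; the hazard equals ``rates[k]`` on ``[bounds[k], bounds[k+1])``.
    Breakpoints occur where the attained age or calendar year crosses an
    integer.
    """
    crossings = {0.0, float(t_max)}
    for x0 in (age_dx, year_dx):
        first = np.ceil(x0) - x0
        if first == 0.0:
            first = 1.0
        crossings.update(np.arange(first, t_max, 1.0).tolist())
    bounds = np.array(sorted(c for c in crossings if 0.0 <= c <= t_max))
    mids = (bounds[:-1] + bounds[1:]) / 2.0
    rates = np.array([table.rate_at(age_dx + m, year_dx + m, sex) for m in mids])
    return bounds, rates


def cumulative_expected_hazard(
    table: LifeTable, age_dx: float, year_dx: float, sex: str, grid
) -> np.ndarray:
    """Lambda_P on `grid`, integrating the step hazard exactly."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must start at 0 and be strictly increasing")
    bounds, rates = hazard_segments(table, age_dx, year_dx, sex, float(grid[-1]))
    # cumulative hazard at the segment bounds, then linear within segments
    cum_bounds = np.concatenate([[0.0], np.cumsum(rates * np.diff(bounds))])
    return np.interp(grid, bounds, cum_bounds)


def expected_survival_individual(table: LifeTable, patient, grid) -> ExpectedCurve:
    """ES(T) = exp(-Lambda_P(T)) for one patient on `grid`."""
    cum = cumulative_expected_hazard(
        table, patient.age_dx, patient.year_dx, patient.sex, grid
    )
    return ExpectedCurve(grid=np.asarray(grid, float), ES=np.exp(-cum), cum_hazard=cum)


def expected_survival_cohort(table: LifeTable, cohort, grid) -> ExpectedCurve:
    """Cohort expected survival: mean of the individual ES curves.

    Every patient contributes at all grid times up to the common horizon
    (cohort method; no censoring of the expected curve).
    """
    if len(cohort.df) == 0:
        raise ValueError("empty cohort")
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for row in cohort.df.itertuples(index=False):
        cum = cumulative_expected_hazard(table, row.age_dx, row.year_dx, row.sex, grid)
        total += np.exp(-cum)
    es = total / len(cohort.df)
    return ExpectedCurve(grid=grid, ES=es, cum_hazard=-np.log(es))
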