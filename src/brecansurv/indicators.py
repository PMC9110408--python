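"""Survival indicators from the excess-hazard decomposition.

Given the fitted overall (all-cause) hazard of a patient profile,
``lambda_O``, and the population (expected) hazard ``lambda_P`` from a
life table, the excess hazard attributed to the cancer is
``lambda_X = lambda_O - lambda_P``.  From the two cumulative hazards this
module derives, on a common time grid:

* overall survival           OS(T)  = exp(-Lambda_O(T));
* expected survival          ES(T)  = exp(-Lambda_P(T));
* relative survival          RS(T)  = OS(T) / ES(T);
* conditional 5-y RS         RS5(T) = RS(T+5) / RS(T), for T <= horizon-5;
* excess mortality           EM(T)  = (1 - RS5(T)) * 100  (percent);
* crude probabilities of death due to cancer, P_BC(T), and to other
  causes, P_OC(T), by competing-risks accumulation.

The crude probabilities are accumulated interval by interval assuming
constant hazards within each grid interval: the probability of dying in
the interval, ``OS(t_k) * (1 - e^{-dLam_O})``, is split between causes in
proportion to their cumulative-hazard increments.  This discretization is
exact for constant hazards and conserves ``OS + P_BC + P_OC = 1`` at
every grid point to floating-point precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import Cohort
from .coxmodel import CoxFit, predict_cumulative_hazard
from .lifetable import LifeTable, cumulative_expected_hazard

DEFAULT_HORIZON = 10.0
DEFAULT_STEP = 1.0 / 12.0


def default_grid(horizon: float = DEFAULT_HORIZON, step: float = DEFAULT_STEP):
    n = int(round(horizon / step))
    if abs(n * step - horizon) > 1e-9:
        raise ValueError("step must divide the horizon")
    return np.arange(n + 1) * step


@dataclass
class IndicatorCurves:
    """The full indicator set for one covariate profile on a time grid.

    RS5 and EM are defined only for T <= horizon - 5 and are NaN beyond.
    """

    grid: np.ndarray
    OS: np.ndarray
    ES: np.ndarray
    RS: np.ndarray
    RS5: np.ndarray
    EM: np.ndarray
    P_BC: np.ndarray
    P_OC: np.ndarray
    profile: dict = field(default_factory=dict)
    horizon: float = DEFAULT_HORIZON

    def at(self, t: float) -> dict:
        i = int(np.argmin(np.abs(self.grid - t)))
        if abs(self.grid[i] - t) > 1e-9:
            raise ValueError(f"time {t} not on the grid")
        return {k: float(getattr(self, k)[i])
                for k in ("OS", "ES", "RS", "RS5", "EM", "P_BC", "P_OC")}

    def check_invariants(self, tol: float = 1e-9) -> None:
        if not (self.OS[0] == 1.0 and self.ES[0] == 1.0 and self.RS[0] == 1.0):
            raise AssertionError("curves must start at 1 at T=0")
        if not (self.P_BC[0] == 0.0 and self.P_OC[0] == 0.0):
            raise AssertionError("crude probabilities must start at 0")
        resid = np.abs(self.OS + self.P_BC + self.P_OC - 1.0)
        if resid.max() > tol:
            raise AssertionError(f"conservation violated: {resid.max():.3g}")
        if np.any(np.diff(self.P_OC) < -tol):
            raise AssertionError("P_OC must be nondecreasing")
        if np.any(np.diff(self.OS) > tol):
            raise AssertionError("OS must be nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.grid, "OS": self.OS, "ES": self.ES, "RS": self.RS,
            "RS5": self.RS5, "EM": self.EM, "P_BC": self.P_BC, "P_OC": self.P_OC,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        d = {k: getattr(self, k).tolist()
             for k in ("grid", "OS", "ES", "RS", "RS5", "EM", "P_BC", "P_OC")}
        d["profile"] = {k: (v if not isinstance(v, (np.floating, np.integer)) else float(v))
                        for k, v in self.profile.items()}
        d["horizon"] = self.horizon
        return json.dumps(d)

    def report_frame(self) -> pd.DataFrame:
        """Annual report view, percentages to 1 decimal place."""
        years = np.arange(1, int(self.horizon) + 1, dtype=float)
        rows = []
        for t in years:
            v = self.at(t)
            rows.append({
                "T": int(t),
                "OS_pct": round(100 * v["OS"], 1),
                "ES_pct": round(100 * v["ES"], 1),
                "RS_pct": round(100 * v["RS"], 1),
                "RS5_pct": round(100 * v["RS5"], 1) if np.isfinite(v["RS5"]) else np.nan,
                "EM_pct": round(v["EM"], 1) if np.isfinite(v["EM"]) else np.nan,
                "P_BC_pct": round(100 * v["P_BC"], 1),
                "P_OC_pct": round(100 * v["P_OC"], 1),
            })
        return pd.DataFrame(rows)


def relative_survival(os_curve, es_curve, grid=None) -> np.ndarray:
    """RS = OS / ES pointwise; values above 1 are kept (negative excess
    hazard) and reported with a warning."""
    if isinstance(os_curve, pd.Series) and isinstance(es_curve, pd.Series):
        if not np.array_equal(os_curve.index.values, es_curve.index.values):
            raise ValueError("OS and ES are on different grids")
    os_ = np.asarray(os_curve, dtype=float)
    es = np.asarray(es_curve, dtype=float)
    if os_.shape != es.shape:
        raise ValueError("OS and ES are on different grids")
    if np.any(es <= 0):
        raise ValueError("ES must be positive")
    rs = os_ / es
    n_above = int(np.sum(rs > 1.0 + 1e-12))
    if n_above:
        warnings.warn(f"RS exceeds 1 at {n_above} grid point(s) "
                      "(negative excess hazard)", stacklevel=2)
    return rs


def conditional_rs5(rs, grid, horizon: float | None = None) -> np.ndarray:
    """RS5(T) = RS(T+5)/RS(T) for T <= horizon - 5; NaN beyond (never
    extrapolated)."""
    rs = np.asarray(rs, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if horizon is None:
        horizon = float(grid[-1])
    if horizon < 5:
        raise ValueError("horizon must be at least 5 years for RS5")
    step = grid[1] - grid[0]
    shift = int(round(5.0 / step))
    if abs(shift * step - 5.0) > 1e-9 or not np.allclose(np.diff(grid), step):
        raise ValueError("grid must be uniform with 5 years a whole number of steps")
    out = np.full_like(rs, np.nan)
    out[: len(rs) - shift] = rs[shift:] / rs[: len(rs) - shift]
    out[grid > horizon - 5.0 + 1e-9] = np.nan
    return out


def excess_mortality(rs5) -> np.ndarray:
    """EM = (1 - RS5) * 100, the percent excess risk of death vs the
    general population over the next five years."""
    return (1.0 - np.asarray(rs5, dtype=float)) * 100.0


def decompose_hazards(grid, cum_o, cum_p, clamp_negative_excess: bool = False):
    """Competing-risks split of the overall hazard on a grid.

    Returns ``(OS, ES, P_BC, P_OC, n_negative_increments)`` where the
    per-interval death mass ``OS(t_k)(1 - e^{-dLam_O})`` is partitioned
    between causes in proportion to ``dLam_O - dLam_P`` and ``dLam_P``.
    Negative excess increments are retained by default (P_BC may locally
    decrease); with `clamp_negative_excess` they are set to zero and the
    whole interval mass goes to other causes.
    """
    grid = np.asarray(grid, dtype=float)
    cum_o = np.asarray(cum_o, dtype=float)
    cum_p = np.asarray(cum_p, dtype=float)
    d_o = np.diff(cum_o)
    d_p = np.diff(cum_p)
    if np.any(d_o < -1e-12):
        raise ValueError("overall cumulative hazard must be nondecreasing")
    d_o = np.clip(d_o, 0.0, None)
    d_x = d_o - d_p
    n_neg = int(np.sum(d_x < -1e-12))
    if clamp_negative_excess:
        d_x = np.clip(d_x, 0.0, None)

    os_ = np.exp(-cum_o)
    es = np.exp(-cum_p)
    # death mass per interval, split by cumulative-hazard shares
    mass = os_[:-1] * -np.expm1(-d_o)
    with np.errstate(invalid="ignore", divide="ignore"):
        share_p = np.where(d_o > 0, d_p / d_o, 1.0)
        share_x = np.where(d_o > 0, d_x / d_o, 0.0)
    # dLam_O = 0 means no deaths in the interval: zero mass either way
    p_oc = np.concatenate([[0.0], np.cumsum(mass * share_p)])
    p_bc = np.concatenate([[0.0], np.cumsum(mass * share_x)])
    return os_, es, p_bc, p_oc, n_neg


def crude_probabilities(
    fit: CoxFit,
    profile: dict,
    table: LifeTable,
    grid=None,
    clamp_negative_excess: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """P_BC and P_OC curves for a profile from a fitted model and a life
    table (convenience wrapper around :func:`decompose_hazards`)."""
    if grid is None:
        grid = default_grid()
    cum_o = predict_cumulative_hazard(fit, profile, grid)
    cum_p = cumulative_expected_hazard(
        table, float(profile["age"]), float(profile.get("year_dx", table.years[0])),
        str(profile.get("sex", "female")), grid,
    )
    _, _, p_bc, p_oc, _ = decompose_hazards(grid, cum_o, cum_p,
                                            clamp_negative_excess)
    return p_bc, p_oc


def predict_profile(
    fit: CoxFit,
    table: LifeTable,
    profile: dict,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    clamp_negative_excess: bool = False,
) -> IndicatorCurves:
    """Assemble the full indicator set for one covariate profile.

    `profile` needs age, stage, her2, adherence, and (for the life-table
    lookup) year_dx and sex (defaults: first table year, female).
    """
    grid = default_grid(horizon, step)
    cum_o = predict_cumulative_hazard(fit, profile, grid)
    cum_p = cumulative_expected_hazard(
        table, float(profile["age"]), float(profile.get("year_dx", table.years[0])),
        str(profile.get("sex", "female")), grid,
    )
    os_, es, p_bc, p_oc, n_neg = decompose_hazards(
        grid, cum_o, cum_p, clamp_negative_excess
    )
    if n_neg:
        warnings.warn(
            f"negative excess-hazard increments on {n_neg} interval(s); "
            "P_BC may locally decrease", stacklevel=2,
        )
    rs = os_ / es
    rs5 = conditional_rs5(rs, grid, horizon)
    em = excess_mortality(rs5)
    return IndicatorCurves(grid=grid, OS=os_, ES=es, RS=rs, RS5=rs5, EM=em,
                           P_BC=p_bc, P_OC=p_oc, profile=dict(profile),
                           horizon=horizon)


@dataclass
class AdherenceComparison:
    """Adherent vs non-adherent indicator comparison for one base profile."""

    profile_base: dict
    horizon: float
    adherent: IndicatorCurves
    non_adherent: IndicatorCurves
    p_bc_adherent: float
    p_bc_non_adherent: float
    difference: float           # non-adherent minus adherent, percentage points
    os_bars: pd.DataFrame       # annual percent survival per arm

    def fold_change_os(self) -> float:
        """Fold increase in OS(horizon) for the adherent arm, 2 dp."""
        return os_fold_change(self.adherent.at(self.horizon)["OS"] * 100,
                              self.non_adherent.at(self.horizon)["OS"] * 100)

    def relative_reduction_pbc(self) -> float:
        return relative_reduction_pct(self.p_bc_adherent, self.p_bc_non_adherent)


def compare_adherence(
    fit: CoxFit,
    table: LifeTable,
    profile_base: dict,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
) -> AdherenceComparison:
    """Run the profile prediction for both adherence arms and tabulate the
    P_BC difference at the horizon plus annual OS bar data."""
    if "adherence" in profile_base:
        raise ValueError("profile_base must not fix adherence")
    curves = {}
    for arm in ("adherent", "non_adherent"):
        curves[arm] = predict_profile(fit, table, {**profile_base, "adherence": arm},
                                      horizon, step)
    p_adh = 100 * curves["adherent"].at(horizon)["P_BC"]
    p_non = 100 * curves["non_adherent"].at(horizon)["P_BC"]
    bars = []
    for t in np.arange(1, int(horizon) + 1, dtype=float):
        for arm in ("adherent", "non_adherent"):
            bars.append({"time": int(t), "arm": arm,
                         "percent_survival": round(100 * curves[arm].at(t)["OS"], 1)})
    return AdherenceComparison(
        profile_base=dict(profile_base), horizon=horizon,
        adherent=curves["adherent"], non_adherent=curves["non_adherent"],
        p_bc_adherent=p_adh, p_bc_non_adherent=p_non,
        difference=pbc_difference(p_non, p_adh),
        os_bars=pd.DataFrame(bars),
    )


def bootstrap_ci(
    cohort: Cohort,
    table: LifeTable,
    statistic,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> dict:
    """Nonparametric percentile bootstrap CI for `statistic`.

    `statistic` is a callable ``(Cohort, LifeTable) -> float`` evaluated on
    each patient-level resample (with replacement).  Failed replicates are
    dropped and counted; more than 10% failures raises.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(cohort.df)
    values = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        df = cohort.df.iloc[idx].reset_index(drop=True).copy()
        df["id"] = [f"b{b}_{i}" for i in range(n)]
        try:
            values.append(float(statistic(Cohort(df), table)))
        except Exception:
            n_failed += 1
    if n_failed > 0.10 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    values = np.asarray(values)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return {"ci_low": float(lo), "ci_high": float(hi), "B": B,
            "n_failed": n_failed, "values": values}


def pbc_age_trend(
    fit: CoxFit,
    table: LifeTable,
    stage: str,
    her2: str,
    ages,
    at_T=(5.0, 10.0),
    year_dx: float | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """P_BC at fixed times as a function of age at diagnosis, per adherence
    arm (long DataFrame: age, arm, T, p_bc)."""
    rows = []
    for age in np.asarray(ages, dtype=float):
        for arm in ("adherent", "non_adherent"):
            profile = {"age": age, "stage": stage, "her2": her2, "adherence": arm}
            if year_dx is not None:
                profile["year_dx"] = year_dx
            curves = predict_profile(fit, table, profile, horizon)
            for t in at_T:
                rows.append({"age": age, "arm": arm, "T": float(t),
                             "p_bc": curves.at(float(t))["P_BC"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting-layer arithmetic (the quantities the narrative prints)

def pbc_difference(p_bc_non_adherent: float, p_bc_adherent: float) -> float:
    """Difference in crude probability of cancer death, non-adherent minus
    adherent, in percentage points."""
    return p_bc_non_adherent - p_bc_adherent


def os_fold_change(os_adherent_pct: float, os_non_adherent_pct: float,
                   digits: int = 2) -> float:
    """Fold increase in overall survival with adherence (e.g. 73.5/58)."""
    return round(os_adherent_pct / os_non_adherent_pct, digits)


def relative_reduction_pct(p_bc_adherent: float, p_bc_non_adherent: float,
                           digits: int = 1) -> float:
    """Percent relative reduction in P_BC with adherence,
    (1 - adherent/non-adherent) * 100."""
    return round((1.0 - p_bc_adherent / p_bc_non_adherent) * 100.0, digits)


def hr_risk_reduction_pct(hr: float, digits: int = 0) -> float:
    """Percent risk reduction implied by a hazard ratio, (1 - HR) * 100."""
    out = round((1.0 - hr) * 100.0, digits)
    return out if digits else float(int(out))
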