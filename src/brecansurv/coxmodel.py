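"""Proportional-hazards modelling of all-cause mortality.

Four model designs are supported for the breast-cancer cohort, differing
in how age at diagnosis enters the log hazard and whether the
endocrine-therapy adherence effect is constant over follow-up:

* C1 -- age as four categories (<=49, 50-59, 60-74, 75-84);
* C2 -- age linear in the log hazard;
* C3 -- age as a restricted cubic spline (default 3 knots at the 10th,
  50th and 90th age percentiles);
* C4 -- as C3, with the adherence coefficient split at five years of
  follow-up (episode splitting of each record at t = 5).

All models additionally adjust for stage (ref. I), HER2 status (ref.
negative) and adherence (ref. non-adherent).  The partial likelihood is
maximized by Newton iteration with step-halving to a gradient norm below
1e-8; ties are handled by the Breslow method by default (Efron
switchable).  The baseline cumulative hazard is the Breslow step
estimator, so the fitted object carries everything needed to predict the
overall survival of an arbitrary covariate profile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .cohort_io import ADHERENCE_CUTOFF, Cohort

__all__ = [
    "SplineBasis", "DesignSpec", "CoxFit", "ConvergenceError",
    "rcs_basis", "fit_cox", "hazard_ratio_table", "predict_cumulative_hazard",
    "predict_overall_survival", "schoenfeld_diagnostic", "SchoenfeldDiagnostic",
    "time_varying_ratio_test", "compare_models", "adjusted_survival_curves",
    "nomogram_points", "fit_to_json", "fit_from_json",
]

Z_95 = 1.959964

AGE_GROUP_EDGES = [-np.inf, 50, 60, 75, np.inf]
AGE_GROUP_LABELS = ["le49", "50_59", "60_74", "75_84"]

#: standard outer/inner knot quantiles per knot count
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SplineBasis:
    """Restricted cubic spline basis (linear beyond the boundary knots).

    With k knots t_1 < ... < t_k the basis spans k-1 columns: x itself and,
    for j = 1..k-2,

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2.
    """

    knots: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if len(self.knots) < 3 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("need >= 3 strictly increasing knots")

    @property
    def n_terms(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self.knots
        k = len(t)
        norm = (t[-1] - t[0]) ** 2
        cols = [x]
        for j in range(k - 2):
            cub = (
                np.clip(x - t[j], 0, None) ** 3
                - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
                + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
            )
            cols.append(cub / norm)
        return np.column_stack(cols)


def rcs_basis(ages, n_knots: int = 3, knots=None) -> SplineBasis:
    """Spline basis with knots at standard quantiles of the observed ages."""
    if knots is not None:
        return SplineBasis(np.asarray(knots, dtype=float))
    ages = np.asarray(ages, dtype=float)
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    if len(np.unique(ages)) <= n_knots:
        raise ValueError("fewer distinct ages than knots")
    qs = _KNOT_QUANTILES.get(n_knots, tuple(np.linspace(0.05, 0.95, n_knots)))
    kn = np.quantile(ages, qs)
    if len(np.unique(kn)) < n_knots:
        raise ValueError("degenerate knots: too few distinct ages")
    return SplineBasis(kn)


@dataclass
class DesignSpec:
    """Covariate coding for one of the four model designs."""

    design_id: str
    age_coding: str            # categorical | log_linear | restricted_cubic_spline
    adherence_coding: str = "constant"   # constant | time_varying
    tv_cutoff: float = 5.0
    n_knots: int = 3

    @classmethod
    def C1(cls):
        return cls("C1", "categorical")

    @classmethod
    def C2(cls):
        return cls("C2", "log_linear")

    @classmethod
    def C3(cls, n_knots: int = 3):
        return cls("C3", "restricted_cubic_spline", n_knots=n_knots)

    @classmethod
    def C4(cls, n_knots: int = 3, tv_cutoff: float = 5.0):
        return cls("C4", "restricted_cubic_spline", "time_varying", tv_cutoff, n_knots)

    @classmethod
    def by_id(cls, design_id: str) -> "DesignSpec":
        try:
            return getattr(cls, design_id)()
        except AttributeError:
            raise ValueError(f"unknown design {design_id!r}") from None


def _age_columns(ages: np.ndarray, design: DesignSpec, basis: SplineBasis | None):
    if design.age_coding == "categorical":
        grp = pd.cut(ages, AGE_GROUP_EDGES, right=False, labels=AGE_GROUP_LABELS)
        cols = {f"age_{lbl}": (grp == lbl).astype(float)
                for lbl in AGE_GROUP_LABELS[1:]}
        return pd.DataFrame(cols), None
    if design.age_coding == "log_linear":
        return pd.DataFrame({"age": ages}), None
    if design.age_coding == "restricted_cubic_spline":
        if basis is None:
            basis = rcs_basis(ages, design.n_knots)
        mat = basis.transform(ages)
        cols = {f"age_rcs{j + 1}": mat[:, j] for j in range(mat.shape[1])}
        return pd.DataFrame(cols), basis
    raise ValueError(f"unknown age coding {design.age_coding!r}")


def _covariate_frame(df: pd.DataFrame, design: DesignSpec,
                     basis: SplineBasis | None):
    """Time-fixed part of the design matrix (adherence handled separately)."""
    bad = ~df["stage"].isin(["I", "II", "III"])
    if bad.any():
        raise ValueError("fit requires stage I-III; apply inclusion criteria first")
    if df["adherence_rate"].isna().any():
        raise ValueError("missing adherence rates; apply inclusion criteria first")
    age_df, basis = _age_columns(df["age_dx"].to_numpy(float), design, basis)
    X = age_df.reset_index(drop=True)
    X["her2_pos"] = (df["her2"] == "pos").astype(float).to_numpy()
    X["stage_II"] = (df["stage"] == "II").astype(float).to_numpy()
    X["stage_III"] = (df["stage"] == "III").astype(float).to_numpy()
    return X, basis


def _build_rows(df: pd.DataFrame, design: DesignSpec, basis: SplineBasis | None):
    """Counting-process rows (start, stop, event, X); episode split for C4."""
    X, basis = _covariate_frame(df, design, basis)
    adherent = (df["adherence_rate"].to_numpy(float) > ADHERENCE_CUTOFF).astype(float)
    stop = np.maximum(df["followup_years"].to_numpy(float), 1e-9)
    event = df["dead"].to_numpy(bool)

    if design.adherence_coding == "constant":
        X = X.assign(adherent=adherent)
        start = np.zeros(len(df))
        return start, stop, event, X, basis

    cut = design.tv_cutoff
    rows, starts, stops, events = [], [], [], []
    base = X.to_numpy(float)
    for i in range(len(df)):
        if stop[i] <= cut:
            rows.append(np.concatenate([base[i], [adherent[i], 0.0]]))
            starts.append(0.0)
            stops.append(stop[i])
            events.append(event[i])
        else:
            rows.append(np.concatenate([base[i], [adherent[i], 0.0]]))
            starts.append(0.0)
            stops.append(cut)
            events.append(False)
            rows.append(np.concatenate([base[i], [0.0, adherent[i]]]))
            starts.append(cut)
            stops.append(stop[i])
            events.append(event[i])
    names = list(X.columns) + ["adherent_early", "adherent_late"]
    Xout = pd.DataFrame(np.array(rows), columns=names)
    return np.array(starts), np.array(stops), np.array(events), Xout, basis


# ---------------------------------------------------------------------------
# partial likelihood machinery

class _PartialLikelihood:
    """Cox partial likelihood over counting-process rows.

    A vectorized suffix-sum path handles the common right-censored
    Breslow case without strata; a per-event-time path handles
    (start, stop] rows, Efron ties and stratified likelihoods.
    """

    def __init__(self, start, stop, event, X, strata=None, ties="breslow"):
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie method {ties!r}")
        self.ties = ties
        self.p = X.shape[1]
        order = np.argsort(stop, kind="stable")
        self.start = np.asarray(start, float)[order]
        self.stop = np.asarray(stop, float)[order]
        self.event = np.asarray(event, bool)[order]
        self.X = np.asarray(X, float)[order]
        self.strata = None if strata is None else np.asarray(strata)[order]
        if not self.event.any():
            raise ValueError("no events in the data")
        self.n_events = int(self.event.sum())
        self.fast = (
            ties == "breslow" and self.strata is None
            and np.all(self.start == 0.0)
        )
        if self.fast:
            te = self.stop[self.event]
            self.ue, self.d = np.unique(te, return_counts=True)
            self.risk_idx = np.searchsorted(self.stop, self.ue, side="left")
            self.ev_group = np.searchsorted(self.ue, te)
        else:
            # precompute risk-set / event-row indices per (stratum, event time)
            if self.strata is None:
                strat = np.zeros(len(self.stop))
                labels = {0.0: None}
            else:
                strat = self.strata
                labels = {s: s for s in pd.unique(strat)}
            self.blocks = []
            for s0, s in ((k, v) for k, v in labels.items()):
                idx = np.where(strat == s0)[0]
                ev_idx = idx[self.event[idx]]
                if len(ev_idx) == 0:
                    self.blocks.append((s, []))
                    continue
                times = np.unique(self.stop[ev_idx])
                per_time = []
                for t in times:
                    risk = idx[(self.start[idx] < t) & (self.stop[idx] >= t)]
                    ev = ev_idx[self.stop[ev_idx] == t]
                    per_time.append((t, risk, ev))
                self.blocks.append((s, per_time))

    # -- log-likelihood, gradient, Hessian -------------------------------
    def llgh(self, beta):
        if self.fast:
            return self._llgh_fast(beta)
        return self._llgh_general(beta)

    def _llgh_fast(self, beta):
        X, e = self.X, self.event
        eta = X @ beta
        w = np.exp(eta)
        xw = X * w[:, None]
        xxw = (X[:, :, None] * X[:, None, :]) * w[:, None, None]
        S0 = np.cumsum(w[::-1])[::-1][self.risk_idx]
        S1 = np.cumsum(xw[::-1], axis=0)[::-1][self.risk_idx]
        S2 = np.cumsum(xxw[::-1], axis=0)[::-1][self.risk_idx]
        d = self.d.astype(float)
        ll = eta[e].sum() - float(d @ np.log(S0))
        m = S1 / S0[:, None]
        grad = X[e].sum(axis=0) - d @ m
        V = S2 / S0[:, None, None] - m[:, :, None] * m[:, None, :]
        hess = -np.einsum("j,jab->ab", d, V)
        return ll, grad, hess

    def _llgh_general(self, beta):
        X, e = self.X, self.event
        eta = X @ beta
        w = np.exp(eta)
        ll = float(eta[e].sum())
        grad = X[e].sum(axis=0).astype(float)
        hess = np.zeros((self.p, self.p))
        for _, per_time in self.blocks:
            for _, risk, ev in per_time:
                d = len(ev)
                wr = w[risk]
                S0 = wr.sum()
                S1 = wr @ X[risk]
                S2 = (X[risk] * wr[:, None]).T @ X[risk]
                if self.ties == "breslow" or d == 1:
                    for _l in range(d):
                        m = S1 / S0
                        ll -= np.log(S0)
                        grad -= m
                        hess -= S2 / S0 - np.outer(m, m)
                else:  # efron
                    wt = w[ev]
                    S0t = wt.sum()
                    S1t = wt @ X[ev]
                    S2t = (X[ev] * wt[:, None]).T @ X[ev]
                    for l in range(d):
                        f = l / d
                        S0l = S0 - f * S0t
                        S1l = S1 - f * S1t
                        S2l = S2 - f * S2t
                        m = S1l / S0l
                        ll -= np.log(S0l)
                        grad -= m
                        hess -= S2l / S0l - np.outer(m, m)
        return ll, grad, hess

    # -- Breslow baseline cumulative hazard ------------------------------
    def baseline(self, beta):
        """(times, cumulative hazard) per stratum; single stratum unwrapped."""
        w = np.exp(self.X @ beta)
        if self.fast:
            S0 = np.cumsum(w[::-1])[::-1][self.risk_idx]
            return {None: (self.ue.copy(), np.cumsum(self.d / S0))}
        out = {}
        for s, per_time in self.blocks:
            times = np.array([t for t, _, _ in per_time])
            inc = np.array([len(ev) / w[risk].sum() for _, risk, ev in per_time])
            out[s] = (times, np.cumsum(inc))
        return out

    # -- Schoenfeld residuals at event rows ------------------------------
    def schoenfeld(self, beta):
        """(event times, residual matrix) sorted by time."""
        w = np.exp(self.X @ beta)
        if self.fast:
            xw = self.X * w[:, None]
            S0 = np.cumsum(w[::-1])[::-1][self.risk_idx]
            S1 = np.cumsum(xw[::-1], axis=0)[::-1][self.risk_idx]
            mbar = (S1 / S0[:, None])[self.ev_group]
            times = self.stop[self.event]
            resid = self.X[self.event] - mbar
            return times, resid
        times, resid = [], []
        for _, per_time in self.blocks:
            for t, risk, ev in per_time:
                wr = w[risk]
                m = (wr @ self.X[risk]) / wr.sum()
                for i in ev:
                    times.append(t)
                    resid.append(self.X[i] - m)
        times = np.array(times)
        order = np.argsort(times, kind="stable")
        return times[order], np.array(resid)[order]


def _newton(pl: _PartialLikelihood, tol: float = 1e-8, max_iter: int = 100):
    beta = np.zeros(pl.p)
    ll, grad, hess = pl.llgh(beta)
    for _ in range(max_iter):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            if np.max(np.abs(beta)) > 15:
                raise ConvergenceError(
                    "implausibly large coefficient at convergence: monotone "
                    "likelihood / separation; consider collapsing the "
                    "offending covariate"
                )
            return beta, ll, grad, hess
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                "singular information matrix: possible separation (a covariate "
                "perfectly orders the event times); remove or coarsen it"
            ) from None
        # accept any step that does not decrease the log likelihood beyond
        # its floating-point resolution (full Newton steps near the optimum
        # change it by less than the rounding noise of the summation)
        ll_tol = 1e-10 * (abs(ll) + 1.0)
        s = 1.0
        for _h in range(40):
            cand = beta + s * step
            nll, ngrad, nhess = pl.llgh(cand)
            if np.isfinite(nll) and nll >= ll - ll_tol:
                break
            s *= 0.5
        else:
            raise ConvergenceError(f"step-halving failed at gradient norm {gnorm:.3g}")
        beta, ll, grad, hess = cand, nll, ngrad, nhess
        if np.max(np.abs(beta)) > 40:
            raise ConvergenceError(
                "coefficients diverging: monotone likelihood / separation; "
                "consider collapsing the offending covariate"
            )
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations; last gradient norm "
        f"{float(np.linalg.norm(grad)):.3g}"
    )


def cox_log_partial_likelihood(beta, stop, event, X, start=None,
                               ties: str = "breslow") -> float:
    """Log partial likelihood at a given coefficient vector."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(stop):
        X = X.T
    start = np.zeros(len(stop)) if start is None else start
    pl = _PartialLikelihood(start, stop, event, X, ties=ties)
    return pl.llgh(np.asarray(beta, float))[0]


# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted proportional-hazards model with its Breslow baseline."""

    design: DesignSpec
    beta: pd.Series
    vcov: pd.DataFrame
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    log_partial_likelihood: float
    aic: float
    n_events: int
    n: int
    ties: str = "breslow"
    knots: np.ndarray | None = None
    age_range: tuple[float, float] | None = None
    _pl: _PartialLikelihood | None = field(default=None, repr=False, compare=False)

    @property
    def terms(self) -> list[str]:
        return list(self.beta.index)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.beta.index)

    def spline(self) -> SplineBasis | None:
        return None if self.knots is None else SplineBasis(self.knots)


def fit_cox(cohort: Cohort, design: DesignSpec, ties: str = "breslow") -> CoxFit:
    """Fit one of the model designs to the cohort by Newton iteration."""
    df = cohort.df
    start, stop, event, X, basis = _build_rows(df, design, None)
    if not np.asarray(event).any():
        raise ValueError("cohort has no events")
    pl = _PartialLikelihood(start, stop, event, X.to_numpy(float), ties=ties)
    beta, ll, _grad, hess = _newton(pl)
    vcov = np.linalg.inv(-hess)
    times, cum = pl.baseline(beta)[None]
    k = len(beta)
    names = list(X.columns)
    return CoxFit(
        design=design,
        beta=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        baseline_times=times,
        baseline_cumhaz=cum,
        log_partial_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n_events=pl.n_events,
        n=len(df),
        ties=ties,
        knots=None if basis is None else basis.knots,
        age_range=(float(df["age_dx"].min()), float(df["age_dx"].max())),
        _pl=pl,
    )


def fit_cox_arrays(stop, event, X, start=None, names=None,
                   ties: str = "breslow") -> CoxFit:
    """Fit a Cox model directly on counting-process arrays.

    Lower-level sibling of :func:`fit_cox` for ad-hoc designs (simulation
    studies, custom covariates); the returned fit supports the baseline,
    diagnostics and model comparison but not profile prediction.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    start = np.zeros(n) if start is None else np.asarray(start, float)
    pl = _PartialLikelihood(start, np.asarray(stop, float),
                            np.asarray(event, bool), X, ties=ties)
    beta, ll, _g, hess = _newton(pl)
    vcov = np.linalg.inv(-hess)
    times, cum = pl.baseline(beta)[None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    k = len(beta)
    return CoxFit(
        design=DesignSpec("custom", "log_linear"),
        beta=pd.Series(beta, index=list(names)),
        vcov=pd.DataFrame(vcov, index=list(names), columns=list(names)),
        baseline_times=times, baseline_cumhaz=cum,
        log_partial_likelihood=ll, aic=2.0 * k - 2.0 * ll,
        n_events=pl.n_events, n=n, ties=ties, _pl=pl,
    )


_TERM_VARIABLES = [
    ("age", lambda t: t.startswith("age")),
    ("her2", lambda t: t.startswith("her2")),
    ("stage", lambda t: t.startswith("stage")),
    ("adherence", lambda t: t.startswith("adherent")),
]

_REF_LEVELS = {"age": "le49", "her2": "neg", "stage": "I", "adherence": "non_adherent"}


def hazard_ratio_table(fit: CoxFit, z: float = Z_95) -> pd.DataFrame:
    """Per-term hazard ratios with Wald 95% CIs; reference rows marked 'Ref'."""
    se = fit.se()
    rows = []
    seen_vars: set[str] = set()
    for term in fit.terms:
        var = next((v for v, pred in _TERM_VARIABLES if pred(term)), term)
        has_ref = var in ("her2", "stage", "adherence") or (
            var == "age" and fit.design.age_coding == "categorical"
        )
        if has_ref and var not in seen_vars:
            rows.append({"variable": var, "term": _REF_LEVELS[var],
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "display": "Ref"})
        seen_vars.add(var)
        b, s = fit.beta[term], se[term]
        hr = float(np.exp(b))
        lo, hi = float(np.exp(b - z * s)), float(np.exp(b + z * s))
        rows.append({"variable": var, "term": term, "hr": hr,
                     "ci_low": lo, "ci_high": hi,
                     "display": f"{hr:.2f} ({lo:.2f}-{hi:.2f})"})
    return pd.DataFrame(rows)


def _profile_vectors(fit: CoxFit, profile: dict) -> tuple[np.ndarray, np.ndarray]:
    """Design vectors (early, late) for a covariate profile.

    For constant-adherence designs both vectors coincide.
    """
    design = fit.design
    missing = [k for k in ("age", "stage", "her2", "adherence") if k not in profile]
    if missing:
        raise KeyError(f"profile missing covariate(s): {missing}")
    age = float(profile["age"])
    stage = str(profile["stage"])
    if stage not in ("I", "II", "III"):
        raise ValueError(f"stage must be I-III, got {stage!r}")
    her2 = str(profile["her2"])
    adh = profile["adherence"]
    adherent = 1.0 if adh in ("adherent", True, 1) else 0.0

    vals = {}
    if design.age_coding == "categorical":
        lbl = pd.cut([age], AGE_GROUP_EDGES, right=False, labels=AGE_GROUP_LABELS)[0]
        for l in AGE_GROUP_LABELS[1:]:
            vals[f"age_{l}"] = float(lbl == l)
    elif design.age_coding == "log_linear":
        vals["age"] = age
    else:
        mat = fit.spline().transform([age])
        for j in range(mat.shape[1]):
            vals[f"age_rcs{j + 1}"] = float(mat[0, j])
    vals["her2_pos"] = float(her2 == "pos")
    vals["stage_II"] = float(stage == "II")
    vals["stage_III"] = float(stage == "III")
    if design.adherence_coding == "constant":
        vals["adherent"] = adherent
        x = np.array([vals[t] for t in fit.terms])
        return x, x
    early = dict(vals, adherent_early=adherent, adherent_late=0.0)
    late = dict(vals, adherent_early=0.0, adherent_late=adherent)
    xe = np.array([early[t] for t in fit.terms])
    xl = np.array([late[t] for t in fit.terms])
    return xe, xl


def _baseline_at(fit: CoxFit, times: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0.0], fit.baseline_cumhaz])
    idx = np.searchsorted(fit.baseline_times, times, side="right")
    return cum[idx]


def predict_cumulative_hazard(fit: CoxFit, profile: dict, times) -> np.ndarray:
    """Profile-specific cumulative hazard Lambda_O on `times`."""
    times = np.asarray(times, dtype=float)
    last = fit.baseline_times[-1]
    if times.max() > last:
        warnings.warn(
            f"extrapolating beyond the last event time ({last:.3g} y); "
            "the cumulative hazard is extended flat", stacklevel=2,
        )
    xe, xl = _profile_vectors(fit, profile)
    if fit.design.adherence_coding == "constant":
        return _baseline_at(fit, times) * np.exp(float(xe @ fit.beta.values))
    cut = fit.design.tv_cutoff
    l_cut = _baseline_at(fit, np.array([cut]))[0]
    l_t = _baseline_at(fit, times)
    l_early = np.minimum(l_t, l_cut)
    l_late = np.clip(l_t - l_cut, 0.0, None)
    return (l_early * np.exp(float(xe @ fit.beta.values))
            + l_late * np.exp(float(xl @ fit.beta.values)))


def predict_overall_survival(fit: CoxFit, profile: dict, grid) -> pd.Series:
    """OS(T) = exp(-Lambda_0(T) e^{x beta}) on `grid` (step baseline)."""
    grid = np.asarray(grid, dtype=float)
    os_ = np.exp(-predict_cumulative_hazard(fit, profile, grid))
    return pd.Series(os_, index=grid, name="OS")


@dataclass
class SchoenfeldDiagnostic:
    """Scaled Schoenfeld residuals for one term with a LOWESS smooth."""

    term: str
    times: np.ndarray
    residuals: np.ndarray       # scaled residuals (beta-hat scale)
    smooth: np.ndarray
    se: np.ndarray
    reference: float            # the constant log-HR beta-hat
    proportional: bool


def _lowess_se(times, resid_to_smooth, frac):
    """Pointwise se of the local-linear tricube smoother.

    At each point the LOWESS estimate is a linear combination l(x0)^T y of
    the responses (first row of the weighted least-squares hat matrix); its
    variance is sigma^2 ||l(x0)||^2 with sigma^2 estimated from the
    residuals about the smooth.  This captures the inflated boundary
    variance of local-linear fits.
    """
    m = len(times)
    k = max(int(np.ceil(frac * m)), 3)
    sigma2 = float(np.mean(resid_to_smooth**2))
    se = np.empty(m)
    for i, x0 in enumerate(times):
        dist = np.abs(times - x0)
        h = max(np.partition(dist, k - 1)[k - 1], 1e-12)
        w = np.clip(1 - (dist / h) ** 3, 0, None) ** 3
        u = times - x0
        s0, s1, s2 = w.sum(), (w * u).sum(), (w * u * u).sum()
        denom = s0 * s2 - s1 * s1
        if denom <= 0:
            l = w / s0
        else:
            l = w * (s2 - u * s1) / denom
        se[i] = np.sqrt(sigma2 * float((l * l).sum()))
    return se


def schoenfeld_diagnostic(fit: CoxFit, term: str,
                          smoother_fraction: float = 0.75) -> SchoenfeldDiagnostic:
    """Scaled Schoenfeld residuals vs time with a LOWESS smooth and a
    pointwise 95% band; flags proportionality when the band covers the
    constant log-HR everywhere."""
    if fit._pl is None:
        raise ValueError("diagnostics need a fit produced by fit_cox (not JSON)")
    if term not in fit.terms:
        raise KeyError(f"unknown term {term!r}")
    if fit.n_events < 10:
        raise ValueError("too few events for a Schoenfeld diagnostic")
    times, resid = fit._pl.schoenfeld(fit.beta.values)
    # Grambsch-Therneau scaling: r* = beta-hat + d * Vcov r
    scaled = fit.beta.values + fit.n_events * (resid @ fit.vcov.values)
    j = fit.terms.index(term)
    y = scaled[:, j]
    sm = _sm_lowess(y, times, frac=smoother_fraction, it=0, return_sorted=False)
    se = _lowess_se(times, y - sm, smoother_fraction)
    ref = float(fit.beta.iloc[j])
    ok = bool(np.all((sm - Z_95 * se <= ref) & (ref <= sm + Z_95 * se)))
    return SchoenfeldDiagnostic(term, times, y, sm, se, ref, ok)


@dataclass
class TimeVaryingRatio:
    hr_early: float
    hr_late: float
    ratio: float
    ci_low: float
    ci_high: float


def time_varying_ratio_test(fit: CoxFit, z: float = Z_95) -> TimeVaryingRatio:
    """Ratio of the early (<= cutoff) to late adherence hazard ratios,
    with a delta-method Wald CI on the log scale."""
    for t in ("adherent_early", "adherent_late"):
        if t not in fit.terms:
            raise ValueError("fit lacks time-varying adherence coefficients")
    be = float(fit.beta["adherent_early"])
    bl = float(fit.beta["adherent_late"])
    v = fit.vcov
    var = (v.loc["adherent_early", "adherent_early"]
           + v.loc["adherent_late", "adherent_late"]
           - 2 * v.loc["adherent_early", "adherent_late"])
    se = float(np.sqrt(var))
    diff = be - bl
    return TimeVaryingRatio(
        hr_early=float(np.exp(be)), hr_late=float(np.exp(bl)),
        ratio=float(np.exp(diff)),
        ci_low=float(np.exp(diff - z * se)), ci_high=float(np.exp(diff + z * se)),
    )


def compare_models(fits: list[CoxFit]) -> pd.DataFrame:
    """AIC ranking (ascending); ties keep input order; flags the minimizer."""
    if len({(f.n_events, f.n) for f in fits}) > 1:
        raise ValueError("fits are not on the same data (event/record counts differ)")
    rows = [{"design": f.design.design_id, "k": len(f.beta),
             "log_partial_likelihood": f.log_partial_likelihood, "aic": f.aic}
            for f in fits]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["selected"] = out["aic"] == out["aic"].min()
    return out


def adjusted_survival_curves(
    cohort: Cohort,
    stratify_var: str,
    n_knots: int = 3,
    grid=None,
    ties: str = "breslow",
) -> dict[str, pd.Series]:
    """Age-adjusted survival curves per category of `stratify_var`.

    Fits a Cox model stratified by the variable with age (restricted cubic
    spline) as the only covariate, then directly standardizes each
    stratum-specific predicted curve over the cohort's age distribution.
    """
    df = cohort.with_adherence_class()
    if stratify_var not in df.columns:
        raise KeyError(f"unknown stratification variable {stratify_var!r}")
    if grid is None:
        grid = np.arange(0, 121) / 12.0
    grid = np.asarray(grid, dtype=float)
    ages = df["age_dx"].to_numpy(float)
    basis = rcs_basis(ages, n_knots)
    X = basis.transform(ages)
    stop = np.maximum(df["followup_years"].to_numpy(float), 1e-9)
    event = df["dead"].to_numpy(bool)
    strata = df[stratify_var].astype(str).to_numpy()
    pl = _PartialLikelihood(np.zeros(len(df)), stop, event, X,
                            strata=strata, ties=ties)
    beta, _ll, _g, _h = _newton(pl)
    baselines = pl.baseline(beta)
    eta = X @ beta
    curves = {}
    for s in pd.unique(strata):
        if s not in baselines or len(baselines[s][0]) == 0:
            warnings.warn(f"stratum {s!r} has no events; curve flat at 1",
                          stacklevel=2)
            curves[s] = pd.Series(np.ones_like(grid), index=grid, name=str(s))
            continue
        times, cum = baselines[s]
        cum0 = np.concatenate([[0.0], cum])
        lam = cum0[np.searchsorted(times, grid, side="right")]
        surv = np.exp(-np.outer(np.exp(eta), lam)).mean(axis=0)
        curves[s] = pd.Series(surv, index=grid, name=str(s))
    return curves


def nomogram_points(fit: CoxFit, age_step: float = 1.0) -> pd.DataFrame:
    """Points table: each variable's log-hazard contribution rescaled so the
    widest single-variable range spans 100 points.

    Total points map back to the linear predictor as
    ``lp = total_points / attrs['points_per_lp'] + attrs['lp_offset']``.
    """
    beta = fit.beta
    groups: dict[str, dict[str, float]] = {}
    age_terms = [t for t in fit.terms if t.startswith("age")]
    if fit.design.age_coding == "categorical":
        groups["age"] = {"le49": 0.0}
        for t in age_terms:
            groups["age"][t.removeprefix("age_")] = float(beta[t])
    elif age_terms:
        lo, hi = fit.age_range if fit.age_range else (20.0, 85.0)
        ages = np.arange(lo, hi + age_step / 2, age_step)
        if fit.design.age_coding == "log_linear":
            contrib = ages * float(beta["age"])
        else:
            contrib = fit.spline().transform(ages) @ beta[age_terms].values
        groups["age"] = {f"{a:g}": float(c) for a, c in zip(ages, contrib)}
    if "her2_pos" in fit.terms:
        groups["her2"] = {"neg": 0.0, "pos": float(beta["her2_pos"])}
    if "stage_II" in fit.terms:
        groups["stage"] = {"I": 0.0, "II": float(beta["stage_II"]),
                           "III": float(beta["stage_III"])}
    if "adherent" in fit.terms:
        groups["adherence"] = {"non_adherent": 0.0,
                               "adherent": float(beta["adherent"])}
    for t in ("adherent_early", "adherent_late"):
        if t in fit.terms:
            groups[t] = {"no": 0.0, "yes": float(beta[t])}

    ranges = {v: max(c.values()) - min(c.values()) for v, c in groups.items()}
    max_range = max(ranges.values())
    if max_range <= 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    scale = 100.0 / max_range
    rows = []
    offset = 0.0
    for var, contrib in groups.items():
        mn = min(contrib.values())
        offset += mn
        for level, c in contrib.items():
            rows.append({"variable": var, "level": level,
                         "points": (c - mn) * scale})
    out = pd.DataFrame(rows)
    out.attrs["points_per_lp"] = scale
    out.attrs["lp_offset"] = offset
    return out


# ---------------------------------------------------------------------------
# serialization: enough to reproduce predictions bit-for-bit

def fit_to_json(fit: CoxFit) -> str:
    payload = {
        "design": {
            "design_id": fit.design.design_id,
            "age_coding": fit.design.age_coding,
            "adherence_coding": fit.design.adherence_coding,
            "tv_cutoff": fit.design.tv_cutoff,
            "n_knots": fit.design.n_knots,
        },
        "terms": fit.terms,
        "beta": fit.beta.tolist(),
        "vcov": fit.vcov.values.tolist(),
        "baseline": [fit.baseline_times.tolist(), fit.baseline_cumhaz.tolist()],
        "log_partial_likelihood": fit.log_partial_likelihood,
        "aic": fit.aic,
        "n_events": fit.n_events,
        "n": fit.n,
        "ties": fit.ties,
        "knots": None if fit.knots is None else np.asarray(fit.knots).tolist(),
        "age_range": None if fit.age_range is None else list(fit.age_range),
    }
    return json.dumps(payload)


def fit_from_json(s: str) -> CoxFit:
    d = json.loads(s)
    names = d["terms"]
    return CoxFit(
        design=DesignSpec(**d["design"]),
        beta=pd.Series(d["beta"], index=names),
        vcov=pd.DataFrame(d["vcov"], index=names, columns=names),
        baseline_times=np.asarray(d["baseline"][0], float),
        baseline_cumhaz=np.asarray(d["baseline"][1], float),
        log_partial_likelihood=d["log_partial_likelihood"],
        aic=d["aic"],
        n_events=d["n_events"],
        n=d["n"],
        ties=d["ties"],
        knots=None if d["knots"] is None else np.asarray(d["knots"], float),
        age_range=None if d["age_range"] is None else tuple(d["age_range"]),
    )
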