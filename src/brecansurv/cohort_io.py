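"""Cohort ingest, validation, inclusion filtering and baseline summaries.

The study population is a registry cohort of women with estrogen
receptor-positive breast cancer, stages I-III, diagnosed before age 85,
with a known five-year endocrine-therapy adherence rate.  Adherence is the
proportion of days covered by filled prescriptions over the treatment
period (at most five years); a refill gap of more than two months counts
as discontinuation, and patients are classified adherent when the rate
exceeds 80%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_COLUMNS = [
    "id", "age_dx", "sex", "year_dx", "stage", "her2", "er", "pr",
    "adherence_rate", "followup_years", "dead",
]

#: columns that must be present (pr and adherence_rate may hold missing values,
#: sex defaults to female when absent -- the cohort is female by design)
REQUIRED_COLUMNS = [
    "id", "age_dx", "year_dx", "stage", "her2", "er",
    "adherence_rate", "followup_years", "dead",
]

STAGE_LEVELS = ["I", "II", "III", "IV", "missing"]

ADHERENCE_CUTOFF = 0.80
#: "more than two months" refill gap, operationalized as a fixed day count
MAX_REFILL_GAP_DAYS = 61


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema or row-level contracts."""


@dataclass
class PatientRecord:
    """One subject: covariates at diagnosis, follow-up and vital status."""

    id: str
    age_dx: float
    sex: str
    year_dx: int
    stage: str
    her2: str
    er: str
    pr: str
    adherence_rate: float | None
    followup_years: float
    dead: bool
    #: simulator bookkeeping only; estimation code never reads it
    true_cause: str | None = None


@dataclass
class Cohort:
    """An ordered collection of patient records backed by a DataFrame."""

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].tolist()
            raise CohortValidationError(f"duplicate patient ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[PatientRecord]:
        cols = [c for c in self.df.columns if c in CANONICAL_COLUMNS + ["true_cause"]]
        for row in self.df[cols].itertuples(index=False):
            d = row._asdict()
            ar = d.get("adherence_rate")
            d["adherence_rate"] = None if pd.isna(ar) else float(ar)
            yield PatientRecord(**d)

    def with_adherence_class(self) -> pd.DataFrame:
        """Return the frame with an `adherence_class` column appended."""
        df = self.df.copy()
        rate = df["adherence_rate"]
        cls = pd.Series(
            np.where(rate > ADHERENCE_CUTOFF, "adherent", "non_adherent"),
            index=df.index,
        )
        df["adherence_class"] = cls.where(rate.notna())
        return df

    def to_csv(self, path) -> None:
        cols = [c for c in CANONICAL_COLUMNS + ["true_cause"] if c in self.df.columns]
        out = self.df[cols].copy()
        out["dead"] = out["dead"].astype(int)
        out.to_csv(path, index=False)


@dataclass
class RefillHistory:
    """Prescription coverage intervals, in days from the first refill."""

    prescription_intervals: list[tuple[float, float]]
    end_of_observation_day: float
    treatment_start_day: float = 0.0


def _normalize_intervals(history: RefillHistory) -> list[tuple[float, float]]:
    """Sort, clip to the observation window and merge touching intervals."""
    end = history.end_of_observation_day
    clipped = []
    n_clipped = 0
    for a, b in history.prescription_intervals:
        if b > end or a < history.treatment_start_day:
            n_clipped += 1
        a = max(a, history.treatment_start_day)
        b = min(b, end)
        if b > a:
            clipped.append((a, b))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} prescription interval(s) outside [start, observation end]"
            " were clipped", stacklevel=3,
        )
    clipped.sort()
    merged: list[tuple[float, float]] = []
    for a, b in clipped:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def compute_adherence_rate(history: RefillHistory) -> float:
    """Proportion of days covered over the treatment period.

    Coverage is truncated at the start of the first refill gap longer than
    :data:`MAX_REFILL_GAP_DAYS` (persistence interpretation of the
    two-month discontinuation rule); switches between endocrine drugs are
    continuation and are expected to be pre-merged into the intervals.
    """
    if history.end_of_observation_day <= 0:
        raise ValueError("end_of_observation_day must be positive")
    merged = _normalize_intervals(history)
    if not merged:
        warnings.warn("empty refill history; adherence rate 0", stacklevel=2)
        return 0.0
    covered = 0.0
    prev_end = history.treatment_start_day
    for a, b in merged:
        if a - prev_end > MAX_REFILL_GAP_DAYS:
            break  # therapy discontinued at prev_end
        covered += b - a
        prev_end = b
    rate = covered / (history.end_of_observation_day - history.treatment_start_day)
    return float(min(max(rate, 0.0), 1.0))


def classify_adherence(rate: float) -> str:
    """'adherent' iff the rate strictly exceeds 80%, else 'non_adherent'."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"adherence rate {rate} outside [0, 1]")
    return "adherent" if rate > ADHERENCE_CUTOFF else "non_adherent"


def _normalize_stage(value) -> str:
    if pd.isna(value):
        return "missing"
    s = str(value).strip().upper()
    mapping = {"1": "I", "2": "II", "3": "III", "4": "IV",
               "I": "I", "II": "II", "III": "III", "IV": "IV"}
    return mapping.get(s, "missing")


def _normalize_marker(value) -> str:
    """HER2 / ER / PR status to {'neg', 'pos', 'missing'}."""
    if pd.isna(value):
        return "missing"
    s = str(value).strip().lower()
    if s in {"pos", "positive", "+", "1", "yes", "true"}:
        return "pos"
    if s in {"neg", "negative", "-", "0", "no", "false"}:
        return "neg"
    return "missing"


def read_cohort(path, schema: dict[str, str] | None = None) -> Cohort:
    """Read a cohort CSV into a validated :class:`Cohort`.

    `schema` maps canonical column names to the file's column names, e.g.
    ``{"age_dx": "AgeAtDiagnosis"}``.  Rows violating row-level contracts
    (negative follow-up, unparseable age, adherence outside [0, 1]) are
    reported with their positions in a :class:`CohortValidationError`.
    """
    raw = pd.read_csv(path, dtype={schema.get("id", "id") if schema else "id": str})
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")

    df = pd.DataFrame(index=raw.index)
    df["id"] = raw["id"].astype(str)
    errors: list[str] = []

    def numeric(col: str, required: bool) -> pd.Series:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = raw[col].notna() & vals.isna()
        if bad.any():
            rows = list(raw.index[bad][:10])
            errors.append(f"column {col}: non-numeric values at rows {rows}")
        if required and raw[col].isna().any():
            rows = list(raw.index[raw[col].isna()][:10])
            errors.append(f"column {col}: missing values at rows {rows}")
        return vals

    df["age_dx"] = numeric("age_dx", required=True)
    df["year_dx"] = numeric("year_dx", required=True)
    df["followup_years"] = numeric("followup_years", required=True)
    df["adherence_rate"] = numeric("adherence_rate", required=False)
    df["sex"] = raw["sex"].astype(str) if "sex" in raw.columns else "female"
    df["stage"] = raw["stage"].map(_normalize_stage)
    for col in ("her2", "er"):
        df[col] = raw[col].map(_normalize_marker)
    df["pr"] = raw["pr"].map(_normalize_marker) if "pr" in raw.columns else "missing"
    dead = pd.to_numeric(
        raw["dead"].replace({"yes": 1, "no": 0, "True": 1, "False": 0}),
        errors="coerce",
    )
    if dead.isna().any():
        errors.append(
            f"column dead: unparseable values at rows {list(raw.index[dead.isna()][:10])}"
        )

    neg = df["followup_years"] < 0
    if neg.any():
        errors.append(f"negative followup_years at rows {list(raw.index[neg][:10])}")
    bad_adh = (df["adherence_rate"] < 0) | (df["adherence_rate"] > 1)
    if bad_adh.any():
        errors.append(
            f"adherence_rate outside [0, 1] at rows {list(raw.index[bad_adh][:10])}"
        )
    if errors:
        raise CohortValidationError("; ".join(errors))
    df["dead"] = dead.astype(bool)
    df["year_dx"] = df["year_dx"].astype(int)
    if "true_cause" in raw.columns:
        df["true_cause"] = raw["true_cause"]
    return Cohort(df.reset_index(drop=True), provenance=[f"read {path}: n={len(df)}"])


#: inclusion rules in application order: (name, mask of rows to drop)
_INCLUSION_RULES = [
    ("er_negative", lambda d: d["er"] != "pos"),
    ("stage_iv_or_missing", lambda d: d["stage"].isin(["IV", "missing"])),
    ("age_85_or_older", lambda d: d["age_dx"] >= 85),
    ("adherence_missing", lambda d: d["adherence_rate"].isna()),
]


def apply_inclusion_criteria(cohort: Cohort) -> tuple[Cohort, list[dict]]:
    """Apply the study's inclusion criteria, returning the filtered cohort
    and an ordered exclusion log ``[{rule, n_removed, n_remaining}, ...]``."""
    df = cohort.df
    log = []
    for name, rule in _INCLUSION_RULES:
        drop = rule(df)
        df = df.loc[~drop]
        log.append({"rule": name, "n_removed": int(drop.sum()), "n_remaining": len(df)})
    if len(df) == 0:
        warnings.warn("no patients remain after inclusion criteria", stacklevel=2)
    out = Cohort(
        df.reset_index(drop=True),
        provenance=cohort.provenance + [f"inclusion criteria: {len(cohort.df)} -> {len(df)}"],
    )
    return out, log


def exclusion_log_json(log: Sequence[dict]) -> str:
    return json.dumps(list(log), indent=2)


def summarize_cohort(
    cohort: Cohort,
    groupby: str,
    categorical: Sequence[str] | None = None,
    continuous: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Baseline table by `groupby`: counts (%) per level for categorical
    variables with chi-square p-values (no continuity correction), mean (SD)
    with two-sample t-test p-values for continuous ones.

    Levels of `groupby` with zero observations are dropped with a note.
    """
    df = cohort.with_adherence_class()
    if groupby not in df.columns:
        raise KeyError(f"unknown grouping variable {groupby!r}")
    if categorical is None:
        categorical = [c for c in ("stage", "her2", "er", "pr", "adherence_class")
                       if c != groupby]
    if continuous is None:
        continuous = ["age_dx", "followup_years"]

    groups = [g for g, sub in df.groupby(groupby, observed=True) if len(sub)]
    rows = []
    totals = df[groupby].value_counts()
    n_all = len(df)
    rows.append({
        "variable": "n", "level": "",
        **{g: f"{totals[g]} ({100 * totals[g] / n_all:.1f}%)" for g in groups},
        "p_value": np.nan, "test": "", "significant": "",
    })
    for var in categorical:
        tab = pd.crosstab(df[var], df[groupby])
        tab = tab[[g for g in groups if g in tab.columns]]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            p = np.nan
        else:
            _, p, _, _ = stats.chi2_contingency(tab.values, correction=False)
        for level in tab.index:
            rows.append({
                "variable": var, "level": str(level),
                **{g: f"{tab.loc[level, g]} ({100 * tab.loc[level, g] / tab[g].sum():.1f}%)"
                   for g in tab.columns},
                "p_value": p, "test": "chi-square",
                "significant": "*" if p == p and p < alpha else "",
            })
    for var in continuous:
        by = [df.loc[df[groupby] == g, var].dropna() for g in groups]
        if len(by) == 2 and all(len(b) > 1 for b in by):
            _, p = stats.ttest_ind(by[0], by[1])
        else:
            p = np.nan
        rows.append({
            "variable": var, "level": "mean (SD)",
            **{g: f"{b.mean():.1f} ({b.std(ddof=1):.1f})" for g, b in zip(groups, by)},
            "p_value": p, "test": "t-test",
            "significant": "*" if p == p and p < alpha else "",
        })
    return pd.DataFrame(rows)
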