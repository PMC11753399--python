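"""Fecal glucocorticoid sample preparation.

Sample-selection, outlier and covariate-coding rules that turn raw fecal
glucocorticoid (GC) records plus per-female demography into the
model-ready table consumed by the hierarchical models:

* reproductive-state assignment from offspring birth/death dates
  (gestation 158 days, split into early/late halves; nursing one year or
  until infant death; pre-reproductive under age 5);
* deterministic within-female sample thinning (study window, dry-mass
  floor, same-day earliest, consecutive-day collapse, ≤ 4 per calendar
  month chosen to maximize spread);
* population-level outlier removal (GC > mean + 10·SD on the raw scale;
  assay CV ≥ 20%);
* the join against the daily drought-index table with natural-log GC and
  z-scored continuous covariates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FemaleRecord",
    "GESTATION_DAYS",
    "DROUGHT_START",
    "assign_reproductive_state",
    "merge_state",
    "select_samples",
    "remove_outliers",
    "build_model_frame",
    "read_samples",
    "read_females",
]

#: average white-faced capuchin gestation, days
GESTATION_DAYS = 158

#: days of nursing following a birth (unless the infant dies first)
NURSING_DAYS = 365

#: age (years) below which a non-pregnant, non-nursing female is pre-reproductive
PRE_REPRODUCTIVE_AGE = 5.0

#: start of the severe El Niño drought; age and rank are fixed here for survival models
DROUGHT_START = pd.Timestamp("2014-05-15")

STATES = (
    "early_pregnancy",
    "late_pregnancy",
    "nursing",
    "pre_reproductive",
    "nonpregnant_nonnursing",
)
MERGED_STATES = ("not_pregnant", "early_pregnancy", "late_pregnancy")


@dataclass
class FemaleRecord:
    """Demography for one female: identity, birth, rank, fate, offspring."""

    female_id: str
    group_id: str
    birth_date: pd.Timestamp
    birth_date_error_years: float = 0.0
    rank: float = 0.5  # proportional rank in (0, 1]; 1.0 = highest
    survived_el_nino: bool | None = None
    death_window: tuple | None = None
    offspring: list = field(default_factory=list)  # [(birth, death-or-None), ...]
    group_size: float = np.nan

    def __post_init__(self):
        self.birth_date = pd.Timestamp(self.birth_date)
        if not (0 < self.rank <= 1):
            raise ValueError(f"rank must be in (0, 1], got {self.rank}")
        if self.survived_el_nino is False and self.death_window is None:
            raise ValueError(f"fatality {self.female_id} lacks a death window")
        self.offspring = [
            (pd.Timestamp(b), None if d is None or pd.isna(d) else pd.Timestamp(d))
            for b, d in self.offspring
        ]

    def age_at(self, date) -> float:
        return (pd.Timestamp(date) - self.birth_date).days / 365.25


def assign_reproductive_state(female: FemaleRecord, sample_date) -> str:
    """Reproductive state of ``female`` on ``sample_date`` (5-level coding).

    Conception is back-dated 158 days from each birth; days 0–78 after
    conception are early pregnancy and days 79–157 late pregnancy.  A
    female nurses for 365 days after a birth, or until the infant's death.
    Raises if two pregnancies overlap on the sample date.
    """
    date = pd.Timestamp(sample_date)
    pregnant_states = []
    for birth, _death in female.offspring:
        conception = birth - pd.Timedelta(days=GESTATION_DAYS)
        days_in = (date - conception).days
        if 0 <= days_in <= 78:
            pregnant_states.append("early_pregnancy")
        elif 79 <= days_in <= GESTATION_DAYS - 1:
            pregnant_states.append("late_pregnancy")
    if len(pregnant_states) > 1:
        raise ValueError(f"{female.female_id}: overlapping pregnancies on {date.date()}")
    if pregnant_states:
        return pregnant_states[0]
    for birth, death in female.offspring:
        days_post = (date - birth).days
        if 0 <= days_post < NURSING_DAYS and (death is None or date < death):
            return "nursing"
    if female.age_at(date) < PRE_REPRODUCTIVE_AGE:
        return "pre_reproductive"
    return "nonpregnant_nonnursing"


def merge_state(state: str) -> str:
    """Collapse the 5-level state to {not_pregnant, early_pregnancy, late_pregnancy}."""
    if state in ("early_pregnancy", "late_pregnancy"):
        return state
    if state not in STATES:
        raise ValueError(f"unknown reproductive state {state!r}")
    return "not_pregnant"


def _max_spread_subset(days: list, k: int) -> list:
    """The k-subset of sorted day-numbers that is most spread out.

    Maximizes the minimum pairwise gap, then the overall span (last −
    first), with remaining ties broken toward earlier dates
    (lexicographically smallest subset).  Exhaustive over all k-subsets;
    month-level inputs are tiny.
    """
    best, best_key = None, None
    for subset in itertools.combinations(days, k):
        gap = min(b - a for a, b in zip(subset, subset[1:]))
        key = (gap, subset[-1] - subset[0])
        if best_key is None or key > best_key:
            best, best_key = subset, key
    return list(best)


def select_samples(
    samples: pd.DataFrame,
    study_window=("2008-01-01", "2013-12-31"),
    min_dry_mass_g: float = 0.1,
    max_per_month: int = 4,
) -> pd.DataFrame:
    """Apply the within-female sample selection rules.

    In order: (1) restrict to the study window; (2) drop samples with less
    than ``min_dry_mass_g`` of dry matter; (3) keep the earliest sample of
    each day; (4) collapse each run of consecutive days to its first and
    last day (a 2-day run keeps only its first day, so no two retained
    samples are ever on consecutive days); (5) cap each female-month at
    ``max_per_month`` samples, choosing the subset that maximizes the
    minimum date gap, earlier dates on ties.  Deterministic and idempotent.
    """
    required = {"female_id", "date", "collection_time_min", "gc_ng_per_g"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table missing columns: {sorted(missing)}")
    df = samples.copy()
    df["date"] = pd.to_datetime(df["date"])
    lo, hi = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    df = df[(df["date"] >= lo) & (df["date"] <= hi)]
    if "dry_mass_g" in df.columns:
        df = df[df["dry_mass_g"].isna() | (df["dry_mass_g"] >= min_dry_mass_g)]
    df = df.sort_values(["female_id", "date", "collection_time_min"], kind="mergesort")
    # (3) earliest sample per female-day
    df = df.groupby(["female_id", "date"], as_index=False).first()

    kept_parts = []
    for _, g in df.groupby("female_id", sort=False):
        g = g.sort_values("date")
        days = g["date"].map(pd.Timestamp.toordinal).to_numpy()
        # (4) split into runs of consecutive days
        run_starts = np.flatnonzero(np.diff(days, prepend=days[0] - 2) > 1)
        keep = np.zeros(len(days), bool)
        for s, e in zip(run_starts, np.append(run_starts[1:], len(days))):
            keep[s] = True
            if e - s >= 3:
                keep[e - 1] = True
        g = g[keep]
        # (5) monthly cap, max-min-gap subset
        sel = []
        for _, m in g.groupby(g["date"].dt.to_period("M"), sort=True):
            if len(m) <= max_per_month:
                sel.append(m)
            else:
                mdays = m["date"].dt.day.tolist()
                chosen = _max_spread_subset(mdays, max_per_month)
                sel.append(m[m["date"].dt.day.isin(chosen)])
        if sel:
            kept_parts.append(pd.concat(sel))
    if not kept_parts:
        return df.iloc[0:0]
    return pd.concat(kept_parts).sort_values(["female_id", "date"]).reset_index(drop=True)


def remove_outliers(
    samples: pd.DataFrame, sd_threshold: float = 10.0, cv_threshold: float = 0.20
):
    """Drop GC outliers and high-CV assays across the pooled candidate set.

    A sample is removed if its raw GC concentration exceeds the mean of
    the remaining samples by more than ``sd_threshold`` of their standard
    deviations.  Flagging peels iteratively from the most extreme value
    down, each time recomputing mean/SD over the not-yet-flagged samples,
    so a cluster of contaminated values cannot mask itself by inflating
    the SD it is judged against.  Samples whose duplicate-well assay CV
    is ``cv_threshold`` or worse are also removed.  Returns
    ``(retained, log)`` where the log records one row per removal with
    the reason.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to estimate an outlier threshold")
    gc = samples["gc_ng_per_g"].to_numpy(float)
    is_gc_outlier = np.zeros(len(gc), bool)
    while True:
        unflagged = np.flatnonzero(~is_gc_outlier)
        if len(unflagged) < 3:
            break
        worst = unflagged[np.argmax(gc[unflagged])]
        rest = gc[unflagged[unflagged != worst]]
        if gc[worst] > rest.mean() + sd_threshold * rest.std(ddof=1):
            is_gc_outlier[worst] = True
        else:
            break
    if "assay_cv" in samples.columns:
        cv = samples["assay_cv"].to_numpy(float)
        is_cv_bad = ~np.isnan(cv) & (cv >= cv_threshold)
    else:
        is_cv_bad = np.zeros(len(samples), bool)
    reasons = np.where(is_gc_outlier, "gc_above_10sd", np.where(is_cv_bad, "assay_cv", ""))
    removed = samples[is_gc_outlier | is_cv_bad].copy()
    removed["reason"] = reasons[is_gc_outlier | is_cv_bad]
    retained = samples[~(is_gc_outlier | is_cv_bad)].copy()
    return retained.reset_index(drop=True), removed.reset_index(drop=True)


def _scale(x: np.ndarray) -> np.ndarray:
    # constant columns carry no information; map them to zeros
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def build_model_frame(
    samples: pd.DataFrame,
    females: dict,
    index_table: pd.DataFrame,
    drought_start=DROUGHT_START,
) -> pd.DataFrame:
    """Join per-date drought indices onto retained samples and code covariates.

    GC is natural-log transformed.  Collection time, age (at the drought
    start, plus age at the sample date for the covariate screen), rank and
    group size are z-scored over the included rows; drought risk and
    expected rainfall stay on their native SD scales.  One output row per
    input sample; unmatched females or dates raise, listing the offenders.
    """
    df = samples.copy()
    df["date"] = pd.to_datetime(df["date"])
    unknown = sorted(set(df["female_id"]) - set(females))
    if unknown:
        raise KeyError(f"samples reference unknown females: {unknown}")
    idx = index_table.set_index(pd.to_datetime(index_table["date"]))
    missing_dates = sorted(set(df["date"]) - set(idx.index))
    if missing_dates:
        raise KeyError(
            f"no drought-index record for sample dates: {[str(d.date()) for d in missing_dates[:10]]}"
        )
    joined = idx.loc[df["date"], ["drought_risk", "expected_rainfall"]].to_numpy()
    bad = np.isnan(joined).any(axis=1)
    if bad.any():
        offenders = df.loc[bad, "date"].dt.strftime("%Y-%m-%d").unique().tolist()
        raise ValueError(f"drought index undefined on sample dates: {offenders[:10]}")

    recs = [females[f] for f in df["female_id"]]
    state5 = [assign_reproductive_state(r, d) for r, d in zip(recs, df["date"])]
    frame = pd.DataFrame(
        {
            "female_id": df["female_id"].to_numpy(),
            "group_id": [r.group_id for r in recs],
            "log_gc": np.log(df["gc_ng_per_g"].to_numpy(float)),
            "drought_risk": joined[:, 0],
            "expected_rainfall": joined[:, 1],
            "collection_time_scaled": _scale(df["collection_time_min"].to_numpy(float)),
            "state": state5,
            "merged_state": [merge_state(s) for s in state5],
            "age_scaled": _scale(
                np.array([r.age_at(drought_start) for r in recs], float)
            ),
            "age_at_sample_scaled": _scale(
                np.array([r.age_at(d) for r, d in zip(recs, df["date"])], float)
            ),
            "rank_scaled": _scale(np.array([r.rank for r in recs], float)),
            "group_size_scaled": _scale(np.array([r.group_size for r in recs], float)),
            "survived": [
                np.nan if r.survived_el_nino is None else int(r.survived_el_nino)
                for r in recs
            ],
        }
    )
    if len(frame) != len(samples):
        raise AssertionError("model frame dropped rows during the join")
    return frame


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def read_females(path) -> dict:
    """Read a demographics table into {female_id: FemaleRecord}.

    Offspring are encoded in one column as ``birth:death|birth:`` pairs
    separated by ``;`` (empty death = infant alive past one year).
    """
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        offspring = []
        cell = row.get("offspring")
        if isinstance(cell, str) and cell.strip():
            for item in cell.split(";"):
                b, _, d = item.partition(":")
                offspring.append((pd.Timestamp(b), pd.Timestamp(d) if d else None))
        death_window = None
        if isinstance(row.get("death_earliest"), str) and row["death_earliest"]:
            death_window = (
                pd.Timestamp(row["death_earliest"]),
                pd.Timestamp(row["death_latest"]),
            )
        survived = row.get("survived_el_nino")
        out[row["female_id"]] = FemaleRecord(
            female_id=row["female_id"],
            group_id=str(row["group_id"]),
            birth_date=pd.Timestamp(row["birth_date"]),
            birth_date_error_years=float(row.get("birth_date_error_years", 0.0)),
            rank=float(row["rank"]),
            survived_el_nino=None if pd.isna(survived) else bool(survived),
            death_window=death_window,
            offspring=offspring,
            group_size=float(row.get("group_size", np.nan)),
        )
    return out
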