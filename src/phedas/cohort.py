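"""Cohort construction: censoring, control matching, aggregate measures.

The analysis dataset is one row per subject: a per-phecode aggregate measure
``m_k`` (presence, occurrence count, or first-to-last duration in years), an
age covariate ``a_k``, a sex covariate ``s_k`` (female=1, male=0) and the
case/control label ``y``.  Before aggregation, visits may be censored three
ways: by an absolute age interval, or by a window of years before
(left-censoring) or after (right-censoring) the index diagnosis.  Window
bounds are closed on the side nearest diagnosis (year 0 included) and open at
the far bound; the age interval is closed below.

Controls have no diagnosis of their own under left/right censoring; each
matched control inherits its case's diagnosis age as a reference age so the
same window applies to both arms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "CensorWindow",
    "load_visits",
    "load_subjects",
    "censor_visits",
    "match_controls",
    "aggregate",
    "MEASURES",
]

MEASURES = ("binary", "count", "duration")

SEX_CODES = {"female": 1, "male": 0, "f": 1, "m": 0, "1": 1, "0": 0}


@dataclass(frozen=True)
class CensorWindow:
    """Visit-extraction window.

    mode
        ``age_interval``: keep visits with ``lo <= age < hi`` (absolute age).
        ``left_censor``: keep visits ``lo``-``hi`` years *before* diagnosis.
        ``right_censor``: keep visits ``lo``-``hi`` years *after* diagnosis.
    bounds in years; ``hi`` may be ``inf`` for age_interval.
    """

    mode: Literal["age_interval", "left_censor", "right_censor"]
    lo: float
    hi: float

    def __post_init__(self):
        if self.mode not in ("age_interval", "left_censor", "right_censor"):
            raise ConfigError(f"unknown censor mode {self.mode!r}")
        if not self.lo < self.hi:
            raise ConfigError(
                f"censor window requires lo < hi, got [{self.lo}, {self.hi}]"
            )


def load_visits(path: str | Path) -> pd.DataFrame:
    """Read visit rows: CSV ``subject_id,age_at_visit,icd9``."""
    df = pd.read_csv(path, dtype={"subject_id": str, "icd9": str})
    missing = {"subject_id", "age_at_visit", "icd9"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: visits file missing columns {sorted(missing)}")
    df["age_at_visit"] = df["age_at_visit"].astype(float)
    if (df["age_at_visit"] < 0).any():
        raise ConfigError(f"{path}: negative age_at_visit")
    return df


def load_subjects(path: str | Path) -> pd.DataFrame:
    """Read the subject table: CSV ``subject_id,sex,is_case[,diagnosis_age]``."""
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str})
    missing = {"subject_id", "sex", "is_case"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: subjects file missing columns {sorted(missing)}")
    df["is_case"] = df["is_case"].astype(int).astype(bool)
    if "diagnosis_age" not in df.columns:
        df["diagnosis_age"] = np.nan
    df["diagnosis_age"] = df["diagnosis_age"].astype(float)
    bad = df["diagnosis_age"].lt(0) | np.isinf(df["diagnosis_age"].fillna(0))
    if bad.any():
        raise ConfigError(f"{path}: diagnosis_age must be finite and >= 0")
    return df


def censor_visits(
    visits: pd.DataFrame, subjects: pd.DataFrame, window: CensorWindow
) -> pd.DataFrame:
    """Restrict visits to the study window.

    For ``left_censor``/``right_censor`` every subject (cases by definition,
    controls via their inherited reference age) must carry ``diagnosis_age``;
    missing values raise a ConfigError naming the offending subjects.
    Idempotent: censoring an already-censored frame changes nothing.
    """
    if window.mode == "age_interval":
        keep = (visits["age_at_visit"] >= window.lo) & (
            visits["age_at_visit"] < window.hi
        )
        return visits.loc[keep].reset_index(drop=True)

    ref = subjects.set_index("subject_id")["diagnosis_age"]
    used = visits["subject_id"].unique()
    missing = [s for s in used if s not in ref.index or math.isnan(ref[s])]
    if missing:
        raise ConfigError(
            f"{window.mode} requires diagnosis_age (or inherited reference age) "
            f"for every subject; missing for: {sorted(missing)[:10]}"
        )
    dx = visits["subject_id"].map(ref)
    age = visits["age_at_visit"]
    if window.mode == "left_censor":
        # closed at the diagnosis-near bound (dx - lo), open at the far bound
        keep = (age > dx - window.hi) & (age <= dx - window.lo)
    else:  # right_censor
        keep = (age >= dx + window.lo) & (age < dx + window.hi)
    return visits.loc[keep].reset_index(drop=True)


def match_controls(
    cases: pd.DataFrame,
    control_pool: pd.DataFrame,
    ratio: int = 1,
    exclusions: Iterable[str] = (),
    seed: int = 0,
    pool_phecodes: Mapping[str, set] | None = None,
) -> pd.DataFrame:
    """Select age- and sex-matched controls for each case.

    Greedy nearest-neighbour on age within exact sex strata, processing cases
    in descending age order; sampling is without replacement and deterministic
    given ``seed``.  Pool members carrying any exclusion phecode for the index
    disease (``pool_phecodes`` maps subject_id -> set of phecodes) are removed
    before matching.  When a stratum runs out a warning is issued and fewer
    controls are returned — a control is never reused.

    Matched controls inherit their case's ``diagnosis_age`` as reference age
    (column overwritten in the returned frame) and gain a ``matched_case``
    column.
    """
    if ratio < 1:
        raise ConfigError("matching ratio must be >= 1")
    overlap = set(cases["subject_id"]) & set(control_pool["subject_id"])
    if overlap:
        raise ConfigError(f"control pool overlaps cases: {sorted(overlap)[:5]}")
    pool = control_pool.copy()
    if exclusions and pool_phecodes is not None:
        excl = set(exclusions)
        carrying = pool["subject_id"].map(
            lambda s: bool(excl & set(pool_phecodes.get(s, ())))
        )
        pool = pool.loc[~carrying]

    rng = np.random.default_rng(seed)
    # reference age for matching: diagnosis age when present, else not matchable
    def _age(df):
        return df["diagnosis_age"]

    picked_rows = []
    used: set[str] = set()
    # descending case-age order; equal-aged cases processed in seeded order
    order = cases.assign(_r=rng.random(len(cases))).sort_values(
        ["diagnosis_age", "_r"], ascending=[False, True]
    )
    pool_by_sex = {s: g for s, g in pool.groupby("sex")}
    for _, case in order.iterrows():
        stratum = pool_by_sex.get(case["sex"])
        if stratum is None:
            warnings.warn(
                f"no controls available for sex {case['sex']!r}", stacklevel=2
            )
            continue
        avail = stratum.loc[~stratum["subject_id"].isin(used)]
        if len(avail) < ratio:
            warnings.warn(
                f"control pool exhausted for sex {case['sex']!r}: "
                f"{len(avail)} of {ratio} controls for case {case['subject_id']}",
                stacklevel=2,
            )
        if len(avail) == 0:
            continue
        diff = (_age(avail) - case["diagnosis_age"]).abs()
        # ties broken by subject id: fully deterministic candidate order
        chosen = (
            avail.assign(_d=diff.fillna(np.inf))
            .sort_values(["_d", "subject_id"])
            .head(ratio)
            .drop(columns="_d")
        )
        chosen = chosen.assign(
            diagnosis_age=case["diagnosis_age"], matched_case=case["subject_id"]
        )
        used.update(chosen["subject_id"])
        picked_rows.append(chosen)
    if not picked_rows:
        return control_pool.head(0).assign(matched_case=pd.Series(dtype=str))
    return pd.concat(picked_rows, ignore_index=True)


def aggregate(
    mapped_visits: pd.DataFrame,
    subjects: pd.DataFrame,
    measure: str = "binary",
    phecodes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Build the per-subject aggregate matrix.

    Parameters
    ----------
    mapped_visits : DataFrame
        Censored, phecode-mapped visits (``subject_id``, ``age_at_visit``,
        ``phecode``).
    subjects : DataFrame
        Subject table; every subject appears as a row even with no visits.
    measure : {"binary", "count", "duration"}
        binary: 1 iff the phecode occurs at least once; count: number of visit
        rows with the phecode; duration: years between first and last
        occurrence (0 for a single occurrence).
    phecodes : optional
        Column universe; defaults to the phecodes observed in the visits.

    Returns
    -------
    DataFrame indexed by subject_id with one column per phecode plus ``age``
    (mean age over the subject's censored visits, falling back to the
    reference/diagnosis age), ``sex`` (female=1, male=0) and ``y``.
    Unknown-sex subjects are dropped with a warning.
    """
    if measure not in MEASURES:
        raise ConfigError(f"unknown measure {measure!r}; choose from {MEASURES}")

    subj = subjects.copy()
    sex_num = subj["sex"].astype(str).str.strip().str.lower().map(SEX_CODES)
    unknown = sex_num.isna()
    if unknown.any():
        warnings.warn(
            f"dropping {int(unknown.sum())} subjects with unknown sex", stacklevel=2
        )
        subj = subj.loc[~unknown.values]
        sex_num = sex_num.loc[~unknown.values]
    subj = subj.set_index("subject_id")
    ids = subj.index

    mv = mapped_visits[mapped_visits["subject_id"].isin(ids)]
    if phecodes is None:
        phecodes = sorted(mv["phecode"].unique())
    else:
        phecodes = sorted(set(phecodes))

    if measure == "binary":
        wide = (
            mv.pivot_table(
                index="subject_id", columns="phecode", values="age_at_visit",
                aggfunc="size", fill_value=0,
            ).gt(0).astype(int)
        )
    elif measure == "count":
        wide = mv.pivot_table(
            index="subject_id", columns="phecode", values="age_at_visit",
            aggfunc="size", fill_value=0,
        ).astype(int)
    else:  # duration
        span = mv.groupby(["subject_id", "phecode"])["age_at_visit"].agg(
            lambda a: a.max() - a.min()
        )
        wide = span.unstack(fill_value=0.0)

    wide = wide.reindex(index=ids, columns=phecodes, fill_value=0)
    if measure == "duration":
        wide = wide.astype(float)

    mean_age = mv.groupby("subject_id")["age_at_visit"].mean().reindex(ids).astype(float)
    age = mean_age.fillna(subj["diagnosis_age"].astype(float))

    out = wide.copy()
    out["age"] = age
    out["sex"] = sex_num.values
    out["y"] = subj["is_case"].astype(int)
    out.attrs["measure"] = measure
    out.attrs["phecodes"] = list(phecodes)
    return out
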