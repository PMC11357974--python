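"""Cohort construction: index dates, gold labels, inclusion, splits.

The analysis cohort is every patient with a claims-identified lung-cancer
diagnosis (ICD-10 C34 family) in the study years, age-eligible at the index
date, and continuously enrolled in Medicare Parts A, B and D with no HMO
coverage for the 12 calendar months before the index month. The index date
is the first day of the registry diagnosis month; the registry histology of
the tumor record closest to the claims-based diagnosis month supplies the
gold SCLC/NSCLC label (small cell = ICD-O-3 8002, 8041-8045). Observation
runs from the index date to the earliest of index+180 days, the start of the
first non-enrolled month, or death.

Conventions (documented, configurable where noted):

* the claims-based diagnosis month is the month of the *earliest* qualifying
  diagnosis claim;
* age is completed years at the index date;
* follow-up windows are half-open, ``[index, index+180)``;
* tumor-record ties are broken by earlier diagnosis month, then smaller
  histology code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import month_index, month_index_of_period, month_start
from .codesets import (
    CodeSetRegistry,
    CodeSystem,
    builtin_registry,
    systemic_therapy_union,
)
from .synth import NSCLC, SCLC, SyntheticPopulation

logger = logging.getLogger(__name__)

FOLLOWUP_DAYS = 180


@dataclass
class InclusionCriteria:
    """Cohort inclusion parameters.

    ``min_age``/``max_age`` bound completed age at the index date (the
    default ``min_age=66`` guarantees a full 12-month Medicare history; the
    younger-population sensitivity analysis uses 19-65). ``require_lookback``
    lets the younger-population analysis optionally drop the enrollment
    requirement.
    """

    diagnosis_years: frozenset[int] = field(default_factory=lambda: frozenset({2016, 2017}))
    min_age: int = 66
    max_age: int | None = None
    lookback_months: int = 12
    require_lookback: bool = True

    def __post_init__(self) -> None:
        if self.max_age is not None and self.min_age > self.max_age:
            raise ValueError("min_age must be <= max_age")
        if self.lookback_months < 0:
            raise ValueError("lookback_months must be >= 0")


def derive_index_date(diagnosis_month: str | pd.Period) -> pd.Timestamp:
    """First day of the registry diagnosis month."""
    p = pd.Period(diagnosis_month, freq="M")
    return pd.Timestamp(p.start_time.date())


def select_tumor_record(tumors: pd.DataFrame, claims_dx_month: str | pd.Period) -> pd.Series:
    """Pick the tumor record closest (in months) to the claims diagnosis month.

    Ties go to the earlier diagnosis month, then the smaller histology code.
    """
    if len(tumors) == 0:
        raise ValueError("no tumor records to select from")
    target = pd.Period(claims_dx_month, freq="M")
    t_midx = target.year * 12 + target.month - 1
    midx = month_index_of_period(tumors["diagnosis_month"])
    order = pd.DataFrame(
        {
            "absdiff": (midx - t_midx).abs(),
            "midx": midx,
            "histology": tumors["histology"].astype(str),
        },
        index=tumors.index,
    ).sort_values(["absdiff", "midx", "histology"], kind="stable")
    return tumors.loc[order.index[0]]


def gold_label(histology: str, registry: CodeSetRegistry | None = None) -> str:
    """SCLC iff the ICD-O-3 histology is in the small-cell set, else NSCLC."""
    registry = registry or builtin_registry()
    cs = registry["sclc_histology"]
    return SCLC if cs.match(str(histology), CodeSystem.ICDO3_HIST) else NSCLC


def _age_at(index_date: pd.Series, birth_date: pd.Series) -> np.ndarray:
    """Completed years between birth and index, elementwise."""
    iy, im, iday = index_date.dt.year, index_date.dt.month, index_date.dt.day
    by, bm, bday = birth_date.dt.year, birth_date.dt.month, birth_date.dt.day
    before_birthday = (im.values < bm.values) | ((im.values == bm.values) & (iday.values < bday.values))
    return iy.values - by.values - before_birthday.astype(int)


def apply_inclusion(
    pop: SyntheticPopulation,
    criteria: InclusionCriteria | None = None,
    registry: CodeSetRegistry | None = None,
) -> pd.DataFrame:
    """Build the analysis cohort from a linked population.

    Returns one row per included patient with columns ``patient_id``,
    ``index_date``, ``gold_label``, ``age``, ``observation_end``,
    ``censor_reason`` and ``treated``. Per-stage attrition counts are logged
    and stored in ``result.attrs["attrition"]``.
    """
    criteria = criteria or InclusionCriteria()
    registry = registry or builtin_registry()
    attrition: dict[str, int] = {"source_patients": len(pop.patients)}

    # (a) claims-based lung-cancer diagnosis in the study years
    lung = registry["lung_cancer_dx"]
    claims = pop.claims
    sysmask = claims["system"] == lung.system.value
    codes = claims.loc[sysmask, "code"].astype(str).str.strip().str.upper().str.replace(
        ".", "", regex=False
    )
    hit = codes.str.startswith(tuple(lung.codes))
    dx = claims.loc[hit[hit].index]
    dx = dx[dx["service_date"].dt.year.isin(criteria.diagnosis_years)]
    first_dx = dx.groupby("patient_id")["service_date"].min()
    attrition["claims_diagnosed"] = len(first_dx)

    base = first_dx.rename("first_dx_date").reset_index()
    base["claims_dx_midx"] = month_index(base["first_dx_date"])

    # registry tumor record closest to the claims diagnosis month
    tumors = pop.tumors.merge(base[["patient_id", "claims_dx_midx"]], on="patient_id", how="inner")
    no_tumor = set(base["patient_id"]) - set(tumors["patient_id"])
    if no_tumor:
        logger.warning("excluding %d diagnosed patients with no registry tumor record", len(no_tumor))
    tumors["midx"] = month_index_of_period(tumors["diagnosis_month"]).to_numpy()
    tumors["absdiff"] = (tumors["midx"] - tumors["claims_dx_midx"]).abs()
    tumors["histology"] = tumors["histology"].astype(str)
    selected = (
        tumors.sort_values(["patient_id", "absdiff", "midx", "histology"], kind="stable")
        .drop_duplicates("patient_id", keep="first")
    )
    attrition["with_tumor_record"] = len(selected)

    cohort = selected[["patient_id", "midx", "histology"]].copy()
    cohort["index_date"] = month_start(cohort["midx"].astype(int)).to_numpy()
    sclc_set = registry["sclc_histology"]
    cohort["gold_label"] = np.where(
        cohort["histology"].isin(sclc_set.codes), SCLC, NSCLC
    )

    cohort = cohort.merge(
        pop.patients[["patient_id", "birth_date", "death_date"]], on="patient_id", how="left"
    )
    cohort["age"] = _age_at(cohort["index_date"], cohort["birth_date"])

    # (b) age bounds at index
    ok = cohort["age"] >= criteria.min_age
    if criteria.max_age is not None:
        ok &= cohort["age"] <= criteria.max_age
    cohort = cohort[ok]
    attrition["age_eligible"] = len(cohort)

    # (c) continuous A/B/D, no-HMO enrollment in the lookback months
    enr = pop.enrollment
    eligible = enr[
        enr["part_a"].astype(bool)
        & enr["part_b"].astype(bool)
        & enr["part_d"].astype(bool)
        & ~enr["hmo"].astype(bool)
    ]
    emidx = month_index_of_period(eligible["month"])
    epairs = pd.DataFrame(
        {"patient_id": eligible["patient_id"].to_numpy(), "midx": emidx.to_numpy()}
    ).drop_duplicates()
    epairs = epairs.merge(
        cohort[["patient_id", "midx"]].rename(columns={"midx": "index_midx"}),
        on="patient_id",
        how="inner",
    )
    epairs["offset"] = epairs["midx"] - epairs["index_midx"]

    if criteria.require_lookback and criteria.lookback_months > 0:
        look = epairs[(epairs["offset"] >= -criteria.lookback_months) & (epairs["offset"] <= -1)]
        n_covered = look.groupby("patient_id")["offset"].nunique()
        full = n_covered[n_covered == criteria.lookback_months].index
        cohort = cohort[cohort["patient_id"].isin(full)]
    attrition["lookback_eligible"] = len(cohort)

    # observation end: earliest of window end, disenrollment, death
    horizon_months = FOLLOWUP_DAYS // 28 + 1  # months that can intersect the window
    post = epairs[(epairs["offset"] >= 0) & (epairs["offset"] <= horizon_months)]
    covered = post.groupby("patient_id")["offset"].apply(frozenset)
    cohort = cohort.merge(covered.rename("covered"), on="patient_id", how="left")

    def first_gap(s) -> int | float:
        if not isinstance(s, frozenset):
            return 0  # no enrolled months at all after index
        for k in range(horizon_months + 2):
            if k not in s:
                return k
        return np.inf

    gap = cohort["covered"].map(first_gap)
    window_end = cohort["index_date"] + pd.to_timedelta(FOLLOWUP_DAYS, unit="D")
    disenroll = pd.Series(pd.NaT, index=cohort.index, dtype="datetime64[ns]")
    finite = gap < np.inf
    disenroll[finite] = month_start(
        (cohort.loc[finite, "midx"] + gap[finite]).astype(int)
    ).to_numpy()

    ends = pd.concat(
        [
            window_end.rename("window_end"),
            disenroll.rename("disenrollment"),
            cohort["death_date"].rename("death"),
        ],
        axis=1,
    )
    obs_end = ends.min(axis=1, skipna=True)
    obs_end = obs_end.clip(lower=cohort["index_date"])
    reason = pd.Series("window_end", index=cohort.index)
    reason[obs_end.eq(ends["disenrollment"])] = "disenrollment"
    reason[obs_end.eq(ends["death"])] = "death"  # death wins exact ties
    cohort["observation_end"] = obs_end
    cohort["censor_reason"] = reason

    # treated: >=1 outpatient claim matching any systemic-therapy set in-window
    union = systemic_therapy_union(registry)
    treated_ids: set = set()
    idx_map = cohort.set_index("patient_id")["index_date"]
    for system, codeset in union.items():
        sub = claims[
            (claims["system"] == system.value) & (claims["setting"] == "outpatient")
        ]
        sub = sub[sub["code"].astype(str).str.strip().str.upper().isin(codeset)]
        sub = sub[sub["patient_id"].isin(idx_map.index)]
        if sub.empty:
            continue
        rel = (sub["service_date"] - sub["patient_id"].map(idx_map)).dt.days
        sub = sub[(rel >= 0) & (rel < FOLLOWUP_DAYS)]
        treated_ids.update(sub["patient_id"].unique())
    cohort["treated"] = cohort["patient_id"].isin(treated_ids)

    out = cohort[
        [
            "patient_id",
            "index_date",
            "gold_label",
            "age",
            "observation_end",
            "censor_reason",
            "treated",
        ]
    ].reset_index(drop=True)
    attrition["final"] = len(out)
    logger.info("cohort attrition: %s", attrition)
    out.attrs["attrition"] = attrition
    return out


def split_sample(
    cohort: pd.DataFrame, fraction: float = 0.25, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact-size random partition into (exploration, validation).

    The exploration sample has ``round(fraction * N)`` members; the two parts
    are disjoint and exhaustive, and the partition is deterministic in
    *seed*.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(cohort)
    k = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    expl = cohort.iloc[np.sort(perm[:k])].reset_index(drop=True)
    valid = cohort.iloc[np.sort(perm[k:])].reset_index(drop=True)
    return expl, valid
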