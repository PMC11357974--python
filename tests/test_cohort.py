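"""Cohort construction: unit examples, a brute-force re-inclusion oracle,
and split arithmetic."""

import numpy as np
import pandas as pd
import pytest

import sclcphen as sp
from sclcphen.codesets import CodeSystem, SYSTEMIC_THERAPY_SETS


# --- small helpers ----------------------------------------------------------

def months(start: str, end: str) -> list[str]:
    return [str(p) for p in pd.period_range(start, end, freq="M")]


def mini_population() -> sp.SyntheticPopulation:
    """Handcrafted linked tables exercising each inclusion rule."""
    patients = []
    tumors = []
    enrollment = []
    claims = []

    def add(pid, birth, tumor_rows, enr_months, claim_rows, death=None):
        patients.append((pid, birth, death, "F", "White"))
        for m, hist in tumor_rows:
            tumors.append((pid, m, hist, "distant"))
        for m in enr_months:
            enrollment.append((pid, m, True, True, True, False))
        for date, code, system, setting in claim_rows:
            claims.append((pid, date, code, system, setting))

    full = months("2015-03", "2016-09")
    dx = ("2016-03-10", "C34.1", "ICD10CM_DX", "outpatient")

    # p1: eligible SCLC, treated via outpatient etoposide
    add(1, "1946-01-15", [("2016-03", "8041")], full,
        [dx, ("2016-04-01", "J9181", "HCPCS_CPT", "outpatient")])
    # p2: age 65 at index -> excluded
    add(2, "1951-02-01", [("2016-03", "8041")], full, [dx])
    # p3: missing a lookback month -> excluded
    add(3, "1946-01-15", [("2016-03", "8041")],
        [m for m in full if m != "2015-12"], [dx])
    # p4: dies at index+90 -> censored at death
    add(4, "1940-06-01", [("2016-03", "8140")], full, [dx], death="2016-05-30")
    # p5: two tumor records; claims month 2016-03 -> nearer 2016-02 record wins
    add(5, "1940-06-01", [("2016-02", "8140"), ("2017-01", "8041")],
        months("2015-02", "2016-09"), [dx])
    # p6: EGFR testing only -> not treated
    add(6, "1940-06-01", [("2016-03", "8140")], full,
        [dx, ("2016-04-01", "81235", "HCPCS_CPT", "outpatient")])
    # p7: disenrolls 2 months after index -> censored at that month start
    add(7, "1940-06-01", [("2016-03", "8140")], months("2015-03", "2016-04"), [dx])
    # p8: diagnosis claim outside the study years -> excluded
    add(8, "1940-06-01", [("2015-06", "8041")], months("2014-06", "2015-12")
        , [("2015-06-10", "C34.1", "ICD10CM_DX", "outpatient")])
    # p9: inpatient-setting etoposide only -> not treated
    add(9, "1940-06-01", [("2016-03", "8140")], full,
        [dx, ("2016-04-01", "J9181", "HCPCS_CPT", "inpatient")])

    return sp.SyntheticPopulation(
        patients=pd.DataFrame(
            patients, columns=["patient_id", "birth_date", "death_date", "sex", "race"]
        ).assign(
            birth_date=lambda d: pd.to_datetime(d["birth_date"]),
            death_date=lambda d: pd.to_datetime(d["death_date"]),
        ),
        tumors=pd.DataFrame(tumors, columns=["patient_id", "diagnosis_month", "histology", "stage"]),
        enrollment=pd.DataFrame(
            enrollment, columns=["patient_id", "month", "part_a", "part_b", "part_d", "hmo"]
        ),
        claims=pd.DataFrame(
            claims, columns=["patient_id", "service_date", "code", "system", "setting"]
        ).assign(service_date=lambda d: pd.to_datetime(d["service_date"])),
    )


# --- unit examples ----------------------------------------------------------

@pytest.mark.parametrize(
    "month,expected",
    [("2016-03", "2016-03-01"), ("2017-12", "2017-12-01"), ("2016-02", "2016-02-01")],
)
def test_derive_index_date(month, expected):
    assert sp.derive_index_date(month) == pd.Timestamp(expected)


class TestSelectTumorRecord:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "diagnosis_month", "histology", "stage"])

    def test_single_record_identity(self):
        df = self._df([(1, "2016-05", "8041", "")])
        assert sp.select_tumor_record(df, "2016-01")["diagnosis_month"] == "2016-05"

    def test_closest_month_wins(self):
        df = self._df([(1, "2016-02", "8140", ""), (1, "2017-01", "8041", "")])
        assert sp.select_tumor_record(df, "2016-03")["diagnosis_month"] == "2016-02"

    def test_tie_broken_by_earlier_month(self):
        df = self._df([(1, "2016-04", "8041", ""), (1, "2016-02", "8140", "")])
        assert sp.select_tumor_record(df, "2016-03")["diagnosis_month"] == "2016-02"

    def test_same_month_tie_broken_by_smaller_histology(self):
        df = self._df([(1, "2016-03", "8140", ""), (1, "2016-03", "8041", "")])
        assert sp.select_tumor_record(df, "2016-03")["histology"] == "8041"

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            sp.select_tumor_record(self._df([]), "2016-03")


@pytest.mark.parametrize(
    "hist,expected", [("8041", "SCLC"), ("8140", "NSCLC"), ("8045", "SCLC"), ("8002", "SCLC")]
)
def test_gold_label(hist, expected, registry):
    assert sp.gold_label(hist, registry) == expected


@pytest.fixture(scope="module")
def cohort(registry):
    return sp.apply_inclusion(mini_population(), sp.InclusionCriteria(), registry)


class TestApplyInclusion:
    def test_membership(self, cohort):
        assert set(cohort["patient_id"]) == {1, 4, 5, 6, 7, 9}

    def test_gold_labels_and_index(self, cohort):
        row = cohort.set_index("patient_id").loc[1]
        assert row["gold_label"] == "SCLC"
        assert row["index_date"] == pd.Timestamp("2016-03-01")
        assert row["censor_reason"] == "window_end"
        assert row["observation_end"] == pd.Timestamp("2016-03-01") + pd.Timedelta(days=180)

    def test_tumor_tie_breaking_drives_label(self, cohort):
        row = cohort.set_index("patient_id").loc[5]
        assert row["gold_label"] == "NSCLC"
        assert row["index_date"] == pd.Timestamp("2016-02-01")

    def test_death_censoring(self, cohort):
        row = cohort.set_index("patient_id").loc[4]
        assert row["censor_reason"] == "death"
        assert row["observation_end"] == pd.Timestamp("2016-05-30")

    def test_disenrollment_censoring(self, cohort):
        row = cohort.set_index("patient_id").loc[7]
        assert row["censor_reason"] == "disenrollment"
        assert row["observation_end"] == pd.Timestamp("2016-05-01")

    def test_treated_requires_outpatient_systemic(self, cohort):
        treated = cohort.set_index("patient_id")["treated"]
        assert treated.loc[1]
        assert not treated.loc[6]  # a molecular test is not systemic therapy
        assert not treated.loc[9]  # inpatient administration not identifiable

    def test_attrition_recorded(self, cohort):
        att = cohort.attrs["attrition"]
        assert att["source_patients"] == 9
        assert att["claims_diagnosed"] == 8  # p8 diagnosed outside study years
        assert att["final"] == 6

    def test_age_band_override_for_younger_population(self, registry):
        young = sp.apply_inclusion(
            mini_population(), sp.InclusionCriteria(min_age=19, max_age=65), registry
        )
        assert set(young["patient_id"]) == {2}


# --- brute-force oracle -----------------------------------------------------

def _oracle_inclusion(pop, criteria, registry):
    """Slow per-patient re-evaluation of every inclusion predicate."""
    lung = registry["lung_cancer_dx"]
    sclc = registry["sclc_histology"]
    members = {}
    for pid in pop.patients["patient_id"]:
        pclaims = pop.claims[pop.claims["patient_id"] == pid]
        dx_dates = sorted(
            d
            for d, c, s in zip(pclaims["service_date"], pclaims["code"], pclaims["system"])
            if sp.match(c, CodeSystem(s), lung) and d.year in criteria.diagnosis_years
        )
        if not dx_dates:
            continue
        dx_midx = dx_dates[0].year * 12 + dx_dates[0].month - 1
        ptum = pop.tumors[pop.tumors["patient_id"] == pid]
        if ptum.empty:
            continue
        recs = []
        for _, t in ptum.iterrows():
            p = pd.Period(t["diagnosis_month"], freq="M")
            midx = p.year * 12 + p.month - 1
            recs.append((abs(midx - dx_midx), midx, str(t["histology"])))
        recs.sort()
        _, midx, hist = recs[0]
        index = pd.Timestamp(year=midx // 12, month=midx % 12 + 1, day=1)
        prow = pop.patients.set_index("patient_id").loc[pid]
        b = prow["birth_date"]
        age = index.year - b.year - ((index.month, index.day) < (b.month, b.day))
        if age < criteria.min_age or (criteria.max_age is not None and age > criteria.max_age):
            continue
        penr = pop.enrollment[pop.enrollment["patient_id"] == pid]
        eligible = set()
        for _, e in penr.iterrows():
            if e["part_a"] and e["part_b"] and e["part_d"] and not e["hmo"]:
                p = pd.Period(e["month"], freq="M")
                eligible.add(p.year * 12 + p.month - 1)
        if criteria.require_lookback and any(
            midx - k not in eligible for k in range(1, criteria.lookback_months + 1)
        ):
            continue
        gap = 0
        while midx + gap in eligible:
            gap += 1
        disenroll = pd.Timestamp(
            year=(midx + gap) // 12, month=(midx + gap) % 12 + 1, day=1
        )
        candidates = [(index + pd.Timedelta(days=180), "window_end"), (disenroll, "disenrollment")]
        if pd.notna(prow["death_date"]):
            candidates.append((prow["death_date"], "death"))
        prio = {"death": 0, "disenrollment": 1, "window_end": 2}
        obs_end, reason = min(candidates, key=lambda t: (t[0], prio[t[1]]))
        obs_end = max(obs_end, index)
        treated = any(
            e["setting"] == "outpatient"
            and 0 <= (e["service_date"] - index).days < 180
            and any(sp.match(e["code"], CodeSystem(e["system"]), registry[s])
                    for s in SYSTEMIC_THERAPY_SETS)
            for _, e in pclaims.iterrows()
        )
        members[pid] = {
            "index_date": index,
            "gold_label": "SCLC" if sp.match(hist, CodeSystem.ICDO3_HIST, sclc) else "NSCLC",
            "age": age,
            "observation_end": obs_end,
            "censor_reason": reason,
            "treated": treated,
        }
    return members


def test_inclusion_agrees_with_bruteforce_oracle(registry):
    """Every member of a messy population (dropout, deaths, duplicate tumors,
    under-age patients) satisfies the inclusion predicates when re-checked
    patient by patient, and no eligible patient is missed."""
    cfg = sp.default_config(
        n_patients=600,
        seed=7,
        age_distribution={"60-65": 0.25, "66-69": 0.25, "70-74": 0.25, "75-79": 0.25},
        lookback_dropout_prob=0.25,
        death_rate_180d={"SCLC": 0.3, "NSCLC": 0.2},
        duplicate_tumor_prob=0.05,
    )
    pop = sp.generate_population(cfg)
    got = sp.apply_inclusion(pop, sp.InclusionCriteria(), registry)
    want = _oracle_inclusion(pop, sp.InclusionCriteria(), registry)
    assert set(got["patient_id"]) == set(want)
    assert 0 < len(got) < 600
    for _, row in got.set_index("patient_id").iterrows():
        ref = want[row.name]
        for key, val in ref.items():
            assert row[key] == val, (row.name, key, row[key], val)


# --- split ------------------------------------------------------------------

class TestSplitSample:
    def test_small_exact_sizes(self):
        df = pd.DataFrame({"patient_id": range(4)})
        a, b = sp.split_sample(df, 0.25, seed=0)
        assert (len(a), len(b)) == (1, 3)

    def test_partition_disjoint_exhaustive(self, study_cohort, study_split):
        a, b = study_split
        ids_a, ids_b = set(a["patient_id"]), set(b["patient_id"])
        assert not ids_a & ids_b
        assert ids_a | ids_b == set(study_cohort["patient_id"])

    def test_determinism(self, study_cohort):
        a1, _ = sp.split_sample(study_cohort, 0.25, seed=5)
        a2, _ = sp.split_sample(study_cohort, 0.25, seed=5)
        assert a1["patient_id"].tolist() == a2["patient_id"].tolist()
        a3, _ = sp.split_sample(study_cohort, 0.25, seed=6)
        assert a1["patient_id"].tolist() != a3["patient_id"].tolist()

    def test_fraction_bounds(self, study_cohort):
        with pytest.raises(ValueError):
            sp.split_sample(study_cohort, 0.0, seed=1)
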