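"""Cohort construction: eligibility filters and one analysis row per person.

A linked person enters the analysis when, in this order:

1. the person's HIV cluster contains at least one laboratory record with a
   documented *positive* HIV result (records labelled negative or unknown
   are dropped);
2. the first HIV record date is on or before the cancer diagnosis date
   (same-day diagnoses are retained: only cancers strictly before the first
   HIV record are excluded);
3. the incident cancer record has a non-missing province of diagnosis.

The incident cancer is the earliest linked pathology report (ties to the
smallest record id). The home province is the modal province over the
person's positive HIV records (ties to the province of the earliest record,
then alphabetical) — the residence proxy used throughout the analysis.
An attrition log records the count removed at each filter.
"""

from __future__ import annotations

import pandas as pd

ATTRITION_STEPS = ("non_positive", "cancer_before_hiv", "missing_diagnosis_province")

CASE_COLUMNS = (
    "cluster_id", "sex", "race", "age_at_diagnosis", "home_province",
    "diagnosis_province", "cancer_type", "hiv_first_date",
    "cancer_diagnosis_date", "out_of_province",
)


def filter_hiv_positive(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only laboratory records with a documented positive HIV result."""
    return records[records["result_label"] == "positive"]


def incident_cancer(cancer_records: pd.DataFrame) -> pd.Series:
    """The first pathology report of one person: earliest diagnosis date,
    ties broken by the smallest record id."""
    if cancer_records.empty:
        raise ValueError("incident_cancer requires at least one record")
    ordered = cancer_records.sort_values(
        ["diagnosis_date", "record_id"], kind="mergesort")
    return ordered.iloc[0]


def temporal_filter(hiv_first_date: str, diagnosis_date: str) -> bool:
    """Keep a case iff the first HIV record is on or before the cancer
    diagnosis (ISO date strings compare lexicographically)."""
    if not hiv_first_date or not diagnosis_date:
        return False
    return hiv_first_date <= diagnosis_date


def home_province(hiv_records: pd.DataFrame) -> str:
    """Modal province over a person's (positive) HIV records.

    Ties break to the province of the earliest record, then alphabetically.
    """
    if hiv_records.empty:
        raise ValueError("home_province requires at least one record")
    g = (hiv_records.groupby("province")
         .agg(n=("province", "size"), first_date=("test_date", "min"))
         .reset_index()
         .sort_values(["n", "first_date", "province"],
                      ascending=[False, True, True], kind="mergesort"))
    return g["province"].iat[0]


def _age_years(dob: str, when: str) -> object:
    """Whole years between an ISO dob and an ISO reference date (floor)."""
    try:
        d = pd.Timestamp(dob)
        w = pd.Timestamp(when)
    except (ValueError, TypeError):
        return pd.NA
    years = w.year - d.year
    if (w.month, w.day) < (d.month, d.day):
        years -= 1
    return years


def build_cases(clusters: pd.DataFrame, links: pd.DataFrame,
                hiv: pd.DataFrame, cancer: pd.DataFrame
                ) -> tuple[pd.DataFrame, dict]:
    """Assemble the analysis cohort: one row per linked person surviving
    the eligibility filters, plus the ordered attrition log.

    ``clusters``: (record_id, cluster_id) over HIV records.
    ``links``: (cancer_record_id, cluster_id, score).
    ``hiv`` / ``cancer``: the source record tables.
    """
    hiv = hiv.merge(clusters, on="record_id")
    linked_cancer = cancer.merge(
        links.rename(columns={"cancer_record_id": "record_id"}),
        on="record_id")

    # incident cancer per cluster: earliest diagnosis, tie -> smaller id
    inc = (linked_cancer
           .sort_values(["diagnosis_date", "record_id"], kind="mergesort")
           .drop_duplicates("cluster_id", keep="first")
           .set_index("cluster_id"))
    n_candidates = len(inc)
    attrition = dict.fromkeys(ATTRITION_STEPS, 0)

    pos = filter_hiv_positive(hiv)
    pos = pos[pos["cluster_id"].isin(inc.index)]

    # modal home province with the documented tie-breaks, vectorised
    g = (pos.groupby(["cluster_id", "province"])
         .agg(n=("record_id", "size"), first_date=("test_date", "min"))
         .reset_index()
         .sort_values(["cluster_id", "n", "first_date", "province"],
                      ascending=[True, False, True, True], kind="mergesort")
         .drop_duplicates("cluster_id", keep="first")
         .set_index("cluster_id"))
    first_pos_date = pos.groupby("cluster_id")["test_date"].min()

    # date of birth: modal non-missing dob over positive records
    dobs = pos[pos["dob"].fillna("") != ""]
    dob_mode = (dobs.groupby(["cluster_id", "dob"]).size()
                .rename("n").reset_index()
                .sort_values(["cluster_id", "n", "dob"],
                             ascending=[True, False, True], kind="mergesort")
                .drop_duplicates("cluster_id", keep="first")
                .set_index("cluster_id")["dob"])

    # fallback demographics from the HIV side (modal sex/race)
    def _modal(col):
        return (pos.groupby(["cluster_id", col]).size().rename("n")
                .reset_index()
                .sort_values(["cluster_id", "n", col],
                             ascending=[True, False, True], kind="mergesort")
                .drop_duplicates("cluster_id", keep="first")
                .set_index("cluster_id")[col])

    sex_hiv = _modal("sex")
    race_hiv = _modal("race")

    # recorded age at the HIV test nearest the diagnosis (dob fallback)
    aged = pos[pos["age"].fillna("") != ""].copy()
    rows = []
    att = attrition
    for cluster_id, cinc in inc.iterrows():
        if cluster_id not in first_pos_date.index:
            att["non_positive"] += 1
            continue
        dx_date = cinc["diagnosis_date"]
        if not temporal_filter(first_pos_date[cluster_id], dx_date):
            att["cancer_before_hiv"] += 1
            continue
        dx_prov = cinc["diagnosis_province"]
        if not isinstance(dx_prov, str) or dx_prov == "":
            att["missing_diagnosis_province"] += 1
            continue
        home = g.loc[cluster_id, "province"]
        dob = dob_mode.get(cluster_id, "")
        if dob:
            age = _age_years(dob, dx_date)
        else:
            sub = aged[aged["cluster_id"] == cluster_id]
            if len(sub):
                delta = (pd.to_datetime(sub["test_date"])
                         - pd.Timestamp(dx_date)).abs()
                age = int(float(sub["age"].iloc[delta.values.argmin()]))
            else:
                age = pd.NA
        sex = cinc["sex"] if isinstance(cinc["sex"], str) and cinc["sex"] \
            else sex_hiv.get(cluster_id, "")
        race = cinc["race"] if isinstance(cinc["race"], str) and cinc["race"] \
            else race_hiv.get(cluster_id, "")
        rows.append({
            "cluster_id": cluster_id,
            "sex": sex,
            "race": race,
            "age_at_diagnosis": age,
            "home_province": home,
            "diagnosis_province": dx_prov,
            "cancer_type": cinc["cancer_type"],
            "hiv_first_date": first_pos_date[cluster_id],
            "cancer_diagnosis_date": dx_date,
            "out_of_province": home != dx_prov,
        })
    cases = pd.DataFrame(rows, columns=list(CASE_COLUMNS))
    attrition_log = {
        "input_clusters": n_candidates,
        "removed": attrition,
        "final_cases": len(cases),
    }
    assert n_candidates - sum(attrition.values()) == len(cases)
    return cases, attrition_log
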