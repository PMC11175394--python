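"""Eligibility filters, incident-cancer selection and cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from hivcanlink import cohort, linkage, standardize, synthgen
from hivcanlink.config import CorruptionModel, GeneratorConfig, identity_mobility


def _hiv(record_id, cluster, result="positive", province="GAU",
         date="2008-01-01", dob="1980-03-04", **kw):
    row = {"record_id": record_id, "first_name": "A", "surname": "B",
           "sex": "F", "race": "Black", "dob": dob, "age": "",
           "episode_number": "", "folder_number": "", "test_type": "CD4 count",
           "result_label": result, "facility_id": f"{province}-F01",
           "province": province, "test_date": date, "_cluster": cluster}
    row.update(kw)
    return row


def _cancer(record_id, cluster, date="2012-06-01", province="GAU", **kw):
    row = {"record_id": record_id, "first_name": "A", "surname": "B",
           "sex": "F", "race": "Black", "dob": "1980-03-04", "age": "",
           "episode_number": "", "folder_number": "",
           "diagnosis_date": date, "cancer_type": "Cervix",
           "basis": "histology", "diagnosis_province": province,
           "facility_id": f"{province}-F01", "_cluster": cluster}
    row.update(kw)
    return row


def _frames(hiv_rows, cancer_rows):
    hiv = pd.DataFrame(hiv_rows)
    cancer = pd.DataFrame(cancer_rows)
    clusters = hiv[["record_id", "_cluster"]].rename(
        columns={"_cluster": "cluster_id"})
    links = cancer[["record_id", "_cluster"]].rename(columns={
        "record_id": "cancer_record_id", "_cluster": "cluster_id"})
    links["score"] = 1.0
    return (clusters, links, hiv.drop(columns="_cluster"),
            cancer.drop(columns="_cluster"))


def test_filter_hiv_positive_keeps_only_positive():
    recs = pd.DataFrame({"result_label": ["positive", "negative", "unknown"]})
    assert len(cohort.filter_hiv_positive(recs)) == 1
    allpos = pd.DataFrame({"result_label": ["positive"] * 4})
    assert len(cohort.filter_hiv_positive(allpos)) == 4


def test_positive_fraction_binomial():
    """With label weights (0.7, 0.2, 0.1) the kept fraction of 10,000
    records is within 3 binomial standard errors of 0.7."""
    cfg = GeneratorConfig(n_entities=4000, seed=77, hiv_records_per_person=2.5)
    data = synthgen.generate(cfg)
    recs = data.hiv.head(10000)
    kept = len(cohort.filter_hiv_positive(recs)) / len(recs)
    se = np.sqrt(0.7 * 0.3 / len(recs))
    assert abs(kept - 0.7) < 3 * se


def test_incident_cancer_earliest_then_smallest_id():
    recs = pd.DataFrame([
        _cancer("C2", "k", date="2012-03-01"),
        _cancer("C1", "k", date="2010-05-01"),
    ])
    assert cohort.incident_cancer(recs)["record_id"] == "C1"
    single = pd.DataFrame([_cancer("C9", "k")])
    assert cohort.incident_cancer(single)["record_id"] == "C9"
    ties = pd.DataFrame([
        _cancer("C5", "k", date="2010-05-01"),
        _cancer("C3", "k", date="2010-05-01"),
    ])
    assert cohort.incident_cancer(ties)["record_id"] == "C3"


@pytest.mark.parametrize("hiv_date, dx_date, keep", [
    ("2009-01-01", "2011-06-01", True),
    ("2012-01-01", "2011-06-01", False),   # cancer prior to HIV: dropped
    ("2011-06-01", "2011-06-01", True),    # same-day retained
])
def test_temporal_filter(hiv_date, dx_date, keep):
    assert cohort.temporal_filter(hiv_date, dx_date) is keep


def test_home_province_mode_and_tiebreaks():
    recs = pd.DataFrame([_hiv("H1", "k", province="GAU"),
                         _hiv("H2", "k", province="GAU"),
                         _hiv("H3", "k", province="KZN")])
    assert cohort.home_province(recs) == "GAU"
    assert cohort.home_province(pd.DataFrame([_hiv("H1", "k",
                                                   province="KZN")])) == "KZN"
    # tie on count -> earliest record's province wins
    tie = pd.DataFrame([_hiv("H1", "k", province="GAU", date="2006-01-01"),
                        _hiv("H2", "k", province="KZN", date="2005-01-01")])
    assert cohort.home_province(tie) == "KZN"


def test_build_cases_toy_attrition():
    """Six handcrafted clusters: one negative-only, one cancer-before-HIV,
    one missing diagnosis province, three valid -> 3 cases, log (1,1,1)."""
    hiv_rows = [
        _hiv("H1", "k1", result="negative"),
        _hiv("H2", "k2", date="2013-01-01"),       # cancer predates HIV
        _hiv("H3", "k3"),
        _hiv("H4", "k4"),
        _hiv("H5", "k5", province="KZN"),
        _hiv("H6", "k6"),
    ]
    cancer_rows = [
        _cancer("C1", "k1"),
        _cancer("C2", "k2", date="2010-01-01"),
        _cancer("C3", "k3", province=""),          # missing province
        _cancer("C4", "k4"),
        _cancer("C5", "k5", province="GAU"),
        _cancer("C6", "k6", province="GAU"),
    ]
    cases, log = cohort.build_cases(*_frames(hiv_rows, cancer_rows))
    assert len(cases) == 3
    assert log["removed"] == {"non_positive": 1, "cancer_before_hiv": 1,
                              "missing_diagnosis_province": 1}
    by = cases.set_index("cluster_id")
    assert bool(by.loc["k5", "out_of_province"]) is True   # KZN home, GAU dx
    assert bool(by.loc["k4", "out_of_province"]) is False
    assert by.loc["k4", "age_at_diagnosis"] == 32          # 1980 -> 2012-06


def test_attrition_counts_sum_to_input_minus_cases(small_run):
    clusters, links = small_run["clusters"], small_run["links"]
    data = small_run["data"]
    cases, log = cohort.build_cases(clusters, links, data.hiv, data.cancer)
    assert log["input_clusters"] - sum(log["removed"].values()) == len(cases)


def test_filter_order_invariance(small_run):
    """Temporal and missing-province filters are independent predicates:
    which one claims a doubly-ineligible cluster does not change the final
    case set."""
    clusters, links = small_run["clusters"], small_run["links"]
    data = small_run["data"]
    cases, _ = cohort.build_cases(clusters, links, data.hiv, data.cancer)
    # swap the order by pre-dropping missing-province cancer records first
    cancer2 = data.cancer[data.cancer["diagnosis_province"] != ""]
    links2 = links[links["cancer_record_id"].isin(cancer2["record_id"])]
    cases2, _ = cohort.build_cases(clusters, links2, data.hiv, cancer2)
    a = cases.sort_values("cluster_id").reset_index(drop=True)
    b = cases2.sort_values("cluster_id").reset_index(drop=True)
    incident_kept = a["cluster_id"].isin(b["cluster_id"])
    # every case surviving the canonical order survives the swapped order
    # unless its incident record itself had a missing province (then the
    # next report is used instead, which is a different case row)
    pd.testing.assert_frame_equal(a[incident_kept].reset_index(drop=True),
                                  b[b["cluster_id"].isin(a["cluster_id"])]
                                  .reset_index(drop=True))


def test_zero_corruption_case_count_matches_truth():
    """On noise-free data the pipeline's case count equals the ground-truth
    count of persons with a positive HIV record, a qualifying cancer and a
    recorded diagnosis province."""
    cfg = GeneratorConfig(n_entities=1200, seed=55,
                          corruption=CorruptionModel.zero(),
                          cancer_fraction=0.5)
    data = synthgen.generate(cfg)
    hc = standardize.clean_records(data.hiv, "test_date")
    cc = standardize.clean_records(data.cancer, "diagnosis_date")
    pairs = standardize.candidate_pairs(hc)
    X, y = linkage.make_training_pairs(hc, pairs, data.truth, 3000,
                                       np.random.default_rng(4))
    model = linkage.train_classifier(X, y)
    scored = linkage.classify_pairs(hc, pairs, model)
    clusters = linkage.deduplicate(hc["record_id"], scored[scored["match"]])
    links = linkage.link_hiv_cancer(hc, clusters, cc, model)
    cases, _ = cohort.build_cases(clusters, links, data.hiv, data.cancer)

    truth = data.truth.set_index("record_id")["entity_id"]
    pos = data.hiv[data.hiv["result_label"] == "positive"].assign(
        entity=lambda d: d["record_id"].map(truth))
    first_pos = pos.groupby("entity")["test_date"].min()
    expected = 0
    for _, c in data.cancer.iterrows():
        ent = truth[c["record_id"]]
        if ent in first_pos.index and c["diagnosis_province"] != "" \
                and first_pos[ent] <= c["diagnosis_date"]:
            expected += 1
    assert len(cases) == expected


def test_identity_mobility_gives_no_out_of_province(small_run):
    cfg = GeneratorConfig(n_entities=800, seed=66,
                          corruption=CorruptionModel.zero(),
                          mobility=identity_mobility(),
                          hiv_away_province_rate=0.0,
                          missing_diagnosis_province_rate=0.0)
    data = synthgen.generate(cfg)
    hc = standardize.clean_records(data.hiv, "test_date")
    cc = standardize.clean_records(data.cancer, "diagnosis_date")
    pairs = standardize.candidate_pairs(hc)
    X, y = linkage.make_training_pairs(hc, pairs, data.truth, 2000,
                                       np.random.default_rng(6))
    model = linkage.train_classifier(X, y)
    scored = linkage.classify_pairs(hc, pairs, model)
    clusters = linkage.deduplicate(hc["record_id"], scored[scored["match"]])
    links = linkage.link_hiv_cancer(hc, clusters, cc, model)
    cases, _ = cohort.build_cases(clusters, links, data.hiv, data.cancer)
    assert len(cases) > 0
    assert not cases["out_of_province"].any()
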