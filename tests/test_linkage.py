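"""Comparison vectors, SVM training, deduplication, linking, evaluation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hivcanlink import linkage, standardize, synthgen
from hivcanlink.config import CorruptionModel, GeneratorConfig


def _clean(rows):
    df = pd.DataFrame(rows)
    return standardize.clean_records(df, "test_date")


BASE = {"record_id": "H1", "first_name": "Martha", "surname": "Dlamini",
        "sex": "F", "race": "Black", "dob": "1980-03-04", "age": "",
        "episode_number": "E0000001", "folder_number": "GAU-F01/00001",
        "test_date": "2010-05-01"}


def test_string_similarity_contract():
    assert linkage.string_similarity("MARTHA", "MARTHA") == 1.0
    assert linkage.string_similarity("ABC", "XYZ") == 0.0
    assert linkage.string_similarity("MARTHA", "MARHTA") == pytest.approx(
        0.9611, abs=1e-4)
    assert linkage.string_similarity("", "MARTHA") == 0.5  # missing midpoint


def test_compare_pair_identical_records_all_ones():
    c = _clean([BASE, {**BASE, "record_id": "H2"}])
    vec = linkage.compare_pair(c.iloc[0], c.iloc[1])
    assert list(vec.values()) == [1.0] * 6


def test_compare_pair_unrelated_records_low_everywhere():
    other = {**BASE, "record_id": "H2", "first_name": "Xolani",
             "surname": "Pretorius", "dob": "1955-07-07",
             "episode_number": "E0009999", "folder_number": "WC-F09/00077"}
    c = _clean([BASE, other])
    vec = linkage.compare_pair(c.iloc[0], c.iloc[1])
    assert vec["sim_first_name"] < 0.6 and vec["sim_surname"] < 0.6
    assert vec["age_agreement"] == 0.0
    assert vec["dob_exact"] == 0.0
    assert vec["episode_match"] == 0.0 and vec["folder_match"] == 0.0


def test_compare_pair_surname_transposition_only():
    b = {**BASE, "record_id": "H2", "surname": "Dlamini"}
    a = {**BASE, "surname": "Dlamini"}
    a["surname"], b["surname"] = "Martha", "Marhta"  # reuse the worked pair
    c = _clean([a, b])
    vec = linkage.compare_pair(c.iloc[0], c.iloc[1])
    assert vec["sim_surname"] == pytest.approx(0.9611, abs=1e-4)
    assert all(vec[k] == 1.0 for k in vec if k != "sim_surname")


def test_compare_pair_symmetric(small_run):
    hc = small_run["hiv_clean"]
    pairs = small_run["pairs"].head(300)
    fwd = linkage.compare_features(hc, hc, pairs["pos_a"].to_numpy(),
                                   pairs["pos_b"].to_numpy())
    rev = linkage.compare_features(hc, hc, pairs["pos_b"].to_numpy(),
                                   pairs["pos_a"].to_numpy())
    np.testing.assert_allclose(fwd, rev, atol=1e-12)


def test_features_bounded(small_run):
    hc = small_run["hiv_clean"]
    pairs = small_run["pairs"].head(2000)
    X = linkage.compare_features(hc, hc, pairs["pos_a"].to_numpy(),
                                 pairs["pos_b"].to_numpy())
    assert (X >= 0).all() and (X <= 1).all()


def test_train_separable_toy_is_perfect():
    X = np.vstack([np.ones((20, 6)), np.zeros((20, 6))])
    y = np.array([1] * 20 + [0] * 20)
    model = linkage.train_classifier(X, y)
    assert (model.predict(X) == y.astype(bool)).all()


def test_train_single_class_raises():
    with pytest.raises(ValueError):
        linkage.train_classifier(np.ones((10, 6)), np.ones(10))


def test_retrain_same_data_identical_weights(small_run):
    hc, pairs = small_run["hiv_clean"], small_run["pairs"]
    truth = small_run["data"].truth
    X1, y1 = linkage.make_training_pairs(hc, pairs, truth, 2000,
                                         np.random.default_rng(5))
    X2, y2 = linkage.make_training_pairs(hc, pairs, truth, 2000,
                                         np.random.default_rng(5))
    m1 = linkage.train_classifier(X1, y1)
    m2 = linkage.train_classifier(X2, y2)
    np.testing.assert_array_equal(m1.weights, m2.weights)
    assert m1.bias == m2.bias


def test_model_json_roundtrip(tmp_path, small_run):
    model = small_run["model"]
    model.to_json(tmp_path / "m.json")
    back = linkage.MatchModel.from_json(tmp_path / "m.json")
    np.testing.assert_array_equal(back.weights, model.weights)
    assert back.bias == model.bias and back.threshold == model.threshold
    assert back.feature_names == linkage.FEATURE_NAMES


def test_deduplicate_transitive_closure():
    matches = pd.DataFrame({"pos_a": [0, 1], "pos_b": [1, 2]})  # A-B, B-C
    out = linkage.deduplicate(["A", "B", "C", "D"], matches)
    cl = out.set_index("record_id")["cluster_id"]
    assert cl["A"] == cl["B"] == cl["C"] == "A"  # closure despite no A-C
    assert cl["D"] == "D"


def test_deduplicate_no_matches_all_singletons():
    out = linkage.deduplicate(["A", "B"], pd.DataFrame({"pos_a": [], "pos_b": []}))
    assert (out["record_id"] == out["cluster_id"]).all()


def test_deduplicate_idempotent(small_run):
    """Re-running on one representative per cluster yields no merges."""
    clusters = small_run["clusters"]
    reps = clusters.drop_duplicates("cluster_id")["record_id"].tolist()
    hc = small_run["hiv_clean"]
    sub = hc[hc["record_id"].isin(reps)].reset_index(drop=True)
    pairs = standardize.candidate_pairs(sub)
    scored = linkage.classify_pairs(sub, pairs, small_run["model"])
    again = linkage.deduplicate(sub["record_id"], scored[scored["match"]])
    merged = again.groupby("cluster_id").size()
    # representatives were split apart by the classifier before; they must
    # not re-merge
    assert (merged == 1).mean() > 0.99


@pytest.mark.parametrize("seed", range(5))
def test_union_find_equals_graph_traversal_oracle(seed):
    """Connected components from union-find match networkx on random
    instances of up to 200 records."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 200))
    m = int(rng.integers(0, 3 * n))
    edges = pd.DataFrame({
        "pos_a": rng.integers(0, n, size=m),
        "pos_b": rng.integers(0, n, size=m)})
    ids = [f"R{i:03d}" for i in range(n)]
    ours = linkage.deduplicate(ids, edges).set_index("record_id")["cluster_id"]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges.to_numpy())
    for comp in nx.connected_components(g):
        rep = min(ids[i] for i in comp)
        for i in comp:
            assert ours[ids[i]] == rep


def test_zero_corruption_clusters_equal_truth_partition():
    cfg = GeneratorConfig(n_entities=1500, seed=31,
                          corruption=CorruptionModel.zero())
    data = synthgen.generate(cfg)
    hc = standardize.clean_records(data.hiv, "test_date")
    pairs = standardize.candidate_pairs(hc)
    X, y = linkage.make_training_pairs(hc, pairs, data.truth, 3000,
                                       np.random.default_rng(2))
    model = linkage.train_classifier(X, y)
    scored = linkage.classify_pairs(hc, pairs, model)
    clusters = linkage.deduplicate(hc["record_id"], scored[scored["match"]])
    m = linkage.evaluate_clusters(clusters, data.truth)
    assert m["pairwise_precision"] == 1.0 and m["pairwise_recall"] == 1.0


def test_evaluate_clusters_counting_identities():
    truth = pd.DataFrame({"record_id": list("abcd"),
                          "entity_id": ["e1", "e1", "e2", "e2"]})
    perfect = pd.DataFrame({"record_id": list("abcd"),
                            "cluster_id": ["a", "a", "c", "c"]})
    m = linkage.evaluate_clusters(perfect, truth)
    assert m["pairwise_precision"] == 1.0 and m["pairwise_recall"] == 1.0
    singletons = pd.DataFrame({"record_id": list("abcd"),
                               "cluster_id": list("abcd")})
    m = linkage.evaluate_clusters(singletons, truth)
    assert m["pairwise_recall"] == 0.0
    # one spurious merge on top of one true pair: precision = 1/(1+2)
    mixed = pd.DataFrame({"record_id": list("abcd"),
                          "cluster_id": ["a", "a", "a", "d"]})
    m = linkage.evaluate_clusters(mixed, truth)
    assert m["pairwise_precision"] == pytest.approx(1 / 3)


def test_evaluate_empty_truth_raises():
    with pytest.raises(ValueError):
        linkage.evaluate_clusters(
            pd.DataFrame({"record_id": [], "cluster_id": []}),
            pd.DataFrame({"record_id": [], "entity_id": []}))


def test_link_picks_identical_cluster_and_skips_nonmatches(small_run):
    model = small_run["model"]
    hiv_rows = [
        BASE,
        {**BASE, "record_id": "H2", "first_name": "Johan",
         "surname": "Botha", "dob": "1962-01-09",
         "episode_number": "E0000002", "folder_number": "WC-F02/00002"},
    ]
    hc = _clean(hiv_rows)
    clusters = linkage.deduplicate(hc["record_id"],
                                   pd.DataFrame({"pos_a": [], "pos_b": []}))
    cancer = pd.DataFrame([
        {**BASE, "record_id": "C1", "diagnosis_date": "2012-01-01"},
        {**BASE, "record_id": "C2", "first_name": "Zanele",
         "surname": "Mokoena", "dob": "1990-12-12",
         "episode_number": "E0007777", "folder_number": "EC-F01/00009",
         "diagnosis_date": "2012-01-01"},
    ]).drop(columns=["test_date"])
    cc = standardize.clean_records(cancer, "diagnosis_date")
    links = linkage.link_hiv_cancer(hc, clusters, cc, model)
    assert links["cancer_record_id"].tolist() == ["C1"]
    assert links["cluster_id"].tolist() == ["H1"]


def test_monotonicity_f1_never_improves_with_noise():
    """Averaged over 5 replicate seeds, pairwise F1 does not increase when
    the typo rate rises (all other settings fixed)."""
    rates = (0.0, 0.1, 0.25)
    mean_f1 = []
    for rate in rates:
        f1s = []
        for seed in range(5):
            cfg = GeneratorConfig(
                n_entities=700, seed=100 + seed,
                corruption=CorruptionModel(typo_rate=rate))
            data = synthgen.generate(cfg)
            hc = standardize.clean_records(data.hiv, "test_date")
            pairs = standardize.candidate_pairs(hc)
            X, y = linkage.make_training_pairs(
                hc, pairs, data.truth, 2000, np.random.default_rng(1))
            model = linkage.train_classifier(X, y)
            scored = linkage.classify_pairs(hc, pairs, model)
            clusters = linkage.deduplicate(hc["record_id"],
                                           scored[scored["match"]])
            f1s.append(linkage.evaluate_clusters(
                clusters, data.truth)["pairwise_f1"])
        mean_f1.append(np.mean(f1s))
    assert mean_f1[0] >= mean_f1[1] >= mean_f1[2]
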