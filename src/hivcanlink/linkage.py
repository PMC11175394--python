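"""Pair comparison, match classification, deduplication and linking.

The linkage stage follows the classical supervised record-linkage recipe:

1. candidate record pairs (from the blocking stage) are turned into
   six-dimensional comparison vectors of field similarities;
2. a linear maximum-margin classifier (support vector machine) trained on
   labelled pairs scores each candidate pair; pairs at or above the decision
   threshold are matches;
3. HIV records are deduplicated into person clusters by transitive closure
   (union–find over the match graph);
4. each cancer record is linked to the highest-scoring matching cluster.

Features are all in [0, 1]. Missing identifier comparisons are encoded at
the uninformative midpoint 0.5: the absence of an episode number is not
evidence against a match, whereas two *different* episode numbers are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from . import standardize
from .similarity import encode_strings, jaro_winkler, jaro_winkler_pairs

FEATURE_NAMES: tuple[str, ...] = (
    "sim_first_name", "sim_surname", "age_agreement",
    "dob_exact", "episode_match", "folder_match",
)


def string_similarity(s1: str, s2: str) -> float:
    """Jaro–Winkler similarity of two canonical strings; 0.5 (the missing
    midpoint) when either side is missing."""
    if not s1 or not s2:
        return 0.5
    return jaro_winkler(s1, s2)


# --------------------------------------------------------------------------
# feature construction

def _gather(df: pd.DataFrame):
    """Pre-extracted comparison columns for fast row gathering."""
    return {
        "first": df["norm_first_name"].to_numpy(dtype=object),
        "surname": df["norm_surname"].to_numpy(dtype=object),
        "year": df["birth_year"].astype("float64").to_numpy(),
        "dob": df["dob"].fillna("").astype(str).to_numpy(dtype=object),
        "episode": df["norm_episode"].to_numpy(dtype=object),
        "folder": df["norm_folder"].to_numpy(dtype=object),
    }


def _exact_feature(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1 where both present and equal, 0 where both present and different,
    0.5 where either side is missing."""
    present = (a != "") & (b != "")
    out = np.full(a.shape, 0.5)
    out[present] = (a[present] == b[present]).astype(float)
    return out


def compare_features(left: pd.DataFrame, right: pd.DataFrame,
                     pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
    """Comparison vectors for row-position pairs between two cleaned tables
    (pass the same table twice for within-table deduplication pairs).

    Returns an (n_pairs, 6) float array, feature order as FEATURE_NAMES.
    """
    ga, gb = _gather(left), _gather(right)
    pos_a = np.asarray(pos_a, dtype=np.int64)
    pos_b = np.asarray(pos_b, dtype=np.int64)

    # name similarities via the batch Jaro-Winkler kernel on a shared
    # string table
    n_left = len(left)
    enc_f, len_f = encode_strings(list(ga["first"]) + list(gb["first"]))
    enc_s, len_s = encode_strings(list(ga["surname"]) + list(gb["surname"]))
    sim_first = jaro_winkler_pairs(enc_f, len_f, pos_a, pos_b + n_left)
    sim_surname = jaro_winkler_pairs(enc_s, len_s, pos_a, pos_b + n_left)
    # overwrite with the missing midpoint where either name is absent
    miss_f = (ga["first"][pos_a] == "") | (gb["first"][pos_b] == "")
    miss_s = (ga["surname"][pos_a] == "") | (gb["surname"][pos_b] == "")
    sim_first[miss_f] = 0.5
    sim_surname[miss_s] = 0.5

    ya, yb = ga["year"][pos_a], gb["year"][pos_b]
    age_agree = 1.0 - np.minimum(np.abs(ya - yb), 5.0) / 5.0
    age_agree[np.isnan(ya) | np.isnan(yb)] = 0.5

    dob_exact = _exact_feature(ga["dob"][pos_a], gb["dob"][pos_b])
    episode = _exact_feature(ga["episode"][pos_a], gb["episode"][pos_b])
    folder = _exact_feature(ga["folder"][pos_a], gb["folder"][pos_b])

    return np.column_stack(
        [sim_first, sim_surname, age_agree, dob_exact, episode, folder])


def compare_pair(a, b) -> dict:
    """Comparison vector for a single pair of cleaned records (mappings or
    DataFrame rows); symmetric in its arguments."""
    fa = pd.DataFrame([dict(a)])
    fb = pd.DataFrame([dict(b)])
    for f in (fa, fb):
        f["birth_year"] = f["birth_year"].astype("Int64")
    x = compare_features(fa, fb, np.array([0]), np.array([0]))[0]
    return dict(zip(FEATURE_NAMES, x.tolist()))


# --------------------------------------------------------------------------
# the match classifier

@dataclass
class MatchModel:
    """A linear maximum-margin pair classifier.

    ``score = w · x + b``; a pair is a match iff score >= threshold
    (the margin zero-point by default). Serialisable to JSON.
    """

    weights: np.ndarray
    bias: float
    threshold: float = 0.0
    feature_names: tuple = FEATURE_NAMES

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.score(X) >= self.threshold

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "threshold": float(self.threshold),
            "feature_names": list(self.feature_names),
        }, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "MatchModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(weights=np.array(d["weights"], dtype=float),
                   bias=float(d["bias"]), threshold=float(d["threshold"]),
                   feature_names=tuple(d["feature_names"]))


def train_classifier(X: np.ndarray, y: np.ndarray,
                     threshold: float = 0.0,
                     false_match_weight: float = 10.0) -> MatchModel:
    """Train the linear SVM on labelled comparison vectors.

    *y* is 1 for matching pairs, 0 otherwise. Training uses the primal
    liblinear formulation, which is deterministic for a fixed input, so
    retraining on the same data reproduces the same weight vector.
    Raises ValueError when only one class is present.

    ``false_match_weight`` scales the hinge penalty of misclassifying a
    non-match. Deduplication merges clusters by transitive closure, so one
    false match fuses two whole persons and its cost grows with cluster
    size, while a false non-match usually costs a single pair (the rest of
    the cluster still connects it). The loss is therefore deliberately
    asymmetric — a precision-leaning boundary that demands positive
    identifier evidence beyond a shared name and birth year.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both matches and "
                         "non-matches")
    svm = LinearSVC(C=1.0, dual=False, fit_intercept=True, tol=1e-6,
                    max_iter=20000,
                    class_weight={0: false_match_weight, 1: 1.0})
    svm.fit(X, y)
    return MatchModel(weights=svm.coef_.ravel().copy(),
                      bias=float(svm.intercept_[0]), threshold=threshold)


def make_training_pairs(clean: pd.DataFrame, pairs: pd.DataFrame,
                        truth: pd.DataFrame, n_pairs: int,
                        rng: np.random.Generator):
    """Sample a labelled training set from blocked candidate pairs.

    Labels come from the generator truth table (or clerical review labels in
    the same format). Sampling is stratified: half matches, a quarter random
    non-matches, and a quarter *ambiguous* non-matches — pairs whose
    canonical surnames and first-name prefixes agree. Ambiguous non-matches
    (different people who share a name and birth year) are rare among random
    candidates but are exactly where the decision boundary lives; without
    them the classifier never learns that disagreeing dates of birth or
    identifiers outweigh identical names. Mirrors the clerical-review
    practice of labelling borderline pairs, done here in a single pass.
    """
    ent = clean["record_id"].map(truth.set_index("record_id")["entity_id"])
    pa = pairs["pos_a"].to_numpy()
    pb = pairs["pos_b"].to_numpy()
    y = (ent.to_numpy()[pa] == ent.to_numpy()[pb]).astype(int)

    surname = clean["norm_surname"].to_numpy(dtype=object)
    first2 = clean["norm_first_name"].str[:2].to_numpy(dtype=object)
    near = (surname[pa] == surname[pb]) & (first2[pa] == first2[pb])

    idx_pos = np.flatnonzero(y == 1)
    idx_hard = np.flatnonzero((y == 0) & near)
    idx_easy = np.flatnonzero((y == 0) & ~near)
    half, quarter = n_pairs // 2, n_pairs // 4
    take_pos = rng.choice(idx_pos, size=min(half, idx_pos.size), replace=False)
    take_hard = rng.choice(idx_hard, size=min(quarter, idx_hard.size),
                           replace=False)
    n_easy = min(n_pairs - take_pos.size - take_hard.size, idx_easy.size)
    take_easy = rng.choice(idx_easy, size=n_easy, replace=False)
    take = np.sort(np.concatenate([take_pos, take_hard, take_easy]))
    X = compare_features(clean, clean, pa[take], pb[take])
    return X, y[take]


# --------------------------------------------------------------------------
# deduplication

class DisjointSet:
    """Union–find with path halving and union by size."""

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return int(x)

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def deduplicate(record_ids, matched_pairs: pd.DataFrame) -> pd.DataFrame:
    """Cluster records by transitive closure of the classified matches.

    ``matched_pairs`` holds row positions (pos_a, pos_b) of pairs classified
    as matches. Every record not involved in any match forms a singleton
    cluster. The cluster id is the smallest member record_id, so cluster ids
    are stable and ordered. Returns a DataFrame (record_id, cluster_id)
    partitioning the input.
    """
    record_ids = list(record_ids)
    n = len(record_ids)
    ds = DisjointSet(n)
    for a, b in zip(matched_pairs["pos_a"].to_numpy(),
                    matched_pairs["pos_b"].to_numpy()):
        ds.union(int(a), int(b))
    roots = np.array([ds.find(i) for i in range(n)])
    rid = np.asarray(record_ids, dtype=object)
    # representative = lexicographically smallest record_id in the component
    rep: dict[int, str] = {}
    for i in range(n):
        r = roots[i]
        if r not in rep or rid[i] < rep[r]:
            rep[r] = rid[i]
    return pd.DataFrame({
        "record_id": rid,
        "cluster_id": [rep[r] for r in roots],
    })


def classify_pairs(clean: pd.DataFrame, pairs: pd.DataFrame,
                   model: MatchModel,
                   batch_size: int = 2_000_000) -> pd.DataFrame:
    """Score blocked pairs with the match model; returns the pairs frame
    with a ``score`` column and a boolean ``match`` column."""
    scores = np.empty(len(pairs), dtype=float)
    pa = pairs["pos_a"].to_numpy()
    pb = pairs["pos_b"].to_numpy()
    for lo in range(0, len(pairs), batch_size):
        hi = min(lo + batch_size, len(pairs))
        X = compare_features(clean, clean, pa[lo:hi], pb[lo:hi])
        scores[lo:hi] = model.score(X)
    out = pairs.copy()
    out["score"] = scores
    out["match"] = scores >= model.threshold
    return out


# --------------------------------------------------------------------------
# linking cancer records to HIV clusters

def link_hiv_cancer(hiv_clean: pd.DataFrame, clusters: pd.DataFrame,
                    cancer_clean: pd.DataFrame,
                    model: MatchModel) -> pd.DataFrame:
    """Link each cancer record to at most one HIV person cluster.

    Candidate (HIV record, cancer record) pairs come from the shared
    blocking keys; each pair inherits the cluster of its HIV record. A
    cancer record links to the cluster of its highest-scoring pair that is
    classified a match; ties break to the smaller cluster_id. Returns a
    DataFrame (cancer_record_id, cluster_id, score).
    """
    pairs = standardize.candidate_pairs_cross(hiv_clean, cancer_clean)
    if pairs.empty:
        return pd.DataFrame(columns=["cancer_record_id", "cluster_id", "score"])
    X = compare_features(hiv_clean, cancer_clean,
                         pairs["pos_a"].to_numpy(), pairs["pos_b"].to_numpy())
    scores = model.score(X)
    keep = scores >= model.threshold
    if not keep.any():
        return pd.DataFrame(columns=["cancer_record_id", "cluster_id", "score"])
    cl_map = clusters.set_index("record_id")["cluster_id"]
    df = pd.DataFrame({
        "cancer_record_id": cancer_clean["record_id"].to_numpy()[
            pairs["pos_b"].to_numpy()[keep]],
        "cluster_id": hiv_clean["record_id"].map(cl_map).to_numpy()[
            pairs["pos_a"].to_numpy()[keep]],
        "score": scores[keep],
    })
    # best pair per (cancer record, cluster), then best cluster per record;
    # ties on score break to the smaller cluster_id
    best = (df.groupby(["cancer_record_id", "cluster_id"], as_index=False)
              ["score"].max())
    best = best.sort_values(
        ["cancer_record_id", "score", "cluster_id"],
        ascending=[True, False, True], kind="mergesort")
    out = best.drop_duplicates("cancer_record_id", keep="first")
    return out.reset_index(drop=True)[["cancer_record_id", "cluster_id", "score"]]


# --------------------------------------------------------------------------
# evaluation against ground truth

def _pair_counts(sizes: pd.Series) -> int:
    s = sizes.to_numpy(dtype=np.int64)
    return int((s * (s - 1) // 2).sum())


def evaluate_clusters(clusters: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Pairwise and entity-level precision/recall/F1 of a deduplication
    against the truth table. Raises on an empty truth table."""
    if truth.empty:
        raise ValueError("truth table is empty")
    merged = clusters.merge(truth, on="record_id", how="inner")
    if merged.empty:
        raise ValueError("no records in common between clusters and truth")
    true_pairs = _pair_counts(merged.groupby("entity_id").size())
    pred_pairs = _pair_counts(merged.groupby("cluster_id").size())
    tp = _pair_counts(merged.groupby(["cluster_id", "entity_id"]).size())
    precision = tp / pred_pairs if pred_pairs else 1.0
    recall = tp / true_pairs if true_pairs else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)

    # entity-level: a cluster is exact when it equals a truth entity's
    # record set
    by_cluster = merged.groupby("cluster_id")["entity_id"].agg(["nunique", "size"])
    by_entity = merged.groupby("entity_id")["cluster_id"].agg(["nunique", "size"])
    ent_sizes = merged.groupby("entity_id").size()
    cl_sizes = merged.groupby("cluster_id").size()
    pure = by_cluster[by_cluster["nunique"] == 1]
    # pure cluster whose size equals its entity's record count = exact
    ent_of_pure = merged.drop_duplicates("cluster_id").set_index("cluster_id")
    exact = 0
    for cl, row in pure.iterrows():
        ent = ent_of_pure.loc[cl, "entity_id"]
        if row["size"] == ent_sizes[ent]:
            exact += 1
    entity_precision = exact / len(cl_sizes) if len(cl_sizes) else 1.0
    entity_recall = exact / len(ent_sizes) if len(ent_sizes) else 1.0
    ef1 = (2 * entity_precision * entity_recall /
           (entity_precision + entity_recall)
           if entity_precision + entity_recall else 0.0)
    return {
        "pairwise_precision": precision,
        "pairwise_recall": recall,
        "pairwise_f1": f1,
        "entity_precision": entity_precision,
        "entity_recall": entity_recall,
        "entity_f1": ef1,
        "n_true_pairs": true_pairs,
        "n_predicted_pairs": pred_pairs,
    }


def evaluate_links(links: pd.DataFrame, clusters: pd.DataFrame,
                   truth: pd.DataFrame) -> dict:
    """Precision/recall of the cancer-to-cluster links.

    A link is correct when the linked cluster's modal ground-truth entity is
    the cancer record's entity. Recall is over all cancer records in the
    truth table."""
    if truth.empty:
        raise ValueError("truth table is empty")
    cl_truth = clusters.merge(truth, on="record_id")
    modal = (cl_truth.groupby("cluster_id")["entity_id"]
             .agg(lambda s: s.mode().iloc[0]))
    cancer_truth = truth[truth["record_id"].str.startswith("C")]
    merged = links.merge(cancer_truth, left_on="cancer_record_id",
                         right_on="record_id", how="left")
    correct = int((merged["cluster_id"].map(modal).to_numpy()
                   == merged["entity_id"].to_numpy()).sum())
    n_pred = len(links)
    n_total = len(cancer_truth)
    precision = correct / n_pred if n_pred else 1.0
    recall = correct / n_total if n_total else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"link_precision": precision, "link_recall": recall,
            "link_f1": f1, "n_links": n_pred, "n_cancer_records": n_total}
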