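import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hivcanlink import linkage, standardize, synthgen
from hivcanlink.config import GeneratorConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_run():
    """One small synthetic universe taken through the full linkage chain,
    shared across test modules (2,000 entities, default corruption)."""
    cfg = GeneratorConfig(n_entities=2000, seed=20)
    data = synthgen.generate(cfg)
    hc = standardize.clean_records(data.hiv, "test_date")
    cc = standardize.clean_records(data.cancer, "diagnosis_date")
    pairs = standardize.candidate_pairs(hc)
    rng = np.random.default_rng(0)
    X, y = linkage.make_training_pairs(hc, pairs, data.truth, 4000, rng)
    model = linkage.train_classifier(X, y)
    scored = linkage.classify_pairs(hc, pairs, model)
    clusters = linkage.deduplicate(hc["record_id"], scored[scored["match"]])
    links = linkage.link_hiv_cancer(hc, clusters, cc, model)
    return {
        "config": cfg, "data": data, "hiv_clean": hc, "cancer_clean": cc,
        "pairs": pairs, "model": model, "scored": scored,
        "clusters": clusters, "links": links,
    }
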