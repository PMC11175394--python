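"""Configuration objects for the synthetic-record generator and pipeline.

Everything the generator does is driven by a :class:`GeneratorConfig`, which
can round-trip through YAML so that a run is fully reproducible from its
config file and seed alone. Probability vectors are validated to sum to one;
the province mobility matrix must be row-stochastic.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .provinces import PROVINCES

STUDY_START = dt.date(2004, 1, 1)
STUDY_END = dt.date(2014, 12, 31)

RACES: tuple[str, ...] = ("Black", "Coloured", "White", "Asian")

# Cancer-type vocabulary: the seventeen site labels reported in the
# out-of-province regression plus the three high-volume groups (cervix,
# breast, residual "Other") that dominate cancer in people living with HIV.
CANCER_TYPES: tuple[str, ...] = (
    "Cervix", "Kaposi Sarcoma", "Breast", "Non Hodgkin lymphoma", "Other",
    "BCC", "Prostate", "Skin other", "Burkitt lymphoma", "Hodgkin lymphoma",
    "Stomach", "Kidney", "Melanoma", "Thyroid", "Tongue", "Bladder", "Bone",
    "Mesothelioma", "Pancreas", "Testis",
)

TEST_TYPES: tuple[str, ...] = (
    "CD4 count", "CD4 percentage", "rapid test", "qualitative PCR",
    "antibody", "antigen",
)

BASES: tuple[str, ...] = ("histology", "cytology", "bone-marrow")

RESULT_LABELS: tuple[str, ...] = ("positive", "negative", "unknown")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _check_prob_vector(name: str, values, keys=None) -> dict:
    d = dict(values)
    if keys is not None:
        missing = set(keys) - set(d)
        extra = set(d) - set(keys)
        if missing or extra:
            raise ConfigurationError(
                f"{name}: keys mismatch (missing={sorted(missing)}, "
                f"extra={sorted(extra)})")
    vals = np.array(list(d.values()), dtype=float)
    if (vals < 0).any():
        raise ConfigurationError(f"{name}: negative probability")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities sum to {vals.sum()!r}, not 1")
    return d


@dataclass
class CorruptionModel:
    """Identifier-noise model applied when a person's records are emitted.

    Each rate is a per-field probability in [0, 1]. ``typo_ops`` weights the
    four single-character edit operations; ``identifier_missing_rate``
    applies independently to the episode number, folder number and date of
    birth (a record losing its date of birth carries an age instead).
    """

    typo_rate: float = 0.05
    typo_ops: dict = field(default_factory=lambda: {
        "substitution": 0.4, "transposition": 0.3,
        "deletion": 0.15, "insertion": 0.15})
    nickname_swap_rate: float = 0.02
    dob_error_rate: float = 0.03
    identifier_missing_rate: float = 0.15

    def validate(self) -> "CorruptionModel":
        for name in ("typo_rate", "nickname_swap_rate", "dob_error_rate",
                     "identifier_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"corruption.{name}={v} not in [0,1]")
        self.typo_ops = _check_prob_vector(
            "corruption.typo_ops", self.typo_ops,
            keys=("substitution", "transposition", "deletion", "insertion"))
        return self

    @classmethod
    def zero(cls) -> "CorruptionModel":
        """A noise-free model: every duplicate record is field-identical."""
        return cls(typo_rate=0.0, nickname_swap_rate=0.0,
                   dob_error_rate=0.0, identifier_missing_rate=0.0)


def default_province_weights() -> dict:
    # Approximate provincial population shares.
    return {"EC": 0.12, "FS": 0.05, "GAU": 0.26, "KZN": 0.19, "LIM": 0.10,
            "MPU": 0.08, "NW": 0.07, "NC": 0.02, "WC": 0.11}


def default_race_weights() -> dict:
    # Proportional to the study-population ethnicity counts.
    counts = {"Black": 57495, "Coloured": 3216, "White": 3044, "Asian": 384}
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def default_cancer_type_weights() -> dict:
    w = {
        "Cervix": 0.26, "Kaposi Sarcoma": 0.16, "Breast": 0.09,
        "Non Hodgkin lymphoma": 0.08, "Other": 0.18, "BCC": 0.04,
        "Prostate": 0.03, "Skin other": 0.03, "Burkitt lymphoma": 0.02,
        "Hodgkin lymphoma": 0.02, "Stomach": 0.015, "Kidney": 0.01,
        "Melanoma": 0.01, "Thyroid": 0.01, "Tongue": 0.01, "Bladder": 0.01,
        "Bone": 0.01, "Mesothelioma": 0.005, "Pancreas": 0.005,
        "Testis": 0.005,
    }
    assert abs(sum(w.values()) - 1.0) < 1e-12
    return w


def observed_mobility() -> pd.DataFrame:
    """Row-stochastic home-province → diagnosis-province matrix derived from
    the packaged origin–destination cell counts (columns of the printed
    cross-tabulation, normalised). This is the generator's default mobility."""
    counts = load_od_fixture()
    # fixture: rows = diagnosis province, columns = HIV-care (home) province
    col_props = counts / counts.sum(axis=0)
    m = col_props.T  # rows = home province, columns = diagnosis province
    m.index.name = None
    m.columns.name = None
    return m


def identity_mobility() -> pd.DataFrame:
    """Everyone is diagnosed in their home province."""
    return pd.DataFrame(np.eye(9), index=list(PROVINCES), columns=list(PROVINCES))


def uniform_offdiag_mobility(off_mass: float) -> pd.DataFrame:
    """Mobility with ``off_mass`` probability of leaving home, spread evenly
    over the eight other provinces."""
    m = np.full((9, 9), off_mass / 8.0)
    np.fill_diagonal(m, 1.0 - off_mass)
    return pd.DataFrame(m, index=list(PROVINCES), columns=list(PROVINCES))


def validate_mobility(mobility: pd.DataFrame) -> pd.DataFrame:
    m = mobility.reindex(index=list(PROVINCES), columns=list(PROVINCES))
    m.index.name = None
    m.columns.name = None
    if m.isna().any().any():
        raise ConfigurationError("mobility matrix must cover all 9 provinces")
    arr = m.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ConfigurationError("mobility matrix has negative entries")
    if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
        raise ConfigurationError("mobility matrix rows must sum to 1")
    return m


@dataclass
class GeneratorConfig:
    """Full parameterisation of a synthetic HIV/cancer record universe."""

    n_entities: int = 5000
    seed: int = 20040101
    hiv_records_per_person: float = 2.5     # mean of 1 + Poisson(mean - 1)
    corruption: CorruptionModel = field(default_factory=CorruptionModel)
    province_weights: dict = field(default_factory=default_province_weights)
    mobility: pd.DataFrame = field(default_factory=observed_mobility)
    female_fraction: float = 0.709
    race_weights: dict = field(default_factory=default_race_weights)
    # age at mid-study, log-normal: exp(N(log(median), sigma)), clipped
    age_median: float = 40.0
    age_sigma: float = 0.28
    age_min: float = 15.0
    age_max: float = 90.0
    cancer_fraction: float = 0.3
    cancer_type_weights: dict = field(default_factory=default_cancer_type_weights)
    hiv_result_label_weights: dict = field(default_factory=lambda: {
        "positive": 0.7, "negative": 0.2, "unknown": 0.1})
    missing_diagnosis_province_rate: float = 0.02
    # fraction of HIV records issued from a province other than home,
    # so that modal-province logic is genuinely exercised
    hiv_away_province_rate: float = 0.1
    # probability that a cancer diagnosis postdates the person's first HIV
    # test (the remainder exercises the temporal eligibility filter)
    cancer_after_hiv_prob: float = 0.9

    def validate(self) -> "GeneratorConfig":
        if self.n_entities <= 0:
            raise ConfigurationError("n_entities must be positive")
        if self.hiv_records_per_person < 1.0:
            raise ConfigurationError("hiv_records_per_person mean must be >= 1")
        self.corruption.validate()
        self.province_weights = _check_prob_vector(
            "province_weights", self.province_weights, keys=PROVINCES)
        self.race_weights = _check_prob_vector(
            "race_weights", self.race_weights, keys=RACES)
        self.cancer_type_weights = _check_prob_vector(
            "cancer_type_weights", self.cancer_type_weights, keys=CANCER_TYPES)
        self.hiv_result_label_weights = _check_prob_vector(
            "hiv_result_label_weights", self.hiv_result_label_weights,
            keys=RESULT_LABELS)
        for name in ("female_fraction", "cancer_fraction",
                     "missing_diagnosis_province_rate",
                     "hiv_away_province_rate", "cancer_after_hiv_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0,1]")
        self.mobility = validate_mobility(self.mobility)
        return self

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["corruption"] = dataclasses.asdict(self.corruption)
        d["mobility"] = {
            row: {col: float(self.mobility.loc[row, col]) for col in PROVINCES}
            for row in PROVINCES}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "corruption" in d and isinstance(d["corruption"], dict):
            d["corruption"] = CorruptionModel(**d["corruption"])
        mob = d.get("mobility")
        if isinstance(mob, str):
            d["mobility"] = {"observed": observed_mobility,
                             "identity": identity_mobility}[mob]()
        elif isinstance(mob, dict):
            d["mobility"] = pd.DataFrame(mob).T.reindex(
                index=list(PROVINCES), columns=list(PROVINCES))
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# packaged fixtures

def _fixture_path(name: str):
    return resources.files("hivcanlink") / "fixtures" / name


def load_od_fixture() -> pd.DataFrame:
    """The printed origin–destination cell counts (rows = province of cancer
    diagnosis, columns = province of HIV care), cells only, no totals."""
    with resources.as_file(_fixture_path("table2_counts.csv")) as p:
        df = pd.read_csv(p, index_col=0)
    return df.reindex(index=list(PROVINCES), columns=list(PROVINCES)).astype(int)


def load_demographics_fixture() -> pd.DataFrame:
    """The printed demographics cell counts: one row per characteristic level
    with outside/within-province counts."""
    with resources.as_file(_fixture_path("table1_counts.csv")) as p:
        return pd.read_csv(p)
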