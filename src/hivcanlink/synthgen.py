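"""Synthetic HIV laboratory and cancer pathology record generator.

Real HIV-care laboratory extracts and pathology-registry records are
restricted data, so every downstream stage of this package is developed and
validated against a synthetic universe with known ground truth:

* a population of person entities with demographics and a home province;
* one or more HIV-related laboratory records per person (CD4 counts and
  percentages, rapid tests, qualitative PCR, antibody/antigen tests), mostly
  issued in the home province, with configurable identifier corruption and
  duplicate records per person;
* for a configurable fraction of people, a cancer pathology record whose
  province of diagnosis is drawn from the mobility row of the person's home
  province — the generative analogue of the origin–destination table the
  analysis estimates;
* a truth table mapping every record to its generating entity.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the config, so identical (config, seed) pairs produce byte-identical
output files.
"""

from __future__ import annotations

import calendar
import datetime as dt
import json
import time
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _namebank
from .config import (
    BASES, CANCER_TYPES, RACES, RESULT_LABELS, STUDY_END, STUDY_START,
    TEST_TYPES, CorruptionModel, GeneratorConfig,
)
from .provinces import PROVINCES

_LETTERS_UP = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_LETTERS_LOW = _LETTERS_UP.lower()

_WINDOW_DAYS = (STUDY_END - STUDY_START).days  # inclusive range end handled below


class SyntheticData(NamedTuple):
    entities: pd.DataFrame
    hiv: pd.DataFrame
    cancer: pd.DataFrame
    truth: pd.DataFrame


# --------------------------------------------------------------------------
# population

def generate_population(config: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``config.n_entities`` ground-truth persons.

    Returns a DataFrame with columns entity_id, first_name, surname, sex,
    race, dob, home_province. Ages are log-normal around ``age_median`` at
    the study midpoint; names are drawn from the packaged bank with
    harmonically decaying rank weights.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_entities

    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    wf = _namebank.rank_weights(len(_namebank.FIRST_NAMES_F))
    wm = _namebank.rank_weights(len(_namebank.FIRST_NAMES_M))
    ws = _namebank.rank_weights(len(_namebank.SURNAMES))
    # draw indices for both sexes in one pass each to keep the stream order
    # independent of the sex vector's contents
    idx_f = rng.choice(len(_namebank.FIRST_NAMES_F), size=n, p=wf)
    idx_m = rng.choice(len(_namebank.FIRST_NAMES_M), size=n, p=wm)
    first = np.where(
        sex == "F",
        np.asarray(_namebank.FIRST_NAMES_F, dtype=object)[idx_f],
        np.asarray(_namebank.FIRST_NAMES_M, dtype=object)[idx_m])
    surname = np.asarray(_namebank.SURNAMES, dtype=object)[
        rng.choice(len(_namebank.SURNAMES), size=n, p=ws)]

    race = rng.choice(RACES, size=n,
                      p=[config.race_weights[r] for r in RACES])
    province = rng.choice(PROVINCES, size=n,
                          p=[config.province_weights[p] for p in PROVINCES])

    age = np.exp(rng.normal(np.log(config.age_median), config.age_sigma, n))
    age = np.clip(age, config.age_min, config.age_max)
    # ``age_median`` targets the median age AT CANCER DIAGNOSIS, so ages are
    # anchored at the expected diagnosis date of an eligible case under the
    # default date model: the first of k ≈ 2.5 uniform test dates falls
    # ≈ window/(k+1) ≈ 3.5 y into the window, the diagnosis is uniform
    # between the first *positive* test and the window end, and the
    # eligibility filters keep only diagnoses at or after that test —
    # together ≈ 8 y into the 2004–2014 window.
    anchor = dt.date(2012, 1, 1)
    jitter = rng.integers(0, 365, size=n)
    dob_days = (age * 365.25).astype(np.int64) + jitter
    dob = np.array([anchor - dt.timedelta(days=int(d)) for d in dob_days],
                   dtype=object)

    return pd.DataFrame({
        "entity_id": [f"P{i:07d}" for i in range(n)],
        "first_name": first,
        "surname": surname,
        "sex": sex,
        "race": race,
        "dob": dob,
        "home_province": province,
    })


# --------------------------------------------------------------------------
# corruption primitives

def corrupt_string(value: str, model: CorruptionModel,
                   rng: np.random.Generator) -> str:
    """Apply at most one single-character edit to *value*.

    With probability ``model.typo_rate`` one edit operation is drawn from
    ``model.typo_ops`` (substitution, adjacent transposition, deletion or
    insertion) and applied at a uniformly random position. With
    ``typo_rate = 0`` the input is returned unchanged.
    """
    if not value:
        raise ValueError("corrupt_string requires a non-empty value")
    if model.typo_rate == 0.0 or rng.random() >= model.typo_rate:
        return value
    ops = ("substitution", "transposition", "deletion", "insertion")
    op = rng.choice(ops, p=[model.typo_ops[o] for o in ops])
    n = len(value)
    if op == "transposition" and n >= 2:
        i = int(rng.integers(0, n - 1))
        return value[:i] + value[i + 1] + value[i] + value[i + 2:]
    if op == "deletion" and n >= 2:
        i = int(rng.integers(0, n))
        return value[:i] + value[i + 1:]
    if op == "insertion":
        i = int(rng.integers(0, n + 1))
        c = _LETTERS_LOW[int(rng.integers(0, 26))]
        return value[:i] + c + value[i:]
    # substitution (also the fallback for length-1 strings)
    i = int(rng.integers(0, n))
    orig = value[i]
    pool = _LETTERS_UP if orig.isupper() else _LETTERS_LOW
    c = pool[int(rng.integers(0, 26))]
    return value[:i] + c + value[i + 1:]


def _nickname(name: str, rng: np.random.Generator) -> str:
    """Truncation-style diminutive (common in South African usage)."""
    if len(name) <= 4:
        return name
    cut = int(rng.integers(3, 6))
    return name[:cut]


def corrupt_dob(d: dt.date, model: CorruptionModel,
                rng: np.random.Generator) -> dt.date:
    """Perturb a date of birth: day/month swap when plausible, otherwise a
    small day shift. Applied with probability ``model.dob_error_rate``."""
    if model.dob_error_rate == 0.0 or rng.random() >= model.dob_error_rate:
        return d
    if d.day <= 12 and d.day != d.month and rng.random() < 0.5:
        return dt.date(d.year, d.day, d.month)
    shift = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
    last = calendar.monthrange(d.year, d.month)[1]
    day = min(max(d.day + shift, 1), last)
    return dt.date(d.year, d.month, day)


# --------------------------------------------------------------------------
# record emission

def _rand_dates(rng: np.random.Generator, n: int) -> list[dt.date]:
    offs = rng.integers(0, _WINDOW_DAYS + 1, size=n)
    return [STUDY_START + dt.timedelta(days=int(o)) for o in offs]


def emit_records(entities: pd.DataFrame, config: GeneratorConfig,
                 rng: np.random.Generator | None = None) -> SyntheticData:
    """Emit HIV laboratory records, cancer pathology records and the truth
    table for a generated population.

    Every person receives at least one HIV record; a fraction
    ``hiv_away_province_rate`` of HIV records is issued outside the home
    province so that modal-province inference is exercised. A fraction
    ``cancer_fraction`` of people receive one cancer record whose province
    of diagnosis is drawn from the mobility row of their home province.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(entities)
    model = config.corruption
    prov_w = np.array([config.province_weights[p] for p in PROVINCES])
    mobility = config.mobility.to_numpy()
    prov_index = {p: i for i, p in enumerate(PROVINCES)}

    # person-level stable identifiers
    n_fac_per_prov = 30
    fac_counters: dict[str, int] = {}
    primary_fac = []
    folder = []
    episode = []
    for i in range(n):
        prov = entities["home_province"].iat[i]
        fac = f"{prov}-F{int(rng.integers(0, n_fac_per_prov)):02d}"
        primary_fac.append(fac)
        serial = fac_counters.get(fac, 0)
        fac_counters[fac] = serial + 1
        folder.append(f"{fac}/{serial:05d}")
        episode.append(f"E{i:07d}")

    k = 1 + rng.poisson(config.hiv_records_per_person - 1.0, size=n)
    owner = np.repeat(np.arange(n), k)
    m = owner.size
    test_dates = _rand_dates(rng, m)
    away = rng.random(m) < config.hiv_away_province_rate
    test_type = rng.choice(TEST_TYPES, size=m)
    result = rng.choice(RESULT_LABELS, size=m,
                        p=[config.hiv_result_label_weights[r]
                           for r in RESULT_LABELS])

    first_hiv: dict[int, dt.date] = {}
    hiv_rows = []
    for j in range(m):
        i = int(owner[j])
        ent = entities.iloc[i]
        prov = ent["home_province"]
        fac = primary_fac[i]
        if away[j]:
            # issued in a different province: renormalised draw over the rest
            # (degenerate one-province configs have nowhere to go)
            w = prov_w.copy()
            w[prov_index[prov]] = 0.0
            if w.sum() > 0:
                prov = PROVINCES[int(rng.choice(9, p=w / w.sum()))]
                fac = f"{prov}-F{int(rng.integers(0, n_fac_per_prov)):02d}"
        rec = _identity_fields(ent, folder[i], episode[i], test_dates[j],
                               model, rng)
        rec.update({
            "record_id": f"H{j:08d}",
            "test_type": test_type[j],
            "result_label": result[j],
            "facility_id": fac,
            "province": prov,
            "test_date": test_dates[j].isoformat(),
        })
        hiv_rows.append(rec)
        if i not in first_hiv or test_dates[j] < first_hiv[i]:
            first_hiv[i] = test_dates[j]

    has_cancer = rng.random(n) < config.cancer_fraction
    cancer_rows = []
    cn = 0
    for i in range(n):
        if not has_cancer[i]:
            continue
        ent = entities.iloc[i]
        home_i = prov_index[ent["home_province"]]
        dx_prov = PROVINCES[int(rng.choice(9, p=mobility[home_i]))]
        if rng.random() < config.missing_diagnosis_province_rate:
            dx_prov_out = ""
        else:
            dx_prov_out = dx_prov
        f0 = first_hiv[i]
        if rng.random() < config.cancer_after_hiv_prob:
            span = (STUDY_END - f0).days
            dx_date = f0 + dt.timedelta(days=int(rng.integers(0, span + 1)))
        else:
            span = (f0 - STUDY_START).days
            dx_date = STUDY_START + dt.timedelta(days=int(rng.integers(0, max(span, 1))))
        rec = _identity_fields(ent, folder[i], episode[i], dx_date, model, rng)
        rec.update({
            "record_id": f"C{cn:08d}",
            "diagnosis_date": dx_date.isoformat(),
            "cancer_type": rng.choice(
                CANCER_TYPES, p=[config.cancer_type_weights[c]
                                 for c in CANCER_TYPES]),
            "basis": rng.choice(BASES, p=[0.8, 0.15, 0.05]),
            "diagnosis_province": dx_prov_out,
            "facility_id": f"{dx_prov}-F{int(rng.integers(0, n_fac_per_prov)):02d}",
        })
        cancer_rows.append(rec)
        cn += 1

    hiv_cols = ["record_id", "first_name", "surname", "sex", "race", "dob",
                "age", "episode_number", "folder_number", "test_type",
                "result_label", "facility_id", "province", "test_date"]
    cancer_cols = ["record_id", "first_name", "surname", "sex", "race", "dob",
                   "age", "episode_number", "folder_number", "diagnosis_date",
                   "cancer_type", "basis", "diagnosis_province", "facility_id"]
    hiv = pd.DataFrame(hiv_rows, columns=hiv_cols)
    cancer = pd.DataFrame(cancer_rows, columns=cancer_cols)

    truth = pd.DataFrame({
        "record_id": list(hiv["record_id"]) + list(cancer["record_id"]),
        "entity_id": [entities["entity_id"].iat[int(i)] for i in owner]
                     + [entities["entity_id"].iat[i] for i in range(n)
                        if has_cancer[i]],
    })
    return SyntheticData(entities=entities, hiv=hiv, cancer=cancer, truth=truth)


def _identity_fields(ent, folder: str, episode: str, ref_date: dt.date,
                     model: CorruptionModel, rng: np.random.Generator) -> dict:
    """The possibly-corrupted identifier block shared by both record types."""
    first = ent["first_name"]
    if model.nickname_swap_rate and rng.random() < model.nickname_swap_rate:
        first = _nickname(first, rng)
    first = corrupt_string(first, model, rng)
    surname = corrupt_string(ent["surname"], model, rng)

    dob_out, age_out = "", ""
    if model.identifier_missing_rate and rng.random() < model.identifier_missing_rate:
        # dob withheld: the record carries age in whole years instead
        age_out = str(_age_at(ent["dob"], ref_date))
    else:
        dob_out = corrupt_dob(ent["dob"], model, rng).isoformat()

    def _ident(value: str) -> str:
        if model.identifier_missing_rate and rng.random() < model.identifier_missing_rate:
            return ""
        return corrupt_string(value, model, rng)

    return {
        "first_name": first,
        "surname": surname,
        "sex": ent["sex"],
        "race": ent["race"],
        "dob": dob_out,
        "age": age_out,
        "episode_number": _ident(episode),
        "folder_number": _ident(folder),
    }


def _age_at(dob: dt.date, when: dt.date) -> int:
    """Age in whole years (floor), the registry convention."""
    years = when.year - dob.year
    if (when.month, when.day) < (dob.month, dob.day):
        years -= 1
    return years


# --------------------------------------------------------------------------
# top-level convenience + file IO

def generate(config: GeneratorConfig) -> SyntheticData:
    """Generate the full synthetic universe for one config."""
    rng = np.random.default_rng(config.seed)
    entities = generate_population(config, rng)
    return emit_records(entities, config, rng)


def write_outputs(data: SyntheticData, outdir: str | Path,
                  config: GeneratorConfig) -> dict:
    """Write hiv_records.csv, cancer_records.csv, truth.csv and a JSON run
    manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.hiv.to_csv(outdir / "hiv_records.csv", index=False,
                    lineterminator="\n")
    data.cancer.to_csv(outdir / "cancer_records.csv", index=False,
                       lineterminator="\n")
    data.truth.to_csv(outdir / "truth.csv", index=False, lineterminator="\n")
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "stage": "simulate",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {
            "entities": int(len(data.entities)),
            "hiv_records": int(len(data.hiv)),
            "cancer_records": int(len(data.cancer)),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "simulate_manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
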