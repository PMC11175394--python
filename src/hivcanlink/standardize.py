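"""Cleaning, normalisation and blocking of identifier fields.

Raw laboratory and pathology records carry free-text names with mixed case,
punctuation, diacritics and typos, and either a date of birth or an age.
This module produces the canonical comparison fields the linkage stage
consumes and the cheap blocking keys that make pairwise comparison
tractable:

* canonical names: uppercase, diacritics folded to ASCII, punctuation
  stripped, single-spaced;
* a Soundex phonetic code of the surname;
* a birth year (from the date of birth when present, otherwise from the
  recorded age and the record's own date);
* blocking keys: phonetic-surname+birth-year, first-two-letters+birth-year,
  and the episode number when present. Two records are compared iff their
  key sets intersect — the union-of-keys design means a single corrupted
  field cannot sever a true pair.

Source columns are never mutated; cleaned values are added as new columns.
"""

from __future__ import annotations

import unicodedata

import pandas as pd

from .similarity import soundex

MISSING = ""


def normalize_name(raw: object) -> str:
    """Canonicalise a name string.

    Uppercase, diacritics folded to ASCII, non-alphabetic characters
    removed, internal whitespace collapsed to single spaces. A string that
    is empty after cleaning becomes the missing marker (empty string).

    >>> normalize_name(" van der Merwe ")
    'VAN DER MERWE'
    >>> normalize_name("N'Dlovu")
    'NDLOVU'
    >>> normalize_name("José")
    'JOSE'
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return MISSING
    s = unicodedata.normalize("NFKD", str(raw))
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.upper()
    # punctuation and digits are deleted outright; only whitespace separates
    s = "".join(c for c in s if "A" <= c <= "Z" or c.isspace())
    return " ".join(s.split())


def phonetic_code(name: str) -> str:
    """Soundex code of a canonical name; missing name gives a missing code."""
    if not name:
        return MISSING
    return soundex(name)


def _norm_identifier(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return MISSING
    return str(raw).strip().upper()


def _birth_year(dob: str, age: str, ref_date: str) -> tuple:
    """(birth year, from_age flag). Year comes from the dob when present,
    else from the recorded age and the record's own date. An age-derived
    year is ambiguous by one (age is floored), which the blocking stage
    compensates for by keying both candidate years."""
    if dob:
        return int(dob[:4]), False
    if age != "":
        try:
            return int(ref_date[:4]) - int(float(age)), True
        except (TypeError, ValueError):
            return pd.NA, False
    return pd.NA, False


def clean_records(df: pd.DataFrame, date_col: str) -> pd.DataFrame:
    """Standardise one record table (HIV or cancer).

    ``date_col`` names the record's own date column (test_date or
    diagnosis_date), used to derive a birth year when only an age is
    recorded. Returns a copy with added columns: norm_first_name,
    norm_surname, phonetic_surname, birth_year, norm_episode, norm_folder.
    """
    out = df.copy()
    sf = out["first_name"].map(normalize_name)
    ss = out["surname"].map(normalize_name)
    out["norm_first_name"] = sf
    out["norm_surname"] = ss
    out["phonetic_surname"] = ss.map(phonetic_code)
    dob = out["dob"].fillna("").astype(str)
    age = out["age"].fillna("").astype(str).str.replace(r"\.0$", "", regex=True)
    ref = out[date_col].astype(str)
    derived = [_birth_year(d, a, r) for d, a, r in zip(dob, age, ref)]
    out["birth_year"] = pd.array([y for y, _ in derived], dtype="Int64")
    out["year_from_age"] = [f for _, f in derived]
    out["norm_episode"] = out["episode_number"].map(_norm_identifier)
    out["norm_folder"] = out["folder_number"].map(_norm_identifier)
    return out


def blocking_keys(rec) -> set[str]:
    """Blocking keys of one cleaned record (a mapping or DataFrame row).

    Keys: ``S:<soundex>|<year>``, ``F:<first two letters>|<year>`` and
    ``E:<episode>`` (episode only when present). Name/year keys are skipped
    when either component is missing.
    """
    keys: set[str] = set()
    year = rec["birth_year"]
    if not pd.isna(year):
        years = [int(year)]
        if rec.get("year_from_age", False):
            years.append(int(year) - 1)  # floor-age ambiguity
        for y in years:
            if rec["phonetic_surname"]:
                keys.add(f"S:{rec['phonetic_surname']}|{y}")
            if rec["norm_first_name"]:
                keys.add(f"F:{rec['norm_first_name'][:2]}|{y}")
    if rec["norm_episode"]:
        keys.add(f"E:{rec['norm_episode']}")
    return keys


def _key_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Long (key, row-position) frame for a cleaned table."""
    rows = []
    year = df["birth_year"]
    from_age = df["year_from_age"] if "year_from_age" in df else None
    sx = df["phonetic_surname"]
    fn = df["norm_first_name"]
    ep = df["norm_episode"]
    for pos in range(len(df)):
        y = year.iat[pos]
        if not pd.isna(y):
            years = [int(y)]
            if from_age is not None and from_age.iat[pos]:
                years.append(int(y) - 1)
            for yy in years:
                if sx.iat[pos]:
                    rows.append((f"S:{sx.iat[pos]}|{yy}", pos))
                if fn.iat[pos]:
                    rows.append((f"F:{fn.iat[pos][:2]}|{yy}", pos))
        if ep.iat[pos]:
            rows.append((f"E:{ep.iat[pos]}", pos))
    return pd.DataFrame(rows, columns=["key", "pos"])


def candidate_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """All within-table record pairs sharing at least one blocking key.

    Returns a DataFrame with integer row positions ``pos_a < pos_b``,
    deduplicated across keys.
    """
    keys = _key_frame(df)
    merged = keys.merge(keys, on="key", suffixes=("_a", "_b"))
    pairs = merged.loc[merged["pos_a"] < merged["pos_b"], ["pos_a", "pos_b"]]
    return pairs.drop_duplicates(ignore_index=True)


def candidate_pairs_cross(left: pd.DataFrame,
                          right: pd.DataFrame) -> pd.DataFrame:
    """Cross-table pairs (pos_a in *left*, pos_b in *right*) sharing a key."""
    ka = _key_frame(left).rename(columns={"pos": "pos_a"})
    kb = _key_frame(right).rename(columns={"pos": "pos_b"})
    merged = ka.merge(kb, on="key")
    return merged[["pos_a", "pos_b"]].drop_duplicates(ignore_index=True)
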