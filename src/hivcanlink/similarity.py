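"""String comparators used by the record-linkage stage.

Two primitives live here:

* :func:`jaro_winkler` — the standard name comparator in record linkage,
  returning a similarity in [0, 1]. A pure-Python reference implementation is
  the public API; a numba kernel (:func:`jaro_winkler_pairs`) computes the
  same quantity over large arrays of candidate pairs.
* :func:`soundex` — the American Soundex phonetic code, used to build
  blocking keys that survive most single-character surname typos.

Both operate on *canonical* strings (uppercase ASCII, see
:mod:`hivcanlink.standardize`); neither performs its own normalisation.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["jaro_winkler", "jaro_winkler_pairs", "soundex", "encode_strings"]

_PREFIX_WEIGHT = 0.1
_MAX_PREFIX = 4


def jaro_winkler(s1: str, s2: str) -> float:
    """Jaro–Winkler similarity between two strings.

    Identical strings score 1.0; strings with no characters matching within
    the Jaro window score 0.0. The Winkler prefix adjustment (weight 0.1,
    at most 4 characters) is applied unconditionally.

    >>> round(jaro_winkler("MARTHA", "MARHTA"), 4)
    0.9611
    """
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    jaro = _jaro(s1, s2)
    if jaro == 0.0:
        return 0.0
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix == _MAX_PREFIX:
            break
        prefix += 1
    return jaro + prefix * _PREFIX_WEIGHT * (1.0 - jaro)


def _jaro(s1: str, s2: str) -> float:
    len1, len2 = len(s1), len(s2)
    window = max(max(len1, len2) // 2 - 1, 0)
    flags1 = [False] * len1
    flags2 = [False] * len2
    matches = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == c:
                flags1[i] = True
                flags2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # half-transpositions: matched characters out of order
    half_t = 0
    j = 0
    for i in range(len1):
        if flags1[i]:
            while not flags2[j]:
                j += 1
            if s1[i] != s2[j]:
                half_t += 1
            j += 1
    t = half_t / 2.0
    return (matches / len1 + matches / len2 + (matches - t) / matches) / 3.0


# --------------------------------------------------------------------------
# batch evaluation
#
# Candidate-pair generation at realistic scale produces millions of pairs;
# the per-pair Python implementation above is kept as the reference and the
# kernel below, compiled once per process, does the bulk work. Strings are
# encoded as fixed-width uint8 rows (zero padded).

MAX_NAME_LEN = 32


def encode_strings(values, max_len: int = MAX_NAME_LEN):
    """Encode an iterable of ASCII strings as a (n, max_len) uint8 array plus
    a length vector. Longer strings are truncated."""
    values = list(values)
    n = len(values)
    enc = np.zeros((n, max_len), dtype=np.uint8)
    lengths = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(values):
        if s is None:
            continue
        b = s.encode("ascii", errors="replace")[:max_len]
        enc[i, : len(b)] = np.frombuffer(b, dtype=np.uint8)
        lengths[i] = len(b)
    return enc, lengths


@numba.njit(cache=True)
def _jw_one(enc, lengths, a, b):  # pragma: no cover - exercised via wrapper
    len1 = lengths[a]
    len2 = lengths[b]
    if len1 == 0 and len2 == 0:
        return 1.0  # identical (degenerate) strings
    if len1 == 0 or len2 == 0:
        return 0.0
    same = len1 == len2
    if same:
        for k in range(len1):
            if enc[a, k] != enc[b, k]:
                same = False
                break
        if same:
            return 1.0
    window = max(len1, len2) // 2 - 1
    if window < 0:
        window = 0
    flags1 = np.zeros(len1, dtype=np.bool_)
    flags2 = np.zeros(len2, dtype=np.bool_)
    matches = 0
    for i in range(len1):
        lo = i - window
        if lo < 0:
            lo = 0
        hi = i + window + 1
        if hi > len2:
            hi = len2
        for j in range(lo, hi):
            if not flags2[j] and enc[b, j] == enc[a, i]:
                flags1[i] = True
                flags2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    half_t = 0
    j = 0
    for i in range(len1):
        if flags1[i]:
            while not flags2[j]:
                j += 1
            if enc[a, i] != enc[b, j]:
                half_t += 1
            j += 1
    t = half_t / 2.0
    jaro = (matches / len1 + matches / len2 + (matches - t) / matches) / 3.0
    prefix = 0
    maxp = min(min(len1, len2), _MAX_PREFIX)
    for k in range(maxp):
        if enc[a, k] != enc[b, k]:
            break
        prefix += 1
    return jaro + prefix * _PREFIX_WEIGHT * (1.0 - jaro)


@numba.njit(cache=True, parallel=False)
def _jw_pairs(enc, lengths, ia, ib, out):  # pragma: no cover
    for k in range(ia.shape[0]):
        out[k] = _jw_one(enc, lengths, ia[k], ib[k])


def jaro_winkler_pairs(enc: np.ndarray, lengths: np.ndarray,
                       ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Jaro–Winkler similarity for index pairs (ia[k], ib[k]) into an encoded
    string table; equals :func:`jaro_winkler` element-wise."""
    out = np.empty(ia.shape[0], dtype=np.float64)
    _jw_pairs(enc, lengths,
              np.ascontiguousarray(ia, dtype=np.int64),
              np.ascontiguousarray(ib, dtype=np.int64), out)
    return out


# --------------------------------------------------------------------------
# phonetic coding

_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


def soundex(name: str) -> str:
    """American Soundex code (letter + three digits) of a canonical name.

    Vowels separate repeated codes; H and W do not. Non-alphabetic
    characters are ignored. Empty input yields an empty code.

    >>> soundex("ROBERT"), soundex("RUPERT")
    ('R163', 'R163')
    """
    letters = [c for c in name.upper() if "A" <= c <= "Z"]
    if not letters:
        return ""
    first = letters[0]
    code = first
    last = _SOUNDEX_CODES.get(first, "")
    for c in letters[1:]:
        if c in "HW":
            continue
        d = _SOUNDEX_CODES.get(c, "")
        if d == "":
            last = ""  # vowel: resets the repeat-suppression state
            continue
        if d != last:
            code += d
            last = d
        if len(code) == 4:
            break
    return code.ljust(4, "0")
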