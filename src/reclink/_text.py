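"""String comparators and phonetic codes used throughout the engine.

Jaro-Winkler is the default approximate comparator for name-like fields;
American Soundex (with the H/W adjacency rule) is the default phonetic
transform for derived blocking/matching columns.  Both are deterministic
pure functions; ``jaro_winkler_cached`` memoises on the (unordered) value
pair because linkage runs compare the same value pairs many times across
candidate record pairs.
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["jaro", "jaro_winkler", "jaro_winkler_cached", "soundex"]


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1]; 1.0 iff equal non-empty strings."""
    if s1 == s2:
        return 1.0 if s1 else 0.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(len1, len2) // 2 - 1
    if window < 0:
        window = 0
    flags1 = [False] * len1
    flags2 = [False] * len2
    matches = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == c:
                flags1[i] = flags2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: matched characters out of relative order, halved
    k = 0
    transpositions = 0
    for i in range(len1):
        if flags1[i]:
            while not flags2[k]:
                k += 1
            if s1[i] != s2[k]:
                transpositions += 1
            k += 1
    t = transpositions // 2
    m = matches
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity boosted for a shared prefix (up to ``max_prefix`` chars)."""
    j = jaro(s1, s2)
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix >= max_prefix:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)


@lru_cache(maxsize=1 << 18)
def _jw_ordered(s1: str, s2: str) -> float:
    return jaro_winkler(s1, s2)


def jaro_winkler_cached(s1: str, s2: str) -> float:
    """Memoised Jaro-Winkler; canonicalises argument order (the score is symmetric)."""
    if s1 > s2:
        s1, s2 = s2, s1
    return _jw_ordered(s1, s2)


_SOUNDEX_CODES = {}
for _letters, _digit in (
    ("BFPV", "1"),
    ("CGJKQSXZ", "2"),
    ("DT", "3"),
    ("L", "4"),
    ("MN", "5"),
    ("R", "6"),
):
    for _ch in _letters:
        _SOUNDEX_CODES[_ch] = _digit


def soundex(value: str) -> str:
    """American Soundex code (letter + 3 digits, zero padded).

    Vowels (A, E, I, O, U, Y) separate identical consonant codes; H and W do
    not — consonants with the same code straddling H/W collapse to one digit.
    Non-alphabetic characters are ignored; an empty or non-alphabetic input
    yields the empty string.
    """
    letters = [c for c in value.upper() if "A" <= c <= "Z"]
    if not letters:
        return ""
    first = letters[0]
    out = [first]
    prev_code = _SOUNDEX_CODES.get(first, "")
    for ch in letters[1:]:
        if ch in "HW":
            continue
        code = _SOUNDEX_CODES.get(ch, "")
        if code == "":
            prev_code = ""  # vowel: breaks adjacency
            continue
        if code != prev_code:
            out.append(code)
            if len(out) == 4:
                break
        prev_code = code
    return ("".join(out) + "000")[:4]
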