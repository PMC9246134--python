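"""Classic Porter (1980) suffix-stripping stemmer.

Implements the five-step algorithm exactly as published: measure-based
conditions on the stem ([C](VC)^m[V]), longest-matching-suffix rule sets,
and the *S / *v* / *d / *o letter conditions.  Words of length 1 or 2 are
returned unchanged.  Outputs are frequently non-words ("stay" -> "stai");
that is intended — stems are equivalence-class labels, not dictionary
entries.
"""

from __future__ import annotations

__all__ = ["porter_stem"]

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if cons and prev_vowel:
            m += 1
        prev_vowel = not cons
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(stem: str) -> bool:
    return (
        len(stem) >= 2
        and stem[-1] == stem[-2]
        and _is_consonant(stem, len(stem) - 1)
    )


def _ends_cvc(stem: str) -> bool:
    """*o: ends consonant-vowel-consonant, final consonant not w, x or y."""
    if len(stem) < 3:
        return False
    return (
        _is_consonant(stem, len(stem) - 3)
        and not _is_consonant(stem, len(stem) - 2)
        and _is_consonant(stem, len(stem) - 1)
        and stem[-1] not in "wxy"
    )


def _replace_longest(word: str, rules, cond=None):
    """Apply the single rule whose suffix is the longest match.

    ``rules`` is a list of (suffix, replacement) with suffixes assumed
    pre-sorted longest-first.  If the longest matching suffix fails the
    condition, no other rule in the set is tried (per the algorithm).
    Returns the (possibly unchanged) word.
    """
    for suffix, repl in rules:
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if cond is None or cond(stem):
                return stem + repl
            return word
    return word


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        stem = word[:-3]
        return stem + "ee" if _measure(stem) > 0 else word
    removed = False
    if word.endswith("ed"):
        stem = word[:-2]
        if _contains_vowel(stem):
            word, removed = stem, True
    elif word.endswith("ing"):
        stem = word[:-3]
        if _contains_vowel(stem):
            word, removed = stem, True
    if removed:
        if word.endswith(("at", "bl", "iz")):
            word += "e"
        elif _ends_double_consonant(word) and word[-1] not in "lsz":
            word = word[:-1]
        elif _measure(word) == 1 and _ends_cvc(word):
            word += "e"
    return word


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


_STEP2_RULES = sorted(
    [
        ("ational", "ate"),
        ("tional", "tion"),
        ("enci", "ence"),
        ("anci", "ance"),
        ("izer", "ize"),
        ("abli", "able"),
        ("alli", "al"),
        ("entli", "ent"),
        ("eli", "e"),
        ("ousli", "ous"),
        ("ization", "ize"),
        ("ation", "ate"),
        ("ator", "ate"),
        ("alism", "al"),
        ("iveness", "ive"),
        ("fulness", "ful"),
        ("ousness", "ous"),
        ("aliti", "al"),
        ("iviti", "ive"),
        ("biliti", "ble"),
    ],
    key=lambda r: -len(r[0]),
)

_STEP3_RULES = sorted(
    [
        ("icate", "ic"),
        ("ative", ""),
        ("alize", "al"),
        ("iciti", "ic"),
        ("ical", "ic"),
        ("ful", ""),
        ("ness", ""),
    ],
    key=lambda r: -len(r[0]),
)

_STEP4_SUFFIXES = sorted(
    [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ],
    key=len,
    reverse=True,
)


def _step4(word: str) -> str:
    for suffix in _STEP4_SUFFIXES:
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and (not stem or stem[-1] not in "st"):
                    return word
                return stem
            return word
    return word


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return word


def _step5b(word: str) -> str:
    if _measure(word) > 1 and word.endswith("ll"):
        return word[:-1]
    return word


def porter_stem(token: str) -> str:
    """Stem one lowercase alphabetic token with the classic Porter algorithm.

    Parameters
    ----------
    token
        Lowercase ASCII-alphabetic word.  Raises ``ValueError`` if empty.

    Examples
    --------
    >>> porter_stem("caresses")
    'caress'
    >>> porter_stem("stay")
    'stai'
    """
    if not token:
        raise ValueError("cannot stem an empty token")
    if not token.isascii() or not token.isalpha() or token != token.lower():
        raise ValueError(f"porter_stem expects a lowercase alphabetic token, got {token!r}")
    if len(token) <= 2:
        return token
    word = _step1a(token)
    word = _step1b(word)
    word = _step1c(word)
    word = _replace_longest(word, _STEP2_RULES, cond=lambda s: _measure(s) > 0)
    word = _replace_longest(word, _STEP3_RULES, cond=lambda s: _measure(s) > 0)
    word = _step4(word)
    word = _step5a(word)
    word = _step5b(word)
    return word
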