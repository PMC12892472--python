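"""Snowball English ("Porter2") stemmer.

A faithful, dependency-free implementation of the Snowball English stemming
algorithm: the R1/R2 region machinery, the special-form exceptions, and the
five suffix-stripping steps.  Consonant ``y`` is tracked internally by
uppercasing to ``Y``; callers always receive lowercase output.

Only lowercase ASCII words are expected (the tokenizer upstream guarantees
this); words of one or two characters are returned unchanged.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = frozenset("aeiouy")  # lowercase y is vocalic; consonant y is 'Y'
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDINGS = frozenset("cdeghkmnrt")

_EXCEPTIONS = {
    "skis": "ski", "skies": "sky", "dying": "die", "lying": "lie",
    "tying": "tie", "idly": "idl", "gently": "gentl", "ugly": "ugli",
    "early": "earli", "only": "onli", "singly": "singl",
    "sky": "sky", "news": "news", "howe": "howe", "atlas": "atlas",
    "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}
_EXCEPTIONS_POST_1A = frozenset(
    ("inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed")
)

_STEP2 = (
    ("ization", "ize"), ("ational", "ate"), ("fulness", "ful"),
    ("ousness", "ous"), ("iveness", "ive"), ("tional", "tion"),
    ("biliti", "ble"), ("lessli", "less"), ("entli", "ent"),
    ("ation", "ate"), ("alism", "al"), ("aliti", "al"), ("ousli", "ous"),
    ("iviti", "ive"), ("fulli", "ful"), ("enci", "ence"), ("anci", "ance"),
    ("abli", "able"), ("izer", "ize"), ("ator", "ate"), ("alli", "al"),
    ("bli", "ble"), ("ogi", "og"), ("li", ""),
)
_STEP3 = (
    ("ational", "ate"), ("tional", "tion"), ("alize", "al"),
    ("icate", "ic"), ("iciti", "ic"), ("ative", ""), ("ical", "ic"),
    ("ness", ""), ("ful", ""),
)
_STEP4 = (
    "ement", "ance", "ence", "able", "ible", "ment", "ant", "ent",
    "ism", "ate", "iti", "ous", "ive", "ize", "ion", "al", "er", "ic",
)


def _is_vowel(word: str, i: int) -> bool:
    return word[i] in _VOWELS


def _r1_start(word: str) -> int:
    # gener-, commun-, arsen- keep their full prefix out of R1
    for prefix in ("gener", "commun", "arsen"):
        if word.startswith(prefix):
            return len(prefix)
    for i in range(1, len(word)):
        if not _is_vowel(word, i) and _is_vowel(word, i - 1):
            return i + 1
    return len(word)


def _r2_start(word: str, r1: int) -> int:
    for i in range(r1 + 1, len(word)):
        if not _is_vowel(word, i) and _is_vowel(word, i - 1):
            return i + 1
    return len(word)


def _ends_in_short_syllable(word: str) -> bool:
    if len(word) >= 3:
        return (
            not _is_vowel(word, -3 + len(word))
            and _is_vowel(word, len(word) - 2)
            and not _is_vowel(word, len(word) - 1)
            and word[-1] not in "wxY"
        )
    if len(word) == 2:
        return _is_vowel(word, 0) and not _is_vowel(word, 1)
    return False


def _is_short(word: str) -> bool:
    return _ends_in_short_syllable(word) and _r1_start(word) >= len(word)


def _has_vowel(segment: str) -> bool:
    return any(c in _VOWELS for c in segment)


def _step_1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ied") or word.endswith("ies"):
        return word[:-2] if len(word) > 4 else word[:-1]
    if word.endswith("us") or word.endswith("ss"):
        return word
    if word.endswith("s") and _has_vowel(word[:-2]):
        return word[:-1]
    return word


def _step_1b(word: str) -> str:
    r1 = _r1_start(word)
    for suffix in ("eedly", "eed"):
        if word.endswith(suffix):
            if len(word) - len(suffix) >= r1:
                return word[: -len(suffix)] + "ee"
            return word
    for suffix in ("ingly", "edly", "ing", "ed"):
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if not _has_vowel(stem):
                return word
            if stem.endswith(("at", "bl", "iz")):
                return stem + "e"
            if stem.endswith(_DOUBLES):
                return stem[:-1]
            if _is_short(stem):
                return stem + "e"
            return stem
    return word


def _step_1c(word: str) -> str:
    if len(word) > 2 and word[-1] in "yY" and not _is_vowel(word, len(word) - 2):
        return word[:-1] + "i"
    return word


def _step_2(word: str) -> str:
    r1 = _r1_start(word)
    for suffix, repl in _STEP2:
        if word.endswith(suffix):
            if len(word) - len(suffix) < r1:
                return word
            if suffix == "ogi":
                if word.endswith("logi"):
                    return word[:-1]
                return word
            if suffix == "li":
                if len(word) > 2 and word[-3] in _LI_ENDINGS:
                    return word[:-2]
                return word
            return word[: -len(suffix)] + repl
    return word


def _step_3(word: str) -> str:
    r1 = _r1_start(word)
    r2 = _r2_start(word, r1)
    for suffix, repl in _STEP3:
        if word.endswith(suffix):
            if len(word) - len(suffix) < r1:
                return word
            if suffix == "ative" and len(word) - len(suffix) < r2:
                return word
            return word[: -len(suffix)] + repl
    return word


def _step_4(word: str) -> str:
    r1 = _r1_start(word)
    r2 = _r2_start(word, r1)
    for suffix in _STEP4:
        if word.endswith(suffix):
            if len(word) - len(suffix) < r2:
                return word
            if suffix == "ion" and word[-4:-3] not in ("s", "t"):
                return word
            return word[: -len(suffix)]
    return word


def _step_5(word: str) -> str:
    r1 = _r1_start(word)
    r2 = _r2_start(word, r1)
    if word.endswith("e"):
        if len(word) - 1 >= r2:
            return word[:-1]
        if len(word) - 1 >= r1 and not _ends_in_short_syllable(word[:-1]):
            return word[:-1]
        return word
    if word.endswith("l") and len(word) - 1 >= r2 and word[-2:-1] == "l":
        return word[:-1]
    return word


def stem(word: str) -> str:
    """Return the Snowball English stem of a lowercase word."""
    word = word.lower()
    if len(word) <= 2:
        return word
    if word.startswith("'"):
        word = word[1:]
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]
    # mark consonant y (word-initial, or following a vowel) as 'Y'
    chars = list(word)
    if chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and chars[i - 1] in _VOWELS:
            chars[i] = "Y"
    word = "".join(chars)
    # step 0: possessive endings
    for suffix in ("'s'", "'s", "'"):
        if word.endswith(suffix):
            word = word[: -len(suffix)]
            break
    word = _step_1a(word)
    if word in _EXCEPTIONS_POST_1A:
        return word
    word = _step_1b(word)
    word = _step_1c(word)
    word = _step_2(word)
    word = _step_3(word)
    word = _step_4(word)
    word = _step_5(word)
    return word.replace("Y", "y")
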