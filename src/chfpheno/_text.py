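"""Text normalization shared by keyword discovery, features, and chunking.

Clinical notes are lowercased and reduced to alphanumeric tokens, with two
exceptions: empty square-bracket and parenthesis pairs (``[ ]``, ``( )``) are
kept as the standalone tokens ``[]`` and ``()``.  These checkbox markers come
from intake questionnaires ("[] CHF") and are meaningful lexicon entries, so
they must survive punctuation stripping.

Normalization modes:

``stem``
    Porter suffix stripping only.
``lemma``
    A light rule-based inflection normalizer (plural folding plus a small
    irregular map) only.
``both`` (default)
    Lemmatize first, then stem — the stemmer has the final say, so lexicon
    forms look like ``histori congest heart failur``.
"""

from __future__ import annotations

import re
from functools import lru_cache

__all__ = [
    "tokenize",
    "split_sentences",
    "normalize_token",
    "normalize_text",
    "sentence_token_lists",
    "porter_stem",
    "lemmatize",
]

_BRACKET_RE = re.compile(r"\[\s*\]")
_PAREN_RE = re.compile(r"\(\s*\)")
# after bracket collapsing, a token is "[]", "()", or a run of alphanumerics
_TOKEN_RE = re.compile(r"\[\]|\(\)|[a-z0-9]+")
_SENTENCE_RE = re.compile(r"[.!?\n]+")

NORMALIZER_MODES = ("stem", "lemma", "both", "none")


def tokenize(text: str) -> list[str]:
    """Lowercase and split into tokens, preserving ``[]`` / ``()`` markers."""
    text = text.lower()
    text = _BRACKET_RE.sub(" [] ", text)
    text = _PAREN_RE.sub(" () ", text)
    return _TOKEN_RE.findall(text)


def split_sentences(text: str) -> list[str]:
    """Split on sentence-ending punctuation and newlines; drops empty pieces."""
    return [s for s in (p.strip() for p in _SENTENCE_RE.split(text)) if s]


def normalize_token(token: str, mode: str = "both") -> str:
    if token in ("[]", "()") or mode == "none":
        return token
    if mode in ("lemma", "both"):
        token = lemmatize(token)
    if mode in ("stem", "both"):
        token = porter_stem(token)
    return token


def normalize_text(text: str, mode: str = "both") -> list[str]:
    """Full normalization: tokenize then per-token normalize.

    Deterministic and pure; an empty string yields an empty list.
    """
    if mode not in NORMALIZER_MODES:
        raise ValueError(f"unknown normalizer mode {mode!r}")
    return [normalize_token(t, mode) for t in tokenize(text)]


@lru_cache(maxsize=200_000)
def _normalize_sentence_cached(sentence: str, mode: str) -> tuple[str, ...]:
    return tuple(normalize_token(t, mode) for t in tokenize(sentence))


def sentence_token_lists(text: str, mode: str = "both") -> list[tuple[str, ...]]:
    """Normalized token tuples per sentence (n-grams never cross sentences).

    Results are memoized per distinct sentence string, which makes repeated
    boilerplate in large corpora cheap to re-normalize.
    """
    if mode not in NORMALIZER_MODES:
        raise ValueError(f"unknown normalizer mode {mode!r}")
    out = []
    for sent in split_sentences(text):
        toks = _normalize_sentence_cached(sent, mode)
        if toks:
            out.append(toks)
    return out


# ---------------------------------------------------------------------------
# Light lemmatizer
# ---------------------------------------------------------------------------

_IRREGULAR_PLURALS = {
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "men": "man",
    "women": "woman",
    "mice": "mouse",
    "geese": "goose",
}


def lemmatize(word: str) -> str:
    """Heuristic inflection folding (plural nouns), not a full lemmatizer."""
    if word in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[word]
    if len(word) > 4 and word.endswith("ies"):
        return word[:-3] + "y"
    if len(word) > 4 and word.endswith(("ses", "xes", "zes", "ches", "shes")):
        return word[:-2]
    if len(word) > 3 and word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


# ---------------------------------------------------------------------------
# Porter stemmer (classic 1980 algorithm, steps 1a-5b)
# ---------------------------------------------------------------------------

_VOWELS = set("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """m in the [C](VC)^m[V] decomposition."""
    n = len(stem)
    i = 0
    while i < n and _is_consonant(stem, i):
        i += 1
    m = 0
    while i < n:
        while i < n and not _is_consonant(stem, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_consonant(stem, i):
            i += 1
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _post_1b(word: str) -> str:
    if word.endswith(("at", "bl", "iz")):
        return word + "e"
    if _ends_double_consonant(word) and word[-1] not in "lsz":
        return word[:-1]
    if _measure(word) == 1 and _ends_cvc(word):
        return word + "e"
    return word


def porter_stem(word: str) -> str:
    if len(word) <= 2:
        return word
    w = word

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _contains_vowel(w[:-2]):
        w = _post_1b(w[:-2])
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w = _post_1b(w[:-3])

    # step 1c
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 3
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 4
    for suffix in sorted(_STEP4, key=len, reverse=True):
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and (not stem or stem[-1] not in "st"):
                    break
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # step 5b
    if w.endswith("ll") and _measure(w) > 1:
        w = w[:-1]

    return w
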