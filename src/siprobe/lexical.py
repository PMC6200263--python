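"""Word-level lexical measures: function-word classification, syllable counts,
and min-max normalized log corpus frequency.

The three measures feed the working-memory load estimators: CW counts buffered
content words, CL scales content words by normalized log frequency, SYL scales
words by syllabic length. Function words (articles, prepositions, auxiliary
verbs, "and" in English; prepositions and "и" in Russian) are assumed to add
negligible memory cost and are excluded from the content-word estimators.

Function-word lists ship as plain-text data files and can be overridden per
call, so the classification is a concrete, reproducible closed list rather
than an open grammatical category.
"""

from __future__ import annotations

import math
import re
from functools import lru_cache
from importlib import resources

from .errors import ConfigurationError, DegenerateTableError

SUPPORTED_LANGUAGES = ("en", "ru")

_VOWELS_RU = "аеёиоуыэюя"
_VOWEL_GROUP_EN = re.compile(r"[aeiouy]+")
_RU_VOWEL = re.compile(f"[{_VOWELS_RU}]")
_LETTER = re.compile(r"[^\W\d_]", re.UNICODE)


def normalize_token(surface: str) -> str:
    """Lowercase and strip non-letter edge characters (punctuation, quotes)."""
    token = surface.strip().lower()
    # peel punctuation/digit clutter off the edges, keep word-internal hyphens
    start, end = 0, len(token)
    while start < end and not _LETTER.match(token[start]) and not token[start].isdigit():
        start += 1
    while end > start and not _LETTER.match(token[end - 1]) and not token[end - 1].isdigit():
        end -= 1
    return token[start:end]


@lru_cache(maxsize=None)
def function_words(language: str) -> frozenset[str]:
    """Shipped closed function-word list for ``language`` ('en' or 'ru')."""
    lang = language.lower()
    if lang not in SUPPORTED_LANGUAGES:
        raise ConfigurationError(f"unsupported language: {language!r}")
    text = (
        resources.files("siprobe.data")
        .joinpath(f"function_words_{lang}.txt")
        .read_text(encoding="utf-8")
    )
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def classify_word(surface: str, language: str, word_list: frozenset[str] | None = None) -> str:
    """Classify ``surface`` as ``"function"`` or ``"content"``.

    A token is a function word iff its normalized form is in the language's
    function-word list; everything else (including out-of-list grammatical
    words, numerals and hyphenated compounds) counts as content.
    """
    if not surface or not surface.strip():
        raise ValueError("empty surface form")
    if word_list is None:
        word_list = function_words(language)
    elif language.lower() not in SUPPORTED_LANGUAGES:
        raise ConfigurationError(f"unsupported language: {language!r}")
    return "function" if normalize_token(surface) in word_list else "content"


def count_syllables(surface: str, language: str) -> int:
    """Heuristic syllable count, floored at 1.

    Russian: the number of Cyrillic vowel letters (а е ё и о у ы э ю я) —
    exact for Russian orthography. English: the number of maximal vowel-letter
    groups (a e i o u y), minus one when the word ends in a lone silent "e"
    and the count would stay >= 1. The English rule is a vowel-group heuristic,
    not a pronunciation dictionary; swap in a dictionary-based counter for
    corpus work where that matters.
    """
    lang = language.lower()
    if lang not in SUPPORTED_LANGUAGES:
        raise ConfigurationError(f"unsupported language: {language!r}")
    token = normalize_token(surface)
    if not _LETTER.search(token):
        raise ValueError(f"no letters in token: {surface!r}")
    if lang == "ru":
        n = len(_RU_VOWEL.findall(token))
        return max(n, 1)
    groups = _VOWEL_GROUP_EN.findall(token)
    n = len(groups)
    if n > 1 and token.endswith("e") and groups[-1] == "e":
        n -= 1
    return max(n, 1)


def normalized_log_frequency(f: float, f_min: float, f_max: float) -> float:
    """Min-max normalized log absolute frequency, clamped to [0, 1].

    Maps ``f`` to ``(log f - log F_min) / (log F_max - log F_min)`` where
    F_min/F_max are the least/most frequent corpus words. Out-of-range ``f``
    (e.g. an out-of-vocabulary lemma assigned a floor count) clamps to the
    unit interval rather than extrapolating.
    """
    if f <= 0 or f_min <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive counts")
    if f_min == f_max:
        raise DegenerateTableError("F_min == F_max: normalization undefined")
    value = (math.log(f) - math.log(f_min)) / (math.log(f_max) - math.log(f_min))
    return min(max(value, 0.0), 1.0)
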