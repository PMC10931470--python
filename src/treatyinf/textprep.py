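"""Clause-text preprocessing: tokenisation, stop-term removal, stemming/lemmatisation.

The default pipeline lower-cases, drops punctuation at tokenisation, removes
English stop words and lemmatises.  Hyphenated compounds stay single tokens
("health-related" is one token), which matters because clause vocabulary is
full of such compounds and splitting them would distort term frequencies.

Reduction is deliberately pluggable: stemming (Porter) collapses inflected
forms aggressively and may produce non-dictionary stems; the lemmatizer is a
light rule-based alternative returning dictionary-looking base forms
("caring" -> "care").  Different reducers give different vectors, so any
cross-implementation comparison should pin the reduction mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

__all__ = [
    "REDUCTION_MODES",
    "PreprocessConfig",
    "TokenizedDoc",
    "tokenize",
    "remove_stopwords",
    "reduce_tokens",
    "porter_stem",
    "lemmatize_token",
    "preprocess",
    "preprocess_corpus",
    "load_stopword_file",
]

REDUCTION_MODES = ("none", "stem", "lemma")

#: Default stop-term list: scikit-learn's standard English list (frozen, 318 terms).
DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)

# Word tokens: runs of word characters, optionally joined by internal
# hyphens/apostrophes; all other punctuation is a separator.
_TOKEN_RE = re.compile(r"\w+(?:['’-]\w+)*")


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the preprocessing pipeline.

    ``reduction`` is one of ``none`` (identity), ``stem`` (Porter) or
    ``lemma`` (rule-based, the default).  ``passthrough()`` gives the
    all-off configuration (lower-casing only) under which every token of the
    raw text survives — the configuration used by the worked vocabulary
    examples, where auxiliary words like "should" are counted.
    """

    lowercase: bool = True
    remove_stopwords: bool = True
    reduction: str = "lemma"
    stopword_list: frozenset[str] = DEFAULT_STOPWORDS

    def __post_init__(self) -> None:
        if self.reduction not in REDUCTION_MODES:
            raise ValueError(
                f"unknown reduction mode {self.reduction!r}; valid modes are {REDUCTION_MODES}"
            )
        object.__setattr__(self, "stopword_list", frozenset(self.stopword_list))

    @classmethod
    def passthrough(cls) -> "PreprocessConfig":
        """Lower-cased tokenisation only: no stop-term removal, no reduction."""
        return cls(lowercase=True, remove_stopwords=False, reduction="none")


@dataclass(frozen=True)
class TokenizedDoc:
    """A preprocessed clause: treaty id plus its ordered token list."""

    treaty_id: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split text into word tokens, dropping punctuation.

    Internal hyphens and apostrophes are kept ("health-related" is a single
    token); every other punctuation character separates tokens.  Whitespace-only
    input yields an empty list.
    """
    if lowercase:
        text = text.lower()
    return _TOKEN_RE.findall(text)


def remove_stopwords(tokens: Sequence[str], stoplist: Iterable[str] = DEFAULT_STOPWORDS) -> list[str]:
    """Order-preserving removal of stop terms (idempotent)."""
    stopset = set(stoplist)
    return [tok for tok in tokens if tok not in stopset]


# ---------------------------------------------------------------------------
# Porter stemmer (classic 1980 algorithm, steps 1a-5b).

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions ([C](VC)^m[V])."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        vowel = not _is_cons(stem, i)
        if not vowel and prev_vowel:
            m += 1
        prev_vowel = vowel
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def porter_stem(word: str) -> str:
    """Porter stem of a single lower-case token.

    Tokens shorter than three characters are returned unchanged, as in the
    original algorithm.
    """
    if len(word) <= 2:
        return word
    w = word

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # Step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 3
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and (not stem or stem[-1] not in "st"):
                    continue
                w = stem
            break

    # Step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# Rule-based lemmatizer.

_LEMMA_EXCEPTIONS = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "has": "have", "had": "have", "having": "have",
    "made": "make", "took": "take", "taken": "take", "given": "give",
    "signed": "sign", "men": "man", "women": "woman",
}


def lemmatize_token(word: str) -> str:
    """Reduce a lower-case token to a dictionary-looking base form.

    Handles regular plural and verbal inflections with light spelling
    repair: ``caring -> care``, ``policies -> policy``, ``measures ->
    measure``, ``running -> run``.  Irregular forms outside the small
    exception table pass through unchanged — the goal is merging inflected
    variants of clause vocabulary, not full morphological analysis.
    """
    if word in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[word]
    if len(word) <= 3:
        return word

    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]

    for suffix in ("ing", "ed"):
        if word.endswith(suffix) and len(word) - len(suffix) >= 2:
            stem = word[: -len(suffix)]
            if not _has_vowel(stem):
                continue
            if _ends_double_cons(stem) and stem[-1] not in "lsz":
                return stem[:-1]
            if _ends_cvc(stem):
                return stem + "e"
            if stem.endswith(("at", "iz", "bl", "v", "c", "g", "u")) and not stem.endswith("ct"):
                # creating -> create, protecting -> protect (ct excluded)
                return stem + "e" if stem[-1] not in _VOWELS else stem
            return stem
    return word


def reduce_tokens(tokens: Sequence[str], mode: str = "lemma") -> list[str]:
    """Per-token reduction; preserves order and length.

    ``none`` is the identity; ``stem`` applies the Porter stemmer; ``lemma``
    the rule-based lemmatizer.
    """
    if mode == "none":
        return list(tokens)
    if mode == "stem":
        return [porter_stem(tok) for tok in tokens]
    if mode == "lemma":
        return [lemmatize_token(tok) for tok in tokens]
    raise ValueError(f"unknown reduction mode {mode!r}; valid modes are {REDUCTION_MODES}")


def preprocess(text: str, config: PreprocessConfig | None = None) -> list[str]:
    """Full pipeline: tokenize -> remove stop terms -> reduce. Deterministic."""
    config = config or PreprocessConfig()
    tokens = tokenize(text, lowercase=config.lowercase)
    if config.remove_stopwords:
        tokens = remove_stopwords(tokens, config.stopword_list)
    return reduce_tokens(tokens, config.reduction)


def preprocess_corpus(corpus, config: PreprocessConfig | None = None) -> list[TokenizedDoc]:
    """Preprocess every clause of a corpus into :class:`TokenizedDoc`."""
    config = config or PreprocessConfig()
    return [
        TokenizedDoc(treaty_id=rec.treaty_id, tokens=tuple(preprocess(rec.clause_text, config)))
        for rec in corpus
    ]


def load_stopword_file(path: str | Path) -> frozenset[str]:
    """Read a one-token-per-line stop-term file (blank lines ignored)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(line.strip().lower() for line in lines if line.strip())
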