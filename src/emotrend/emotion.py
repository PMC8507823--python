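"""Lexicon-based per-text emotion scoring.

A text is preprocessed into lowercase alphabetic tokens (emojis replaced by
word names, contractions/shortcuts expanded, URLs and punctuation stripped,
stopwords removed), each token is looked up in a word->emotion dictionary,
and the per-emotion hit counts are divided by the total token count, giving
five scores in [0, 1]. The compound negative-emotion scale is
``anger + fear - happiness + sadness`` (surprise is excluded because it is
ambiguous in valence), so it ranges over [-1, 3].
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence

import pandas as pd

from .config import EMOTIONS

__all__ = [
    "Lexicon",
    "EmotionScores",
    "preprocess",
    "score_text",
    "score_string",
    "compound_scale",
    "score_frame",
    "load_lexicon",
    "load_stopwords",
    "load_contractions",
    "load_emoji_map",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_NONALPHA_RE = re.compile(r"[^a-z]+")


def _resource_text(name: str) -> str:
    return resources.files("emotrend.resources").joinpath(name).read_text(encoding="utf-8")


def _read_tsv_pairs(name: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for line in _resource_text(name).splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        out[key] = value.strip()
    return out


@dataclass(frozen=True)
class Lexicon:
    """Word -> emotion mapping over the five target emotions."""

    words: Mapping[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for word, emotion in self.words.items():
            if emotion not in EMOTIONS:
                raise ValueError(f"unknown emotion {emotion!r} for word {word!r}")
            if word != word.lower():
                raise ValueError(f"lexicon word {word!r} is not lowercase")
            seen.add(emotion)
        missing = set(EMOTIONS) - seen
        if missing:
            raise ValueError(f"lexicon has no words for emotions {sorted(missing)}")

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)

    def emotion_of(self, word: str):
        return self.words.get(word)

    def words_for(self, emotion: str) -> List[str]:
        return sorted(w for w, e in self.words.items() if e == emotion)

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "Lexicon":
        words: Dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                word, _, emotion = line.partition("\t")
                words[word.strip()] = emotion.strip()
        return cls(words=words, provenance=provenance or str(path))


def load_lexicon() -> Lexicon:
    """The bundled five-emotion lexicon."""
    words = _read_tsv_pairs("lexicon.tsv")
    return Lexicon(words=words, provenance="bundled:lexicon.tsv")


def load_stopwords() -> frozenset:
    lines = _resource_text("stopwords.txt").splitlines()
    return frozenset(w.strip() for w in lines if w.strip() and not w.startswith("#"))


def load_contractions() -> Dict[str, str]:
    return _read_tsv_pairs("contractions.tsv")


def load_emoji_map() -> Dict[str, str]:
    return _read_tsv_pairs("emoji.tsv")


class _Preprocessor:
    """Compiled preprocessing state (built once, reused for every text)."""

    def __init__(self) -> None:
        self.stopwords = load_stopwords()
        self.contractions = load_contractions()
        self.emoji_map = load_emoji_map()
        keys = sorted(self.contractions, key=len, reverse=True)
        self._contraction_re = re.compile(
            r"(?<![a-z'])(" + "|".join(re.escape(k) for k in keys) + r")(?![a-z'])"
        )
        self._emoji_re = re.compile("|".join(re.escape(e) for e in sorted(self.emoji_map, key=len, reverse=True)))

    def __call__(self, text: str) -> List[str]:
        if not text:
            return []
        text = self._emoji_re.sub(lambda m: f" {self.emoji_map[m.group(0)]} ", text)
        text = text.lower().replace("’", "'")
        text = _URL_RE.sub(" ", text)
        text = self._contraction_re.sub(lambda m: self.contractions[m.group(1)], text)
        tokens = _NONALPHA_RE.sub(" ", text).split()
        return [t for t in tokens if t not in self.stopwords]


_PREPROCESSOR: _Preprocessor | None = None


def _preprocessor() -> _Preprocessor:
    global _PREPROCESSOR
    if _PREPROCESSOR is None:
        _PREPROCESSOR = _Preprocessor()
    return _PREPROCESSOR


def preprocess(text: str) -> List[str]:
    """Normalize a raw text into scoring tokens.

    Steps, in order: replace emojis with word names, lowercase, strip URLs,
    expand contractions and common shortcuts, strip punctuation, drop
    non-alphabetic tokens and stopwords. Total on strings; '' -> [].
    """
    return _preprocessor()(text)


@dataclass(frozen=True)
class EmotionScores:
    """Five per-text emotion proportions plus the compound negative scale."""

    anger: float
    fear: float
    happiness: float
    sadness: float
    surprise: float
    n_tokens: int

    def __post_init__(self) -> None:
        for name in EMOTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} score {v} outside [0, 1]")

    @property
    def compound(self) -> float:
        return compound_scale(self)

    def as_dict(self) -> Dict[str, float]:
        d = {name: getattr(self, name) for name in EMOTIONS}
        d["compound"] = self.compound
        d["n_tokens"] = self.n_tokens
        return d


ZERO_SCORES = dict.fromkeys(EMOTIONS, 0.0)


def score_text(tokens: Sequence[str], lexicon: Lexicon) -> EmotionScores:
    """Count lexicon hits per emotion and normalize by the token count.

    Tokens absent from the lexicon contribute only to the denominator. An
    empty token sequence scores all-zero with ``n_tokens == 0``.
    """
    n = len(tokens)
    if n == 0:
        return EmotionScores(n_tokens=0, **ZERO_SCORES)
    counts = dict.fromkeys(EMOTIONS, 0)
    words = lexicon.words
    for tok in tokens:
        emotion = words.get(tok)
        if emotion is not None:
            counts[emotion] += 1
    return EmotionScores(n_tokens=n, **{e: counts[e] / n for e in EMOTIONS})


def score_string(text: str, lexicon: Lexicon) -> EmotionScores:
    """Preprocess then score a raw string (title and body are concatenated
    with a single space by callers before reaching here)."""
    return score_text(preprocess(text), lexicon)


def compound_scale(scores) -> float:
    """Compound negative-emotion value: anger + fear - happiness + sadness.

    Surprise is ignored. Accepts an EmotionScores or any object with the four
    attributes; validates each component lies in [0, 1].
    """
    vals = {}
    for name in ("anger", "fear", "happiness", "sadness"):
        v = float(getattr(scores, name))
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} score {v} outside [0, 1]")
        vals[name] = v
    return vals["anger"] + vals["fear"] - vals["happiness"] + vals["sadness"]


def score_frame(df: pd.DataFrame, lexicon: Lexicon | None = None) -> pd.DataFrame:
    """Score every record of a corpus frame, appending the five emotion
    columns, ``compound`` and ``n_tokens``.

    Expects ``title`` and ``body`` columns; they are joined with one space
    (comments carry empty titles). Returns a new frame; scoring metadata
    (denominator convention, lexicon provenance) goes in ``attrs``.
    """
    lexicon = lexicon or load_lexicon()
    pre = _preprocessor()
    words = lexicon.words
    rows = []
    titles = df["title"].fillna("").to_numpy()
    bodies = df["body"].fillna("").to_numpy()
    for title, body in zip(titles, bodies):
        text = f"{title} {body}" if title else body
        tokens = pre(text)
        n = len(tokens)
        counts = dict.fromkeys(EMOTIONS, 0)
        for tok in tokens:
            e = words.get(tok)
            if e is not None:
                counts[e] += 1
        if n:
            row = [counts[e] / n for e in EMOTIONS]
        else:
            row = [0.0] * len(EMOTIONS)
        rows.append(row + [n])
    scored = pd.DataFrame(rows, columns=list(EMOTIONS) + ["n_tokens"], index=df.index)
    scored["compound"] = (
        scored["anger"] + scored["fear"] - scored["happiness"] + scored["sadness"]
    )
    out = pd.concat([df, scored], axis=1)
    out.attrs["score_denominator"] = "tokens after preprocessing"
    out.attrs["lexicon"] = lexicon.provenance
    out.attrs["empty_texts_scored_zero"] = True
    return out
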