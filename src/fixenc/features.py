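"""Word-level linguistic features: orthographic, phonologic, and semantic.

Seven features per word, in three groups:

* orthographic — word length (log10 character count), mean character unigram
  surprisal, orthographic neighborhood size (log10 of single-substitution
  neighbors + 1);
* phonologic — mean phoneme unigram surprisal, phonotactic surprisal (weighted
  maxent constraint violations);
* semantic — lexical surprisal (−log10 word probability) and contextual
  surprisal (−log10 p(word | preceding words) under a pluggable language
  model).

Surprisal is the negative log probability of a unit under a statistical model
of the language; all log10 except the phonotactic score, which stays on the
grammar's own penalty scale.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .events import SentenceLayout
from .lexicon import Lexicon, MaxentGrammar

FEATURE_NAMES = (
    "word_length",
    "character_surprisal",
    "neighborhood_size",
    "phoneme_surprisal",
    "phonotactic_surprisal",
    "lexical_surprisal",
    "contextual_surprisal",
)

#: Probability assigned to out-of-lexicon words for lexical surprisal.
DEFAULT_FLOOR_PROBABILITY = 1e-9

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_word(word: str) -> str:
    """Case-fold and strip punctuation (features are computed on folded forms)."""
    return word.lower().translate(_PUNCT_TABLE)


@dataclass(frozen=True)
class WordFeatures:
    word_length: float
    character_surprisal: float
    neighborhood_size: float
    phoneme_surprisal: float
    phonotactic_surprisal: float
    lexical_surprisal: float
    contextual_surprisal: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


def word_length(word: str) -> float:
    """Base-10 log of the character count (0 for single letters, 1.46 at 29)."""
    if not word:
        raise ValueError("empty word")
    return math.log10(len(word))


def unigram_probs(lexicon: Lexicon, level: str = "character") -> dict[str, float]:
    """Probability of each character or phoneme, weighted by word probability.

    p(s) = sum_w count(s in w) p(w) / sum_w len(w) p(w); the output sums to 1.
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    if level not in ("character", "phoneme"):
        raise ValueError(f"unknown level {level!r}")
    counts: dict[str, float] = {}
    total = 0.0
    for word, entry in lexicon.entries.items():
        symbols = entry.phonemes if level == "phoneme" else tuple(word)
        for s in symbols:
            counts[s] = counts.get(s, 0.0) + entry.probability
        total += len(symbols) * entry.probability
    if total <= 0:
        raise ValueError("zero total symbol mass")
    return {s: c / total for s, c in counts.items()}


def mean_unigram_surprisal(symbols: Sequence[str],
                           probs: Mapping[str, float]) -> float:
    """Mean over symbols of −log10 p(symbol)."""
    if not symbols:
        raise ValueError("empty symbol sequence")
    try:
        return -sum(math.log10(probs[s]) for s in symbols) / len(symbols)
    except KeyError as err:
        raise KeyError(f"symbol {err} has no probability; smooth the lexicon") from err


def neighborhood_size(word: str, lexicon: Lexicon,
                      alphabet: Optional[frozenset[str]] = None) -> float:
    """log10(1 + number of single-letter-substitution neighbors in the lexicon).

    Substitutions only (each letter swapped with every other letter of the
    alphabet); the +1 keeps neighborless words at the observed floor of 0.
    """
    if not word:
        raise ValueError("empty word")
    if alphabet is None:
        alphabet = lexicon.alphabet
    neighbors = set()
    for i, original in enumerate(word):
        for ch in alphabet:
            if ch == original:
                continue
            candidate = word[:i] + ch + word[i + 1:]
            if candidate in lexicon:
                neighbors.add(candidate)
    neighbors.discard(word)
    return math.log10(len(neighbors) + 1)


def phonotactic_surprisal(phonemes: Sequence[str], grammar: MaxentGrammar,
                          inventory: Optional[frozenset[str]] = None) -> float:
    """Weighted sum of constraint violations; 0 when no constraint fires."""
    if inventory is not None:
        unknown = [p for p in phonemes if p not in inventory]
        if unknown:
            raise ValueError(f"phonemes {unknown} not in inventory")
    return grammar.score(phonemes)


def lexical_surprisal(word: str, lexicon: Lexicon,
                      floor_probability: Optional[float] = DEFAULT_FLOOR_PROBABILITY
                      ) -> float:
    """−log10 of the word's corpus probability (floor for unlisted words)."""
    if word in lexicon:
        return -math.log10(lexicon.probability(word))
    if floor_probability is None:
        raise KeyError(f"{word!r} not in lexicon and no floor probability configured")
    return -math.log10(floor_probability)


def contextual_surprisal(sentence: Sequence[str], position: int,
                         lm: Callable[[str, Sequence[str]], float]) -> float:
    """−log10 p(word | sentence-start marker + preceding words).

    The first word is conditioned on the start marker only.
    """
    if not 0 <= position < len(sentence):
        raise IndexError(f"position {position} outside sentence of {len(sentence)} words")
    p = lm(sentence[position], tuple(sentence[:position]))
    if not (isinstance(p, (int, float)) and 0 < p <= 1):
        raise ValueError(f"language model returned invalid probability {p!r}")
    return -math.log10(p)


def featurize_words(layout: SentenceLayout, lexicon: Lexicon,
                    grammar: MaxentGrammar,
                    lm: Callable[[str, Sequence[str]], float],
                    char_probs: Optional[Mapping[str, float]] = None,
                    phoneme_probs: Optional[Mapping[str, float]] = None,
                    floor_probability: float = DEFAULT_FLOOR_PROBABILITY,
                    ) -> dict[int, WordFeatures]:
    """All seven features for every word of a sentence.

    Unigram probability tables may be passed in to avoid recomputing them per
    sentence.  Errors in any single feature are re-raised with the word
    identity attached.
    """
    if char_probs is None:
        char_probs = unigram_probs(lexicon, "character")
    if phoneme_probs is None:
        phoneme_probs = unigram_probs(lexicon, "phoneme")
    sentence = [normalize_word(w) for w in layout.word_texts]
    out: dict[int, WordFeatures] = {}
    for pos, (box, word) in enumerate(zip(layout.words, sentence)):
        try:
            phonemes = lexicon.phonemes(word)
            out[box.word_index] = WordFeatures(
                word_length=word_length(word),
                character_surprisal=mean_unigram_surprisal(tuple(word), char_probs),
                neighborhood_size=neighborhood_size(word, lexicon),
                phoneme_surprisal=mean_unigram_surprisal(phonemes, phoneme_probs),
                phonotactic_surprisal=phonotactic_surprisal(phonemes, grammar),
                lexical_surprisal=lexical_surprisal(word, lexicon, floor_probability),
                contextual_surprisal=contextual_surprisal(sentence, pos, lm),
            )
        except Exception as err:
            raise type(err)(
                f"feature error for word {box.word_index} ({word!r}) "
                f"in {layout.sentence_id}: {err}") from err
    return out
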