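"""Lexicon, maxent phonotactic grammar, and pluggable context language models.

The lexicon maps words to corpus probabilities and pronunciations (phoneme
sequences).  The grammar scores phoneme sequences by weighted constraint
violations, in the style of maxent phonotactics.  Context models provide
p(word | preceding words) for contextual surprisal; any callable with that
contract plugs in, and an add-one-smoothed bigram model is bundled so no
external language model is required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

START_MARKER = "<s>"


@dataclass(frozen=True)
class LexiconEntry:
    probability: float
    phonemes: tuple[str, ...]


@dataclass
class Lexicon:
    """Word list with probabilities and pronunciations.

    Probabilities must be positive and may sum to less than one (a
    sub-distribution: real corpus word lists never cover all tokens).
    ``g2p`` is an optional grapheme-to-phoneme fallback table used to
    pronounce out-of-lexicon words.
    """

    entries: dict[str, LexiconEntry]
    g2p: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        total = 0.0
        for word, e in self.entries.items():
            if not e.probability > 0:
                raise ValueError(f"nonpositive probability for {word!r}")
            total += e.probability
        if total > 1 + 1e-9:
            raise ValueError(f"word probabilities sum to {total} > 1")

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(ch for w in self.entries for ch in w)

    @property
    def phoneme_inventory(self) -> frozenset[str]:
        inv = set()
        for e in self.entries.values():
            inv.update(e.phonemes)
        if self.g2p:
            inv.update(self.g2p.values())
        return frozenset(inv)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def probability(self, word: str) -> float:
        return self.entries[word].probability

    def phonemes(self, word: str) -> tuple[str, ...]:
        """Pronunciation of a word, via the g2p fallback table if unlisted."""
        if word in self.entries:
            return self.entries[word].phonemes
        if self.g2p is not None:
            try:
                return tuple(self.g2p[ch] for ch in word)
            except KeyError as err:
                raise KeyError(f"no g2p mapping for character {err} in {word!r}") from err
        raise KeyError(f"{word!r} not in lexicon and no g2p fallback configured")


@dataclass(frozen=True)
class Constraint:
    """A weighted phonotactic constraint: a regex over space-joined phoneme symbols."""

    pattern: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("constraint weights must be nonnegative")

    def violations(self, phonemes: Sequence[str]) -> int:
        """Count positions (token-aligned, overlapping) where the pattern matches."""
        rx = re.compile(self.pattern)
        count = 0
        for i in range(len(phonemes)):
            if rx.match(" ".join(phonemes[i:])):
                count += 1
        return count


@dataclass
class MaxentGrammar:
    """Weighted phonotactic constraints; the empty grammar scores every word 0."""

    constraints: list[Constraint] = field(default_factory=list)

    def score(self, phonemes: Sequence[str]) -> float:
        return sum(c.weight * c.violations(phonemes) for c in self.constraints)


class BigramLM:
    """Add-one-smoothed bigram language model over a word corpus.

    p(w | prefix) conditions on the last word of the prefix, or on the
    sentence-start marker for the first word.
    """

    def __init__(self, corpus: Sequence[Sequence[str]]):
        vocab: set[str] = set()
        bigram: dict[tuple[str, str], int] = {}
        context: dict[str, int] = {}
        for sentence in corpus:
            prev = START_MARKER
            for word in sentence:
                vocab.add(word)
                bigram[(prev, word)] = bigram.get((prev, word), 0) + 1
                context[prev] = context.get(prev, 0) + 1
                prev = word
        if not vocab:
            raise ValueError("empty corpus")
        self.vocab = vocab
        self._bigram = bigram
        self._context = context

    def __call__(self, word: str, prefix: Sequence[str]) -> float:
        prev = prefix[-1] if prefix else START_MARKER
        v = len(self.vocab)
        return (self._bigram.get((prev, word), 0) + 1) / (self._context.get(prev, 0) + v)


class UniformLM:
    """p(word | prefix) = 1/V regardless of context; useful as a null model."""

    def __init__(self, vocab_size: int):
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        self.vocab_size = vocab_size

    def __call__(self, word: str, prefix: Sequence[str]) -> float:
        return 1.0 / self.vocab_size


# ---------------------------------------------------------------------------
# File formats: TSV lexicon (word, probability, phonemes) and grammar
# (pattern, weight).  Stress digits are stripped from phoneme symbols.

def read_lexicon(path: str | Path, g2p: Optional[dict[str, str]] = None) -> Lexicon:
    df = pd.read_csv(path, sep="\t", dtype={"word": str, "phonemes": str})
    entries = {}
    for row in df.itertuples(index=False):
        phonemes = tuple(re.sub(r"\d", "", p) for p in str(row.phonemes).split())
        entries[row.word] = LexiconEntry(float(row.probability), phonemes)
    return Lexicon(entries=entries, g2p=g2p)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    rows = [(w, e.probability, " ".join(e.phonemes))
            for w, e in sorted(lexicon.entries.items())]
    pd.DataFrame(rows, columns=["word", "probability", "phonemes"]).to_csv(
        path, sep="\t", index=False)


def read_grammar(path: str | Path) -> MaxentGrammar:
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str})
    return MaxentGrammar([Constraint(row.pattern, float(row.weight))
                          for row in df.itertuples(index=False)])


def write_grammar(grammar: MaxentGrammar, path: str | Path) -> None:
    pd.DataFrame([(c.pattern, c.weight) for c in grammar.constraints],
                 columns=["pattern", "weight"]).to_csv(path, sep="\t", index=False)
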