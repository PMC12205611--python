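"""Shared fixtures: tiny lexica, layouts, and small random sessions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fixenc.encoding import FeatureChannel
from fixenc.events import SentenceLayout, WordBox
from fixenc.lexicon import Lexicon, LexiconEntry
from fixenc.trf import SessionDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def ab_lexicon() -> Lexicon:
    """Two words, equal probability: character probs are p(a)=1/3, p(b)=2/3."""
    return Lexicon(entries={
        "ab": LexiconEntry(0.5, ("AA", "B")),
        "b": LexiconEntry(0.5, ("B",)),
    })


@pytest.fixture
def cat_lexicon() -> Lexicon:
    """'cat' has exactly 3 substitution neighbors here: bat, hat, cot."""
    return Lexicon(entries={
        w: LexiconEntry(0.1, tuple(w.upper()))
        for w in ("cat", "bat", "hat", "cot", "at", "cats")
    })


def make_layout(words, words_per_line=3, sentence_id="s0") -> SentenceLayout:
    boxes = []
    for i, w in enumerate(words):
        line, col = divmod(i, words_per_line)
        x0 = 50.0 + col * 100.0
        y0 = 100.0 + line * 40.0
        boxes.append(WordBox(word_index=i, text=w, line=line,
                             bbox=(x0, y0, x0 + 80.0, y0 + 24.0)))
    return SentenceLayout(sentence_id=sentence_id, words=tuple(boxes))


@pytest.fixture
def layout6() -> SentenceLayout:
    return make_layout(["aa", "bb", "cc", "dd", "ee", "ff"])


def gaze_on(layout: SentenceLayout, word_index: int) -> tuple[float, float]:
    x0, y0, x1, y1 = layout.words[word_index].bbox
    return ((x0 + x1) / 2, (y0 + y1) / 2)


def random_session(rng: np.random.Generator, n_blocks=3, n_samples=400,
                   bands=("a", "b"), n_channels=2,
                   delays=(-0.1, 0.3), fs=100.0) -> SessionDesign:
    """A small SessionDesign with random sparse regressors and random EEG."""
    block_channels, block_eeg = [], []
    for _ in range(n_blocks):
        channels = []
        for band in bands:
            values = np.zeros(n_samples)
            idx = rng.choice(n_samples, size=n_samples // 20, replace=False)
            values[idx] = rng.normal(size=len(idx))
            channels.append(FeatureChannel(name=band, band=band,
                                           values=values, fs=fs))
        block_channels.append(channels)
        block_eeg.append(rng.normal(size=(n_samples, n_channels)))
    return SessionDesign(block_channels, block_eeg, delays=delays, fs=fs)
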