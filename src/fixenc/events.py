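"""Fixation event streams: word assignment, reading-specific classification, binarization.

A fixation is a period of stable gaze; during natural sentence reading most
fixations land on a word ("word fixations"), some return to the word just read
("refixations"), and some return to an earlier word ("regressions").  These
event classes, encoded as binary onset trains at the analysis rate, are the
base regressors of the encoding model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LABEL_FIXATION = "fixation"
LABEL_WORD_FIXATION = "word_fixation"
LABEL_REFIXATION = "refixation"
LABEL_REGRESSION = "regression"

#: Minimum duration of a valid fixation (seconds).  Shorter events are dropped
#: at parse time with a logged count.
MIN_FIXATION_DURATION = 0.1


@dataclass(frozen=True)
class WordBox:
    """One word of a laid-out sentence: text plus its screen geometry."""

    word_index: int
    text: str
    line: int
    bbox: tuple[float, float, float, float]  # (x0, y0, x1, y1) pixels


@dataclass(frozen=True)
class SentenceLayout:
    """Word/line geometry of a single sentence as presented on screen."""

    sentence_id: str
    words: tuple[WordBox, ...]

    def __post_init__(self) -> None:
        idx = [w.word_index for w in self.words]
        if idx != sorted(set(idx)):
            raise ValueError(f"word_index not strictly increasing in {self.sentence_id}")

    def validate(self, max_lines: int = 7, max_words_per_line: int = 13,
                 max_chars_per_line: int = 80) -> None:
        """Check presentation constraints (≤7 lines, ≤13 words and ≤80 letters per line)."""
        lines: dict[int, list[WordBox]] = {}
        for w in self.words:
            lines.setdefault(w.line, []).append(w)
        if len(lines) > max_lines:
            raise ValueError(f"{self.sentence_id}: {len(lines)} lines > {max_lines}")
        for line, boxes in lines.items():
            if len(boxes) > max_words_per_line:
                raise ValueError(f"{self.sentence_id} line {line}: too many words")
            if sum(len(b.text) for b in boxes) > max_chars_per_line:
                raise ValueError(f"{self.sentence_id} line {line}: too many letters")
            boxes = sorted(boxes, key=lambda b: b.bbox[0])
            for a, b in zip(boxes, boxes[1:]):
                if b.bbox[0] < a.bbox[2]:
                    raise ValueError(
                        f"{self.sentence_id} line {line}: overlapping bboxes "
                        f"for words {a.word_index} and {b.word_index}")

    @property
    def word_texts(self) -> list[str]:
        return [w.text for w in self.words]

    def line_of(self, word_index: int) -> int:
        return self.words[word_index].line

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class FixationEvent:
    """A single fixation: onset/duration in seconds from session start, gaze in pixels."""

    onset: float
    duration: float
    gaze: tuple[float, float]
    word_index: Optional[int] = None
    labels: frozenset[str] = frozenset({LABEL_FIXATION})
    sentence_id: Optional[str] = None

    def has(self, label: str) -> bool:
        return label in self.labels


@dataclass(frozen=True)
class EventTrain:
    """Binary onset train at the analysis rate (1 at each event onset)."""

    name: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        vals = np.unique(self.samples)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"EventTrain {self.name} is not binary")


def onset_to_sample(onset: float, fs: float, n_samples: int) -> int:
    """Nearest-integer sample index (ties to even) for an onset in seconds.

    Onsets must fall in [0, n_samples/fs); an onset in the final half-sample
    maps to the last sample.
    """
    if not 0.0 <= onset < n_samples / fs:
        raise ValueError(f"onset {onset} s outside [0, {n_samples / fs}) s")
    idx = int(np.round(onset * fs))
    return min(idx, n_samples - 1)


def binarize_onsets(onsets: Iterable[float], fs: float, n_samples: int,
                    name: str = "events") -> EventTrain:
    """Encode event onsets as a binary time series (1 at each onset sample).

    Two onsets rounding to the same sample keep a single 1 (the train stays
    binary).
    """
    samples = np.zeros(n_samples, dtype=np.uint8)
    for onset in onsets:
        samples[onset_to_sample(onset, fs, n_samples)] = 1
    return EventTrain(name=name, samples=samples, fs=fs)


def assign_fixations_to_words(fixations: Sequence[FixationEvent],
                              layout: SentenceLayout) -> list[FixationEvent]:
    """Pair each fixation's gaze with the word bounding boxes of a sentence.

    Containment is half-open (x0 <= x < x1, y0 <= y < y1) so a point on a
    shared edge belongs to at most one box.  A gaze inside exactly one box
    gets that word's index and the word-fixation label; a miss keeps only the
    plain fixation label.  Two boxes containing the same point mean the
    layout is invalid.
    """
    out = []
    for fix in fixations:
        x, y = fix.gaze
        hits = [w for w in layout.words
                if w.bbox[0] <= x < w.bbox[2] and w.bbox[1] <= y < w.bbox[3]]
        if len(hits) > 1:
            raise ValueError(
                f"layout {layout.sentence_id}: gaze ({x}, {y}) inside "
                f"{len(hits)} overlapping bounding boxes")
        if hits:
            out.append(replace(
                fix, word_index=hits[0].word_index,
                labels=fix.labels | {LABEL_WORD_FIXATION},
                sentence_id=fix.sentence_id or layout.sentence_id))
        else:
            out.append(replace(fix, word_index=None,
                               labels=frozenset({LABEL_FIXATION}),
                               sentence_id=fix.sentence_id or layout.sentence_id))
    return out


def classify_fixations(fixations: Sequence[FixationEvent]) -> list[FixationEvent]:
    """Label refixations and regressions within one sentence's fixation sequence.

    A refixation is a word fixation whose word equals the previously fixated
    word; a regression is a word fixation on a word fixated before that is
    not the previously fixated word.  "Previously fixated word" skips
    intervening non-word fixations.  The two labels are mutually exclusive.
    Word-fixation history starts empty (sentences are presented one at a
    time, so history cannot span sentences).
    """
    onsets = [f.onset for f in fixations]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("fixations must be sorted by onset")
    seen: set[int] = set()
    prev_word: Optional[int] = None
    out = []
    for fix in fixations:
        if fix.word_index is None:
            out.append(fix)
            continue
        w = fix.word_index
        labels = set(fix.labels) | {LABEL_FIXATION, LABEL_WORD_FIXATION}
        labels.discard(LABEL_REFIXATION)
        labels.discard(LABEL_REGRESSION)
        if prev_word is not None:
            if w == prev_word:
                labels.add(LABEL_REFIXATION)
            elif w in seen:
                labels.add(LABEL_REGRESSION)
        out.append(replace(fix, labels=frozenset(labels)))
        seen.add(w)
        prev_word = w
    return out


def drop_short_fixations(fixations: Sequence[FixationEvent],
                         min_duration: float = MIN_FIXATION_DURATION
                         ) -> list[FixationEvent]:
    """Drop fixations shorter than the validity threshold, logging the count."""
    kept = [f for f in fixations if f.duration >= min_duration]
    n_dropped = len(fixations) - len(kept)
    if n_dropped:
        logger.info("dropped %d fixations shorter than %.3f s", n_dropped, min_duration)
    return kept


def label_shares(fixations: Sequence[FixationEvent]) -> dict[str, float]:
    """Fraction of total fixations carrying each reading-specific label."""
    n = len(fixations)
    if n == 0:
        raise ValueError("no fixations")
    return {
        label: sum(f.has(label) for f in fixations) / n
        for label in (LABEL_WORD_FIXATION, LABEL_REFIXATION, LABEL_REGRESSION)
    }
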