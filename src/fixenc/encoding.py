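"""Regressor construction: binary fixation-type trains and feature impulse trains.

Each regressor ("band" for regularization purposes) is a time series at the
analysis rate with nonzero samples only at fixation onsets.  Feature bands
carry the feature value of a word as the impulse amplitude; positional bands
carry the value of the word at offset a (n−4 … n+4) from the fixated word n,
still timed to the fixation on n, and only when both words share a line of
text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .events import (LABEL_REFIXATION, LABEL_REGRESSION, LABEL_WORD_FIXATION,
                     EventTrain, FixationEvent, SentenceLayout, onset_to_sample)

#: Fixed order in which bands enter the progressive regularization search.
BASE_BAND_ORDER = ("blinks", "saccades", "fixations", "word_fixations",
                   "regressions", "refixations")

MAX_POSITION_OFFSET = 4


@dataclass(frozen=True)
class FeatureChannel:
    """A named regressor: values at the analysis rate plus its band identity."""

    name: str
    band: str
    values: np.ndarray
    fs: float
    position_offset: Optional[int] = None


@dataclass(frozen=True)
class DesignSpec:
    """Feature order and regularization search grid of the banded model."""

    band_order: tuple[str, ...]
    delays: tuple[float, float] = (-0.2, 1.0)
    fs: float = 100.0
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(0.0, 4.0, 15))

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if not np.all(np.diff(grid) > 0):
            raise ValueError("lambda grid must be strictly increasing")


def positional_band_name(feature: str, offset: int) -> str:
    """Canonical band name for a feature at a word-position offset, e.g. lexical@n+1."""
    if offset == 0:
        return f"{feature}@n"
    return f"{feature}@n{offset:+d}"


def channel_from_train(train: EventTrain, band: Optional[str] = None) -> FeatureChannel:
    return FeatureChannel(name=train.name, band=band or train.name,
                          values=train.samples.astype(float), fs=train.fs)


def encode_feature_impulses(fixations: Sequence[FixationEvent],
                            feature_values: Mapping[int, float],
                            fs: float, n_samples: int,
                            name: str, band: Optional[str] = None,
                            ) -> FeatureChannel:
    """Impulse of height feature(word) at each word-fixation onset sample.

    Impulses that round to the same sample sum.  A fixated word without a
    feature value is an error.
    """
    values = np.zeros(n_samples)
    for fix in fixations:
        if fix.word_index is None:
            continue
        if fix.word_index not in feature_values:
            raise KeyError(f"no feature value for word {fix.word_index} "
                           f"(sentence {fix.sentence_id})")
        values[onset_to_sample(fix.onset, fs, n_samples)] += feature_values[fix.word_index]
    return FeatureChannel(name=name, band=band or name, values=values, fs=fs,
                          position_offset=0)


def encode_positional_features(fixations: Sequence[FixationEvent],
                               layout: SentenceLayout,
                               feature_values: Mapping[int, float],
                               offset: int, fs: float, n_samples: int,
                               name: Optional[str] = None,
                               band: Optional[str] = None,
                               ) -> FeatureChannel:
    """Impulses timed to fixations on word n with amplitude from word n+offset.

    The surrounding word contributes only if it exists in the sentence and
    lies on the same line of text as the fixated word; otherwise the onset
    carries no impulse (the same-line rule is applied symmetrically to left
    and right offsets).
    """
    if abs(offset) > MAX_POSITION_OFFSET:
        raise ValueError(f"|offset| must be <= {MAX_POSITION_OFFSET}")
    indices = {w.word_index for w in layout.words}
    values = np.zeros(n_samples)
    for fix in fixations:
        n = fix.word_index
        if n is None:
            continue
        m = n + offset
        if m not in indices:
            continue
        if layout.line_of(m) != layout.line_of(n):
            continue
        if m not in feature_values:
            raise KeyError(f"no feature value for word {m} (sentence {fix.sentence_id})")
        values[onset_to_sample(fix.onset, fs, n_samples)] += feature_values[m]
    if name is None:
        name = positional_band_name("feature", offset)
    return FeatureChannel(name=name, band=band or name, values=values, fs=fs,
                          position_offset=offset)


def parse_band(band: str) -> Optional[tuple[str, int]]:
    """Split a positional band name like ``lexical_surprisal@n+1`` into
    (feature, offset); base (fixation-type) bands return None."""
    if "@" not in band:
        return None
    feature, pos = band.split("@", 1)
    if pos == "n":
        return feature, 0
    if not pos.startswith("n") or pos[1] not in "+-":
        raise ValueError(f"malformed band name {band!r}")
    return feature, int(pos[1:])


def build_session_channels(bands: Sequence[str],
                           fixations: Sequence[FixationEvent],
                           layouts: Mapping[str, SentenceLayout],
                           word_features: Mapping[str, Mapping[int, object]],
                           fs: float, n_samples: int,
                           blink_onsets: Sequence[float] = (),
                           saccade_onsets: Sequence[float] = (),
                           ) -> list[FeatureChannel]:
    """Build the named regressor bands over one recording segment.

    ``word_features`` maps sentence id → word index → a mapping/record of
    feature values (e.g. ``WordFeatures``).  Fixations carry sentence ids so
    positional bands can apply each sentence's layout and same-line rule.
    """
    base = {c.name: c for c in build_fixation_type_channels(
        fixations, fs, n_samples, blink_onsets, saccade_onsets)}
    by_sentence: dict[str, list[FixationEvent]] = {}
    for fix in fixations:
        if fix.sentence_id is not None:
            by_sentence.setdefault(fix.sentence_id, []).append(fix)
    out = []
    for band in bands:
        parsed = parse_band(band)
        if parsed is None:
            if band not in base:
                raise KeyError(f"unknown base band {band!r}")
            out.append(base[band])
            continue
        feature, offset = parsed
        values = np.zeros(n_samples)
        for sid, fxs in by_sentence.items():
            fv = {wi: wf[feature] for wi, wf in word_features[sid].items()}
            ch = encode_positional_features(fxs, layouts[sid], fv, offset,
                                            fs, n_samples, name=band)
            values += ch.values
        out.append(FeatureChannel(name=band, band=band, values=values, fs=fs,
                                  position_offset=offset))
    return out


def build_fixation_type_channels(fixations: Sequence[FixationEvent],
                                 fs: float, n_samples: int,
                                 blink_onsets: Sequence[float] = (),
                                 saccade_onsets: Sequence[float] = (),
                                 ) -> list[FeatureChannel]:
    """Binary onset trains for blinks, saccades, and the four fixation types.

    Blink and saccade regressors are built exactly like fixation trains; they
    absorb ocular responses and are reported only as nuisance.
    """
    def _train(name: str, onsets: Sequence[float]) -> FeatureChannel:
        values = np.zeros(n_samples)
        for onset in onsets:
            values[onset_to_sample(onset, fs, n_samples)] = 1.0
        return FeatureChannel(name=name, band=name, values=values, fs=fs)

    all_fix = [f.onset for f in fixations]
    word_fix = [f.onset for f in fixations if f.has(LABEL_WORD_FIXATION)]
    regress = [f.onset for f in fixations if f.has(LABEL_REGRESSION)]
    refix = [f.onset for f in fixations if f.has(LABEL_REFIXATION)]
    return [
        _train("blinks", blink_onsets),
        _train("saccades", saccade_onsets),
        _train("fixations", all_fix),
        _train("word_fixations", word_fix),
        _train("regressions", regress),
        _train("refixations", refix),
    ]
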