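"""In-memory containers for one reading session and its simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .events import FixationEvent, SentenceLayout


@dataclass
class GroundTruth:
    """Simulation bookkeeping: the true kernels and noise level behind a session."""

    kernels: dict[str, np.ndarray]  # band → channels × lags
    lags: np.ndarray                # seconds
    noise_sigma: float


@dataclass
class SessionDataset:
    """One reading session: EEG, event streams, block partition, metadata.

    The session is the unit of cross-validation (its blocks) and of
    session-level statistics.  Block ranges are disjoint, ordered sample
    intervals covering all analyzed samples.
    """

    eeg: np.ndarray                      # samples × channels
    fs: float
    channel_names: list[str]
    channel_roles: dict[str, str]        # scalp / eog / face-neck
    fixations: list[FixationEvent]       # absolute onsets, sorted
    layouts: dict[str, SentenceLayout]
    blocks: list[tuple[int, int]]        # (start, stop) sample ranges
    blink_onsets: np.ndarray
    saccade_onsets: np.ndarray
    metadata: dict = field(default_factory=dict)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        prev_stop = 0
        for start, stop in self.blocks:
            if start != prev_stop or stop <= start:
                raise ValueError("block ranges must be ordered, disjoint and covering")
            prev_stop = stop
        if prev_stop != len(self.eeg):
            raise ValueError("block ranges do not cover the EEG")

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def scalp_indices(self) -> list[int]:
        return [i for i, name in enumerate(self.channel_names)
                if self.channel_roles[name] == "scalp"]

    def block_eeg(self, block: int) -> np.ndarray:
        start, stop = self.blocks[block]
        return self.eeg[start:stop]

    def block_fixations(self, block: int) -> list[FixationEvent]:
        """Fixations of one block, onsets re-referenced to the block start."""
        start, stop = self.blocks[block]
        t0 = start / self.fs
        span = (stop - start) / self.fs
        # filter on the re-referenced onset so float rounding cannot push an
        # event at the block edge outside the [0, span) range used downstream
        return [replace(f, onset=f.onset - t0) for f in self.fixations
                if 0.0 <= f.onset - t0 < span]

    def block_onsets(self, onsets: Sequence[float], block: int) -> list[float]:
        start, stop = self.blocks[block]
        t0 = start / self.fs
        span = (stop - start) / self.fs
        return [t - t0 for t in onsets if 0.0 <= t - t0 < span]

    def reading_time(self) -> float:
        """Mean time spent per sentence (s), a simple session reading-speed index."""
        per_sentence: dict[str, list[float]] = {}
        for f in self.fixations:
            if f.sentence_id is not None:
                per_sentence.setdefault(f.sentence_id, []).append(f.onset)
        spans = [max(v) - min(v) for v in per_sentence.values() if len(v) > 1]
        if not spans:
            raise ValueError("no multi-fixation sentences")
        return float(np.mean(spans))
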