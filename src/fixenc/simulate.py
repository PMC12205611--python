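"""Synthetic co-registered eye-tracking + EEG studies with known ground truth.

The generator emulates the structure of a multi-session natural-reading
study: a Zipf-distributed toy lexicon with pronunciations and a small maxent
grammar; sentences laid out on up to 7 lines of at most 13 words / 80
letters; scanpaths with word skips (about one third of words), refixations
(target 14.3% of fixations) and regressions (target 21.4%), word fixations
making up 92.0% of fixations; and EEG at 100 Hz built as the linear
superposition of fixation-locked kernels scaled by feature values, plus
noise.  The generative model is the analysis model run forward, so every
fitted quantity has a known ground truth.

All generation is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .dataset import GroundTruth, SessionDataset
from .encoding import build_session_channels
from .events import (FixationEvent, SentenceLayout, WordBox,
                     assign_fixations_to_words, classify_fixations)
from .features import featurize_words, unigram_probs
from .lexicon import BigramLM, Constraint, Lexicon, LexiconEntry, MaxentGrammar


def visual_angle(height_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees subtended by an object at a viewing distance.

    2·arctan(height / (2·distance)); a 0.8 cm letter at 68 cm subtends 0.674°.
    """
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    if height_cm < 0:
        raise ValueError("height must be nonnegative")
    return math.degrees(2 * math.atan(height_cm / (2 * distance_cm)))


#: Fixed toy grapheme-to-phoneme table over a small ARPABET-style inventory.
G2P_TABLE = {
    "a": "AA", "b": "B", "c": "K", "d": "D", "e": "IY", "f": "F", "g": "G",
    "h": "HH", "i": "IH", "j": "JH", "k": "K", "l": "L", "m": "M", "n": "N",
    "o": "OW", "p": "P", "q": "K", "r": "R", "s": "S", "t": "T", "u": "UW",
    "v": "V", "w": "W", "x": "S", "y": "IY", "z": "Z",
}

PHONEME_INVENTORY = tuple(sorted(set(G2P_TABLE.values())))

#: Toy phonotactic constraints (regex over space-joined phonemes, weight).
TOY_CONSTRAINTS = (
    Constraint(r"(\S+) \1( |$)", 2.0),     # adjacent identical phonemes
    Constraint(r"Z (K|T|P)( |$)", 1.5),    # voiced fricative before voiceless stop
    Constraint(r"(AA|IY|OW|UW) (AA|IY|OW|UW)", 1.0),  # vowel hiatus
    Constraint(r"^(JH|HH) \S+ (JH|HH)", 0.5),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic generator.

    Defaults mirror the source study: 29 participants over 41 sessions (12
    participants contribute two sessions), ~50 sentences per block, word skip
    probability ~1/3, refixation/regression/word-fixation shares of
    14.3/21.4/92.0% of total fixations, 100 Hz, and delays −0.2 … 1.0 s.
    """

    n_participants: int = 29
    n_double_session_participants: int = 12  # 29 participants, 41 sessions
    blocks_per_session: int = 7
    sentences_per_block: int = 50
    vocab_size: int = 500
    corpus_sentences: int = 200              # for the bundled bigram LM
    words_mean: float = 19.6
    words_sd: float = 9.4
    words_min: int = 3
    words_max: int = 65
    skip_probability: float = 1 / 3
    word_fixation_target: float = 0.920
    refixation_target: float = 0.143
    regression_target: float = 0.214
    fs: float = 100.0
    n_channels: int = 16                     # 4×4 grid montage
    delays: tuple[float, float] = (-0.2, 1.0)
    snr: Optional[float] = 1.0               # signal/noise variance; None = noiseless
    noise_model: str = "white"               # "white" or "pink"
    kernel_bands: tuple[str, ...] = ("fixations", "word_fixations",
                                     "lexical_surprisal@n")
    blink_rate: float = 0.2                  # Hz
    saccade_lead: float = 0.02               # s before each fixation onset
    zipf_exponent: float = 1.1
    # screen geometry (pixels); derived from the 0.674° letter at 68 cm on an
    # 800×600 monitor
    char_width_px: int = 8
    line_height_px: int = 24
    line_spacing_px: int = 40
    x_margin_px: int = 50
    y_margin_px: int = 100
    max_words_per_line: int = 13
    max_chars_per_line: int = 80
    max_lines: int = 7
    seed: int = 0

    @property
    def n_sessions(self) -> int:
        return self.n_participants + min(self.n_participants,
                                         self.n_double_session_participants)

    @property
    def grid_shape(self) -> tuple[int, int]:
        rows = int(round(math.sqrt(self.n_channels)))
        if rows * (self.n_channels // rows) != self.n_channels:
            raise ValueError("n_channels must factor into a grid")
        return rows, self.n_channels // rows


@dataclass
class LexiconBundle:
    lexicon: Lexicon
    grammar: MaxentGrammar
    lm: Callable[[str, Sequence[str]], float]
    char_probs: dict[str, float] = field(default_factory=dict)
    phoneme_probs: dict[str, float] = field(default_factory=dict)


def make_toy_lexicon(config: SyntheticConfig,
                     rng: np.random.Generator) -> LexiconBundle:
    """Zipf lexicon with g2p-derived (then perturbed) pronunciations, toy
    grammar, and a bigram LM estimated from a generated corpus."""
    if config.vocab_size < 10:
        raise ValueError("vocabulary must have at least 10 words")
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    words: list[str] = []
    seen = set()
    while len(words) < config.vocab_size:
        length = 1 + rng.geometric(0.28)
        w = "".join(rng.choice(letters, size=min(length, 10)))
        if w not in seen:
            seen.add(w)
            words.append(w)
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    probs = ranks ** (-config.zipf_exponent)
    probs *= 0.9 / probs.sum()  # sub-distribution, as in corpus word lists
    entries = {}
    for w, p in zip(words, probs):
        phonemes = [G2P_TABLE[ch] for ch in w]
        for i in range(len(phonemes)):  # decorrelate from orthography
            if rng.random() < 0.3:
                phonemes[i] = str(rng.choice(PHONEME_INVENTORY))
        entries[w] = LexiconEntry(float(p), tuple(phonemes))
    lexicon = Lexicon(entries=entries, g2p=dict(G2P_TABLE))
    grammar = MaxentGrammar(list(TOY_CONSTRAINTS))
    corpus = [list(rng.choice(words, size=int(rng.integers(5, 25)),
                              p=probs / probs.sum()))
              for _ in range(config.corpus_sentences)]
    lm = BigramLM(corpus)
    return LexiconBundle(lexicon=lexicon, grammar=grammar, lm=lm,
                         char_probs=unigram_probs(lexicon, "character"),
                         phoneme_probs=unigram_probs(lexicon, "phoneme"))


def make_sentence_layout(sentence_id: str, words: Sequence[str],
                         config: SyntheticConfig) -> SentenceLayout:
    """Wrap words into lines and assign pixel bounding boxes."""
    boxes: list[WordBox] = []
    line = 0
    line_words = 0
    x = config.x_margin_px
    for word in words:
        width = len(word) * config.char_width_px
        end_chars = (x - config.x_margin_px) // config.char_width_px + len(word)
        if line_words >= config.max_words_per_line or end_chars > config.max_chars_per_line:
            line += 1
            line_words = 0
            x = config.x_margin_px
            if line >= config.max_lines:
                break  # truncate overly long sentences
        y0 = config.y_margin_px + line * config.line_spacing_px
        boxes.append(WordBox(word_index=len(boxes), text=word, line=line,
                             bbox=(float(x), float(y0),
                                   float(x + width), float(y0 + config.line_height_px))))
        x += width + config.char_width_px  # one-character gap between words
        line_words += 1
    return SentenceLayout(sentence_id=sentence_id, words=tuple(boxes))


def make_layouts(config: SyntheticConfig, bundle: LexiconBundle,
                 rng: np.random.Generator) -> dict[str, SentenceLayout]:
    """All sentence layouts of the study (materials are shared by sessions)."""
    words = list(bundle.lexicon.entries)
    probs = np.array([bundle.lexicon.probability(w) for w in words])
    probs /= probs.sum()
    n_sentences = config.blocks_per_session * config.sentences_per_block
    layouts = {}
    for i in range(n_sentences):
        n_words = int(np.clip(round(rng.normal(config.words_mean, config.words_sd)),
                              config.words_min, config.words_max))
        sentence = rng.choice(words, size=n_words, p=probs)
        sid = f"s{i:04d}"
        layouts[sid] = make_sentence_layout(sid, list(sentence), config)
    return layouts


def _gaze_in_box(box: WordBox, rng: np.random.Generator) -> tuple[float, float]:
    x0, y0, x1, y1 = box.bbox
    return (float(rng.uniform(x0 + 0.05 * (x1 - x0), x1 - 0.05 * (x1 - x0))),
            float(rng.uniform(y0 + 0.2 * (y1 - y0), y1 - 0.2 * (y1 - y0))))


def simulate_scanpath(layout: SentenceLayout, config: SyntheticConfig,
                      rng: np.random.Generator) -> list[FixationEvent]:
    """First-order scanpath: left-to-right pass with skips, refixations and
    regressions at rates calibrated to the configured shares.

    The behavioral rules are intentionally simple (a test harness, not a
    cognitive model): at each step the reader refixates the current word,
    regresses to a previously read word, or advances to the next unskipped
    word; a small fraction of fixations misses all words.  Fixation durations
    are 0.1–0.5 s.
    """
    p_nonword = 1 - config.word_fixation_target
    p_refix = config.refixation_target / config.word_fixation_target
    p_regress = config.regression_target / config.word_fixation_target
    reading_order = [w.word_index for w in layout.words
                     if rng.random() > config.skip_probability]
    if not reading_order:
        reading_order = [layout.words[0].word_index]

    below_text = config.y_margin_px + config.max_lines * config.line_spacing_px + 60
    events: list[FixationEvent] = []
    t = 0.0
    pos = 0                      # next index into reading_order
    current: Optional[int] = None
    history: list[int] = []
    while True:
        duration = float(rng.uniform(0.1, 0.35))
        if rng.random() < p_nonword:
            gaze = (float(rng.uniform(0, 800)), float(below_text + rng.uniform(0, 40)))
        else:
            u = rng.random()
            candidates = [h for h in history if h != current]
            if u < p_refix and current is not None:
                word = current
            elif u < p_refix + p_regress and candidates:
                word = int(rng.choice(candidates))
            else:
                if pos >= len(reading_order):
                    break
                word = reading_order[pos]
                pos += 1
            gaze = _gaze_in_box(layout.words[word], rng)
            if word not in history:
                history.append(word)
            current = word
        events.append(FixationEvent(onset=t, duration=duration, gaze=gaze,
                                    sentence_id=layout.sentence_id))
        t += duration + config.saccade_lead + float(rng.uniform(0.01, 0.04))
        if pos >= len(reading_order) and rng.random() < 0.5:
            break
    fixations = assign_fixations_to_words(events, layout)
    return classify_fixations(fixations)


def make_ground_truth_kernels(bands: Sequence[str], n_channels: int,
                              lags: np.ndarray, rng: np.random.Generator,
                              amplitude: float = 1.0,
                              max_pairwise_corr: float = 0.5,
                              ) -> dict[str, np.ndarray]:
    """Smooth damped-oscillation kernels, distinct per band and channel.

    Each kernel is a windowed sinusoid with band-specific frequency, latency
    and phase and a random channel amplitude profile, peak-normalized; a band
    is redrawn until its flattened correlation with every earlier band is
    below the distinctness bound.
    """
    def _draw() -> np.ndarray:
        f = rng.uniform(2.0, 8.0)
        center = rng.uniform(0.05, min(0.5, lags[-1] - 0.1))
        width = rng.uniform(0.2, 0.4)
        phase = rng.uniform(0, 2 * np.pi)
        envelope = np.exp(-0.5 * ((lags - center) / (width / 2.355)) ** 2)
        base = envelope * np.sin(2 * np.pi * f * (lags - center) + phase)
        topo = rng.normal(size=n_channels)
        topo = topo / np.max(np.abs(topo))
        kernel = np.outer(topo, base)
        peak = np.max(np.abs(kernel))
        return amplitude * kernel / peak if peak > 0 else kernel

    kernels: dict[str, np.ndarray] = {}
    for band in bands:
        for _ in range(50):
            cand = _draw()
            flat = cand.ravel()
            if all(abs(np.corrcoef(flat, k.ravel())[0, 1]) < max_pairwise_corr
                   for k in kernels.values()):
                kernels[band] = cand
                break
        else:
            raise RuntimeError("could not draw a distinct kernel")
    return kernels


def _superpose(channel_values: np.ndarray, kernel: np.ndarray,
               n_neg_lags: int) -> np.ndarray:
    """y(t) = Σ_τ x(t−τ)·k(τ) for a kernel over lags −n_neg … +n_pos."""
    n = len(channel_values)
    out = np.empty((n, kernel.shape[0]))
    for c in range(kernel.shape[0]):
        out[:, c] = np.convolve(channel_values, kernel[c])[n_neg_lags:n_neg_lags + n]
    return out


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise for robustness checks (real EEG noise is not white)."""
    n, c = shape
    freqs = np.fft.rfftfreq(n)
    scale = np.where(freqs > 0, 1 / np.sqrt(np.maximum(freqs, freqs[1])), 0.0)
    spectrum = (rng.normal(size=(len(freqs), c)) +
                1j * rng.normal(size=(len(freqs), c))) * scale[:, None]
    return np.fft.irfft(spectrum, n=n, axis=0)


def synthesize_session(config: SyntheticConfig, bundle: LexiconBundle,
                       layouts: dict[str, SentenceLayout],
                       word_features: dict[str, dict],
                       kernels: dict[str, np.ndarray],
                       participant: str, session: str,
                       rng: np.random.Generator) -> SessionDataset:
    """One session: scanpaths over the shared materials, then EEG as the
    kernel superposition plus noise, with block boundaries recorded."""
    from .trf import lag_axis  # local import to avoid a cycle at module load

    lags = lag_axis(config.delays, config.fs)
    n_neg = int(round(-lags[0] * config.fs))
    sentence_ids = sorted(layouts)
    fs = config.fs

    all_fix: list[FixationEvent] = []
    blink_onsets: list[float] = []
    saccade_onsets: list[float] = []
    blocks: list[tuple[int, int]] = []
    block_signals: list[np.ndarray] = []
    t_session = 0.0
    start_sample = 0
    for b in range(config.blocks_per_session):
        block_sids = sentence_ids[b * config.sentences_per_block:
                                  (b + 1) * config.sentences_per_block]
        block_fix: list[FixationEvent] = []
        t_block = 0.0
        for sid in block_sids:
            path = simulate_scanpath(layouts[sid], config, rng)
            for f in path:
                block_fix.append(replace(f, onset=f.onset + t_block))
            t_block += max(f.onset + f.duration for f in path) \
                + float(rng.uniform(0.4, 0.8))
        n_samples = int(math.ceil(t_block * fs)) + 1
        block_sacc = [max(0.0, f.onset - config.saccade_lead) for f in block_fix]
        n_blinks = int(rng.poisson(config.blink_rate * t_block))
        block_blinks = sorted(rng.uniform(0, t_block, size=n_blinks).tolist())
        channels = build_session_channels(
            list(kernels), block_fix, layouts, word_features, fs, n_samples,
            blink_onsets=block_blinks, saccade_onsets=block_sacc)
        signal = np.zeros((n_samples, config.n_channels))
        for ch in channels:
            signal += _superpose(ch.values, kernels[ch.band], n_neg)
        block_signals.append(signal)
        for f in block_fix:
            all_fix.append(replace(f, onset=f.onset + t_session))
        blink_onsets.extend(t + t_session for t in block_blinks)
        saccade_onsets.extend(t + t_session for t in block_sacc)
        blocks.append((start_sample, start_sample + n_samples))
        start_sample += n_samples
        t_session += n_samples / fs

    signal = np.vstack(block_signals)
    if config.snr is None:
        sigma = 0.0
    else:
        sigma = float(np.sqrt(signal.var(axis=0).mean() / config.snr))
    if sigma > 0:
        if config.noise_model == "pink":
            noise = _pink_noise(signal.shape, rng)
        else:
            noise = rng.normal(size=signal.shape)
        eeg = signal + noise / noise.std(axis=0) * sigma
    else:
        eeg = signal.copy()

    names = [f"E{i + 1:02d}" for i in range(config.n_channels)]
    return SessionDataset(
        eeg=eeg, fs=fs, channel_names=names,
        channel_roles={n: "scalp" for n in names},
        fixations=all_fix, layouts=layouts, blocks=blocks,
        blink_onsets=np.array(blink_onsets),
        saccade_onsets=np.array(saccade_onsets),
        metadata={"participant": participant, "session": session},
        ground_truth=GroundTruth(kernels=dict(kernels), lags=lags,
                                 noise_sigma=sigma),
    )


@dataclass
class StudyData:
    """A complete synthetic study: shared materials plus per-session data."""

    config: SyntheticConfig
    bundle: LexiconBundle
    layouts: dict[str, SentenceLayout]
    word_features: dict[str, dict]
    kernels: dict[str, np.ndarray]
    sessions: list[SessionDataset]

    def hierarchy(self) -> dict[str, list[str]]:
        """participant → session ids, for hierarchical statistics."""
        out: dict[str, list[str]] = {}
        for s in self.sessions:
            out.setdefault(s.metadata["participant"], []).append(s.metadata["session"])
        return out


def simulate_study(config: SyntheticConfig,
                   seed: Optional[int] = None) -> StudyData:
    """Generate the full nested study (participants → sessions → blocks)."""
    from .trf import lag_axis

    root = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_materials, ss_kernels, ss_sessions = root.spawn(3)
    rng_materials = np.random.default_rng(ss_materials)
    bundle = make_toy_lexicon(config, rng_materials)
    layouts = make_layouts(config, bundle, rng_materials)
    word_features = {
        sid: featurize_words(layout, bundle.lexicon, bundle.grammar, bundle.lm,
                             char_probs=bundle.char_probs,
                             phoneme_probs=bundle.phoneme_probs)
        for sid, layout in layouts.items()}
    lags = lag_axis(config.delays, config.fs)
    kernels = make_ground_truth_kernels(config.kernel_bands, config.n_channels,
                                        lags, np.random.default_rng(ss_kernels))
    session_seeds = ss_sessions.spawn(config.n_sessions)
    sessions = []
    k = 0
    for p in range(config.n_participants):
        n_sess = 2 if p < config.n_double_session_participants else 1
        for s in range(n_sess):
            participant = f"p{p + 1:02d}"
            session = f"{participant}_s{s + 1}"
            sessions.append(synthesize_session(
                config, bundle, layouts, word_features, kernels,
                participant, session, np.random.default_rng(session_seeds[k])))
            k += 1
    return StudyData(config=config, bundle=bundle, layouts=layouts,
                     word_features=word_features, kernels=kernels,
                     sessions=sessions)
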