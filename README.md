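# fixenc — fixation-locked neural encoding of linguistic features

`fixenc` implements an analysis pipeline for studying how the brain encodes
linguistic information during natural sentence reading, exercised end-to-end
on synthetic co-registered eye-tracking + EEG data with known ground truth.

## Scientific problem

During natural reading the eyes fixate words in rapid, self-paced succession.
Each fixation delivers a new word to the visual system, and the EEG response
that follows carries information about that word's linguistic properties —
how long it is, how predictable, how it sounds. The analysis question: which
word-level features measurably modulate fixation-locked EEG, at which word
positions relative to fixation, with what time course — and does the strength
of that encoding track reading speed?

The model is a linear superposition of temporal response functions (TRFs):
the EEG at each channel is predicted as a sum of convolutions of event
regressors with per-band kernels spanning −0.2 to 1.0 s around each event.
Regressors come in two kinds:

- **Fixation-type onset trains** — all fixations, word fixations,
  refixations (same word as the previous fixated word), regressions
  (an earlier word), saccades, blinks.
- **Feature impulse trains** — an impulse at the fixation on word *n* whose
  amplitude is a linguistic feature of word *n+k* (positions *k* = −4…+4):
  word length, character/phoneme unigram surprisal, orthographic
  neighborhood size, phonotactic surprisal (maxent grammar), lexical
  surprisal (unigram) and contextual surprisal (pluggable language model;
  an add-one bigram model is bundled).

Fitting uses **banded ridge regression** with a per-band regularization
strength chosen by a progressive search that maximizes leave-one-block-out
cross-validated prediction correlation. The **unique contribution** of a band
is Δr = r(full model) − r(model without it), with the band of interest always
added last. Inference is nonparametric: a hierarchical bootstrap that
respects the participant → session → block nesting tests Δr > 0, a Wilcoxon
signed-rank test compares per-session correlations before/after adding a
band, and a spatiotemporal cluster permutation test (sign flips of whole
sessions) localizes TRF deflections across channels and lags.

Because everything runs on synthetic data, every claim is checkable: the
generator plants known kernels, a calibrated scanpath (≈92% word fixations,
≈14% refixations, ≈21% regressions) and a known noise level, and the test
suite verifies that the pipeline recovers the planted structure and stays
calibrated under the null.

## Worked example

Word features from a five-word toy lexicon:

```python
from fixenc.features import (contextual_surprisal, lexical_surprisal,
                             neighborhood_size, word_length)
from fixenc.lexicon import BigramLM, Lexicon, LexiconEntry

lex = Lexicon({"the": LexiconEntry(0.20, ("DH", "AH")),
               "cat": LexiconEntry(0.05, ("K", "AE", "T")),
               "sat": LexiconEntry(0.05, ("S", "AE", "T")),
               "mat": LexiconEntry(0.03, ("M", "AE", "T")),
               "on":  LexiconEntry(0.10, ("AA", "N"))})

word_length("reading")                      # 0.8451   (log10 of 7)
lexical_surprisal("cat", lex)               # 1.3010   (−log10 0.05)
neighborhood_size("cat", lex)               # 0.4771   (log10(2 neighbors + 1))

lm = BigramLM([["the", "cat", "sat", "on", "the", "mat"]])
contextual_surprisal(["the", "cat", "sat"], 1, lm)   # 0.5441  (−log10 p(cat|the))
```

End-to-end pipeline on a small synthetic study (two participants, three
blocks each, two features at the fixated word; ~6 s on one CPU):

```bash
python analysis/02_fit_encoding_models.py --config configs/smoke.yaml --out results/run
```

```
               band  delta_r_mean   p_boot   W  p_wilcoxon  significant  trf_selected
lexical_surprisal@n      0.026402 0.001996 3.0        0.25         True          True
      word_length@n      0.000001 0.255489 3.0        0.25        False         False

1/2 bands significant; bundle written to results/run
```

The generator plants a lexical-surprisal kernel, and the pipeline finds
exactly that band: Δr ≈ 0.026 with hierarchical-bootstrap p ≈ 0.002, while
the non-planted word-length band stays at Δr ≈ 10⁻⁶, p ≈ 0.26. The bundle
contains `block_results.tsv`, `stats_report.tsv`, `cluster_report.tsv`,
`reading_time.tsv`, `trf_archive.npz` and a `manifest.json`; re-running with
the same config and seed reproduces every table byte for byte.

## Reproduction

The numbered drivers under `analysis/` run the study stages (each is a thin
wrapper over `src/fixenc/`):

```bash
python analysis/01_simulate_study.py       --config configs/positions.yaml --out results/study
python analysis/02_fit_encoding_models.py  --config configs/positions.yaml --out results/run   # ~9 min
python analysis/03_fixated_word_features.py --run results/run
python analysis/04_word_position_profile.py --run results/run
python analysis/05_reading_speed.py         --run results/run
```

`configs/positions.yaml` (four sessions, positions n−1…n+1, contextual
surprisal included) exercises the word-position profile and the
reading-speed correlation; `configs/default.yaml` holds the full-scale
analysis constants (15-value λ grid, 10⁴ bootstrap resamples, positions ±4).

The headline quantities are recomputed from scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports, among others: Wilcoxon W = 861 for 41 all-positive pairs,
visual angle 0.674° for 0.8 cm at 68 cm, 105 of 128 channels retained,
scanpath shares 92.1 / 13.9 / 21.0%, minimum planted-kernel recovery
correlation 0.987, planted-band detection rate 1.0 over 20 simulations,
hierarchical-bootstrap type-I error 0.065 at α = 0.05, and cluster-test
familywise error 0.02 (values for seed 1; resampled quantities vary slightly
with the seed).

There is also a console entry point: `fixenc simulate …` writes a synthetic
study to disk, `fixenc run …` runs the pipeline on a config.

## Layout

```
src/fixenc/      library (events, lexicon, features, encoding, trf, stats,
                 simulate, preprocess, dataset, io, pipeline, cli)
analysis/        numbered stage drivers (thin wrappers over the library)
configs/         YAML run configurations (smoke, positions, default)
scripts/         acceptance.py — recompute headline quantities as JSON
tests/           unit, property-based and acceptance tests
docs/methods.md  methods note: model, estimators, inference, generator
```

See `docs/methods.md` for the precise definitions, numerical choices and
known limitations.
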