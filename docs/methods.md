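# Methods note

This note defines the model, estimators, inference procedures and synthetic
generator precisely, and records the numerical choices and known limitations.
All symbols: sampling rate `fs` = 100 Hz, TRF delays −0.2…1.0 s (121 lags),
λ grid 15 log-spaced values 10⁰…10⁴ unless a config overrides them.

## Events and fixation classification

A fixation is assigned to a word when its gaze point falls inside the word's
bounding box, using half-open containment (`x0 ≤ x < x1`, `y0 ≤ y < y1`) so
abutting boxes never double-assign. Classification within a sentence:

- **word fixation** — the fixation lands on a word;
- **refixation** — the fixated word equals the *previously fixated* word,
  where "previously fixated" skips fixations that landed on no word;
- **regression** — the previously fixated word is a different, earlier word
  in the sentence (refixation and regression are mutually exclusive).

Event onsets are binarized at the analysis rate with `np.round`
(ties-to-even); an onset landing within half a sample of the segment end is
clipped to the last sample. Block-relative onsets are computed by
re-referencing to the block start and keeping `0 ≤ t − t0 < span`, so float
rounding at a block edge cannot produce an out-of-range event.

## Word features

All logarithms are base 10.

- **word length** — log10 of the character count.
- **character / phoneme surprisal** — mean unigram surprisal of the word's
  symbols; unigram tables are probability-weighted over the lexicon (each
  word contributes its corpus probability to each of its symbols).
- **neighborhood size** — log10(count + 1) of lexicon words reachable by a
  single substitution (same length; insertions/deletions excluded).
- **phonotactic surprisal** — weighted sum of maxent-grammar constraint
  violations over the phoneme string, counted with overlapping,
  token-anchored regex matches.
- **lexical surprisal** — −log10 of the word's corpus probability, floored
  at 10⁻⁹ for out-of-lexicon words.
- **contextual surprisal** — −log10 p(word | preceding words) from a
  pluggable language model callable; the bundled fallback is an add-one
  smoothed bigram model with a sentence-start marker. Any callable
  `(word, prefix) → probability` can be substituted (e.g., a transformer).

A positional band `feature@n+k` (|k| ≤ 4) places an impulse at the fixation
on word *n* with amplitude equal to the feature of word *n+k*, only when
word *n+k* exists on the same line of the same sentence.

## Encoding model and estimation

For each block, the design matrix stacks lagged copies of every regressor:
column (band, τ) at row *t* is x(t − τ), zero-padded at block edges (no
leakage across blocks). The model is linear: EEG ≈ X·W per channel.

**Banded ridge.** Each band *b* gets its own regularization λ_b. We solve
the regularized normal equations (XᵀX + diag(λ_b²)) W = XᵀY via Cholesky;
dividing band *b*'s columns by λ_b and applying unit ridge is algebraically
identical (tested). Per block we cache only the Gram statistics
(G = XᵀX, C = XᵀY, Σy², n), so cross-validated correlations are computed
without rebuilding design matrices: for held-out weights w,
cov(ŷ, y) = wᵀC and var(ŷ) = wᵀGw.

**Progressive λ search.** Bands are processed in a fixed order; for each
band the grid is swept with earlier bands' λ frozen at their selected values
and later bands at the current candidate, maximizing the grand-mean
leave-one-block-out correlation over channels and folds. Exact ties break to
the smaller λ. A memoizing searcher reuses sweeps across the N re-orderings
required by the unique-variance procedure.

**Cross-validation and model averaging.** Leave-one-block-out: each fold
fits on the remaining blocks and predicts the held-out block; the session's
TRF is the average of the per-fold weight vectors, reshaped per band into a
channels × lags kernel.

**Unique variance.** Δr(band) = r(full) − r(full minus band), computed per
block and channel, with the band of interest added *last* in the progressive
search so its λ is selected conditional on everything else.

## Inference

- **Hierarchical bootstrap.** Resample participants with replacement, then
  sessions within participants, then block-level Δr values within sessions
  (vectorized over a rectangular index array). p = (1 + #{resampled means ≤ 0})
  / (n_boot + 1), one-sided. The procedure guards against pseudo-replication;
  when variance is concentrated at the lowest (block) level it is markedly
  conservative (simulated type-I ≈ 0.006), and calibrates near the nominal
  level when participant-level variance dominates (≈ 0.04–0.07 in our
  simulations) — the regime a multi-participant design implies.
- **Wilcoxon signed rank.** W = sum of positive ranks; exact p by dynamic
  programming over doubled ranks for n ≤ 12 (handles ties), otherwise a
  normal approximation with tie correction and 0.5 continuity correction.
  For 41 uniformly positive pairs W = 41·42/2 = 861.
- **Feature masks.** A band is *significant* when bootstrap p < α and mean
  Δr ≥ 2×10⁻⁵; TRFs enter the cluster test at the stricter 3×10⁻⁵.
- **Cluster permutation.** One-sample t per (channel, lag) across sessions;
  cells with |t| ≥ 2.5 form signed clusters via channel adjacency plus
  temporal contiguity; cluster mass is the summed t. The null distribution is
  the maximum |mass| under whole-session sign flips; p is add-one. Synthetic
  sessions use a grid adjacency; real montages can supply any adjacency
  matrix.
- **Reading speed.** Spearman correlation across sessions between mean
  sentence reading time and the mean Δr of contextual surprisal at positions
  n−1, n, n+1, Bonferroni-corrected over the feature set.

## Synthetic generator

- **Lexicon** — Zipf-distributed toy vocabulary (probabilities sum to 0.9,
  leaving out-of-vocabulary mass), deterministic grapheme-to-phoneme mapping
  with 30% random phoneme perturbation, and a four-constraint toy maxent
  grammar.
- **Scanpath** — word-by-word progression with skips, refixations and
  regressions, calibrated so large samples produce ≈92.0% word fixations,
  ≈14.3% refixations and ≈21.4% regressions.
- **EEG** — the analysis model run forward: the sum over planted bands of
  the regressor convolved with a per-channel kernel, plus Gaussian noise
  scaled to a target SNR. Kernels are windowed sinusoids constructed so the
  planted set is mutually distinguishable (pairwise |correlation| < 0.5).
- **Reproducibility** — all randomness flows from `numpy.random.SeedSequence`
  spawning; derived integer seeds are reduced mod 2³¹. The pipeline is a
  deterministic function of (config, seed) down to byte-identical TSVs.

## Preprocessing

Offline zero-phase (forward–backward Butterworth) 30 Hz low-pass, then
downsampling to 100 Hz; zero-phase filtering is chosen because the analysis
is acausal by design — this preserves TRF latencies that a causal filter
would shift. Channel retention keeps scalp channels only (e.g., 105 of a
128-channel montage after dropping EOG and face/neck channels).

## Known limitations

- **Identifiability of per-band kernels.** Binary onset trains that share
  most of their onsets (e.g., all-fixations vs word-fixations, ~92% overlap)
  are near-collinear; the *summed* response is well estimated but its split
  between bands is not. Similarly, a feature band whose amplitudes have a
  large positive mean at shared onsets trades off against the corresponding
  onset train. Kernel-recovery checks therefore plant bands with distinct
  timing or amplitude variation (blinks, fixations, lexical surprisal).
- **λ selection plateau.** Held-out Pearson correlation is scale-invariant,
  so as λ → ∞ the weights converge in direction to XᵀY and the CV curve
  flattens; on some realizations the curve is flat to < 10⁻⁵ from moderate λ
  to the grid edge, and the argmax can land at 10⁴. Predictions are
  unaffected (same correlation) but recovered kernels are then biased toward
  the raw cross-correlation. We keep the maximize-correlation rule with
  exact-tie → smaller-λ tie-breaking; users wanting maximally unbiased
  kernels can narrow the grid or use an MSE criterion externally.
- The bundled bigram language model is a stand-in; contextual-surprisal
  results are only as good as the language model supplied.
- The toy maxent grammar and g2p map are structural stand-ins for a real
  phonological grammar and pronunciation dictionary.
- The generator's EEG is stationary Gaussian noise plus the planted model;
  it does not simulate artifacts, drift or volume conduction beyond the
  channel dimension of the planted kernels.
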