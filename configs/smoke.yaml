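# Small, fast configuration for smoke runs and reproducibility checks.
# Two participants, one session each, three blocks; two features at the
# fixated word only; reduced regularization grid and resampling counts.
fs: 100.0
delays: [-0.2, 1.0]
lambda_grid: {lo: 0.0, hi: 4.0, num: 4}
n_boot: 500
n_perm: 200
t_threshold: 2.5
features: [lexical_surprisal, word_length]
offsets: [0]
study:
  n_participants: 2
  n_double_session_participants: 0
  blocks_per_session: 3
  sentences_per_block: 10
  vocab_size: 120
  corpus_sentences: 60
  words_mean: 8.0
  words_sd: 3.0
  words_min: 3
  words_max: 20
  snr: 2.0
seed: 0
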