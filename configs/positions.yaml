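# Desk-scale configuration exercising word-position encoding and the
# reading-speed correlation: four sessions, contextual surprisal included,
# positions n-1..n+1.  Larger than smoke.yaml but still minutes, not hours.
lambda_grid: {lo: 0.0, hi: 4.0, num: 8}
n_boot: 2000
n_perm: 500
features: [word_length, lexical_surprisal, contextual_surprisal]
offsets: [-1, 0, 1]
study:
  n_participants: 4
  n_double_session_participants: 0
  blocks_per_session: 4
  sentences_per_block: 15
  vocab_size: 150
  corpus_sentences: 80
  words_mean: 9.0
  words_sd: 3.0
  words_min: 3
  words_max: 20
  snr: 1.5
seed: 0
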