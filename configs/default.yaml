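# Full-scale configuration mirroring the reference study design:
# 29 participants (12 with two sessions → 41 sessions), 7 blocks per session,
# 7 features × word positions n−4..n+4, 15-point log-spaced λ grid.
# All values below equal the built-in defaults; the file exists as a template.
fs: 100.0
delays: [-0.2, 1.0]
lambda_grid: {lo: 0.0, hi: 4.0, num: 15}
n_boot: 10000
n_perm: 1000
t_threshold: 2.5
dr_display_min: 2.0e-5
dr_trf_min: 3.0e-5
alpha: 0.05
features: [word_length, character_surprisal, neighborhood_size,
           phoneme_surprisal, phonotactic_surprisal,
           lexical_surprisal, contextual_surprisal]
offsets: [-4, -3, -2, -1, 0, 1, 2, 3, 4]
study: {}
seed: 0
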