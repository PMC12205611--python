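"""Stage 2: fit the fixation-locked encoding models and run the statistics.

Runs the full pipeline (simulate -> featurize -> progressive banded ridge ->
unique variance -> hierarchical bootstrap / Wilcoxon -> cluster permutation ->
reading-time correlation) and writes the results bundle.  Later stages read
the TSV tables written here.

Usage: python analysis/02_fit_encoding_models.py [--config configs/smoke.yaml]
                                                 [--seed 0] [--out results/run]
"""

import argparse
from pathlib import Path

from fixenc.pipeline import run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="configs/smoke.yaml")
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    result = run_pipeline(args.config, seed=args.seed, out_dir=args.out)
    print(result.stats_table.to_string(index=False))
    n_sig = int(result.stats_table["significant"].sum())
    print(f"\n{n_sig}/{len(result.stats_table)} bands significant; "
          f"bundle written to {args.out}")


if __name__ == "__main__":
    main()
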