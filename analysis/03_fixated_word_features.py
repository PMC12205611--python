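"""Stage 3: unique variance of the fixated word's linguistic features.

Reads the stats table produced by stage 2 and reports, for each feature at
word position n (the fixated word), the mean unique contribution to held-out
prediction accuracy (delta r), the hierarchical-bootstrap p value, and the
before/after Wilcoxon test.

Usage: python analysis/03_fixated_word_features.py [--run results/run]
"""

import argparse
from pathlib import Path

from fixenc import io as fio
from fixenc.encoding import parse_band


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    stats = fio.read_table(args.run / "stats_report.tsv")
    parsed = stats["band"].map(parse_band)
    stats["feature"] = parsed.map(lambda fo: fo[0])
    stats["offset"] = parsed.map(lambda fo: fo[1])
    fixated = stats[stats["offset"] == 0].sort_values("delta_r_mean",
                                                      ascending=False)
    cols = ["feature", "delta_r_mean", "p_boot", "W", "p_wilcoxon",
            "significant"]
    print(fixated[cols].to_string(index=False))
    fio.write_table(fixated[cols], args.run / "fixated_word_features.tsv")


if __name__ == "__main__":
    main()
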