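"""Stage 4: unique variance of features at words left and right of fixation.

Pivots the stage-2 stats table into a feature x word-position matrix of mean
delta r, showing how far from the fixated word each feature still contributes
to the EEG prediction.

Usage: python analysis/04_word_position_profile.py [--run results/run]
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
    profile = stats.pivot(index="feature", columns="offset",
                          values="delta_r_mean").sort_index()
    print(profile.to_string(float_format=lambda v: f"{v:.2e}"))
    fio.write_table(profile.reset_index(),
                    args.run / "word_position_profile.tsv")


if __name__ == "__main__":
    main()
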