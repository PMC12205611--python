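"""Stage 5: does contextual-surprisal encoding track reading speed?

Reads the stage-2 reading-time table: per-session Spearman correlation
between the mean unique contribution of contextual surprisal (positions
n-1, n, n+1) and the session's mean time spent per sentence, Bonferroni
corrected over the feature set.  The table is empty when the run had fewer
than three sessions or did not include contextual surprisal at those
positions.

Usage: python analysis/05_reading_speed.py [--run results/run]
"""

import argparse
from pathlib import Path

from fixenc import io as fio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    table = fio.read_table(args.run / "reading_time.tsv")
    if table.empty:
        print("no reading-time correlation in this run (needs >=3 sessions "
              "and contextual_surprisal at offsets -1, 0, +1)")
        return
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
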