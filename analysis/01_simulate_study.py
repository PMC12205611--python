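"""Stage 1: simulate a co-registered eye-tracking + EEG reading study.

Writes the fixation and sentence-layout tables and prints the scanpath
composition (word-fixation / refixation / regression shares), the quantities
the generator is calibrated against.

Usage: python analysis/01_simulate_study.py [--config configs/smoke.yaml]
                                            [--seed 0] [--out results/study]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from fixenc import io as fio
from fixenc.events import (LABEL_REFIXATION, LABEL_REGRESSION,
                           LABEL_WORD_FIXATION, label_shares)
from fixenc.simulate import SyntheticConfig, simulate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="configs/smoke.yaml")
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--out", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    config = fio.load_config(args.config)
    seed = int(config["seed"] if args.seed is None else args.seed)
    study_kwargs = dict(config["study"])
    study_kwargs.setdefault("fs", config["fs"])
    study_kwargs.setdefault("delays", tuple(config["delays"]))
    study = simulate_study(SyntheticConfig(**study_kwargs, seed=seed))

    args.out.mkdir(parents=True, exist_ok=True)
    fio.write_fixation_table(
        {ds.metadata["session"]: ds.fixations for ds in study.sessions},
        args.out / "fixations.tsv")
    fio.write_layout_table(study.layouts, args.out / "layouts.tsv")

    fixations = [f for ds in study.sessions for f in ds.fixations]
    shares = label_shares(fixations)
    summary = {
        "n_sessions": len(study.sessions),
        "n_fixations": len(fixations),
        "word_fixation_pct": round(100 * shares[LABEL_WORD_FIXATION], 2),
        "refixation_pct": round(100 * shares[LABEL_REFIXATION], 2),
        "regression_pct": round(100 * shares[LABEL_REGRESSION], 2),
        "eeg_minutes": round(sum(ds.n_samples / ds.fs
                                 for ds in study.sessions) / 60, 2),
    }
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
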