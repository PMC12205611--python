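"""Readers and writers for the on-disk formats.

Tables are TSV; run manifests and axis metadata are JSON; EEG/TRF tensors go
into a single-file archive of named arrays (NumPy ``.npz``) with a JSON
sidecar for axes and event metadata — synthetic data needs no acquisition
semantics, so no EEG acquisition format is used.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .dataset import GroundTruth, SessionDataset
from .events import (MIN_FIXATION_DURATION, FixationEvent, SentenceLayout,
                     WordBox, drop_short_fixations)

logger = logging.getLogger(__name__)

#: Analysis constants used when a config omits them.
DEFAULT_CONFIG: dict = {
    "fs": 100.0,
    "delays": [-0.2, 1.0],
    "lambda_grid": {"lo": 0.0, "hi": 4.0, "num": 15},  # log10 endpoints
    "n_boot": 10_000,
    "n_perm": 1000,
    "t_threshold": 2.5,
    "dr_display_min": 2e-5,
    "dr_trf_min": 3e-5,
    "alpha": 0.05,
    "base_bands": ["blinks", "saccades", "fixations", "word_fixations",
                   "regressions", "refixations"],
    "features": ["word_length", "character_surprisal", "neighborhood_size",
                 "phoneme_surprisal", "phonotactic_surprisal",
                 "lexical_surprisal", "contextual_surprisal"],
    "offsets": [-4, -3, -2, -1, 0, 1, 2, 3, 4],
    "study": {},   # SyntheticConfig overrides
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config and fill unspecified keys with the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = {**DEFAULT_CONFIG, **user}
    config["study"] = dict(config.get("study") or {})
    return config


def lambda_grid_from_config(config: Mapping) -> np.ndarray:
    g = config["lambda_grid"]
    return np.logspace(float(g["lo"]), float(g["hi"]), int(g["num"]))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Fixation and layout tables

def write_fixation_table(fixations_by_session: Mapping[str, list[FixationEvent]],
                         path: str | Path) -> None:
    rows = [(sid, f.sentence_id, f.onset, f.duration, f.gaze[0], f.gaze[1])
            for sid, fixations in fixations_by_session.items()
            for f in fixations]
    write_table(pd.DataFrame(rows, columns=["session_id", "sentence_id", "onset_s",
                                            "duration_s", "gaze_x", "gaze_y"]), path)


def read_fixation_table(path: str | Path,
                        min_duration: float = MIN_FIXATION_DURATION
                        ) -> dict[str, list[FixationEvent]]:
    """Parse fixation events per session; sub-threshold fixations are dropped."""
    df = pd.read_csv(path, sep="\t", dtype={"session_id": str, "sentence_id": str})
    out: dict[str, list[FixationEvent]] = {}
    for sid, group in df.groupby("session_id", sort=False):
        fixations = [FixationEvent(onset=row.onset_s, duration=row.duration_s,
                                   gaze=(row.gaze_x, row.gaze_y),
                                   sentence_id=row.sentence_id)
                     for row in group.itertuples(index=False)]
        out[str(sid)] = drop_short_fixations(sorted(fixations, key=lambda f: f.onset),
                                             min_duration)
    return out


def write_layout_table(layouts: Mapping[str, SentenceLayout],
                       path: str | Path) -> None:
    rows = [(sid, w.word_index, w.text, w.line, *w.bbox)
            for sid, layout in layouts.items() for w in layout.words]
    write_table(pd.DataFrame(rows, columns=["sentence_id", "word_index", "text",
                                            "line", "x0", "y0", "x1", "y1"]), path)


def read_layout_table(path: str | Path) -> dict[str, SentenceLayout]:
    df = pd.read_csv(path, sep="\t", dtype={"sentence_id": str, "text": str})
    out = {}
    for sid, group in df.groupby("sentence_id", sort=False):
        words = tuple(WordBox(word_index=int(r.word_index), text=r.text,
                              line=int(r.line),
                              bbox=(r.x0, r.y0, r.x1, r.y1))
                      for r in group.sort_values("word_index").itertuples(index=False))
        out[str(sid)] = SentenceLayout(sentence_id=str(sid), words=words)
    return out


# ---------------------------------------------------------------------------
# Session archive (named-array container + JSON sidecar)

def save_session(ds: SessionDataset, basepath: str | Path) -> None:
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    arrays = {
        "eeg": ds.eeg,
        "blink_onsets": ds.blink_onsets,
        "saccade_onsets": ds.saccade_onsets,
        "blocks": np.array(ds.blocks, dtype=np.int64),
    }
    meta: dict = {
        "fs": ds.fs,
        "channel_names": ds.channel_names,
        "channel_roles": ds.channel_roles,
        "metadata": ds.metadata,
        "fixations": [
            {"onset": f.onset, "duration": f.duration, "gaze": list(f.gaze),
             "word_index": f.word_index, "labels": sorted(f.labels),
             "sentence_id": f.sentence_id}
            for f in ds.fixations],
        "layouts": {
            sid: [{"word_index": w.word_index, "text": w.text, "line": w.line,
                   "bbox": list(w.bbox)} for w in layout.words]
            for sid, layout in ds.layouts.items()},
    }
    if ds.ground_truth is not None:
        gt = ds.ground_truth
        meta["ground_truth"] = {"bands": list(gt.kernels),
                                "noise_sigma": gt.noise_sigma}
        arrays["gt_kernels"] = np.stack([gt.kernels[b] for b in gt.kernels])
        arrays["gt_lags"] = gt.lags
    np.savez(basepath.with_suffix(".npz"), **arrays)
    with open(basepath.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_session(basepath: str | Path) -> SessionDataset:
    basepath = Path(basepath)
    arrays = np.load(basepath.with_suffix(".npz"))
    with open(basepath.with_suffix(".json")) as fh:
        meta = json.load(fh)
    fixations = [FixationEvent(onset=f["onset"], duration=f["duration"],
                               gaze=tuple(f["gaze"]),
                               word_index=f["word_index"],
                               labels=frozenset(f["labels"]),
                               sentence_id=f["sentence_id"])
                 for f in meta["fixations"]]
    layouts = {
        sid: SentenceLayout(sentence_id=sid, words=tuple(
            WordBox(word_index=w["word_index"], text=w["text"], line=w["line"],
                    bbox=tuple(w["bbox"])) for w in words))
        for sid, words in meta["layouts"].items()}
    ground_truth: Optional[GroundTruth] = None
    if "ground_truth" in meta:
        bands = meta["ground_truth"]["bands"]
        ground_truth = GroundTruth(
            kernels={b: arrays["gt_kernels"][i] for i, b in enumerate(bands)},
            lags=arrays["gt_lags"],
            noise_sigma=meta["ground_truth"]["noise_sigma"])
    return SessionDataset(
        eeg=arrays["eeg"], fs=meta["fs"],
        channel_names=list(meta["channel_names"]),
        channel_roles=dict(meta["channel_roles"]),
        fixations=fixations, layouts=layouts,
        blocks=[tuple(b) for b in arrays["blocks"].tolist()],
        blink_onsets=arrays["blink_onsets"],
        saccade_onsets=arrays["saccade_onsets"],
        metadata=dict(meta["metadata"]),
        ground_truth=ground_truth)
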