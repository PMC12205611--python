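"""Signal conditioning and channel bookkeeping applied before model fitting."""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

CHANNEL_ROLES = ("scalp", "eog", "face-neck")


def lowpass_downsample(eeg: np.ndarray, fs_in: float, cutoff: float = 30.0,
                       order: int = 5, fs_out: float = 100.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass, then downsample.

    Forward-backward filtering (no causality constraint in offline analysis;
    note this symmetrizes the filter delay, unlike a causal filter, which
    would shift TRF latencies).  Integer rate ratios decimate by slicing;
    otherwise polyphase resampling is used.  Output length is
    ceil(n · fs_out / fs_in).
    """
    if fs_in < 2 * cutoff:
        raise ValueError(f"fs_in {fs_in} violates Nyquist for cutoff {cutoff}")
    eeg = np.asarray(eeg, dtype=float)
    sos = sps.butter(order, cutoff, btype="low", fs=fs_in, output="sos")
    filtered = sps.sosfiltfilt(sos, eeg, axis=0)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        return np.ascontiguousarray(filtered[::int(round(ratio))])
    up = int(round(fs_out))
    down = int(round(fs_in))
    g = math.gcd(up, down)
    out = sps.resample_poly(filtered, up // g, down // g, axis=0)
    n_target = math.ceil(len(eeg) * fs_out / fs_in)
    return out[:n_target]


def select_scalp_channels(channel_roles: Mapping[str, str] | Sequence[tuple[str, str]]
                          ) -> list[str]:
    """Retain scalp channels only, in original order, with counts logged.

    EOG channels serve artifact removal upstream and face/neck channels are
    discarded; neither enters the encoding model.
    """
    items = list(channel_roles.items()) if isinstance(channel_roles, Mapping) \
        else list(channel_roles)
    counts = {role: 0 for role in CHANNEL_ROLES}
    retained = []
    for name, role in items:
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r} for {name!r}")
        counts[role] += 1
        if role == "scalp":
            retained.append(name)
    if not retained:
        raise ValueError("no scalp channels to analyze")
    logger.info("channels: %d scalp retained, %d EOG, %d face/neck discarded",
                counts["scalp"], counts["eog"], counts["face-neck"])
    return retained
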