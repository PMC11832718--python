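"""Channel layouts and region selections for 64-channel 10-20 recordings."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["CHANNELS_64", "REGIONS", "RegionSelection", "region", "channel_positions"]

# 64-electrode extended 10-20 cap layout (10-10 names), covering every channel
# named by the mixed and frontal analysis regions.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "FT9", "FT10",
)

# Bilateral temporal/parietal + midline set reflecting auditory-response
# physiology, and the frontal set implicated in executive function.
REGIONS: dict[str, tuple[str, ...]] = {
    "mixed": ("FT7", "T7", "TP7", "P7", "P5", "Fz", "FCz", "Cz", "CPz",
              "FT8", "T8", "TP8", "P6", "P8"),
    "frontal": ("F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"),
    "whole": CHANNELS_64,
}


@dataclass(frozen=True)
class RegionSelection:
    name: str
    channels: tuple[str, ...]


def region(name: str) -> RegionSelection:
    """Return a named analysis region (``mixed``, ``frontal`` or ``whole``)."""
    try:
        return RegionSelection(name=name, channels=REGIONS[name])
    except KeyError:
        raise ValueError(f"unknown region {name!r}; choose from {sorted(REGIONS)}") from None


@lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    montage = mne.channels.make_standard_montage("colin27_1005")
    return {k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()}


def channel_positions(labels) -> np.ndarray:
    """3-D electrode positions (meters, head frame) from the standard 10-05
    template montage, one row per label."""
    pos = _montage_positions()
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise ValueError(f"no template position for channels: {missing}")
    return np.stack([pos[lab] for lab in labels])
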