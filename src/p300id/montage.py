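"""62-channel extended 10-20 montage and the default scalp gain profile."""

from __future__ import annotations

import numpy as np

# Anterior-to-posterior, left-to-right ordering of a 62-electrode cap
# (FCz is the on-line reference and AFz the ground, hence absent).
MONTAGE_62: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

# Relative P300 gain per electrode row: the evoked response is strongest
# over fronto-central sites and falls off toward temporal/posterior sites.
_ROW_GAIN = {
    "Fp": 0.75, "AF": 0.85, "FT": 0.50, "FC": 1.00, "F": 0.95,
    "TP": 0.40, "CP": 0.65, "T": 0.40, "C": 0.90,
    "PO": 0.30, "P": 0.45, "O": 0.25,
}


def row_of(channel: str) -> str:
    """Electrode row prefix ('FC' for 'FC1', 'F' for 'Fz', ...)."""
    for prefix in ("Fp", "AF", "FT", "FC", "TP", "CP", "PO"):
        if channel.startswith(prefix):
            return prefix
    return channel[0]


def default_frontal_weighting(channel_names) -> np.ndarray:
    """Per-channel multiplicative gain applied to the injected P300 template."""
    return np.array([_ROW_GAIN[row_of(ch)] for ch in channel_names], dtype=float)
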