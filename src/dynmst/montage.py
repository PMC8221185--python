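"""Default electrode naming for the 63-channel 10-10 montage.

The default layout matches a 64-electrode actiCAP-style cap with the Iz
electrode used as the online reference, leaving 63 scalp channels. Nodal
results (degree, betweenness) are reported against these labels so that
regions such as the left frontal pole (Fp1, AF3) or the right
occipito-temporal strip (PO8, P8, TP10) are addressable by name.
"""

from __future__ import annotations

# 64-channel actiCAP layout minus the Iz reference.
CHANNELS_63 = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "F2", "AF4", "AF8",
]

#: Occipito-temporal channels used for the time-segment baseline features.
OCCIPITO_TEMPORAL = [
    "P7", "PO7", "PO3", "O1", "POz", "Oz", "O2", "PO4", "PO8", "P8",
    "TP9", "TP10",
]


def default_labels(n_channels: int) -> list[str]:
    """Channel labels for an ``n_channels`` montage.

    Uses the 10-10 names for up to 63 channels; falls back to generic
    ``CH01``-style labels for larger (non-physiological) montages.
    """
    if n_channels <= len(CHANNELS_63):
        return list(CHANNELS_63[:n_channels])
    width = max(2, len(str(n_channels)))
    return [f"CH{i + 1:0{width}d}" for i in range(n_channels)]
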