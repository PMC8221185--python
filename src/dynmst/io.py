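"""Optional ingestion of standard EEG epoch formats into the epoch archive.

Requires ``mne`` (optional dependency). Continuous EDF or BrainVision
recordings are epoched around annotation/event markers; already-epoched
``mne.Epochs`` objects convert directly. The pipeline itself never
imports this module.
"""

from __future__ import annotations

import numpy as np

from .synth import EpochSet


def from_mne_epochs(epochs, condition_map: dict[int, str] | None = None,
                    subject: str = "S01") -> EpochSet:
    """Convert an ``mne.Epochs``/``EpochsArray`` to an :class:`EpochSet`.

    ``condition_map`` maps event codes to condition labels; by default
    the mne event-id names are used.
    """
    data = epochs.get_data(copy=True)
    codes = epochs.events[:, 2]
    if condition_map is None:
        inv = {v: k for k, v in epochs.event_id.items()}
        condition_map = inv
    condition = np.asarray([condition_map[int(c)] for c in codes])
    time_zero_index = int(np.searchsorted(epochs.times, 0.0))
    return EpochSet(
        data=data,
        sample_rate=float(epochs.info["sfreq"]),
        time_zero_index=time_zero_index,
        channel_labels=list(epochs.ch_names),
        condition=condition,
        subject=np.repeat(subject, data.shape[0]),
    )


def read_raw_epochs(path: str, span_ms: tuple[float, float] = (-200.0, 800.0),
                    condition_map: dict[int, str] | None = None,
                    subject: str = "S01") -> EpochSet:
    """Read a continuous EDF or BrainVision (.vhdr) file and epoch it
    around its annotation events."""
    import mne

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    epochs = mne.Epochs(raw, events, event_id=event_id,
                        tmin=span_ms[0] / 1000.0, tmax=span_ms[1] / 1000.0,
                        baseline=None, preload=True, verbose="error")
    return from_mne_epochs(epochs, condition_map=condition_map, subject=subject)
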