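"""Re-referencing, zero-phase band filtering, baseline correction, windowing.

The order of operations for the pipeline is: common average reference,
band-pass filter, baseline correction, then slicing into the sequential
post-stimulus analysis windows. Filtering (and the later Hilbert
transform) always runs over the full epoch; windows are cut afterwards so
filter edge transients stay outside the analysed 0-500 ms segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .synth import EpochSet


@dataclass
class BandWindow:
    """One (band, analysis-window) slice of an epoch set.

    window_index is 1-based (T1..T5); window_span is in ms relative to
    stimulus onset; data is (trials, channels, window-samples).
    """

    band_label: str
    band_edges: tuple[float, float]
    window_index: int
    window_span: tuple[float, float]
    data: np.ndarray


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over channels from every channel."""
    if epochs.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data)


def bandpass(epochs: EpochSet, band_edges: tuple[float, float],
             order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass over the full epoch.

    The filter is applied forward and backward (sosfiltfilt), so the net
    response has no group delay and instantaneous phase is undistorted —
    a requirement for phase-lag-index estimation downstream.
    """
    low, high = band_edges
    nyq = epochs.sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band edges {band_edges} invalid for fs={epochs.sample_rate}")
    sos = butter(order, [low, high], btype="bandpass",
                 fs=epochs.sample_rate, output="sos")
    return epochs.copy_with(sosfiltfilt(sos, epochs.data, axis=-1))


def baseline_correct(epochs: EpochSet,
                     baseline_span: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``baseline_span`` (ms)."""
    times = epochs.times
    mask = (times >= baseline_span[0]) & (times < baseline_span[1])
    if not mask.any():
        raise ValueError(f"baseline span {baseline_span} holds no samples")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.copy_with(epochs.data - base)


def window_slices(epochs: EpochSet, n_windows: int = 5,
                  window_ms: float = 100.0) -> list[slice]:
    """Sample slices for ``n_windows`` contiguous windows starting at onset."""
    fs = epochs.sample_rate
    samples_per = window_ms * fs / 1000.0
    if abs(samples_per - round(samples_per)) > 1e-9:
        raise ValueError("window_ms must hold an integer number of samples")
    samples_per = int(round(samples_per))
    t0 = epochs.time_zero_index
    if t0 + n_windows * samples_per > epochs.n_samples:
        raise ValueError("analysis windows exceed the post-stimulus span")
    return [slice(t0 + w * samples_per, t0 + (w + 1) * samples_per)
            for w in range(n_windows)]


def window_split(epochs: EpochSet, n_windows: int = 5, window_ms: float = 100.0,
                 band_label: str = "", band_edges: tuple[float, float] = (0.0, 0.0),
                 ) -> list[BandWindow]:
    """Slice the post-stimulus segment into contiguous analysis windows.

    Windows tile 0..n_windows*window_ms ms without overlap; concatenating
    the slices reproduces that segment exactly.
    """
    out = []
    for w, sl in enumerate(window_slices(epochs, n_windows, window_ms), start=1):
        out.append(BandWindow(
            band_label=band_label, band_edges=tuple(band_edges), window_index=w,
            window_span=((w - 1) * window_ms, w * window_ms),
            data=epochs.data[:, :, sl]))
    return out
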