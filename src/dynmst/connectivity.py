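"""Phase lag index (PLI) functional connectivity.

The PLI between two signals is the absolute time-average of the sign of
the sine of their instantaneous phase difference::

    PLI = | (1/N) sum_k sgn( sin(phi_a(t_k) - phi_b(t_k)) ) |

with the three-valued signum (sgn(0) = 0). Phase differences locked at
exactly 0 (or pi) therefore contribute nothing: zero-lag synchronization
— the signature of volume conduction, where one source projects to many
electrodes — is removed by construction. PLI ranges from 0 (no coupling,
or coupling at zero lag) to 1 (perfectly constant nonzero lag).

Instantaneous phase comes from the analytic signal z(t) = x(t) + i x~(t),
where x~ is the Hilbert transform of x; phase is the four-quadrant
arctangent of (x~, x) and amplitude is |z|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

#: |sin| values below this are treated as exactly zero before the signum,
#: so analytically zero-lag inputs behave deterministically.
SIN_ZERO_TOL = 1e-12


@dataclass
class AnalyticSignal:
    """Analytic-signal decomposition of a real signal (last axis = time)."""

    real: np.ndarray
    quadrature: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels PLI adjacency with provenance."""

    values: np.ndarray
    trial: int = -1
    condition: str = ""
    band_label: str = ""
    window_index: int = 0
    n_samples: int = 0
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(v, v.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI entries must lie in [0, 1]")
        self.values = v


def analytic_signal(x: np.ndarray, axis: int = -1) -> AnalyticSignal:
    """Hilbert-transform analytic signal, amplitude and phase.

    Raises on an all-zero input, whose phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 4:
        raise ValueError("need at least 4 samples")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples")
    if not np.any(x):
        raise ValueError("all-zero signal: phase undefined")
    z = hilbert(x, axis=axis)
    return AnalyticSignal(real=z.real, quadrature=z.imag,
                          amplitude=np.abs(z), phase=np.angle(z))


def instantaneous_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Instantaneous phase in (-pi, pi] via the analytic signal."""
    return analytic_signal(x, axis=axis).phase


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> np.ndarray:
    """PLI between two phase series (time on the last axis; broadcasts)."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape[-1] != phase_b.shape[-1]:
        raise ValueError("phase series must have equal length")
    s = np.sin(phase_a - phase_b)
    s = np.where(np.abs(s) <= SIN_ZERO_TOL, 0.0, s)
    return np.abs(np.mean(np.sign(s), axis=-1))


def pli_matrix_stack(phases: np.ndarray) -> np.ndarray:
    """PLI adjacency for stacked phase arrays.

    phases : (..., n_channels, n_samples) -> (..., n_channels, n_channels)
    """
    phases = np.asarray(phases, dtype=float)
    n_ch = phases.shape[-2]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    iu, ju = np.triu_indices(n_ch, k=1)
    vals = pli_pair(phases[..., iu, :], phases[..., ju, :])
    out = np.zeros(phases.shape[:-2] + (n_ch, n_ch))
    out[..., iu, ju] = vals
    out[..., ju, iu] = vals
    return out


def pli_matrix(window_data: np.ndarray, trial: int = -1, condition: str = "",
               band_label: str = "", window_index: int = 0,
               channel_labels: list[str] | None = None,
               precomputed_phase: bool = False) -> ConnectivityMatrix:
    """PLI adjacency for one (channels x samples) window.

    ``window_data`` is raw signal by default; pass phases directly with
    ``precomputed_phase=True`` (the pipeline computes phase over the full
    epoch and slices it, rather than per window).
    """
    window_data = np.asarray(window_data, dtype=float)
    if window_data.ndim != 2:
        raise ValueError("expected (channels, samples)")
    phases = window_data if precomputed_phase else instantaneous_phase(window_data)
    values = pli_matrix_stack(phases)
    return ConnectivityMatrix(
        values=values, trial=trial, condition=condition, band_label=band_label,
        window_index=window_index, n_samples=window_data.shape[-1],
        channel_labels=list(channel_labels or []))
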