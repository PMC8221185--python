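"""Synthetic multichannel epochs with planted phase-coupling topologies.

Real event-related EEG for the face/non-face paradigm is not publicly
deposited, so this module generates trial-structured, band-limited
multichannel signals in which the *phase* relations between channels are
controlled: within a chosen (condition, band, time-window) cell, selected
channel pairs share a common narrowband carrier offset by a fixed,
nonzero phase lag. Because the phase lag index (PLI) depends only on the
sign of the instantaneous phase difference, this is sufficient to plant
arbitrary coupling graphs — star-like or line-like backbones — that the
downstream network pipeline should recover.

The coupling mechanism is filtered-noise mixing rather than a coupled
differential-equation integrator: each planted graph gets an analytic
(complex) band-limited Gaussian carrier per trial; a channel's signal in
that band is a variance-preserving blend of its own independent carrier
and the shared carrier rotated by the channel's accumulated target lag.
The blend coefficient is localized to the planted time window with short
cosine ramps so that window borders introduce no discontinuities.

Also hosts the experiment bookkeeping helpers (trial-count arithmetic and
the stratified analysis/validation split) and the on-disk epoch archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .montage import default_labels

#: Canonical frequency bands (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 46.0),
}

DEFAULT_CONDITIONS = ("face", "ketch", "scrambled")


@dataclass(frozen=True)
class CouplingGraph:
    """Planted phase-coupling structure over the channel nodes.

    Each edge ``(i, j, lag, weight)`` requests that channel ``i`` lead
    channel ``j`` by ``lag`` radians with mixing weight ``weight`` in
    [0, 1]. Zero lag is rejected for any edge meant to produce nonzero
    PLI: zero-lag synchronization is invisible to the PLI by design.
    """

    n_nodes: int
    edges: tuple[tuple[int, int, float, float], ...]

    def __post_init__(self):
        seen = set()
        for i, j, lag, w in self.edges:
            if i == j:
                raise ValueError(f"self-edge ({i},{i}) not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) outside 0..{self.n_nodes - 1}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            if not (-np.pi < lag <= np.pi):
                raise ValueError(f"lag {lag} outside (-pi, pi]")
            if lag == 0.0:
                raise ValueError("zero-lag edges produce no phase-lag-index signal")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge weight {w} outside [0, 1]")


def star_graph(n_nodes: int, hub: int = 0, lag: float = np.pi / 2,
               weight: float = 1.0, alternate: bool = True) -> CouplingGraph:
    """Hub-and-spokes coupling with a ``lag`` phase offset per spoke.

    By default the sign of the lag alternates between consecutive spokes.
    With a common lag sign every spoke would carry the shared carrier at
    the *same* phase, the montage average would be dominated by it, and
    common-average re-referencing would subtract the coupling right back
    out; alternating signs keep the average carrier-free while every
    hub-spoke pair still has a nonzero (PLI-visible) lag.
    """
    edges = []
    k = 0
    for j in range(n_nodes):
        if j == hub:
            continue
        sign = (-1) ** k if alternate else 1
        edges.append((hub, j, sign * lag, weight))
        k += 1
    return CouplingGraph(n_nodes, tuple(edges))


def chain_graph(n_nodes: int, lag: float = np.pi / 2,
                weight: float = 1.0) -> CouplingGraph:
    """Nearest-neighbour chain coupling with a constant per-link lag.

    The default quarter-cycle lag makes the accumulated lag of
    even-distance pairs a multiple of pi — invisible to the PLI — so
    together with the per-edge phase jitter of the generator the planted
    backbone decays with chain distance instead of forming a clique.
    """
    edges = tuple((k, k + 1, lag, weight) for k in range(n_nodes - 1))
    return CouplingGraph(n_nodes, edges)


@dataclass
class EpochSet:
    """Trial-structured multichannel signals with labels.

    data : (n_trials, n_channels, n_samples) array, signal units
    sample_rate : Hz
    time_zero_index : sample index of stimulus onset
    channel_labels : one name per channel
    condition, subject : per-trial labels
    """

    data: np.ndarray
    sample_rate: float
    time_zero_index: int
    channel_labels: list[str]
    condition: np.ndarray
    subject: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        self.subject = np.asarray(self.subject)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length mismatch")
        if not 0 <= self.time_zero_index < self.data.shape[2]:
            raise ValueError("time_zero_index outside epoch")
        if len(self.condition) != self.n_trials or len(self.subject) != self.n_trials:
            raise ValueError("per-trial label length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time in milliseconds relative to stimulus onset."""
        idx = np.arange(self.n_samples) - self.time_zero_index
        return idx * 1000.0 / self.sample_rate

    def select(self, index) -> "EpochSet":
        """Sub-EpochSet keeping trials at ``index`` (mask or integer array)."""
        return EpochSet(self.data[index], self.sample_rate, self.time_zero_index,
                        list(self.channel_labels), self.condition[index],
                        self.subject[index])

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(data, self.sample_rate, self.time_zero_index,
                        list(self.channel_labels), self.condition.copy(),
                        self.subject.copy())


@dataclass
class SynthConfig:
    """Generator configuration; defaults mirror the emulated recording setup:

    63 channels at 1000 Hz, epochs spanning -200..800 ms around stimulus
    onset, the five canonical frequency bands, and five sequential 100-ms
    analysis windows after onset. Coupling is planted per
    (condition, band, window-index) cell; windows without an entry carry
    independent phases in every channel.
    """

    n_subjects: int = 1
    trials_per_condition_per_subject: int = 100
    n_channels: int = 63
    sample_rate: float = 1000.0
    epoch_span: tuple[float, float] = (-200.0, 800.0)
    band_plan: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    coupling_plan: dict[tuple[str, str, int], CouplingGraph] = field(
        default_factory=dict)
    coupling_strength: float = 0.9
    noise_sd: float = 1.0
    edge_phase_jitter: float = 0.6
    n_windows: int = 5
    window_ms: float = 100.0
    seed: int = 0

    def __post_init__(self):
        start, end = self.epoch_span
        if not (start < 0 < end):
            raise ValueError("epoch_span must straddle stimulus onset (start < 0 < end)")
        n_samp = (end - start) * self.sample_rate / 1000.0
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch span must hold an integer number of samples")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_windows * self.window_ms > end:
            raise ValueError("analysis windows exceed the post-stimulus span")
        for (cond, band, win), graph in self.coupling_plan.items():
            if cond not in self.conditions:
                raise ValueError(f"coupling_plan condition {cond!r} not in conditions")
            if band not in self.band_plan:
                raise ValueError(f"coupling_plan band {band!r} not in band_plan")
            if not 1 <= win <= self.n_windows:
                raise ValueError(
                    f"coupling_plan window {win} outside 1..{self.n_windows}")
            if graph.n_nodes != self.n_channels:
                raise ValueError("coupling graph node count != n_channels")

    @property
    def n_samples(self) -> int:
        start, end = self.epoch_span
        return int(round((end - start) * self.sample_rate / 1000.0))

    @property
    def time_zero_index(self) -> int:
        return int(round(-self.epoch_span[0] * self.sample_rate / 1000.0))


def _band_sos(low: float, high: float, fs: float):
    return butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _analytic_band_noise(rng: np.random.Generator, shape: tuple[int, ...],
                         sos) -> np.ndarray:
    """Constant-modulus analytic carrier with a band-limited Gaussian phase.

    Band-limited Gaussian noise supplies the phase trajectory; the
    Rayleigh envelope is normalized away because only phase matters to
    the PLI: envelope fades of a complex Gaussian carrier would cause
    correlated drop-outs of the planted coupling (both channels of a
    pair share the carrier, hence its fades). The real part has RMS
    1/sqrt(2) per unit mixing coefficient.
    """
    x = rng.standard_normal(shape)
    x = sosfiltfilt(sos, x, axis=-1)
    a = hilbert(x, axis=-1)
    mag = np.abs(a)
    mag = np.where(mag == 0, 1.0, mag)
    return a / mag


def _window_envelope(config: SynthConfig, window_index: int,
                     ramp_ms: float = 30.0) -> np.ndarray:
    """Mixing envelope for a 1-based analysis window.

    Unity across the whole window, with cosine ramps extending ``ramp_ms``
    *outside* each border: the planted window is then fully coupled while
    the crossfade (which avoids mixing discontinuities) spills only a few
    low-amplitude milliseconds into the neighbouring windows.
    """
    fs = config.sample_rate
    n = config.n_samples
    t0 = config.time_zero_index
    start = t0 + int(round((window_index - 1) * config.window_ms * fs / 1000.0))
    stop = t0 + int(round(window_index * config.window_ms * fs / 1000.0))
    env = np.zeros(n)
    env[start:stop] = 1.0
    ramp = int(round(ramp_ms * fs / 1000.0))
    if ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(1, ramp + 1) / (ramp + 1)))
        lo = max(0, start - ramp)
        env[lo:start] = up[ramp - (start - lo):]
        hi = min(n, stop + ramp)
        env[stop:hi] = up[::-1][:hi - stop]
    return env


def _phase_offsets(graph: CouplingGraph, strength: float):
    """Per-channel carrier offsets, mixing fractions and jitter paths.

    A breadth-first traversal of the coupling graph accumulates the edge
    lags: for an edge (i, j, lag) the phase of channel i leads channel j
    by ``lag``. Each non-root node mixes with fraction strength x (weight
    of the edge used to reach it); a component root uses its strongest
    incident edge weight. Channels outside any edge get mixing 0.

    The returned incidence matrix (n_nodes x n_edges, 0/1) marks, per
    node, the edges on its breadth-first path from the component root;
    the generator sums independent per-edge phase-noise processes along
    these paths so that phase coherence decays with graph distance —
    without it every pair in a component would be equally coherent and
    the planted topology could not be recovered from per-trial networks.
    """
    n = graph.n_nodes
    nbrs: dict[int, list[tuple[int, float, float, int]]] = {k: [] for k in range(n)}
    # Node k's signal is Re(carrier * exp(-i o_k)), so its phase is
    # phi_carrier - o_k and an edge (i, j, lag) with phi_i - phi_j = lag
    # needs o_j = o_i + lag.
    for e, (i, j, lag, w) in enumerate(graph.edges):
        nbrs[i].append((j, +lag, w, e))
        nbrs[j].append((i, -lag, w, e))
    offsets = np.zeros(n)
    mix = np.zeros(n)
    incidence = np.zeros((n, len(graph.edges)))
    visited = np.zeros(n, dtype=bool)
    for root in range(n):
        if visited[root] or not nbrs[root]:
            continue
        visited[root] = True
        mix[root] = strength * max(w for _, _, w, _ in nbrs[root])
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v, dlag, w, e in nbrs[u]:
                if visited[v]:
                    continue
                visited[v] = True
                offsets[v] = offsets[u] + dlag
                incidence[v] = incidence[u]
                incidence[v, e] = 1.0
                mix[v] = strength * w
                queue.append(v)
    return offsets, mix, incidence


def generate_dataset(config: SynthConfig) -> EpochSet:
    """Generate the full synthetic EpochSet described by ``config``.

    Deterministic given ``config.seed``; regenerating with the same
    configuration yields bit-identical data.
    """
    rng = np.random.default_rng(config.seed)
    n_per = config.n_subjects * config.trials_per_condition_per_subject
    n_ch = config.n_channels
    n_samp = config.n_samples
    fs = config.sample_rate

    sos_by_band = {b: _band_sos(lo, hi, fs) for b, (lo, hi) in config.band_plan.items()}
    env_cache = {w: _window_envelope(config, w) for w in range(1, config.n_windows + 1)}

    blocks, conds, subjs = [], [], []
    # Chunk trials to bound the complex intermediate arrays.
    chunk = max(1, int(4_000_000 // max(1, n_ch * n_samp)))
    for cond in config.conditions:
        planted = {w: g for (c, b, w), g in config.coupling_plan.items()
                   if c == cond}  # filled per band below
        out = np.zeros((n_per, n_ch, n_samp))
        for band in config.band_plan:
            sos = sos_by_band[band]
            plan_bw = {w: g for (c, b, w), g in config.coupling_plan.items()
                       if c == cond and b == band}
            for lo in range(0, n_per, chunk):
                hi = min(lo + chunk, n_per)
                m = hi - lo
                indep = _analytic_band_noise(rng, (m, n_ch, n_samp), sos)
                shared = np.zeros((m, n_ch, n_samp), dtype=complex)
                mix_sq = np.zeros((n_ch, n_samp))
                for w, graph in sorted(plan_bw.items()):
                    carrier = _analytic_band_noise(rng, (m, 1, n_samp), sos)
                    offs, mixes, incidence = _phase_offsets(
                        graph, config.coupling_strength)
                    env = env_cache[w]
                    coef = mixes[:, None] * env[None, :]       # (n_ch, n_samp)
                    rot = np.exp(-1j * offs)[:, None]
                    contrib = coef[None] * rot[None] * carrier
                    if config.edge_phase_jitter > 0:
                        # independent narrowband phase noise per edge,
                        # accumulated along each node's path from the root
                        xi = rng.standard_normal((m, len(graph.edges), n_samp))
                        xi = sosfiltfilt(sos, xi, axis=-1)
                        xi /= np.sqrt(np.mean(xi ** 2, axis=-1, keepdims=True))
                        jitter = np.einsum("ke,men->mkn", incidence, xi)
                        contrib = contrib * np.exp(
                            1j * config.edge_phase_jitter * jitter)
                    shared += contrib
                    mix_sq += coef ** 2
                resid = np.sqrt(np.clip(1.0 - mix_sq, 0.0, 1.0))
                out[lo:hi] += (resid[None] * indep + shared).real
        out += rng.normal(0.0, config.noise_sd, out.shape)
        blocks.append(out)
        conds.append(np.repeat(cond, n_per))
        subj = np.repeat(
            [f"S{s + 1:02d}" for s in range(config.n_subjects)],
            config.trials_per_condition_per_subject)
        subjs.append(subj)
        del planted

    return EpochSet(
        data=np.concatenate(blocks, axis=0),
        sample_rate=fs,
        time_zero_index=config.time_zero_index,
        channel_labels=default_labels(n_ch),
        condition=np.concatenate(conds),
        subject=np.concatenate(subjs),
    )


def experiment_counts(n_subjects: int, stimuli_per_category: int,
                      repetitions: int) -> int:
    """Total trials per stimulus category: subjects x stimuli x repetitions."""
    if min(n_subjects, stimuli_per_category, repetitions) <= 0:
        raise ValueError("all counts must be positive")
    return n_subjects * stimuli_per_category * repetitions


def split_dataset(epochs: EpochSet, fraction: float,
                  seed: int) -> tuple[EpochSet, EpochSet]:
    """Stratified random split into analysis and validation subsets.

    Per condition, ``round(fraction * n)`` trials (round-half-to-even on
    the exact rational product) go to the first subset and the remainder
    to the second; membership is disjoint, exhaustive, and reproducible
    under ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    first, second = [], []
    for cond in np.unique(epochs.condition):
        idx = np.flatnonzero(epochs.condition == cond)
        if len(idx) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 trials")
        n1 = int(round(Fraction(str(fraction)) * len(idx)))
        perm = rng.permutation(idx)
        first.append(np.sort(perm[:n1]))
        second.append(np.sort(perm[n1:]))
    return (epochs.select(np.sort(np.concatenate(first))),
            epochs.select(np.sort(np.concatenate(second))))


def validation_study_config(trials_per_condition: int = 200,
                            n_channels: int = 16,
                            conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
                            bands: dict[str, tuple[float, float]] | None = None,
                            windows: tuple[int, ...] = (2, 3),
                            coupling_strength: float = 0.9,
                            seed: int = 0) -> SynthConfig:
    """The package's canonical planted-topology validation study.

    One contrast condition carries star coupling (hub = channel 0), the
    other chain coupling, planted in the given post-stimulus windows of
    each band; a third condition, when present, stays uncoupled and
    serves as the neutral reference. The defaults use the two widest
    canonical bands (beta, gamma): their short filter memory keeps the
    planted coupling localized to its 100-ms window, which the narrow
    low-frequency bands cannot resolve. 16 channels keep the per-trial
    network estimation tractable while leaving tree topology enough room
    to vary between the line and star extremes.
    """
    if bands is None:
        bands = {"beta": DEFAULT_BANDS["beta"], "gamma": DEFAULT_BANDS["gamma"]}
    star_cond, chain_cond = conditions[0], conditions[1]
    plan: dict[tuple[str, str, int], CouplingGraph] = {}
    for band in bands:
        for w in windows:
            plan[(star_cond, band, w)] = star_graph(n_channels, hub=0,
                                                    lag=np.pi / 2)
            plan[(chain_cond, band, w)] = chain_graph(n_channels,
                                                      lag=np.pi / 2)
    return SynthConfig(
        n_subjects=1,
        trials_per_condition_per_subject=trials_per_condition,
        n_channels=n_channels,
        band_plan=bands,
        conditions=conditions,
        coupling_plan=plan,
        coupling_strength=coupling_strength,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Epoch archive: block .npy matrices + JSON sidecars + CSV manifest.

_BLOCK_TRIALS = 256


def save_epochs(epochs: EpochSet, directory: str | Path) -> Path:
    """Write an epoch archive: one matrix file per trial block, a JSON
    sidecar with labels and timing, and a CSV manifest listing trials."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for b, lo in enumerate(range(0, epochs.n_trials, _BLOCK_TRIALS)):
        hi = min(lo + _BLOCK_TRIALS, epochs.n_trials)
        np.save(directory / f"block_{b:04d}.npy", epochs.data[lo:hi])
        sidecar = {
            "sample_rate": epochs.sample_rate,
            "time_zero_index": int(epochs.time_zero_index),
            "channel_labels": list(epochs.channel_labels),
            "condition": [str(c) for c in epochs.condition[lo:hi]],
            "subject": [str(s) for s in epochs.subject[lo:hi]],
        }
        (directory / f"block_{b:04d}.json").write_text(json.dumps(sidecar))
        for r, t in enumerate(range(lo, hi)):
            rows.append({"trial": t, "block": b, "row": r,
                         "condition": str(epochs.condition[t]),
                         "subject": str(epochs.subject[t])})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def load_epochs(directory: str | Path) -> EpochSet:
    """Read an epoch archive written by :func:`save_epochs`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    blocks = sorted(manifest["block"].unique())
    data, cond, subj = [], [], []
    meta = None
    for b in blocks:
        meta = json.loads((directory / f"block_{b:04d}.json").read_text())
        data.append(np.load(directory / f"block_{b:04d}.npy"))
        cond.extend(meta["condition"])
        subj.extend(meta["subject"])
    if meta is None:
        raise ValueError(f"empty archive: {directory}")
    return EpochSet(np.concatenate(data, axis=0), meta["sample_rate"],
                    meta["time_zero_index"], meta["channel_labels"],
                    np.asarray(cond), np.asarray(subj))
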