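"""End-to-end pipeline orchestration with resumable stage artifacts.

A run executes seven stages — synth (or load), preprocess, connect, mst,
dissim, stats, classify — into a run directory of flat CSV/JSON/npy
artifacts, so each stage is independently inspectable. Completed stages
are skipped on re-run unless forced; every random draw derives from the
single configuration seed, and a machine-readable run manifest records
the configuration hash and stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import connectivity, dissimilarity, msttools, preprocess, stats, synth

log = logging.getLogger("dynmst")

STAGES = ("synth", "preprocess", "connect", "mst", "dissim", "stats", "classify")


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    synth: synth.SynthConfig
    bands: dict[str, tuple[float, float]]
    n_windows: int = 5
    window_ms: float = 100.0
    split_fraction: float = 0.7
    split_seed: int = 11
    reference_condition: str = "scrambled"
    contrast_conditions: tuple[str, str] = ("face", "ketch")
    alpha: float = 0.05
    distance: str = "reciprocal"
    svm: dict = field(default_factory=lambda: {
        "folds": 5, "repeats": 5, "C": 1.0, "gamma": "scale"})
    run_classify: bool = True
    run_timesegment: bool = False
    epoch_archive: str | None = None
    seed: int = 0

    def __post_init__(self):
        a, b = self.contrast_conditions
        if a == b:
            raise ValueError("contrast conditions must be distinct")
        if self.reference_condition in (a, b):
            raise ValueError("reference condition must differ from contrasts")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        bands = {k: tuple(v) for k, v in cfg.get(
            "bands", {"alpha": (8.0, 12.0)}).items()}
        windows = cfg.get("windows", {})
        n_windows = int(windows.get("count", 5))
        window_ms = float(windows.get("ms", 100.0))
        seed = int(cfg.get("seed", 0))

        s = dict(cfg.get("synth", {}))
        coupling_spec = s.pop("coupling", [])
        n_channels = int(s.get("n_channels", 63))
        plan = {}
        for item in coupling_spec:
            key = (item["condition"], item["band"], int(item["window"]))
            topo = item.get("topology", "star")
            lag = float(item.get("lag", np.pi / 2))
            weight = float(item.get("weight", 1.0))
            if topo == "star":
                graph = synth.star_graph(n_channels, hub=int(item.get("hub", 0)),
                                         lag=lag, weight=weight)
            elif topo == "chain":
                graph = synth.chain_graph(n_channels, lag=lag, weight=weight)
            else:
                edges = tuple((int(i), int(j), float(l), float(w))
                              for i, j, l, w in item["edges"])
                graph = synth.CouplingGraph(n_channels, edges)
            plan[key] = graph
        conditions = tuple(s.pop("conditions", synth.DEFAULT_CONDITIONS))
        epoch_span = tuple(s.pop("epoch_span", (-200.0, 800.0)))
        synth_cfg = synth.SynthConfig(
            n_subjects=int(s.get("n_subjects", 1)),
            trials_per_condition_per_subject=int(
                s.get("trials_per_condition_per_subject", 100)),
            n_channels=n_channels,
            sample_rate=float(s.get("sample_rate", 1000.0)),
            epoch_span=epoch_span,
            band_plan=bands,
            conditions=conditions,
            coupling_plan=plan,
            coupling_strength=float(s.get("coupling_strength", 0.9)),
            noise_sd=float(s.get("noise_sd", 1.0)),
            edge_phase_jitter=float(s.get("edge_phase_jitter", 0.6)),
            n_windows=n_windows,
            window_ms=window_ms,
            seed=seed,
        )
        split = cfg.get("split", {})
        stages = cfg.get("stages", {})
        return cls(
            synth=synth_cfg, bands=bands, n_windows=n_windows,
            window_ms=window_ms,
            split_fraction=float(split.get("fraction", 0.7)),
            split_seed=int(split.get("seed", seed + 1)),
            reference_condition=cfg.get("reference_condition", "scrambled"),
            contrast_conditions=tuple(cfg.get("contrast_conditions",
                                              ("face", "ketch"))),
            alpha=float(cfg.get("alpha", 0.05)),
            distance=cfg.get("distance", "reciprocal"),
            svm=dict(cfg.get("svm", {"folds": 5, "repeats": 5,
                                     "C": 1.0, "gamma": "scale"})),
            run_classify=bool(stages.get("classify", True)),
            run_timesegment=bool(stages.get("timesegment", False)),
            epoch_archive=cfg.get("epoch_archive"),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _done(out: Path, stage: str) -> Path:
    return out / f".{stage}.done"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 force: bool = False) -> dict:
    """Execute all enabled stages into ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config),
                      "seed": config.seed, "stages": []}

    def stage(name):
        def deco(fn):
            def run():
                marker = _done(out, name)
                if marker.exists() and not force:
                    log.info("stage %s: cached", name)
                else:
                    log.info("stage %s: running", name)
                    try:
                        fn()
                    except Exception as exc:  # halt with stage context
                        raise PipelineError(name, str(exc)) from exc
                    marker.write_text("ok")
                manifest["stages"].append(name)
            return run
        return deco

    cond_a, cond_b = config.contrast_conditions

    @stage("synth")
    def s_synth():
        if config.epoch_archive:
            epochs = synth.load_epochs(config.epoch_archive)
        else:
            epochs = synth.generate_dataset(config.synth)
        synth.save_epochs(epochs, out / "epochs")

    @stage("preprocess")
    def s_preprocess():
        epochs = synth.load_epochs(out / "epochs")
        epochs = preprocess.common_average_reference(epochs)
        epochs = preprocess.baseline_correct(epochs)
        synth.save_epochs(epochs, out / "preproc")

    @stage("connect")
    def s_connect():
        epochs = synth.load_epochs(out / "preproc")
        slices = preprocess.window_slices(epochs, config.n_windows,
                                          config.window_ms)
        index_rows = []
        for band, edges in config.bands.items():
            filt = preprocess.bandpass(epochs, edges)
            # phase over the full epoch, then sliced per window
            stacks = []
            chunk = max(1, int(2_000_000 // max(1, epochs.n_channels
                                                * epochs.n_samples)))
            for lo in range(0, epochs.n_trials, chunk):
                hi = min(lo + chunk, epochs.n_trials)
                phase = connectivity.instantaneous_phase(filt.data[lo:hi])
                win = np.stack([phase[:, :, sl] for sl in slices], axis=1)
                stacks.append(connectivity.pli_matrix_stack(win))
            pli = np.concatenate(stacks, axis=0)
            np.save(out / f"pli_{band}.npy", pli)
            for t in range(epochs.n_trials):
                for w in range(config.n_windows):
                    index_rows.append({"trial": t, "band": band,
                                       "window": w + 1,
                                       "condition": str(epochs.condition[t]),
                                       "file": f"pli_{band}.npy"})
        pd.DataFrame(index_rows).to_csv(out / "pli_index.csv", index=False)

    @stage("mst")
    def s_mst():
        epochs_meta = pd.read_csv(out / "epochs" / "manifest.csv")
        labels = json.loads(
            (out / "epochs" / "block_0000.json").read_text())["channel_labels"]
        global_rows, node_rows = [], []
        for band in config.bands:
            pli = np.load(out / f"pli_{band}.npy")
            trees = np.zeros((pli.shape[0], pli.shape[1], pli.shape[2] - 1, 3))
            for t in range(pli.shape[0]):
                cond = epochs_meta.loc[t, "condition"]
                for w in range(pli.shape[1]):
                    tree = msttools.max_spanning_tree(pli[t, w], labels)
                    trees[t, w] = np.asarray(tree.edges)
                    ms = msttools.mst_measures(tree)
                    row = {"trial": t, "condition": cond, "band": band,
                           "window": w + 1}
                    row.update(ms.as_dict())
                    global_rows.append(row)
                    for node, (k, bc) in enumerate(zip(ms.node_degree,
                                                       ms.node_bc)):
                        node_rows.append({"trial": t, "condition": cond,
                                          "band": band, "window": w + 1,
                                          "node": labels[node],
                                          "K": k, "BC": bc})
            np.save(out / f"trees_{band}.npy", trees)
        pd.DataFrame(global_rows).to_csv(out / "measures.csv", index=False)
        pd.DataFrame(node_rows).to_csv(out / "node_measures.csv", index=False)

    @stage("dissim")
    def s_dissim():
        epochs_meta = pd.read_csv(out / "epochs" / "manifest.csv")
        conditions = epochs_meta["condition"].to_numpy()
        # stratified split of trial indices, written once
        split_path = out / "split.json"
        if not split_path.exists():
            from fractions import Fraction
            first, second = [], []
            srng = np.random.default_rng(config.split_seed)
            for cond in np.unique(conditions):
                idx = np.flatnonzero(conditions == cond)
                n1 = int(round(Fraction(str(config.split_fraction)) * len(idx)))
                perm = srng.permutation(idx)
                first.extend(int(x) for x in perm[:n1])
                second.extend(int(x) for x in perm[n1:])
            split_path.write_text(json.dumps(
                {"analysis": sorted(first), "validation": sorted(second)}))
        split = json.loads(split_path.read_text())
        analysis = np.asarray(split["analysis"])
        rows = []
        for band in config.bands:
            pli = np.load(out / f"pli_{band}.npy")
            trees_arr = np.load(out / f"trees_{band}.npy")
            for w in range(pli.shape[1]):
                ref_idx = analysis[conditions[analysis]
                                   == config.reference_condition]
                if ref_idx.size == 0:
                    raise ValueError("no reference-condition trials in subset")
                ref = dissimilarity.reference_mst(pli[ref_idx, w])
                for cond in config.contrast_conditions:
                    tidx = analysis[conditions[analysis] == cond]
                    for t in tidx:
                        edges = [(int(i), int(j), float(wt))
                                 for i, j, wt in trees_arr[t, w]]
                        tree = msttools.SpanningTree(pli.shape[2], edges)
                        s = dissimilarity.tree_dissimilarity(
                            tree, ref, distance=config.distance)
                        rows.append({"trial": int(t), "condition": cond,
                                     "band": band, "window": w + 1,
                                     "value": s.value})
        pd.DataFrame(rows).to_csv(out / "dissimilarity.csv", index=False)

    @stage("stats")
    def s_stats():
        split = json.loads((out / "split.json").read_text())
        analysis = set(split["analysis"])
        scores = pd.read_csv(out / "dissimilarity.csv")
        grid = len(config.bands) * config.n_windows
        gate, gate_table = stats.gate_by_dissimilarity(
            scores, cond_a, cond_b, alpha=config.alpha, family_size=grid)
        gate_table.to_csv(out / "gate.csv", index=False)
        gm = pd.read_csv(out / "measures.csv")
        nm = pd.read_csv(out / "node_measures.csv")
        gm_a = gm[gm["trial"].isin(analysis)]
        nm_a = nm[nm["trial"].isin(analysis)]
        sel = stats.select_features(gm_a, nm_a, gate, cond_a, cond_b,
                                    alpha=config.alpha, grid_size=grid,
                                    n_nodes=config.synth.n_channels)
        sel.table.to_csv(out / "selection.csv", index=False)
        (out / "feature_manifest.json").write_text(
            json.dumps(sel.to_manifest(), indent=1))

    @stage("classify")
    def s_classify():
        if not config.run_classify:
            return
        split = json.loads((out / "split.json").read_text())
        validation = set(split["validation"])
        manifest_feats = json.loads(
            (out / "feature_manifest.json").read_text())
        if not manifest_feats:
            (out / "classification.json").write_text(
                json.dumps({"note": "empty feature manifest; nothing to train"}))
            return
        gm = pd.read_csv(out / "measures.csv")
        nm = pd.read_csv(out / "node_measures.csv")
        keep = gm["trial"].isin(validation) & gm["condition"].isin(
            [cond_a, cond_b])
        gm_v = gm[keep]
        nm_v = nm[nm["trial"].isin(set(gm_v["trial"]))]
        fm = _classify.build_feature_matrix(gm_v, nm_v, manifest_feats,
                                            positive_condition=cond_a)
        report = _classify.crossval_svm(
            fm, n_folds=int(config.svm.get("folds", 5)),
            n_repeats=int(config.svm.get("repeats", 5)),
            seed=config.seed, c=float(config.svm.get("C", 1.0)),
            gamma=config.svm.get("gamma", "scale"))
        payload = report.as_dict()
        payload["n_trials"] = int(fm.values.shape[0])
        payload["n_features"] = int(fm.values.shape[1])
        (out / "classification.json").write_text(json.dumps(payload, indent=1))
        if config.run_timesegment:
            epochs = synth.load_epochs(out / "preproc").select(
                sorted(set(gm_v["trial"])))
            ts = _classify.timesegment_features(
                epochs, positive_condition=cond_a,
                decimate=int(config.svm.get("ts_decimate", 10)))
            ts_report = _classify.crossval_svm(
                ts, n_folds=int(config.svm.get("folds", 5)),
                n_repeats=int(config.svm.get("repeats", 5)),
                seed=config.seed)
            (out / "classification_ts.json").write_text(
                json.dumps(ts_report.as_dict(), indent=1))

    for fn in (s_synth, s_preprocess, s_connect, s_mst, s_dissim,
               s_stats, s_classify):
        fn()

    (out / "run.json").write_text(json.dumps(manifest, indent=1))
    return manifest
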