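"""Single-trial condition classification from selected tree measures.

The feature vector of a trial concatenates, in a deterministic
(band, window, measure, node) order, the tree measures that survived the
statistical selection on the analysis subset. An RBF-kernel support
vector machine is evaluated with repeated stratified five-fold
cross-validation: features are z-scored with statistics fitted on the
training folds only, decision values are pooled within a repetition for
the ROC curve, and accuracy / sensitivity / specificity / AUC are
averaged over repetitions.

A raw time-segment (TS) baseline — concatenated amplitude samples from
the occipito-temporal channels — is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .montage import OCCIPITO_TEMPORAL
from .synth import EpochSet


@dataclass
class FeatureMatrix:
    """Trials x features with binary labels and the generating manifest."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    manifest: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains missing values")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length mismatch")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")


@dataclass
class ClassificationReport:
    """Cross-validated performance, averaged over repetitions."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: np.ndarray            # (k, 2) pooled (FPR, TPR) of first rep
    per_repetition: pd.DataFrame
    seed: int

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc}


def _manifest_name(entry: dict) -> str:
    node = entry.get("node")
    suffix = f":{node}" if node else ""
    return f"{entry['band']}/T{entry['window']}/{entry['measure']}{suffix}"


def build_feature_matrix(global_measures: pd.DataFrame,
                         node_measures: pd.DataFrame,
                         manifest: list[dict],
                         positive_condition: str) -> FeatureMatrix:
    """Assemble the per-trial feature matrix for a feature manifest.

    The column order follows the manifest (already sorted by band,
    window, measure, node). Every manifest entry must be computable for
    every trial; a missing (band, window) computation raises with the
    offending trial named.
    """
    trials = np.sort(global_measures["trial"].unique())
    cond = (global_measures.drop_duplicates("trial")
            .set_index("trial")["condition"])
    columns = []
    for entry in manifest:
        if entry.get("node"):
            src = node_measures[(node_measures["band"] == entry["band"])
                                & (node_measures["window"] == entry["window"])
                                & (node_measures["node"] == entry["node"])]
            col = src.set_index("trial")[entry["measure"]]
        else:
            src = global_measures[(global_measures["band"] == entry["band"])
                                  & (global_measures["window"] == entry["window"])]
            col = src.set_index("trial")[entry["measure"]]
        missing = np.setdiff1d(trials, col.index.to_numpy())
        if missing.size:
            raise ValueError(
                f"trial {missing[0]} lacks {_manifest_name(entry)}")
        columns.append(col.loc[trials].to_numpy())
    values = (np.column_stack(columns) if columns
              else np.empty((trials.size, 0)))
    labels = (cond.loc[trials].to_numpy() == positive_condition).astype(int)
    return FeatureMatrix(values=values, labels=labels,
                         feature_names=[_manifest_name(e) for e in manifest],
                         manifest=list(manifest))


def crossval_svm(features: FeatureMatrix, n_folds: int = 5,
                 n_repeats: int = 5, seed: int = 0, c: float = 1.0,
                 gamma: str | float = "scale") -> ClassificationReport:
    """Repeated stratified k-fold evaluation of an RBF-kernel SVM.

    Per fold, a fresh StandardScaler+SVC pipeline is fitted on the
    training split only (no leakage); per repetition, decision values of
    all folds are pooled for the ROC; metrics are means over repetitions.
    """
    X, y = features.values, features.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need two classes")
    counts = np.bincount(y)
    if counts[counts > 0].min() < n_folds:
        raise ValueError("need at least n_folds trials per class")

    reps = []
    roc_points = None
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed * n_repeats + rep)
        scores = np.zeros(len(y))
        pred = np.zeros(len(y), dtype=int)
        fold_acc = []
        for train, test in skf.split(X, y):
            clf = make_pipeline(StandardScaler(),
                                SVC(kernel="rbf", C=c, gamma=gamma))
            clf.fit(X[train], y[train])
            pred[test] = clf.predict(X[test])
            scores[test] = clf.decision_function(X[test])
            fold_acc.append(float(np.mean(pred[test] == y[test])))
        tp = np.sum((pred == 1) & (y == 1))
        tn = np.sum((pred == 0) & (y == 0))
        rep_row = {
            "repetition": rep,
            "accuracy": float(np.mean(pred == y)),
            "sensitivity": tp / max(1, np.sum(y == 1)),
            "specificity": tn / max(1, np.sum(y == 0)),
            "auc": float(roc_auc_score(y, scores)),
            "fold_accuracy_sd": float(np.std(fold_acc)),
        }
        reps.append(rep_row)
        if roc_points is None:
            fpr, tpr, _ = roc_curve(y, scores)
            roc_points = np.column_stack([fpr, tpr])

    per_rep = pd.DataFrame(reps)
    return ClassificationReport(
        accuracy=float(per_rep["accuracy"].mean()),
        sensitivity=float(per_rep["sensitivity"].mean()),
        specificity=float(per_rep["specificity"].mean()),
        auc=float(per_rep["auc"].mean()),
        roc_points=roc_points, per_repetition=per_rep, seed=seed)


def timesegment_features(epochs: EpochSet,
                         channels: list[str] | None = None,
                         span: tuple[float, float] = (0.0, 500.0),
                         decimate: int = 1,
                         positive_condition: str = "") -> FeatureMatrix:
    """Raw amplitude baseline: concatenated samples of named channels.

    Defaults to the occipito-temporal montage subset over the analysed
    post-stimulus span, optionally decimated (simple subsampling; the
    signals are already band-limited upstream).
    """
    channels = channels if channels is not None else [
        ch for ch in OCCIPITO_TEMPORAL if ch in epochs.channel_labels]
    idx = []
    for ch in channels:
        if ch not in epochs.channel_labels:
            raise ValueError(f"unknown channel label {ch!r}")
        idx.append(epochs.channel_labels.index(ch))
    times = epochs.times
    mask = (times >= span[0]) & (times < span[1])
    seg = epochs.data[:, idx, :][:, :, mask][:, :, ::decimate]
    n_trials = seg.shape[0]
    values = seg.reshape(n_trials, -1)
    names = [f"{ch}@{k}" for ch in channels for k in range(seg.shape[2])]
    labels = (epochs.condition == positive_condition).astype(int)
    return FeatureMatrix(values=values, labels=labels, feature_names=names)
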