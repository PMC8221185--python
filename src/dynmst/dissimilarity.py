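"""Information-based dissimilarity between spanning trees.

Two trees over the same nodes are compared through per-node neighbourhood
distance sums: for node i in tree k, S_k(i) is the sum of edge distances
from i to its direct tree neighbours, with the edge distance the
reciprocal of the edge's PLI weight (strong coupling = short distance).
The dissimilarity of tree n given tree m is the average log ratio

    S_n/m = (1/N) sum_i log10( S_n(i) / S_m(i) )

which is 0 for identical trees, antisymmetric under argument swap, and
invariant to a common rescaling of all PLI weights.

In the pipeline each trial's tree is scored against a reference tree
built from the mean adjacency of the neutral ("scrambled") condition;
the per-condition score distributions feed the statistical gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .msttools import SpanningTree, max_spanning_tree


@dataclass
class DissimilarityScore:
    """S_n/m score with provenance metadata."""

    value: float
    reference_id: str = "ref"
    trial: int = -1
    condition: str = ""
    band_label: str = ""
    window_index: int = 0


def _neighbor_distance_sums(tree: SpanningTree, distance: str) -> np.ndarray:
    s = np.zeros(tree.n_nodes)
    for i, j, w in tree.edges:
        if distance == "reciprocal":
            if w <= 0:
                raise ValueError("zero-PLI tree edge: distance undefined")
            d = 1.0 / w
        elif distance == "one-minus":
            d = 1.0 - w
            if d <= 0:
                raise ValueError("unit-PLI tree edge: 1-PLI distance degenerates")
        else:
            raise ValueError(f"unknown distance convention {distance!r}")
        s[i] += d
        s[j] += d
    return s


def tree_dissimilarity(tree_n: SpanningTree, tree_m: SpanningTree,
                  distance: str = "reciprocal") -> DissimilarityScore:
    """Average log10 ratio of per-node neighbour distance sums."""
    if tree_n.n_nodes != tree_m.n_nodes:
        raise ValueError("trees must share the node set")
    s_n = _neighbor_distance_sums(tree_n, distance)
    s_m = _neighbor_distance_sums(tree_m, distance)
    value = float(np.mean(np.log10(np.abs(s_n / s_m))))
    return DissimilarityScore(value=value)


def reference_mst(matrices, node_labels: list[str] | None = None) -> SpanningTree:
    """Maximum spanning tree of the element-wise mean adjacency.

    ``matrices`` is a stack of adjacency arrays or ConnectivityMatrix
    objects from the same (band, window) cell; mixing cells is an error.
    """
    arrays, meta = [], set()
    for m in matrices:
        if isinstance(m, ConnectivityMatrix):
            meta.add((m.band_label, m.window_index))
            arrays.append(m.values)
        else:
            arrays.append(np.asarray(m, dtype=float))
    if not arrays:
        raise ValueError("need at least one adjacency matrix")
    if len(meta) > 1:
        raise ValueError(f"mixed (band, window) metadata: {sorted(meta)}")
    mean = np.mean(np.stack(arrays, axis=0), axis=0)
    return max_spanning_tree(mean, node_labels=node_labels)


def condition_dissimilarity(trial_trees: dict[int, SpanningTree],
                            ref: SpanningTree, distance: str = "reciprocal",
                            condition: str = "", band_label: str = "",
                            window_index: int = 0,
                            reference_id: str = "ref") -> list[DissimilarityScore]:
    """Score every trial tree against the reference tree."""
    scores = []
    for trial, tree in sorted(trial_trees.items()):
        s = tree_dissimilarity(tree, ref, distance=distance)
        scores.append(DissimilarityScore(
            value=s.value, reference_id=reference_id, trial=trial,
            condition=condition, band_label=band_label,
            window_index=window_index))
    return scores
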