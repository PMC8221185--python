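"""Dissimilarity gating, rank-sum testing and FDR feature selection.

Condition comparison is nonparametric throughout: per measure, per
frequency band and per time window, the two conditions' trial
distributions are compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test, exact for small samples and normal-approximated
with tie and continuity corrections otherwise. P-values are corrected
with the Benjamini-Hochberg step-up procedure.

Testing proceeds in two stages. The *gate* first compares the per-trial
tree-dissimilarity scores of the two conditions in every
(band, window) cell, FDR-corrected across the grid; only cells with a
significant dissimilarity difference enter the second stage. There, each
global tree measure (and, per node, degree and betweenness) is tested in
the gated cells. The correction family for a measure always spans the
full band x window grid (x nodes for nodal measures), regardless of how
many cells the gate admitted, so the gate never makes the correction
more lenient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

GLOBAL_MEASURES = ("D", "Lf", "MaxBC", "MaxK", "Th", "MST_PLI")
NODE_MEASURES = ("K", "BC")


@dataclass
class RankSumResult:
    p_value: float
    direction: int      # sign of median(a) - median(b)
    degenerate: bool = False


def rank_sum_test(sample_a, sample_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with a median-difference direction.

    Exact enumeration when the combined sample is small (n <= 20) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections. Two completely identical samples are degenerate: the
    test carries no information and p = 1 is returned with a flag.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    direction = int(np.sign(np.median(a) - np.median(b)))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankSumResult(p_value=1.0, direction=0, degenerate=True)
    n = a.size + b.size
    tie_free = np.unique(pooled).size == n
    method = "exact" if (n <= 20 and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return RankSumResult(p_value=float(res.pvalue), direction=direction)


def fdr_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``family_size`` sets the correction family m when it exceeds the
    number of observed p-values (e.g. when only gate-passing cells were
    tested but the family is the full band x window grid). Adjusted
    values are order-preserving and monotone, clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = max(int(family_size or p.size), p.size)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


@dataclass
class SelectionTable:
    """Per-(measure, band, window[, node]) test results with flags."""

    table: pd.DataFrame
    alpha: float = 0.05
    scope: str = ""

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def to_manifest(self) -> list[dict]:
        """Ordered feature manifest for the classifier: one entry per
        significant row, sorted by (band, window, measure, node)."""
        rows = self.significant().copy()
        rows["_node"] = rows["node"].fillna("")
        rows = rows.sort_values(["band", "window", "measure", "_node"],
                                kind="stable")
        return [{"measure": r.measure, "band": r.band,
                 "window": int(r.window),
                 "node": (None if pd.isna(r.node) else r.node)}
                for r in rows.itertuples()]


def gate_by_dissimilarity(scores: pd.DataFrame, condition_a: str,
                          condition_b: str, alpha: float = 0.05,
                          family_size: int | None = None
                          ) -> tuple[set[tuple[str, int]], pd.DataFrame]:
    """Find (band, window) cells whose dissimilarity scores separate the
    two conditions after FDR correction across the grid.

    ``scores`` needs columns band, window, condition, value (one row per
    trial). Cells missing either condition are skipped with a warning row
    rather than an error. Returns the passing cell set and the gate table.
    """
    rows = []
    for (band, window), cell in scores.groupby(["band", "window"], sort=True):
        a = cell.loc[cell["condition"] == condition_a, "value"].to_numpy()
        b = cell.loc[cell["condition"] == condition_b, "value"].to_numpy()
        if a.size == 0 or b.size == 0:
            import warnings
            warnings.warn(f"cell ({band}, T{window}) lacks a condition; skipped")
            continue
        res = rank_sum_test(a, b)
        rows.append({"band": band, "window": int(window),
                     "p_raw": res.p_value, "direction": res.direction})
    gate_table = pd.DataFrame(rows)
    if gate_table.empty:
        return set(), gate_table
    gate_table["p_adj"] = fdr_adjust(gate_table["p_raw"].to_numpy(),
                                     family_size=family_size)
    gate_table["significant"] = gate_table["p_adj"] <= alpha
    passing = {(r.band, int(r.window))
               for r in gate_table[gate_table["significant"]].itertuples()}
    return passing, gate_table


def select_features(global_measures: pd.DataFrame, node_measures: pd.DataFrame,
                    gate: set[tuple[str, int]], condition_a: str,
                    condition_b: str, alpha: float = 0.05,
                    grid_size: int | None = None,
                    n_nodes: int | None = None) -> SelectionTable:
    """Test every tree measure in the gate-passing cells and flag survivors.

    ``global_measures``: one row per (trial, band, window) with columns
    condition and the global measures (D, Lf, MaxBC, MaxK, Th, MST_PLI).
    ``node_measures``: long format with columns trial, condition, band,
    window, node, K, BC. Each measure forms its own correction family:
    the full band x window grid for global measures and grid x nodes for
    nodal ones (``grid_size``/``n_nodes`` default to the observed counts).
    """
    grid = grid_size or (global_measures.groupby(["band", "window"]).ngroups)
    if n_nodes is None and not node_measures.empty:
        n_nodes = node_measures["node"].nunique()

    records = []
    for measure in GLOBAL_MEASURES:
        if measure not in global_measures.columns:
            continue
        for (band, window), cell in global_measures.groupby(["band", "window"]):
            if (band, int(window)) not in gate:
                continue
            a = cell.loc[cell["condition"] == condition_a, measure].to_numpy()
            b = cell.loc[cell["condition"] == condition_b, measure].to_numpy()
            res = rank_sum_test(a, b)
            records.append({"measure": measure, "band": band,
                            "window": int(window), "node": np.nan,
                            "p_raw": res.p_value, "direction": res.direction,
                            "family": measure})
    if not node_measures.empty and gate:
        for measure in NODE_MEASURES:
            for (band, window, node), cell in node_measures.groupby(
                    ["band", "window", "node"]):
                if (band, int(window)) not in gate:
                    continue
                a = cell.loc[cell["condition"] == condition_a, measure].to_numpy()
                b = cell.loc[cell["condition"] == condition_b, measure].to_numpy()
                res = rank_sum_test(a, b)
                records.append({"measure": measure, "band": band,
                                "window": int(window), "node": node,
                                "p_raw": res.p_value, "direction": res.direction,
                                "family": f"node_{measure}"})

    table = pd.DataFrame(records, columns=["measure", "band", "window", "node",
                                           "p_raw", "direction", "family"])
    if table.empty:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return SelectionTable(table=table.drop(columns=["family"]), alpha=alpha,
                              scope="per-measure family over band x window grid")

    table["p_adj"] = np.nan
    for fam, idx in table.groupby("family").groups.items():
        fam_size = grid * (n_nodes or 1) if str(fam).startswith("node_") else grid
        table.loc[idx, "p_adj"] = fdr_adjust(
            table.loc[idx, "p_raw"].to_numpy(), family_size=fam_size)
    table["significant"] = table["p_adj"] <= alpha
    table = table.drop(columns=["family"]).reset_index(drop=True)
    return SelectionTable(table=table, alpha=alpha,
                          scope="per-measure family over band x window grid"
                                " (x nodes for nodal measures)")
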