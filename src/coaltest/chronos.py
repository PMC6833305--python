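"""Standardized comparison of divergence-time estimates between analyses.

Given a reference table of posterior node ages (mean and 95% interval) and a
comparison table of means for the same nodes, each comparison age y_i is
standardized as (y_i - x_i) / d_i, where x_i is the reference mean and d_i
the half-width of the reference interval.  |y*| > 1 (strict) means y_i falls
outside the reference 95% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .trees import Tree, leaf_labels

__all__ = ["TimeEstimateTable", "standardize_times", "chronogram_ages", "clade_label"]


@dataclass
class TimeEstimateTable:
    """Per-node standardized divergence times plus summary fractions."""

    table: pd.DataFrame  # columns: label, x, d, y, ystar, flagged
    frac_flagged: float
    frac_below: float
    frac_above: float
    excluded: list[str]  # labels dropped for degenerate intervals

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _as_frame(table, columns) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"table is missing columns: {missing}")
        return df[list(columns)]
    return pd.DataFrame(list(table), columns=list(columns))


def standardize_times(reference, comparison) -> TimeEstimateTable:
    """Standardize comparison node ages against reference posterior intervals.

    Parameters
    ----------
    reference : DataFrame or iterable of (label, mean, lower, upper)
    comparison : DataFrame or iterable of (label, mean)

    Rows with a degenerate reference interval (upper == lower) are excluded
    with a warning; comparison labels absent from the reference are an error.
    """
    ref = _as_frame(reference, ("label", "mean", "lower", "upper"))
    cmp_ = _as_frame(comparison, ("label", "mean"))
    if ref["label"].duplicated().any() or cmp_["label"].duplicated().any():
        raise ValueError("duplicate node labels in input tables")
    missing = sorted(set(cmp_["label"]) - set(ref["label"]))
    if missing:
        raise ValueError(f"comparison labels missing from reference: {missing}")
    bad = ref[ref["upper"] < ref["lower"]]
    if len(bad):
        raise ValueError(f"reference rows with upper < lower: {list(bad['label'])}")

    merged = cmp_.rename(columns={"mean": "y"}).merge(
        ref.rename(columns={"mean": "x"}), on="label", how="left"
    )
    merged["d"] = (merged["upper"] - merged["lower"]) / 2.0
    degenerate = merged["d"] == 0
    excluded = sorted(merged.loc[degenerate, "label"])
    if excluded:
        warnings.warn(
            f"degenerate reference intervals, rows excluded: {excluded}",
            stacklevel=2,
        )
    keep = merged[~degenerate].copy()
    keep["ystar"] = (keep["y"] - keep["x"]) / keep["d"]
    keep["flagged"] = keep["ystar"].abs() > 1
    n = len(keep)
    below = int((keep["ystar"] < -1).sum())
    above = int((keep["ystar"] > 1).sum())
    out = keep[["label", "x", "d", "y", "ystar", "flagged"]].reset_index(drop=True)
    return TimeEstimateTable(
        table=out,
        frac_flagged=(below + above) / n if n else 0.0,
        frac_below=below / n if n else 0.0,
        frac_above=above / n if n else 0.0,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Deriving node labels and ages from chronograms
# ---------------------------------------------------------------------------

def clade_label(labels) -> str:
    """Canonical clade signature: sorted leaf labels joined by '|'."""
    return "|".join(sorted(labels))


def chronogram_ages(tree: Tree) -> pd.DataFrame:
    """Internal-node ages of an ultrametric chronogram.

    Each internal node is keyed by its sorted-leaf-set signature; its age is
    the maximum root-ward path length to a descendant leaf.  Two chronograms
    on the same leaf set yield matching labels for shared clades, which is
    how tables for :func:`standardize_times` are aligned.
    """
    rows = []
    for nd in tree.preorder_internal_node_iter():
        leaves = [l.taxon.label for l in nd.leaf_iter()]
        age = 0.0
        for leaf in nd.leaf_iter():
            dist = 0.0
            cur = leaf
            while cur is not nd:
                dist += cur.edge.length or 0.0
                cur = cur.parent_node
            age = max(age, dist)
        rows.append((clade_label(leaves), age))
    if not rows:
        raise ValueError("tree has no internal nodes")
    assert len(leaf_labels(tree)) >= 2
    return pd.DataFrame(rows, columns=["label", "mean"])
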