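"""Global structure analyses: hierarchical clustering of the mean
treatment × cytokine response matrix, and correlation-based clustering of
cytokines.

The response matrix holds normalized values averaged across donors (and
replicates).  Rows (treatment conditions) and columns (cytokines) are
clustered agglomeratively on Euclidean distances with complete or Ward
linkage; cytokines can additionally be clustered on 1 − Pearson r across
all treatment conditions.  Dendrograms are exportable as Newick trees with
merge heights as node depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .catalog import ROLE_TREATMENT, format_concentration
from .errors import ValidationError

LINKAGES = ("complete", "ward")


def condition_label(stimulus: str, concentration: float, unit: str,
                    co_exposure: str, role: str) -> str:
    if role != ROLE_TREATMENT:
        return stimulus
    label = f"{stimulus} {format_concentration(concentration, unit)}"
    return f"{label} +{co_exposure}" if co_exposure else label


def build_response_matrix(averaged: pd.DataFrame,
                          by_cohort: bool = False) -> pd.DataFrame:
    """Mean normalized response per (condition, cytokine), averaged over
    donors.

    Returns a conditions × cytokines frame.  Combinations never measured
    are imputed as 0 (the post-censoring floor) and listed in
    ``attrs['imputed']``.
    """
    if len(averaged) == 0:
        raise ValidationError("cannot build a response matrix from an "
                              "empty table")
    df = averaged.copy()
    df["condition"] = [
        condition_label(s, c, u, co, r) + (f" [{coh}]" if by_cohort else "")
        for s, c, u, co, r, coh in zip(
            df["stimulus"], df["concentration"], df["unit"],
            df["co_exposure"], df["role"], df["cohort"])
    ]
    matrix = df.pivot_table(index="condition", columns="cytokine",
                            values="value", aggfunc="mean")
    # preserve first-appearance condition order
    matrix = matrix.reindex(index=pd.unique(df["condition"]))
    imputed = [(matrix.index[int(i)], matrix.columns[int(j)])
               for i, j in zip(*np.nonzero(matrix.isna().to_numpy()))]
    matrix = matrix.fillna(0.0)
    matrix.attrs["imputed"] = imputed
    return matrix


@dataclass
class Dendrogram:
    """An agglomerative clustering result on one axis of a matrix.

    ``linkage_matrix`` follows the standard (n-1) × 4 agglomeration layout:
    each row merges two node ids (leaves are 0..n-1, internal nodes n, n+1,
    ...) at a given height.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str
    axis: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Each merge as (members_a, members_b, height), by label."""
        clusters: dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        out = []
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            fa, fb = clusters[int(a)], clusters[int(b)]
            out.append((fa, fb, float(h)))
            clusters[self.n_leaves + step] = fa | fb
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            node = n + step
            heights[node] = float(h)
            children[node] = (int(a), int(b))

        def esc(label: str) -> str:
            return "'" + label.replace("'", "''") + "'"

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{esc(self.labels[node])}:{bl:g}"
            a, b = children[node]
            inner = ",".join(render(c, heights[node]) for c in (a, b))
            return f"({inner}):{bl:g}"

        root = n + len(self.linkage_matrix) - 1
        a, b = children[root]
        inner = ",".join(render(c, heights[root]) for c in (a, b))
        return f"({inner});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n", encoding="utf-8")


def _axis_data(matrix: pd.DataFrame, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis == "rows":
        return matrix.to_numpy(dtype=float), list(matrix.index)
    if axis == "columns":
        return matrix.to_numpy(dtype=float).T, list(matrix.columns)
    raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")


def cluster(matrix: pd.DataFrame, axis: str = "rows",
            method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of matrix rows or columns on Euclidean
    distances with complete or Ward linkage."""
    if method not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    data, labels = _axis_data(matrix, axis)
    if len(labels) < 2:
        raise ValidationError("need at least 2 items to cluster")
    if not np.isfinite(data).all():
        raise ValidationError("non-finite values in the response matrix")
    z = linkage(pdist(data, metric="euclidean"), method=method)
    return Dendrogram(z, labels, method, axis)


def correlation_cluster(matrix: pd.DataFrame, axis: str = "columns",
                        method: str = "complete"
                        ) -> tuple[pd.DataFrame, Dendrogram, list[str]]:
    """Pearson-correlation clustering of matrix items on distance 1 − r.

    Zero-variance items cannot be correlated; they are excluded and
    returned as the third element.
    """
    if method not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    data, labels = _axis_data(matrix, axis)
    variances = data.var(axis=1)
    keep = variances > 0
    excluded = [lab for lab, k in zip(labels, keep) if not k]
    data, labels = data[keep], [lab for lab, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise ValidationError(
            "fewer than 2 items with positive variance to correlate")

    r = np.corrcoef(data)
    corr = pd.DataFrame(r, index=labels, columns=labels)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    return corr, Dendrogram(z, labels, method, axis), excluded
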