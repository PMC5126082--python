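"""FPKM expression matrices, expressed-gene calls, and hierarchical
clustering with the uncentered-correlation metric and average linkage.

The dissimilarity is d(x, y) = 1 − Σxy / (‖x‖·‖y‖) on the raw (not
mean-centered) vectors — the "correlation (uncentered)" option of the
classic Cluster 3.0 workflow, identical to cosine distance — so
clustering is invariant to positive rescaling of any gene's row. Linkage
is unweighted average (UPGMA-style) via :mod:`scipy.cluster.hierarchy`;
all-zero rows, for which the metric is undefined, are dropped with a log
message before clustering, matching heatmap practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .records import MipkitError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene × sample FPKM table; values ≥ 0, NaN allowed for missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise MipkitError("duplicate gene or sample ids")
        if (df.to_numpy(dtype=float) < 0).any():
            raise MipkitError("negative FPKM values")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def log2(self) -> "ExpressionMatrix":
        """log2(x+1) transform, offered for parity with common practice."""
        return ExpressionMatrix(np.log2(self.data + 1.0))


def uncentered_correlation_distance(x, y) -> float:
    """1 − uncentered correlation over pairwise-complete entries ∈ [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise MipkitError("vectors must share a length ≥ 2")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise MipkitError("fewer than 2 pairwise-complete entries")
    x, y = x[mask], y[mask]
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise MipkitError("uncentered correlation undefined for an all-zero vector")
    return float(1.0 - (x * y).sum() / (nx * ny))


@dataclass
class LinkageTree:
    """Agglomeration result: retained gene order + scipy linkage matrix."""

    ids: list[str]
    linkage: np.ndarray
    dropped: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]


def _pairwise_distances(df: pd.DataFrame) -> np.ndarray:
    genes = list(df.index)
    n = len(genes)
    d = np.zeros((n, n))
    values = df.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = uncentered_correlation_distance(values[i], values[j])
    return d


def average_linkage(matrix: ExpressionMatrix) -> LinkageTree:
    """UPGMA-style agglomeration on the uncentered-correlation metric."""
    df = matrix.data
    keep = []
    dropped = []
    for g in df.index:
        row = df.loc[g].to_numpy(dtype=float)
        if np.nansum(np.abs(row)) == 0:
            dropped.append(g)
        else:
            keep.append(g)
    if dropped:
        logger.info("average_linkage: dropped all-zero gene(s): %s", ", ".join(dropped))
    if len(keep) < 2:
        raise MipkitError("need ≥2 genes with non-zero expression")
    sub = df.loc[keep]
    dist = _pairwise_distances(sub)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return LinkageTree(ids=keep, linkage=link, dropped=dropped)


def cut_clusters(tree: LinkageTree, k: int) -> dict[str, int]:
    """Cut the k−1 highest merges; clusters labelled 1..k by first
    appearance in leaf order (deterministic)."""
    n = len(tree.ids)
    if not 1 <= k <= n:
        raise MipkitError(f"k={k} out of range 1..{n}")
    flat = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for leaf in tree.leaf_order():
        raw = int(flat[tree.ids.index(leaf)])
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        assignment[leaf] = relabel[raw]
    return assignment


def call_expressed(matrix: ExpressionMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Per-gene per-sample presence (FPKM > threshold) with a
    ``detected_anywhere`` summary column."""
    presence = matrix.data.fillna(0.0) > threshold
    presence["detected_anywhere"] = presence.any(axis=1)
    return presence


def text_heatmap(matrix: ExpressionMatrix, tree: LinkageTree,
                 ramp: str = " .:-=+*#%@") -> str:
    """ASCII heatmap with rows in dendrogram leaf order."""
    order = tree.leaf_order()
    df = matrix.data.loc[order].fillna(0.0)
    vmax = float(df.to_numpy().max()) or 1.0
    lines = ["\t".join(["gene"] + list(df.columns))]
    for g in order:
        cells = []
        for v in df.loc[g]:
            level = min(int(v / vmax * (len(ramp) - 1)), len(ramp) - 1)
            cells.append(ramp[level])
        lines.append(g + "\t" + "".join(cells))
    return "\n".join(lines) + "\n"


def linkage_table(tree: LinkageTree) -> str:
    """Merge table (node pair + height), a CDT/GTR-like TSV export."""
    lines = ["node\tchild_a\tchild_b\theight"]
    n = len(tree.ids)

    def label(idx: int) -> str:
        return tree.ids[idx] if idx < n else f"NODE{idx - n + 1}"

    for step, (a, b, h, _cnt) in enumerate(tree.linkage, start=1):
        lines.append(f"NODE{step}\t{label(int(a))}\t{label(int(b))}\t{h:.6g}")
    return "\n".join(lines) + "\n"
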