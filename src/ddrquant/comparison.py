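"""Cross-model comparison: profile assembly, Euclidean distances and
hierarchical clustering of culture models / reporters / exposure durations.

GFP responses are min-max normalised within each culture model, laid out as a
profile matrix (rows = conditions, columns = compound x concentration
features), compared by Euclidean distance — averaged over the three reporters
when clustering culture models — and clustered agglomeratively.  Both
complete linkage and Ward linkage are supported because the source protocols
name one in the text and the other in the figure legends; neither is
privileged, complete is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .doseresponse import min_max_normalize
from .errors import ConfigurationError, InsufficientDataError, InvalidDistanceError

__all__ = [
    "ClusterTree",
    "assemble_profile_matrix",
    "encode_pod_features",
    "euclidean_distances",
    "mean_over_reporters",
    "hierarchical_cluster",
]

#: one dilution step of an 8-point series spanning e.g. 0.10-21.54 uM
DILUTION_STEP = 10.0 ** (1.0 / 3.0)


def assemble_profile_matrix(
    tidy: pd.DataFrame,
    value_col: str = "value",
    row_cols: Sequence[str] = ("model", "duration"),
    feature_cols: Sequence[str] = ("compound", "concentration_uM"),
    normalize_within: Optional[str] = "model",
) -> pd.DataFrame:
    """Pivot a tidy response table into a profile matrix.

    Values are min-max normalised within each ``normalize_within`` group
    (per culture model, matching the published procedure) before pivoting;
    pass ``normalize_within=None`` for pre-normalised input.  Replicates are
    averaged.  Missing combinations raise, because downstream distances
    require complete rows.
    """
    df = tidy.copy()
    if normalize_within is not None:
        out = np.empty(len(df), dtype=float)
        for _, idx in df.groupby(normalize_within, sort=False).groups.items():
            vals, _ = min_max_normalize(df.loc[idx, value_col].to_numpy(dtype=float))
            out[df.index.get_indexer(idx)] = vals
        df[value_col] = out
    mat = df.pivot_table(
        index=list(row_cols), columns=list(feature_cols), values=value_col, aggfunc="mean"
    )
    if mat.isna().any().any():
        missing = int(mat.isna().sum().sum())
        raise ConfigurationError(f"profile matrix has {missing} missing cells after assembly")
    return mat


def encode_pod_features(
    pod_table: pd.DataFrame,
    highest_tested: Dict[str, float],
    pod_col: str = "pod",
    compound_col: str = "compound",
) -> pd.DataFrame:
    """log10-encode PoD values for clustering, replacing undefined PoDs by a
    sentinel one dilution step (10^(1/3)) above the compound's highest tested
    concentration so insensitive conditions cluster together.

    Adds a boolean ``pod_undefined`` column marking sentinel rows.
    """
    out = pod_table.copy()
    undefined = out[pod_col].isna()
    sentinel = out[compound_col].map(
        {k: v * DILUTION_STEP for k, v in highest_tested.items()}
    )
    if sentinel.isna().any():
        unknown = sorted(out.loc[sentinel.isna(), compound_col].unique())
        raise ConfigurationError(f"no highest_tested concentration for compounds {unknown}")
    out[pod_col] = np.log10(out[pod_col].where(~undefined, sentinel))
    out["pod_undefined"] = undefined.to_numpy()
    return out


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between the rows of a profile matrix."""
    if len(matrix) < 2:
        raise InsufficientDataError("need at least 2 profile rows for distances")
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def mean_over_reporters(distances_by_reporter: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-reporter distance matrices over reporters.

    All matrices must share one row/column index (the model x duration
    conditions); symmetry and the zero diagonal are preserved by averaging.
    """
    if not distances_by_reporter:
        raise InsufficientDataError("no distance matrices supplied")
    mats = list(distances_by_reporter.values())
    ref = mats[0].index
    for m in mats:
        if not (m.index.equals(ref) and m.columns.equals(ref)):
            raise ConfigurationError("distance matrices have mismatched row sets")
    return sum(mats) / len(mats)


def _check_distance_matrix(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidDistanceError(f"distance matrix must be square, got {d.shape}")
    if not np.allclose(d, d.T, rtol=0, atol=1e-10):
        raise InvalidDistanceError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise InvalidDistanceError("distance matrix diagonal is not zero")
    if np.any(d < 0):
        raise InvalidDistanceError("distances must be nonnegative")


@dataclass
class ClusterTree:
    """Agglomerative clustering result.

    ``merges`` is the scipy linkage matrix: row i merges clusters
    ``merges[i, 0]`` and ``merges[i, 1]`` at height ``merges[i, 2]`` into new
    cluster ``n_leaves + i``.
    """

    merges: np.ndarray
    leaf_labels: List[str]
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster ids (1..n_clusters) per leaf, in leaf order."""
        return hierarchy.fcluster(self.merges, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialise as a newick string with merge heights as branch lengths."""
        root = hierarchy.to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges[:, :3], columns=["cluster_a", "cluster_b", "height"]
        ).astype({"cluster_a": int, "cluster_b": int})


def hierarchical_cluster(distmat: pd.DataFrame, linkage: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a precomputed distance matrix.

    ``linkage`` is ``complete`` (maximum pairwise distance, the protocol
    text's choice) or ``ward`` (minimum variance increase on the distances,
    as R's hclust/pheatmap apply it to a precomputed matrix — the figure
    legends' choice).  Given equal merge candidates scipy's ordering is
    deterministic, so repeated runs give identical trees.
    """
    if linkage not in ("complete", "ward"):
        raise ValueError(f"linkage must be 'complete' or 'ward', got {linkage!r}")
    d = distmat.to_numpy(dtype=float)
    _check_distance_matrix(d)
    condensed = squareform(d, checks=False)
    merges = hierarchy.linkage(condensed, method=linkage)
    labels = [" | ".join(map(str, ix)) if isinstance(ix, tuple) else str(ix) for ix in distmat.index]
    return ClusterTree(merges, labels, linkage)
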