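"""Static figures: clustered heatmaps and concentration-response overviews."""

from __future__ import annotations

import pandas as pd

from .comparison import ClusterTree, euclidean_distances, hierarchical_cluster


def clustered_heatmap(matrix: pd.DataFrame, linkage: str = "complete", ax=None):
    """Heatmap of a profile matrix with a row dendrogram.

    Rows are reordered by the leaf order of the hierarchical clustering of
    their Euclidean distances.  Returns (figure, ClusterTree).
    """
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    tree = hierarchical_cluster(euclidean_distances(matrix), linkage=linkage)
    order = hierarchy.leaves_list(tree.merges)
    data = matrix.to_numpy(dtype=float)[order]

    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(10, 0.4 * len(matrix) + 2), width_ratios=[1, 4]
    )
    hierarchy.dendrogram(tree.merges, orientation="left", no_labels=True, ax=ax_d)
    ax_d.set_axis_off()
    im = ax_h.imshow(data, aspect="auto", cmap="viridis")
    ax_h.set_yticks(range(len(order)))
    ax_h.set_yticklabels([tree.leaf_labels[i] for i in order], fontsize=8)
    ax_h.set_xticks([])
    ax_h.set_xlabel(f"{matrix.columns.nlevels}-level features ({matrix.shape[1]} columns)")
    fig.colorbar(im, ax=ax_h, shrink=0.7, label="normalised response")
    fig.tight_layout()
    return fig, tree
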