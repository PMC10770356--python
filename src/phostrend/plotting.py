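"""Basic cluster-profile plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cluster import SoftClustering
from .matrix import GROUPS


def plot_cluster_profiles(
    sc: SoftClustering,
    groups,
    path: str | Path,
    membership_min: float = 0.0,
) -> None:
    """One panel per cluster: member profiles coloured by membership.

    Profiles are the standardised log2 values the clustering saw;
    the centroid is overlaid in black.
    """
    c = sc.n_clusters
    ncol = min(c, 3)
    nrow = -(-c // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    hard = sc.hard
    order = [s for g in GROUPS for s in sc.centroids.columns if groups[s] == g]
    x = range(len(order))
    cmap = plt.get_cmap("coolwarm")
    for ci in range(c):
        ax = axes[ci // ncol][ci % ncol]
        members = hard.index[hard == ci]
        if sc.data is not None:
            for f in members:
                u = float(sc.membership.at[f, ci])
                if u < membership_min:
                    continue
                ax.plot(x, sc.data.loc[f, order], color=cmap(u), alpha=0.5, lw=0.7)
        ax.plot(x, sc.centroids.loc[ci, order], color="black", lw=2)
        ax.set_title(f"cluster {ci} (n={len(members)})")
        ax.set_xticks(list(x), order, rotation=90, fontsize=6)
    for j in range(c, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
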