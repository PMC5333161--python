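"""Correlation-profile clustering and the integrated heatmap.

Entities are clustered not on their raw time courses but on their vectors
of correlations to every other entity of the same axis ("correlation
profiles"): two metabolites belong together when they relate to the rest
of the metabolome in the same way.  Agglomerative clustering (average
linkage / UPGMA on Euclidean distances by default) builds a dendrogram per
axis; the two largest flat clusters at a configurable cut are promoted to
named clusters A and B and everything else is left unassigned — mirroring
the common practice of reading only the two dominant blocks off a
clustered heatmap.

Determinism: entities are sorted lexicographically before any distance is
computed, so the merge tree does not depend on input order, and cluster
naming ties are broken by the lexicographically smallest member.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .correlation import CorrelationMatrix
from .errors import InputError

logger = logging.getLogger(__name__)

METABOLITE_AXIS = "metabolite_axis"
GENE_AXIS = "gene_axis"


def correlation_profile_features(cm: CorrelationMatrix) -> tuple[list[str], np.ndarray]:
    """Feature vectors for clustering: entity i's features are row i of the
    square within-set correlation matrix.  NaN entries (constant profiles)
    are imputed as 0 — no correlation — with a logged warning."""
    if not cm.is_square:
        raise InputError("correlation-profile features need a square "
                         "within-set matrix (row_ids == col_ids)")
    feats = np.array(cm.values, dtype=float, copy=True)
    n_na = int(np.isnan(feats).sum())
    if n_na:
        logger.warning("imputing %d NA correlation entries as 0 for clustering", n_na)
        feats = np.nan_to_num(feats, nan=0.0)
    return list(cm.row_ids), feats


@dataclass
class LinkageTree:
    """Agglomerative merge tree over lexicographically sorted entity ids."""

    ids: list[str]
    Z: np.ndarray  # scipy linkage matrix

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.Z)]

    def to_json(self, path: str | Path) -> None:
        data = {
            "ids": self.ids,
            "merges": [
                {"left": int(a), "right": int(b), "height": float(h),
                 "size": int(n)}
                for a, b, h, n in self.Z
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1))


def hierarchical_cluster(ids: list[str], features: np.ndarray,
                         linkage_method: str = "average",
                         metric: str = "euclidean") -> LinkageTree:
    """Cluster feature rows agglomeratively (default UPGMA / Euclidean).

    Rows are re-sorted by entity id first, making the tree independent of
    input order.
    """
    if len(ids) < 2:
        raise InputError("clustering needs >= 2 entities")
    if len(ids) != features.shape[0]:
        raise InputError("ids / feature rows mismatch")
    order = np.argsort(np.asarray(ids, dtype=object))
    ids_sorted = [ids[i] for i in order]
    feats = np.asarray(features, dtype=float)[order]
    Z = hierarchy.linkage(pdist(feats, metric=metric), method=linkage_method)
    return LinkageTree(ids=ids_sorted, Z=Z)


@dataclass
class ClusterAssignment:
    """Entity -> {A, B, unassigned} for one heatmap axis.

    A and B are the two largest flat clusters at the cut; A is the one
    containing the lexicographically smallest member of the pair's union.
    """

    axis: str
    labels: dict[str, str]
    linkage: LinkageTree
    order: list[str] = field(default_factory=list)

    def members(self, cluster: str) -> list[str]:
        return sorted(e for e, c in self.labels.items() if c == cluster)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"entity_id": e, "axis": self.axis, "cluster": c}
             for e, c in sorted(self.labels.items())],
            columns=["entity_id", "axis", "cluster"],
        )


def two_largest_clusters(tree: LinkageTree, k: int = 2,
                         axis: str = METABOLITE_AXIS) -> ClusterAssignment:
    """Cut the tree into ``k`` flat clusters; keep the two largest as A/B.

    Size ties are broken in favour of the cluster with the
    lexicographically smallest member; with k=2 nothing is unassigned.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    if k > tree.n_leaves:
        raise InputError(f"k={k} exceeds {tree.n_leaves} leaves")
    flat = hierarchy.fcluster(tree.Z, t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for eid, g in zip(tree.ids, flat):
        groups.setdefault(int(g), []).append(eid)
    ranked = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    top2 = sorted(ranked[:2], key=min)  # A holds the smallest member
    labels = {eid: "unassigned" for eid in tree.ids}
    for name, members in zip(("A", "B"), top2):
        for eid in members:
            labels[eid] = name
    return ClusterAssignment(axis=axis, labels=labels, linkage=tree,
                             order=tree.leaf_order())


def cluster_axis(cm: CorrelationMatrix, k: int = 2, axis: str = METABOLITE_AXIS,
                 linkage_method: str = "average",
                 metric: str = "euclidean") -> ClusterAssignment:
    """Convenience: features -> tree -> two-largest assignment for one axis."""
    ids, feats = correlation_profile_features(cm)
    tree = hierarchical_cluster(ids, feats, linkage_method, metric)
    return two_largest_clusters(tree, k=k, axis=axis)


# ---------------------------------------------------------------------------
# heatmap rendering
# ---------------------------------------------------------------------------

_NEG = (0x22 / 255, 0x57 / 255, 0xC4 / 255)   # blue anchor at r = -1
_MID = (1.0, 1.0, 1.0)                        # white at r = 0
_POS = (0xD0 / 255, 0x02 / 255, 0x1B / 255)   # red anchor at r = +1


def color_for_r(r: float) -> str:
    """Hex colour of a correlation value on the symmetric diverging scale
    blue (-1) -> white (0) -> red (+1); linear in each half."""
    if np.isnan(r):
        return "#FFFFFF"
    r = float(np.clip(r, -1.0, 1.0))
    lo, hi = (_MID, _POS) if r >= 0 else (_MID, _NEG)
    w = abs(r)
    rgb = [(1 - w) * a + w * b for a, b in zip(lo, hi)]
    return "#%02X%02X%02X" % tuple(int(round(255 * c)) for c in rgb)


def _diverging_cmap():
    from matplotlib.colors import LinearSegmentedColormap
    return LinearSegmentedColormap.from_list(
        "corrpath_diverging", [_NEG, _MID, _POS], N=511)


def render_heatmap(cross: CorrelationMatrix,
                   row_assign: ClusterAssignment,
                   col_assign: ClusterAssignment,
                   out_prefix: str | Path,
                   culture_ids: set[str] | None = None,
                   formats: tuple[str, ...] = ("png", "svg")) -> pd.DataFrame:
    """Render the integrated cross-correlation heatmap with marginal
    dendrograms and write the dendrogram-ordered matrix as CSV.

    Rows/columns follow each axis's dendrogram leaf order; culture-metric
    labels are flagged (bold, marked with an asterisk).  Returns the
    ordered matrix as a DataFrame.  Files written: ``<prefix>.csv`` plus
    one image per requested format.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    culture_ids = culture_ids or set()
    row_order = [e for e in row_assign.order if e in cross.row_ids]
    col_order = [e for e in col_assign.order if e in cross.col_ids]
    if set(row_order) != set(cross.row_ids) or set(col_order) != set(cross.col_ids):
        raise InputError("cluster assignments do not cover the matrix axes")

    df = cross.to_frame().loc[row_order, col_order]
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_prefix.with_suffix(".csv"), na_rep="NA")

    fig = plt.figure(figsize=(max(6, 0.28 * len(col_order) + 2),
                              max(5, 0.28 * len(row_order) + 2)))
    gs = fig.add_gridspec(2, 3, width_ratios=[1.2, 8, 0.35],
                          height_ratios=[1.2, 8], wspace=0.05, hspace=0.05)

    ax_top = fig.add_subplot(gs[0, 1])
    hierarchy.dendrogram(col_assign.linkage.Z, ax=ax_top, no_labels=True,
                         color_threshold=0, above_threshold_color="0.3")
    ax_top.set_axis_off()

    ax_left = fig.add_subplot(gs[1, 0])
    hierarchy.dendrogram(row_assign.linkage.Z, ax=ax_left, orientation="left",
                         no_labels=True, color_threshold=0,
                         above_threshold_color="0.3")
    ax_left.invert_yaxis()
    ax_left.set_axis_off()

    ax = fig.add_subplot(gs[1, 1])
    masked = np.ma.masked_invalid(df.to_numpy())
    im = ax.imshow(masked, cmap=_diverging_cmap(), vmin=-1, vmax=1,
                   aspect="auto", interpolation="nearest")
    ax.set_xticks(range(len(col_order)))
    ax.set_yticks(range(len(row_order)))
    ax.set_xticklabels(
        [f"{c}*" if c in culture_ids else c for c in col_order],
        rotation=90, fontsize=6)
    ax.set_yticklabels(
        [f"{r}*" if r in culture_ids else r for r in row_order], fontsize=6)
    for tick, name in zip(ax.get_xticklabels(), col_order):
        if name in culture_ids:
            tick.set_fontweight("bold")
    for tick, name in zip(ax.get_yticklabels(), row_order):
        if name in culture_ids:
            tick.set_fontweight("bold")
    ax.tick_params(length=0)

    cax = fig.add_subplot(gs[1, 2])
    fig.colorbar(im, cax=cax, label="Pearson r")

    for fmt in formats:
        fig.savefig(out_prefix.with_suffix(f".{fmt}"),
                    dpi=150, metadata={"Date": None} if fmt == "svg" else None)
    plt.close(fig)
    return df
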