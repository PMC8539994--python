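"""Differential presence/absence screens between tolerant and non-tolerant strains.

Two mirrored screens over the ortholog copy-number matrix:

* **variable genes** — tolerant-group core genes deleted (copy 0) in at least
  ``k_deletion`` non-tolerant strains: candidate tolerance-conferring genes.
* **redundant genes** — non-tolerant-group core genes deleted in at least
  ``k_deletion`` tolerant strains: genes dispensable under tolerance.

"Deleted" means copy number 0 for the group in that strain, not merely a
reduced copy count; mean per-group copy numbers are reported alongside so the
reduced-copy pattern can still be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class ScreenConfig:
    """Cohort split and screen thresholds.

    ``high_threshold``/``low_threshold`` are the survival-rate percentages
    that define the tolerant (> 9.5%) and non-tolerant (<= 0.7%) groups;
    ``k_deletion`` is the minimum number of strains a gene must be missing
    from before it is called.
    """

    tolerant_strains: tuple[str, ...]
    nontolerant_strains: tuple[str, ...]
    k_deletion: int = 2
    high_threshold: float = 9.5
    low_threshold: float = 0.7

    def __post_init__(self) -> None:
        tol, non = set(self.tolerant_strains), set(self.nontolerant_strains)
        if not tol or not non:
            raise ValueError("both strain sets must be non-empty")
        if tol & non:
            raise ValueError("tolerant and non-tolerant strain sets must be disjoint")
        if not (0 < self.k_deletion <= len(non)):
            raise ValueError("require 0 < k_deletion <= |nontolerant_strains|")


def _deletion_screen(
    matrix: pd.DataFrame,
    core_strains: Sequence[str],
    deletion_strains: Sequence[str],
    k_deletion: int,
) -> list[str]:
    """Groups core in ``core_strains`` and absent in >= k of ``deletion_strains``,
    ordered by number of deletion strains missing the gene (desc), then group id."""
    core = matrix[list(core_strains)]
    deletions = (matrix[list(deletion_strains)] == 0).sum(axis=1)
    selected = matrix.index[((core >= 1).all(axis=1)) & (deletions >= k_deletion)]
    order = sorted(selected, key=lambda g: (-int(deletions.loc[g]), g))
    return order


def variable_genes(matrix: pd.DataFrame, cfg: ScreenConfig) -> list[str]:
    """Tolerant-core groups with copy 0 in >= k_deletion non-tolerant strains."""
    return _deletion_screen(matrix, cfg.tolerant_strains, cfg.nontolerant_strains, cfg.k_deletion)


def redundant_genes(matrix: pd.DataFrame, cfg: ScreenConfig) -> list[str]:
    """Non-tolerant-core groups with copy 0 in >= k_deletion tolerant strains."""
    return _deletion_screen(matrix, cfg.nontolerant_strains, cfg.tolerant_strains, cfg.k_deletion)


def group_mean_copies(matrix: pd.DataFrame, groups: Sequence[str], cfg: ScreenConfig) -> pd.DataFrame:
    """Mean copy number per selected group in each strain class.

    Supports the "copy numbers reduced in tolerant strains" inspection for the
    redundancy screen (and its mirror for the variable screen).
    """
    sub = matrix.loc[list(groups)]
    return pd.DataFrame(
        {
            "mean_copy_tolerant": sub[list(cfg.tolerant_strains)].mean(axis=1),
            "mean_copy_nontolerant": sub[list(cfg.nontolerant_strains)].mean(axis=1),
        }
    )


def screen_report(
    variable: Sequence[str],
    redundant: Sequence[str],
    matrix: pd.DataFrame,
    cfg: ScreenConfig,
) -> pd.DataFrame:
    """One row per selected group: screen label, mean copies and the per-strain copy vector."""
    strains = list(cfg.tolerant_strains) + list(cfg.nontolerant_strains)
    rows = []
    for label, groups in (("Variable Genes", variable), ("Redundant Genes", redundant)):
        if not groups:
            continue
        means = group_mean_copies(matrix, groups, cfg)
        for gid in groups:
            row = {
                "screen": label,
                "group": gid,
                "mean_copy_tolerant": means.loc[gid, "mean_copy_tolerant"],
                "mean_copy_nontolerant": means.loc[gid, "mean_copy_nontolerant"],
            }
            row.update({s: int(matrix.loc[gid, s]) for s in strains})
            rows.append(row)
    columns = ["screen", "group", "mean_copy_tolerant", "mean_copy_nontolerant"] + strains
    return pd.DataFrame(rows, columns=columns)


@dataclass
class HierarchicalResult:
    """Agglomerative clustering of a real-valued matrix (heatmap ordering)."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    flat_clusters: dict[str, int] = field(default_factory=dict)
    newick: str = ""


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
    cut_height: float | None = None,
) -> HierarchicalResult:
    """Agglomerative clustering of matrix rows (Euclidean distance by default).

    Returns the scipy linkage, the dendrogram leaf order, the dendrogram as a
    Newick string, and (if ``cut_height`` is given) flat clusters from cutting
    the dendrogram at that height.  A constant matrix is valid: all distances
    are 0 and every merge happens at height 0.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    labels = [str(i) for i in matrix.index]
    dists = pdist(matrix.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(dists, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    result = HierarchicalResult(
        linkage=Z,
        labels=labels,
        leaf_order=[labels[i] for i in leaves],
        newick=_linkage_to_newick(Z, labels),
    )
    if cut_height is not None:
        flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
        result.flat_clusters = {lab: int(c) for lab, c in zip(labels, flat)}
    return result
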