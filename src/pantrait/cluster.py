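"""Ortholog grouping from a hit table: reciprocal-hit graph + Markov clustering.

The similarity graph draws an edge between two genes only when both ordered
hits exist and pass the e-value / identity cutoffs (reciprocity); the edge
weight is the mean of the two directions' -log10(e-value).  Markov clustering
(MCL) then partitions the graph; genes with no edges become singleton groups.
"""

from __future__ import annotations

import warnings
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: weight assigned to e-value 0 (-log10 of the smallest positive double, rounded)
WEIGHT_CEILING = 300.0


def _neglog10(ev: float, ceiling: float) -> float:
    if ev <= 0:
        return ceiling
    return min(-np.log10(ev), ceiling)


def build_graph(
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_identity: float = 0.0,
    weight_ceiling: float = WEIGHT_CEILING,
) -> nx.Graph:
    """Reciprocal-hit similarity graph from an all-vs-all hit table.

    An edge joins two distinct genes iff hits exist in both directions, each
    with ``evalue <= max_evalue`` and identity fraction ``>= min_identity``.
    Edge weight = mean over the two directions of -log10(evalue), capped at
    ``weight_ceiling``.  Every gene seen in the table becomes a node (self-hits
    guarantee coverage of the whole cohort).
    """
    g = nx.Graph()
    g.add_nodes_from(hits["qseqid"].unique())
    g.add_nodes_from(hits["sseqid"].unique())

    passing = hits[
        (hits["qseqid"] != hits["sseqid"])
        & (hits["evalue"] <= max_evalue)
        & (hits["pident"] / 100.0 >= min_identity)
    ]
    # best (smallest) e-value per ordered pair, in case of duplicate rows
    best = passing.groupby(["qseqid", "sseqid"])["evalue"].min()
    seen = set(best.index)
    for (q, s), ev_qs in best.items():
        if q >= s:
            continue
        if (s, q) not in seen:
            continue  # reciprocity: one-directional hits never make an edge
        ev_sq = best.loc[(s, q)]
        w = 0.5 * (_neglog10(ev_qs, weight_ceiling) + _neglog10(ev_sq, weight_ceiling))
        g.add_edge(q, s, weight=w)
    return g


def _mcl_component(
    sub: nx.Graph,
    nodes: list,
    inflation: float,
    tol: float,
    max_iter: int,
) -> tuple[list[set], bool]:
    """Run MCL on one connected component; returns (clusters, converged)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in sub.edges(data=True):
        M[idx[u], idx[v]] = data["weight"]
        M[idx[v], idx[u]] = data["weight"]
    np.fill_diagonal(M, 1.0)  # self-loops stabilise the flow
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = np.power(M, inflation)  # inflation
        M[M < tol] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break

    # read clusters off the converged flow: connected sets of the nonzero structure
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M >= tol)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = [{nodes[i] for i in comp} for comp in nx.connected_components(support)]
    return clusters, converged


def mcl(
    g: nx.Graph,
    inflation: float = 1.5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[set]:
    """Markov clustering of a weighted similarity graph.

    Column-normalise the weighted adjacency (with unit self-loops), then
    iterate expansion (matrix square) and inflation (elementwise power,
    renormalise) with pruning of entries below ``tol`` until the matrix is
    stationary.  Clusters are the connected attractor sets of the converged
    flow.  Disconnected components are clustered independently — MCL flow
    never crosses a component boundary, and this keeps the dense linear
    algebra small.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    clusters: list[set] = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(set(nodes))
            continue
        comp_clusters, converged = _mcl_component(g.subgraph(nodes), nodes, inflation, tol, max_iter)
        if not converged:
            warnings.warn(
                f"MCL did not converge within {max_iter} iterations on a "
                f"{len(nodes)}-node component; returning current partition",
                stacklevel=2,
            )
        clusters.extend(comp_clusters)
    return sorted(clusters, key=lambda c: sorted(c)[0])


def partition_to_frame(clusters: Sequence[set], prefix: str = "OG") -> pd.DataFrame:
    """(gene, group) table with deterministic group ids.

    Groups are numbered in order of their lexicographically smallest member.
    """
    ordered = sorted(clusters, key=lambda c: sorted(c)[0])
    width = max(4, len(str(len(ordered))))
    rows = []
    for i, cluster in enumerate(ordered, start=1):
        gid = f"{prefix}{i:0{width}d}"
        for gene in sorted(cluster):
            rows.append((gene, gid))
    return pd.DataFrame(rows, columns=["gene", "group"])


def copy_number_matrix(
    clusters: Sequence[set] | pd.DataFrame,
    strains: Sequence[str],
    gene_to_strain: Mapping[str, str],
) -> pd.DataFrame:
    """Ortholog-group x strain matrix of gene copy counts.

    ``cell(group, strain)`` is the number of that strain's genes assigned to
    the group; column sums therefore equal clustered proteome sizes.
    """
    if not isinstance(clusters, pd.DataFrame):
        clusters = partition_to_frame(clusters)
    unmapped = set(clusters["gene"]) - set(gene_to_strain)
    if unmapped:
        raise ValueError(f"genes with no strain mapping: {sorted(unmapped)[:5]} ...")
    df = clusters.copy()
    df["strain"] = df["gene"].map(gene_to_strain)
    mat = (
        df.pivot_table(index="group", columns="strain", values="gene", aggfunc="count", fill_value=0)
        .reindex(columns=list(strains), fill_value=0)
        .astype(int)
    )
    mat = mat.sort_index()
    mat.columns.name = "strain"
    mat.index.name = "group"
    return mat


def core_groups(matrix: pd.DataFrame, strain_set: Iterable[Hashable]) -> set:
    """Groups present (copy >= 1) in every strain of ``strain_set``."""
    strain_set = list(strain_set)
    if not strain_set:
        raise ValueError("strain_set must be non-empty")
    missing = set(strain_set) - set(matrix.columns)
    if missing:
        raise ValueError(f"strains not in matrix: {sorted(missing)}")
    sub = matrix[strain_set]
    return set(sub.index[(sub >= 1).all(axis=1)])
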