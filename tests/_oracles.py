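"""Independent brute-force oracles used only by the test suite.

Each oracle is written as plainly as possible (explicit loops, no shared code
with the package) so that agreement with the implementation is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

NEG = float("-inf")


def brute_force_smith_waterman(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0,
                               matrix_name: str = "BLOSUM62") -> float:
    """Quadratic Gotoh local-alignment DP, no optimisations.

    A gap of length L costs ``gap_open + L * gap_extend`` (BLAST convention).
    Returns the optimal local score (floor 0).
    """
    mat = substitution_matrices.load(matrix_name)
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (moving along b)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + mat[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def reference_mcl(edges: dict[tuple[int, int], float], n: int, inflation: float = 1.5,
                  tol: float = 1e-6, max_iter: int = 100) -> list[set[int]]:
    """Plain dense-loop Markov clustering over node indices 0..n-1.

    Same conventions as the package (unit self-loops, column normalisation,
    expansion = matrix square, elementwise inflation, pruning below tol,
    clusters = connected sets of the converged nonzero structure) but written
    entirely with Python loops over a list-of-lists matrix.
    """
    M = [[0.0] * n for _ in range(n)]
    for (i, j), w in edges.items():
        M[i][j] = w
        M[j][i] = w
    for i in range(n):
        M[i][i] = 1.0
    def normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s > 0:
                for i in range(n):
                    mat[i][j] /= s
    normalize(M)
    for _ in range(max_iter):
        sq = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)] for i in range(n)]
        for i in range(n):
            for j in range(n):
                sq[i][j] = sq[i][j] ** inflation
                if sq[i][j] < tol:
                    sq[i][j] = 0.0
        normalize(sq)
        delta = max(abs(sq[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = sq
        if delta < tol:
            break
    # connected components of the nonzero structure
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in range(n):
                if not seen[v] and (M[u][v] >= tol or M[v][u] >= tol):
                    seen[v] = True
                    stack.append(v)
        clusters.append(comp)
    return clusters


def enumerate_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1.

    A topology is an edge list over node ids; leaves are 0..n-1, internal
    nodes are numbered from n upward.  Built by sequential insertion of each
    leaf into every existing edge (1 x 3 x 5 x ... choices).
    """
    base = [(0, n), (1, n), (2, n)]  # 3-leaf star, internal node n

    def insert(edges, next_leaf, next_internal):
        if next_leaf == n:
            yield edges
            return
        for k in range(len(edges)):
            u, v = edges[k]
            new = edges[:k] + edges[k + 1 :]
            new = new + [(u, next_internal), (v, next_internal), (next_leaf, next_internal)]
            yield from insert(new, next_leaf + 1, next_internal + 1)

    if n == 3:
        yield base
        return
    yield from insert(base, 3, n + 1)


def _leaf_paths(edges, n):
    """For each leaf pair (i<j), the set of edge indices on the path."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for i in range(n):
        # DFS from leaf i recording edge sets
        stack = [(i, -1, [])]
        while stack:
            node, parent, used = stack.pop()
            if node != i and node < n:
                if i < node:
                    paths[(i, node)] = used
                continue
            for nxt, eidx in adj[node]:
                if nxt != parent:
                    stack.append((nxt, node, used + [eidx]))
    return paths


def least_squares_nj_oracle(D: np.ndarray) -> tuple[frozenset, dict]:
    """Best-fit tree by exhaustive least squares over all unrooted topologies.

    Returns the split set (each split a frozenset of leaf indices, the side
    not containing leaf 0) and a dict edge->length for the minimal-residual
    topology.  For an additive matrix the residual of the true topology is 0
    and the fitted branch lengths are exact.
    """
    n = D.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    best = None
    for edges in enumerate_topologies(n):
        paths = _leaf_paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        for r, (i, j) in enumerate(pairs):
            for eidx in paths[(i, j)]:
                A[r, eidx] = 1.0
        y = np.array([D[i, j] for i, j in pairs])
        coef, residual, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ coef - y) ** 2).sum())
        if best is None or resid < best[0] - 1e-12:
            best = (resid, edges, coef)
    resid, edges, coef = best
    splits = splits_of_topology(edges, n)
    lengths = {tuple(sorted(e)): float(c) for e, c in zip(edges, coef)}
    return splits, {"edges": edges, "lengths": lengths, "residual": resid}


def splits_of_topology(edges, n) -> frozenset:
    """Non-trivial bipartitions induced by the edges (side without leaf 0)."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge (u,v) removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 0 in side:
            side = set(range(n)) - side
        if 1 < len(side) < n - 1:
            splits.add(frozenset(side))
    return frozenset(splits)


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random binary tree over n leaves with uniform(0.5, 2) branch lengths.

    Returns (edge list, edge->length dict, n x n additive distance matrix,
    split set).
    """
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        u, v = edges.pop(k)
        edges += [(u, next_internal), (v, next_internal), (leaf, next_internal)]
        next_internal += 1
    lengths = {tuple(sorted(e)): float(rng.uniform(0.5, 2.0)) for e in edges}
    paths = _leaf_paths(edges, n)
    D = np.zeros((n, n))
    for (i, j), eidxs in paths.items():
        d = sum(lengths[tuple(sorted(edges[e]))] for e in eidxs)
        D[i, j] = D[j, i] = d
    return edges, lengths, D, splits_of_topology(edges, n)


def tree_splits_and_lengths(tree, labels: list[str]):
    """Splits (as frozensets of leaf indices, side without labels[0]) and the
    multiset of internal/pendant branch lengths of a dendropy tree."""
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    splits = set()
    lengths = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lengths.append(node.edge.length or 0.0)
        side = {index[leaf.taxon.label] for leaf in node.leaf_iter()}
        if 0 in side:
            side = set(range(n)) - side
        if 1 < len(side) < n - 1:
            splits.add(frozenset(side))
    return frozenset(splits), sorted(lengths)
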