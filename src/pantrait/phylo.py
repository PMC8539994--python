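"""Distance-based phylogenetics for BSH protein families.

Pairwise distances from global alignments (p-distance or Poisson-corrected),
Saitou-Nei neighbor joining, outgroup rooting with Newick output, and
distance-threshold clade grouping.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
from skbio import DistanceMatrix

from pantrait.align import ScoringParams, _aligner
from pantrait.proteomes import validate_protein


def pairwise_distance(
    seqs: Mapping[str, str],
    model: str = "p",
    params: ScoringParams = ScoringParams(),
) -> DistanceMatrix:
    """Pairwise evolutionary distances between protein sequences.

    Each pair is globally aligned (Needleman-Wunsch under the same scoring
    parameters as the local search); the proportion of differing sites
    p = mismatches / compared positions is computed over gap-free columns.
    ``model="p"`` returns p itself, ``model="poisson"`` the Poisson correction
    -ln(1 - p).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    clean = {k: validate_protein(v) for k, v in seqs.items()}
    aligner = _aligner(params, "global")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = clean[labels[i]], clean[labels[j]]
            aln = aligner.align(a, b)[0]
            qblocks, sblocks = aln.aligned
            compared = mism = 0
            for (qs, qe), (ss, se) in zip(qblocks, sblocks):
                for ca, cb in zip(a[qs:qe], b[ss:se]):
                    compared += 1
                    mism += ca != cb
            if compared == 0:
                raise ValueError(f"no comparable positions between {labels[i]} and {labels[j]}")
            p = mism / compared
            if model == "p":
                d[i, j] = d[j, i] = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1.0 between {labels[i]} and {labels[j]}: "
                        "Poisson distance is infinite"
                    )
                d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    At each step the pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined (Q-ties resolved toward the lexicographically smallest pair of
    subtree labels).  Negative branch lengths are clamped to 0 with the
    deficit moved to the sibling edge so the pair's path length is preserved.
    For two taxa the result is a single edge of length d(1,2) split across
    the root.
    """
    labels = list(dm.ids)
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[str, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes[lab] = node

    # active-node distance store keyed by the smallest leaf label in each subtree
    dist: dict[frozenset, float] = {}
    active = sorted(labels)
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            dist[frozenset((a, b))] = float(dm[a, b])

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    if len(active) < 2:
        raise ValueError("need at least 2 taxa")

    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(d(a, k) for k in active if k != a) for a in active}
        best_pair = None
        best_q = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * d(a, b) - rowsum[a] - rowsum[b]
                if best_q is None or q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (a, b) < best_pair
                ):
                    best_q, best_pair = q, (a, b)
        a, b = best_pair
        dab = d(a, b)
        la = 0.5 * dab + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        key = min(a, b)
        other = max(a, b)
        for k in active:
            if k in (a, b):
                continue
            dist[frozenset((key, k))] = 0.5 * (d(a, k) + d(b, k) - dab)
        active = sorted(set(active) - {other})
        nodes[key] = parent

    root = dendropy.Node()
    if len(active) == 2:
        a, b = active
        root.add_child(nodes[a])
        nodes[a].edge.length = d(a, b) / 2.0
        root.add_child(nodes[b])
        nodes[b].edge.length = d(a, b) / 2.0
    else:
        a, b, c = active
        la = max(0.0, 0.5 * (d(a, b) + d(a, c) - d(b, c)))
        lb = max(0.0, 0.5 * (d(a, b) + d(b, c) - d(a, c)))
        lc = max(0.0, 0.5 * (d(a, c) + d(b, c) - d(a, b)))
        for lab, length in ((a, la), (b, lb), (c, lc)):
            root.add_child(nodes[lab])
            nodes[lab].edge.length = length

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> tuple[dendropy.Tree, str]:
    """Root a tree at the midpoint of the outgroup's pendant edge.

    Returns the rooted tree and its Newick serialization.
    """
    rooted = tree.clone(depth=1)
    leaf = None
    for node in rooted.leaf_node_iter():
        if node.taxon is not None and node.taxon.label == outgroup_label:
            leaf = node
            break
    if leaf is None:
        raise ValueError(f"outgroup label {outgroup_label!r} is not a leaf of the tree")
    pendant = leaf.edge.length if leaf.edge.length is not None else 0.0
    rooted.reroot_at_edge(leaf.edge, length1=pendant / 2.0, length2=pendant / 2.0)
    rooted.is_rooted = True
    newick = rooted.as_string(schema="newick", suppress_rooting=True).strip()
    return rooted, newick


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def cut_groups(tree: dendropy.Tree, height_threshold: float) -> dict[str, int]:
    """Partition leaves into maximal monophyletic clades of bounded diameter.

    A clade qualifies when every within-clade leaf-to-leaf path distance is
    <= ``height_threshold``; descending from the root, the first qualifying
    node claims its whole clade as one group.  Returns leaf label -> group
    index (groups numbered in tree preorder).
    """
    if height_threshold < 0:
        raise ValueError("height_threshold must be >= 0")

    max_depth: dict[int, float] = {}
    max_pair: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            max_depth[id(node)] = 0.0
            max_pair[id(node)] = 0.0
            continue
        child_depths = []
        pair = 0.0
        for child in node.child_nodes():
            elen = child.edge.length or 0.0
            child_depths.append(max_depth[id(child)] + elen)
            pair = max(pair, max_pair[id(child)])
        for i in range(len(child_depths)):
            for j in range(i + 1, len(child_depths)):
                pair = max(pair, child_depths[i] + child_depths[j])
        max_depth[id(node)] = max(child_depths)
        max_pair[id(node)] = pair

    groups: dict[str, int] = {}
    counter = 0

    def assign(node: dendropy.Node) -> None:
        nonlocal counter
        if max_pair[id(node)] <= height_threshold:
            counter += 1
            for leaf in node.leaf_iter():
                groups[leaf.taxon.label] = counter
            return
        for child in node.child_nodes():
            assign(child)

    assign(tree.seed_node)
    return groups


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for lab in dm.ids:
            row = " ".join(f"{dm[lab, other]:.6f}" for other in dm.ids)
            fh.write(f"{lab} {row}\n")
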