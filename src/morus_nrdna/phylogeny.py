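"""Neighbor-joining over IUPAC haplotypes and species-cluster extraction.

Distances between haplotypes are ambiguity-aware p-distances: a column
contributes 1 when the two IUPAC base sets are disjoint (e.g. R vs C) and 0
when they share a base (R vs A), divided by the alignment length.  Trees
are built with Saitou–Nei neighbor joining (Studier–Keppler Q-criterion),
which recovers additive distance matrices exactly.  Negative branch
lengths, an artefact of non-additive inputs, are clamped to zero with the
deficit transferred to the sibling branch.

Species clusters are counted on the midpoint-rooted tree as the maximal
clades whose leaves all share one species label; the clusters partition
the leaf set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
}


def ambiguity_aware_distance(a: str, b: str) -> float:
    """Fraction of columns whose IUPAC base sets are disjoint."""
    if len(a) != len(b):
        raise ValueError("haplotype strings must have equal length")
    if not a:
        raise ValueError("haplotype strings must be non-empty")
    mismatches = sum(
        1 for x, y in zip(a.upper(), b.upper())
        if IUPAC_SETS[x].isdisjoint(IUPAC_SETS[y])
    )
    return mismatches / len(a)


def distance_matrix(
    labels: Sequence[str], seqs: Sequence[str]
) -> DistanceMatrix:
    """Pairwise ambiguity-aware p-distance matrix over labelled haplotypes."""
    n = len(labels)
    if n != len(seqs):
        raise ValueError("labels and sequences differ in number")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ambiguity_aware_distance(seqs[i], seqs[j])
    return DistanceMatrix(d, ids=list(labels))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; deterministic given input order.

    Exact on additive matrices.  Ties in the Q-criterion are broken by the
    first (row-major) minimal pair.  Negative branch lengths are clamped to
    zero and the deficit moved to the sibling so path lengths are
    preserved where possible.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]

        dij = d[i, j]
        li = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent.extend([child_i, child_j])

        # distances from the new node to the remaining taxa
        new_row = np.empty(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # final three-taxon star: closed-form branch lengths
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        child = nodes[idx]
        child.length = max(0.0, length)
        root.append(child)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def species_clusters(
    tree: TreeNode, species_of_leaf: Mapping[str, str]
) -> tuple[int, list[frozenset[str]]]:
    """Count species-pure maximal clades on the midpoint-rooted tree.

    Every leaf must be labelled; returns the number of clusters and the
    partition of leaf names.  A clade is pure when all its leaves share one
    species; maximal pure clades jointly cover all leaves.
    """
    leaves = [leaf.name for leaf in tree.tips()]
    unlabeled = [name for name in leaves if name not in species_of_leaf]
    if unlabeled:
        raise KeyError(f"unlabelled leaves: {unlabeled[:5]}")

    rooted = tree.copy()
    if len(leaves) > 2:
        rooted = rooted.root_at_midpoint()

    def pure_species(node) -> str | None:
        """Species label if the clade is pure, else None."""
        if node.is_tip():
            return species_of_leaf[node.name]
        child_species = [pure_species(ch) for ch in node.children]
        if None in child_species or len(set(child_species)) != 1:
            return None
        return child_species[0]

    clusters: list[frozenset[str]] = []

    def walk(node) -> None:
        if pure_species(node) is not None:
            clusters.append(frozenset(t.name for t in node.tips())
                            if not node.is_tip() else frozenset({node.name}))
            return
        for ch in node.children:
            walk(ch)

    walk(rooted)
    return len(clusters), clusters


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_phylip_distances(dm: DistanceMatrix, path) -> None:
    """PHYLIP square distance-matrix writer."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label, row in zip(dm.ids, dm.data):
            fh.write(label + "  " + " ".join(f"{x:.6f}" for x in row) + "\n")
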