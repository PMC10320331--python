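"""Trees, Brownian-motion covariance matrices and phylogenetic means.

Under a Brownian-motion model of trait evolution on a rooted tree, the
expected covariance between two tips is the branch length they share on
the path from the root -- the depth of their most recent common ancestor.
Collecting these shared path lengths gives the species-by-species matrix
C used to discount phylogenetic relatedness in the pPCA, and the
generalized-least-squares mean a = (1'C^-1 1)^-1 1'C^-1 X is the root
(ancestral-state) estimate of each trait.

Trees are handled with dendropy; branch lengths are treated as relative
time with no unit conversion.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "tip_labels",
    "vcv_matrix",
    "phylo_mean",
    "patristic_matrix",
    "average_tree",
]


class TreeError(ValueError):
    """Malformed tree input."""


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick string into a rooted dendropy tree.

    Requires branch lengths on every non-root edge and unique tip labels;
    matching of species names to tips is case-sensitive and exact.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"cannot parse Newick: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise TreeError(f"missing branch length above node {name!r}")
        if edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    tree.is_rooted = True
    return tree


def read_newick_file(path) -> list[dendropy.Tree]:
    """Read a multi-tree file: one Newick string per non-empty line."""
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                trees.append(read_newick(line))
            except TreeError as exc:
                raise TreeError(f"{path}, line {i}: {exc}") from None
    if not trees:
        raise TreeError(f"no trees in {path}")
    return trees


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _root_distances(tree: dendropy.Tree) -> dict[str, float]:
    dist = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        dist[leaf.taxon.label] = d
    return dist


def patristic_matrix(
    tree: dendropy.Tree, species_order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length matrix, rows/columns in ``species_order``."""
    order = list(species_order) if species_order is not None else tip_labels(tree)
    _check_species(tree, order)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(order)}
    n = len(order)
    D = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i < j:
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    return D, order


def _check_species(tree: dendropy.Tree, species: Sequence[str]) -> None:
    tips = set(tip_labels(tree))
    missing = [s for s in species if s not in tips]
    if missing:
        raise TreeError(f"species absent from tree: {missing}")


def vcv_matrix(
    tree: dendropy.Tree, species_order: Sequence[str]
) -> np.ndarray:
    """Brownian-motion phylogenetic covariance matrix C.

    C[i, j] is the root-to-MRCA depth of tips i and j, computed as
    (d_i + d_j - d_ij) / 2 from root-to-tip and patristic distances;
    the diagonal holds each tip's root-to-tip distance.
    """
    _check_species(tree, species_order)
    root = _root_distances(tree)
    D, order = patristic_matrix(tree, species_order)
    d = np.array([root[s] for s in order])
    C = (d[:, None] + d[None, :] - D) / 2.0
    C[np.diag_indices_from(C)] = d
    # shared depth cannot be negative; clip fp noise
    np.clip(C, 0.0, None, out=C)
    return C


def phylo_mean(X: np.ndarray, C: np.ndarray, ridge_log: list | None = None) -> np.ndarray:
    """GLS (phylogenetic) mean of each trait column of X under covariance C.

    a = (1' C^-1 1)^-1 1' C^-1 X.  A singular C gets a ridge of
    1e-10 * trace(C)/n on the diagonal (recorded in ``ridge_log`` when
    provided); zero-length terminal branches in published trees make this
    case real rather than hypothetical.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != C.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but C is {C.shape[0]}x{C.shape[1]}"
        )
    C = _ensure_invertible(C, ridge_log)
    n = C.shape[0]
    ones = np.ones(n)
    Cinv_1 = np.linalg.solve(C, ones)
    Cinv_X = np.linalg.solve(C, X)
    return (ones @ Cinv_X) / (ones @ Cinv_1)


def _ensure_invertible(C: np.ndarray, ridge_log: list | None = None) -> np.ndarray:
    n = C.shape[0]
    # cheap conditioning check; eigvalsh is fine at these sizes
    w = np.linalg.eigvalsh(C)
    if w.min() <= 1e-12 * max(w.max(), 1.0):
        ridge = 1e-10 * np.trace(C) / n
        if ridge <= 0:
            ridge = 1e-10
        if ridge_log is not None:
            ridge_log.append(ridge)
        C = C + ridge * np.eye(n)
    return C


def average_tree(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Representative tree for a tree set sharing one tip set.

    Averages the patristic distance matrices element-wise and rebuilds a
    tree by neighbor-joining; on an additive (e.g. unanimous) input
    matrix NJ recovers it exactly.  The construction method is stamped
    into ``tree.annotations`` as ``average_method``.
    """
    trees = list(trees)
    if not trees:
        raise TreeError("empty tree collection")
    order = sorted(tip_labels(trees[0]))
    for t in trees[1:]:
        if sorted(tip_labels(t)) != order:
            raise TreeError("trees have mismatched tip sets")
    if len(trees) == 1 and len(order) < 3:
        return trees[0]
    D = np.zeros((len(order), len(order)))
    for t in trees:
        Dt, _ = patristic_matrix(t, order)
        D += Dt
    D /= len(trees)
    avg = _nj_from_distances(D, order)
    avg.annotations.add_new("average_method", "mean-patristic+NJ")
    return avg


def _nj_from_distances(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Deterministic neighbor-joining (Saitou-Nei with midpoint-rooted
    final edge); ties broken by lowest index so reruns are byte-identical.

    On an additive input matrix NJ reconstructs it exactly; tiny negative
    branch lengths from near-degenerate matrices are clamped to zero.
    """
    D = np.asarray(D, dtype=float).copy()
    n = len(labels)
    if n < 2:
        raise TreeError("neighbor joining needs at least 2 tips")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(lab)
        nodes.append(node)

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    half = max(D[0, 1], 0.0) / 2.0
    for node in nodes:
        node.edge.length = half
        root.add_child(node)
    tree.is_rooted = True
    return tree
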