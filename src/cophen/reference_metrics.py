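"""Classical tree-comparison metrics used as references: Robinson-Foulds,
nodal (patristic) distances, and splitted nodal distances.

Robinson-Foulds compares the cluster families of two trees (the
descendant-taxon set of every node); trivial clusters — singletons and
the full taxon set — are present in both trees and cancel, so including
them does not change the value.  The nodal distances compare the vectors
of patristic path lengths over unordered taxon pairs with the L^1 or L^2
norm; the splitted nodal distances compare the full (asymmetric)
matrices of splitted path lengths over ordered pairs.  Both nodal
families are derived here from the cophenetic encoding via
d(i,j) = delta(i) + delta(j) - 2 phi(i,j) and l(i,j) = delta(i) - phi(i,j),
which shares the O(n^2) per-tree work across all metrics.
"""

from __future__ import annotations

import numpy as np

from .tree_model import PhyloTree, TreeError
from .cophenetic import (
    cophenetic_vector,
    patristic_from_cophenetic,
    splitted_lengths_from_cophenetic,
)

__all__ = [
    "cluster_sets",
    "robinson_foulds",
    "nodal_distance",
    "splitted_nodal_distance",
    "patristic_pair_vector",
    "splitted_pair_vector",
]


def cluster_sets(tree: PhyloTree) -> frozenset[frozenset[str]]:
    """The cluster family of a tree without nested taxa: the
    descendant-taxon set of every node (a laminar family containing all
    singletons and the full taxon set)."""
    if tree.has_nested_taxa():
        raise TreeError("cluster sets are defined for trees without nested taxa")
    clusters = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.root.postorder():
        taxa = frozenset().union(*(below[id(c)] for c in node.children)) \
            if node.children else frozenset()
        if node.label is not None:
            taxa |= {node.label}
        below[id(node)] = taxa
        clusters.add(taxa)
    return frozenset(clusters)


def _check_taxa(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.taxa != t2.taxa:
        raise TreeError(f"taxon sets differ: {t1.taxa} vs {t2.taxa}")


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Size of the symmetric difference of the two cluster families."""
    _check_taxa(t1, t2)
    return len(cluster_sets(t1) ^ cluster_sets(t2))


def patristic_pair_vector(tree: PhyloTree) -> np.ndarray:
    """Patristic distances d(i, j) over unordered pairs i < j, in the
    lexicographic order of the sorted taxon list."""
    d = patristic_from_cophenetic(cophenetic_vector(tree))
    iu, ju = np.triu_indices(len(tree.taxa), k=1)
    return d[iu, ju]


def splitted_pair_vector(tree: PhyloTree) -> np.ndarray:
    """Splitted path lengths l(i, j) over ordered pairs i != j (row-major
    with the diagonal removed)."""
    ell = splitted_lengths_from_cophenetic(cophenetic_vector(tree))
    n = len(tree.taxa)
    mask = ~np.eye(n, dtype=bool)
    return ell[mask]


def _lp(diff: np.ndarray, p: int) -> float:
    if p == 1:
        return float(np.abs(diff).sum())
    if p == 2:
        return float(np.sqrt((diff * diff).sum()))
    raise ValueError("p must be 1 or 2")


def nodal_distance(t1: PhyloTree, t2: PhyloTree, p: int = 1) -> float:
    """L^p distance between the patristic pair vectors (a metric on BT_n,
    only a pseudo-metric on larger spaces)."""
    _check_taxa(t1, t2)
    return _lp(patristic_pair_vector(t1) - patristic_pair_vector(t2), p)


def splitted_nodal_distance(t1: PhyloTree, t2: PhyloTree, p: int = 1) -> float:
    """L^p distance between the splitted path-length matrices over
    ordered pairs; zero iff the trees are isomorphic."""
    _check_taxa(t1, t2)
    return _lp(splitted_pair_vector(t1) - splitted_pair_vector(t2), p)
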