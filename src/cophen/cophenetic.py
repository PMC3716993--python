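"""Cophenetic vectors and the L^p cophenetic metric family.

For a tree T on taxa {1..n}, the cophenetic value of a pair of taxa i, j
is the depth of their lowest common ancestor,

    phi_T(i, j) = delta_T([i, j]_T),

and by convention phi_T(i, i) = delta_T(i), the depth of taxon i.  The
cophenetic vector phi(T) lists all n(n+1)/2 values phi_T(i, j), i <= j,
lexicographically ordered over the sorted taxon list.  This vector
characterizes a weighted phylogenetic tree with nested taxa up to
isomorphism, so comparing vectors with an L^p norm yields a genuine
metric on each space of trees over a fixed taxon set:

    d_phi_p(T1, T2) = || phi(T1) - phi(T2) ||_p        (p >= 1)
    d_phi_0(T1, T2) = Hamming distance of the vectors  (p = 0)

D_p denotes the root-free variant (the p-th power of d_phi_p for p >= 1,
the Hamming count for p = 0), integer-valued on unweighted trees and
therefore used for exact minimum-value statements.

Patristic distances and splitted path lengths are linear images of the
cophenetic vector:

    d(i, j)  = delta(i) + delta(j) - 2 phi(i, j)
    l(i, j)  = delta(i) - phi(i, j),   l(i, j) + l(j, i) = d(i, j)

The vector is computed in O(n^2): depths in one preorder pass, then each
unordered taxon pair charged to its LCA in one postorder pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree_model import PhyloTree, TreeError

__all__ = [
    "CopheneticVector",
    "ReducedCopheneticVector",
    "cophenetic_vector",
    "cophenetic_matrix",
    "reduced_vector",
    "depths_from_reduced",
    "d_phi_p",
    "d_phi_0",
    "D_p",
    "patristic_from_cophenetic",
    "splitted_lengths_from_cophenetic",
]


def _triu(n: int):
    return np.triu_indices(n)


@dataclass(frozen=True)
class CopheneticVector:
    """The n(n+1)/2 cophenetic values of a tree, diagonal included.

    ``values[k]`` holds phi(i, j) for the k-th pair (i, j), i <= j, in
    lexicographic order over ``taxa``; the diagonal entries are the taxon
    depths.
    """

    taxa: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = len(self.taxa)
        if self.values.shape != (n * (n + 1) // 2,):
            raise ValueError("cophenetic vector has wrong length")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def index(self, i: str, j: str) -> int:
        a, b = self.taxa.index(i), self.taxa.index(j)
        if a > b:
            a, b = b, a
        n = self.n
        return a * n - a * (a - 1) // 2 + (b - a)

    def get(self, i: str, j: str) -> float:
        """phi(i, j); phi(i, i) is the depth of taxon i."""
        return float(self.values[self.index(i, j)])

    def as_matrix(self) -> np.ndarray:
        """Symmetric n x n matrix with depths on the diagonal."""
        n = self.n
        m = np.zeros((n, n))
        iu, ju = _triu(n)
        m[iu, ju] = self.values
        m[ju, iu] = self.values
        return m

    def to_tsv(self) -> str:
        lines = ["i\tj\tvalue"]
        k = 0
        for a in range(self.n):
            for b in range(a, self.n):
                lines.append(f"{self.taxa[a]}\t{self.taxa[b]}\t{self.values[k]:g}")
                k += 1
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ReducedCopheneticVector:
    """Off-diagonal cophenetic values only (n(n-1)/2 entries, i < j).

    Enough to single out unweighted trees without nested taxa, but not
    weighted trees: e.g. cherries with pendant weights (1,1) and (2,2)
    share the reduced vector (0,)."""

    taxa: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = len(self.taxa)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError("reduced cophenetic vector has wrong length")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def get(self, i: str, j: str) -> float:
        a, b = self.taxa.index(i), self.taxa.index(j)
        if a == b:
            raise KeyError("reduced vector has no diagonal entries")
        if a > b:
            a, b = b, a
        n = self.n
        return float(self.values[a * n - a * (a + 1) // 2 + (b - a - 1)])


def cophenetic_matrix(tree: PhyloTree) -> np.ndarray:
    """Symmetric n x n matrix of cophenetic values (depths on the
    diagonal), taxa in canonical sorted order.

    One preorder pass computes depths; one postorder pass assigns each
    taxon pair to the depth of its LCA: at a node v with child subtrees
    carrying taxon index blocks B1..Bk (plus v's own label, if any, whose
    LCA with every proper descendant is v itself), every cross-block pair
    receives depth(v).  Each pair is touched exactly once, so the total
    work is O(n^2).
    """
    taxa = tree.taxa
    pos = {t: k for k, t in enumerate(taxa)}
    n = len(taxa)
    m = np.zeros((n, n))
    depth = tree.depths()

    below: dict[int, np.ndarray] = {}
    for node in tree.root.postorder():
        blocks = [below[id(c)] for c in node.children]
        if node.label is not None:
            blocks.append(np.array([pos[node.label]], dtype=np.intp))
        d = depth[node]
        if len(blocks) > 1:
            for a in range(len(blocks)):
                for b in range(a + 1, len(blocks)):
                    m[np.ix_(blocks[a], blocks[b])] = d
                    m[np.ix_(blocks[b], blocks[a])] = d
        merged = blocks[0] if len(blocks) == 1 else np.concatenate(blocks)
        below[id(node)] = merged
        if node.label is not None:
            m[pos[node.label], pos[node.label]] = d
    return m


def cophenetic_vector(tree: PhyloTree) -> CopheneticVector:
    """Cophenetic vector phi(T), lexicographically ordered with the taxon
    depths interleaved on the diagonal positions."""
    m = cophenetic_matrix(tree)
    iu, ju = _triu(len(tree.taxa))
    return CopheneticVector(taxa=tree.taxa, values=m[iu, ju].copy())


def reduced_vector(tree: PhyloTree) -> ReducedCopheneticVector:
    """Off-diagonal slice of the cophenetic vector (pairs i < j only)."""
    m = cophenetic_matrix(tree)
    n = len(tree.taxa)
    iu, ju = np.triu_indices(n, k=1)
    return ReducedCopheneticVector(taxa=tree.taxa, values=m[iu, ju].copy())


def depths_from_reduced(vec: ReducedCopheneticVector) -> dict[str, float]:
    """Reconstruct taxon depths from off-diagonal cophenetic values via
    delta(i) = 1 + max_j phi(i, j).

    Valid only for unweighted trees without nested taxa (the caller must
    guarantee this); a single-taxon vector yields depth 0.
    """
    n = vec.n
    if n == 1:
        return {vec.taxa[0]: 0.0}
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = vec.values
    m[ju, iu] = vec.values
    np.fill_diagonal(m, -np.inf)
    return {t: float(1.0 + m[k].max()) for k, t in enumerate(vec.taxa)}


# -- metrics ----------------------------------------------------------


def _aligned_values(t1: PhyloTree, t2: PhyloTree) -> tuple[np.ndarray, np.ndarray]:
    if t1.taxa != t2.taxa:
        raise TreeError(f"taxon sets differ: {t1.taxa} vs {t2.taxa}")
    return cophenetic_vector(t1).values, cophenetic_vector(t2).values


def d_phi_p(t1: PhyloTree, t2: PhyloTree, p: float = 1.0) -> float:
    """Cophenetic metric d_phi_p: L^p norm of phi(T1) - phi(T2), p >= 1."""
    if p < 1:
        raise ValueError("p must be >= 1 (use d_phi_0 for the Hamming variant)")
    v1, v2 = _aligned_values(t1, t2)
    diff = np.abs(v1 - v2)
    if p == 1:
        return float(diff.sum())
    if p == 2:
        return float(np.sqrt((diff * diff).sum()))
    return float((diff ** p).sum() ** (1.0 / p))


def d_phi_0(t1: PhyloTree, t2: PhyloTree, eps: float = 0.0) -> int:
    """Hamming cophenetic distance: number of entries where the vectors
    differ by more than *eps* (default exact, for unweighted trees)."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    v1, v2 = _aligned_values(t1, t2)
    return int((np.abs(v1 - v2) > eps).sum())


def D_p(t1: PhyloTree, t2: PhyloTree, p: float) -> float | int:
    """Root-free variant: the Hamming count for p = 0, the p-th power of
    d_phi_p for p >= 1.  Integer exact on unweighted trees with integer p."""
    if p == 0:
        return d_phi_0(t1, t2)
    if p < 1:
        raise ValueError("p must be 0 or >= 1")
    v1, v2 = _aligned_values(t1, t2)
    diff = np.abs(v1 - v2)
    if float(p).is_integer() and np.allclose(diff, np.round(diff)):
        return int(np.round((np.round(diff).astype(np.int64) ** int(p)).sum()))
    return float((diff ** p).sum())


# -- derived encodings -------------------------------------------------


def patristic_from_cophenetic(vec: CopheneticVector) -> np.ndarray:
    """Symmetric matrix of patristic distances,
    d(i, j) = delta(i) + delta(j) - 2 phi(i, j), zero diagonal."""
    m = vec.as_matrix()
    delta = np.diag(m)
    d = delta[:, None] + delta[None, :] - 2.0 * m
    np.fill_diagonal(d, 0.0)
    return d


def splitted_lengths_from_cophenetic(vec: CopheneticVector) -> np.ndarray:
    """Full (generally asymmetric) matrix of splitted path lengths,
    l(i, j) = delta(i) - phi(i, j), zero diagonal.  Row + transposed row
    recovers the patristic matrix."""
    m = vec.as_matrix()
    delta = np.diag(m)
    ell = delta[:, None] - m
    np.fill_diagonal(ell, 0.0)
    return ell
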