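"""Tree-space enumeration, exact counting, and uniform random sampling.

Spaces over the taxon set {1..n}:

* ``BT`` — rooted binary leaf-labeled trees (no nested taxa);
  |BT_n| = (2n-3)!!.
* ``T``  — rooted multifurcating leaf-labeled trees, internal nodes
  unlabeled with >= 2 children; |T_n| follows the set-partition
  recurrence below (1, 1, 4, 26, 236, 2752, ... for n = 1..6).
* ``UT`` — unweighted phylogenetic trees with nested taxa: any node may
  carry a label, leaves and non-root elementary nodes must, and an
  unlabeled elementary root is permitted.  Enumerated by recursive
  construction with canonical-form deduplication (small n only).

Counting and exact-uniform sampling of T_n use the forest recurrence

    f(0, 0) = 1
    f(m, k) = sum_{s=1..m-k+1} C(m-1, s-1) * t(s) * f(m-s, k-1)
    t(1) = 1,  t(m) = sum_{k>=2} f(m, k)

where f(m, k) counts forests of k trees on m distinguished labels and
t(m) = |T_m|.  All weights are arbitrary-precision integers, so the
samplers are exactly uniform (no floating-point bias).  Randomness comes
from :class:`random.Random`, which draws unbiased integers of any size.
"""

from __future__ import annotations

import random
from functools import lru_cache
from math import comb
from typing import Iterator

from .tree_model import PhyloNode, PhyloTree

__all__ = [
    "enumerate_binary",
    "enumerate_multifurcating",
    "enumerate_nested",
    "enumerate_space",
    "sample_binary",
    "sample_multifurcating",
    "sample_tree",
    "space_count",
    "count_binary",
    "count_multifurcating",
]

#: guard for UT enumeration (generate-then-dedup blows up quickly)
MAX_NESTED_N = 5


def _labels(n: int) -> list[str]:
    return [str(i) for i in range(1, n + 1)]


def _as_rng(seed) -> random.Random:
    if isinstance(seed, random.Random):
        return seed
    return random.Random(seed)


# -- counting ---------------------------------------------------------


def count_binary(n: int) -> int:
    """|BT_n| = (2n-3)!! for n >= 2; |BT_1| = 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 3
    return out


@lru_cache(maxsize=None)
def _forest_count(m: int, k: int) -> int:
    """Number of forests of k multifurcating trees on m labeled taxa."""
    if m == 0 and k == 0:
        return 1
    if m <= 0 or k <= 0 or k > m:
        return 0
    return sum(comb(m - 1, s - 1) * count_multifurcating(s) * _forest_count(m - s, k - 1)
               for s in range(1, m - k + 2))


@lru_cache(maxsize=None)
def count_multifurcating(n: int) -> int:
    """|T_n| via the forest recurrence (series of "total partitions")."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return 1
    return sum(_forest_count(n, k) for k in range(2, n + 1))


def space_count(kind: str, n: int) -> int:
    """Exact cardinality of the space ``kind`` in {"BT", "T", "UT"} on n
    taxa.  UT is counted by exhaustive enumeration and only for small n."""
    kind = kind.upper()
    if kind == "BT":
        if n < 2:
            raise ValueError("BT requires n >= 2")
        return count_binary(n)
    if kind == "T":
        return count_multifurcating(n)
    if kind == "UT":
        if n > MAX_NESTED_N:
            raise ValueError(f"UT enumeration supported only for n <= {MAX_NESTED_N}")
        return sum(1 for _ in enumerate_nested(n))
    raise ValueError(f"unknown tree space {kind!r}")


# -- enumeration ------------------------------------------------------


def enumerate_binary(n: int) -> Iterator[PhyloTree]:
    """All rooted binary trees on taxa {1..n}, each exactly once, by
    sequential leaf insertion: leaf k attaches to any of the 2k-3 arcs
    (counting the virtual arc above the root)."""
    if n < 2:
        raise ValueError("binary enumeration requires n >= 2")
    labels = _labels(n)

    def grow(root: PhyloNode, k: int) -> Iterator[PhyloNode]:
        if k == n:
            yield root
            return
        label = labels[k]
        nodes = [nd for nd in root.preorder() if nd is not root]
        for target in nodes:
            parent = target.parent
            idx = parent.children.index(target)
            mid = PhyloNode()
            mid.add_child(target)
            mid.add_child(PhyloNode(label=label))
            mid.parent = parent
            parent.children[idx] = mid
            yield from grow(root, k + 1)
            parent.children[idx] = target
            target.parent = parent
        # above the old root
        top = PhyloNode()
        top.add_child(root)
        top.add_child(PhyloNode(label=label))
        yield from grow(top, k + 1)
        root.parent = None

    cherry = PhyloNode(children=[PhyloNode(label=labels[0]), PhyloNode(label=labels[1])])
    for shape in grow(cherry, 2):
        yield PhyloTree(shape.copy())


def _set_partitions(items: list, min_blocks: int) -> Iterator[list[list]]:
    """Partitions of *items* into >= min_blocks nonempty blocks; the block
    containing the first item comes first, so no partition repeats."""
    if not items:
        if min_blocks <= 0:
            yield []
        return
    first, rest = items[0], items[1:]
    # choose the block of `first` as first ∪ subset of rest
    m = len(rest)
    for mask in range(1 << m):
        block = [first] + [rest[i] for i in range(m) if mask >> i & 1]
        remainder = [rest[i] for i in range(m) if not mask >> i & 1]
        for tail in _set_partitions(remainder, max(min_blocks - 1, 1) if remainder else min_blocks - 1):
            yield [block] + tail


def _multifurcating_shapes(labels: list[str]) -> Iterator[PhyloNode]:
    if len(labels) == 1:
        yield PhyloNode(label=labels[0])
        return
    for blocks in _set_partitions(labels, 2):
        if len(blocks) < 2:
            continue
        yield from _assemble(blocks, 0, [])


def _assemble(blocks, i, chosen) -> Iterator[PhyloNode]:
    if i == len(blocks):
        yield PhyloNode(children=[c.copy() for c in chosen])
        return
    for sub in _multifurcating_shapes(blocks[i]):
        chosen.append(sub)
        yield from _assemble(blocks, i + 1, chosen)
        chosen.pop()


def enumerate_multifurcating(n: int) -> Iterator[PhyloTree]:
    """All trees of T_n exactly once: internal nodes unlabeled with >= 2
    children, leaves labeled {1..n}.  Children carry disjoint taxon sets,
    so the set-partition recursion never produces duplicates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for shape in _multifurcating_shapes(_labels(n)):
        yield PhyloTree(shape)


def _nested_shapes(labels: frozenset, allow_unlabeled_elementary: bool) -> list[PhyloNode]:
    """All phylogenetic-tree shapes on a label set, allowing nested taxa.

    A subtree root is either labeled (with children partitioning the
    remaining labels into any number >= 0 of blocks) or unlabeled (>= 2
    child blocks, or exactly 1 when an unlabeled elementary root is
    allowed, i.e. only at the global root).
    """
    out: list[PhyloNode] = []
    items = sorted(labels)
    # labeled root
    for a in items:
        rest = [x for x in items if x != a]
        if not rest:
            out.append(PhyloNode(label=a))
            continue
        for blocks in _set_partitions(rest, 1):
            for node in _assemble_labeled(a, blocks):
                out.append(node)
    # unlabeled root
    min_blocks = 1 if allow_unlabeled_elementary else 2
    if len(items) >= 1:
        for blocks in _set_partitions(items, min_blocks):
            if len(blocks) < min_blocks:
                continue
            for node in _assemble_nested(blocks, 0, []):
                out.append(node)
    return out


def _assemble_labeled(label: str, blocks) -> Iterator[PhyloNode]:
    for node in _assemble_nested(blocks, 0, []):
        node.label = label
        yield node


def _assemble_nested(blocks, i, chosen) -> Iterator[PhyloNode]:
    if i == len(blocks):
        yield PhyloNode(children=[c.copy() for c in chosen])
        return
    for sub in _nested_shapes(frozenset(blocks[i]), False):
        chosen.append(sub)
        yield from _assemble_nested(blocks, i + 1, chosen)
        chosen.pop()


def enumerate_nested(n: int) -> Iterator[PhyloTree]:
    """All trees of UT_n exactly once (nested taxa and an unlabeled
    elementary root allowed), deduplicated by canonical form.  Intended
    for small n only."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > MAX_NESTED_N:
        raise ValueError(f"UT enumeration supported only for n <= {MAX_NESTED_N}")
    seen = set()
    for shape in _nested_shapes(frozenset(_labels(n)), True):
        tree = PhyloTree(shape)
        key = tree.canonical_key()
        if key not in seen:
            seen.add(key)
            yield tree


def enumerate_space(kind: str, n: int) -> Iterator[PhyloTree]:
    kind = kind.upper()
    if kind == "BT":
        return enumerate_binary(n)
    if kind == "T":
        return enumerate_multifurcating(n)
    if kind == "UT":
        return enumerate_nested(n)
    raise ValueError(f"unknown tree space {kind!r}")


# -- uniform sampling -------------------------------------------------


def sample_binary(n: int, seed) -> PhyloTree:
    """One uniform draw from BT_n by sequential insertion: leaf k picks
    one of the 2k-3 equiprobable attachment positions (any arc, or above
    the root).  *seed* is an int or a :class:`random.Random`."""
    if n < 2:
        raise ValueError("binary sampling requires n >= 2")
    rng = _as_rng(seed)
    labels = _labels(n)
    root = PhyloNode(children=[PhyloNode(label=labels[0]), PhyloNode(label=labels[1])])
    arcs = list(root.children)  # nodes with an incoming arc
    for k in range(3, n + 1):
        pos = rng.randrange(2 * k - 3)
        leaf = PhyloNode(label=labels[k - 1])
        if pos == len(arcs):  # above the root
            new_root = PhyloNode(children=[root, leaf])
            arcs.append(root)
            root = new_root
        else:
            target = arcs[pos]
            parent = target.parent
            idx = parent.children.index(target)
            mid = PhyloNode()
            mid.add_child(target)
            mid.add_child(leaf)
            mid.parent = parent
            parent.children[idx] = mid
            arcs.append(mid)
        arcs.append(leaf)
    return PhyloTree(root)


def _weighted_choice(rng: random.Random, weights: list[int]) -> int:
    total = sum(weights)
    r = rng.randrange(total)
    acc = 0
    for i, w in enumerate(weights):
        acc += w
        if r < acc:
            return i
    raise AssertionError("unreachable")


def _sample_forest(rng: random.Random, labels: list[str], k: int) -> list[PhyloNode]:
    """Uniform forest of k multifurcating trees on *labels*, weighted by
    the exact counts so every forest is equiprobable."""
    if k == 0:
        return []
    m = len(labels)
    if k == m:
        return [PhyloNode(label=x) for x in labels]
    # block containing the smallest label has size s with weight
    # C(m-1, s-1) * t(s) * f(m-s, k-1)
    sizes = list(range(1, m - k + 2))
    weights = [comb(m - 1, s - 1) * count_multifurcating(s) * _forest_count(m - s, k - 1)
               for s in sizes]
    s = sizes[_weighted_choice(rng, weights)]
    rest = labels[1:]
    members = sorted(rng.sample(range(len(rest)), s - 1))
    block = [labels[0]] + [rest[i] for i in members]
    remainder = [x for i, x in enumerate(rest) if i not in set(members)]
    return [_sample_multi_shape(rng, block)] + _sample_forest(rng, remainder, k - 1)


def _sample_multi_shape(rng: random.Random, labels: list[str]) -> PhyloNode:
    m = len(labels)
    if m == 1:
        return PhyloNode(label=labels[0])
    ks = list(range(2, m + 1))
    weights = [_forest_count(m, k) for k in ks]
    k = ks[_weighted_choice(rng, weights)]
    return PhyloNode(children=_sample_forest(rng, labels, k))


def sample_multifurcating(n: int, seed) -> PhyloTree:
    """One exactly-uniform draw from T_n by count-weighted recursion on
    the forest recurrence (arbitrary-precision integer weights)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return PhyloTree(_sample_multi_shape(rng, _labels(n)))


def sample_tree(kind: str, n: int, seed) -> PhyloTree:
    kind = kind.upper()
    if kind == "BT":
        return sample_binary(n, seed)
    if kind == "T":
        return sample_multifurcating(n, seed)
    raise ValueError(f"sampling supported for BT and T only, not {kind!r}")
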