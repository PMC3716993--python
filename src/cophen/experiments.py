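"""Numerical studies over tree spaces: pairwise distance tables, Spearman
rank correlations between metrics, 2D histograms, distance distributions,
and brute-force extreme-value searches.

Two regimes are supported.  In *exhaustive* mode every tree of a space is
enumerated and every unordered pair of distinct trees contributes one
distance per metric; per-tree encodings (cophenetic vector, patristic and
splitted path-length vectors, cluster family) are computed once and all
pairwise distances are evaluated vectorized.  In *sampled* mode i.i.d.
uniform tree pairs are drawn in batches and the correlations are
recomputed after each batch until every coefficient is stable to a fixed
number of significant digits across two consecutive batches.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, skew

from .tree_model import PhyloNode, PhyloTree, contract_arc, replace_subtree
from .cophenetic import cophenetic_matrix, d_phi_p
from .reference_metrics import cluster_sets
from .treespaces import enumerate_space, sample_tree

__all__ = [
    "METRICS",
    "DistanceTable",
    "CorrelationTable",
    "spearman_rho",
    "distance_tables",
    "exhaustive_correlations",
    "sampled_correlations",
    "histogram2d",
    "distance_distribution",
    "min_nonzero_distance",
    "diameter_bruteforce",
    "pendant_contraction_neighbors",
    "cherry_contraction_neighbors",
    "uncle_regraft_neighbors",
    "triplet_reorganization_neighbors",
    "quartet_reorganization_neighbors",
]

#: supported metric names (phi-p for arbitrary p >= 1 also accepted)
METRICS = ("phi-0", "phi-1", "phi-2", "rf", "nodal-1", "nodal-2",
           "snodal-1", "snodal-2")


@dataclass
class DistanceTable:
    """Pairwise values of one metric over a tree collection, in a fixed
    pair order shared by all metrics of the same run."""

    collection: str
    metric: str
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CorrelationTable:
    """Spearman rho for each metric pair (upper triangle), plus run
    metadata (space, n, mode, seed, number of tree pairs)."""

    rho: pd.DataFrame
    meta: dict

    def get(self, a: str, b: str) -> float:
        return float(self.rho.loc[a, b]) if not np.isnan(self.rho.loc[a, b]) \
            else float(self.rho.loc[b, a])

    def to_csv(self) -> str:
        header = "".join(f"# {k}: {v}\n" for k, v in self.meta.items())
        return header + self.rho.to_csv(float_format="%.6f")


# -- Spearman ---------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of fractional
    (mean) ranks, ties receiving the average of their rank range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def _rank_correlations(columns: dict[str, np.ndarray], metrics) -> pd.DataFrame:
    ranks = {m: rankdata(columns[m]) for m in metrics}
    out = pd.DataFrame(np.nan, index=list(metrics), columns=list(metrics))
    for i, a in enumerate(metrics):
        for b in metrics[i + 1:]:
            out.loc[a, b] = float(np.corrcoef(ranks[a], ranks[b])[0, 1])
    return out


# -- per-tree encodings and vectorized pairwise distances -------------


def _phi_vector(tree: PhyloTree) -> np.ndarray:
    m = cophenetic_matrix(tree)
    iu, ju = np.triu_indices(len(tree.taxa))
    return m[iu, ju]


def _patristic_vector_from_matrix(m: np.ndarray) -> np.ndarray:
    delta = np.diag(m)
    d = delta[:, None] + delta[None, :] - 2.0 * m
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return d[iu, ju]


def _splitted_vector_from_matrix(m: np.ndarray) -> np.ndarray:
    delta = np.diag(m)
    ell = delta[:, None] - m
    mask = ~np.eye(m.shape[0], dtype=bool)
    return ell[mask]


_METRIC_FEATURE = {
    "phi-0": "phi", "phi-1": "phi", "phi-2": "phi",
    "nodal-1": "pat", "nodal-2": "pat",
    "snodal-1": "spl", "snodal-2": "spl",
    "rf": "clu",
}


def _feature_matrices(trees: list[PhyloTree], features: set[str]) -> dict[str, np.ndarray]:
    out: dict[str, list] = {f: [] for f in features}
    cluster_rows = []
    for t in trees:
        m = cophenetic_matrix(t) if features & {"phi", "pat", "spl"} else None
        if "phi" in features:
            iu, ju = np.triu_indices(m.shape[0])
            out["phi"].append(m[iu, ju])
        if "pat" in features:
            out["pat"].append(_patristic_vector_from_matrix(m))
        if "spl" in features:
            out["spl"].append(_splitted_vector_from_matrix(m))
        if "clu" in features:
            cluster_rows.append(cluster_sets(t))
    result = {f: np.asarray(out[f]) for f in features if f != "clu"}
    if "clu" in features:
        universe = sorted(set().union(*cluster_rows), key=lambda c: (len(c), sorted(c)))
        index = {c: k for k, c in enumerate(universe)}
        ind = np.zeros((len(trees), len(universe)))
        for r, clusters in enumerate(cluster_rows):
            for c in clusters:
                ind[r, index[c]] = 1.0
        result["clu"] = ind
    return result


def _pairwise(metric: str, feat: np.ndarray) -> np.ndarray:
    """Condensed pairwise distances for one metric from its per-tree
    feature matrix (rows = trees)."""
    if metric in ("phi-1", "nodal-1", "snodal-1", "rf"):
        return pdist(feat, "cityblock")
    if metric in ("phi-2", "nodal-2", "snodal-2"):
        return pdist(feat, "euclidean")
    if metric == "phi-0":
        return pdist(feat, "hamming") * feat.shape[1]
    if metric.startswith("phi-"):
        p = float(metric[4:])
        return pdist(feat, "minkowski", p=p)
    raise ValueError(f"unknown metric {metric!r}")


def _pair_distance(metric: str, fa: np.ndarray, fb: np.ndarray) -> float:
    diff = fa - fb
    if metric in ("phi-1", "nodal-1", "snodal-1", "rf"):
        return float(np.abs(diff).sum())
    if metric in ("phi-2", "nodal-2", "snodal-2"):
        return float(np.sqrt((diff * diff).sum()))
    if metric == "phi-0":
        return float((diff != 0).sum())
    if metric.startswith("phi-"):
        p = float(metric[4:])
        return float((np.abs(diff) ** p).sum() ** (1 / p))
    raise ValueError(f"unknown metric {metric!r}")


def _metric_feature(metric: str) -> str:
    if metric in _METRIC_FEATURE:
        return _METRIC_FEATURE[metric]
    if metric.startswith("phi-"):
        return "phi"
    raise ValueError(f"unknown metric {metric!r}")


def distance_tables(trees: list[PhyloTree], metrics, collection: str = "") -> dict[str, DistanceTable]:
    """All-pairs distance tables over *trees* for every requested metric,
    sharing per-tree encodings; pair order is lexicographic over the
    enumeration indices (scipy condensed order)."""
    metrics = list(metrics)
    feats = _feature_matrices(trees, {_metric_feature(m) for m in metrics})
    return {m: DistanceTable(collection, m, _pairwise(m, feats[_metric_feature(m)]))
            for m in metrics}


# -- correlation experiments ------------------------------------------


def exhaustive_correlations(kind: str, n: int, metrics=None,
                            max_trees: int = 5000,
                            include_self_pairs: bool = True) -> CorrelationTable:
    """Spearman correlations between metrics over all unordered pairs of
    trees of a space (guarded by *max_trees*).

    With ``include_self_pairs`` (the default) each tree is also paired
    with itself, contributing a zero distance under every metric; this
    only adds a block of simultaneous ties at zero, but with heavily
    tied distance tables it shifts the mean-rank coefficients in the
    fourth decimal, so the convention is part of the result.
    """
    metrics = list(metrics) if metrics is not None else \
        (["phi-1", "phi-2", "nodal-1", "nodal-2", "rf"] if kind.upper() == "BT"
         else ["phi-1", "phi-2", "snodal-1", "snodal-2", "rf"])
    trees = list(enumerate_space(kind, n))
    if len(trees) > max_trees:
        raise ValueError(f"space too large ({len(trees)} trees > {max_trees})")
    tables = distance_tables(trees, metrics, collection=f"{kind}{n}")
    extra = len(trees) if include_self_pairs else 0
    columns = {m: np.concatenate([tables[m].values, np.zeros(extra)])
               for m in metrics}
    rho = _rank_correlations(columns, metrics)
    meta = {"space": kind.upper(), "n": n, "mode": "exhaustive",
            "trees": len(trees), "pairs": len(next(iter(columns.values()))),
            "include_self_pairs": include_self_pairs}
    return CorrelationTable(rho, meta)


def _round_sig(x: float, digits: int) -> str:
    return "%.*g" % (digits, x)


def sampled_correlations(kind: str, n: int, metrics, seed,
                         batch_pairs: int = 10_000,
                         max_pairs: int = 1_000_000,
                         sig_digits: int = 3) -> CorrelationTable:
    """Spearman correlations over i.i.d. uniform tree pairs, drawn in
    batches until every coefficient is stable to *sig_digits* significant
    digits across two consecutive batches.

    Raises ``RuntimeError`` if *max_pairs* is exhausted before
    convergence.
    """
    metrics = list(metrics)
    features = {_metric_feature(m) for m in metrics}
    rng = random.Random(seed)
    columns: dict[str, list[float]] = {m: [] for m in metrics}
    previous: dict | None = None
    n_pairs = 0
    while n_pairs < max_pairs:
        for _ in range(batch_pairs):
            fa = _sample_features(kind, n, rng, features)
            fb = _sample_features(kind, n, rng, features)
            for m in metrics:
                f = _metric_feature(m)
                columns[m].append(_rf_pair(fa[f], fb[f]) if f == "clu"
                                  else _pair_distance(m, fa[f], fb[f]))
        n_pairs += batch_pairs
        rho = _rank_correlations({m: np.asarray(columns[m]) for m in metrics}, metrics)
        snapshot = {(a, b): _round_sig(rho.loc[a, b], sig_digits)
                    for i, a in enumerate(metrics) for b in metrics[i + 1:]}
        if previous is not None and snapshot == previous:
            meta = {"space": kind.upper(), "n": n, "mode": "sampled",
                    "seed": seed, "pairs": n_pairs, "batch_pairs": batch_pairs,
                    "sig_digits": sig_digits}
            return CorrelationTable(rho, meta)
        previous = snapshot
    raise RuntimeError(f"correlations did not converge within {max_pairs} pairs")


def _sample_features(kind: str, n: int, rng: random.Random, features: set[str]) -> dict:
    tree = sample_tree(kind, n, rng)
    out: dict = {}
    if features & {"phi", "pat", "spl"}:
        m = cophenetic_matrix(tree)
        if "phi" in features:
            iu, ju = np.triu_indices(n)
            out["phi"] = m[iu, ju]
        if "pat" in features:
            out["pat"] = _patristic_vector_from_matrix(m)
        if "spl" in features:
            out["spl"] = _splitted_vector_from_matrix(m)
    if "clu" in features:
        out["clu"] = cluster_sets(tree)
    return out


def _rf_pair(ca, cb) -> float:
    return float(len(ca ^ cb))


# -- distributions ----------------------------------------------------


def histogram2d(table_a: DistanceTable, table_b: DistanceTable, bins: int = 25):
    """Joint counts of two distance tables over a *bins* x *bins* grid
    spanning the range of each metric; the grid sums to the number of
    pairs."""
    if table_a.collection != table_b.collection or len(table_a) != len(table_b):
        raise ValueError("tables must share the same tree-pair ordering")
    counts, xedges, yedges = np.histogram2d(table_a.values, table_b.values, bins=bins)
    return counts, xedges, yedges


def distance_distribution(kind: str, n: int, metric: str,
                          mode: str = "exhaustive", seed=None,
                          pairs: int = 100_000, bins: int = 25):
    """Histogram and sample skewness (standardized third moment) of one
    metric's distance distribution over a space.

    Returns ``(counts, edges, skewness)``.  Raises ``ValueError`` on a
    degenerate (constant) distribution.
    """
    if mode == "exhaustive":
        trees = list(enumerate_space(kind, n))
        values = distance_tables(trees, [metric], f"{kind}{n}")[metric].values
    elif mode == "sampled":
        rng = random.Random(seed)
        feature = _metric_feature(metric)
        vals = []
        for _ in range(pairs):
            fa = _sample_features(kind, n, rng, {feature})
            fb = _sample_features(kind, n, rng, {feature})
            vals.append(_rf_pair(fa[feature], fb[feature]) if feature == "clu"
                        else _pair_distance(metric, fa[feature], fb[feature]))
        values = np.asarray(vals)
    else:
        raise ValueError("mode must be 'exhaustive' or 'sampled'")
    if values.min() == values.max():
        raise ValueError("degenerate distance distribution: skewness undefined")
    counts, edges = np.histogram(values, bins=bins)
    return counts, edges, float(skew(values))


# -- extreme values ---------------------------------------------------


def min_nonzero_distance(trees: list[PhyloTree], p: float, atol: float = 1e-9):
    """Brute-force minimum nonzero D_p over all distinct pairs of
    *trees*, together with every pair (as index tuples) achieving it."""
    feats = _feature_matrices(trees, {"phi"})["phi"]
    if p == 0:
        dist = pdist(feats, "hamming") * feats.shape[1]
    elif p == 1:
        dist = pdist(feats, "cityblock")
    elif p == 2:
        dist = pdist(feats, "sqeuclidean")
    elif p >= 1:
        dist = pdist(feats, "minkowski", p=p) ** p
    else:
        raise ValueError("p must be 0 or >= 1")
    nonzero = dist[dist > atol]
    if len(nonzero) == 0:
        raise ValueError("no distinct pairs")
    value = nonzero.min()
    m = len(trees)
    pairs = []
    k = 0
    for i in range(m):
        for j in range(i + 1, m):
            if abs(dist[k] - value) <= atol:
                pairs.append((i, j))
            k += 1
    return float(value), pairs


def diameter_bruteforce(trees: list[PhyloTree], p: float = 1.0) -> float:
    """Maximum d_phi_p over all pairs of *trees* (0 for a single tree)."""
    if len(trees) < 2:
        return 0.0
    feats = _feature_matrices(trees, {"phi"})["phi"]
    if p == 1:
        return float(pdist(feats, "cityblock").max())
    if p == 2:
        return float(pdist(feats, "euclidean").max())
    if p == 0:
        return float((pdist(feats, "hamming") * feats.shape[1]).max())
    return float(pdist(feats, "minkowski", p=p).max())


# -- neighbor constructions (minimal-pair characterizations) ----------


def _is_cherry_root(node: PhyloNode) -> bool:
    return (node.label is None and len(node.children) == 2
            and all(c.is_leaf for c in node.children))


def pendant_contraction_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees obtained by contracting a pendant arc whose tail is
    unlabeled (the leaf's label moves onto the parent as a nested taxon)."""
    out = []
    for node in tree.root.preorder():
        if node.is_leaf and node.parent is not None and node.parent.label is None:
            out.append(contract_arc(tree, node))
    return out


def cherry_contraction_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees obtained by contracting an arc ending in the parent of a
    cherry (the cherry's two leaves move up one level)."""
    out = []
    for node in tree.root.preorder():
        if node.parent is not None and _is_cherry_root(node):
            out.append(contract_arc(tree, node))
    return out


def uncle_regraft_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees obtained by pruning a leaf that is the sibling of a
    cherry's root and regrafting it inside the cherry (making a
    three-leaf fan), whenever the result is a valid tree without
    elementary nodes."""
    out = []
    for node in tree.root.preorder():
        if len(node.children) < 3:
            continue  # removing a child would leave an elementary node
        leaves = [c for c in node.children if c.is_leaf]
        cherries = [c for c in node.children if _is_cherry_root(c)]
        for x in leaves:
            for c in cherries:
                root2, mapping = _copy_pair(tree, x, c)
                x2, c2 = mapping
                x2.parent.children.remove(x2)
                c2.add_child(x2)
                out.append(PhyloTree(root2))
    return out


def _copy_pair(tree: PhyloTree, a: PhyloNode, b: PhyloNode):
    from .tree_model import _copy_with_map
    root2, mapping = _copy_with_map(tree.root)
    return root2, (mapping[id(a)], mapping[id(b)])


def _subtree_on(leaves_split) -> PhyloTree:
    """Binary subtree ((a,b),c) or ((a,b),(c,d)) from a nested label spec."""
    def build(spec) -> PhyloNode:
        if isinstance(spec, str):
            return PhyloNode(label=spec)
        return PhyloNode(children=[build(s) for s in spec])
    return PhyloTree(build(leaves_split))


def triplet_reorganization_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees obtained by rearranging a rooted triplet ((i,j),k) into
    one of its two alternative topologies."""
    out = []
    for node in tree.root.preorder():
        if node.label is not None or len(node.children) != 2:
            continue
        kids = node.children
        for c, x in ((kids[0], kids[1]), (kids[1], kids[0])):
            if _is_cherry_root(c) and x.is_leaf:
                i, j = (n.label for n in c.children)
                k = x.label
                for spec in (((i, k), j), ((j, k), i)):
                    out.append(replace_subtree(tree, node, _subtree_on(spec)))
    return out


def quartet_reorganization_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees obtained by rearranging a completely branched quartet
    ((i,j),(k,l)) into one of the two alternative balanced pairings."""
    out = []
    for node in tree.root.preorder():
        if node.label is not None or len(node.children) != 2:
            continue
        c1, c2 = node.children
        if _is_cherry_root(c1) and _is_cherry_root(c2):
            i, j = (n.label for n in c1.children)
            k, l = (n.label for n in c2.children)
            for spec in (((i, k), (j, l)), ((i, l), (j, k))):
                out.append(replace_subtree(tree, node, _subtree_on(spec)))
    return out
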