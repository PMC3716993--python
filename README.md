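# cophen

Cophenetic vectors and the `d_φ,p` metric family for rooted phylogenetic
trees, including weighted arcs and nested taxa.

## The problem

Alternative phylogenies for the same organisms — built from different
data, models, or reconstruction methods — need to be compared
quantitatively, and the safest comparison is a genuine metric: zero
distance exactly when the trees are isomorphic. Classical encodings fall
short of this on general trees: cophenetic values of *different* taxa
alone cannot distinguish some weighted trees, and patristic (nodal)
vectors are only a pseudo-metric once multifurcations appear.

`cophen` implements the cophenetic encoding that does work. For a rooted
tree *T* on taxa {1,…,n} with strictly positive arc weights (weight 1
when unweighted), possibly with *nested taxa* (labeled internal nodes)
and an unlabeled elementary root, define

- δ(i) — the depth of taxon *i* (weighted distance from the root),
- φ(i,j) = δ([i,j]) — the depth of the lowest common ancestor of *i*
  and *j*, with φ(i,i) = δ(i).

The **cophenetic vector** φ(T) = (φ(i,j))_{i≤j} ∈ ℝ^{n(n+1)/2}
(lexicographic order) characterizes the tree up to isomorphism, so each
L^p norm induces a metric

    d_φ,p(T₁, T₂) = ‖ φ(T₁) − φ(T₂) ‖_p        (p ≥ 1)
    d_φ,0(T₁, T₂) = Hamming distance of the two vectors

computable in O(n²). Patristic distances and splitted path lengths are
linear images of φ — d(i,j) = δ(i)+δ(j)−2φ(i,j) and
ℓ(i,j) = δ(i)−φ(i,j) — so the package derives the classical nodal and
splitted nodal metrics from the same encoding, and also provides
Robinson–Foulds, exhaustive enumerators and exactly-uniform samplers for
the tree spaces BTₙ (binary), Tₙ (multifurcating, no nested taxa) and
UTₙ (nested taxa allowed), and experiment drivers for rank-correlation
and distance-distribution studies.

## Worked example

The 7-taxon tree `((5,6),((2,(1)7),(3,4)));` has taxon 7 *nested*: node
7 is internal with child 1.

```python
>>> from cophen import parse_newick, cophenetic_vector, d_phi_p
>>> t = parse_newick("((5,6),((2,(1)7),(3,4)));")
>>> v = cophenetic_vector(t)
>>> v.get("1", "1"), v.get("1", "2"), v.get("1", "7"), v.get("5", "6")
(4.0, 2.0, 3.0, 1.0)
```

Taxon 1 sits at depth 4; the lowest common ancestor of 1 and 2 has depth
2; the LCA of 1 and its ancestor-taxon 7 is node 7 itself, depth 3.
Distances:

```python
>>> d_phi_p(parse_newick("((1,2),3);"), parse_newick("(1,2,3);"), p=1)
3.0
```

Contracting the arc above a cherry changes the three entries φ(1,2),
δ(1), δ(2) by one each — the minimum nonzero Manhattan distance on any
Tₙ (n ≥ 3).

The same operations are available from the shell:

```
$ cophen dist a.nwk b.nwk --metric phi-1
3.000000
$ cophen experiment correlations --space BT --n 6
```

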