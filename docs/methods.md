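# Methods

## Tree model

A phylogenetic tree here is a rooted tree with strictly positive arc
weights and a partial node labeling that is bijective onto the taxon set
and covers every leaf and every non-root elementary (out-degree-1) node.
Labeled internal nodes are nested taxa. An *unlabeled* elementary root
is permitted; we place no extra restriction on the weight of its single
outgoing arc, since nothing in the theory requires one. Unweighted trees
are identified with weight-1 trees, so a missing Newick branch length
parses as 1.0. Newick comment blocks are rejected rather than silently
stripped, to avoid ambiguity about whether a bracketed token was data.

Isomorphism is decided through a canonical form: the recursive
serialization `(label, incoming weight, sorted children keys)`. Two
trees on the same taxon set are isomorphic iff their keys are equal;
the canonical Newick writer sorts children by this key, so output is
deterministic and `parse ∘ write` is the identity up to isomorphism.
Weights inside the key are rounded to 12 significant digits (also the
serialization precision); unweighted (integer) trees therefore compare
exactly, and real-weighted trees at the precision of their
serialization.

Taxon order — the order of the cophenetic vector — is numeric when every
label is an integer literal, lexicographic otherwise.

## Cophenetic encoding

φ(T) is computed in O(n²): one preorder pass assigns depths; one
postorder pass walks each node v with child taxon blocks B₁…B_k (plus
v's own label, whose LCA with every proper descendant is v), assigning
depth(v) to every cross-block pair. Each unordered pair is touched
exactly once. The diagonal entries are the taxon depths, interleaved at
their lexicographic positions.

`d_phi_p` takes any real p ≥ 1 (p-th roots by floating power); `D_p`
(the p-th power, or the Hamming count at p = 0) avoids root-induced
error and is accumulated in exact integers whenever the entry
differences are integral and p is an integer — the extreme-value
statements (minimum 1 on UTₙ, 3 on Tₙ, 4 on BTₙ) are exact integer
facts. `d_phi_0` uses tolerance 0 by default; for real-weighted trees a
caller-supplied eps (we suggest 1e-9) decides when two entries count as
equal — the theory assumes exact real arithmetic and fixes no tolerance,
so this is a package choice.

Patristic distances and splitted path lengths are derived from φ via
d(i,j) = δ(i)+δ(j)−2φ(i,j) and ℓ(i,j) = δ(i)−φ(i,j); the reference
nodal metrics (L¹/L² on unordered patristic pairs) and splitted nodal
metrics (L¹/L² on ordered ℓ pairs) reuse the cached encoding, sharing
the O(n²) per-tree work across all five metrics of an experiment.
Nodal vectors are raw path lengths, not normalized — the linear relation
to φ requires it. Robinson–Foulds includes *all* clusters (the
descendant-taxon set of every node); the trivial clusters are present in
both trees and cancel, so the convention does not change values but is
stated for reproducibility.

## Tree spaces

* BTₙ is enumerated by sequential leaf insertion (leaf k has 2k−3
  attachment positions), giving (2n−3)!! trees, and sampled uniformly by
  the same insertion process with equiprobable positions.
* Tₙ is enumerated by set partitions (children carry disjoint taxon
  sets, so no deduplication is needed) and counted by the forest
  recurrence f(0,0)=1, f(m,k)=Σ_s C(m−1,s−1)·t(s)·f(m−s,k−1),
  t(m)=Σ_{k≥2} f(m,k), all in arbitrary-precision integers. The uniform
  sampler unranks against these exact counts (root child-count k with
  weight f(n,k); the block containing the smallest unplaced label with
  its exact weight), so it is exactly uniform with no floating bias.
  Integer draws use `random.Random`, which produces unbiased big
  integers; every sampler is deterministic under an explicit seed.
* UTₙ (nested taxa, unlabeled elementary root allowed) is enumerated by
  recursive construction — root labeled or unlabeled, children
  partitioning the remaining labels, elementary unlabeled nodes allowed
  only at the global root — deduplicated by canonical key, and guarded
  to n ≤ 5 (the space grows very fast and no experiment samples it).
  Note that Tₙ, following the counting convention of its recurrence,
  contains no elementary nodes at all (|T₆| = 2752), while UTₙ admits
  the elementary root.

## Experiments

Exhaustive correlation runs compute all pairwise distances per metric
(vectorized over stacked encodings), then Spearman's rank correlation
with mean (fractional) ranks for ties — distance tables are heavily
tied, so tie handling is load-bearing. **Pair convention:** exhaustive
tables include the identical-tree pairs (each tree with itself, distance
zero under every metric) by default. Both conventions are implemented
(`include_self_pairs`); with self-pairs the BT₆ and T₆ tables agree with
the published six-decimal values to ~5e-7, while distinct-pairs-only
shifts several coefficients by up to 6e-3, which is how the convention
was identified. The convention is recorded in each run's metadata.

Sampled runs draw i.i.d. uniform tree pairs in batches (default 10⁴),
recompute all coefficients after each batch, and stop when every
coefficient is unchanged to 3 significant digits across two consecutive
batches, up to a configurable pair budget (default 10⁶, reproducible
under the run seed). 2D histograms use a fixed 25×25 grid over each
metric's observed range; distribution summaries report the standardized
third-moment sample skewness and refuse degenerate (constant) inputs.

Minimum-value searches are brute force over a whole enumerated space and
return every minimizing pair; the companion neighbor constructions
(pendant-arc contraction; cherry-parent contraction and uncle regraft;
triplet and branched-quartet reorganization) let the tests verify that
the minimal pairs are exactly the ones those operations generate.
Diameter growth is recorded as a diagnostic only (empirical diameters
for n = 3..6 against n³); the exact diameter constants are not asserted,
only the growth order is monitored.

## Problem sizes and what the tests show

The suite exercises: the 7-taxon worked example (all 28 entries);
exhaustive spaces up to BT₆ (945 trees, 446 985 pairs with self-pairs)
and T₆ (2752 trees, ~3.79M pairs); brute-force oracles on BT₅/T₅
(ancestor-set LCA, graph-path patristic, laminar-family RF); 1000 random
BT₁₀ pairs for norm dominance; 100 random host/plug instances for
locality; χ² uniformity of both samplers against full enumeration of
BT₄ and T₄ (15 000 and 26 000 draws, α = 0.001); 10⁵ sampled T₁₀ pairs
for distribution skewness; and a BT₁₀₀ sampled correlation run to
convergence. All inputs are enumerated or generated — the study needs no
external data, so the generators *are* the study conditions, and the
passing tests speak exactly to those spaces: uniform topologies with
unit weights. Real phylogenies have non-uniform shapes and real branch
lengths; the metric properties (injectivity of φ, metric axioms,
locality, dominance) are topology-level facts that carry over, but the
correlation values themselves are properties of the uniform
distributions only.

## Known limitations

* Unrooted trees, networks, rerooting, and polytomy resolution are out
  of scope; L^∞ is not offered (the family is p ∈ {0} ∪ [1, ∞)).
* UTₙ sampling is not implemented (no experiment requires it).
* RF correlations at n = 100 hover near zero; their sign is sampling
  noise and should not be interpreted.
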