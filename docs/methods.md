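# Methods

This note records the definitions, conventions and design choices
behind `netpat`, in the order the pipeline uses them.

## Pattern space and canonical ids

A pattern is an isomorphism class of weakly connected, self-loop-free,
binary directed graphs on k nodes.  Mutual arcs (i→j and j→i) are
allowed; multi-arcs and self-loops are not, so the adjacency matrix A
is binary with a zero diagonal.  A labeled digraph is encoded by
reading A row-major, most-significant bit first: entry (i, j)
contributes 2^(k²−(k(i−1)+j)).  The canonical id of a pattern is the
minimum encoding over all k! relabelings, which matches the
conventional decimal naming of small directed motifs (id 38 =
feed-forward loop, id 6 = single-input module, id 12 = cascade, id 36
= multiple-input module, id 98 = 3-cycle, id 238 = complete 3-node
digraph).  Exhaustive enumeration scans all 2^(k(k−1)) off-diagonal
bit assignments and keeps weakly connected canonical representatives;
the expected class counts are 2, 13, 199 and 9,364 for k = 2…5.  For
k = 5 the orbit minimum of every code is computed with per-permutation
bit tables vectorized over the whole 2²⁰ code space (numpy uint32
shifts/masks), followed by a vectorized k−1-round neighborhood
expansion for the connectivity filter; the full enumeration takes a
few seconds on one core.  Six-node patterns (1.5 M classes) are out of
scope.

## Census

Occurrences are **induced** subgraphs on weakly connected k-node
subsets.  Subsets are enumerated with the ESU scheme (recursive
extension through exclusive neighbors with a higher root index), which
visits each connected subset exactly once and avoids the C(n, k) scan;
a brute-force subset classifier is retained as the test oracle and the
two agree exactly on seeded random networks up to n = 12.  Each
subset's induced matrix is classified by canonical id, and the stored
node order is the relabeling that realizes the canonical
representative (ties between relabelings broken by lexicographic node
label), so each gene can be placed at its pattern position.  Two
occurrences of the same pattern may share nodes; both are counted.  A
subset whose induced graph is disconnected belongs to no pattern.
Frequency distributions are normalized over the *full* catalog, absent
patterns receiving probability 0.

## Spectral descriptors

For a pattern with adjacency A, total-degree diagonal D (in-degree +
out-degree), Laplacian L = D − A and signless Laplacian Q = D + A:

* E = Σ|α_i| over eigenvalues of A (moduli; spectra of asymmetric
  patterns are complex and come in conjugate pairs, and Σα_i = 0);
* LE, QE = Σ|eigenvalues of L resp. Q| − 2e/n;
* generalized energies for M, N ∈ {A, L, Q}: Σ√|λ_i(M·Nᵗ)|, with no
  −2e/n shift.  For M = N this is the sum of singular values of M
  (Schatten 1-norm); the asymmetric pairs ALᵗ, AQᵗ, LQᵗ extend it.
  Eigenvalues of M·Nᵗ and N·Mᵗ coincide, so the pair order does not
  matter.

Two conventions deserve emphasis because plausible alternatives fail:
D uses **total** degree (out-degree-only does not reproduce the
reference energy values of the complete digraph), and the generalized
energy takes **square roots** of eigenvalue moduli of the product (the
plain eigenvalue-modulus sum does not reproduce LQᵗ = √12 + 2√15 ≈
11.21 for id 238).  The published 13×9 reference table for 3-node
patterns is reproduced at the printed 2-decimal precision in 114 of
117 cells; three cells (LQᵗ of ids 38 and 102, AQᵗ of id 110) differ
by exactly one unit in the last printed digit and appear to be
rounding slips in the source, so table-wide regression tests use a
one-ULP tolerance (0.0105) while spot checks use 0.005.

Spectra are ordered by descending real part, then descending imaginary
part, and compared element-wise with tolerance 1e−6.

Converse patterns (all arcs reversed) share all nine energies exactly
— D is invariant and transposition preserves eigenvalue sets of the
products — which accounts for identical descriptor rows such as ids 46
and 108.  The genuinely equienergetic pairs (6, 36) and (14, 74) agree
on all nine energies to 1e−9.

## Reciprocity, cyclomatic complexity

Traditional reciprocity R = L↔/L is the fraction of arcs with a
reversed partner.  It is implemented exactly as defined; note that the
published reference column prints 0 for several patterns that contain
mutual dyads (ids 14, 46, 74, 102, 108, 110), which contradicts the
definition (their r > 0 confirms the bidirectional links).  The
definitional values are used and the discrepancy is only documented.

Correlation reciprocity r is the Pearson-style correlation between
mirror off-diagonal entries, with ā the off-diagonal mean.  On the
complete digraph all off-diagonal entries equal ā and the defining
ratio is 0/0; since the edge set is exactly symmetric there, r is
defined as 1.  Both measures require e ≥ 1.

CC = e − N + 2P with P = number of out-degree-zero (exit) nodes.
This reading of P is the only one consistent with the full set of
reference values (sink-free cycles must give CC = 0, the two-output
SIM must give CC = 3).

## Algorithmic complexity (KC)

KC estimation is a pluggable backend (`ComplexityBackend`: a
`complexity(bits) -> float` plus name/version).  The default backend
is a context-tree-weighting (CTW) universal code: the complexity of a
bit string is the ideal code length −log₂ P(s) under the CTW mixture
over binary tree sources up to depth 6, with Krichevsky–Trofimov leaf
estimators, a zero-padded past, and exact rational arithmetic (fully
deterministic).  Matrices are serialized as their row-major bits
followed by their column-major bits: the doubled scan exposes both row
and column regularities to the 1-D code, and with it the backend
assigns pairwise distinct values to all 13 three-node and all 199
four-node patterns (a single row-major scan leaves a dozen four-node
collisions).  KC values are backend-conditional by nature — estimates
from other calculators based on precomputed small-machine frequency
tables differ in scale and in detailed ranking — so the tested
contract is distinctness and coarse ordering (sparse regular patterns
below dense irregular ones), not specific values.

## Unique identifiers

Patterns are grouped by equality of a descriptor combination (floats
within tolerance 1e−6 on full-precision values; spectra element-wise
after canonical ordering).  Two counts are exposed: the number of
equivalence classes and the number of singletons, because published
distinguishability tables mix the two readings in places; `classes` is
the default and matches the cells that can be verified from the energy
table (E → 7, LE → 6, AAᵗ → 10 for the 3-node catalog).  Case presets:
A = {energy}, B = {energy, r, CC}, C = B + spectrum of the same
matrix (product).  The greedy search adds at each step the candidate
maximizing the class count, breaking ties by candidate order, and
stops when the count stops increasing or every pattern is a singleton.
The tie-break and stopping rules are this package's own choices.

## Functional subgraphs and irreducibility

A functional subgraph of a pattern is obtained by choosing a node
subset and any subset of its induced edges such that the result spans
the subset and is weakly connected; at the pattern's own size the
pattern itself is excluded (proper containment).  A pattern with no
same-size functional subgraph is irreducible, which is equivalent to
having exactly k−1 edges (tree support): {6, 12, 36} at k = 3 and the
eight patterns {14, 28, 74, 76, 280, 328, 392, 2184} at k = 4.  Every
one of those eight embeds at least one 3-node functional pattern —
irreducibility does not persist at the smaller size — and the pure
star/chain forms (14, 328, 2184) embed exactly one; the five mixed
trees embed two.  Containment is transitive and is tabulated as a
binary container × contained matrix.

## Entropy, ranks, enrichment

Shannon entropy H = −Σ p log₂ p (bits, 0·log 0 = 0) of the pattern
frequency distribution is normalized by log₂(13) or log₂(199), so the
uniform distributions give exactly 3.700 and 7.637 bits and H_R ∈
[0, 1].  Rank columns use ascending competition ("minimum") ranks —
rank = 1 + number of strictly smaller values — and rank correlations
are Pearson correlations of the rank vectors.

The subgraph module of a network is the node set covered by at least
one 3- or 4-node occurrence (membership is node-level: one occurrence
suffices).  Genes are cross-classified as driver/non-driver ×
module/non-module, and enrichment is OR = (a·d)/(b·c).  When any cell
is zero the OR is degenerate, so a pseudo-count (default 1) is added
to **all four** cells in that case only; both the magnitude and the
all-cells application are configurable since conventions vary.

## Synthetic networks

`random_digraph` draws, for every unordered node pair, one of {no
edge, i→j, j→i, mutual} with the mutual probability m = r·p(1−p) + p²,
which makes the expected density p_edge and the population correlation
reciprocity equal target_r; infeasible (p, r) combinations are
rejected.  Dyad-level sampling is necessary: independent arc sampling
fixes r = 0.  Generator defaults for the recovery tests — n = 200,
p_edge = 0.05, 20 replicates — mirror the size regime of curated
pathway networks (tens to ~160 nodes, sparse).  The generator emulates
density and reciprocity only; it has no degree hubs, no community
structure and no biological edge semantics, so passing recovery tests
demonstrates correctness of the estimators, not realism of any
particular biological network.  `planted_pattern_network` lays pattern
instances on disjoint node sets (exact census ground truth, one
occurrence per instance); optional background dyads are separate
two-node components, which cannot create or join occurrences at k ≥ 3.

## Problem sizes and numerics

Default test and acceptance runs use: full catalogs up to k = 5
(seconds, vectorized); censuses on networks of ≤ 200 nodes; 50 seeded
oracle networks with n ≤ 12; 20 reciprocity replicates at n = 200.
Eigenvalues come from `numpy.linalg.eigvals`; energies are compared at
1e−9 where exact equality is structural (equienergetic and converse
pairs) and at printed precision against reference tables.  Degenerate
inputs raise typed errors (empty networks, edgeless reciprocity,
zero-probability distributions, infeasible generator configs) rather
than returning sentinel values.

## Known limitations

* Catalog enumeration stops at k = 5; censuses are practical for
  k ≤ 4 on hundreds of nodes (the subset count, not the classifier,
  is the bottleneck beyond that).
* The KGML reader extracts topology only (entries and relations);
  relation subtypes, compound mediation and multi-gene entry semantics
  beyond the first listed name (or `expand_entries`) are ignored.
* KC values are not comparable across backends; only within-backend
  comparisons (ranking, distinctness) are meaningful.
* Network-level empirical claims about specific pathway collections
  (which patterns dominate real cancer networks, their entropy medians,
  driver-gene odds ratios) require the external pathway and gene-census
  data and are outside the test surface; the package computes the
  statistics, not those datasets.
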