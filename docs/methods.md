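# Methods

`motifclust` quantifies how network motifs — small, statistically
overrepresented subgraphs such as the feed-forward loop (FFL) and the
feedback loop (FBL) — are organized into larger structures in directed
networks. This note records the model, its assumptions, the defaults, the
numerical choices, and the limits of what the test suite demonstrates.

## Substrate and matching semantics

The universal substrate is a **simple directed graph** with opaque string
node labels: no weights, signs, multi-edges or self-loops. Self-loops and
duplicate edges are removed at load time with logged counts, because every
definition below assumes a simple digraph; users who need to audit this
preprocessing can read the counts from the log.

Motif occurrences use **induced** matching throughout: an occurrence is a
node set whose induced subgraph equals the pattern exactly, found with the
VF2 matcher and deduplicated up to pattern automorphism, so the set of
found motifs F = {f_1, …, f_n} is literally a set of node sets. Induced
semantics is not optional here — it is the only convention under which the
pairwise overlap taxonomy is finite and total (see below), and under which
two FFLs sharing two nodes always have a 4-node/5-edge union and two
sharing one node a 5-node/6-edge union. Non-induced ("at least these
edges") matching would let a node set host several overlapping role
assignments and break the classification's totality.

## Motif clustering coefficient

For the found motifs F,

    Mc = S / T,
    S  = Σ_{i<j} |f_i ∩ f_j|,
    T  = Σ_{i<j} (min(|f_i|, |f_j|) − 1),

the observed shared-node count over the maximum possible (two distinct
motifs can share at most min(|f_i|,|f_j|) − 1 nodes). For a single pattern
of size |M| this gives the closed form T = C(n,2)(|M|−1). Mc = 0 means
fully isolated motifs; Mc = 1 means every pair is fully clustered.

Two deliberate numerical choices:

* **The −1 applies per pair.** In the cross-type denominator the
  subtraction is applied inside each pair's term,
  T_ij = Σ (min(|f_ia|,|f_jb|) − 1), keeping the single-type closed form
  and the decomposition below consistent.
* **Cross-type sums run over all |F_i| × |F_j| pairs** when i ≠ j, and
  over unordered within-type pairs (a < b) when i = j. With equal-size
  motifs this makes S and T decompose exactly into homologous
  (same-type, Mc+) plus heterologous (cross-type) parts.

Undefined ratios (T = 0, e.g. fewer than two motifs) are reported as NaN
with a warning, never as 0 — zero is a meaningful measurement.

## Pairwise clustering types

Two clustered instances define a union graph: their own edges on the union
of their node sets. The catalog of possible union graphs is generated by
enumerating every injective identification of ≥ 1 node between two pattern
copies such that **each copy remains induced in the union** — this forbids,
for instance, antiparallel identification of a shared edge — and
deduplicating by canonical labeling (exhaustive permutation minimization,
exact and cheap at ≤ 6 nodes). For {FFL} this yields exactly 12 types (six
one-node, six two-node); for {FBL} exactly 2; mixed FFL+FBL catalogs add
the cross-pattern overlap graphs.

FFL type numbering follows the published taxonomy anchors (type 6 =
shared input, type 4 = shared intermediate, types 7/10/12 = duplicated
input/intermediate/output, type 9 = three-level hierarchy with linked
intermediates, types 1/2 = shared-sink forms); the remaining ids follow
the fixed role-pair order documented in `motifclust.motiftypes`. Any
pattern structurally isomorphic to the FFL inherits this numbering;
other catalogs are ordered by shared-node count, then canonical
certificate.

**Classification is a descriptor lookup, not an isomorphism search.** The
role-pair identification descriptor of a clustered pair determines its
union graph up to isomorphism, so each catalog entry records the
descriptors that generate it and classifying a pair is O(1). The explicit
union-graph-isomorphism route is retained as an independent oracle in the
tests, which verify the two routes agree on random networks. Because both
instances are induced, their edges agree on shared nodes and every
clustered pair maps to exactly one catalog entry; a failed lookup is an
internal error, not a data condition. The pair subgraph deliberately
excludes bystander network edges between non-shared nodes — including them
would make classification depend on context outside the two motifs.

## MCD and node spin

The **motif clustering diversity** of a node is computed by extracting all
motifs that contain the node, classifying every pair of those motifs, and
counting the distinct types. Note both motifs of a counted pair contain
the node; a node inside a single motif has MCD 0 even if that motif is
clustered with others. MCD is bounded by the catalog size (12 for {FFL}).

**Node spin** is (k_in − k_out)/(k_in + k_out): −1 for pure sources
(producers), 0 for balanced relayers, +1 for pure sinks (receivers).
The sign convention (sinks positive) is fixed here because it cannot be
recovered from a histogram alone. Isolated nodes have undefined spin and
are excluded from distributions with a logged count. The default
histogram uses 21 bins positioned so −1, 0 and +1 are bin centers, which
keeps the three pure classes visually separated.

## Null models

* **Erdős-Rényi**: every ordered pair is an edge with fixed probability p.
  The induced-FFL census expectation, 6·C(n,3)·p³(1−p)³, is used as a
  calibration oracle in the tests.
* **Duplication growth**: start from a template motif; repeatedly pick a
  node (uniformly, or weighted per template role) and add a copy with the
  same in- and out-neighborhood. The copy gains no edge to its
  originator, since plain neighborhood copying is the minimal model and
  any originator-copy edge would be an additional mechanistic assumption.
  Duplicating a motif member always creates a new instance of the same
  pattern fully clustered with the original; because duplication
  preserves role lineages, a growth run seeded with an FFL puts type mass
  only on the role-diagonal types {1, 4, 6, 7, 10, 12}, with the
  two-node types 7/10/12 as the characteristic duplication signature.
* **Degree-preserving randomization**: directed double-edge swaps
  (a→b, c→d) ⇒ (a→d, c→b), rejecting self-loops and duplicates; in- and
  out-degrees are preserved exactly. Default 10 attempted swaps per edge,
  a common mixing heuristic; this is the default null for motif-count
  significance. Note that some degree sequences pin the motif count
  entirely (e.g. a star of FFLs on a shared input), in which case the
  null is degenerate and the z-score sentinel logic applies.
* **Motif-count-preserving rejection sampling**: build a network with the
  same node, edge and motif counts by placing motif copies on uniformly
  drawn node tuples, then filling in the remaining edges at random;
  restart whenever either count overshoots, or when edge placement
  destroys induced instances so the target can no longer be met. The
  placement granularity (whole motifs on uniform tuples) and the restart
  budget (default 10,000, always named in the failure error) are
  configurable since the scheme itself does not dictate them. This is
  the default null for Mc significance: it asks whether the *clustering*
  exceeds chance given the number of motifs present.

Significance is a standard z-score using the sample standard deviation
(n − 1); a degenerate null (sd = 0) yields a signed-infinity sentinel with
a warning (0 when the observed value equals the null mean). An empirical
one-sided p, (r + 1)/(n + 1) with r = #samples ≥ observed, is reported
alongside. Robustness analysis removes round(fraction·|E|) distinct edges
uniformly at random per trial and averages type-fraction vectors (all-zero
when no clustered pairs survive) and motif counts across trials.

## Enrichment

Whether a binary label (e.g. essentiality) concentrates at particular MCD
values is scored per MCD group with a fixed-margin hypergeometric model:
population N scored nodes, K labeled, group size n_g, so
z_g = (obs − n_g·K/N)/sd_hyp, with the moments in closed form and a
one-sided hypergeometric p alongside. A label-permutation null (default
10,000 shuffles) is exposed as a cross-check because the analytic model's
form is a modeling choice, not a given. Top-k comparison against total
degree and normalized directed betweenness uses threshold-inclusive
ties: everything tied with the k-th ranked value enters the set and the
effective k is reported, matching selection rules like "all nodes with
the maximal MCD".

## Fixtures

The fixture generator builds networks whose clustered pairs all realize a
single requested type, with ground truth (census, S, T, Mc, distribution,
per-node MCD) derived from the construction arithmetic rather than from
the analysis code. Diagonal types use stars on a shared node or edge;
off-diagonal one-node types use chains (non-consecutive motifs are
disjoint); off-diagonal two-node types (8, 9, 11) use disjoint two-motif
blocks, because chaining them provably creates extra one-node overlaps of
other types — requesting an odd k > 2 for these types is a validation
error explaining that constraint. Mixed fixtures are node-disjoint unions
of two-motif blocks, so cross-block pairs are disjoint and the achieved
composition is exact.

These fixtures exercise correctness, not realism: they have none of the
degree heterogeneity, reciprocity, or community structure of real
networks. Passing fixture tests shows the estimators compute their
definitions exactly; the random-digraph oracle tests show the same on
unstructured graphs; neither says anything about what values real
networks take.

## Problem sizes and limitations

Test and acceptance runs use desk-scale problems chosen to make the
brute-force oracles exhaustive: random digraphs up to 25 nodes are checked
triple-by-triple against the census, 200 Erdős-Rényi seeds at n = 50
calibrate the count expectation, 100 self-null repetitions with 30 null
samples calibrate the z-score, 60 duplication runs to 30 nodes establish
the signature, and robustness uses 50 trials on a ten-FFL fixture. Larger
runs (the published analyses used 500 robustness trials and 10,000-sample
nulls) are a matter of the same code with bigger parameters.

Known limitations:

* Patterns beyond a handful of nodes are unsupported in spirit: canonical
  labeling is exhaustive over permutations and pair enumeration is
  quadratic in the instance count, which is fine for 3–4-node motifs on
  desk-scale networks but not for large dense networks (the rejection
  sampler in particular scales poorly with edge density).
* Weighted, signed and temporal networks, motif generalizations beyond
  pairwise overlap, and analytic expected type distributions for the
  random models are out of scope; the generators plus Monte Carlo stand
  in for the latter.
* The rejection sampler can be genuinely infeasible for dense networks
  (the restart budget then fails loudly rather than silently biasing the
  ensemble).
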