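# Methods

## The kSIM model

kSIM formalizes a community as a connected union of *anchor dyads*. For
every non-isolated node v, rank its neighbors by a structural similarity
index; among the top k entries, the anchor is the neighbor with the
smallest degree (low-degree nodes are less likely to be hubs shared by
several communities). The graph whose edges are all {v, anchor(v)}
pairs decomposes into connected components — the seed communities.
Degree-0 nodes stay singleton communities throughout and are reported
separately.

Two local criteria then define a valid partition:

* **membership**: each node has strictly more neighbors in its own
  community than in any other single community;
* **community**: each community has strictly more internal edges than
  cut edges to any other single community (note: *any single other*, not
  the sum — a dense module may well have more total external than
  internal edges and still be a community).

Refinement alternates one membership sweep and community-criterion
enforcement until a full pass changes nothing. The reported iteration
count includes that final all-zero pass. On all bundled networks and on
LFR benchmarks up to μ = 0.5 convergence takes 2–4 passes;
`max_iterations` (default 100) is purely a safety net, and hitting it
flags the result as non-converged rather than raising.

## Determinism and tie-breaking

The method is deterministic by construction; every potential tie has a
fixed resolution:

* Node processing order: sorted node labels (string-keyed fallback for
  mixed types), mapped to indices 0..n−1.
* Neighbor ranking: similarity descending, then degree ascending, then
  node index ascending. Floating-point similarities closer than 1e−12
  (absolute) count as tied before the degree comparison, so platform
  rounding cannot reorder ranks.
* Anchor choice within the top-k window: smallest degree, then the
  earlier-ranked (more similar / smaller index) candidate.
* Membership sweep: sequential, ascending node index, updates in place.
  A node tied for the plurality keeps its current community if that is
  among the winners; otherwise it follows its most similar neighbor
  among the winning communities. Label propagation along the similarity
  ranking is the package's own choice here: it resolves ties by the same
  principle that built the seed partition, and on the classic networks
  it is what keeps structurally ambiguous boundary nodes (e.g. the two
  contested members of the karate club) on the side their strongest tie
  points to.
* Merging: communities are scanned in ascending (size, label) order; the
  first violator is merged into the partner with the largest cut. On
  equal cut the partner with the *smaller* internal edge count wins —
  for that community the shared edges weigh most, which keeps small
  sibling fragments merging with each other instead of being swallowed
  by the largest community — then the smaller label. Counts are updated
  incrementally and the scan restarts after every merge.

Sequential (in-place) sweeps were chosen over synchronous updates
because they converge fast and cannot oscillate; order-independence on
tie-free graphs is verified by a relabeling-invariance test rather than
assumed.

## Similarity indexes

The default index `cn_closed` counts common members of closed
neighborhoods, |N[u] ∩ N[v]|: it orders pairs exactly like plain common
neighbors but never degenerates to all-zero on triangle-free regions
(adjacent pairs always score ≥ 2). Also selectable: open-neighborhood
`cn`, and the normalized link-prediction family jaccard, salton
(cosine), sorensen, hpi (hub-promoted), hdi (hub-depressed),
adamic_adar, resource_allocation. All are symmetric, non-negative, and
zero for pairs with no neighborhood overlap. The default reproduces the
reference results on the karate club exactly; on the football schedule
network the degree-penalizing indexes (adamic_adar,
resource_allocation) recover the 12 conferences more cleanly, which
matches the intuition that shared low-degree neighbors (round-robin
conference mates) are more informative there.

## Quality measures

All structural measures derive from one exact integer edge-count matrix
(internal counts on the diagonal, cut counts off it) normalized to the
edge-fraction matrix: Q = Σ(e_ii − a_i²); coverage = Σ int/m;
MinMaxCut = Σ ext/int, with a community that has external but no
internal edges making the measure undefined (error, or +inf under the
permissive flag). MinMaxCut is oriented external-over-internal so that
smaller values mean better-separated, denser communities (a zero-cut
partition scores 0).

NMI uses the arithmetic normalization 2I/(H(X)+H(Y)) (the geometric
√-variant is selectable); the computation is delegated to
scikit-learn's `normalized_mutual_info_score` after mapping both
partitions onto a common node order, and small-case values are verified
against closed forms in the tests. Two single-community partitions get
NMI 1; a partition carrying no information gets 0. Logarithm base is
irrelevant after normalization.

## Synthetic benchmarks

`generate_lfr` emulates the LFR benchmark family with a two-level
configuration model rather than the original rewiring machinery: it
reproduces the three marginals that drive recovery experiments — degree
distribution (truncated power law, exponent gamma on [kmin, kmax],
defaults 2.0 on [15, 25]), community-size distribution (exponent beta
on [smin, smax], defaults 1.0 on [20, 100]; smin must exceed kmin), and
per-node mixing (each node gets round((1−μ)·d) internal stubs, at least
one internal and, for μ > 0, one external). Internal stubs are matched
within communities and external stubs globally, rejecting self-loops,
duplicates and within-community external pairs, with up to 30 reshuffle
passes; residual unmatched stubs are dropped and logged (well under 1%
of stubs at N ≥ 1000). Mean realized mixing is within ±0.02 of the
requested μ for μ ≤ 0.6 at N = 1000.

What this generator does *not* model: degree–community-size
correlations beyond feasibility (a node whose internal degree fits no
open community is assigned to the largest one and its internal degree
capped, logged), guaranteed within-community connectivity (configuration
model communities of size ≥ 20 with internal degree ≥ 7 are connected
with overwhelming probability, but not by construction), and
overlapping or weighted variants. Passing recovery tests on these
benchmarks therefore demonstrates robustness to mixing and size/degree
heterogeneity, not to the full messiness of real data (degree
assortativity, clustering gradients, noisy annotations).

`generate_planted_partition` (equal-size blocks, Bernoulli p_in/p_out)
is the controlled fixture for unit tests.

## Problem sizes and runtime

Similarity computation is O(d²n) with d the maximum degree; community
formation O(m); refinement O(K·n + m) per pass with incremental merge
bookkeeping. The bundled classics run in well under a second. The
benchmark reproduction (`scripts/acceptance.py`) uses N = 5000 with 5
replicates at each of 5 mixing values — 25 detector runs, about a minute
total; the exhaustive modularity cross-check in the tests enumerates
every partition of every graph with ≤ 7 nodes (~950k cases, ~30 s).

## Known limitations

* Accuracy collapses once μ passes 0.5: with most of each node's edges
  external, the membership plurality no longer favors the planted
  community and the merge criterion folds everything together (NMI ≈ 0
  at μ = 0.6, N = 1000). This cliff is intrinsic to the two strict
  criteria, not a tuning artifact.
* The canonical football schedule file contains 616 edge records of
  which 3 are duplicates; as a simple graph m = 613, and quality values
  computed on it differ in the third decimal from values computed on the
  raw record multiset (e.g. modularity 0.601 vs 0.602 for the same
  partition).
* The dolphins and polbooks classics are catalogued with their known
  sizes but not redistributed here; `load_fixture` raises with
  provenance pointers instead.
* Hard partitions only: boundary (overlapping) nodes are assigned to
  exactly one side by the tie cascade, not emitted as overlaps.
* Only undirected, unweighted simple graphs; weights and directions in
  input files are ignored with a warning.
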