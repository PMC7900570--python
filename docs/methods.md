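# Methods

## Model and assumptions

A pathway is a finite directed graph. Nodes hold zero or more gene
products (HGNC symbols; one node may hold several, e.g. a protein complex
or an enzyme family, and several nodes may hold the same gene). Edges are
signed: activation, inhibition, or undefined. Terminal
"molecular-function" nodes represent physiological outcomes and hold no
genes. The annotation procedure assumes the graph is weakly connected —
roles are propagated relative to one reference point, so disconnected
fragments have no common frame; a `per_component` mode relaxes this by
annotating each weak component from its own central node.

The ARR coefficient is an ordinal role on the five-point scale
{−1, −0.5, 0, 0.5, 1}. It is pathway-centric: the same gene may be an
activator in one pathway and a repressor in another.

## Central-node selection

N and M are **transitive** reachability counts (descendants and
ancestors), not degrees. This choice degenerates gracefully on cycles —
in a directed cycle every node reaches every other, so all nodes tie and
the central node is a pure tie-break decision — and makes hubs on long
cascades win over locally dense but peripheral nodes. Ties are broken
lexicographically by node id by default; a seeded uniform draw is
available (`tie_break="random"`). Lexicographic is the default because it
makes annotation a pure function of the input, which matters for
regression-testing a knowledgebase.

## Propagation

Traversal is breadth-first from the central node. Both edge orientations
are followed (an edge into the current node is traversed "backwards" with
its stored sign unchanged): the role relationship an edge encodes is
symmetric in this respect — if A activates B, evidence about either
endpoint constrains the other the same way. Each edge is consumed at most
once, globally, which bounds edge-processing events by |E| and guarantees
termination on cyclic graphs.

Within one node expansion, unconsumed incident edges are processed in a
fixed order: outgoing first, then incoming, each block sorted by
(neighbour id, edge type, edge index). Results are order-sensitive at
conflicts, so the order is part of the contract; any fixed order would do,
this one is simply deterministic and explainable.

The proposal carried by an edge is, by default, the source node's role
times the edge sign (`propagation="multiplicative"`), so inhibition of an
inhibitor proposes activation — the biologically expected double-negation.
The alternative `edge_only` mode emits the edge sign alone regardless of
the source role; the two modes coincide for all nodes adjacent to the
central node. Undefined edges propagate the source sign unchanged by
default (`undefined_edge_policy="pass_through"`), preserving connectivity
through incompletely curated regions; `"skip"` consumes them silently.

## Conflict resolution and the stop rule

When a node or gene with a held role receives a differing proposal, rules
are checked in order: (1) equal — keep; (2) opposite signs — 0;
(3) difference ≤ 0.5 with a positive member — 0.5; (4) difference ≤ 0.5
with a negative member — −0.5; (5) otherwise keep the held value. Rule 5
makes 0 sticky against a ±1 proposal: an inconsistent role is not
rehabilitated by later evidence. Only the single currently-held value is
consulted (the full proposal history is logged in the trace but not used);
consulting the whole history would let one early sign conflict permanently
absorb the half-role rules.

Nodes resolving to 0 or ±0.5 are not expanded further. Without this rule
a single inconsistency would propagate 0 everywhere. A consequence is
that genes lying exclusively behind stopped nodes are never annotated;
they are reported in `excluded_genes` rather than silently dropped.

Note that under ±1 proposals the half-roles ±0.5 cannot arise from the
propagation itself — they require a held ±0.5, which first arises only if
conflict resolution is entered with mixed half/full values (e.g. roles
imported from a curated genes worksheet, or direct use of
`resolve_conflict`). The rules are implemented and tested in full
regardless, since imported knowledgebases do carry half-roles.

## Micropathways

The bound "paths of length 3" counts **edges** and is an upper limit: the
retained set is every node whose directed distance *to* the function node
is ≤ `max_len` (default 3), which equals the union of nodes on directed
paths of ≤ 3 edges ending there. All edges induced between retained nodes
are kept, including chords not on any qualifying path, so a micropathway
is a self-consistent graph that can be re-annotated on its own. When no
node is explicitly flagged as a function node, a reader heuristic treats
gene-less nodes with no outgoing edges as outcomes.

## CNR and PAL

Case-to-norm ratios use the arithmetic mean of the control samples, with
both numerator and control mean floored at ε = 10⁻⁸ (configurable) so
zero counts never divide; consequently CNR is strictly positive and its
log finite. Node activation is the sum of log₁₀ CNR over a node's genes.

The PAL formula is this package's own choice among the family of
ARR-weighted scores: the ARR-weighted **mean** of per-gene log₁₀ CNR,
normalized by Σ|ARR|. The normalization makes PALs comparable across
pathways of different sizes and gives the identities the tests rely on:
PAL = 0 when all CNR = 1; a uniform 10-fold up-shift of an all-activator
pathway adds exactly 1; |PAL| never exceeds the largest |log₁₀ CNR|. The
raw weighted sum is available (`normalized=False`), as are log bases 2
and e. Genes with ARR = 0 contribute to neither sum; genes absent from
the expression matrix are skipped, with a warning when fewer than half of
a pathway's annotated genes are present.

## Synthetic fixtures

The generators produce the structures the algorithm's correctness
arguments rest on, with analytically known ground truth:

* **Signed out-trees** (uniform random attachment; inhibition probability
  per edge; one gene per node). The true role of each node is the product
  of edge signs along its root path. Non-root nodes are named to sort
  after the root so that the root — which always attains the maximal
  N+M on an out-tree but may tie with a path-child — is the deterministic
  central node, keeping the stored ground truth valid.
* **Directed cycles** with random signs: every node ties on N+M by
  symmetry, exercising tie-breaking and the edge-once termination bound.
* **Expression matrices for a target PAL**: controls sit at a baseline of
  100 arbitrary units; each case value for gene *g* is
  100·10^(ARR_g·target). With zero noise the recovered PAL equals the
  target exactly (machine precision); optional noise is Gaussian on the
  log₁₀ scale (multiplicative lognormal on the raw scale, keeping
  expression nonnegative), applied to cases only so the control mean stays
  at baseline.

These fixtures deliberately do not emulate real transcriptomes — no
library-size variation, dispersion structure, correlated genes or missing
measurements — so passing tests demonstrate algorithmic correctness, not
robustness to real-data noise.

## Problem sizes and tolerances

The oracle-equivalence checks run 200 random graphs (≤ 30 nodes) against
brute-force transitive closure and 200 random signed trees against an
independent path-sign oracle; termination is checked on cyclic graphs up
to 100 nodes plus a 60-node cycle with 120 random chords; round-trip I/O
on 100 random pathways; noise-free PAL recovery is asserted to 10⁻⁹
absolute, noisy recovery (σ = 0.1 on log₁₀, 30 cases) to within three
standard errors of the mean. These sizes keep the whole suite under a few
seconds while exercising every code path.

## Known limitations

* The half-role bootstrap issue above: pure ±1 propagation can only
  produce {−1, 0, 1}; ±0.5 enters through imported annotations.
* No reconciliation of the same pathway across source databases, no
  cross-pathway crosstalk, no statistical significance for PALs
  (permutation or bootstrap), and no topological weighting of genes
  beyond the ARR sign.
* The file formats are the plain-CSV worksheet triplet described in the
  README; spreadsheet workbooks and BioPAX/SBML/KGML are out of scope.
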