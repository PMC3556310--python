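# Methods

`shredmod` implements a flux-weighted, cycle-preserving modularity analysis
for reaction-centric metabolic networks.  This note describes the model and
its assumptions, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic test networks
do and do not show about real data.

## The graph model

A metabolic network is represented as a directed graph whose nodes are
reactions and whose edges are metabolite-mediated producer→consumer
interactions: an edge R_i → R_j exists whenever R_i produces an internal
metabolite that R_j consumes.  Metabolites are treated as shared resources,
not module members, so cofactors (ATP, NAD(H), NADPH, CoA, …) are
deliberately *retained* as edge mediators — they carry exactly the
long-range cyclical couplings this analysis is designed to expose.
Metabolites that are only ever produced or only ever consumed anywhere in
the model are classified as external pools: they take part in no
steady-state balance and mediate no edge.  Reversible reactions carrying
negative flux are direction-canonicalized (stoichiometry negated, flux sign
flipped) before any graph is built, so all fluxes are nonnegative.

Three edge-weighting schemes are supported:

* **unit** — every edge has distance 1; pure topology.
* **flux** — the distance of an edge into R_j via metabolite M is the
  inverse of R_j's fractional draw on M's total production flux:

      D_ij = (Σ_k v_k · c_k) / (v_j · |c_j|)

  where k runs over M's producers and c are stoichiometric coefficients
  (a consumer taking 2 units per turnover draws a double share).  The pool
  is assumed homogeneous: every producer projects the same distance onto a
  given consumer, regardless of how production is split among producers.
  At steady state the reciprocal distances of a metabolite's edges sum to 1
  over its consumers.  Reactions with flux below `zero_tol` (default 1e-9,
  a numeric floor for division) keep their node but contribute and draw no
  edges.
* **degree** — the distance is the number of distinct reactions consuming
  the mediator, a static proxy for how contested the pool is.

When several metabolites mediate the same ordered reaction pair, the
minimum distance is kept (the strongest interaction; under shortest-path
semantics the longer parallel edges can never matter).  Distance ties are
broken by lexicographic metabolite id so provenance is deterministic.

## ShReD and its cap

The Shortest Retroactive Distance of a pair (i, j) is the exact shortest
directed path length i→j plus the shortest return path j→i — the tightest
cyclical interaction through both nodes.  The two legs may share edges; no
simple-cycle restriction is imposed, because the sum of two shortest paths
is the definition.  Paths are computed by Dijkstra's algorithm per source
(all distances are nonnegative and networks are small, ≤ ~10² nodes), and
every value is exact.

Pairs with no directed cycle through them are *unreachable* and carry no
number.  ShReDs exceeding a cap (default 100, configurable) are clamped to
the cap and flagged *capped*: near-zero fluxes produce enormous edge
distances, and letting them run free would exaggerate differences between
reactions whose fluxes are not statistically distinguishable from zero.
Distribution summaries report the third-standardized-moment skewness over
all numeric values with capped entries included at the cap (a switch
restricts to values strictly below the cap, since either convention is
defensible); the histogram export always excludes capped values, and the
mean is reported over non-capped finite values.

## Rank-based modularity matrix

Flux weighting skews the ShReD distribution strongly to the right, so
whether a pair interacts more tightly than expected is judged by rank, not
by distance from an arithmetic mean.  For each pair with a numeric ShReD,

    p_ij = fraction of all numeric ShReDs involving i or j
           (the pair itself excluded) that are longer than ShReD_ij
    V_ij = ln( p_ij / (1 − p_ij) )

Ranking details, each of which matters in degenerate subnetworks:

* Ties contribute half a count (midrank).  This keeps the defining
  property that a pair sitting exactly at the median gets V = 0: a strict
  "longer than" count would send an all-tied subnetwork to p = 0 and give
  every pair the most extreme negative entry instead of a neutral one.
  Where ranks are strict the midrank and strict conventions coincide (the
  10-of-25 → V = −0.41 worked example is unaffected).
* Capped entries participate at the cap value and therefore tie with each
  other; unreachable pairs are excluded from numerator and denominator and
  get no V entry at all (any constant contribution would bias partitions
  of sparse subnetworks).
* p is clamped to [0.01, 0.99].  The lower floor keeps the most extreme
  entry (V = −4.60) on the same order of magnitude as the rest of the
  matrix; the upper clamp is the symmetric extension, keeping V bounded
  and antisymmetric around p = 0.5.
* A pair whose comparison set is empty (a 2-node subnetwork) has no rank
  information and gets p = 0.5, i.e. V = 0.  The practical consequence is
  that an isolated 2-cycle is not force-split: a split needs positive
  evidence.

The modularity score of a ±1 assignment vector **s** is the quadratic form
Q = Σ_{i≠j} V_ij s_i s_j (ordered pairs, diagonal excluded, undefined pairs
contributing 0).  Summing ordered pairs doubles every unordered
contribution; the argmax is unaffected and the form matches s V sᵀ
literally.

## Optimization and the partition hierarchy

Each connected subnetwork is bipartitioned to maximize Q:

* up to 8 nodes: exhaustive enumeration of all 2^(n−1) sign-distinct
  vectors, ties broken by lexicographically smallest vector;
* larger: a genetic algorithm — population 100, truncation selection of
  the top 60% by Q, offspring by agreement crossover (elements on which
  two random parents agree are inherited, the rest drawn uniformly from
  ±1), per-element mutation probability 0.2, constant population size.
  The best vector ever seen is returned (hall of fame).  Termination:
  the ordinary-least-squares slope of the population-mean Q over the last
  20 generations falls below 0.05 in absolute value, or 500 generations.
  The plateau window (20) and the generation bound are this package's
  choices; the slope threshold and all other settings are the method's
  stated parameters.  A leading-eigenvector solver is included as a
  comparator only.

The hierarchy is built recursively.  Per node set: (1) weakly disconnected
sets are first separated into components ("component" links, drawn red in
tree exports; they do not increase depth); (2) a connected set of ≥ 2 nodes
is bipartitioned, and the split is accepted only if the best Q is strictly
positive *and* at least one daughter still contains a directed cycle (a
strongly connected component of ≥ 2 reactions).  One daughter without a
cycle is fine — that is how acyclic appendages and transport reactions peel
off.  The Q > 0 requirement is the stopping rule where none is otherwise
specified: a non-positive optimum means no rank-enriched split exists.
ShReDs and V are recomputed on each induced subnetwork at every level,
because shortest cyclical paths may not leave the subnetwork being
partitioned (a switchable `matrix_builder` allows root-level reuse for
sensitivity comparisons).  Depth and height count partition links only.
Every GA call draws from a generator spawned from (seed, module id), so
trees are reproducible end to end.

## Scores across states

* **Homogeneity index** of a module: modal canonical-group share among its
  members, in (0, 1]; 1 iff the module is functionally pure.  Reported per
  module and as unweighted means by height (height 0 = terminal modules).
* **Partition score** H_ij = (Shared − 1) · ½ · (1/m_i + 1/m_j), where m
  is a reaction's terminal partition-link depth and Shared counts the
  nested modules containing both reactions, one per partition level (the
  root counts; component separations change membership but not depth and
  are not counted — counting them could push H above 1 whenever a red
  split intervenes, and H is a fraction of hierarchy by construction).
  H = 0 when the pair separates at the first partition, or when either
  reaction peels off before any partition-driven split (m = 0); H = 1 when
  the pair shares a terminal module.
* **Robust pairs**: pairs with H > h_min and V > v_min — strictly, with V
  taken from the initial un-partitioned network's modularity matrix — in
  every examined state (defaults 0.7 and 3.0).  Pairs whose root ShReD is
  unreachable have no V coordinate and are excluded and reported
  separately.
* **H-V distance** between two states: per-pair Euclidean displacement
  after dividing each state's H coordinates by that state's mean H and V
  coordinates by its mean V (means over defined pairs).  If a mean is
  numerically zero the mean absolute value is used instead, with a logged
  warning — dividing by a vanishing signed mean would be meaningless.

## Flux estimation

Fluxes are estimated from measured exchange rates by minimizing the
unweighted sum of squared differences between measured and computed
exchange fluxes subject to S·v = 0 over internal metabolites — no
metabolic objective is assumed.  Without sign bounds the problem is solved
exactly in an orthonormal basis of the balance nullspace; `lstsq` then
returns the minimum-norm optimum, and the dimension of the optimal set is
reported as the remaining degrees of freedom, so externally supplied flux
tables can be substituted when the system is underdetermined.  Optional
bounds (e.g. nonnegativity of irreversible reactions) switch the solver to
SLSQP.  Inverse-variance weighting is available when standard deviations
accompany the measurements.

## Synthetic networks: what they emulate and what they do not

The generator plants `cycle_count` directed reaction cycles (one
metabolite between successive reactions) and chains adjacent cycles with
bridge *shuttles*: a forward and a backward bridge reaction per pair,
forming a small local loop.  The flux vector is a nonnegative combination
of closed-loop modes — each cycle's circulating flux (drawn around
`flux_scale`), each shuttle's flux (`bridge_ratio` × mean cycle flux,
default 0.01) — so S·v = 0 holds exactly by construction, and the
bridge:cycle contrast is a single dial.  Cycles of ≥ 5 reactions spend one
reaction on a chord, an internal shortcut drawing a 20–40% share: with
perfectly uniform ring fluxes every within-cycle ShReD ties and the
rank-based V carries no information at all, whereas branch points — which
real pathways have — are precisely what flux weighting resolves.  Bridges
are attached as local shuttles rather than one global ring deliberately: a
ring couples the *reachability* of distant cycles, so a correct first cut
severs every cross-cycle return path and strands rank-isolated nodes,
which says nothing about the weighting schemes under comparison.

Planted cycle ids double as canonical group labels, so homogeneity and
module-recovery scores are meaningful on fixtures.  What passing the
recovery battery shows: on networks whose module structure is expressed as
flux contrast (strong internal cycling, weak cross-module exchange), the
flux-weighted partition finds the planted boundaries at least as well as
the unit-weighted one.  What it does not show: behaviour under measurement
noise in fluxes, non-steady states, genome-scale networks, or modules
defined by anything other than cyclical flux — real data have all of
these.  The worked single-producer (100 split 60/40) and shared-pool
(100 split 70/30) fixtures, and a five-reaction cofactor-closed cycle
(synthetic, with configurable fluxes and exchange closures for unequal
flux choices), cover the edge-weighting arithmetic end to end.

## Problem sizes and determinism

The bundled test battery uses networks of 12–72 reactions, 2–4 planted
cycles, and 30 recovery fixtures; exact oracles (simple-path enumeration,
full assignment enumeration) are run on instances of ≤ 8 nodes, which is
also the exhaustive-search bound of the partitioner.  All stochastic
components (fixture generation, GA) are seeded; identical seeds give
byte-identical trees and result bundles.

## Known limitations

* Boundary handling classifies only ever-produced / only-ever-consumed
  metabolites as external; models using explicit boundary species on both
  sides of exchange reactions should write them as one-sided equations.
* The GA is exact in practice on small subnetworks but carries no
  optimality certificate above 8 nodes; nodes whose pairs are all
  undefined in a subnetwork are Q-neutral and their daughter assignment is
  arbitrary.
* The cap (default 100) discards rank information among very weak
  interactions; in cap-saturated regimes (many capped pairs) partitions of
  the affected subnetworks are weakly determined.
* H-V normalization by a signed mean is unstable when a state's mean V is
  near zero; the fallback to mean |V| changes the scale of that state's
  coordinates and is logged.
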