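# Methods

## The model

`motifpol` analyzes Boolean threshold models of plant–pollinator community
assembly. A regional species pool is a signed, weighted, directed bipartite
network: every habitual visitation of a plant by a pollinator contributes
two directed edges, one toward each partner. The sign of each direction
follows from the morphological match between corolla depth `l_pl` and
proboscis length `l_po`:

* `l_pl > 1.1 l_po` — contact without nectar access: `+` to the plant,
  `-` to the pollinator;
* `l_pl < 0.9 l_po` — nectar robbery without pollination: `-` to the
  plant, `+` to the pollinator;
* otherwise a match: `+` to both.

Positive edges carry weight `+4`, negative edges `-1`; a single benefit
outweighs up to three costs. Species are binary (present/absent) and
update synchronously:

    sigma_i(t+1) = H( sum_j E(j,i) sigma_j(t) ),     H(x) = 1 iff x > 0.

A species persists exactly when it receives net positive support. The
attractors of this dynamical system are the stable communities the pool
can sustain.

## From threshold rules to logical rules

Stable-motif analysis needs each update function in disjunctive prime form
(the complete sum of prime implicants, Blake canonical form). Threshold
functions with `+4/-1` weights are unate, so the complete sum follows in
closed form: an implicant activates `a` benefactors and silences
`b = max(0, N_n - 4a + 1)` inhibitors; once `b` hits zero, adding more
benefactors is superfluous. A generic Quine–McCluskey-style truth-table
routine provides an independent oracle for small rules.

Three reductions make the expanded network tractable:

1. **Pruning.** A species without any positive in-edge can never
   establish; its removal can strip another species' only benefactor, so
   removal iterates to a fixpoint.
2. **Superfluous negative edges.** With at least one benefactor and at
   most three inhibitors, the inhibitors never flip the outcome; such
   negative edges are deleted (their positive partner edges remain, so the
   guilds stay connected).
3. **Probability-conserving simplification.** The remaining rule is
   replaced by the inhibitor-dominant form
   `(P_1 | ... | P_Np) & !N_1 & ... & !N_x`, where the `x` retained
   inhibitors are drawn uniformly without replacement and `x` minimizes
   `|(1 - 2^-Np) 2^-x - P(H>0)|` with `P(H>0)` evaluated exactly under
   independent fair-coin regulators. Ties break toward smaller `x` (fewer
   retained inhibitors); the nearest candidate is used rather than the
   nearest from above. Each retained inhibitor stands in for the
   collective cost of the dropped ones, hence inhibitor dominance.

## Expanded network, motifs, LDOI

The expanded network holds two virtual nodes per species (present/absent)
and one composite node per multi-literal prime implicant. Stable motifs
are the minimal, consistent, composite-closed strongly connected
subgraphs — the generalized positive feedback loops whose stabilization is
self-sustaining. For the inhibitor-dominant rule class they are
single-polarity and admit a direct characterization on the
positive-interaction digraph `G+`:

* **all-inactive motifs** are the source SCCs of `G+` (a species stays
  absent only while *all* its benefactors are absent, so benefactor
  closure drags every ancestor in; inside an SCC that means everything);
* **all-active motifs** are the node-minimal simple cycles of `G+` among
  species retaining no inhibitor (activation needs only one benefactor,
  so minimal strongly connected subgraphs are bare cycles; a cycle
  strictly containing a shorter cycle is not minimal);
* **conditionally stable motifs**: active cycles whose members retain
  inhibitors (conditions = the inhibitors' absence), and the non-source
  SCCs of `G+` taken whole for the inactive polarity (conditions = the
  absence of every outside benefactor). Inactive conditional motifs must
  be whole SCCs, not cycles: benefactor closure is all-or-nothing within
  an SCC, and cycle-sized pieces provably miss attractors.

A conditionally stable motif paired with a support whose LDOI covers its
conditions forms a **motif group**; groups join the support pool so chains
resolve by closure.

The **logical domain of influence** (LDOI) of a set of pinned states is
computed two ways, which the test suite holds against each other: a
percolation on the expanded network (a composite fires when all its
inputs are in the set; candidates contradicting a seed are truncated),
and a breadth-first search directly on the threshold rules that decides
sufficiency under worst-case assumptions about unknown regulators
(unknown benefactors absent / inhibitors present when testing forced
activation, and vice versa for forced deactivation; undecided nodes are
revisited when a regulator acquires a state). For inactive seeds the two
LDOIs agree exactly — deactivation propagates through "all benefactors
absent" conditions that the simplification never touches — so extinction
cascades computed on the simplified model are faithful to the threshold
model. For active seeds the simplified model can only overestimate,
except for one documented mechanism: four or more active inhibitors
jointly silencing a target is representable in the threshold rules but
may be lost with the dropped negative edges, so the only possible
underestimates are missing *inactive* states.

## Attractors and control

Attractors are identified without state-space search: build the relation
graph over stable motifs and motif groups (mutually exclusive iff they
share a species in opposite states; an LDOI-containment edge when one
implies another), enumerate maximal consistent combinations (maximal
cliques of the compatibility graph), and percolate each combination's
states through the rules. In this rule class every minimal trap space
normally fixes all species (a point attractor); equal trap spaces from
different combinations are collapsed. The attractor with the most
established species is the maximal richness community, and all other
attractors' communities are subsets of it.

One caveat is inherited from the simplification: if a retained inhibitor
sits on a feedback loop (plant feeds pollinator, pollinator robs plant),
the minimal trap space leaves the loop species free — they oscillate and
are reported in the attractor's `free` list as not stably established.
Such loops survive in a few percent of generated networks; perturbation
closure falls back to synchronous simulation there.

**Driver sets** of a motif are the minimal sets of virtual nodes whose
LDOI contains the whole motif, searched in increasing size over the
motif's own states with composite-node targets prioritized (a virtual
node feeding only composites cannot drive anything alone). A **control
set** of an attractor is the union of one driver set per member of its
(reduced) combination; members already implied by the others' joint LDOI
are dropped first, minimum-cardinality unions are kept, and every
reported control set is re-verified by percolation.

## Experiments

All experiments start from the maximal richness community.

* **Extinction damage.** Pin an extinction set absent, percolate, overlay
  the untouched species' previous states, and verify a fixed point of the
  pinned dynamics (the synchronous closure is the cross-check: pinning
  established species absent cannot create bi-stability in an
  inhibitor-dominant model, because every retained inhibitor is already
  absent in the maximal richness community). Damage percentage =
  lost-but-not-targeted species over non-targeted established species.
  Modes: driver sets of inactive motifs/groups; equally sized non-driver
  sets (species driving no inactive motif at any size up to the examined
  one); half of a four-species driver set plus two random non-drivers;
  and top/bottom-10% candidates by betweenness, nestedness contribution
  or MusRank.
* **Blocking.** All driver sets of the largest inactive motif or group
  (virtual-node count, ties by LDOI size then label order) are
  identified; the blocked arm excludes those driver species from the
  extinction choices, the control arm does not, and both draw sets of the
  motif's minimal driver-set size.
* **Restoration.** The damaged community is the worst outcome over
  same-size inactive driver sets. Candidates are either driver sets of
  active stable motifs (pinned present, percolated) or species drawn from
  the top-10% contributors to functional diversity (added single-linkage
  branch length over the survivors' dendrogram, one dendrogram per guild
  since the incidence is directed). The restoration percentage counts the
  re-introduced species themselves (an exclusive tally is also emitted).
  Chosen sets can be re-verified on the threshold rules: pin the species
  present, close the synchronous dynamics from the damaged state, and
  count species stable through the whole cycle — oscillators do not count
  as re-established, so the threshold percentage never exceeds the
  simplified one.
* **Attractor control.** For every attractor holding at least 70% of the
  maximal richness, the minimal control-set size is recorded and bucketed
  by richness band (70–80 / 80–90 / 90–100%).

## Structural baselines

* **Betweenness**: standard shortest-path betweenness on the directed,
  unweighted simplified network.
* **Nestedness contribution**:
  `eta_i = (1/N) sum_{j != i} n_ij / (k_in_i k_in_j)` with `n_ij` the
  number of shared in-neighbours (row products of the in-adjacency) and
  `N` the species count. The self-term is excluded — the contribution is
  defined through partners shared with *other* species. Zero-in-degree
  species are excluded with a warning. Species with few interactions
  shared with other low-degree species score highest and are the most
  extinction-vulnerable; the bottom 10% are the keystone candidates.
* **MusRank**: pollinators are active (importance), plants passive
  (vulnerability); the incidence is binarized and symmetrized, which is
  precisely the information loss that can make the ranking miss
  direction-dependent keystones. Iteration starts from all ones with
  mean-1 renormalization each step, tolerance 1e-9 in sup norm. The
  update is sequential — vulnerabilities see the freshly renormalized
  importances — because the simultaneous variant can settle into a
  period-2 cycle on realistic incidences and then never reaches the fixed
  point the ranking is defined by. Scores are floored at 1e-12 (specialist
  scores decay to exact zero and the vulnerability update divides by
  importance). On nested incidences convergence toward the boundary fixed
  point is only algebraic, so the iteration cap is a generous 2x10^5;
  hitting the cap raises with diagnostics.
* **Functional diversity**: total branch length of the single-linkage
  (nearest point) dendrogram over Euclidean distances between interaction
  profiles; `FD(S)` is the length of the segment set connecting the
  surviving leaves to the root, which makes FD monotone and makes greedy
  restoration gains sum exactly to `FD(all) - FD(survivors)`.

## Synthetic ensemble

The generator emulates the statistical shape of empirical pollination
webs, not any particular field site:

* **Degrees**: exponentially cut-off power law
  `P(k) ~ k^-gamma exp(-k/kappa)`, defaults `gamma = 1.8`,
  `kappa = 20`. At the default 25+25 pool size this gives connectance
  ~0.09 and a pool-survival fraction of ~0.34 after pruning — both in the
  empirical range for webs of this size. Both guilds are sampled
  independently, the stub-count mismatch is repaired by random unit
  increments/decrements (bounded by 1 and the opposite guild size), and
  edges are placed by configuration-model stub matching with multi-edge
  rejection (greedy largest-first realization plus randomizing edge
  swaps as a fallback; unrealizable sequences are resampled).
* **Traits** (length units, think millimetres): right-skewed skew-normal
  distributions, plants `skewnorm(shape 4, loc 1, scale 8)` and
  pollinators `skewnorm(shape 4, loc 1, scale 6)`; non-positive draws are
  resampled. These scales put the mutually beneficial share of pool
  interactions near 8%, the hallmark minority of this model family (the
  overwhelming majority of encounters are morphologically mismatched and
  benefit one side only).
* Boundary trait ratios (`l_pl` exactly `0.9 l_po` or `1.1 l_po`)
  classify as matches, since the mismatch conditions are strict.
* Every stochastic stage consumes a generator seeded from the
  configuration, so equal configurations give byte-identical edge lists;
  ensembles spawn per-network child seeds from the master seed.

What the generator does **not** emulate: phenological or spatial
structure, interaction rewiring, abundance-dependent interaction
strengths, or empirical degree-trait correlations. Passing tests
demonstrate the machinery's correctness on pools with realistic degree
and trait marginals, not calibration to any real community.

## Problem sizes and numerical choices

The test suite and worked examples run at desk scale: exhaustive oracles
(full state-space enumeration, definition-based motif search, minimal
driver subsets) cover generated pools that simplify to at most 8–18
species; ensemble-level comparisons (driver vs non-driver damage,
blocking, LDOI agreement) use ~30 pools of 50 species plus 25 pools of 70
species for the four-species driver comparison, with extinction-set
subsampling capped and seeded. Combinatorial sweeps cap at 10^4 driver
union candidates with a completeness flag. Canonical label order breaks
all remaining ties (motif listings, equal-richness attractors, ranking
ties at the 10% cutoff), so every report is reproducible under a fixed
seed.

## Known limitations

* Motif enumeration targets the inhibitor-dominant class produced by the
  conversion; arbitrary logical models (non-unate rules, multi-level
  logic) are out of scope, though the definition-based exhaustive search
  accepts any small expanded network.
* Mixed-polarity stable motifs (possible only with negative feedback
  loops through retained inhibitors) are not enumerated; their influence
  on trap spaces is captured by percolation, and affected species surface
  as `free` oscillators.
* The spec-level claim that every attractor is a subset of the maximal
  richness community holds for fixed-point attractors; trap spaces with
  free oscillators are compared by their stably established sets only.
* MusRank is reported as defined, including its known insensitivity to
  edge direction — that insensitivity is part of what the motif-based
  analysis is demonstrated against.
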