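# Methods

mptree implements the classical cladistic workflow for discrete
morphological matrices: equal-weights unordered (Fitch) maximum parsimony,
with exact and heuristic tree search, ensemble fit indices, Bremer (decay)
support, outgroup rooting and ACCTRAN synapomorphy mapping. This note
records the model conventions, the algorithms and their numerical choices,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Data model

A character matrix is a taxa × characters table of single states `0`–`7`,
plus `?` (missing: unobservable) and `-` (inapplicable: not logically
scorable). Both special codes are treated as **full ambiguity over the
character's observed states** in every computation. For unordered Fitch
parsimony this is lossless: a state that no terminal exhibits can never
reduce tree length, so restricting the ambiguity set to observed states
changes nothing while keeping state sets small (≤ 8 bits per cell).
Polymorphic codes such as `(01)` and ordered/step-matrix characters are
out of scope.

A character is *parsimony-informative* iff at least two of its states are
each unambiguously scored in at least two taxa. Uninformative characters
still contribute steps (their steps equal their number of observed states
minus one, on **every** binary tree) and are included in the ensemble
indices by default.

## Tree length and fit indices

Tree length is the Fitch downpass sum over characters; it is invariant to
rooting and rotation (property-tested, and checked against a brute-force
enumeration of all ancestral assignments on small trees, and against
phangorn's independent implementation).

Per character, `m_c` = (observed states − 1) is the minimum conceivable
steps and `g_c` = (scored taxa − frequency of the commonest state) the
maximum (star-tree) steps; ambiguous cells are excluded from both counts.
The ensemble indices are

    CI = Σ m_c / Σ s_c        RI = (Σ g_c − Σ s_c) / (Σ g_c − Σ m_c)

summed over **all** characters (the reporting convention of the common
parsimony programs; an informative-only variant is available via
`fit_statistics(..., informative_only=True)`). Display forms are integer
percentages rounded half away from zero; on the bundled study matrix the
optimal tree yields CI 0.4505 → 45 and RI 0.5349 → 53. When
`Σ g = Σ m` (no informative variation at all) RI is reported as 1 by
convention.

## Tree search

*Heuristic*: random-addition-sequence Wagner builds followed by
first-improvement branch swapping (SPR, or full TBR including
reattachment at the merged edges left by bisection). All stochastic
choices flow from one integer seed. Insertion costs during Wagner
building are exact and cheap: rooting the enlarged tree at the new leaf
shows that attaching leaf *x* to branch *e* adds one step exactly for the
characters in which *x*'s state set is disjoint from the branch state set
(the Fitch combination of the two directional state sets meeting at *e*).

*Exact*: implicit enumeration (branch and bound) by stepwise addition,
compiled with numba. Identical columns are collapsed into weighted
patterns and uninformative columns into a constant offset, and state sets
travel as 8-bit lanes packed into 64-bit words. At every partial tree the
next taxon is chosen dynamically (the unplaced taxon whose cheapest
insertion is most expensive) and the partial tree is abandoned when an
admissible bound exceeds the best known length. The bound is the partial
tree's length plus a *chain* of insertion costs: unplaced taxa are taken
greedily, each contributing the minimum over branches of the summed
weight of characters in which its states are disjoint from both the
branch state-set union and the accumulated states of taxa chained before
it. Earlier chain members can only add their own states to any branch of
a grown tree, so each term lower-bounds that taxon's true attachment cost
in any completion, making the sum admissible. Once at most `fast_u`
(default 11) taxa remain, enumeration switches to a lane-packed fast tail
whose suffix bounds are inherited from the switch node's chain terms, and
whose last taxon is scored entirely at its parent. Completed trees are
re-verified with the reference Fitch implementation before being
returned; `branch_and_bound` equals exhaustive enumeration (all `(2n−5)!!`
topologies) on every randomized test instance, including the full sets of
optimal trees.

Exactness is proven only by complete enumeration, and the search cost is
driven by the matrix's homoplasy, not just its size. The bundled study
matrix is extreme in this respect (CI 0.45: most of its 182 steps exist
only through character conflict), and the admissible bounds above leave
on the order of 10⁹ partial trees to visit at the optimal ceiling —
hours of single-core work. The default analysis therefore establishes
the optimum heuristically (independent TBR batches converge on one and
the same topology at 182 steps from every tested seed, matching the
published tree), while exact search is routine for moderately sized or
cleaner matrices, and its equivalence to exhaustive enumeration is
asserted by the test suite on randomized instances.

## Bremer support

Absolute Bremer (decay) support of a clade is the extra length of the
best tree *not* showing the clade as a bipartition. Two routes:

* `exact`: the enumeration kernel tracks, per clade of interest, the
  shortest completion lacking it (reverse-constrained search), seeded by
  an SPR-scan upper bound. A partial tree with taxa still unplaced can
  never force a bipartition of the full leaf set, so filtering completed
  trees is exact. Verified against oracle enumeration on small instances.
* `tree_set`: the classical decay-script procedure — collect every tree
  within a margin (default 6 steps) of the optimum met during SPR+TBR
  sweeps around the optimal tree(s), take per clade the best collected
  counter-tree, and refine it by a constrained hill-climb. Values are
  upper bounds that converge to the decay index as the collection grows;
  this is the procedure of the scripts used in practice for matrices
  beyond exact reach, and it reproduces the exact values on every small
  test instance.

Relative Bremer support follows the relative-fit-difference convention:
with per-character steps `s` on the optimal tree and `s'` on the best
counter-tree, `F = Σ max(s'−s, 0)` favors the clade, `C = Σ max(s−s', 0)`
contradicts it, and the relative support is `(F − C)/F ∈ [0, 1]`
(undefined when no counter-tree lies within the margin; clades absent
from some optimal tree score 0).

## ACCTRAN mapping

The optimal tree is rooted on the outgroup's pendant branch. Per
character, a unit-cost Sankoff table `cost[v][s]` (minimum changes in
`v`'s subtree when `v` has state `s`) is filled bottom-up; a pre-order
pass then fixes one state per vertex, choosing a state minimizing
`cost[v][s] + [s ≠ parent]` and breaking ties by **preferring a state
different from the parent** — the change is pulled rootward, which is the
accelerated-transformation convention (reversals are favored over
parallelisms). Remaining ties go to the lowest-numbered state, and root
ties prefer a state in the outgroup's cell, so reconstructions are fully
deterministic. Ambiguous leaves resolve to a state avoiding a change on
their pendant branch whenever possible. The number of mapped changes
always equals the Fitch length (property-tested).

A change is classified **unique** (an exclusive synapomorphy, the filled
circle of a printed cladogram) iff its derived state arises on exactly
one branch of the whole tree and is not the root state. A later reversal
inside the clade does not revoke the single origin — e.g. on the study
tree the twisted leg IV (28→1) and elongate trochanter (37→1) revert in
*S. funestus* yet remain exclusive supports of *Sadocus*, exactly as the
published counts require; a parallel origin or a re-derivation of the
root state is homoplastic. This single-origin reading reproduces all
three published tallies (7 changes / 4 exclusive for *Sadocus*, 7/2 for
*Sadocus*+*Neogonyleptes*, 7/3 for the *D. catharinensis* +
*R. bittencourti* pair).

## Synthetic data

`random_tree` draws uniformly over unrooted binary topologies (sequential
random attachment). `simulate_matrix` evolves each character root-to-tips
with a per-branch switch process: uniform root state, and on every branch
a switch to a uniformly chosen *different* state with probability
`change_probability`. The switch probability directly tunes homoplasy —
which is the property a parsimony estimator must be tested against — but
the process is deliberately not a continuous-time Mk model: there are no
branch lengths, no rate variation, and no correlation between characters.
Missing and inapplicable cells are injected uniformly at random, whereas
real inapplicable entries are structurally clustered (they follow the
absence of a primary character). Passing tests on these simulations
therefore demonstrate correct recovery under controlled homoplasy and
random cell loss, not robustness to the correlated patterns of real
morphological data. `decisive_matrix` (one clean binary character per
internal branch) is the homoplasy-free special case for which search must
return exactly the generating topology; the recovery benchmark (8 taxa,
60 characters, 10% missing) asks the true tree to stay among the optima
in ≥95% of replicates.

## Numerical and interface choices

* States are bit masks; all-ambiguous characters contribute nothing.
* Ties in Wagner insertion and branch swapping resolve to the first
  candidate in deterministic enumeration order; replicate starting orders
  come from `numpy.random.default_rng(seed)`.
* Optimal-tree sets treat trees as distinct unrooted binary topologies
  (canonical nested-tuple form anchored at the lexicographically smallest
  leaf); no branch collapsing when counting optima.
* The exact kernel supports up to 64 taxa (leaf sets as 64-bit masks);
  `exhaustive_search` refuses beyond 9 taxa; `run_full_analysis` refuses
  exact strategies beyond 25 taxa and points to the heuristic.
* The bundled fixture keeps the matrix row label *Metagyndes martensii*
  exactly as printed in the source table, although the outgroup listing
  of the study names *M. pulchella*; the two are not reconciled there.
* TNT/NEXUS serializations replace internal spaces in taxon labels with
  underscores; TSV keeps spaces; Newick quotes labels when needed.

## Limitations

* Exact search on highly homoplastic matrices beyond ~14 taxa is
  impractical (see above); the heuristic plus tree-set support route is
  the default at study scale.
* DELTRAN and full enumeration of all most-parsimonious reconstructions
  are not implemented; ACCTRAN is the single deterministic convention.
* No implied weighting, no ordered characters, no resampling supports
  (bootstrap/jackknife), no ratchet or driven searches.
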