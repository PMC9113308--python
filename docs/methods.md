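# Methods

## Model

A species tree *S* is a planted rooted binary tree with edge lengths in
coalescent units (generations divided by effective population size);
leaves sit at time 0 and time increases rootward. Gene families evolve
under the two-stage duplication-loss-coalescence (DLCoal) model.

**Stage 1 — gene duplication and loss (GDL).** A birth-death process with
duplication rate λ and loss rate μ (events per coalescent unit per locus
lineage) starts with a single lineage at the top of the finite species
root edge and runs toward the leaves. A duplication splits a lineage into
a mother (which continues the parent locus) and a daughter (a novel
locus); the daughter edge is marked with a *duplication-point* at the
duplication height. A loss terminates the lineage. At every speciation
each surviving lineage is copied into both descendant branches. Extinct
subtrees are pruned; degree-2 nodes are suppressed with their edge lengths
summed, and duplication-points on merged edges migrate with them (only the
lowest point per edge is kept — it implies the higher ones). The result is
the *locus tree*, again planted, binary and ultrametric, with leaves
labelled `species_copyIndex`. The simulator records the number *l* of
locus lineages crossing the root speciation (the *root lineages*) and the
root-lineage index of every surviving leaf, which downstream analyses use
to stratify families into scenarios such as (ab,cd) or (abc,d).

**Stage 2 — bounded multispecies coalescent (b-MSC).** One gene lineage
starts at each extant locus leaf. Within each locus edge, co-existing
lineage pairs coalesce at rate 1 per pair; the process is symmetric, so
the merging pair is uniform among pairs at each event. A duplication-point
at height *z* constrains all lineages descending from the daughter locus
to have coalesced to a single lineage strictly below *z*. Above the locus
root the remaining lineages coalesce on an unbounded stem, so every gene
tree is fully resolved.

## Closed-form quartet probabilities

For a 4-leaf locus tree (one gene per species, four distinct species)
displaying ab|cd, the gene-tree quartet distribution is available in
closed form for every duplication placement. All formulas are built from
the Tavaré transition probability

    g_ij(x) = Σ_{k=j}^{i} e^{−k(k−1)x/2} (2k−1)(−1)^{k−j}
              / ( j!(k−j)!(j+k−1) ) · Π_{m=0}^{k−1} (j+m)(i−m)/(i+m),

the probability that i lineages coalesce to exactly j within time x. The
series coefficients are computed once as exact rationals and cached, so
evaluation is a short alternating sum that is stable for the small i
(≤ 20) arising here.

With x, y the internal-edge lengths (cherry edges for the balanced shape;
edge above the cherry and edge above the 3-clade for the caterpillar):

| shape | duplication | P[ab|cd ∈ G] |
|---|---|---|
| balanced | none | 1 − (2/3) e^−(x+y) |
| balanced | on X or Y | 1 |
| balanced | at root vertex | 1 (the dup-point tops a cherry edge) |
| balanced | root edge, t above root | 1 − (2/3) e^−(x+y) g₄₁(t)/D |
| caterpillar | none | 1 − (2/3) e^−x |
| caterpillar | on X | 1 |
| caterpillar | on Y, t above the cherry top | 1 − (2/3) e^−x g₃₁(t)/D′ |
| caterpillar | root edge, t above root | 1 − (2/3) e^−x (g₃₂(y)g₃₁(t) + g₃₁(y)g₂₁(t) + g₃₃(y)g₄₁(t))/D″ |

The denominators D are the prior probabilities that the constrained
lineages have fully coalesced before the duplication-point, computed by a
lineage-count dynamic program (convolve counts with g along each edge,
add counts at nodes, finish with g(·,1,·) on the stem) — exact given g,
with no numerical integration. In every case the two non-matching
quartets have equal probability, the matching probability is ≥ 1/3,
strictly exceeds the alternatives, and is non-decreasing in x (strictly,
unless a duplication on X already forces certainty). A caterpillar whose
root is a duplication is handled as the Y-edge case with t = y: the
root-as-duplication certainty argument applies to the balanced shape
only, where the dup-point tops a cherry edge.

The geometry of t and z is the one piece the closed forms leave implicit:
we take z as the absolute height of the duplication-point and t as z
minus the height at which the constrained lineages enter the edge
carrying the point (the quartet root for root-edge duplications, the top
of edge X for the caterpillar Y-edge case). This reading was frozen only
after the Monte-Carlo oracle agreed with every bounded closed form within
sampling error at both tight and loose t.

`classify_locus_case` maps a concrete annotated 4-leaf locus tree onto
the correct case with the precedences that the certainty cases impose: a
duplication-point on an internal edge below the displayed cherry
dominates a root-edge point, and for the caterpillar an X-edge point
dominates a Y-edge point (once the cherry is forced, and once a,b,c are
forced to coalesce below the Y-point, points higher up cannot change the
topology distribution). Duplication-points on pendant edges constrain a
single lineage and are ignored.

## Exact sampling of the bounded coalescent

Enforcing the bounds by rejection (resample a daughter locus until its
lineages coalesce in time) is correct but can be arbitrarily slow: the
acceptance probability is the before-bound coalescence probability, which
for daughters with many lineages and tight bounds falls below 10⁻⁵ at
plausible rates, and a single such family then dominates a whole
experiment. The package therefore samples the conditional law directly:

1. **Forward filter.** Propagate the distribution of lineage counts from
   the leaves up, using g_ij along each edge segment and convolution at
   nodes, forcing the count to 1 at every duplication-point (the
   unnormalized masses then carry the joint bound probabilities).
2. **Backward sample.** From the root stem down, sample each segment's
   entry count from (forward mass × g to the known exit count), split
   counts among children proportionally to their forward masses, and
   sample the coalescence times within a segment from the death chain
   conditioned on its entry and exit counts. The conditional
   next-jump-time CDF is a closed-form exponential sum (the spectral
   expansion of g), inverted by bisection to 10⁻¹¹ relative precision.
3. **Assembly.** At each sampled coalescence the merging pair is chosen
   uniformly: by exchangeability the pair choices are independent of the
   count trajectory, and the bound events depend on counts only, so this
   is the exact conditional law.

A bound of probability zero (a duplication-point below the subtree where
its lineages can first meet) is detected in the forward pass and raises
immediately. The rejection sampler is retained (`method="rejection"`) and
the test suite checks that both samplers produce the same quartet
distribution; the forward filter of one locus tree is reusable across
replicates (`BmscSampler`), which the Monte-Carlo driver exploits.

## Quartet extraction and estimation

For a multi-copy gene tree and a species 4-tuple, the *one* rule samples
one copy per species uniformly (once per gene tree) and records the
displayed quartet; the *multi* rule counts the quartets of all copy
combinations, so one tree contributes n_a·n_b·n_c·n_d counts. Gene trees
missing one of the four species cast no vote, matching the conditioning
on all four genes existing. Species names are taken from leaf labels by
splitting on the last underscore. The estimator exhaustively scores every
unrooted topology (n ≤ 8 taxa, (2n−5)!! candidates) by the total count of
displayed quartets; ties are broken lexicographically on the canonical
Newick string and reported, so runs are reproducible.

## Verification design and problem sizes

The closed forms and the simulator are independent routes to the same
distributions, so each validates the other. The default verification grid
uses one or two parameter cells per closed-form case with x, y ∈
{0.5, 1.0} and t ∈ {0.5, 1.0} — each formula has no remaining interaction
these cells leave unexercised — at 10⁵ replicates per cell, flagged at 4
standard errors (two-sided; with ~30 z-scores per run the family-wise
false-alarm rate stays well below 1%).

Full-model checks simulate families on 4-taxon balanced and caterpillar
species trees (internal edges 1.0, pendants 1.0, root edge 1.0) over
λ = μ ∈ {0.1, 0.3, 0.5}: quartet dominance and equality of alternatives
at 12 000 families per cell, scenario stratification by root-lineage
partition (cross-species index agreement = 1/l within error), convergence
of the one-copy estimator over 20 replicate datasets of 5000 families at
λ = μ = 0.3, and the all-copies expectation ordering over 10⁴ families.
Families that lose one of the four species entirely are discarded and the
discard rate reported; at λ = μ = 0.3 roughly a quarter of families
retain all four species. The λ = 0 cell reduces to the unbounded
coalescent and is checked against the classic formulas separately.

Master seeds are fixed constants; all randomness flows through
string-seeded `random.Random` substreams keyed by (seed, stage, index),
which are stable across platforms, so every reported table is
bit-reproducible.

## What the generator does and does not emulate

The simulator realizes the generative model faithfully: coalescent-unit
branch lengths (constant effective population size is absorbed into the
units), one haploid sample per extant locus, asymmetric duplications with
the daughter side chosen uniformly (no tested distribution depends on the
choice, by symmetry of the subsequent process), and losses as instant
terminations. It does not model hemiplasy/introgression,
population-size variation along branches, sequence evolution or
gene-tree estimation error — passing checks say the *model's* quartet
laws hold, not that estimated gene trees from real alignments behave this
way. Locus trees with more than four leaves have no closed-form quartet
distribution here; they are handled by simulation and by restriction to
sampled 4-tuples.

## Numerical choices and degenerate inputs

* Probabilities are clipped to [0, 1] only within 10⁻¹² of the
  boundaries; larger violations raise rather than clip silently.
* Trees must be ultrametric to 10⁻⁶ relative tolerance wherever heights
  matter; the canonical Newick writer prints 10 significant digits and
  orders children by smallest descendant label, so parse∘write is the
  identity on canonical output.
* A conditioning event of probability zero (t = 0 root-edge bounds,
  impossible duplication-points) raises; t → 0⁺ limits are handled by the
  formulas themselves (the conditional match probability tends to 1).
* Quartet extraction of a 4-leaf tree finds the cherry directly; larger
  trees are restricted first. Ties between equal-height internal nodes
  cannot arise from the continuous-time samplers and are resolved by
  traversal order for hand-built trees.
* Two-leaf restrictions are allowed internally (the machinery needs
  them); quartet operations require four distinct leaves and raise
  otherwise.

## Known limitations

* The exhaustive estimator is deliberately capped at 8 taxa; it is a
  stand-in for quartet-score search, not a scalable inference tool.
* Scenario-stratified checks condition on the number of root lineages
  post hoc (by recording l per family) rather than fixing it exogenously,
  so strata sizes are random; strata with too few families are reported
  as inconclusive rather than dropped.
* The GDL stage requires a finite species root edge (the process must
  start somewhere); the planted edge above the locus root is open-ended
  for the coalescent unless a duplication-point bounds it.
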