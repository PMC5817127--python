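# Methods

This note documents the models implemented in `cophylotrack`, the
conventions chosen where several were defensible, and what the
synthetic-data experiments do and do not demonstrate.

## Trees, tanglegrams and clade ranks

Trees are rooted, with unique non-empty tip labels and non-negative
branch lengths when lengths are present. Newick parsing is delegated to
dendropy (quoted labels supported; underscores preserved by default,
with an opt-in underscore-to-space mode); writing is our own, and the
canonical form orders every node's children by their lexicographically
smallest descendant tip label, so canonical output is bit-stable and
idempotent. Polytomies are rejected at tanglegram construction rather
than silently resolved — reconciliation semantics assume binary trees —
but `resolve_polytomies` offers an explicit, opt-in arbitrary
resolution with zero-length branches.

**Clade rank** of a tip is the number of internal nodes on the
root-to-tip path, root included, tip excluded: both children of the
root have rank 1, and on a binary tree the rank equals the tip's depth
in edges. With this convention ranks are strictly positive for n ≥ 2
and satisfy the Kraft equality Σ 2^(−rank) = 1 over tips, which the
property tests exploit.

Association tables mix ingroup records with outgroup specimens that
often lack host data; a host field of `Unknown` yields an *unmapped*
record rather than an error. Assembling a tanglegram with
`drop_unmapped` prunes the corresponding symbiont tips and reports the
count; without the flag any unmappable record is a validation error.
The packaged fixture transcribes the study's 61 specimen records
(species, host, locality, collection date; one record has no recorded
locality, and one host name's capitalization is normalized to match the
host tree tip) and the 15-taxon host cladogram over eight angiosperm
orders. The order backbone is stored as data because it derives from
published angiosperm phylogenies, not from any computation this package
performs.

## Event-based reconciliation

A reconciliation embeds the symbiont tree into the host tree, assigning
each internal symbiont node one event:

- **cospeciation** at an internal host node, the two symbiont children
  descending into the two distinct host child subtrees;
- **duplication** at a host position, both children remaining within
  its subtree;
- **switch** at a host position, one child remaining, the other jumping
  to a host edge neither ancestral nor descendant to the source
  (incomparable) by default;

plus per-crossing **losses** (a symbiont lineage passing through a host
speciation without an event) and, for a symbiont tip mapped to k ≥ 2
host tips, **failures to diverge**: the tip occupies the minimal host
subtree spanning its hosts, each branching node of that spanning
subtree (both host daughters inside it) contributing one ftd and each
edge leaving it one loss — so a k-host widespread tip costs exactly
k − 1 ftd events. The symbiont root may start anywhere with no charges
above its starting point. Total cost is the dot product of event counts
with the five-component cost vector; all costs must be non-negative and
finite.

The host tree is untimed. Restricting switch targets to incomparable
positions is the weakest constraint that forbids a lineage jumping into
its own past; global time-consistency across multiple switches is *not*
enforced (as in most untimed duplication-transfer-loss solvers —
enforcing it exactly is NP-hard). An `unconstrained` mode lifts the
restriction entirely.

The solver is an exact dynamic program: `A[p, v]` (optimal cost of the
subtree of symbiont node p with p's event exactly at host node v),
an enter-subtree table `in[p, v]` charging one loss per host speciation
crossed, and a jump-out table `out[p, v]` giving the cheapest
incomparable landing site. Exactness replaces the genetic-algorithm
search of the classical tools; what those tools explore with iteration
and solution-pool budgets becomes an enumeration cap (default 1,000)
on the backtracking enumeration of co-optimal reconciliations.
Backtracking order is deterministic: events in the order cospeciation <
duplication < switch, host positions by canonical label with ties
resolved root-ward (so perfectly congruent tanglegrams reconcile to the
pure-tracking solution under any cost scheme that admits it). Floating
point ties are compared at 1e−9; all-integer cost vectors are exact.

`brute_force_solve` is an independently written oracle — memoized
recursion enumerating every pair of child placements with losses from
host path lengths, no auxiliary tables — guard-railed at seven tips per
tree. The test suite checks exact cost agreement with the production
solver on hundreds of random tanglegrams with random integer costs.

Three preset cost schemes sweep the switch cost over 0, 1, 2 units with
tracking at 0 and duplication/loss/ftd at 1, except that the zero
switch-cost scheme also zeroes the duplication cost, kept literally as
published for the tool this reimplements.

## Permutation null

The null model reassigns every symbiont tip independently to one
uniformly random host tip and re-solves; the test is one-sided (lower
cost = better fit). Monte-Carlo p-values use add-one smoothing,
p = (1 + #{null ≤ observed}) / (N + 1), so p ∈ (0, 1]; exhaustive mode
enumerates all |H|^|S| single-host mappings (≤ 10^6 guard rail) and
needs no smoothing, the observed mapping counting among the
enumerated ones. A `permute_observed` variant shuffles the observed
host multiset across tips instead, for users who prefer a
degree-preserving null; the default matches the cited software's
documented randomization.

## The Poisson phylogenetic GLMM

The model, priors and H² are as given in the README. Conventions:

- **Host correlation matrix.** Entry (i, j) is the depth of the MRCA of
  tips i and j divided by the maximum root-to-tip depth; the diagonal
  is exactly 1. On cladograms, Grafen's rule (node height proportional
  to descendant tip count minus one, root normalized to 1) assigns
  depths first. When the covariate is computed on a coarser tree (e.g.
  order-level), several hosts simply share one correlation-matrix
  label.
- **Priors.** Variance components: scaled inverse-chi-squared with
  scale V = 1 and degree of belief ν = 0.02 by default (shape ν/2,
  scale νV/2) — a standard weakly-informative choice for this model
  family. Fixed effects: zero-mean Gaussians with variance 10^10.
- **H² denominator.** V_phylo + V_genus + V_resid by default; the
  genus-free variant is always computed alongside, since conventions
  differ on whether a non-phylogenetic grouping factor belongs in the
  "total" variance.
- **Sampler.** Metropolis-within-Gibbs, numba-compiled: random-walk
  updates on fixed effects and each latent effect (host effects use the
  multivariate-normal conditional through the precision matrix),
  conjugate inverse-gamma draws for the variances, and five
  likelihood-invariant translation moves that decorrelate the
  intercept from each random-effect block and the slope from the host
  and observation blocks (the covariate is constant within a host, so
  β1 ↦ β1 + δ, a ↦ a − δx leaves the linear predictor unchanged and is
  accepted on prior ratios alone). The covariate is mean-centered
  internally and the intercept transformed back. Step sizes adapt
  toward 0.44 acceptance during burn-in only, preserving detailed
  balance for retained samples.
- **Chain settings.** Default 3 chains × 10^5 iterations, burn-in
  2 × 10^4, thinning 50 — the package's desk-scale default; the
  original analysis's 5 × 10^6 iterations are one argument change and
  target the identical posterior. Convergence is monitored with the
  Gelman–Rubin PSRF, √(((m−1)/m·W + B/m)/W).
- **Degenerate inputs.** An empty record list samples the variance
  components from their priors (the prior-recovery test uses ν = 6,
  V = 2, whose mean νV/(ν−2) = 3 is finite; the default ν = 0.02 prior
  has no finite mean, so no mean-recovery statement is possible for
  it). Near-singular correlation matrices receive a 10^−10 ridge
  before inversion.

Correctness is defined behaviorally, not by sampler identity: slope
recovery within ±0.25 at β1 = 0.5, V_phylo = 0.3, n = 100; 95% CI
coverage of 0 under the null; prior-only recovery; PSRF < 1.1 — all at
the default chain settings.

## Synthetic data: what it emulates, and what it does not

`simulate_host_tree` draws ultrametric Yule trees (waiting time
exponential with rate k·λ at k lineages, observed after a final wait at
n lineages, so E[height] = Σ_{k=2..n} 1/(kλ)). `simulate_cophylogeny`
runs one symbiont lineage down the host tree: cospeciation with
probability `p_cospeciation` at each host speciation (default 0.8);
otherwise a loss on one uniformly chosen daughter, except at a host
cherry where with probability `p_ftd_cherry` (default 0.05) the lineage
becomes a widespread tip (one ftd) — failure to diverge is simulated
only at cherries so that widespread lineages stay tip-level, matching
the solver's ftd semantics. Switches and duplications arrive along
edges as Poisson processes (defaults 0.5 and 0.1 per unit length per
lineage); a switch recipient is drawn uniformly among the host edges
extant at the switch time, so the simulated truth is time-consistent
even though the solver is untimed — recovery experiments therefore also
measure the cost of that relaxation. Every event is ledgered, and
cospeciations + duplications + switches equals the internal symbiont
node count by construction. At switch rate 2 the branching process is
strongly supercritical and symbiont trees can run to thousands of tips;
a 10^5-lineage cap guards against runaway configurations.

`simulate_claderank_table` computes host clade ranks from the tree,
assigns genus labels from the host subtree blocks two speciations below
the root, and draws responses from exactly the GLMM the fitter targets.
Simulated responses are Poisson counts and may be zero, unlike observed
clade ranks (≥ 1); the record type accepts both.

Problem sizes in the tests and the acceptance script — 10-tip hosts for
the simulation grids, 200 oracle comparisons at ≤ 6 tips, 20 replicates
per GLMM scenario, 50-tip congruence checks — are the package's chosen
desk-scale defaults; they exercise every code path while keeping a full
run in minutes.

**Limitations.** The simulators do not emulate: phylogenetic
uncertainty (tips are observed without error, whereas the motivating
system's symbiont tree had low support), extinction (the host process
is pure-birth), within-host population structure or incomplete lineage
sorting, correlated switch preferences (recipients are uniform,
not distance-dependent), or widespread *internal* lineages (ftd is
tip-level only). Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative
model, not robustness to gene-tree error or model misspecification in
real data. The reconciliation cost model itself is the standard
parsimony abstraction: it cannot distinguish co-evolution from
phylogenetically correlated host shifting, which is precisely why the
clade-rank GLMM is implemented alongside it.
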