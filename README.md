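# cophylotrack

Did a clade of host-associated organisms diversify by *tracking* their
hosts' phylogeny (codivergence), or by *shifting* between hosts?
`cophylotrack` implements the two complementary tests used to answer
this for the *Enchenopa binotata* treehopper species complex and its
host plants, as reusable, fully tested components:

1. **Event-based cophylogenetic reconciliation.** A tanglegram — host
   tree H, symbiont tree S, and a tip association map φ — is scored by
   embedding S into H under the five-event model (cospeciation /
   phylogenetic tracking, duplication, host switch, loss, failure to
   diverge), each event carrying a user-chosen cost. The solver is an
   exact dynamic program over (symbiont node, host position) pairs, so
   the returned reconciliation is a global optimum rather than the
   output of a heuristic search; all co-optimal reconciliations can be
   enumerated, and cost schemes swept to test sensitivity.
2. **A random-tip-mapping permutation null.** Significance of the
   observed reconciliation cost is assessed against tanglegrams whose
   symbiont tips are independently reassigned to uniformly random host
   tips (Monte-Carlo, or exhaustively on small instances).
3. **A clade-rank co-phylogenesis test.** Clade rank — the number of
   speciation events between a tree's root and a tip — is a
   topology-only proxy for relative taxon age. A Bayesian Poisson GLMM
   with log link regresses symbiont clade rank y on host clade rank x,

       y_i ~ Poisson(exp(β0 + β1 x_i + a_host(i) + g_genus(i) + e_i)),

   with a phylogenetically structured host effect a ~ N(0, V_phylo C),
   an i.i.d. genus effect g ~ N(0, V_genus I) and observation-level
   overdispersion e ~ N(0, V_resid I). Phylogenetic heritability
   H² = V_phylo / (V_phylo + V_genus + V_resid), the analogue of
   Pagel's λ, measures phylogenetic signal in the distribution of
   speciation events.

A synthetic-data module generates tanglegrams from a joint
host–symbiont branching process with a known event ledger, and
clade-rank tables drawn from exactly the GLMM above, so every stage can
be validated against ground truth. The package also ships the study
fixture: the 15-taxon host-plant cladogram spanning eight angiosperm
orders and the 61-specimen association table.

## Worked example: reconciliation with known truth

```python
from cophylotrack import (CophyloSimConfig, EventCosts, PAPER_SCHEMES,
                          cost_sweep, permutation_test,
                          simulate_cophylogeny, simulate_host_tree, solve)

host = simulate_host_tree(10, seed=42)            # ultrametric Yule tree
cfg = CophyloSimConfig(seed=43, p_cospeciation=0.7, switch_rate=0.8)
tg, truth = simulate_cophylogeny(host, cfg)       # tanglegram + event ledger

costs = EventCosts(tracking_cost=0, duplication_cost=1, switch_cost=1,
                   loss_cost=1, ftd_cost=1)
rec = solve(tg, costs)
print(truth.counts)   # EventCounts(cospeciations=18, duplications=1, switches=13, losses=6, ftd=0)
print(rec.counts)     # EventCounts(cospeciations=19, duplications=2, switches=11, losses=2, ftd=0)
print(rec.total_cost) # 15.0

res = permutation_test(tg, costs, n_permutations=999, seed=7)
print(res.p_value)    # 0.001
```

The solver recovers the simulated history closely (19 inferred vs. 18
true cospeciations, 11 vs. 13 switches; the optimum may legitimately
explain a few true switches more parsimoniously), and the observed cost
beats all 999 random tip mappings (p = 0.001, the smallest value a
999-draw test can report). Sweeping the three cost schemes of the
sensitivity analysis (`cost_sweep(tg, PAPER_SCHEMES)`) shows how
inferred event counts respond to the switch cost:

```
switch_cost  cospeciations  switches  losses  total_cost  n_optima
        0.0             10        21       0         0.0      1000
        1.0             19        11       2        15.0        28
        2.0             19        11       2        26.0        16
```

## Worked example: the clade-rank GLMM

```python
from cophylotrack import (build_phylo_correlation, fit_poisson_pglmm,
                          phylogenetic_heritability,
                          simulate_claderank_table, simulate_host_tree)

host = simulate_host_tree(10, seed=77)
corr = build_phylo_correlation(host)
records = simulate_claderank_table(host, beta0=1.0, beta1=0.5, V_phylo=0.3,
                                   V_genus=0.1, V_resid=0.1,
                                   n_per_host=10, seed=78)
result = fit_poisson_pglmm(records, corr, seed=79)
print(result.summary.round(3))
```

```
              mean  ci_lower  ci_upper   psrf
parameter
intercept    0.732    -1.281     2.860  1.000
slope        0.511    -0.071     1.041  1.001
V_phylo      0.480     0.102     1.486  1.001
V_genus      0.469     0.005     3.108  1.000
V_resid      0.081     0.048     0.126  1.000
H2           0.613     0.071     0.927  1.001
H2_no_genus  0.804     0.536     0.954  1.001
```

The posterior mean slope (0.511) recovers the simulated β1 = 0.5; PSRF
(Gelman–Rubin) ≈ 1.0 across three chains indicates convergence.
`phylogenetic_heritability(result)` summarizes the H² posterior.

## Command line

Each analysis is also exposed as a subcommand:

```
cophylotrack validate  --host H.nwk --symbiont S.nwk --assoc A.tsv
cophylotrack reconcile --host H.nwk --symbiont S.nwk --assoc A.tsv \
    --costs tracking=0,dup=1,switch=1,loss=1,ftd=1 --out rec.json
cophylotrack sweep     --host H.nwk --symbiont S.nwk --assoc A.tsv --out sweep.tsv
cophylotrack permtest  --host H.nwk --symbiont S.nwk --assoc A.tsv \
    --n 1000 --seed 7 --out perm.json
cophylotrack pglmm     --records r.tsv --host H.nwk --lengths grafen \
    --chains 3 --seed 11 --out glmm.json
cophylotrack simulate cophylo --n-hosts 10 --p-cosp 0.8 --switch-rate 0.5 \
    --seed 3 --out-dir sim/
cophylotrack fixture   --out-dir fixtures/
```

Association tables are TSVs with columns `symbiont_tip` and `host`
(multiple hosts separated by `;`, `Unknown` for missing host data) and
optional `species` / `genus` columns.

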