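"""Random-tip-mapping significance test for reconciliation cost.

The null model reassigns every symbiont tip independently to one host
tip drawn uniformly at random (the "random tip mapping" randomization of
event-based cophylogeny software), re-solves the reconciliation under
the same event costs, and asks how often a random association is at
least as cheap as the observed one.  Lower cost means better fit, so the
test is one-sided.

Two modes are available: Monte-Carlo sampling of mappings (with add-one
smoothing so the p-value is never zero) and exhaustive enumeration of
all ``n_hosts ** n_symbiont_tips`` single-host mappings on small
instances.  A ``permute_observed`` variant shuffles the observed host
multiset across symbiont tips instead of resampling uniformly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .reconcile import EventCosts, solve
from .trees import Tanglegram

__all__ = ["PermutationResult", "random_tip_mapping", "permutation_test"]

_EXHAUSTIVE_LIMIT = 10 ** 6


@dataclass
class PermutationResult:
    observed_cost: float
    null_costs: list[float]
    n_permutations: int
    p_value: float
    mode: str
    seed: int | None


def random_tip_mapping(tg: Tanglegram, rng: np.random.Generator,
                       permute_observed: bool = False) -> Tanglegram:
    """Return a copy of ``tg`` with randomized tip associations.

    By default each symbiont tip is independently reassigned to a single
    host tip chosen uniformly at random.  With ``permute_observed``, the
    observed multiset of host assignments is shuffled across symbiont
    tips instead (widespread tips keep their host sets together).
    """
    sym_tips = sorted(tg.assoc)
    host_tips = sorted(tg.host.tip_labels())
    if permute_observed:
        pool = [tg.assoc[t] for t in sym_tips]
        perm = rng.permutation(len(pool))
        assoc = {t: pool[perm[i]] for i, t in enumerate(sym_tips)}
    else:
        draws = rng.integers(0, len(host_tips), size=len(sym_tips))
        assoc = {t: frozenset({host_tips[draws[i]]})
                 for i, t in enumerate(sym_tips)}
    return Tanglegram(tg.host, tg.symbiont, assoc)


def permutation_test(tg: Tanglegram, costs: EventCosts,
                     n_permutations: int = 1000, seed: int = 0,
                     mode: str = "monte_carlo",
                     permute_observed: bool = False,
                     switch_constraint: str = "incomparable"
                     ) -> PermutationResult:
    """Test whether the observed association beats random tip mappings.

    monte_carlo
        ``p = (1 + #{null <= observed}) / (n_permutations + 1)``.
    exhaustive
        All single-host mappings are enumerated (observed mapping is one
        of them when it is single-host); ``p = #{cost <= observed} /
        total``.  Guard-railed to 10^6 mappings.
    """
    observed = solve(tg, costs, switch_constraint).total_cost

    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        null_costs = []
        for _ in range(n_permutations):
            rnd = random_tip_mapping(tg, rng, permute_observed)
            null_costs.append(solve(rnd, costs, switch_constraint).total_cost)
        hits = sum(1 for c in null_costs if c <= observed + 1e-9)
        p = (1 + hits) / (n_permutations + 1)
        return PermutationResult(observed, null_costs, n_permutations, p,
                                 "monte_carlo", seed)

    if mode == "exhaustive":
        if permute_observed:
            raise ValueError("exhaustive mode enumerates uniform mappings only")
        sym_tips = sorted(tg.assoc)
        host_tips = sorted(tg.host.tip_labels())
        total = len(host_tips) ** len(sym_tips)
        if total > _EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration of {total} mappings exceeds the "
                f"{_EXHAUSTIVE_LIMIT} guard rail")
        null_costs = []
        hits = 0
        for combo in itertools.product(host_tips, repeat=len(sym_tips)):
            assoc = {t: frozenset({h}) for t, h in zip(sym_tips, combo)}
            c = solve(Tanglegram(tg.host, tg.symbiont, assoc), costs,
                      switch_constraint).total_cost
            null_costs.append(c)
            if c <= observed + 1e-9:
                hits += 1
        p = hits / total
        return PermutationResult(observed, null_costs, total, p,
                                 "exhaustive", None)

    raise ValueError(f"unknown mode {mode!r}")
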