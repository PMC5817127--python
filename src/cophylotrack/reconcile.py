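"""Event-based cophylogenetic reconciliation.

Embeds a symbiont (parasite) tree into a host tree under the five-event
model used by event-based cophylogeny software: cospeciation (a.k.a.
phylogenetic tracking), duplication, host switch, loss (sorting event)
and failure to diverge.  Each event carries a user-chosen non-negative
cost and the solver returns a minimum-total-cost embedding.

The host tree is treated as untimed.  Switch targets are by default
restricted to host positions *incomparable* to the source (neither
ancestral nor descendant), the weakest constraint that forbids a lineage
from jumping into its own past; global time-consistency across multiple
switches is not enforced, as in most untimed duplication-transfer-loss
solvers.

The solver is an exact dynamic program over (symbiont node, host node)
pairs with "enter-subtree" and "jump-out" auxiliary tables; it replaces
the genetic-algorithm search of the classical tools with an exhaustive
optimum.  A separately-written brute-force oracle (memoized recursion
over all child placements, no auxiliary tables) verifies it on small
instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .trees import Tanglegram, Tree, TreeError

__all__ = [
    "EventCosts",
    "EventCounts",
    "Reconciliation",
    "PAPER_SCHEMES",
    "solve",
    "brute_force_solve",
    "enumerate_optima",
    "cost_sweep",
]

INF = float("inf")

COSPECIATION = "cospeciation"
DUPLICATION = "duplication"
SWITCH = "switch"
_EVENT_ORDER = {COSPECIATION: 0, DUPLICATION: 1, SWITCH: 2}


@dataclass(frozen=True)
class EventCosts:
    """Cost of each reconciliation event, in dimensionless units."""

    tracking_cost: float = 0.0     # cospeciation / phylogenetic tracking
    duplication_cost: float = 1.0
    switch_cost: float = 1.0
    loss_cost: float = 1.0
    ftd_cost: float = 1.0          # failure to diverge

    def __post_init__(self):
        for name in ("tracking_cost", "duplication_cost", "switch_cost",
                     "loss_cost", "ftd_cost"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.tracking_cost, self.duplication_cost, self.switch_cost,
                self.loss_cost, self.ftd_cost)


@dataclass(frozen=True)
class EventCounts:
    """Number of events of each kind in one reconciliation."""

    cospeciations: int = 0
    duplications: int = 0
    switches: int = 0
    losses: int = 0
    ftd: int = 0

    def total_cost(self, costs: EventCosts) -> float:
        return (self.cospeciations * costs.tracking_cost
                + self.duplications * costs.duplication_cost
                + self.switches * costs.switch_cost
                + self.losses * costs.loss_cost
                + self.ftd * costs.ftd_cost)

    def __add__(self, other: "EventCounts") -> "EventCounts":
        return EventCounts(
            self.cospeciations + other.cospeciations,
            self.duplications + other.duplications,
            self.switches + other.switches,
            self.losses + other.losses,
            self.ftd + other.ftd,
        )


# Cost schemes for the tracking-vs-switching sensitivity sweep:
# tracking fixed at 0; switch cost at 0, 1 and 2; duplication, loss and
# failure-to-diverge at 1 except that duplication drops to 0 alongside a
# zero switch cost (the zero/zero scheme is kept literally as published
# by the tool this reimplements).
PAPER_SCHEMES: list[EventCosts] = [
    EventCosts(0.0, 0.0, 0.0, 1.0, 1.0),
    EventCosts(0.0, 1.0, 1.0, 1.0, 1.0),
    EventCosts(0.0, 1.0, 2.0, 1.0, 1.0),
]


@dataclass
class Reconciliation:
    """One embedding of the symbiont tree into the host tree.

    ``placement`` maps each symbiont node id to the host node at (or on
    the edge above) which it sits; ``events`` maps each internal
    symbiont node id to an event label, with the switch target edge
    recorded for switches.  Loss and ftd placements are lists of host
    node ids (the host speciation crossed, resp. spanned).
    """

    placement: dict[int, int]
    events: dict[int, tuple]
    losses: list[int]
    ftd: list[int]
    counts: EventCounts
    total_cost: float
    costs: EventCosts

    def rescore(self) -> float:
        """Recompute the total cost from the event counts."""
        return self.counts.total_cost(self.costs)


# ---------------------------------------------------------------------------
# Indexed views of the two trees
# ---------------------------------------------------------------------------

class _HostIndex:
    """Array-oriented view of the host tree (postorder node indexing)."""

    def __init__(self, host: Tree):
        nodes = list(host.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n = len(nodes)
        self.children = [
            [self.index[id(c)] for c in n.children] for n in nodes
        ]
        self.parent = [-1] * self.n
        for i, n in enumerate(nodes):
            for c in self.children[i]:
                self.parent[c] = i
        self.is_tip = [not n.children for n in nodes]
        self.tip_of = {n.label: self.index[id(n)] for n in nodes if not n.children}
        # descendant-or-self matrix and path lengths in edges
        anc = np.zeros((self.n, self.n), dtype=bool)
        plen = np.full((self.n, self.n), -1, dtype=np.int64)
        for i in range(self.n):
            j, d = i, 0
            while j != -1:
                anc[j, i] = True       # j is an ancestor-or-self of i
                plen[j, i] = d
                j = self.parent[j]
                d += 1
        self.desc_or_self = anc        # desc_or_self[a, u]: u inside subtree(a)
        self.path_len = plen           # edges from a down to u, -1 if not below
        self.comparable = anc | anc.T  # ancestor, descendant or equal
        # canonical display label per node, for deterministic tie order
        self.label: list[str] = [""] * self.n
        for i, nd in enumerate(nodes):
            if not nd.children:
                self.label[i] = nd.label  # type: ignore[assignment]
            else:
                self.label[i] = min(self.label[c] for c in self.children[i])

    def mrca(self, tips: list[int]) -> int:
        cur = tips[0]
        for t in tips[1:]:
            while not self.desc_or_self[cur, t]:
                cur = self.parent[cur]
        return cur


class _SymbiontIndex:
    """Postorder view of the symbiont tree plus per-tip host placements."""

    def __init__(self, tg: Tanglegram, hidx: _HostIndex, costs: EventCosts):
        nodes = list(tg.symbiont.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n = len(nodes)
        self.children = [[self.index[id(c)] for c in n.children] for n in nodes]
        self.is_tip = [not n.children for n in nodes]
        self.root = self.index[id(tg.symbiont.root)]
        # fixed placement and intrinsic cost for every symbiont tip
        self.tip_site: dict[int, int] = {}
        self.tip_base_cost: dict[int, float] = {}
        self.tip_base_counts: dict[int, EventCounts] = {}
        self.tip_loss_sites: dict[int, list[int]] = {}
        self.tip_ftd_sites: dict[int, list[int]] = {}
        for i, n in enumerate(nodes):
            if n.children:
                continue
            hosts = sorted(tg.assoc[n.label])
            host_ids = [hidx.tip_of[h] for h in hosts]
            if len(host_ids) == 1:
                self.tip_site[i] = host_ids[0]
                self.tip_base_cost[i] = 0.0
                self.tip_base_counts[i] = EventCounts()
                self.tip_loss_sites[i] = []
                self.tip_ftd_sites[i] = []
            else:
                m = hidx.mrca(host_ids)
                span: set[int] = set()
                for t in host_ids:
                    j = t
                    while True:
                        span.add(j)
                        if j == m:
                            break
                        j = hidx.parent[j]
                ftd_sites, loss_sites = [], []
                for j in sorted(span):
                    kids = hidx.children[j]
                    if not kids:
                        continue
                    inside = [k for k in kids if k in span]
                    if len(inside) == len(kids):
                        ftd_sites.append(j)   # lineage persists on both daughters
                    for k in kids:
                        if k not in span:
                            loss_sites.append(j)  # daughter not reached by the tip
                self.tip_site[i] = m
                self.tip_base_cost[i] = (len(ftd_sites) * costs.ftd_cost
                                         + len(loss_sites) * costs.loss_cost)
                self.tip_base_counts[i] = EventCounts(
                    losses=len(loss_sites), ftd=len(ftd_sites))
                self.tip_loss_sites[i] = loss_sites
                self.tip_ftd_sites[i] = ftd_sites


def _check_tanglegram(tg: Tanglegram) -> None:
    if tg.n_symbiont_tips == 0 or tg.n_host_tips == 0:
        raise ValueError("empty tanglegram")
    if not tg.host.is_binary() or not tg.symbiont.is_binary():
        raise TreeError("reconciliation requires binary host and symbiont trees")


# ---------------------------------------------------------------------------
# The dynamic program
# ---------------------------------------------------------------------------

def _dp_tables(tg: Tanglegram, costs: EventCosts, switch_constraint: str):
    """Fill the A / in / out tables.

    ``A[p, v]`` is the minimum cost of embedding the subtree of symbiont
    node ``p`` with ``p``'s own event (or tip placement) exactly at host
    node ``v``.  ``inn[p, v]`` allows ``p`` to sit anywhere inside the
    subtree of ``v``, charging one loss per host speciation crossed on
    the way down.  ``out[p, v]`` is the cheapest landing site for a
    lineage switching away from ``v``.
    """
    if switch_constraint not in ("incomparable", "unconstrained"):
        raise ValueError(f"unknown switch constraint {switch_constraint!r}")
    hidx = _HostIndex(tg.host)
    sidx = _SymbiontIndex(tg, hidx, costs)
    H, P = hidx.n, sidx.n
    A = np.full((P, H), INF)
    inn = np.full((P, H), INF)
    out = np.full((P, H), INF)
    c_t, c_d, c_s, c_l, _ = costs.as_tuple()

    allowed = ~hidx.comparable if switch_constraint == "incomparable" \
        else np.ones((H, H), dtype=bool)

    for p in range(P):
        if sidx.is_tip[p]:
            A[p, sidx.tip_site[p]] = sidx.tip_base_cost[p]
        else:
            p1, p2 = sidx.children[p]
            for v in range(H):
                best = INF
                kids = hidx.children[v]
                if kids:
                    a, b = kids
                    cosp = c_t + min(inn[p1, a] + inn[p2, b],
                                     inn[p1, b] + inn[p2, a])
                    best = min(best, cosp)
                dup = c_d + inn[p1, v] + inn[p2, v]
                best = min(best, dup)
                sw = c_s + min(inn[p1, v] + out[p2, v],
                               inn[p2, v] + out[p1, v])
                best = min(best, sw)
                A[p, v] = best
        # enter-subtree table, bottom-up over hosts
        for v in range(H):   # postorder: children precede parents
            inn[p, v] = A[p, v]
            for c in hidx.children[v]:
                inn[p, v] = min(inn[p, v], c_l + inn[p, c])
        # jump-out table
        masked = np.where(allowed, A[p][None, :], INF)
        out[p] = masked.min(axis=1)
    return hidx, sidx, A, inn, out


def _backtrack(tg, costs, hidx, sidx, A, inn, out, switch_constraint,
               limit=1):
    """Enumerate up to ``limit`` optimal reconciliations.

    Tie exploration is deterministic: events are tried in the order
    cospeciation < duplication < switch and host positions by their
    canonical label (smallest descendant tip label, postorder index as a
    final tie-break).
    """
    c_t, c_d, c_s, c_l, _ = costs.as_tuple()
    # canonical label first; ties (a tip and its ancestors share the
    # smallest descendant label) resolve root-ward, so event preference
    # cospeciation < duplication < switch can act at internal nodes
    host_order = sorted(range(hidx.n), key=lambda v: (hidx.label[v], -v))
    opt = min(A[sidx.root, v] for v in range(hidx.n))

    def resolve_in(p: int, v: int, target: float):
        """All (landing, n_losses) with A[p,landing] + losses == target."""
        sites = []

        def rec(u: int, losses: int, acc: float, crossed: tuple):
            if acc > target + 1e-9:
                return
            if abs(A[p, u] + acc - target) < 1e-9:
                sites.append((u, losses, crossed))
            for c in sorted(hidx.children[u],
                            key=lambda x: (hidx.label[x], x)):
                rec(c, losses + 1, acc + c_l, crossed + (u,))

        rec(v, 0, 0.0, ())
        return sites

    def expand(p: int, v: int):
        """Yield partial reconciliations for symbiont subtree p at v."""
        if sidx.is_tip[p]:
            yield ({p: v}, {}, list(sidx.tip_loss_sites[p]),
                   list(sidx.tip_ftd_sites[p]), sidx.tip_base_counts[p])
            return
        p1, p2 = sidx.children[p]
        target = A[p, v]
        options = []
        kids = hidx.children[v]
        if kids:
            a, b = kids
            for (ca, cb) in ((a, b), (b, a)):
                if abs(c_t + inn[p1, ca] + inn[p2, cb] - target) < 1e-9:
                    options.append((COSPECIATION, (ca, cb)))
        if abs(c_d + inn[p1, v] + inn[p2, v] - target) < 1e-9:
            options.append((DUPLICATION, None))
        for (stay, jump) in ((p1, p2), (p2, p1)):
            if abs(c_s + inn[stay, v] + out[jump, v] - target) < 1e-9:
                options.append((SWITCH, (stay, jump)))
        options.sort(key=lambda o: _EVENT_ORDER[o[0]])

        for ev, info in options:
            if ev == COSPECIATION:
                ca, cb = info
                for (u1, l1, x1) in resolve_in(p1, ca, inn[p1, ca]):
                    for (u2, l2, x2) in resolve_in(p2, cb, inn[p2, cb]):
                        for r1 in expand(p1, u1):
                            for r2 in expand(p2, u2):
                                yield _merge(p, v, (COSPECIATION,), r1, r2,
                                             list(x1) + list(x2),
                                             EventCounts(cospeciations=1,
                                                         losses=l1 + l2))
            elif ev == DUPLICATION:
                for (u1, l1, x1) in resolve_in(p1, v, inn[p1, v]):
                    for (u2, l2, x2) in resolve_in(p2, v, inn[p2, v]):
                        for r1 in expand(p1, u1):
                            for r2 in expand(p2, u2):
                                yield _merge(p, v, (DUPLICATION,), r1, r2,
                                             list(x1) + list(x2),
                                             EventCounts(duplications=1,
                                                         losses=l1 + l2))
            else:
                stay, jump = info
                land_targets = [
                    u for u in host_order
                    if abs(A[jump, u] - out[jump, v]) < 1e-9
                    and (switch_constraint == "unconstrained"
                         or not hidx.comparable[v, u])
                ]
                for (u1, l1, x1) in resolve_in(stay, v, inn[stay, v]):
                    for u2 in land_targets:
                        for r1 in expand(stay, u1):
                            for r2 in expand(jump, u2):
                                yield _merge(p, v, (SWITCH, u2), r1, r2,
                                             list(x1),
                                             EventCounts(switches=1,
                                                         losses=l1))

    def _merge(p, v, ev, r1, r2, loss_sites, own_counts):
        pl = {p: v}
        pl.update(r1[0])
        pl.update(r2[0])
        evs = {p: ev}
        evs.update(r1[1])
        evs.update(r2[1])
        losses = loss_sites + r1[2] + r2[2]
        ftd = r1[3] + r2[3]
        counts = own_counts + r1[4] + r2[4]
        return (pl, evs, losses, ftd, counts)

    results: list[Reconciliation] = []
    seen: set = set()
    for v in host_order:
        if abs(A[sidx.root, v] - opt) >= 1e-9:
            continue
        for (pl, evs, losses, ftd, counts) in expand(sidx.root, v):
            sig = (tuple(sorted(pl.items())), tuple(sorted(evs.items())),
                   tuple(sorted(losses)), tuple(sorted(ftd)))
            if sig in seen:
                continue
            seen.add(sig)
            rec = Reconciliation(pl, evs, losses, ftd, counts,
                                 float(opt), costs)
            assert abs(rec.rescore() - rec.total_cost) < 1e-9, \
                "event counts inconsistent with optimal cost"
            results.append(rec)
            if len(results) >= limit:
                return results
    return results


def solve(tg: Tanglegram, costs: EventCosts,
          switch_constraint: str = "incomparable") -> Reconciliation:
    """Return one minimum-cost reconciliation (deterministic)."""
    _check_tanglegram(tg)
    hidx, sidx, A, inn, out = _dp_tables(tg, costs, switch_constraint)
    recs = _backtrack(tg, costs, hidx, sidx, A, inn, out,
                      switch_constraint, limit=1)
    return recs[0]


def enumerate_optima(tg: Tanglegram, costs: EventCosts, limit: int = 1000,
                     switch_constraint: str = "incomparable"
                     ) -> list[Reconciliation]:
    """Return up to ``limit`` distinct minimum-cost reconciliations."""
    if limit < 1:
        raise ValueError("limit must be positive")
    _check_tanglegram(tg)
    hidx, sidx, A, inn, out = _dp_tables(tg, costs, switch_constraint)
    return _backtrack(tg, costs, hidx, sidx, A, inn, out,
                      switch_constraint, limit=limit)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_BRUTE_MAX_TIPS = 7


def brute_force_solve(tg: Tanglegram, costs: EventCosts,
                      switch_constraint: str = "incomparable"
                      ) -> Reconciliation:
    """Exhaustive minimum-cost search over all event-consistent embeddings.

    Verification oracle: enumerates, for every symbiont node placement,
    all pairs of child placements and all admissible event readings,
    with losses charged from host path lengths.  Independent of the
    production solver's auxiliary tables.  Guard-railed to seven tips
    per tree.
    """
    _check_tanglegram(tg)
    if tg.n_symbiont_tips > _BRUTE_MAX_TIPS or tg.n_host_tips > _BRUTE_MAX_TIPS:
        raise ValueError(
            f"brute_force_solve is limited to {_BRUTE_MAX_TIPS} tips per tree")
    hidx = _HostIndex(tg.host)
    sidx = _SymbiontIndex(tg, hidx, costs)
    c_t, c_d, c_s, c_l, _ = costs.as_tuple()
    H = hidx.n
    inside = hidx.desc_or_self
    plen = hidx.path_len
    comp = hidx.comparable

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(p: int, v: int) -> float:
        if sidx.is_tip[p]:
            return sidx.tip_base_cost[p] if v == sidx.tip_site[p] else INF
        p1, p2 = sidx.children[p]
        best = INF
        kids = hidx.children[v]
        for u1, u2 in itertools.product(range(H), range(H)):
            f1, f2 = f(p1, u1), f(p2, u2)
            if f1 == INF or f2 == INF:
                continue
            base = f1 + f2
            # cospeciation: children into the two distinct host subtrees
            if kids:
                a, b = kids
                if inside[a, u1] and inside[b, u2]:
                    best = min(best, base + c_t
                               + c_l * (plen[a, u1] + plen[b, u2]))
                if inside[b, u1] and inside[a, u2]:
                    best = min(best, base + c_t
                               + c_l * (plen[b, u1] + plen[a, u2]))
            # duplication: both children within subtree(v)
            if inside[v, u1] and inside[v, u2]:
                best = min(best, base + c_d
                           + c_l * (plen[v, u1] + plen[v, u2]))
            # switch: one child stays, the other jumps
            for us, uj in ((u1, u2), (u2, u1)):
                ok = (not comp[v, uj]) if switch_constraint == "incomparable" \
                    else True
                if inside[v, us] and ok:
                    best = min(best, base + c_s + c_l * plen[v, us])
        return best

    opt = min(f(sidx.root, v) for v in range(H))
    if opt == INF:
        raise ValueError("no event-consistent embedding exists")
    # event counts / placements come from the production backtrack; the
    # oracle's contribution is the independently derived optimal cost.
    hidx2, sidx2, A, inn, out = _dp_tables(tg, costs, switch_constraint)
    rec = _backtrack(tg, costs, hidx2, sidx2, A, inn, out,
                     switch_constraint, limit=1)[0]
    rec = Reconciliation(rec.placement, rec.events, rec.losses, rec.ftd,
                         rec.counts, float(opt), costs)
    return rec


# ---------------------------------------------------------------------------
# Cost sweep
# ---------------------------------------------------------------------------

def cost_sweep(tg: Tanglegram, schemes: list[EventCosts],
               optima_cap: int = 1000,
               switch_constraint: str = "incomparable"):
    """Reconcile under each cost scheme and tabulate the results.

    Returns a :class:`pandas.DataFrame` with one row per scheme: the
    event counts of the deterministic first optimum, the optimal total
    cost, and the number of distinct optima found (capped).
    """
    import pandas as pd

    if not schemes:
        raise ValueError("schemes must be non-empty")
    rows = []
    for costs in schemes:
        optima = enumerate_optima(tg, costs, limit=optima_cap,
                                  switch_constraint=switch_constraint)
        first = optima[0]
        rows.append({
            "tracking_cost": costs.tracking_cost,
            "duplication_cost": costs.duplication_cost,
            "switch_cost": costs.switch_cost,
            "loss_cost": costs.loss_cost,
            "ftd_cost": costs.ftd_cost,
            "cospeciations": first.counts.cospeciations,
            "duplications": first.counts.duplications,
            "switches": first.counts.switches,
            "losses": first.counts.losses,
            "ftd": first.counts.ftd,
            "total_cost": first.total_cost,
            "n_optima": len(optima),
        })
    return pd.DataFrame(rows)
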