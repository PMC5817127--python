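"""Synthetic tanglegrams, clade-rank tables and the packaged study fixture.

Two generators make every pipeline stage testable against known truth:

* a joint host-symbiont branching process that produces tanglegrams with
  a full event ledger (cospeciations, duplications, host switches,
  losses, failures to diverge), the generative converse of the
  reconciliation event model; and
* a clade-rank table simulator that draws Poisson responses from exactly
  the GLMM fitted by :mod:`cophylotrack.pglmm`.

The packaged fixture is the treehopper study system: a 15-taxon host
plant cladogram spanning eight angiosperm orders (order backbone stored
as static data following its published sources; within-order structure:
the two *Juglans* species are sisters relative to *Carya*, and among the
four *Viburnum* species *V. prunifolium* + *V. rufidulum* are the
closest pair, joined next by *V. lentago*, then *V. cassinoides*) and
the 61-specimen association table (44 ingroup specimens over 15 host
taxa in 10 genera, plus 17 outgroup specimens mostly without host data).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .pglmm import CladeRankRecord, build_phylo_correlation
from .trees import (AssociationTable, Tanglegram, Tree, TreeNode, clade_rank,
                    parse_newick, read_association_table)
from .reconcile import EventCounts

__all__ = [
    "CophyloSimConfig",
    "TrueHistory",
    "simulate_host_tree",
    "simulate_cophylogeny",
    "simulate_claderank_table",
    "random_binary_tree",
    "study_fixture",
]


# ---------------------------------------------------------------------------
# Host tree: Yule process
# ---------------------------------------------------------------------------

def simulate_host_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Tree:
    """Ultrametric Yule (pure-birth) tree with ``n_tips`` tips.

    Waiting times between births are exponential with rate ``k *
    birth_rate`` while ``k`` lineages are extant; the tree is observed
    after a final exponential wait at ``n_tips`` lineages, so the
    expected height is ``sum_{k=2}^{n} 1/(k * birth_rate)``.  Tips are
    labelled ``h1..hn`` left to right; bit-reproducible given ``seed``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    t = 0.0
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode()
        root.add_child(child)
        active.append((child, 0.0))
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(len(active)))
        node, start = active.pop(i)
        node.length = t - start
        for _ in range(2):
            child = TreeNode()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node, start in active:
        node.length = t - start
    tree = Tree(root)
    for i, tip in enumerate(tree.tips()):
        tip.label = f"h{i + 1}"
    return tree.validate()


# ---------------------------------------------------------------------------
# Joint host-symbiont branching process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CophyloSimConfig:
    """Rates and probabilities of the joint branching process.

    ``p_cospeciation`` applies at every host speciation met by a
    resident symbiont lineage; ``switch_rate`` and ``duplication_rate``
    are per unit branch length per symbiont lineage; ``p_ftd_cherry`` is
    the chance that a non-cospeciating lineage arriving at a host cherry
    spans both tips as one widespread tip.
    """

    seed: int = 0
    n_host_tips: int = 10
    host_birth_rate: float = 1.0
    p_cospeciation: float = 0.8
    switch_rate: float = 0.5
    duplication_rate: float = 0.1
    p_ftd_cherry: float = 0.05

    def __post_init__(self):
        for name in ("p_cospeciation", "p_ftd_cherry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("host_birth_rate", "switch_rate", "duplication_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_host_tips < 3:
            raise ValueError("n_host_tips must be >= 3")


@dataclass
class TrueHistory:
    """Ground-truth event ledger of a simulated cophylogeny."""

    counts: EventCounts
    provenance: list  # (event, host tip/node label or id, time)


_MAX_LINEAGES = 100_000


def simulate_cophylogeny(host: Tree, cfg: CophyloSimConfig
                         ) -> tuple[Tanglegram, TrueHistory]:
    """Run one symbiont lineage down ``host`` and record every event.

    The lineage starts at the host root.  At each host speciation it
    cospeciates with probability ``p_cospeciation``; otherwise, on a
    host cherry it may become a widespread tip spanning both daughters
    (one failure to diverge), else it follows one uniformly chosen
    daughter (one loss).  Along edges, switches and duplications arrive
    as Poisson processes; a switching daughter lands on a host edge
    chosen uniformly among the edges extant at the switch time.
    """
    if not host.has_branch_lengths():
        raise ValueError("host tree must carry branch lengths")
    if not host.is_binary():
        raise ValueError("host tree must be binary")
    rng = np.random.default_rng(cfg.seed)

    # host node times
    time_of: dict[int, float] = {id(host.root): 0.0}
    for node in host.preorder():
        if node.parent is not None:
            time_of[id(node)] = time_of[id(node.parent)] + float(node.length)
    host_nodes = list(host.preorder())
    node_by_id = {id(n): n for n in host_nodes}
    # an "edge" is identified by its child node; extant at time t when
    # time(parent) <= t < time(node)
    edges = [n for n in host_nodes if n.parent is not None]

    def edges_alive(t: float, exclude) -> list[TreeNode]:
        out = []
        for n in edges:
            if time_of[id(n.parent)] <= t < time_of[id(n)] and n is not exclude:
                out.append(n)
        return out

    events: list[tuple] = []
    n_cosp = n_dup = n_switch = n_loss = n_ftd = 0

    sym_root = TreeNode()
    # work stack of (symbiont node, host node, arrival time, mode)
    # mode "edge": travelling on the edge above the host node
    # mode "node": sitting at the host node itself (speciation or tip)
    stack = [(sym_root, host.root, 0.0, "node")]
    n_lineages = 1
    while stack:
        if n_lineages > _MAX_LINEAGES:
            raise RuntimeError("symbiont lineage count exploded; lower the rates")
        sym, hnode, t, mode = stack.pop()
        if mode == "edge":
            end = time_of[id(hnode)]
            total_rate = cfg.switch_rate + cfg.duplication_rate
            t_ev = t + rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if t_ev < end:
                left, right = TreeNode(), TreeNode()
                sym.add_child(left)
                sym.add_child(right)
                n_lineages += 1
                if rng.random() < cfg.switch_rate / total_rate:
                    targets = edges_alive(t_ev, exclude=hnode)
                    if targets:
                        n_switch += 1
                        tgt = targets[int(rng.integers(len(targets)))]
                        events.append(("switch", tgt.label or id(tgt), t_ev))
                        stack.append((right, tgt, t_ev, "edge"))
                        stack.append((left, hnode, t_ev, "edge"))
                        continue
                    # no contemporaneous recipient: degenerate to duplication
                n_dup += 1
                events.append(("duplication", hnode.label or id(hnode), t_ev))
                stack.append((right, hnode, t_ev, "edge"))
                stack.append((left, hnode, t_ev, "edge"))
            else:
                stack.append((sym, hnode, end, "node"))
            continue

        # mode == "node"
        if hnode.is_tip:
            sym.label = f"@single:{hnode.label}"  # relabelled below
            continue
        ca, cb = hnode.children
        if rng.random() < cfg.p_cospeciation:
            n_cosp += 1
            events.append(("cospeciation", hnode.label or id(hnode), t))
            left, right = TreeNode(), TreeNode()
            sym.add_child(left)
            sym.add_child(right)
            n_lineages += 1
            stack.append((right, cb, t, "edge"))
            stack.append((left, ca, t, "edge"))
            continue
        is_cherry = ca.is_tip and cb.is_tip
        if is_cherry and rng.random() < cfg.p_ftd_cherry:
            n_ftd += 1
            events.append(("ftd", hnode.label or id(hnode), t))
            sym.label = f"@wide:{ca.label};{cb.label}"
            continue
        n_loss += 1
        follow = ca if rng.random() < 0.5 else cb
        lost = cb if follow is ca else ca
        events.append(("loss", lost.label or id(lost), t))
        stack.append((sym, follow, t, "edge"))

    # relabel symbiont tips deterministically and build the association
    sym_tree = Tree(sym_root)
    assoc: dict[str, frozenset[str]] = {}
    for i, tip in enumerate(sym_tree.tips()):
        tag = tip.label
        label = f"s{i + 1}"
        tip.label = label
        if tag.startswith("@single:"):
            assoc[label] = frozenset({tag[len("@single:"):]})
        else:
            assoc[label] = frozenset(tag[len("@wide:"):].split(";"))
    sym_tree.validate()

    counts = EventCounts(n_cosp, n_dup, n_switch, n_loss, n_ftd)
    n_internal = len(sym_tree.internal_nodes())
    assert counts.cospeciations + counts.duplications + counts.switches == n_internal
    tg = Tanglegram(host, sym_tree, assoc)
    return tg, TrueHistory(counts, events)


# ---------------------------------------------------------------------------
# Clade-rank tables with known regression structure
# ---------------------------------------------------------------------------

def simulate_claderank_table(host: Tree, beta0: float, beta1: float,
                             V_phylo: float, V_genus: float, V_resid: float,
                             n_per_host: int, seed: int,
                             lengths: str = "given") -> list[CladeRankRecord]:
    """Draw clade-rank records from the exact Poisson PGLMM.

    Host clade ranks are computed from ``host``; genus labels are the
    host subtree blocks two speciations below the root (so related hosts
    share a genus); responses follow
    ``y ~ Poisson(exp(beta0 + beta1 x + a_host + g_genus + e))`` with
    ``a ~ N(0, V_phylo C)`` for the tree's correlation matrix ``C``.
    Simulated responses may be zero even though observed clade ranks are
    at least 1.
    """
    if min(V_phylo, V_genus, V_resid) < 0:
        raise ValueError("variances must be >= 0")
    rng = np.random.default_rng(seed)
    tips = host.tips()
    labels = [t.label for t in tips]
    ranks = {lab: clade_rank(host, lab) for lab in labels}

    # genus blocks: ancestor at depth 2 (or the tip itself when shallower)
    genus_of: dict[str, str] = {}
    block_ids: dict[int, int] = {}
    for tip in tips:
        node = tip
        chain = [node]
        while node.parent is not None:
            node = node.parent
            chain.append(node)
        chain.reverse()  # root .. tip
        block = chain[min(2, len(chain) - 1)]
        if id(block) not in block_ids:
            block_ids[id(block)] = len(block_ids) + 1
        genus_of[tip.label] = f"g{block_ids[id(block)]}"

    corr = build_phylo_correlation(host, lengths=lengths)
    order = [corr.index[lab] for lab in labels]
    C = corr.matrix[np.ix_(order, order)]
    if V_phylo > 0:
        a = rng.multivariate_normal(np.zeros(len(labels)), V_phylo * C,
                                    method="eigh")
    else:
        a = np.zeros(len(labels))
    genera = sorted({genus_of[lab] for lab in labels})
    g = {gen: (rng.normal(0.0, np.sqrt(V_genus)) if V_genus > 0 else 0.0)
         for gen in genera}

    records: list[CladeRankRecord] = []
    i = 0
    for j, lab in enumerate(labels):
        for _ in range(n_per_host):
            i += 1
            e = rng.normal(0.0, np.sqrt(V_resid)) if V_resid > 0 else 0.0
            eta = beta0 + beta1 * ranks[lab] + a[j] + g[genus_of[lab]] + e
            y = int(rng.poisson(np.exp(eta)))
            records.append(CladeRankRecord(f"sim_s{i}", y, lab, ranks[lab],
                                           genus_of[lab]))
    return records


# ---------------------------------------------------------------------------
# Miscellaneous generators and the packaged fixture
# ---------------------------------------------------------------------------

def random_binary_tree(labels: list[str], seed: int) -> Tree:
    """Random binary topology over ``labels`` (no branch lengths).

    Synthetic stand-in: joins uniformly chosen lineage pairs; useful as
    a symbiont topology when only associations are packaged.
    """
    if not labels:
        raise ValueError("need at least one label")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return Tree(nodes[0]).validate()


def study_fixture() -> tuple[Tree, AssociationTable]:
    """The packaged study system: host cladogram and association table.

    Returns the 15-taxon, eight-order host plant cladogram and the
    61-record specimen association table (44 ingroup records over 10
    host genera; 17 outgroup records, mostly with unknown hosts).
    """
    data = resources.files("cophylotrack.data")
    host = parse_newick((data / "host_tree.nwk").read_text(encoding="utf-8"))
    with (data / "associations.tsv").open("r", encoding="utf-8") as fh:
        assoc = read_association_table(fh)
    return host, assoc
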