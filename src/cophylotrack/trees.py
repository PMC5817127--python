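"""Rooted trees, newick I/O, association tables and tanglegrams.

This module supplies the substrate for cophylogenetic analysis: a light
rooted-tree container with validated invariants, newick reading/writing
(delegated to :mod:`dendropy` for parsing), tab-separated association
tables linking symbiont tips to host taxa, and the :class:`Tanglegram`
bundle consumed by the reconciliation and permutation machinery.

Clade rank — the number of speciation events separating a tip from the
root of its tree — is computed here because it is a purely topological
quantity; root's children have rank 1, so ranks are strictly positive on
any tree with at least two tips.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "TreeNode",
    "Tree",
    "NewickParseError",
    "TreeError",
    "AssociationError",
    "AssociationRecord",
    "AssociationTable",
    "Tanglegram",
    "parse_newick",
    "write_newick",
    "read_association_table",
    "build_tanglegram",
    "clade_rank",
    "resolve_polytomies",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed or violates tree invariants."""


class TreeError(ValueError):
    """Raised when a tree violates a structural precondition (e.g. polytomies)."""


class AssociationError(ValueError):
    """Raised for malformed or inconsistent association tables."""


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted tree.

    Parameters
    ----------
    label
        Tip label (required for tips, optional for internal nodes).
    length
        Branch length of the edge subtending this node, or ``None``.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind}>"


class Tree:
    """A rooted tree with uniquely-labelled tips.

    Child order is preserved as constructed.  Invariants (single root,
    unique non-empty tip labels, non-negative branch lengths) are checked
    by :meth:`validate`, which is called by the public constructors.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]  # type: ignore[misc]

    def find_tip(self, label: str) -> TreeNode:
        for n in self.tips():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not found in tree")

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.preorder() if n is not self.root
        )

    def depth_of(self, node: TreeNode) -> int:
        """Number of edges between ``node`` and the root."""
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def root_to_tip_length(self, label: str) -> float:
        node = self.find_tip(label)
        total = 0.0
        while node.parent is not None:
            if node.length is None:
                raise TreeError(f"edge above {node.label!r} lacks a branch length")
            total += node.length
            node = node.parent
        return total

    def validate(self) -> "Tree":
        labels = [n.label for n in self.tips()]
        if any(not lab for lab in labels):
            raise NewickParseError("tree contains an unlabelled or empty-labelled tip")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        for n in self.preorder():
            if n is not self.root and n.length is not None and n.length < 0:
                raise NewickParseError(
                    f"negative branch length {n.length} above node {n.label!r}"
                )
            for c in n.children:
                if c.parent is not n:
                    raise TreeError("parent pointers inconsistent")
        return self

    def copy(self) -> "Tree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Tree(rec(self.root))

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Return a copy restricted to the tips in ``keep``.

        Internal nodes left with a single child are suppressed (their
        branch lengths, when present, are summed).
        """
        keep_set = set(keep)
        missing = keep_set - set(self.tip_labels())
        if missing:
            raise TreeError(f"cannot prune to unknown tips: {sorted(missing)}")

        def rec(node: TreeNode) -> TreeNode | None:
            if node.is_tip:
                if node.label in keep_set:
                    return TreeNode(node.label, node.length)
                return None
            kept = [rec(c) for c in node.children]
            kept = [k for k in kept if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None and node.length is not None:
                    child.length = child.length + node.length
                elif node.length is not None:
                    child.length = node.length
                return child
            new = TreeNode(node.label, node.length)
            for k in kept:
                new.add_child(k)
            return new

        new_root = rec(self.root)
        if new_root is None:
            raise TreeError("pruning removed every tip")
        new_root.length = None
        return Tree(new_root).validate()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree with {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, underscores_to_spaces: bool = False) -> Tree:
    """Parse a single rooted newick statement into a :class:`Tree`.

    Parameters
    ----------
    text
        A newick string terminated by ``;``.  Quoted labels are
        supported; underscores in unquoted labels are preserved verbatim
        unless ``underscores_to_spaces`` is set.

    Raises
    ------
    NewickParseError
        On malformed input (with the offending position where the parser
        reports one), duplicate or empty tip labels, or negative branch
        lengths.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=not underscores_to_spaces,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several reader subclasses
        raise NewickParseError(f"newick parse failure: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = TreeNode(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Tree(convert(dtree.seed_node)).validate()


_UNQUOTED_OK = re.compile(r"^[A-Za-z0-9_.\-|/]+$")


def _format_label(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def write_newick(tree: Tree, canonical: bool = False) -> str:
    """Serialize a tree to newick.

    With ``canonical`` set, children of every node are ordered by their
    lexicographically smallest descendant tip label, so equal trees
    produce bit-identical strings.
    """
    tree.validate()

    def min_tip(node: TreeNode) -> str:
        if node.is_tip:
            return node.label  # type: ignore[return-value]
        return min(min_tip(c) for c in node.children)

    def rec(node: TreeNode) -> str:
        if node.is_tip:
            s = _format_label(node.label)  # type: ignore[arg-type]
        else:
            children = node.children
            if canonical:
                children = sorted(children, key=min_tip)
            s = "(" + ",".join(rec(c) for c in children) + ")"
            if node.label:
                s += _format_label(node.label)
        if node.length is not None and node.parent is not None:
            s += ":" + _format_length(node.length)
        return s

    return rec(tree.root) + ";"


def resolve_polytomies(tree: Tree) -> Tree:
    """Return a binary copy, resolving polytomies left-to-right with
    zero-length internal branches.  Opt-in: the rest of the pipeline
    rejects polytomies outright."""
    new = tree.copy()
    for node in list(new.preorder()):
        while len(node.children) > 2:
            a = node.children.pop()
            b = node.children.pop()
            merged = TreeNode(None, 0.0 if a.length is not None else None)
            merged.add_child(b)
            merged.add_child(a)
            node.add_child(merged)
    return new.validate()


# ---------------------------------------------------------------------------
# Clade rank
# ---------------------------------------------------------------------------

def clade_rank(tree: Tree, taxon: str) -> int:
    """Number of speciation events between the root and a tip.

    Counts the internal nodes on the root-to-tip path, root included and
    tip excluded; on a binary tree this equals the tip's depth in edges.
    Both children of the root therefore have rank 1.
    """
    if not tree.is_binary():
        raise TreeError("clade rank is defined on binary trees")
    node = tree.find_tip(taxon)
    return tree.depth_of(node)


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    """One symbiont specimen and the host taxa it was recorded on."""

    symbiont_tip: str
    hosts: frozenset[str]
    species: str | None = None
    genus: str | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def unmapped(self) -> bool:
        return not self.hosts


class AssociationTable:
    """An ordered collection of :class:`AssociationRecord`."""

    def __init__(self, records: Sequence[AssociationRecord]):
        labels = [r.symbiont_tip for r in records]
        if any(not lab for lab in labels):
            raise AssociationError("association record with empty symbiont tip label")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise AssociationError(f"duplicate symbiont tip labels: {dupes}")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    def filter(self, predicate) -> "AssociationTable":
        return AssociationTable([r for r in self.records if predicate(r)])

    def host_taxa(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= r.hosts
        return out

    def host_genera(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            for h in r.hosts:
                out.add(_derive_genus(h))
        return out


_UNKNOWN_HOST_TOKENS = {"unknown", "?", "na", ""}


def _derive_genus(host_name: str) -> str:
    return host_name.split()[0]


def read_association_table(source) -> AssociationTable:
    """Read a TSV association table.

    The header must contain ``symbiont_tip`` and ``host`` columns;
    ``species`` and ``genus`` are optional, and any further columns are
    kept as per-record metadata.  Multiple hosts are separated by ``;``
    within the host field.  A host field equal to ``Unknown`` (case
    insensitive) yields a record with an empty host set, flagged
    unmapped rather than rejected — outgroup specimens routinely lack
    host data.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in io.StringIO(text) if ln.strip()]
    if not lines:
        raise AssociationError("empty association table")
    header = [c.strip() for c in lines[0].rstrip("\n").split("\t")]
    required = {"symbiont_tip", "host"}
    if not required.issubset(header):
        missing = sorted(required - set(header))
        raise AssociationError(f"association table missing required columns: {missing}")
    idx = {name: i for i, name in enumerate(header)}

    records: list[AssociationRecord] = []
    for ln in lines[1:]:
        cells = ln.rstrip("\n").split("\t")
        cells += [""] * (len(header) - len(cells))
        tip = cells[idx["symbiont_tip"]].strip()
        raw_host = cells[idx["host"]].strip()
        if raw_host.lower() in _UNKNOWN_HOST_TOKENS:
            hosts: frozenset[str] = frozenset()
        else:
            hosts = frozenset(h.strip() for h in raw_host.split(";") if h.strip())
        species = cells[idx["species"]].strip() if "species" in idx else None
        if "genus" in idx and cells[idx["genus"]].strip():
            genus = cells[idx["genus"]].strip()
        elif hosts:
            genus = _derive_genus(sorted(hosts)[0])
        else:
            genus = None
        meta = {
            name: cells[i].strip()
            for name, i in idx.items()
            if name not in {"symbiont_tip", "host", "species", "genus"}
        }
        records.append(AssociationRecord(tip, hosts, species or None, genus, meta))
    return AssociationTable(records)


# ---------------------------------------------------------------------------
# Tanglegram
# ---------------------------------------------------------------------------

class Tanglegram:
    """A host tree, a symbiont tree, and the tip-to-tip association map.

    Both trees must be binary and every symbiont tip must map to a
    non-empty set of host-tree tips.
    """

    def __init__(self, host: Tree, symbiont: Tree, assoc: Mapping[str, frozenset[str]]):
        if not host.is_binary():
            raise TreeError("host tree contains polytomies; resolve or reject upstream")
        if not symbiont.is_binary():
            raise TreeError("symbiont tree contains polytomies")
        host_tips = set(host.tip_labels())
        sym_tips = set(symbiont.tip_labels())
        keys = set(assoc)
        if keys != sym_tips:
            missing = sorted(sym_tips - keys)
            extra = sorted(keys - sym_tips)
            raise AssociationError(
                f"association keys must equal symbiont tips; missing={missing}, extra={extra}"
            )
        for tip, hosts in assoc.items():
            if not hosts:
                raise AssociationError(f"symbiont tip {tip!r} has an empty host set")
            bad = sorted(set(hosts) - host_tips)
            if bad:
                raise AssociationError(
                    f"symbiont tip {tip!r} maps to non-host-tree taxa: {bad}"
                )
        self.host = host
        self.symbiont = symbiont
        self.assoc = {k: frozenset(v) for k, v in assoc.items()}

    @property
    def n_symbiont_tips(self) -> int:
        return self.symbiont.n_tips

    @property
    def n_host_tips(self) -> int:
        return self.host.n_tips

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Tanglegram {self.n_symbiont_tips} symbiont tips on "
            f"{self.n_host_tips} hosts>"
        )


def build_tanglegram(
    host: Tree,
    symbiont: Tree,
    assoc: AssociationTable,
    drop_unmapped: bool = False,
) -> tuple[Tanglegram, int]:
    """Assemble a :class:`Tanglegram` from trees and an association table.

    A record is *unmappable* when none of its recorded hosts is a tip of
    the host tree (this includes unknown-host records).  With
    ``drop_unmapped`` set, unmappable records are excluded and the
    matching symbiont tips pruned; the number of exclusions is returned
    alongside the tanglegram.  Without it, any unmappable record is an
    error.

    Returns
    -------
    (tanglegram, n_dropped)
    """
    host_tips = set(host.tip_labels())
    sym_tips = set(symbiont.tip_labels())

    mapping: dict[str, frozenset[str]] = {}
    dropped: list[str] = []
    for rec in assoc:
        mappable = frozenset(h for h in rec.hosts if h in host_tips)
        if not mappable:
            if drop_unmapped:
                dropped.append(rec.symbiont_tip)
                continue
            raise AssociationError(
                f"record {rec.symbiont_tip!r} has no host present in the host tree "
                f"(hosts={sorted(rec.hosts) or ['<unknown>']})"
            )
        if rec.symbiont_tip not in sym_tips:
            raise AssociationError(
                f"record {rec.symbiont_tip!r} is not a tip of the symbiont tree"
            )
        mapping[rec.symbiont_tip] = mappable

    uncovered = sym_tips - set(mapping) - set(dropped)
    if uncovered:
        raise AssociationError(
            f"symbiont tips without an association record: {sorted(uncovered)}"
        )

    pruned_symbiont = symbiont
    if dropped:
        keep = sorted(set(mapping))
        pruned_symbiont = symbiont.prune_to(keep)

    return Tanglegram(host, pruned_symbiont, mapping), len(dropped)
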