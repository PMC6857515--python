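"""Rooted leaf-labeled trees: Newick I/O, clusters, rooting, pruning, enumeration.

The central container is :class:`RootedTree`, a lightweight rooted tree whose
leaves carry unique taxon labels and whose edges optionally carry non-negative
branch lengths (units are context dependent: coalescent units, expected
substitutions, or substitutions/site).  Polytomies are first class: consensus
gene trees may be unresolved and every operation in the package either handles
or explicitly rejects them.

Newick parsing is delegated to dendropy; the dialect accepted is the one
produced by mainstream maximum-likelihood tools (quoted labels, internal node
labels, ``:`` branch lengths, ``[...]`` comments ignored).  Taxon names are
matched case-sensitively by exact string equality.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence

import dendropy


class TreeError(ValueError):
    """Invalid tree structure or invalid tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


# ---------------------------------------------------------------------------
# node / tree containers
# ---------------------------------------------------------------------------


class Node:
    """A tree node; ``length`` is the length of the edge above the node."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def copy(self) -> "Node":
        new = Node(self.label, self.length)
        for child in self.children:
            new.add(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


def _merge_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    """Degree-2 suppression merges branch lengths by addition."""
    if a is None:
        return b
    if b is None:
        return a
    return a + b


class RootedTree:
    """Rooted leaf-labeled tree with optional branch lengths.

    Invariants (enforced on construction): exactly one root, unique non-empty
    leaf labels, no degree-2 internal nodes, branch lengths (when present)
    non-negative.
    """

    __slots__ = ("root", "_clusters", "_leaf_labels")

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._clusters: Optional[frozenset[frozenset[str]]] = None
        self._leaf_labels: Optional[frozenset[str]] = None
        self._normalize()
        if validate:
            self._validate()

    # -- construction & I/O -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        """Parse a single Newick statement (must end in ';')."""
        if not text.strip().endswith(";"):
            raise NewickParseError("newick statement must end in ';'")
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises several DataParseError types
            raise NewickParseError(f"malformed newick: {exc}") from exc
        return cls(_from_dendropy(dt.seed_node))

    def to_newick(self, precision: int = 10) -> str:
        parts: list[str] = []
        _serialize(self.root, parts, precision)
        parts.append(";")
        return "".join(parts)

    def copy(self) -> "RootedTree":
        return RootedTree(self.root.copy(), validate=False)

    # -- invariants ---------------------------------------------------------

    def _normalize(self) -> None:
        # drop degree-1 roots
        while len(self.root.children) == 1:
            child = self.root.children[0]
            child.parent = None
            child.length = None
            if self.root.label is not None and child.label is None and child.children:
                child.label = self.root.label
            self.root = child
        # suppress degree-2 internal nodes (merge lengths by addition)
        for node in list(self.root.postorder()):
            if node is self.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length = _merge_lengths(node.length, child.length)
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        self._clusters = None
        self._leaf_labels = None

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label: {node.label!r}")
                seen.add(node.label)
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length on edge above {node.label!r}")

    # -- basic queries ------------------------------------------------------

    def leaves(self) -> Iterator[Node]:
        for node in self.root.postorder():
            if node.is_leaf:
                yield node

    @property
    def leaf_labels(self) -> frozenset[str]:
        if self._leaf_labels is None:
            self._leaf_labels = frozenset(n.label for n in self.leaves())
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.root.postorder() if not n.is_leaf
        )

    def clusters(self) -> frozenset[frozenset[str]]:
        """All nontrivial clusters (one per internal edge below the root)."""
        if self._clusters is None:
            below: dict[int, frozenset[str]] = {}
            result = []
            for node in self.root.postorder():
                if node.is_leaf:
                    below[id(node)] = frozenset((node.label,))
                else:
                    cl = frozenset().union(*(below[id(c)] for c in node.children))
                    below[id(node)] = cl
                    if node is not self.root and len(cl) >= 2:
                        result.append(cl)
            self._clusters = frozenset(result)
        return self._clusters

    def topology_key(self) -> tuple[frozenset[str], frozenset[frozenset[str]]]:
        """Hashable key identifying the rooted topology exactly (polytomies
        bin only with identical polytomies: the cluster set determines the
        rooted topology)."""
        return (self.leaf_labels, self.clusters())

    def has_cluster(self, cluster: Iterable[str]) -> bool:
        return frozenset(cluster) in self.clusters()

    def find_leaf(self, label: str) -> Node:
        for node in self.leaves():
            if node.label == label:
                return node
        raise TreeError(f"taxon {label!r} not present in tree")

    # -- editing operations (all return new trees) --------------------------

    def prune_taxa(self, taxa: Iterable[str], missing_ok: bool = True) -> "RootedTree":
        """Remove the given leaves, suppressing resulting degree-2 nodes
        (lengths merged by addition)."""
        drop = set(taxa)
        if not missing_ok:
            absent = drop - self.leaf_labels
            if absent:
                raise TreeError(f"taxa not in tree: {sorted(absent)}")
        keep = self.leaf_labels - drop
        if not keep:
            raise TreeError("pruning would remove every leaf")
        return self.restrict_to(keep)

    def restrict_to(self, taxa: Iterable[str]) -> "RootedTree":
        """Restriction of the tree to the given leaf subset."""
        keep = set(taxa)
        absent = keep - self.leaf_labels
        if absent:
            raise TreeError(f"taxa not in tree: {sorted(absent)}")

        def _restrict(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in keep:
                    return Node(node.label, node.length)
                return None
            kids = [k for k in (_restrict(c) for c in node.children) if k is not None]
            if not kids:
                return None
            new = Node(node.label, node.length)
            for k in kids:
                new.add(k)
            return new

        root = _restrict(self.root)
        return RootedTree(root, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree({self.to_newick()})"


def _from_dendropy(nd) -> Node:
    if nd.is_leaf():
        label = nd.taxon.label if nd.taxon is not None else nd.label
        return Node(label, nd.edge.length)
    node = Node(nd.label, nd.edge.length)
    for child in nd.child_nodes():
        node.add(_from_dendropy(child))
    return node


_NEEDS_QUOTE = set("(),:;[]' \t\n")


def _fmt_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _serialize(node: Node, parts: list[str], precision: int) -> None:
    if node.is_leaf:
        parts.append(_fmt_label(node.label))
    else:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _serialize(child, parts, precision)
        parts.append(")")
        if node.label is not None:
            parts.append(_fmt_label(str(node.label)))
    if node.length is not None:
        parts.append(f":{node.length:.{precision}g}")


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> RootedTree:
    """Parse one well-formed Newick statement into a normalized RootedTree."""
    return RootedTree.from_newick(text)


def write_newick(tree: RootedTree, precision: int = 10) -> str:
    """Serialize; parse(write(t)) preserves clusters and lengths (to print
    precision)."""
    return tree.to_newick(precision=precision)


def clusters(tree: RootedTree) -> frozenset[frozenset[str]]:
    return tree.clusters()


def outgroup_root(tree: RootedTree, outgroup: str) -> RootedTree:
    """Re-root so that ``outgroup`` attaches at the root; ingroup topology is
    preserved.  Idempotent when the tree is already rooted on the outgroup.

    When the root is relocated onto the outgroup's pendant edge, the full
    pendant length stays on the outgroup's edge and the sister edge at the new
    root gets length 0 (topology-only consumers are unaffected).
    """
    t = tree.copy()
    leaf = t.find_leaf(outgroup)
    if leaf.parent is t.root and len(t.root.children) == 2:
        return t

    # detach the outgroup and reverse parent links along the path to the root
    old_parent = leaf.parent
    old_parent.children.remove(leaf)
    new_root = Node()
    new_root.add(leaf)

    # walk up from old_parent to the old root, re-hanging each node under its
    # (former) child; edge lengths shift one step toward the old root
    node = old_parent
    attach_to = new_root
    carried_length = 0.0 if leaf.length is not None else None
    while node is not None:
        next_node = node.parent
        next_length = node.length
        node.parent = None
        if next_node is not None:
            next_node.children.remove(node)
        attach_to.add(node)
        node.length = carried_length
        carried_length = next_length
        attach_to = node
        node = next_node

    return RootedTree(new_root, validate=False)


@dataclass
class FilterReport:
    """Bookkeeping attached to the output of :func:`filter_gene_trees`."""

    n_input: int
    n_retained: int
    n_omitted: int
    dropped_taxa: tuple[str, ...]
    required_taxa: frozenset[str]


@dataclass
class GeneTreeSet:
    """Ordered collection of rooted gene trees sharing a taxon universe."""

    trees: list[RootedTree]
    taxon_universe: frozenset[str] = field(default=None)  # type: ignore[assignment]
    marker_class: str = ""
    filter_report: Optional[FilterReport] = None

    def __post_init__(self) -> None:
        if self.taxon_universe is None:
            universe: set[str] = set()
            for t in self.trees:
                universe |= t.leaf_labels
            self.taxon_universe = frozenset(universe)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[RootedTree]:
        return iter(self.trees)

    def __getitem__(self, idx):
        return self.trees[idx]

    @classmethod
    def from_string(cls, text: str, marker_class: str = "") -> "GeneTreeSet":
        try:
            tl = dendropy.TreeList.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
                rooting="force-rooted",
            )
        except Exception as exc:
            raise NewickParseError(f"malformed newick: {exc}") from exc
        trees = [RootedTree(_from_dendropy(t.seed_node)) for t in tl]
        return cls(trees, marker_class=marker_class)

    @classmethod
    def from_file(cls, path, marker_class: str = "") -> "GeneTreeSet":
        with open(path) as fh:
            return cls.from_string(fh.read(), marker_class=marker_class)

    def to_file(self, path, precision: int = 10) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.to_newick(precision=precision) + "\n")


def filter_gene_trees(
    gene_trees: GeneTreeSet,
    drop_taxa: Sequence[str] = (),
    required_taxa: Optional[Iterable[str]] = None,
) -> GeneTreeSet:
    """Prune ``drop_taxa`` from every tree, then retain only trees whose leaf
    set equals ``required_taxa`` (default: the universe minus dropped taxa).

    An empty result is a warning, not an error.  A :class:`FilterReport` with
    retained/omitted counts is attached to the returned set.
    """
    drop = set(drop_taxa)
    if required_taxa is None:
        required = frozenset(gene_trees.taxon_universe - drop)
    else:
        required = frozenset(required_taxa) - drop
    retained: list[RootedTree] = []
    for tree in gene_trees:
        pruned = tree.prune_taxa(drop) if (drop & tree.leaf_labels) else tree
        if pruned.leaf_labels == required:
            retained.append(pruned)
    if not retained:
        warnings.warn("filter_gene_trees: no trees retained", stacklevel=2)
    report = FilterReport(
        n_input=len(gene_trees),
        n_retained=len(retained),
        n_omitted=len(gene_trees) - len(retained),
        dropped_taxa=tuple(sorted(drop)),
        required_taxa=required,
    )
    return GeneTreeSet(
        retained,
        taxon_universe=required,
        marker_class=gene_trees.marker_class,
        filter_report=report,
    )


def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def n_rooted_topologies(n_leaves: int) -> int:
    """(2n-3)!! rooted binary leaf-labeled topologies on n leaves."""
    if n_leaves < 2:
        raise TreeError("need at least 2 leaves")
    return double_factorial(2 * n_leaves - 3)


def _insertion_positions(root: Node) -> list[Node]:
    return list(root.postorder())


def _insert_leaf(root: Node, position: Node, label: str) -> Node:
    """Copy of the tree with a new leaf attached on the edge above
    ``position`` (attaching above the root creates a new root)."""
    mapping: dict[int, Node] = {}

    def _copy(node: Node) -> Node:
        new = Node(node.label, node.length)
        mapping[id(node)] = new
        for child in node.children:
            new.add(_copy(child))
        return new

    new_root = _copy(root)
    target = mapping[id(position)]
    joint = Node()
    if target.parent is None:
        joint.add(target)
        joint.add(Node(label))
        return joint
    parent = target.parent
    idx = parent.children.index(target)
    parent.children[idx] = joint
    joint.parent = parent
    target.parent = None
    joint.add(target)
    joint.add(Node(label))
    return joint if joint.parent is None else new_root


def _all_binary_trees(labels: Sequence[str]) -> list[Node]:
    trees = [Node(labels[0])]
    for label in labels[1:]:
        nxt: list[Node] = []
        for tree in trees:
            for pos in _insertion_positions(tree):
                nxt.append(_insert_leaf(tree, pos, label))
        trees = nxt
    return trees


def enumerate_rooted_topologies(
    leaves: Sequence[str],
    constraint: Optional[Mapping[str, Sequence[str]]] = None,
    max_leaves: int = 9,
) -> list[RootedTree]:
    """All distinct rooted binary leaf-labeled topologies on ``leaves``.

    ``constraint`` maps a label in ``leaves`` to the member taxa of a clade
    constrained to be monophyletic; the clade's internal resolutions are
    enumerated independently and grafted in place of the label, so the count
    is the product of the (2n-3)!! factors.  ``max_leaves`` guards each
    enumerated part against combinatorial blow-up.
    """
    labels = list(leaves)
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate labels in leaf list")
    if len(labels) < 2:
        raise TreeError("need at least 2 leaves")
    constraint = dict(constraint or {})
    for key, members in constraint.items():
        if key not in labels:
            raise TreeError(f"constraint key {key!r} not among leaves")
        if len(members) < 2:
            raise TreeError(f"constrained clade {key!r} needs >= 2 members")

    def _guard(part: Sequence[str]) -> None:
        if len(part) > max_leaves:
            raise TreeError(
                f"{len(part)} leaves would enumerate "
                f"{n_rooted_topologies(len(part))} topologies "
                f"(guard is {max_leaves} leaves)"
            )

    _guard(labels)
    backbones = _all_binary_trees(labels)
    if not constraint:
        return [RootedTree(t, validate=False) for t in backbones]

    sub_enums: dict[str, list[Node]] = {}
    for key, members in constraint.items():
        _guard(members)
        sub_enums[key] = _all_binary_trees(list(members))

    def _graft(node: Node, subs: Mapping[str, Node]) -> Node:
        if node.is_leaf:
            if node.label in subs:
                return subs[node.label].copy()
            return Node(node.label, node.length)
        new = Node(node.label, node.length)
        for child in node.children:
            new.add(_graft(child, subs))
        return new

    result: list[RootedTree] = []
    keys = sorted(sub_enums)
    for backbone in backbones:
        for combo in itertools.product(*(sub_enums[k] for k in keys)):
            subs = dict(zip(keys, combo))
            result.append(RootedTree(_graft(backbone, subs), validate=False))
    return result


def apply_random_nni(tree: RootedTree, rng, moves: int = 1) -> RootedTree:
    """Apply ``moves`` random nearest-neighbour-interchange moves.

    Each move picks an internal edge (an internal non-root node ``v``) and
    swaps a random child of ``v`` with a random sibling of ``v``; on a binary
    tree one move changes exactly one cluster (RF cluster distance 2 from the
    input).  Trees with no internal edge are returned unchanged.
    """
    t = tree.copy()
    for _ in range(moves):
        candidates = [
            n
            for n in t.root.postorder()
            if not n.is_leaf and n.parent is not None
        ]
        if not candidates:
            return t
        v = candidates[int(rng.integers(len(candidates)))]
        u = v.parent
        siblings = [c for c in u.children if c is not v]
        w = siblings[int(rng.integers(len(siblings)))]
        c = v.children[int(rng.integers(len(v.children)))]
        # swap subtrees c <-> w
        vi = v.children.index(c)
        ui = u.children.index(w)
        v.children[vi] = w
        u.children[ui] = c
        w.parent = v
        c.parent = u
        t._clusters = None
    t._clusters = None
    t._leaf_labels = None
    return t
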