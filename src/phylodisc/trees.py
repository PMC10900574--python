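"""Rooted tree data model, Newick I/O, clade sets and tree distances.

Everything downstream (coalescent simulation, concordance factors, topology
weighting) runs on the :class:`Tree` defined here.  Two distances between
trees sharing a taxon set are provided:

* Robinson–Foulds cluster distance — the size of the symmetric difference of
  the two sets of non-trivial rooted clusters (raw count, not halved, not
  normalised).
* Matching cluster distance — minimum-cost perfect matching between the two
  cluster sets (padded with empty clusters), where the cost of pairing two
  clusters is the size of their symmetric difference.  Solved exactly with
  the Hungarian algorithm.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Iterator

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "clades",
    "rf_cluster_distance",
    "matching_cluster_distance",
    "restrict",
    "root_with_outgroup",
    "canonical_topology",
    "enumerate_rooted_topologies",
]


class TreeError(ValueError):
    """Invalid tree structure or incompatible tree pair."""


class NewickParseError(TreeError):
    """Malformed Newick string; ``pos`` is the 0-based offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class Node:
    """A node of a rooted tree.

    ``length`` is the length of the branch above the node (``None`` for no
    length; the root's length is its stem length, if any).  ``annotations``
    holds per-branch key/value metadata such as ``theta`` or ``tau``.
    """

    __slots__ = ("parent", "children", "label", "length", "annotations")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label
        self.length = length
        self.annotations: dict = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class Tree:
    """A rooted tree with unique tip labels and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- structure ----------------------------------------------------------
    def validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if any(not lbl for lbl in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        for node in self.root.preorder():
            if node.length is not None and not (
                np.isfinite(node.length) and node.length >= 0
            ):
                raise TreeError(f"negative or non-finite branch length on {node.label!r}")

    def tips(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> frozenset:
        return frozenset(t.label for t in self.tips())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [
            n
            for n in self.root.preorder()
            if not n.is_tip and (include_root or n.parent is not None)
        ]

    def find_tip(self, label: str) -> Node:
        for t in self.tips():
            if t.label == label:
                return t
        raise TreeError(f"tip {label!r} not in tree")

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.annotations = dict(node.annotations)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return Tree(_copy(self.root))

    # -- measures -----------------------------------------------------------
    def depths(self) -> dict:
        """Tip label -> sum of branch lengths from root (missing lengths = 0)."""
        out = {}
        stack = [(self.root, self.root.length or 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_tip:
                out[node.label] = d
            for c in node.children:
                stack.append((c, d + (c.length or 0.0)))
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = list(self.depths().values())
        return max(d) - min(d) <= tol * max(1.0, max(d))

    # -- I/O ----------------------------------------------------------------
    def newick(self, lengths: bool = True, annotations: bool = False) -> str:
        return write_newick(self, lengths=lengths, annotations=annotations)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.newick()})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_END = set("(),:;[")


def _parse_annotations(text: str) -> dict:
    # "[&theta=0.01,tau=0.5]" -> {"theta": 0.01, "tau": 0.5}
    body = text.strip("[]").lstrip("&")
    out: dict = {}
    for item in body.split(","):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            try:
                out[k.strip()] = float(v)
            except ValueError:
                out[k.strip()] = v.strip()
        else:
            out[item.strip()] = True
    return out


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree.

    Supports optional branch lengths, internal-node labels and bracketed
    per-branch annotations (``[&key=value,...]``, before or after the
    length).  Raises :class:`NewickParseError` with the offending position
    for malformed input and :class:`TreeError` for duplicate tip labels.
    """
    s = text.strip()
    if not s:
        raise NewickParseError("empty Newick string", 0)
    pos = 0
    n = len(s)

    def skip_comment() -> str | None:
        nonlocal pos
        if pos < n and s[pos] == "[":
            end = s.find("]", pos)
            if end < 0:
                raise NewickParseError("unterminated comment", pos)
            com = s[pos : end + 1]
            pos = end + 1
            return com
        return None

    def read_label() -> str:
        nonlocal pos
        if pos < n and s[pos] in "'\"":
            quote = s[pos]
            end = s.find(quote, pos + 1)
            if end < 0:
                raise NewickParseError("unterminated quoted label", pos)
            lbl = s[pos + 1 : end]
            pos = end + 1
            return lbl
        start = pos
        while pos < n and s[pos] not in _LABEL_END:
            pos += 1
        return s[start:pos].strip()

    def read_node() -> Node:
        nonlocal pos
        if pos >= n:
            raise NewickParseError("unexpected end of string", pos)
        if s[pos] == "(":
            pos += 1
            node = Node()
            node.add_child(read_node())
            while pos < n and s[pos] == ",":
                pos += 1
                node.add_child(read_node())
            if pos >= n or s[pos] != ")":
                raise NewickParseError("expected ')' or ','", pos)
            pos += 1
            lbl = read_label()
            if lbl:
                node.label = lbl
        else:
            lbl = read_label()
            if not lbl:
                raise NewickParseError("expected a tip label", pos)
            node = Node(lbl)
        com = skip_comment()
        if com:
            node.annotations.update(_parse_annotations(com))
        if pos < n and s[pos] == ":":
            pos += 1
            com = skip_comment()
            if com:
                node.annotations.update(_parse_annotations(com))
            start = pos
            while pos < n and s[pos] not in "(),;[":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise NewickParseError("invalid branch length", start) from None
            com = skip_comment()
            if com:
                node.annotations.update(_parse_annotations(com))
        return node

    root = read_node()
    if pos >= n or s[pos] != ";":
        raise NewickParseError("expected ';'", pos)
    if s[pos + 1 :].strip():
        raise NewickParseError("trailing characters after ';'", pos + 1)
    tree = Tree(root)
    # Internal labels on tips-only grammar: root label allowed; nothing more to check.
    return tree


def read_newick(path) -> list[Tree]:
    """Read a file with one Newick tree per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: Tree, lengths: bool = True, annotations: bool = False) -> str:
    def _write(node: Node) -> str:
        if node.is_tip:
            core = node.label
        else:
            core = "(" + ",".join(_write(c) for c in node.children) + ")"
            if node.label:
                core += node.label
        if annotations and node.annotations:
            items = ",".join(
                f"{k}={_fmt_len(v) if isinstance(v, float) else v}"
                for k, v in sorted(node.annotations.items())
            )
            core += f"[&{items}]"
        if lengths and node.length is not None:
            core += ":" + _fmt_len(node.length)
        return core

    return _write(tree.root) + ";"


# ---------------------------------------------------------------------------
# Clades and distances
# ---------------------------------------------------------------------------

def _cluster_map(tree: Tree) -> dict:
    """Node -> frozenset of descendant tip labels, in postorder."""
    clusters: dict = {}
    for node in tree.root.postorder():
        if node.is_tip:
            clusters[node] = frozenset([node.label])
        else:
            clusters[node] = frozenset().union(*(clusters[c] for c in node.children))
    return clusters


def clades(tree: Tree) -> frozenset:
    """Non-trivial clusters (rooted clades) induced by internal non-root nodes.

    Singletons and the full taxon set are excluded; for a binary tree on
    n tips this yields n - 2 clusters.
    """
    cm = _cluster_map(tree)
    full = cm[tree.root]
    return frozenset(
        c
        for node, c in cm.items()
        if node.parent is not None and not node.is_tip and c != full and len(c) >= 2
    )


def _check_same_taxa(t1: Tree, t2: Tree) -> None:
    if t1.tip_labels != t2.tip_labels:
        only1 = sorted(t1.tip_labels - t2.tip_labels)
        only2 = sorted(t2.tip_labels - t1.tip_labels)
        raise TreeError(f"tip sets differ: only in first {only1}, only in second {only2}")


def rf_cluster_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds cluster distance: |C1 Δ C2| over non-trivial rooted clusters."""
    _check_same_taxa(t1, t2)
    return len(clades(t1) ^ clades(t2))


def matching_cluster_distance(t1: Tree, t2: Tree) -> int:
    """Matching cluster distance (exact optimal assignment).

    The two cluster sets are padded with empty clusters to equal size; the
    cost of matching cluster a with cluster b is |a Δ b| (so an unmatched
    cluster costs its own size), and the reported distance is the minimum
    total cost over perfect matchings.
    """
    _check_same_taxa(t1, t2)
    c1 = sorted(clades(t1), key=sorted)
    c2 = sorted(clades(t2), key=sorted)
    k = max(len(c1), len(c2))
    if k == 0:
        return 0
    c1 = c1 + [frozenset()] * (k - len(c1))
    c2 = c2 + [frozenset()] * (k - len(c2))
    cost = np.empty((k, k), dtype=np.int64)
    for i, a in enumerate(c1):
        for j, b in enumerate(c2):
            cost[i, j] = len(a ^ b)
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


# ---------------------------------------------------------------------------
# Restriction and canonical topologies
# ---------------------------------------------------------------------------

def restrict(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Induced subtree on ``taxa``; degree-2 nodes suppressed, lengths summed."""
    keep = set(taxa)
    unknown = keep - tree.tip_labels
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("restriction needs at least 2 taxa")

    def _prune(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        new = Node(node.label, node.length)
        for c in kept:
            new.add_child(c)
        return new

    root = _prune(tree.root)
    assert root is not None
    root.length = None  # stem above the induced root is not part of the subtree
    return Tree(root)


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Re-root on the branch leading to ``outgroup`` (lengths split in half).

    Degree-2 nodes created by discarding the old root are suppressed with
    lengths summed.  Used to orient unrooted (e.g. neighbor-joining) trees
    before rooted-cluster comparisons.
    """
    adj: dict = {}
    lens: dict = {}
    for node in tree.root.preorder():
        for c in node.children:
            adj.setdefault(node, []).append(c)
            adj.setdefault(c, []).append(node)
            lens[frozenset((id(node), id(c)))] = c.length

    out_tip = tree.find_tip(outgroup)
    (attach,) = adj[out_tip]

    def _build(node: Node, parent: Node) -> Node:
        kids = [x for x in adj[node] if x is not parent]
        blen = lens[frozenset((id(node), id(parent)))]
        if not kids:
            return Node(node.label, blen)
        if len(kids) == 1:  # old root of degree 2: suppress, merge lengths
            inner = _build(kids[0], node)
            if blen is not None or inner.length is not None:
                inner.length = (blen or 0.0) + (inner.length or 0.0)
            return inner
        new = Node(node.label, blen)
        for k in kids:
            new.add_child(_build(k, node))
        return new

    stem = lens[frozenset((id(out_tip), id(attach)))]
    half = None if stem is None else stem / 2.0
    root = Node()
    new_tip = Node(out_tip.label, half)
    root.add_child(new_tip)
    rest = _build(attach, out_tip)  # arrives carrying the full stem length
    rest.length = half
    root.add_child(rest)
    return Tree(root)


def canonical_topology(tree: Tree, rooted: bool = True) -> str:
    """Canonical string identifying the leaf-labelled topology (lengths ignored).

    Rooted: children are ordered by their lexicographically smallest
    descendant tip, recursively.  Unrooted: the tree is re-rooted at the tip
    with the smallest label and the remainder canonicalised, so any rooting
    of the same unrooted topology yields the same ID.
    """
    if rooted:
        s, _ = _canon(tree.root)
        return s
    # Unrooted: view the topology from the smallest tip.
    adj: dict = {}
    for node in tree.root.preorder():
        for c in node.children:
            adj.setdefault(node, []).append(c)
            adj.setdefault(c, []).append(node)
    tips = sorted(tree.tips(), key=lambda t: t.label)
    anchor = tips[0]
    (neighbor,) = adj[anchor]

    def _canon_from(node: Node, parent: Node) -> tuple[str, str]:
        neighbors = [x for x in adj[node] if x is not parent]
        if not neighbors:
            return node.label, node.label
        parts = [_canon_from(x, node) for x in neighbors]
        if len(parts) == 1:  # degree-2 node (e.g. the discarded root): suppress
            return parts[0]
        parts.sort(key=lambda p: p[1])
        return "(" + ",".join(p[0] for p in parts) + ")", parts[0][1]

    body, _ = _canon_from(neighbor, anchor)
    return f"({anchor.label},{body})"


def _canon(node: Node) -> tuple[str, str]:
    if node.is_tip:
        return node.label, node.label
    parts = [_canon(c) for c in node.children]
    parts.sort(key=lambda p: p[1])
    return "(" + ",".join(p[0] for p in parts) + ")", parts[0][1]


def enumerate_rooted_topologies(labels: list[str]) -> list[Tree]:
    """All rooted binary leaf-labelled topologies on ``labels`` (15 for 4 tips).

    Generated by stepwise tip addition on every branch (including the root
    stem), which enumerates each topology exactly once.
    """
    labels = sorted(labels)
    if len(labels) < 2:
        raise TreeError("need at least 2 labels")

    def _grow(struct, label):
        # struct is a nested tuple; regraft `label` onto every edge incl. stem
        results = [(struct, label)]
        if isinstance(struct, tuple):
            left, right = struct
            results += [(l, right) for l in _grow(left, label)]
            results += [(left, r) for r in _grow(right, label)]
        return results

    structs = [ (labels[0], labels[1]) ]
    for lbl in labels[2:]:
        structs = [s2 for s in structs for s2 in _grow(s, lbl)]

    def _build(struct) -> Node:
        if isinstance(struct, str):
            return Node(struct)
        node = Node()
        node.add_child(_build(struct[0]))
        node.add_child(_build(struct[1]))
        return node

    return [Tree(_build(s)) for s in structs]
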