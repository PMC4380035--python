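"""Unrooted bifurcating trees as triple-linked half-edge records.

Every inner node is a cycle of three half-edge records; ``rec.nxt`` walks
the cycle and ``rec.back`` crosses the edge to the neighbouring node's
record.  Tips are single records with ``nxt is None``.  The two records of
an edge agree on branch length and edge id.

Each inner node stores exactly one conditional likelihood vector (CLV).
``Tree.orientation[node_id]`` remembers which of the node's three records
that CLV "points along": the CLV summarises the subtree behind the other
two records and is valid for evaluation toward ``orientation.back``.  A
*full* traversal recomputes every inner CLV toward a chosen virtual-root
edge; a *partial* traversal recomputes only nodes whose stored orientation
disagrees with the orientation the root edge induces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

MIN_BRANCH = 1e-8
MAX_BRANCH = 100.0
DEFAULT_BRANCH = 0.1

FULL = "FULL"
PARTIAL = "PARTIAL"


class TreeError(ValueError):
    pass


class HalfEdge:
    __slots__ = ("node_id", "label", "nxt", "back", "length", "edge_id")

    def __init__(self, node_id: int, label: str | None = None):
        self.node_id = node_id
        self.label = label
        self.nxt: "HalfEdge | None" = None
        self.back: "HalfEdge | None" = None
        self.length: float = DEFAULT_BRANCH
        self.edge_id: int = -1

    @property
    def is_tip(self) -> bool:
        return self.nxt is None

    def __repr__(self) -> str:  # pragma: no cover
        tag = self.label if self.label else f"inner{self.node_id}"
        to = "?" if self.back is None else (self.back.label or f"inner{self.back.node_id}")
        return f"<{tag}->{to} e{self.edge_id} t={self.length:.4g}>"


def clamp_branch(t: float, warn: bool = True) -> float:
    if t < MIN_BRANCH or t > MAX_BRANCH:
        clamped = min(max(t, MIN_BRANCH), MAX_BRANCH)
        if warn:
            warnings.warn(
                f"branch length {t:g} outside [{MIN_BRANCH:g}, {MAX_BRANCH:g}];"
                f" clamped to {clamped:g}", stacklevel=3)
        return clamped
    return t


@dataclass
class TraversalOp:
    """One CLV update: compute the CLV of ``rec``'s node toward ``rec``.

    ``left``/``right`` are the node's other two records; the child CLVs live
    at ``left.back`` / ``right.back`` and the child branch lengths are
    ``left.length`` / ``right.length``.
    """

    rec: HalfEdge
    left: HalfEdge
    right: HalfEdge

    @property
    def node_id(self) -> int:
        return self.rec.node_id


@dataclass
class TraversalDescriptor:
    ops: list[TraversalOp]
    root: HalfEdge  # virtual-root edge, as one of its two records


class Tree:
    """Unrooted bifurcating tree over ``n_taxa`` labelled tips."""

    def __init__(self) -> None:
        self.tips: dict[str, HalfEdge] = {}
        self.inner: dict[int, HalfEdge] = {}      # node_id -> one cycle record
        self.edges: dict[int, HalfEdge] = {}      # edge_id -> one of the two records
        self.orientation: dict[int, HalfEdge | None] = {}
        self._next_node = 0
        self._next_edge = 0

    # -- construction primitives ------------------------------------------

    def new_tip(self, label: str) -> HalfEdge:
        if label in self.tips:
            raise TreeError(f"duplicate taxon label {label!r}")
        rec = HalfEdge(self._next_node, label)
        self._next_node += 1
        self.tips[label] = rec
        return rec

    def new_inner(self) -> HalfEdge:
        nid = self._next_node
        self._next_node += 1
        a, b, c = HalfEdge(nid), HalfEdge(nid), HalfEdge(nid)
        a.nxt, b.nxt, c.nxt = b, c, a
        self.inner[nid] = a
        self.orientation[nid] = None
        return a

    def fresh_edge_id(self) -> int:
        eid = self._next_edge
        self._next_edge += 1
        return eid

    def connect(self, a: HalfEdge, b: HalfEdge, length: float,
                edge_id: int | None = None) -> int:
        """Join two free records into an edge; returns the edge id."""
        if edge_id is None:
            edge_id = self.fresh_edge_id()
        a.back, b.back = b, a
        a.length = b.length = clamp_branch(length, warn=False)
        a.edge_id = b.edge_id = edge_id
        self.edges[edge_id] = a
        return edge_id

    def disconnect(self, edge_id: int) -> tuple[HalfEdge, HalfEdge]:
        rec = self.edges.pop(edge_id)
        other = rec.back
        rec.back = other.back = None
        rec.edge_id = other.edge_id = -1
        return rec, other

    def drop_inner(self, node_id: int) -> None:
        del self.inner[node_id]
        del self.orientation[node_id]

    # -- basic queries ------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.tips)

    @property
    def n_inner(self) -> int:
        return len(self.inner)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def taxon_names(self) -> list[str]:
        return sorted(self.tips)

    def inner_records(self, node_id: int) -> tuple[HalfEdge, HalfEdge, HalfEdge]:
        r = self.inner[node_id]
        return r, r.nxt, r.nxt.nxt

    def edge_records(self, edge_id: int) -> tuple[HalfEdge, HalfEdge]:
        r = self.edges[edge_id]
        return r, r.back

    def set_length(self, edge_id: int, t: float, warn: bool = False) -> None:
        """Set a branch length; stored CLVs containing this edge become stale."""
        r, b = self.edge_records(edge_id)
        r.length = b.length = clamp_branch(t, warn=warn)
        self.invalidate_dependents([edge_id])

    def validate(self) -> None:
        n = self.n_taxa
        if n < 3:
            raise TreeError("tree needs at least 3 taxa")
        if self.n_inner != n - 2 or self.n_edges != 2 * n - 3:
            raise TreeError(
                f"Euler identities violated: {n} tips, {self.n_inner} inner,"
                f" {self.n_edges} edges")
        for nid, r in self.inner.items():
            if not (r.nxt.nxt.nxt is r):
                raise TreeError(f"inner node {nid}: record cycle not closed")
            for rec in (r, r.nxt, r.nxt.nxt):
                if rec.back is None or rec.back.back is not rec:
                    raise TreeError(f"inner node {nid}: broken back pointer")
                if rec.length != rec.back.length or rec.edge_id != rec.back.edge_id:
                    raise TreeError(f"edge {rec.edge_id}: half-edges disagree")
        for label, rec in self.tips.items():
            if rec.back is None or rec.back.back is not rec:
                raise TreeError(f"tip {label!r}: broken back pointer")

    # -- traversals ---------------------------------------------------------

    def root_records(self, edge_id: int) -> tuple[HalfEdge, HalfEdge]:
        if edge_id not in self.edges:
            raise TreeError(f"unknown edge id {edge_id}")
        return self.edge_records(edge_id)

    def build_traversal(self, edge_id: int, mode: str = FULL) -> TraversalDescriptor:
        """Post-order CLV-update schedule toward the virtual-root edge."""
        if mode not in (FULL, PARTIAL):
            raise ValueError(f"unknown traversal mode {mode!r}")
        h, hb = self.root_records(edge_id)
        ops: list[TraversalOp] = []
        # iterative post-order over both root-edge sides
        stack: list[tuple[HalfEdge, bool]] = []
        for side in (h, hb):
            if not side.is_tip:
                stack.append((side, False))
            while stack:
                rec, expanded = stack.pop()
                if expanded:
                    ops.append(TraversalOp(rec, rec.nxt, rec.nxt.nxt))
                    continue
                if mode == PARTIAL and self.orientation[rec.node_id] is rec:
                    continue  # CLV already valid toward the root
                stack.append((rec, True))
                for child_side in (rec.nxt.back, rec.nxt.nxt.back):
                    if not child_side.is_tip:
                        stack.append((child_side, False))
        return TraversalDescriptor(ops, h)

    def mark_computed(self, op: TraversalOp) -> None:
        self.orientation[op.node_id] = op.rec

    def invalidate_all(self) -> None:
        for nid in self.orientation:
            self.orientation[nid] = None

    def invalidate_dependents(self, edge_ids: list[int]) -> None:
        """Unset orientations of nodes whose stored CLV contains any edge.

        A node's CLV covers the subtree behind its two non-oriented records;
        it contains edge e exactly when the orientation does not point toward
        e.  Walk outward from both endpoints of e; a visited node's "toward
        e" record is the record through which the walk arrived.
        """
        for eid in edge_ids:
            if eid not in self.edges:
                continue
            h, hb = self.edge_records(eid)
            stack: list[HalfEdge] = []
            for side in (h, hb):
                if side.is_tip:
                    continue
                stack.append(side)  # facing record of this node w.r.t. e
            while stack:
                facing = stack.pop()
                nid = facing.node_id
                if self.orientation[nid] is not facing:
                    self.orientation[nid] = None
                for rec in (facing.nxt, facing.nxt.nxt):
                    child = rec.back
                    if not child.is_tip:
                        stack.append(child)

    # -- bipartitions (topology comparison) --------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Nontrivial splits, each as the frozenset of labels on one side
        (the side not containing the alphabetically smallest taxon)."""
        ref = min(self.tips)
        out = set()
        for eid, rec in self.edges.items():
            r, b = rec, rec.back
            if r.is_tip or b.is_tip:
                continue
            side = frozenset(self._labels_behind(r))
            if ref in side:
                side = frozenset(self.tips) - side
            out.add(side)
        return frozenset(out)

    def _labels_behind(self, rec: HalfEdge) -> list[str]:
        """Tip labels in the subtree behind ``rec`` (on ``rec``'s node side,
        away from ``rec.back``)."""
        labels: list[str] = []
        stack = [rec]
        while stack:
            r = stack.pop()
            if r.is_tip:
                labels.append(r.label)
                continue
            stack.extend([r.nxt.back, r.nxt.nxt.back])
        return labels


# ---------------------------------------------------------------------------
# Newick I/O

def _tokenize_newick(text: str):
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "(),:;":
            yield c
            i += 1
        elif c == "'":
            j = text.find("'", i + 1)
            if j < 0:
                raise TreeError("unterminated quoted label")
            yield ("LABEL", text[i + 1:j])
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),:;" and not text[j].isspace():
                j += 1
            yield ("LABEL", text[i:j])
            i = j


class _NwNode:
    __slots__ = ("children", "label", "length")

    def __init__(self):
        self.children: list["_NwNode"] = []
        self.label: str | None = None
        self.length: float | None = None


def _parse_newick_ast(text: str) -> _NwNode:
    tokens = list(_tokenize_newick(text))
    if not tokens or tokens[-1] != ";":
        raise TreeError("Newick string must end with ';'")
    pos = 0

    def parse_clade() -> _NwNode:
        nonlocal pos
        node = _NwNode()
        if tokens[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise TreeError("malformed Newick: expected ',' or ')'")
        if pos < len(tokens) and isinstance(tokens[pos], tuple):
            node.label = tokens[pos][1]
            pos += 1
        if pos < len(tokens) and tokens[pos] == ":":
            pos += 1
            if pos >= len(tokens) or not isinstance(tokens[pos], tuple):
                raise TreeError("malformed Newick: expected branch length after ':'")
            try:
                node.length = float(tokens[pos][1])
            except ValueError:
                raise TreeError(f"bad branch length {tokens[pos][1]!r}") from None
            pos += 1
        return node

    root = parse_clade()
    if tokens[pos] != ";":
        raise TreeError("malformed Newick: trailing tokens")
    return root


def parse_newick(text: str) -> Tree:
    """Parse Newick into an unrooted tree.

    A bifurcating root is collapsed by fusing its two child edges (lengths
    summed); a trifurcating base is used as-is.  Missing branch lengths
    default to 0.1.
    """
    ast = _parse_newick_ast(text)
    if len(ast.children) == 2:
        # collapse the root: fuse the two child edges
        a, b = ast.children
        la = a.length if a.length is not None else DEFAULT_BRANCH
        lb = b.length if b.length is not None else DEFAULT_BRANCH
        if not a.children:  # make sure the surviving base is an inner node
            a, b = b, a
            la, lb = lb, la
        if not a.children:
            raise TreeError("tree needs at least 3 taxa")
        b.length = la + lb
        a.children.append(b)
        ast = a
        ast.label = None
    elif len(ast.children) != 3:
        if not ast.children:
            raise TreeError("tree needs at least 3 taxa")
        raise TreeError(
            f"base node must be bifurcating (rooted) or trifurcating; got"
            f" {len(ast.children)} children")

    tree = Tree()

    def build(node: _NwNode) -> HalfEdge:
        """Return a free record representing this clade, to be connected
        to its parent."""
        if not node.children:
            if node.label is None:
                raise TreeError("tip without a label")
            return tree.new_tip(node.label)
        if len(node.children) != 2:
            raise TreeError("inner nodes must be bifurcating")
        rec = tree.new_inner()
        for child, slot in zip(node.children, (rec.nxt, rec.nxt.nxt)):
            sub = build(child)
            length = child.length if child.length is not None else DEFAULT_BRANCH
            tree.connect(slot, sub, clamp_branch(length))
        return rec

    base = tree.new_inner()
    for child, slot in zip(ast.children, (base, base.nxt, base.nxt.nxt)):
        sub = build(child)
        length = child.length if child.length is not None else DEFAULT_BRANCH
        tree.connect(slot, sub, clamp_branch(length))
    tree.validate()
    return tree


def _min_label_behind(rec: HalfEdge) -> str:
    best = None
    stack = [rec]
    while stack:
        r = stack.pop()
        if r.is_tip:
            if best is None or r.label < best:
                best = r.label
            continue
        stack.extend([r.nxt.back, r.nxt.nxt.back])
    return best


def _format_length(t: float) -> str:
    return f"{t:.17g}"


def write_newick(tree: Tree) -> str:
    """Deterministic unrooted Newick: trifurcation at the inner node next to
    the alphabetically smallest taxon, children ordered by smallest
    descendant label, branch lengths at full precision (17 significant digits)."""
    tree.validate()
    ref_tip = tree.tips[min(tree.tips)]
    base = ref_tip.back  # inner node adjacent to the reference tip
    subtrees = []
    r = base
    for rec in (r, r.nxt, r.nxt.nxt):
        subtrees.append((rec.back, rec.length))

    def render(rec: HalfEdge, length: float) -> tuple[str, str]:
        """-> (min descendant label, newick fragment)"""
        if rec.is_tip:
            return rec.label, f"{_quote(rec.label)}:{_format_length(length)}"
        kids = [render(c.back, c.length) for c in (rec.nxt, rec.nxt.nxt)]
        kids.sort(key=lambda kv: kv[0])
        frag = "(" + ",".join(k[1] for k in kids) + f"):{_format_length(length)}"
        return kids[0][0], frag

    rendered = [render(rec, length) for rec, length in subtrees]
    rendered.sort(key=lambda kv: kv[0])
    return "(" + ",".join(k[1] for k in rendered) + ");"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:; '\t"):
        return "'" + label + "'"
    return label


# ---------------------------------------------------------------------------
# Random trees

def random_tree(taxon_names: list[str], seed: int | np.random.Generator,
                mean_branch: float = 0.1) -> Tree:
    """Random topology by sequential random-edge addition (uniform over
    labelled unrooted topologies); branch lengths i.i.d. exponential."""
    names = list(taxon_names)
    if len(names) < 3:
        raise TreeError("need at least 3 taxon names")
    if len(set(names)) != len(names):
        raise TreeError("duplicate taxon names")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tree = Tree()
    base = tree.new_inner()
    for name, slot in zip(names[:3], (base, base.nxt, base.nxt.nxt)):
        tree.connect(slot, tree.new_tip(name), DEFAULT_BRANCH)
    for name in names[3:]:
        eids = sorted(tree.edges)
        eid = eids[rng.integers(len(eids))]
        a, b = tree.disconnect(eid)
        mid = tree.new_inner()
        tree.connect(mid, a, DEFAULT_BRANCH)
        tree.connect(mid.nxt, b, DEFAULT_BRANCH)
        tree.connect(mid.nxt.nxt, tree.new_tip(name), DEFAULT_BRANCH)
    for eid in sorted(tree.edges):
        tree.set_length(eid, max(MIN_BRANCH, rng.exponential(mean_branch)))
    tree.validate()
    return tree
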