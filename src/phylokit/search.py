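"""Topological rearrangements (NNI, SPR, TBR) with exact undo, and a
parsimony-filtered hill-climbing search.

Moves operate by pointer surgery on the half-edge records.  Edge ids and
branch lengths travel with the subtree they belong to, so an edge that
survives a move keeps its identity (and any cached transition matrices
keyed by id and length stay usable).  Applying or undoing a move
invalidates the stored CLV orientations of exactly the nodes whose CLV
covers a changed region; a subsequent partial traversal therefore
recomputes just what the move made stale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .likelihood import AUTO, TreeLikelihood
from .optimize import OptimizerSettings, optimize_all_branches, optimize_branch
from .parsimony import ParsimonyData, fitch_score
from .tree import HalfEdge, Tree


class MoveError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NNI

@dataclass
class NNIMove:
    """Swap the subtree at one end of an internal edge with a subtree at
    the other end; ``variant`` picks which of the two far subtrees."""

    edge_id: int
    variant: int  # 0 or 1
    applied: bool = False

    def records(self, tree: Tree) -> tuple[HalfEdge, HalfEdge]:
        if self.edge_id not in tree.edges:
            raise MoveError(f"stale move: edge {self.edge_id} no longer exists")
        p, q = tree.edge_records(self.edge_id)
        if p.is_tip or q.is_tip:
            raise MoveError("NNI edge must be internal")
        ra = p.nxt
        rb = q.nxt if self.variant == 0 else q.nxt.nxt
        return ra, rb

    def apply(self, tree: Tree) -> None:
        if self.applied:
            raise MoveError("move already applied")
        ra, rb = self.records(tree)
        _swap_subtrees(tree, ra, rb)
        self._invalidate(tree)
        self.applied = True

    def undo(self, tree: Tree) -> None:
        if not self.applied:
            raise MoveError("move not applied")
        ra, rb = self.records(tree)
        _swap_subtrees(tree, ra, rb)
        self._invalidate(tree)
        self.applied = False

    def _invalidate(self, tree: Tree) -> None:
        tree.invalidate_dependents([self.edge_id])
        p, q = tree.edge_records(self.edge_id)
        tree.orientation[p.node_id] = None
        tree.orientation[q.node_id] = None

    def sort_key(self):
        return ("NNI", self.edge_id, self.variant)


def _swap_subtrees(tree: Tree, ra: HalfEdge, rb: HalfEdge) -> None:
    """Exchange the subtrees behind ``ra.back`` and ``rb.back``; each
    subtree keeps its edge id and branch length."""
    a, b = ra.back, rb.back
    la, ea = ra.length, ra.edge_id
    lb, eb = rb.length, rb.edge_id
    ra.back, b.back = b, ra
    rb.back, a.back = a, rb
    ra.length = b.length = lb
    ra.edge_id = b.edge_id = eb
    rb.length = a.length = la
    rb.edge_id = a.edge_id = ea
    tree.edges[ea] = rb
    tree.edges[eb] = ra


def nni_alternatives(tree: Tree, edge_id: int) -> list[NNIMove]:
    """The two nearest-neighbour-interchange alternatives around an
    internal edge."""
    p, q = tree.edge_records(edge_id)
    if p.is_tip or q.is_tip:
        raise MoveError("NNI requires an internal edge")
    return [NNIMove(edge_id, 0), NNIMove(edge_id, 1)]


# ---------------------------------------------------------------------------
# SPR

@dataclass
class SPRMove:
    """Prune the subtree hanging at ``subtree_edge`` (on the far side of
    inner node ``v_node``) and regraft it onto ``target_edge``."""

    subtree_edge: int
    v_node: int
    target_edge: int
    applied: bool = False
    _undo: dict = field(default_factory=dict, repr=False)

    def sort_key(self):
        return ("SPR", self.subtree_edge, self.v_node, self.target_edge)

    def _rv(self, tree: Tree) -> HalfEdge:
        if self.subtree_edge not in tree.edges:
            raise MoveError("stale move: subtree edge gone")
        r, b = tree.edge_records(self.subtree_edge)
        rv = r if r.node_id == self.v_node else b
        if rv.node_id != self.v_node or rv.is_tip:
            raise MoveError("stale move: junction node changed")
        return rv

    def apply(self, tree: Tree) -> None:
        if self.applied:
            raise MoveError("move already applied")
        if self.target_edge not in tree.edges:
            raise MoveError("stale move: target edge gone")
        rv = self._rv(tree)
        ra, rb = rv.nxt, rv.nxt.nxt
        a, b = ra.back, rb.back
        st = self._undo
        st["ea"], st["la"] = ra.edge_id, ra.length
        st["eb"], st["lb"] = rb.edge_id, rb.length
        if self.target_edge in (st["ea"], st["eb"], self.subtree_edge):
            raise MoveError("SPR target recreates the original topology")
        touched_pre = [st["ea"], st["eb"], self.subtree_edge, self.target_edge]
        tree.invalidate_dependents(touched_pre)
        # detach the junction and close the gap
        tree.disconnect(st["ea"])
        tree.disconnect(st["eb"])
        merged = tree.connect(a, b, st["la"] + st["lb"], edge_id=st["ea"])
        st["merged"] = merged
        # split the target edge and graft the junction in
        rt, bt = tree.edge_records(self.target_edge)
        st["lt"] = rt.length
        tree.disconnect(self.target_edge)
        tree.connect(ra, rt, st["lt"] / 2.0, edge_id=self.target_edge)
        st["new_eid"] = tree.connect(rb, bt, st["lt"] / 2.0)
        st["rt_id"], st["bt_id"] = id(rt), id(bt)
        tree.invalidate_dependents([merged, self.target_edge, st["new_eid"],
                                    self.subtree_edge])
        tree.orientation[self.v_node] = None
        self.applied = True

    def undo(self, tree: Tree) -> None:
        if not self.applied:
            raise MoveError("move not applied")
        rv = self._rv(tree)
        ra, rb = rv.nxt, rv.nxt.nxt
        st = self._undo
        tree.invalidate_dependents([st["merged"], self.target_edge,
                                    st["new_eid"], self.subtree_edge])
        rt = ra.back
        bt = rb.back
        tree.disconnect(self.target_edge)
        tree.disconnect(st["new_eid"])
        a, b = tree.edge_records(st["merged"])
        tree.disconnect(st["merged"])
        tree.connect(rt, bt, st["lt"], edge_id=self.target_edge)
        tree.connect(ra, a, st["la"], edge_id=st["ea"])
        tree.connect(rb, b, st["lb"], edge_id=st["eb"])
        tree.invalidate_dependents([st["ea"], st["eb"], self.target_edge,
                                    self.subtree_edge])
        tree.orientation[self.v_node] = None
        self.applied = False


def spr_candidates(tree: Tree, prune_edge: int, radius: int,
                   v_node: int | None = None) -> list[SPRMove]:
    """Regraft targets within ``radius`` edge steps of the pruning point.

    ``prune_edge`` connects the pruned subtree to the junction node V that
    will be relocated; targets are enumerated by breadth-first search over
    the remaining tree, treating the merged gap edge as distance zero (the
    gap itself is excluded — regrafting there recreates the topology).
    """
    if radius < 1:
        raise MoveError("radius must be >= 1")
    r, b = tree.edge_records(prune_edge)
    if v_node is None:
        if not r.is_tip and not b.is_tip:
            raise MoveError("ambiguous junction: pass v_node for an internal"
                            " prune edge")
        rv = r if not r.is_tip else b
        v_node = rv.node_id
    else:
        rv = r if r.node_id == v_node else b
    if rv.is_tip:
        raise MoveError("junction endpoint must be an inner node")
    ra, rb = rv.nxt, rv.nxt.nxt
    # BFS over half-edges leading away from the gap
    out: list[SPRMove] = []
    frontier: list[HalfEdge] = []
    for rec in (ra.back, rb.back):
        if not rec.is_tip:
            frontier.extend([rec.nxt, rec.nxt.nxt])
    dist = 1
    seen = {ra.edge_id, rb.edge_id}
    while frontier and dist <= radius:
        nxt_frontier: list[HalfEdge] = []
        for rec in frontier:
            if rec.edge_id in seen:
                continue
            seen.add(rec.edge_id)
            out.append(SPRMove(prune_edge, v_node, rec.edge_id))
            child = rec.back
            if not child.is_tip:
                nxt_frontier.extend([child.nxt, child.nxt.nxt])
        frontier = nxt_frontier
        dist += 1
    out.sort(key=lambda m: m.sort_key())
    return out


# ---------------------------------------------------------------------------
# TBR

@dataclass
class TBRMove:
    """Bisect an internal edge, then reconnect the two components by a new
    edge between the midpoints of one target edge on each side."""

    bisect_edge: int
    left_target: int
    right_target: int
    applied: bool = False
    _undo: dict = field(default_factory=dict, repr=False)

    def sort_key(self):
        return ("TBR", self.bisect_edge, self.left_target, self.right_target)

    def apply(self, tree: Tree) -> None:
        if self.applied:
            raise MoveError("move already applied")
        if self.bisect_edge not in tree.edges:
            raise MoveError("stale move: bisection edge gone")
        p, q = tree.edge_records(self.bisect_edge)
        if p.is_tip or q.is_tip:
            raise MoveError("TBR requires an internal edge")
        st = self._undo
        st["p_node"], st["q_node"] = p.node_id, q.node_id
        st["lt"] = p.length
        pa, pb = p.nxt, p.nxt.nxt
        qa, qb = q.nxt, q.nxt.nxt
        st["pea"], st["pla"] = pa.edge_id, pa.length
        st["peb"], st["plb"] = pb.edge_id, pb.length
        st["qea"], st["qla"] = qa.edge_id, qa.length
        st["qeb"], st["qlb"] = qb.edge_id, qb.length
        if self.left_target in (st["pea"], st["peb"]) and \
           self.right_target in (st["qea"], st["qeb"]):
            raise MoveError("TBR reconnection recreates the original topology")
        tree.invalidate_dependents([self.bisect_edge, st["pea"], st["peb"],
                                    st["qea"], st["qeb"], self.left_target,
                                    self.right_target])
        a1, a2 = pa.back, pb.back
        b1, b2 = qa.back, qb.back
        tree.disconnect(self.bisect_edge)
        tree.disconnect(st["pea"])
        tree.disconnect(st["peb"])
        tree.disconnect(st["qea"])
        tree.disconnect(st["qeb"])
        tree.connect(a1, a2, st["pla"] + st["plb"], edge_id=st["pea"])
        tree.connect(b1, b2, st["qla"] + st["qlb"], edge_id=st["qea"])
        # split the two targets and rebuild the bridge p--q
        for rec_pair, target, key in ((p, self.left_target, "l"),
                                      (q, self.right_target, "r")):
            rt, bt = tree.edge_records(target)
            st[f"{key}_len"] = rt.length
            tree.disconnect(target)
            tree.connect(rec_pair.nxt, rt, st[f"{key}_len"] / 2.0, edge_id=target)
            st[f"{key}_new"] = tree.connect(rec_pair.nxt.nxt, bt,
                                            st[f"{key}_len"] / 2.0)
        tree.connect(p, q, st["lt"], edge_id=self.bisect_edge)
        tree.invalidate_dependents([self.bisect_edge, st["pea"], st["qea"],
                                    self.left_target, self.right_target,
                                    st["l_new"], st["r_new"]])
        tree.orientation[p.node_id] = None
        tree.orientation[q.node_id] = None
        self.applied = True

    def undo(self, tree: Tree) -> None:
        if not self.applied:
            raise MoveError("move not applied")
        st = self._undo
        p, q = tree.edge_records(self.bisect_edge)
        if p.node_id != st["p_node"]:
            p, q = q, p
        tree.invalidate_dependents([self.bisect_edge, st["pea"], st["qea"],
                                    self.left_target, self.right_target,
                                    st["l_new"], st["r_new"]])
        tree.disconnect(self.bisect_edge)
        for rec_pair, target, key in ((p, self.left_target, "l"),
                                      (q, self.right_target, "r")):
            rt = rec_pair.nxt.back
            bt = rec_pair.nxt.nxt.back
            tree.disconnect(target)
            tree.disconnect(st[f"{key}_new"])
            tree.connect(rt, bt, st[f"{key}_len"], edge_id=target)
        a1, a2 = tree.edge_records(st["pea"])
        tree.disconnect(st["pea"])
        b1, b2 = tree.edge_records(st["qea"])
        tree.disconnect(st["qea"])
        tree.connect(p.nxt, a1, st["pla"], edge_id=st["pea"])
        tree.connect(p.nxt.nxt, a2, st["plb"], edge_id=st["peb"])
        tree.connect(q.nxt, b1, st["qla"], edge_id=st["qea"])
        tree.connect(q.nxt.nxt, b2, st["qlb"], edge_id=st["qeb"])
        tree.connect(p, q, st["lt"], edge_id=self.bisect_edge)
        tree.invalidate_dependents([self.bisect_edge, st["pea"], st["peb"],
                                    st["qea"], st["qeb"], self.left_target,
                                    self.right_target])
        tree.orientation[p.node_id] = None
        tree.orientation[q.node_id] = None
        self.applied = False


def tbr_candidates(tree: Tree, bisect_edge: int, radius: int) -> list[TBRMove]:
    """Cross product of reconnection targets within ``radius`` edge steps on
    each side of the bisected edge; the original reconnection is excluded."""
    if radius < 1:
        raise MoveError("radius must be >= 1")
    p, q = tree.edge_records(bisect_edge)
    if p.is_tip or q.is_tip:
        raise MoveError("TBR requires an internal edge")

    def side_edges(rec: HalfEdge) -> list[int]:
        # edges within radius of the dissolved junction, by BFS
        pa, pb = rec.nxt, rec.nxt.nxt
        seen = {pa.edge_id, pb.edge_id}
        found: list[int] = []
        frontier = []
        for r in (pa.back, pb.back):
            if not r.is_tip:
                frontier.extend([r.nxt, r.nxt.nxt])
        # the merged gap edge (distance 0) is a valid reconnection target
        # only in combination with a different target on the other side;
        # represent it by the surviving id of its first half (pa).
        found.append(pa.edge_id)
        dist = 1
        while frontier and dist <= radius:
            nxt = []
            for r in frontier:
                if r.edge_id in seen:
                    continue
                seen.add(r.edge_id)
                found.append(r.edge_id)
                if not r.back.is_tip:
                    nxt.extend([r.back.nxt, r.back.nxt.nxt])
            frontier = nxt
            dist += 1
        return found

    left = side_edges(p)
    right = side_edges(q)
    out = []
    for lt in left:
        for rt in right:
            if lt == p.nxt.edge_id and rt == q.nxt.edge_id:
                continue  # original reconnection
            out.append(TBRMove(bisect_edge, lt, rt))
    out.sort(key=lambda m: m.sort_key())
    return out


# ---------------------------------------------------------------------------
# Hill-climbing search with parsimony filtering

@dataclass
class SearchRound:
    n_candidates: int
    n_evaluated: int
    best_logl: float
    accepted: str | None


@dataclass
class SearchResult:
    logl: float
    rounds: list[SearchRound]

    def trace_tsv(self) -> str:
        lines = ["round\tcandidates\tevaluated\tbest_logl\taccepted"]
        for i, r in enumerate(self.rounds, 1):
            lines.append(f"{i}\t{r.n_candidates}\t{r.n_evaluated}"
                         f"\t{r.best_logl:.6f}\t{r.accepted or '-'}")
        return "\n".join(lines) + "\n"


def _enumerate_moves(tree: Tree, strategy: str, radius: int):
    moves = []
    if strategy == "NNI":
        for eid in sorted(tree.edges):
            r, b = tree.edge_records(eid)
            if r.is_tip or b.is_tip:
                continue
            moves.extend(nni_alternatives(tree, eid))
    elif strategy == "SPR":
        for eid in sorted(tree.edges):
            r, b = tree.edge_records(eid)
            for rec in (r, b):
                if rec.is_tip:
                    continue
                try:
                    moves.extend(spr_candidates(tree, eid, radius, rec.node_id))
                except MoveError:
                    continue
    else:
        raise ValueError(f"unknown search strategy {strategy!r}")
    return moves


def _move_local_edges(tree: Tree, move) -> list[int]:
    """Edges re-optimised when trialling a move (the regraft neighbourhood)."""
    if isinstance(move, NNIMove):
        return [move.edge_id]
    if isinstance(move, SPRMove):
        rv = move._rv(tree)
        return [rv.edge_id, rv.nxt.edge_id, rv.nxt.nxt.edge_id]
    p, q = tree.edge_records(move.bisect_edge)
    return [move.bisect_edge, p.nxt.edge_id, q.nxt.edge_id]


def search(tl: TreeLikelihood, strategy: str = "SPR",
           settings: OptimizerSettings | None = None,
           radius: int = 10, filter_fraction: float = 0.25,
           min_evaluated: int = 5) -> SearchResult:
    """Hill climbing over NNI or SPR neighbourhoods.

    Each round enumerates candidate moves, ranks them by the Fitch
    parsimony score of the rearranged tree (ascending), evaluates the best
    ``filter_fraction`` (at least ``min_evaluated``) by log-likelihood with
    partial traversals and local branch-length optimisation, and accepts
    the best strictly improving move followed by a full branch smoothing.
    Stops when the best candidate improves logL by at most epsilon.
    """
    settings = settings or OptimizerSettings()
    tree = tl.tree
    pdata = ParsimonyData.from_alignment(tl.paln)
    rounds: list[SearchRound] = []
    current = optimize_all_branches(tl, settings).total
    while True:
        moves = _enumerate_moves(tree, strategy, radius)
        scored = []
        for mv in moves:
            try:
                mv.apply(tree)
            except MoveError:
                continue
            score = fitch_score(tree, pdata, informative_only=True)
            mv.undo(tree)
            scored.append((score, mv.sort_key(), mv))
        scored.sort(key=lambda t: (t[0], t[1]))
        n_eval = max(min_evaluated, int(np.ceil(filter_fraction * len(scored))))
        n_eval = min(n_eval, len(scored))
        best_logl, best_mv = -np.inf, None
        for score, _, mv in scored[:n_eval]:
            mv.apply(tree)
            local = _move_local_edges(tree, mv)
            saved = {eid: tree.edge_records(eid)[0].length for eid in local}
            for eid in local:
                optimize_branch(tl, eid, settings)
            trial = tl.evaluate(local[0], mode=AUTO).total
            for eid, length in saved.items():
                tl.set_branch_length(eid, length)
            mv.undo(tree)
            if trial > best_logl:
                best_logl, best_mv = trial, mv
        if best_mv is None or best_logl - current <= settings.epsilon_logl:
            rounds.append(SearchRound(len(scored), n_eval, current, None))
            break
        best_mv.apply(tree)
        for eid in _move_local_edges(tree, best_mv):
            optimize_branch(tl, eid, settings)
        res = optimize_all_branches(tl, settings)
        if res.total <= current:
            # numerical tie after smoothing: revert and stop
            best_mv.undo(tree)
            res = optimize_all_branches(tl, settings)
            rounds.append(SearchRound(len(scored), n_eval, res.total, None))
            break
        rounds.append(SearchRound(len(scored), n_eval, res.total,
                                  str(best_mv.sort_key())))
        current = res.total
    return SearchResult(current, rounds)
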