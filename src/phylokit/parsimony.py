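"""Fitch parsimony on state-set bitmasks, and randomized stepwise-addition
starting trees.

Each tip character becomes a bitmask over the partition's states (ambiguity
codes set several bits, gaps set all).  The Fitch post-order intersects the
two child sets; an empty intersection costs one mutation (times the
pattern weight) and takes the union instead.  The total score does not
depend on where the traversal is rooted.

Site patterns whose minimal mutation count is the same on every topology
(constant columns, and columns where at most one state occurs more than
once) are scored once and carried as a constant offset, so the inner loop
of stepwise addition and move ranking only touches parsimony-informative
patterns; reported scores always include the offset and are complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import PatternAlignment, tip_bitmask_vector
from .states import get_type
from .tree import DEFAULT_BRANCH, FULL, Tree


@dataclass
class ParsimonyData:
    """Per-partition tip bitmasks, weights, and the uninformative offset."""

    tip_masks: list[dict[str, np.ndarray]]   # per partition: label -> (npat,)
    weights: list[np.ndarray]
    offsets: list[float]                      # topology-independent score part
    informative: list[np.ndarray]             # bool mask over patterns

    @classmethod
    def from_alignment(cls, paln: PatternAlignment) -> "ParsimonyData":
        tip_masks, weights, offsets, informative = [], [], [], []
        for pp in paln.parts:
            dt = get_type(pp.partition.data_type)
            masks = {name: tip_bitmask_vector(pp, ti, dt)
                     for ti, name in enumerate(paln.taxon_names)}
            info = np.ones(pp.n_patterns, dtype=bool)
            offset = 0.0
            for p, col in enumerate(pp.patterns):
                fixed = [dt.codes[ch] for ch in col]
                if any(len(c) != 1 for c in fixed):
                    continue  # ambiguity present: keep in the full recursion
                counts: dict[str, int] = {}
                for c in fixed:
                    counts[c] = counts.get(c, 0) + 1
                if sum(1 for v in counts.values() if v >= 2) <= 1:
                    info[p] = False
                    offset += float(pp.weights[p]) * (len(counts) - 1)
            tip_masks.append(masks)
            weights.append(pp.weights.astype(float))
            offsets.append(offset)
            informative.append(info)
        return cls(tip_masks, weights, offsets, informative)


def fitch_score(tree: Tree, data: ParsimonyData | PatternAlignment,
                root_edge: int | None = None,
                informative_only: bool = False) -> float:
    """Weighted Fitch parsimony score of the tree.

    ``informative_only`` skips the topology-independent offset (useful when
    only score differences matter); the default reports the full score.
    """
    if isinstance(data, PatternAlignment):
        data = ParsimonyData.from_alignment(data)
    if root_edge is None:
        root_edge = min(tree.edges)
    td = tree.build_traversal(root_edge, FULL)
    total = 0.0
    for masks, w, offset, info in zip(data.tip_masks, data.weights,
                                      data.offsets, data.informative):
        use = info
        wsel = w[use]
        if wsel.size == 0:
            if not informative_only:
                total += offset
            continue
        node_masks: dict[int, np.ndarray] = {}

        def mask_of(rec) -> np.ndarray:
            if rec.is_tip:
                return masks[rec.label][use]
            return node_masks[rec.node_id]

        cost = np.zeros(wsel.size)
        for op in td.ops:
            l = mask_of(op.left.back)
            r = mask_of(op.right.back)
            inter = l & r
            empty = inter == 0
            cost += empty
            node_masks[op.node_id] = np.where(empty, l | r, inter)
        u, v = td.root, td.root.back
        inter = mask_of(u) & mask_of(v)
        cost += inter == 0
        total += float(wsel @ cost)
        if not informative_only:
            total += offset
    return total


def stepwise_addition_tree(paln: PatternAlignment, seed: int) -> Tree:
    """Randomized stepwise-addition parsimony starting tree.

    Taxa are shuffled by the seed; each taxon is inserted on the edge that
    minimises the Fitch score of the grown tree (ties break to the lowest
    edge id), so the result is reproducible per seed.
    """
    names = list(paln.taxon_names)
    if len(names) < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    rng = np.random.default_rng(seed)
    order = [names[i] for i in rng.permutation(len(names))]
    data = ParsimonyData.from_alignment(paln)

    tree = Tree()
    base = tree.new_inner()
    for name, slot in zip(order[:3], (base, base.nxt, base.nxt.nxt)):
        tree.connect(slot, tree.new_tip(name), DEFAULT_BRANCH)

    for name in order[3:]:
        tip = tree.new_tip(name)
        mid = tree.new_inner()
        best_eid, best_score = None, np.inf
        for eid in sorted(tree.edges):
            a, b = tree.disconnect(eid)
            tree.connect(mid, a, a.length, edge_id=eid)
            e2 = tree.connect(mid.nxt, b, b.length)
            e3 = tree.connect(mid.nxt.nxt, tip, DEFAULT_BRANCH)
            score = fitch_score(tree, data, informative_only=True)
            if score < best_score:
                best_score, best_eid = score, eid
            # take the insertion back out
            tree.disconnect(e3)
            tree.disconnect(e2)
            ra, _ = tree.disconnect(eid)
            tree.connect(a, b, a.length, edge_id=eid)
        a, b = tree.disconnect(best_eid)
        tree.connect(mid, a, a.length, edge_id=best_eid)
        tree.connect(mid.nxt, b, b.length)
        tree.connect(mid.nxt.nxt, tip, DEFAULT_BRANCH)
    tree.validate()
    tree.invalidate_all()
    return tree
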