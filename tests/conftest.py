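"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's pruning/Fitch code paths:
likelihoods are computed by exhaustive summation over all inner-node state
assignments, parsimony by Sankoff dynamic programming, and topologies by
explicit enumeration, so every comparison is against an independent
implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phylokit.alignment import compress_patterns, default_scheme
from phylokit.models import PartitionModel
from phylokit.states import get_type
from phylokit.tree import Tree


# ---------------------------------------------------------------------------
# Exhaustive likelihood oracle

def brute_force_partition_logl(tree, ps, model) -> float:
    """Log-likelihood of one partition by summing over every assignment of
    states to inner nodes (and every rate category)."""
    sub = model.subst
    n = sub.n_states
    rates = model.category_rates()
    cat_w = model.category_weights()
    inner_ids = sorted(tree.inner)
    n_obs = ps.n_obs
    # orient every edge away from the root node by BFS, so each factor is
    # P[x_parent, x_child] (direction matters for non-symmetric P)
    root_id = inner_ids[0]
    directed: list[tuple[int, object, float]] = []  # (parent_id, child_rec, t)
    start = tree.inner[root_id]
    stack = [(rec, root_id) for rec in (start, start.nxt, start.nxt.nxt)]
    while stack:
        rec, parent = stack.pop()
        child = rec.back
        directed.append((parent, child, rec.length))
        if not child.is_tip:
            stack.extend([(r, child.node_id)
                          for r in (child.nxt, child.nxt.nxt)])
    site_l = np.zeros(ps.n_pat)
    for j, rj in enumerate(rates):
        pmats = {id(child): sub.transition_matrix(t, rj)
                 for _, child, t in directed}
        cat_l = np.zeros(ps.n_pat)
        for assign in itertools.product(range(n), repeat=len(inner_ids)):
            st = dict(zip(inner_ids, assign))
            prob = np.full(ps.n_pat, sub.freqs[st[root_id]])
            for parent, child, _t in directed:
                p = pmats[id(child)]
                if child.is_tip:
                    prob = prob * (ps.tip_clv[child.label] @ p[st[parent]])
                else:
                    prob = prob * p[st[parent], st[child.node_id]]
            cat_l += prob
        if model.het.mode == "PSR":
            sel = model_assign(ps) == j
            site_l[:n_obs][sel] += cat_l[:n_obs][sel]
        else:
            site_l += cat_w[j] * cat_l
    obs = site_l[:n_obs]
    logl = np.log(obs)
    if ps.asc:
        v = site_l[n_obs:].sum()
        logl = logl - np.log1p(-v)
    return float(ps.weights @ logl)


def model_assign(ps):
    return ps.psr_assign


def brute_force_logl(tl) -> float:
    return sum(brute_force_partition_logl(tl.tree, ps, ps.model)
               for ps in tl.parts)


# ---------------------------------------------------------------------------
# Sankoff parsimony oracle (minimum mutation count per pattern)

def sankoff_min_mutations(tree, masks_by_label: dict[str, int],
                          n_states: int) -> int:
    """Minimal number of state changes for one site pattern, by dynamic
    programming from an arbitrary edge root."""
    eid = min(tree.edges)
    u, v = tree.edge_records(eid)
    inf = 10 ** 6

    def cost(rec) -> np.ndarray:
        """Cost vector of the subtree behind rec (at rec's node, looking
        away from rec.back)."""
        if rec.is_tip:
            mask = masks_by_label[rec.label]
            return np.array([0 if mask & (1 << s) else inf
                             for s in range(n_states)])
        out = np.zeros(n_states, dtype=np.int64)
        for child in (rec.nxt.back, rec.nxt.nxt.back):
            c = cost(child)
            out += np.array([min(c[s2] + (0 if s1 == s2 else 1)
                                 for s2 in range(n_states))
                             for s1 in range(n_states)])
        return out

    cu, cv = cost(u), cost(v)
    best = min(cu[s1] + cv[s2] + (0 if s1 == s2 else 1)
               for s1 in range(n_states) for s2 in range(n_states))
    return int(best)


def brute_force_parsimony(tree, paln) -> float:
    total = 0.0
    for pp in paln.parts:
        dt = get_type(pp.partition.data_type)
        for col, w in zip(pp.patterns, pp.weights):
            masks = {name: dt.bitmasks[ch]
                     for name, ch in zip(paln.taxon_names, col)}
            total += float(w) * sankoff_min_mutations(tree, masks, dt.n_states)
    return total


# ---------------------------------------------------------------------------
# Topology enumeration (nested-tuple form -> newick)

def all_topologies(labels: list[str]) -> list[str]:
    """Newick strings of every unrooted bifurcating topology over the
    labels (3, 15, 105, 945... for 4, 5, 6, 7 taxa)."""

    def subtrees(struct):
        # yields (subtree, replacer) pairs for every edge of the structure
        for i, child in enumerate(struct):
            def replace_top(newsub, i=i):
                out = list(struct)
                out[i] = newsub
                return tuple(out)
            yield child, replace_top
            if isinstance(child, tuple):
                for sub, rep in edge_iter(child):
                    def replace_deep(newsub, rep=rep, i=i):
                        out = list(struct)
                        out[i] = rep(newsub)
                        return tuple(out)
                    yield sub, replace_deep

    def edge_iter(pair):
        for i, child in enumerate(pair):
            def replace_here(newsub, i=i):
                out = list(pair)
                out[i] = newsub
                return tuple(out)
            yield child, replace_here
            if isinstance(child, tuple):
                for sub, rep in edge_iter(child):
                    def replace_deeper(newsub, rep=rep, i=i):
                        out = list(pair)
                        out[i] = rep(newsub)
                        return tuple(out)
                    yield sub, replace_deeper

    trees = [tuple(labels[:3])]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            for sub, rep in subtrees(t):
                nxt.append(rep((sub, label)))
        trees = nxt

    def to_newick(struct) -> str:
        def render(x):
            if isinstance(x, tuple):
                return "(" + ",".join(render(c) for c in x) + "):0.1"
            return f"{x}:0.1"
        return "(" + ",".join(render(c) for c in struct) + ");"

    return [to_newick(t) for t in trees]


# ---------------------------------------------------------------------------
# Random instance helpers

DNA_CHARS = "ACGT"


def random_alignment_text(rng, names, n_sites, chars=DNA_CHARS,
                          gap_rate=0.0) -> str:
    rows = []
    for name in names:
        seq = "".join(rng.choice(list(chars), size=n_sites))
        if gap_rate > 0:
            seq = "".join("-" if rng.random() < gap_rate else c for c in seq)
        rows.append(f">{name}\n{seq}")
    return "\n".join(rows) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
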