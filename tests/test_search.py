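"""Tree rearrangements, Fitch parsimony, stepwise addition, and the
hill-climbing search."""

import numpy as np
import pytest

from conftest import all_topologies, brute_force_parsimony
from phylokit.alignment import Alignment, compress_patterns, default_scheme
from phylokit.likelihood import AUTO, TreeLikelihood
from phylokit.models import PartitionModel
from phylokit.optimize import OptimizerSettings
from phylokit.parsimony import ParsimonyData, fitch_score, stepwise_addition_tree
from phylokit.search import (MoveError, NNIMove, nni_alternatives, search,
                             spr_candidates, tbr_candidates)
from phylokit.simulate import SimulationSpec, random_instance, simulate_alignment
from phylokit.tree import parse_newick, random_tree, write_newick


def _internal_edges(tree):
    return [e for e in sorted(tree.edges)
            if not tree.edge_records(e)[0].is_tip
            and not tree.edge_records(e)[1].is_tip]


class TestNNI:
    def test_quartet_reaches_all_three_topologies(self):
        tree = parse_newick("((a:1,b:1):1,c:1,d:1);")
        seen = {frozenset(tree.bipartitions())}
        e = _internal_edges(tree)[0]
        for mv in nni_alternatives(tree, e):
            mv.apply(tree)
            seen.add(frozenset(tree.bipartitions()))
            mv.undo(tree)
        assert len(seen) == 3

    def test_involution(self):
        tree = random_tree([f"t{i}" for i in range(8)], 3)
        before = write_newick(tree)
        for e in _internal_edges(tree):
            for variant in (0, 1):
                mv = NNIMove(e, variant)
                mv.apply(tree)
                mv2 = NNIMove(e, variant)
                mv2.apply(tree)
                assert write_newick(tree) == before
                mv2.undo(tree)
                mv.undo(tree)
                assert write_newick(tree) == before

    def test_tip_edge_rejected(self):
        tree = parse_newick("((a:1,b:1):1,c:1,d:1);")
        tip_edge = tree.tips["a"].edge_id
        with pytest.raises(MoveError):
            nni_alternatives(tree, tip_edge)

    def test_hill_climb_recovers_quartet(self):
        """Strong signal for ((a,b),(c,d)): NNI from either wrong topology
        finds the true one (exhaustive three-topology comparison)."""
        true = parse_newick("((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3);")
        m = PartitionModel.from_spec("JC")
        sim = simulate_alignment(SimulationSpec(true, [m], [2000], seed=5))
        paln = compress_patterns(sim.alignment, sim.scheme)
        for wrong in ("((a:0.2,c:0.2):0.2,(b:0.2,d:0.2):0.2);",
                      "((a:0.2,d:0.2):0.2,(b:0.2,c:0.2):0.2);"):
            tree = parse_newick(wrong)
            tl = TreeLikelihood(tree, paln)
            result = search(tl, "NNI", OptimizerSettings())
            assert tree.bipartitions() == true.bipartitions()
            assert result.logl >= TreeLikelihood(
                parse_newick(wrong), paln).evaluate(
                    min(parse_newick(wrong).edges)).total


class TestMoveUndoExactness:
    def test_random_moves_restore_everything(self, rng):
        """Apply+undo restores canonical newick, edge ids, and lengths for
        hundreds of random (tree, move) pairs."""
        checked = 0
        for seed in range(40):
            tree = random_tree([f"t{i}" for i in range(9)], seed)
            before_newick = write_newick(tree)
            before_edges = {e: tree.edges[e].length for e in tree.edges}
            moves = []
            for e in _internal_edges(tree):
                moves.extend(nni_alternatives(tree, e))
                moves.extend(tbr_candidates(tree, e, 3)[:4])
            for e in sorted(tree.edges):
                r, b = tree.edge_records(e)
                for rec in (r, b):
                    if not rec.is_tip:
                        moves.extend(spr_candidates(tree, e, 3, rec.node_id)[:3])
            for mv in moves:
                mv.apply(tree)
                tree.validate()
                mv.undo(tree)
                tree.validate()
                assert write_newick(tree) == before_newick
                got = {e: tree.edges[e].length for e in tree.edges}
                assert got == before_edges
                checked += 1
        assert checked >= 1000

    def test_partial_equals_full_after_each_move(self, rng):
        inst = random_instance(8, 150, "GTR+G", seed=8)
        tl = TreeLikelihood(inst.tree, inst.pattern_alignment,
                            models=[inst.true_model])
        tree = inst.tree
        moves = []
        for e in _internal_edges(tree):
            moves.extend(nni_alternatives(tree, e))
        for e in sorted(tree.edges)[:6]:
            r, b = tree.edge_records(e)
            for rec in (r, b):
                if not rec.is_tip:
                    moves.extend(spr_candidates(tree, e, 4, rec.node_id)[:2])
        for mv in moves:
            mv.apply(tree)
            e = min(tree.edges)
            partial = tl.evaluate(e, mode=AUTO).total
            fresh = TreeLikelihood(tree, inst.pattern_alignment,
                                   models=[inst.true_model])
            assert partial == pytest.approx(
                fresh.evaluate(e, mode="FULL").total, abs=1e-8)
            mv.undo(tree)


class TestSPRCandidates:
    def test_radius_one_is_adjacent_only(self):
        tree = random_tree([f"t{i}" for i in range(8)], 11)
        e = sorted(tree.edges)[0]
        r, b = tree.edge_records(e)
        v = r if not r.is_tip else b
        cands = spr_candidates(tree, e, 1, v.node_id)
        # radius 1: only the (up to) four edges adjacent to the gap
        assert 1 <= len(cands) <= 4

    def test_unbounded_radius_count(self):
        """Candidate count equals the brute-force formula: every edge of
        the pruned remainder except the merged gap edge."""
        for seed in (0, 5, 9):
            tree = random_tree([f"t{i}" for i in range(9)], seed)
            for e in sorted(tree.edges):
                r, b = tree.edge_records(e)
                for rec in (r, b):
                    if rec.is_tip:
                        continue
                    cands = spr_candidates(tree, e, 100, rec.node_id)
                    # count edges behind the pruned subtree (on the far side
                    # of e from rec): those are unavailable
                    far = rec.back
                    sub_edges = set()
                    stack = [far]
                    while stack:
                        x = stack.pop()
                        if x.is_tip:
                            continue
                        for rr in (x.nxt, x.nxt.nxt):
                            sub_edges.add(rr.edge_id)
                            stack.append(rr.back)
                    # total - subtree edges - prune edge - two gap edges,
                    # + 1 for the merged gap = candidates... equivalently:
                    expected = (tree.n_edges - len(sub_edges) - 1) - 2
                    assert len(cands) == expected

    def test_candidates_exclude_original(self):
        tree = random_tree([f"t{i}" for i in range(7)], 2)
        e = sorted(tree.edges)[0]
        r, b = tree.edge_records(e)
        v = r if not r.is_tip else b
        gap = {v.nxt.edge_id, v.nxt.nxt.edge_id}
        for mv in spr_candidates(tree, e, 100, v.node_id):
            assert mv.target_edge not in gap


class TestTBRCandidates:
    def test_superset_of_spr_same_edge(self):
        """Unbounded TBR neighbourhood contains the SPR neighbourhoods of
        both directed prunings of the same internal edge."""
        tree = random_tree([f"t{i}" for i in range(7)], 21)
        e = _internal_edges(tree)[0]
        tbr_tops = set()
        before = write_newick(tree)
        for mv in tbr_candidates(tree, e, 100):
            mv.apply(tree)
            tbr_tops.add(frozenset(tree.bipartitions()))
            mv.undo(tree)
        assert write_newick(tree) == before
        r, b = tree.edge_records(e)
        for rec in (r, b):
            for mv in spr_candidates(tree, e, 100, rec.node_id):
                mv.apply(tree)
                top = frozenset(tree.bipartitions())
                mv.undo(tree)
                assert top in tbr_tops

    def test_count_matches_pair_enumeration(self):
        tree = random_tree([f"t{i}" for i in range(6)], 31)
        for e in _internal_edges(tree):
            cands = tbr_candidates(tree, e, 100)
            p, q = tree.edge_records(e)

            def side_count(rec):
                n = 1  # the merged gap edge
                stack = [rec.nxt.back, rec.nxt.nxt.back]
                while stack:
                    x = stack.pop()
                    if x.is_tip:
                        continue
                    n += 2
                    stack.extend([x.nxt.back, x.nxt.nxt.back])
                return n

            assert len(cands) == side_count(p) * side_count(q) - 1

    def test_tip_edge_rejected(self):
        tree = random_tree([f"t{i}" for i in range(6)], 1)
        tip_edge = tree.tips["t1"].edge_id
        with pytest.raises(MoveError):
            tbr_candidates(tree, tip_edge, 2)


class TestFitch:
    def test_identical_sequences_score_zero(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        paln = compress_patterns(aln, default_scheme(aln, "JC"))
        tree = random_tree(["a", "b", "c", "d"], 0)
        assert fitch_score(tree, paln) == 0

    def test_quartet_single_column(self):
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "C", "C"])
        paln = compress_patterns(aln, default_scheme(aln, "JC"))
        good = parse_newick("((a:1,b:1):1,c:1,d:1);")
        bad = parse_newick("((a:1,c:1):1,b:1,d:1);")
        assert fitch_score(good, paln) == 1
        assert fitch_score(bad, paln) == 2

    def test_root_placement_invariance(self, rng):
        inst = random_instance(7, 40, "GTR", seed=3)
        scores = {fitch_score(inst.tree, inst.pattern_alignment, root_edge=e)
                  for e in inst.tree.edges}
        assert len(scores) == 1

    def test_equals_sankoff_oracle_all_topologies(self, rng):
        """Fitch == brute-force minimal mutation count on every 5-taxon
        topology, random characters with ambiguity and gaps."""
        labels = list("abcde")
        rows = ["".join(rng.choice(list("ACGTRN-"), size=6))
                for _ in labels]
        aln = Alignment(labels, rows)
        paln = compress_patterns(aln, default_scheme(aln, "GTR"))
        for nw in all_topologies(labels):
            tree = parse_newick(nw)
            assert fitch_score(tree, paln) == brute_force_parsimony(tree, paln)

    def test_informative_filter_consistent(self, rng):
        """Full score equals informative-only score plus the constant
        offset on data with many uninformative columns."""
        labels = [f"t{i}" for i in range(6)]
        rows_arr = rng.choice(list("ACGT"), size=(6, 30), p=[.85, .05, .05, .05])
        aln = Alignment(labels, ["".join(r) for r in rows_arr])
        paln = compress_patterns(aln, default_scheme(aln, "JC"))
        tree = random_tree(labels, 9)
        data = ParsimonyData.from_alignment(paln)
        full = fitch_score(tree, data)
        assert full == brute_force_parsimony(tree, paln)
        assert full == fitch_score(tree, data, informative_only=True) + \
            sum(data.offsets)


class TestStepwiseAddition:
    def test_three_taxa_unique(self):
        aln = Alignment(["a", "b", "c"], ["ACGT", "ACGA", "ACCA"])
        paln = compress_patterns(aln, default_scheme(aln, "JC"))
        t1 = stepwise_addition_tree(paln, 1)
        t2 = stepwise_addition_tree(paln, 99)
        assert t1.bipartitions() == t2.bipartitions() == frozenset()

    def test_deterministic_per_seed(self, rng):
        inst = random_instance(9, 60, "GTR", seed=5)
        a = stepwise_addition_tree(inst.pattern_alignment, 7)
        b = stepwise_addition_tree(inst.pattern_alignment, 7)
        c = stepwise_addition_tree(inst.pattern_alignment, 8)
        assert write_newick(a) == write_newick(b)
        assert write_newick(c) != "" and c.n_taxa == 9

    def test_homoplasy_free_data_reaches_minimum(self):
        """On perfectly compatible characters the stepwise tree attains the
        global parsimony minimum (verified over all 6-taxon topologies)."""
        labels = list("abcdef")
        # characters generated from a known tree, one mutation each:
        # splits ab|cdef, abc|def, abcd|ef
        cols = {"a": "000", "b": "000", "c": "100", "d": "110",
                "e": "111", "f": "111"}
        aln = Alignment(labels, [cols[l] for l in labels])
        paln = compress_patterns(aln, default_scheme(aln, "BIN"))
        best = min(fitch_score(parse_newick(nw), paln)
                   for nw in all_topologies(labels))
        for seed in range(5):
            tree = stepwise_addition_tree(paln, seed)
            assert fitch_score(tree, paln) == best == 3


class TestSearch:
    def _high_signal_instance(self, seed, n_sites=2000):
        names = [f"t{i}" for i in range(8)]
        true = random_tree(names, seed, mean_branch=0.25)
        m = PartitionModel.from_spec("JC")
        sim = simulate_alignment(SimulationSpec(true, [m], [n_sites],
                                                seed=seed + 1000))
        paln = compress_patterns(sim.alignment, sim.scheme)
        return true, paln

    def test_true_topology_is_local_optimum(self):
        true, paln = self._high_signal_instance(2)
        tl = TreeLikelihood(true, paln)
        result = search(tl, "NNI", OptimizerSettings())
        assert all(r.accepted is None for r in result.rounds)
        assert true.bipartitions() == tl.tree.bipartitions()

    def test_spr_recovers_topology_from_random_start(self):
        true, paln = self._high_signal_instance(4)
        start = stepwise_addition_tree(paln, 123)
        tl = TreeLikelihood(start, paln)
        before = tl.evaluate(min(start.edges)).total
        result = search(tl, "SPR", OptimizerSettings(), radius=10)
        assert tl.tree.bipartitions() == true.bipartitions()
        assert result.logl >= before

    def test_accepted_moves_strictly_improve(self):
        true, paln = self._high_signal_instance(6)
        start = random_tree([f"t{i}" for i in range(8)], 777)
        tl = TreeLikelihood(start, paln)
        result = search(tl, "SPR", OptimizerSettings(), radius=10)
        logls = [r.best_logl for r in result.rounds if r.accepted]
        assert all(b > a for a, b in zip(logls, logls[1:]))
        assert result.trace_tsv().startswith("round\t")
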