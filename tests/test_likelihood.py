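"""Likelihood core: pruning vs exhaustive enumeration, virtual-root
invariance, partial traversals, numerical scaling, ascertainment
correction, ancestral states, and PSR assignment."""

import numpy as np
import pytest

from conftest import brute_force_logl, brute_force_partition_logl
from phylokit.alignment import (Alignment, compress_patterns, default_scheme,
                                parse_fasta, parse_partition_file)
from phylokit.likelihood import (AUTO, NO_SCALING, PER_NODE, PER_SITE,
                                 LikelihoodError, TreeLikelihood,
                                 UnderflowError, pair_log_likelihood)
from phylokit.models import PartitionModel
from phylokit.simulate import SimulationSpec, random_instance, simulate_alignment
from phylokit.states import get_type
from phylokit.tree import FULL, Tree, parse_newick, random_tree


def _random_dna_paln(rng, names, n_sites, spec="GTR+G", gap_rate=0.0):
    rows = []
    for _ in names:
        seq = rng.choice(list("ACGT"), size=n_sites)
        if gap_rate:
            mask = rng.random(n_sites) < gap_rate
            seq = np.where(mask, "-", seq)
        rows.append("".join(seq))
    aln = Alignment(list(names), rows)
    return compress_patterns(aln, default_scheme(aln, spec))


class TestUpdateCLV:
    def test_gap_children_give_unit_clv(self, rng):
        names = ["a", "b", "c", "d"]
        aln = Alignment(names, ["----", "----", "ACGT", "ACGT"])
        paln = compress_patterns(aln, default_scheme(aln, "GTR"))
        tree = parse_newick("((a:0.2,b:0.3):0.1,c:0.2,d:0.4);")
        tl = TreeLikelihood(tree, paln)
        # root on the central edge so the a,b node's children are the
        # two all-gap tips
        central = next(e for e in tree.edges
                       if not tree.edge_records(e)[0].is_tip
                       and not tree.edge_records(e)[1].is_tip)
        tl.evaluate(central, mode=FULL)
        ab_parent = tree.tips["a"].back.node_id
        clv = tl.parts[0].clvs[ab_parent]
        assert clv == pytest.approx(np.ones_like(clv))

    def test_matches_naive_double_loop(self, rng):
        """Vectorised pruning step equals the direct nested-loop formula."""
        m = PartitionModel.from_spec("GTR+G")
        m.subst.set_frequencies(rng.dirichlet(np.ones(4) * 3))
        p_l = m.subst.transition_matrices(0.37, m.category_rates())
        p_r = m.subst.transition_matrices(0.91, m.category_rates())
        clv_l = rng.random((4, 7, 4))
        clv_r = rng.random((4, 7, 4))
        res = np.matmul(clv_l, np.swapaxes(p_l, 1, 2)) * \
            np.matmul(clv_r, np.swapaxes(p_r, 1, 2))
        naive = np.zeros_like(res)
        for j in range(4):
            for s in range(7):
                for x in range(4):
                    left = sum(p_l[j, x, y] * clv_l[j, s, y] for y in range(4))
                    right = sum(p_r[j, x, z] * clv_r[j, s, z] for z in range(4))
                    naive[j, s, x] = left * right
        assert res == pytest.approx(naive, abs=1e-14)


class TestClosedForms:
    def test_two_taxon_jc_single_site(self):
        dt = get_type("DNA")
        m = PartitionModel.from_spec("JC")
        enc = lambda s: np.array([dt.tip_vectors[c] for c in s])
        for t in (0.05, 0.3, 1.7):
            got = pair_log_likelihood(m, enc("A"), enc("A"), np.ones(1), t)
            expect = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3)))
            assert got == pytest.approx(expect, abs=1e-12)
            got_diff = pair_log_likelihood(m, enc("A"), enc("C"), np.ones(1), t)
            expect_diff = np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3)))
            assert got_diff == pytest.approx(expect_diff, abs=1e-12)

    def test_all_gap_column_logl_zero(self):
        aln = Alignment(["a", "b", "c"], ["A-", "A-", "A-"])
        paln = compress_patterns(aln, default_scheme(aln, "JC"))
        tree = parse_newick("(a:0.1,b:0.1,c:0.1);")
        res = TreeLikelihood(tree, paln).evaluate(min(tree.edges))
        site = res.site_log_likelihoods()
        assert site[1] == pytest.approx(0.0, abs=1e-12)


class TestExhaustiveOracle:
    @pytest.mark.parametrize("spec,chars,n_taxa", [
        ("GTR+G", "ACGT", 5),
        ("HKY", "ACGTRYN-", 6),
        ("JC+G", "ACGT", 6),
        ("WAG+G", "ARNDCQEGHILKX-", 4),
        ("BIN", "01-?", 6),
    ])
    def test_pruning_equals_enumeration(self, rng, spec, chars, n_taxa):
        names = [f"t{i}" for i in range(n_taxa)]
        tree = random_tree(names, int(rng.integers(1000)))
        rows = ["".join(rng.choice(list(chars), size=8)) for _ in names]
        aln = Alignment(names, rows)
        paln = compress_patterns(aln, default_scheme(aln, spec))
        tl = TreeLikelihood(tree, paln)
        got = tl.evaluate(min(tree.edges)).total
        assert got == pytest.approx(brute_force_logl(tl), abs=1e-10)

    def test_psr_matches_enumeration(self, rng):
        names = [f"t{i}" for i in range(5)]
        tree = random_tree(names, 77)
        paln = _random_dna_paln(rng, names, 12, "HKY+PSR")
        tl = TreeLikelihood(tree, paln)
        tl.assign_psr_categories(0, min(tree.edges))
        got = tl.evaluate(min(tree.edges)).total
        assert got == pytest.approx(brute_force_logl(tl), abs=1e-10)


class TestVirtualRoot:
    def test_pulley_principle(self, rng):
        """Full-traversal logL is identical for every root edge."""
        inst = random_instance(7, 60, "GTR+G", seed=5)
        tl = TreeLikelihood(inst.tree, inst.pattern_alignment,
                            models=[inst.true_model])
        values = [tl.evaluate(e, mode=FULL).total
                  for e in sorted(inst.tree.edges)]
        assert np.ptp(values) < 1e-8

    def test_partial_equals_full_after_root_moves(self, rng):
        inst = random_instance(9, 80, "GTR+G", seed=6)
        tl = TreeLikelihood(inst.tree, inst.pattern_alignment,
                            models=[inst.true_model])
        edges = sorted(inst.tree.edges)
        ref = tl.evaluate(edges[0], mode=FULL).total
        for _ in range(25):
            e = edges[rng.integers(len(edges))]
            got = tl.evaluate(e, mode=AUTO).total
            assert got == pytest.approx(ref, abs=1e-8)

    def test_full_after_model_change_forced(self):
        inst = random_instance(6, 50, "GTR+G", seed=8)
        tl = TreeLikelihood(inst.tree, inst.pattern_alignment,
                            models=[inst.true_model])
        e = min(inst.tree.edges)
        before = tl.evaluate(e).total
        inst.true_model.het.set_alpha(inst.true_model.het.alpha * 2)
        after = tl.evaluate(e, mode=AUTO).total  # AUTO must go FULL
        fresh = TreeLikelihood(inst.tree, inst.pattern_alignment,
                               models=[inst.true_model]).evaluate(e, FULL).total
        assert after == pytest.approx(fresh, abs=1e-10)
        assert after != pytest.approx(before, abs=1e-6)


class TestScaling:
    def _chain_tree(self, n, branch=0.3):
        names = [f"s{i}" for i in range(n)]
        t = Tree()
        base = t.new_inner()
        t.connect(base, t.new_tip(names[0]), branch)
        t.connect(base.nxt, t.new_tip(names[1]), branch)
        prev = base.nxt.nxt
        for nm in names[2:-1]:
            mid = t.new_inner()
            t.connect(prev, mid, branch)
            t.connect(mid.nxt, t.new_tip(nm), branch)
            prev = mid.nxt.nxt
        t.connect(prev, t.new_tip(names[-1]), branch)
        t.validate()
        return t

    def test_three_modes_agree_when_no_underflow(self, rng):
        inst = random_instance(8, 60, "GTR+G", seed=9)
        vals = {}
        for mode in (PER_SITE, PER_NODE, NO_SCALING):
            tl = TreeLikelihood(inst.tree, inst.pattern_alignment,
                                models=[inst.true_model], scaling=mode)
            vals[mode] = tl.evaluate(min(inst.tree.edges)).total
        assert vals[PER_SITE] == pytest.approx(vals[NO_SCALING], abs=1e-8)
        assert vals[PER_SITE] == pytest.approx(vals[PER_NODE], abs=1e-8)

    def test_deep_chain_requires_scaling(self):
        tree = self._chain_tree(600)
        m = PartitionModel.from_spec("JC")
        sim = simulate_alignment(SimulationSpec(tree, [m], [6], seed=4))
        paln = compress_patterns(sim.alignment, sim.scheme)
        scaled = {}
        for mode in (PER_SITE, PER_NODE):
            tl = TreeLikelihood(tree, paln, scaling=mode)
            res = tl.evaluate(min(tree.edges))
            assert np.isfinite(res.total)
            assert res.scaling_events > 0
            scaled[mode] = res.total
        assert scaled[PER_SITE] == pytest.approx(scaled[PER_NODE], abs=1e-8)
        with pytest.raises(UnderflowError):
            TreeLikelihood(tree, paln, scaling=NO_SCALING).evaluate(
                min(tree.edges))


class TestAscertainment:
    def test_two_taxon_closed_form_via_triplet(self):
        """With one gap taxon and a near-zero branch, the three-taxon
        likelihood collapses to the two-sequence JC formula; check the
        corrected variable-site likelihood against hand computation."""
        t = 0.4
        aln = Alignment(["a", "b", "c"], ["A", "C", "-"])
        paln = compress_patterns(
            aln, parse_partition_file("JC+ASC, p1 = 1-1", 1))
        tree = parse_newick(f"(a:{t},b:1e-8,c:1e-8);")
        res = TreeLikelihood(tree, paln).evaluate(min(tree.edges))
        e = np.exp(-4 * t / 3)
        l_ac = 0.25 * (0.25 - 0.25 * e)
        v = 4 * 0.25 * (0.25 + 0.75 * e)
        expect = np.log(l_ac) - np.log(1 - v)
        assert res.total == pytest.approx(expect, abs=1e-6)
        assert res.asc_probs[0] == pytest.approx(v, abs=1e-6)

    def test_matches_enumeration(self, rng):
        names = [f"t{i}" for i in range(5)]
        tree = random_tree(names, 13)
        # variable-sites-only data
        rows = None
        while rows is None:
            cand = rng.choice(list("ACGT"), size=(5, 10))
            if all(len(set(cand[:, s])) > 1 for s in range(10)):
                rows = ["".join(cand[:, s][i] for s in range(10))
                        for i in range(5)]
        aln = Alignment(names, ["".join(r) for r in
                                (np.array(list(map(list, rows))))])
        paln = compress_patterns(
            aln, parse_partition_file("GTR+G+ASC, p1 = 1-10", 10))
        tl = TreeLikelihood(tree, paln)
        got = tl.evaluate(min(tree.edges)).total
        assert got == pytest.approx(brute_force_logl(tl), abs=1e-10)

    def test_constant_column_rejected(self):
        aln = Alignment(["a", "b", "c", "d"], ["AA", "AC", "AG", "AT"])
        with pytest.raises(LikelihoodError, match="constant"):
            TreeLikelihood(
                random_tree(["a", "b", "c", "d"], 0),
                compress_patterns(aln,
                                  parse_partition_file("JC+ASC, p1 = 1-2", 2)))

    def test_correction_increases_site_logl(self, rng):
        names = [f"t{i}" for i in range(4)]
        tree = random_tree(names, 3)
        aln = Alignment(names, ["AC", "CA", "GG", "TT"])
        base = compress_patterns(aln, default_scheme(aln, "JC"))
        corr = compress_patterns(
            aln, parse_partition_file("JC+ASC, p1 = 1-2", 2))
        r0 = TreeLikelihood(tree, base).evaluate(min(tree.edges))
        r1 = TreeLikelihood(tree, corr).evaluate(min(tree.edges))
        assert np.all(r1.pattern_logl[0] > r0.pattern_logl[0])

    def test_degenerate_star_flagged(self):
        aln = Alignment(["a", "b", "c"], ["A", "C", "G"])
        paln = compress_patterns(
            aln, parse_partition_file("JC+ASC, p1 = 1-1", 1))
        tree = parse_newick("(a:1e-8,b:1e-8,c:1e-8);")
        with pytest.raises(LikelihoodError, match="degenerate"):
            TreeLikelihood(tree, paln).evaluate(min(tree.edges))


class TestSiteLogLikelihoods:
    def test_identical_columns_equal_values(self):
        aln = Alignment(["a", "b", "c"], ["AAA", "AAA", "CCC"])
        paln = compress_patterns(aln, default_scheme(aln, "JC"))
        tree = parse_newick("(a:0.1,b:0.1,c:0.4);")
        res = TreeLikelihood(tree, paln).evaluate(min(tree.edges))
        site = res.site_log_likelihoods()
        assert site[0] == site[1] == site[2]
        assert res.weights[0] @ res.pattern_logl[0] == pytest.approx(
            res.total, abs=1e-10)

    def test_sum_matches_total_random(self, rng):
        inst = random_instance(6, 40, "GTR+G", seed=17)
        tl = TreeLikelihood(inst.tree, inst.pattern_alignment,
                            models=[inst.true_model])
        res = tl.evaluate(min(inst.tree.edges))
        assert res.site_log_likelihoods().sum() == pytest.approx(
            res.total, abs=1e-10)


class TestAncestralStates:
    def test_uniform_tips_argmax(self):
        names = ["a", "b", "c", "d"]
        aln = Alignment(names, ["AAAA"] * 4)
        paln = compress_patterns(aln, default_scheme(aln, "JC"))
        tree = parse_newick("((a:0.05,b:0.05):0.05,c:0.05,d:0.05);")
        tl = TreeLikelihood(tree, paln)
        for nid in tree.inner:
            post = tl.ancestral_states(nid)
            assert post.shape == (1, 4)
            assert post.sum(axis=1) == pytest.approx(1.0)
            assert np.argmax(post[0]) == 0  # state A

    def test_matches_brute_force_posterior(self, rng):
        """Marginal posterior at one inner node of a quartet equals the
        explicit sum over the other inner node's states."""
        names = ["a", "b", "c", "d"]
        tree = parse_newick("((a:0.2,b:0.4):0.3,c:0.5,d:0.15);")
        aln = Alignment(names, ["ACGTA", "AGGTC", "ACTTA", "GCGTA"])
        paln = compress_patterns(aln, default_scheme(aln, "HKY+G"))
        tl = TreeLikelihood(tree, paln)
        nid = tree.tips["a"].back.node_id
        other = next(n for n in tree.inner if n != nid)
        post = tl.ancestral_states(nid)

        m = tl.models[0]
        sub = m.subst
        dt = m.dtype
        rates, cw = m.category_rates(), m.category_weights()
        pp = tl.paln.parts[0]
        expect = np.zeros_like(post)
        for p, col in enumerate(pp.patterns):
            chars = dict(zip(paln.taxon_names, col))
            for j, rj in enumerate(rates):
                pm = {e: sub.transition_matrix(tree.edges[e].length, rj)
                      for e in tree.edges}
                for x in range(4):
                    for y in range(4):
                        val = sub.freqs[x] * cw[j]
                        for rec in tree.inner_records(nid):
                            nb = rec.back
                            if nb.is_tip:
                                val *= dt.tip_vectors[chars[nb.label]] @ \
                                    pm[rec.edge_id][x]
                        # the three neighbours: two tips + the other inner
                        inner_rec = next(r for r in tree.inner_records(nid)
                                         if not r.back.is_tip)
                        val *= pm[inner_rec.edge_id][x, y]
                        for rec in tree.inner_records(other):
                            nb = rec.back
                            if nb.is_tip:
                                val *= dt.tip_vectors[chars[nb.label]] @ \
                                    pm[rec.edge_id][y]
                        expect[p, x] += val
        expect /= expect.sum(axis=1, keepdims=True)
        assert post == pytest.approx(expect, abs=1e-10)

    def test_tip_rejected(self):
        inst = random_instance(5, 20, "JC", seed=1)
        tl = TreeLikelihood(inst.tree, inst.pattern_alignment,
                            models=[inst.true_model])
        with pytest.raises(LikelihoodError):
            tl.ancestral_states(inst.tree.tips["t1"].node_id)


class TestPSR:
    def test_single_category_trivial(self, rng):
        names = [f"t{i}" for i in range(5)]
        tree = random_tree(names, 2)
        paln = _random_dna_paln(rng, names, 20, "HKY+PSR1")
        tl = TreeLikelihood(tree, paln)
        assign = tl.assign_psr_categories(0, min(tree.edges))
        assert np.all(assign == 0)
        assert tl.models[0].het.rates() == pytest.approx([1.0])

    def test_duplicate_columns_same_category(self, rng):
        names = [f"t{i}" for i in range(5)]
        aln = Alignment(names, ["AACA", "AACA", "CCGC", "CCGC", "AATA"])
        paln = compress_patterns(aln, default_scheme(aln, "JC+PSR"))
        tree = random_tree(names, 4)
        tl = TreeLikelihood(tree, paln)
        assign = tl.assign_psr_categories(0, min(tree.edges))
        # sites 1, 2 and 4 are the same column, hence the same pattern
        p2s = paln.parts[0].pattern_to_sites
        assert any(len(sites) == 3 for sites in p2s)

    def test_assignment_never_decreases_logl(self, rng):
        names = [f"t{i}" for i in range(6)]
        tree = random_tree(names, 19)
        paln = _random_dna_paln(rng, names, 60, "GTR+PSR")
        tl = TreeLikelihood(tree, paln)
        e = min(tree.edges)
        before = tl.evaluate(e).total
        tl.assign_psr_categories(0, e)
        after = tl.evaluate(e).total
        assert after >= before - 1e-9


class TestErrors:
    def test_taxon_mismatch_lists_difference(self):
        inst = random_instance(5, 20, "JC", seed=2)
        tree = random_tree(["t1", "t2", "t3", "t4", "x9"], 0)
        with pytest.raises(LikelihoodError, match="t5.*x9|x9.*t5"):
            TreeLikelihood(tree, inst.pattern_alignment)
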