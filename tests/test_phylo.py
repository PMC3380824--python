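"""Distance phylogenetics, pruning likelihood and topology testing."""

import math

import dendropy
import numpy as np
import pytest

from introgrescan.phylo import (
    SubstitutionModel,
    bootstrap_support,
    neighbor_joining,
    nj_tree,
    optimize_branch_lengths,
    p_distance_matrix,
    sh_test,
    tree_from_newick,
    tree_loglikelihood,
    tree_to_newick,
    _bipartitions,
)
from introgrescan.seqdata import HaplotypeAlignment, InputError

from conftest import random_alignment


def tree_distances(newick, taxa):
    """Patristic distances from a newick string (independent oracle via
    dendropy's path-length machinery)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tn = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(tn[taxa[i]], tn[taxa[j]])
    return out


class TestPDistance:
    def test_examples(self):
        aln = HaplotypeAlignment("L", ["a", "b", "c"], ["ACGT", "ACGA", "AC-T"])
        d = p_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(0.25)
        assert d[0, 2] == pytest.approx(0.0)  # pairwise deletion: 3 columns
        assert d[1, 2] == pytest.approx(1 / 3)

    def test_no_comparable_columns_names_pair(self):
        aln = HaplotypeAlignment("L", ["a", "b"], ["A-", "-A"])
        with pytest.raises(InputError, match="'a'.*'b'"):
            p_distance_matrix(aln)


class TestNeighborJoining:
    def test_recovers_four_taxon_additive_tree(self):
        # distances computed by hand from ((A:1,B:2):1,(C:3,D:4))
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        d[3, 2] = d[2, 3] = 7
        d[3, 3] = 0
        tree = neighbor_joining(d, taxa)
        got = tree_distances(tree_to_newick(tree), taxa)
        assert np.allclose(got, d)
        # AB|CD is the split
        bps = set(_bipartitions(tree))
        assert frozenset({"C", "D"}) in bps or frozenset({"A", "B"}) in bps

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_recovers_random_additive_matrices(self, n_taxa, rng):
        # build a random tree by successive joins, read its patristic
        # distances, invert with NJ
        taxa = [f"t{i}" for i in range(n_taxa)]
        parts = list(taxa)
        while len(parts) > 2:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            a = parts.pop(j)
            b = parts.pop(i)
            la, lb = rng.uniform(0.1, 2.0, size=2)
            parts.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
        la = rng.uniform(0.1, 2.0)
        newick = f"({parts[0]}:{la:.4f},{parts[1]}:{rng.uniform(0.1, 2.0):.4f});"
        d = tree_distances(newick, taxa)
        nj = neighbor_joining(d, taxa)
        got = tree_distances(tree_to_newick(nj), taxa)
        assert np.allclose(got, d, atol=1e-8)

    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        got = tree_distances(tree_to_newick(tree), ["a", "b", "c"])
        assert np.allclose(got, d)

    def test_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        t1 = tree_to_newick(neighbor_joining(d, list("abcde")))
        t2 = tree_to_newick(neighbor_joining(d, list("abcde")))
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(InputError):
            neighbor_joining(d, list("abc"))


class TestBootstrap:
    def make_two_clade_alignment(self, rng):
        # 10 diagnostic sites per clade plus random noise
        n = 8
        noise = rng.choice(list("ACGT"), size=(n, 40))
        block = np.full((n, 20), "A")
        block[:4, :10] = "T"
        block[4:, 10:] = "G"
        mat = np.hstack([noise, block])
        return HaplotypeAlignment(
            "L", [f"h{i}" for i in range(n)], ["".join(r) for r in mat]
        )

    def test_planted_split_gets_high_support(self, rng):
        aln = self.make_two_clade_alignment(rng)
        tree = bootstrap_support(aln, n_reps=200, seed=3)
        bps = _bipartitions(tree)
        target = frozenset({"h4", "h5", "h6", "h7"})
        alt = frozenset({"h0", "h1", "h2", "h3"})
        node = bps.get(target) or bps.get(alt)
        assert node is not None
        assert float(node.label) >= 95

    def test_single_replicate_support_binary(self, rng):
        aln = random_alignment(rng, n=6, length=30)
        tree = bootstrap_support(aln, n_reps=1, seed=0)
        for bp, node in _bipartitions(tree).items():
            assert float(node.label) in (0.0, 100.0)

    def test_seed_reproducible(self, rng):
        aln = random_alignment(rng, n=6, length=30)
        t1 = tree_to_newick(bootstrap_support(aln, n_reps=50, seed=11))
        t2 = tree_to_newick(bootstrap_support(aln, n_reps=50, seed=11))
        assert t1 == t2


def jc_two_taxon_lnl(seq1, seq2, t):
    """Closed-form JC likelihood of two sequences at branch length t."""
    p_same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
    p_diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
    lnl = 0.0
    for a, b in zip(seq1, seq2):
        lnl += math.log(0.25 * (p_same if a == b else p_diff))
    return lnl


class TestLikelihood:
    def test_matches_jc_closed_form(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), size=60))
        s2 = "".join(rng.choice(list("ACGT"), size=60))
        aln = HaplotypeAlignment("L", ["a", "b"], [s1, s2])
        t = 0.3
        tree = tree_from_newick(f"(a:{t/2},b:{t/2});")
        lnl, per_site = tree_loglikelihood(aln, tree, SubstitutionModel.jc())
        assert lnl == pytest.approx(jc_two_taxon_lnl(s1, s2, t), abs=1e-10)
        assert per_site.sum() == pytest.approx(lnl, abs=1e-9)

    def test_zero_branch_conflicting_bases(self):
        aln = HaplotypeAlignment("L", ["a", "b"], ["A", "C"])
        tree = tree_from_newick("(a:0,b:0);")
        with pytest.warns(UserWarning):
            lnl, per_site = tree_loglikelihood(aln, tree, SubstitutionModel.jc())
        assert lnl == -math.inf

    def exhaustive_lnl(self, aln, tree, model):
        """Brute-force likelihood: sum over all internal-state assignments."""
        pi = np.asarray(model.base_frequencies)
        nodes = list(tree.postorder_node_iter())
        internals = [n for n in nodes if not n.is_leaf()]
        leaves = {n.taxon.label: n for n in nodes if n.is_leaf()}
        P = {}
        for n in nodes:
            if n.parent_node is not None:
                P[id(n)] = model.transition_matrices(n.edge.length)[0]
        row = {hid: i for i, hid in enumerate(aln.ids)}
        mat = aln.matrix()
        code = {b: i for i, b in enumerate("ACGT")}
        total = []
        for site in range(aln.length):
            lik = 0.0
            for states in np.ndindex(*(4,) * len(internals)):
                assign = {id(n): s for n, s in zip(internals, states)}
                term = pi[assign[id(tree.seed_node)]]
                ok = True
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    parent_state = assign[id(n.parent_node)]
                    if n.is_leaf():
                        obs = mat[row[n.taxon.label], site]
                        if obs not in code:
                            term *= 1.0
                            continue
                        term *= P[id(n)][parent_state, code[obs]]
                    else:
                        term *= P[id(n)][parent_state, assign[id(n)]]
                lik += term
            total.append(math.log(lik))
        return sum(total), np.array(total)

    def test_matches_exhaustive_state_sum(self, rng):
        aln = random_alignment(rng, n=4, length=20)
        tree = tree_from_newick("((h0:0.2,h1:0.4):0.15,(h2:0.3,h3:0.1):0.05);")
        model = SubstitutionModel(
            exchangeabilities=(1.2, 2.5, 0.8, 1.1, 3.0, 1.0),
            base_frequencies=(0.3, 0.2, 0.25, 0.25),
        )
        lnl, per_site = tree_loglikelihood(aln, tree, model)
        want, want_sites = self.exhaustive_lnl(aln, tree, model)
        assert lnl == pytest.approx(want, rel=1e-10)
        assert np.allclose(per_site, want_sites, rtol=1e-10)

    def test_invariant_to_rerooting(self, rng):
        aln = random_alignment(rng, n=5, length=40)
        tree = nj_tree(aln)
        model = SubstitutionModel.jc(alpha=0.5, p_inv=0.0)
        lnl1, _ = tree_loglikelihood(aln, tree, model)
        tree2 = tree.clone(depth=1)
        leaf = tree2.find_node_with_taxon_label("h0")
        half = leaf.edge.length / 2
        tree2.reroot_at_edge(leaf.edge, length1=half, length2=half,
                             update_bipartitions=False)
        lnl2, _ = tree_loglikelihood(aln, tree2, model)
        assert lnl1 == pytest.approx(lnl2, rel=1e-9)

    def test_gamma_and_pinv_mixture_direction(self, rng):
        # adding rate variation must change the likelihood smoothly and
        # the per-site vector must always sum to the total
        aln = random_alignment(rng, n=4, length=30)
        tree = nj_tree(aln)
        for model in (
            SubstitutionModel.jc(),
            SubstitutionModel.jc(alpha=0.3),
            SubstitutionModel.jc(p_inv=0.4, alpha=1.0),
        ):
            lnl, per_site = tree_loglikelihood(aln, tree, model)
            assert per_site.sum() == pytest.approx(lnl, abs=1e-8)


class TestOptimizeBranches:
    def test_lnl_non_decreasing_and_fixed_point(self, rng):
        aln = random_alignment(rng, n=4, length=60)
        tree = nj_tree(aln)
        model = SubstitutionModel.jc()
        before, _ = tree_loglikelihood(aln, tree, model)
        fitted = optimize_branch_lengths(aln, tree, model)
        after, _ = tree_loglikelihood(aln, fitted, model)
        assert after >= before - 1e-9
        again = optimize_branch_lengths(aln, fitted, model)
        final, _ = tree_loglikelihood(aln, again, model)
        assert final == pytest.approx(after, abs=1e-3)

    def test_recovers_simulated_lengths(self, rng):
        # two taxa at known divergence: ML p-distance inversion
        t_true = 0.2
        p_same = 0.25 + 0.75 * math.exp(-4 * t_true / 3)
        n = 2000
        same = rng.random(n) < p_same
        s1 = rng.choice(list("ACGT"), size=n)
        s2 = s1.copy()
        for i in np.where(~same)[0]:
            s2[i] = rng.choice([b for b in "ACGT" if b != s1[i]])
        aln = HaplotypeAlignment("L", ["a", "b"], ["".join(s1), "".join(s2)])
        tree = tree_from_newick("(a:0.05,b:0.05);")
        fitted = optimize_branch_lengths(aln, tree, SubstitutionModel.jc())
        total = sum(
            nd.edge.length for nd in fitted.preorder_node_iter()
            if nd.parent_node is not None
        )
        assert abs(total - t_true) / t_true < 0.2


class TestSHTest:
    def test_best_tree_p_one(self, rng):
        aln = random_alignment(rng, n=5, length=60)
        t1 = nj_tree(aln)
        t2 = tree_from_newick("((h0:0.1,h2:0.1):0.1,(h1:0.1,h3:0.1):0.1,h4:0.1);")
        res = sh_test(aln, [t1, t2], SubstitutionModel.jc(), n_resamples=200, seed=4)
        assert res.deltas[res.best_index] == 0
        assert res.p_values[res.best_index] == 1.0
        assert np.all(res.p_values > 0)
        # monotone: larger delta cannot get larger p
        order = np.argsort(res.deltas)
        assert np.all(np.diff(res.p_values[order]) <= 1e-12)

    def test_requires_two_topologies(self, rng):
        aln = random_alignment(rng, n=4, length=20)
        with pytest.raises(InputError):
            sh_test(aln, [nj_tree(aln)], SubstitutionModel.jc())


class TestNewick:
    def test_roundtrip_topology_and_lengths(self, rng):
        aln = random_alignment(rng, n=6, length=40)
        tree = nj_tree(aln)
        back = tree_from_newick(tree_to_newick(tree))
        assert set(_bipartitions(back)) == set(_bipartitions(tree))
        d1 = tree_distances(tree_to_newick(tree), list(aln.ids))
        d2 = tree_distances(tree_to_newick(back), list(aln.ids))
        assert np.allclose(d1, d2)
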